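"""End-to-end pipeline with a YAML run configuration and manifest.

``run_pipeline`` chains preprocess -> CMA -> selection -> motifs ->
classification -> tree annotation, writes every stage product under
the configured output directory, and returns a manifest (tool version,
config hash, input checksums, per-stage counts).  Reruns with
identical inputs and configuration produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cma import (
    DEFAULT_EDGE_THRESHOLD,
    DEFAULT_H_MIN,
    DEFAULT_MIN_PAIRS,
    DEFAULT_MIN_PARTNERS,
    DEFAULT_STRONG_THRESHOLD,
    build_network,
    cma_matrix,
    henikoff_weights,
    select_positions,
    write_edges_tsv,
    write_matrix_tsv,
    write_selection_tsv,
)
from .errors import ConfigError, DimensionError
from .family_io import build_numbering_map, read_alignment, read_tree, write_alignment
from .fingerprints import (
    DEFAULT_ACCEPT_THRESHOLD,
    SubgroupPartition,
    classify_sequence,
    extract_motifs,
    load_fingerprint_table,
)
from .preprocess import curate
from .tree_annotation import (
    DEFAULT_HOMOGENEITY,
    DEFAULT_MIN_CLADE_SIZE,
    assign_subgroups,
    export_itol_rings,
)

log = logging.getLogger("specmap")


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the standard thresholds.

    Unknown keys in the YAML are rejected before any work is done.
    """

    alignment: str
    out_dir: str
    format: str = "fasta"
    tree: str | None = None
    reference_id: str | None = None
    partition: str | None = None
    fingerprint_table: str | None = None
    keep_list: str | None = None
    identity_threshold: float | None = 0.90
    max_gap_frac: float = 0.95
    catalytic_column: int | None = None
    allowed_residues: str = "DE"
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD
    strong_threshold: float = DEFAULT_STRONG_THRESHOLD
    min_partners: int = DEFAULT_MIN_PARTNERS
    min_pairs: int = DEFAULT_MIN_PAIRS
    h_min: float = DEFAULT_H_MIN
    accept_threshold: float = DEFAULT_ACCEPT_THRESHOLD
    min_clade_size: int = DEFAULT_MIN_CLADE_SIZE
    homogeneity: float = DEFAULT_HOMOGENEITY
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"alignment", "out_dir"} - set(raw)
        if missing:
            raise ConfigError(f"missing required config keys: {sorted(missing)}")
        return cls(**raw)

    def canonical(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "specmap",
        "version": __version__,
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "inputs": {"alignment": _sha256(config.alignment)},
        "stages": {},
    }
    if config.tree:
        manifest["inputs"]["tree"] = _sha256(config.tree)

    stage = "preprocess"
    try:
        aln = read_alignment(config.alignment, config.format)
        keep = None
        if config.keep_list:
            keep = {l.strip() for l in Path(config.keep_list).read_text().splitlines() if l.strip()}
        aln, reports, removed_cols = curate(
            aln,
            identity_threshold=config.identity_threshold,
            max_gap_frac=config.max_gap_frac,
            catalytic_column=config.catalytic_column,
            allowed_residues=frozenset(config.allowed_residues),
            keep_list=keep,
        )
        write_alignment(aln, out / "curated.fasta", "fasta")
        manifest["stages"][stage] = {
            "n_sequences": aln.n_sequences,
            "n_columns": aln.n_columns,
            "n_columns_removed": len(removed_cols),
            **{f"n_removed_{r.stage}": r.n_removed for r in reports},
        }

        stage = "cma"
        numbering = (
            build_numbering_map(aln, config.reference_id)
            if config.reference_id
            else None
        )
        w = henikoff_weights(aln)
        cr = cma_matrix(
            aln, w, numbering=numbering,
            min_pairs=config.min_pairs, h_min=config.h_min,
        )
        write_matrix_tsv(cr, out / "cma_matrix.tsv")
        net = build_network(cr, config.edge_threshold)
        write_edges_tsv(net, out / "cma_edges.tsv", cr)
        manifest["stages"][stage] = {
            "n_network_positions": cr.n_positions_above(config.edge_threshold),
            "n_edges": len(net.edges),
        }

        stage = "select"
        sel = select_positions(net, cr, config.strong_threshold, config.min_partners)
        write_selection_tsv(sel, out / "selected_positions.tsv")
        manifest["stages"][stage] = {
            "n_selected": len(sel.positions),
            "positions": sel.positions,
        }

        stage = "subgroups"
        if config.partition:
            part = SubgroupPartition.from_tsv(config.partition)
        elif config.tree:
            tree = read_tree(config.tree)
            part = assign_subgroups(
                tree, aln, sel, config.min_clade_size, config.homogeneity
            )
        else:
            part = None
        if part is not None:
            part.to_tsv(out / "subgroups.tsv")
            manifest["stages"][stage] = {
                "n_subgroups": len([g for g in part.subgroup_ids() if g != "0"])
            }

        stage = "motifs"
        predictions = []
        if part is not None and sel.positions:
            motifs = extract_motifs(aln, part, sel, w)
            table = load_fingerprint_table(config.fingerprint_table)
            with open(out / "motifs.tsv", "w") as fh:
                fh.write("subgroup_id\tconsensus\n")
                for mot in motifs:
                    fh.write(f"{mot.subgroup_id}\t{mot.consensus}\n")
            stage = "classify"
            with open(out / "predictions.tsv", "w") as fh:
                fh.write("subgroup_id\tbest_label\tmatch_score\n")
                for mot in motifs:
                    # classify the subgroup's modal residue string
                    query = "".join(
                        str(mot.frequencies.loc[pos].idxmax())
                        for pos in mot.positions
                    )
                    try:
                        pred = classify_sequence(
                            query, table, config.accept_threshold, mot.subgroup_id
                        )
                    except DimensionError:
                        # reference motifs span a different number of
                        # positions than this run selected; skip quietly
                        continue
                    predictions.append(pred)
                    fh.write(
                        f"{pred.query_id}\t{pred.best_label}\t{pred.match_score:.4f}\n"
                    )
            manifest["stages"]["classify"] = {"n_classified": len(predictions)}

        stage = "annotate"
        if config.tree:
            tree = read_tree(config.tree)
            files = export_itol_rings(tree, aln, sel, out / "rings")
            manifest["stages"][stage] = {"n_ring_files": len(files)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
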