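"""Fingerprint motifs, sequence-logo matrices, and specificity prediction.

A subgroup's *fingerprint motif* is the concatenation of consensus
tokens at the selected (specificity-determining) positions: a single
residue where one residue dominates, a bracketed set like ``[MF]``
where two residues split the column, and the wildcard ``x`` where no
clear consensus exists.  Residue frequencies are sequence-weighted and
exclude gaps from the normalization; per-position information content
is Schneider-Stephens (log2 20 minus the column entropy, no
small-sample correction), as drawn in standard sequence logos.

Prediction against a reference motif table scores the fraction of
matched non-wildcard positions, so a motif like ``EEAPxx`` acts as a
four-position constraint.  A separate, cruder rule calls the reaction
mechanism (phosphorylase vs hydrolase) from the residues at
user-configured phosphate-binding positions; the package ships no
default position list because that knowledge is structural and must be
supplied explicitly.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DimensionError, LookupError_
from .family_io import AMINO_ACIDS, GAP, UNKNOWN, Alignment, NumberingMap
from .cma import SelectedPositions, SequenceWeights

MAX_BITS = math.log2(20)

SPECIFICITY_LABELS = (
    "MP", "TP", "T6PP", "KP", "NP", "GRP", "GGP", "oligoNP", "TH", "PGGHG",
    "unknown",
)

DEFAULT_ACCEPT_THRESHOLD = 0.8
# Consensus token rules (see consensus_token).
TOP_SINGLE = 0.5
SINGLE_MARGIN = 0.2
PAIR_EACH = 0.2
PAIR_JOINT = 0.7


def _data_path(name: str) -> Path:
    return Path(str(resources.files("specmap").joinpath("data", name)))


def load_specificity_table(path: str | Path | None = None) -> pd.DataFrame:
    """The packaged controlled vocabulary of characterized specificities."""
    path = path or _data_path("specificities.tsv")
    return pd.read_csv(path, sep="\t", dtype=str)


def load_fingerprint_table(path: str | Path | None = None) -> pd.DataFrame:
    """Reference motifs: columns specificity_label, motif_string."""
    path = path or _data_path("fingerprints.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for needed in ("specificity_label", "motif_string"):
        if needed not in df.columns:
            raise ConfigError(f"fingerprint table lacks column {needed!r}")
    return df


@dataclass
class SubgroupPartition:
    """Mapping sequence id -> subgroup id, with optional specificity labels.

    Subgroup ids are strings so dotted sub-labels like "10.1" pass
    through untouched.  Every sequence belongs to at most one subgroup.
    """

    assignments: dict[str, str]
    specificity: dict[str, str] = field(default_factory=dict)

    def subgroup_ids(self) -> list[str]:
        return sorted(set(self.assignments.values()), key=_subgroup_sort_key)

    def members(self, subgroup_id: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == subgroup_id]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sequence_id\tsubgroup_id\tspecificity_label\n")
            for sid in sorted(self.assignments):
                g = self.assignments[sid]
                fh.write(f"{sid}\t{g}\t{self.specificity.get(g, 'unknown')}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubgroupPartition":
        df = pd.read_csv(path, sep="\t", dtype=str)
        assignments = dict(zip(df["sequence_id"], df["subgroup_id"]))
        spec = {}
        if "specificity_label" in df.columns:
            for g, lab in zip(df["subgroup_id"], df["specificity_label"]):
                if isinstance(lab, str) and lab != "unknown":
                    spec[g] = lab
        return cls(assignments=assignments, specificity=spec)


def _subgroup_sort_key(g: str):
    try:
        return (0, tuple(int(p) for p in g.split(".")))
    except ValueError:
        return (1, (g,))


@dataclass
class FingerprintMotif:
    """Per-subgroup residue frequencies, information content, consensus."""

    subgroup_id: str
    positions: list[int]  # reference residue numbers (or columns)
    frequencies: pd.DataFrame  # index: positions, columns: 20 residues
    information: dict[int, float]  # bits per position
    tokens: list[str]

    @property
    def consensus(self) -> str:
        return "".join(self.tokens)


def consensus_token(
    freqs: dict[str, float] | pd.Series,
    top_single: float = TOP_SINGLE,
    single_margin: float = SINGLE_MARGIN,
    pair_each: float = PAIR_EACH,
    pair_joint: float = PAIR_JOINT,
) -> str:
    """Consensus token from a normalized residue-frequency vector.

    Single residue if its frequency is >= ``top_single`` and exceeds the
    runner-up by >= ``single_margin``; a bracketed pair ``[AB]`` if the
    top two each reach ``pair_each`` and jointly ``pair_joint``;
    otherwise the wildcard 'x'.  An all-zero vector (no coverage) also
    yields 'x'.
    """
    s = pd.Series(freqs, dtype=float)
    total = s.sum()
    if total == 0:
        return "x"
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"frequency vector must sum to 1, got {total}")
    # rank by frequency; exact ties fall back to descending alphabetical
    # order, which matches the conventional [MF]-style rendering
    ranked = sorted(s.items(), key=lambda kv: (-kv[1], [-ord(c) for c in kv[0]]))
    top = ranked[0][1]
    second = ranked[1][1] if len(ranked) > 1 else 0.0
    if top >= top_single and top - second >= single_margin:
        return str(ranked[0][0])
    if top >= pair_each and second >= pair_each and top + second >= pair_joint:
        return f"[{ranked[0][0]}{ranked[1][0]}]"
    return "x"


def extract_motifs(
    aln: Alignment,
    part: SubgroupPartition,
    sel: SelectedPositions,
    w: SequenceWeights | None = None,
    **token_kwargs,
) -> list[FingerprintMotif]:
    """Weighted per-subgroup residue frequencies and consensus motifs.

    Gaps and 'X' are excluded from normalization.  A subgroup with zero
    coverage at a position receives the wildcard token there.
    """
    wmap = (
        dict(zip(w.ids, w.values)) if w is not None else {sid: 1.0 for sid in aln.ids}
    )
    residues = list(AMINO_ACIDS)
    out = []
    for gid in part.subgroup_ids():
        members = [m for m in part.members(gid) if m in set(aln.ids)]
        if not members:
            raise LookupError_(f"subgroup {gid!r} has no members in the alignment")
        rows = {m: aln.row(m) for m in members}
        freq_rows, info, tokens = [], {}, []
        for pos, col in zip(sel.positions, sel.columns):
            counts = {r: 0.0 for r in residues}
            for m in members:
                ch = rows[m][col - 1]
                if ch in (GAP, UNKNOWN):
                    continue
                counts[ch] += wmap.get(m, 1.0)
            total = sum(counts.values())
            if total > 0:
                freqs = {r: c / total for r, c in counts.items()}
                h = -sum(p * math.log2(p) for p in freqs.values() if p > 0)
                info[pos] = MAX_BITS - h
            else:
                freqs = counts
                info[pos] = 0.0
            freq_rows.append(pd.Series(freqs, name=pos))
            tokens.append(consensus_token(freqs, **token_kwargs) if total > 0 else "x")
        out.append(
            FingerprintMotif(
                subgroup_id=gid,
                positions=list(sel.positions),
                frequencies=pd.DataFrame(freq_rows),
                information=info,
                tokens=tokens,
            )
        )
    return out


_TOKEN_RE = re.compile(r"\[([A-Z]+)\]|([A-Zx])")


def parse_motif(motif_string: str) -> list[str]:
    """Split a motif string like 'KV[MF]NES' into per-position tokens."""
    tokens = []
    pos = 0
    for m in _TOKEN_RE.finditer(motif_string):
        if m.start() != pos:
            raise ValueError(f"cannot parse motif {motif_string!r}")
        tokens.append(m.group(0))
        pos = m.end()
    if pos != len(motif_string):
        raise ValueError(f"cannot parse motif {motif_string!r}")
    return tokens


def _token_matches(token: str, residue: str) -> bool:
    if token == "x":
        return True
    if token.startswith("["):
        return residue in token[1:-1]
    return residue == token


@dataclass
class PredictionResult:
    query_id: str
    best_label: str
    match_score: float
    per_label: dict[str, float]
    per_position: list[tuple[str, str, bool]]  # (token, residue, matched)
    mechanism: str = "undetermined"


def classify_sequence(
    query_residues: str,
    reference: pd.DataFrame | None = None,
    accept_threshold: float = DEFAULT_ACCEPT_THRESHOLD,
    query_id: str = "query",
) -> PredictionResult:
    """Match a residue string at the selected positions against motifs.

    The match fraction counts matched non-wildcard positions over
    non-wildcard positions.  Labels whose motifs are entirely wildcards
    are excluded.  Ties for the best label, or a best fraction below
    ``accept_threshold``, yield "unknown".
    """
    if reference is None:
        reference = load_fingerprint_table()
    query = query_residues.upper()
    per_label: dict[str, float] = {}
    details: dict[str, list[tuple[str, str, bool]]] = {}
    for _, row in reference.iterrows():
        label, motif = row["specificity_label"], row["motif_string"]
        tokens = parse_motif(motif)
        if len(tokens) != len(query):
            raise DimensionError(
                f"query length {len(query)} != motif length {len(tokens)} "
                f"for label {label!r}"
            )
        informative = [t for t in tokens if t != "x"]
        det = [(t, q, _token_matches(t, q)) for t, q in zip(tokens, query)]
        details[label] = det
        if not informative:
            continue  # all-wildcard motif can never win
        matched = sum(ok for t, _, ok in det if t != "x")
        per_label[label] = matched / len(informative)
    if not per_label:
        return PredictionResult(query_id, "unknown", 0.0, {}, [])
    best = max(per_label.values())
    winners = sorted(lab for lab, v in per_label.items() if v == best)
    if len(winners) != 1 or best < accept_threshold:
        label = "unknown"
    else:
        label = winners[0]
    return PredictionResult(
        query_id=query_id,
        best_label=label,
        match_score=best,
        per_label=per_label,
        per_position=details.get(winners[0], []),
    )


def mechanism_call(
    full_sequence_row: str,
    phosphate_positions: list[int],
    phosphorylase_residues: dict[int, set[str]],
    numbering: NumberingMap | None = None,
) -> str:
    """Phosphorylase/hydrolase/undetermined from phosphate-binding residues.

    ``phosphate_positions`` are reference residue numbers when a
    numbering map is supplied, else 1-based alignment columns.
    Phosphorylase requires the configured residue set at *every*
    position; any deviation calls hydrolase; a gap at any configured
    position leaves the call undetermined.
    """
    if not phosphate_positions:
        raise ConfigError(
            "mechanism_call requires configured phosphate-binding positions; "
            "supply phosphate_positions and phosphorylase_residues"
        )
    row = full_sequence_row.upper()
    for pos in phosphate_positions:
        col = numbering.column(pos) if numbering is not None else pos
        if not 1 <= col <= len(row):
            raise IndexError(f"column {col} out of range for row of length {len(row)}")
        ch = row[col - 1]
        if ch == GAP:
            return "undetermined"
        allowed = {r.upper() for r in phosphorylase_residues.get(pos, set())}
        if not allowed:
            raise ConfigError(f"no phosphorylase residue set configured for {pos}")
        if ch not in allowed:
            return "hydrolase"
    return "phosphorylase"
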