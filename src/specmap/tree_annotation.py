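"""Subgroup assignment on the phylogeny and iTOL colored-ring export.

The automated subgroup heuristic is a reconstruction aid, not a
replacement for expert curation: a clade becomes a subgroup when it is
large enough and its members agree well at the selected positions.
User-supplied partitions (TSV) always take precedence in the pipeline.

Homogeneity of a clade is the mean, over the selected positions, of
the frequency of the modal residue among the clade's leaves (gaps and
'X' count against the modal residue).  This per-position definition
degrades gracefully with per-site noise, unlike exact residue-string
agreement which decays geometrically with the number of positions.

Ring export writes one iTOL COLORSTRIP dataset per selected position
(RasMol amino-acid colors, gap = neutral white), byte-stable for
identical inputs, with rings ordered inner to outer by ascending
reference position.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import dendropy

from .cma import SelectedPositions
from .colors import RASMOL_AMINO_HEX, residue_color
from .errors import LookupError_
from .family_io import Alignment, GAP
from .fingerprints import SubgroupPartition

DEFAULT_MIN_CLADE_SIZE = 5
DEFAULT_HOMOGENEITY = 0.9


def _clade_homogeneity(rows: list[str], columns: list[int]) -> float:
    per_pos = []
    for col in columns:
        chars = [r[col - 1] for r in rows]
        informative = [c for c in chars if c != GAP and c != "X"]
        if not informative:
            per_pos.append(0.0)
            continue
        modal = Counter(informative).most_common(1)[0][1]
        per_pos.append(modal / len(rows))
    return sum(per_pos) / len(per_pos)


def assign_subgroups(
    tree: dendropy.Tree,
    aln: Alignment,
    sel: SelectedPositions,
    min_clade_size: int = DEFAULT_MIN_CLADE_SIZE,
    homogeneity: float = DEFAULT_HOMOGENEITY,
) -> SubgroupPartition:
    """Partition tree leaves into subgroups of agreeing clades.

    Top-down traversal from the root: the first (largest) clade on each
    root-to-leaf path with >= ``min_clade_size`` leaves and homogeneity
    >= ``homogeneity`` at the selected positions becomes a subgroup;
    traversal does not descend into assigned clades.  Leaves never
    captured by a qualifying clade end up in subgroup "0" (unassigned).
    Subgroups are numbered "1", "2", ... in traversal order.
    """
    ids = set(aln.ids)
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in ids:
            raise LookupError_(f"tree leaf {leaf.taxon.label!r} missing from alignment")
    assignments: dict[str, str] = {
        leaf.taxon.label: "0" for leaf in tree.leaf_node_iter()
    }
    counter = 0
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        leaves = [l.taxon.label for l in node.leaf_iter()]
        if len(leaves) >= min_clade_size:
            rows = [aln.row(l) for l in leaves]
            if _clade_homogeneity(rows, sel.columns) >= homogeneity:
                counter += 1
                for l in leaves:
                    assignments[l] = str(counter)
                continue  # do not descend into an assigned clade
        stack.extend(reversed(node.child_nodes()))
    return SubgroupPartition(assignments=assignments)


_HEADER = """\
DATASET_COLORSTRIP
SEPARATOR COMMA
DATASET_LABEL,{label}
COLOR,#7f7f7f
COLOR_BRANCHES,0
STRIP_WIDTH,25
LEGEND_TITLE,RasMol amino-acid colors
LEGEND_SHAPES,{shapes}
LEGEND_COLORS,{colors}
LEGEND_LABELS,{labels}
DATA
"""


def _legend() -> tuple[str, str, str]:
    # one legend entry per distinct color group, deterministic order
    groups: dict[str, list[str]] = {}
    for aa in sorted(RASMOL_AMINO_HEX):
        groups.setdefault(RASMOL_AMINO_HEX[aa], []).append(aa)
    items = sorted(groups.items(), key=lambda kv: "".join(kv[1]))
    shapes = ",".join("1" for _ in items)
    colors = ",".join(c for c, _ in items)
    labels = ",".join("/".join(aas) for _, aas in items)
    return shapes, colors, labels


def export_itol_rings(
    tree: dendropy.Tree,
    aln: Alignment,
    sel: SelectedPositions,
    out_dir: str | Path,
) -> list[Path]:
    """One COLORSTRIP dataset file per selected position, inner to outer.

    Every tree leaf gets a line ``leaf_id,hex,residue``; the residue at
    the position is looked up in the alignment row of that leaf.
    Output is byte-stable given identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    for l in leaves:
        if l not in set(aln.ids):
            raise LookupError_(f"tree leaf {l!r} missing from alignment")
    shapes, colors, labels = _legend()
    files = []
    order = sorted(zip(sel.positions, sel.columns))
    for ring_index, (pos, col) in enumerate(order, start=1):
        path = out_dir / f"ring_{ring_index:02d}_pos{pos}.txt"
        lines = [_HEADER.format(label=pos, shapes=shapes, colors=colors, labels=labels)]
        for leaf in leaves:
            res = aln.row(leaf)[col - 1]
            lines.append(f"{leaf},{residue_color(res)},{res}\n")
        path.write_text("".join(lines))
        files.append(path)
    return files


def read_itol_ring(path: str | Path) -> dict[str, str]:
    """Residue-per-leaf mapping from a COLORSTRIP dataset (round trip)."""
    mapping = {}
    in_data = False
    for line in Path(path).read_text().splitlines():
        if line.strip() == "DATA":
            in_data = True
            continue
        if in_data and line.strip():
            leaf, _, res = line.split(",")
            mapping[leaf] = res
    return mapping
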