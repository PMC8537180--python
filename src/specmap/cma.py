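"""Correlated mutations analysis (CMA) over alignment columns.

The pairwise column statistic is weighted normalized mutual information,

    score(i, j) = MI(i, j) / min(H(i), H(j)),

computed in bits from Henikoff position-based sequence weights, with
pairwise-complete handling of missing data: rows carrying a gap or an
'X' at either column are excluded from the counts for that pair.  The
normalization bounds the score in [0, 1] — 1 for a perfect bijection
between the residues of the two columns, 0 for independence — and is
symmetric, which makes it a natural stand-in for correlation scores
produced by dedicated coevolution services.  Pairs with too few
remaining rows or with a near-constant column are masked (NaN) because
normalized MI is unstable at low counts and meaningless at zero
entropy.

Positions are then ranked by the two-stage rule used for
specificity-determining-position selection: keep positions with at
least one score strictly above ``strong_threshold`` *and* at least
``min_partners`` partners at or above the network edge threshold.

No average-product correction is applied by default; the statistic is
deliberately the plain normalized MI so that threshold semantics match
the documented definition.  ``column_pair_score`` accepts any score
callable via :func:`cma_matrix`'s ``statistic`` argument for variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from pathlib import Path

from .errors import DegenerateInputError
from .family_io import AMINO_ACIDS, Alignment, NumberingMap

_N_AA = len(AMINO_ACIDS)
_CODE = {aa: k for k, aa in enumerate(AMINO_ACIDS)}

DEFAULT_MIN_PAIRS = 20
DEFAULT_H_MIN = 0.1  # bits
DEFAULT_EDGE_THRESHOLD = 0.8
DEFAULT_STRONG_THRESHOLD = 0.9
DEFAULT_MIN_PARTNERS = 2


@dataclass(frozen=True)
class SequenceWeights:
    """Per-sequence weights, normalized to sum to the number of sequences."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if len(v) != len(self.ids):
            raise ValueError("one weight per sequence id required")
        if np.any(v <= 0):
            raise ValueError("all weights must be positive")
        if len(v) and abs(v.sum() - len(v)) > 1e-9:
            raise ValueError("weights must sum to the number of sequences")

    def weight(self, sequence_id: str) -> float:
        return float(self.values[self.ids.index(sequence_id)])


def encode_alignment(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes (0..19) and a missing mask (gap or X) per cell."""
    arr = aln.to_array()
    codes = np.zeros(arr.shape, dtype=np.int16)
    missing = np.ones(arr.shape, dtype=bool)
    for aa, k in _CODE.items():
        hit = arr == aa
        codes[hit] = k
        missing[hit] = False
    return codes, missing


def henikoff_weights(aln: Alignment) -> SequenceWeights:
    """Position-based sequence weights.

    At each column, a sequence carrying residue a among n_a like
    sequences out of k distinct residues contributes 1 / (k * n_a);
    gaps and 'X' contribute nothing.  Per-sequence sums are normalized
    so the weights total the number of sequences.  Identical sequences
    receive equal weight and the result is invariant under row
    permutation.
    """
    if aln.n_sequences == 0:
        raise DegenerateInputError("empty alignment")
    codes, missing = encode_alignment(aln)
    n, m = codes.shape
    raw = np.zeros(n)
    any_counted = False
    for j in range(m):
        col = codes[:, j]
        obs = ~missing[:, j]
        if not obs.any():
            continue
        counts = np.bincount(col[obs], minlength=_N_AA)
        k = int((counts > 0).sum())
        contrib = np.zeros(n)
        contrib[obs] = 1.0 / (k * counts[col[obs]])
        raw += contrib
        any_counted = True
    if not any_counted or raw.sum() == 0:
        raise DegenerateInputError("alignment has no non-gap columns")
    # rows that are all gap/X carry no information; give them the mean
    # raw weight so the positivity invariant holds
    if np.any(raw == 0):
        raw[raw == 0] = raw[raw > 0].mean()
    values = raw * (n / raw.sum())
    return SequenceWeights(ids=aln.ids, values=values)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _nmi_from_joint(joint: np.ndarray) -> tuple[float, float, float]:
    """(score, H_i, H_j) from a weighted joint count table."""
    p = joint / joint.sum()
    hi = _entropy(p.sum(axis=1))
    hj = _entropy(p.sum(axis=0))
    mi = hi + hj - _entropy(p.ravel())
    hmin = min(hi, hj)
    score = 0.0 if hmin == 0 else min(max(mi / hmin, 0.0), 1.0)
    return score, hi, hj


def column_pair_score(
    aln: Alignment,
    i: int,
    j: int,
    w: SequenceWeights,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    h_min: float = DEFAULT_H_MIN,
) -> float:
    """Weighted normalized MI of 1-based columns ``i`` and ``j``.

    Returns NaN (masked) when fewer than ``min_pairs`` rows remain
    after pairwise-complete exclusion, or when either column's weighted
    entropy falls below ``h_min`` bits.
    """
    if i == j:
        raise ValueError("column pair requires i != j")
    for c in (i, j):
        if not 1 <= c <= aln.n_columns:
            raise IndexError(f"column {c} out of range 1..{aln.n_columns}")
    codes, missing = encode_alignment(aln)
    return _pair_score(
        codes[:, i - 1], missing[:, i - 1], codes[:, j - 1], missing[:, j - 1],
        w.values, min_pairs, h_min,
    )


def _pair_score(ci, mi_, cj, mj, wv, min_pairs, h_min) -> float:
    valid = ~(mi_ | mj)
    if valid.sum() < min_pairs:
        return float("nan")
    joint = np.bincount(
        ci[valid] * _N_AA + cj[valid], weights=wv[valid], minlength=_N_AA * _N_AA
    ).reshape(_N_AA, _N_AA)
    score, hi, hj = _nmi_from_joint(joint)
    if min(hi, hj) < h_min:
        return float("nan")
    return score


@dataclass
class CorrelationResult:
    """Symmetric matrix of pairwise column correlation scores.

    ``scores`` is (n_columns, n_columns) with NaN on the diagonal and
    for masked pairs.  ``columns`` are the 1-based alignment columns;
    ``numbering`` (optional) translates them into reference residue
    numbers for display.
    """

    scores: np.ndarray
    columns: tuple[int, ...]
    numbering: NumberingMap | None = None

    def label(self, col: int) -> int:
        """Reference residue number for 1-based alignment column ``col``."""
        if self.numbering is not None:
            r = self.numbering.residue(col)
            if r is not None:
                return r
        return col

    def score(self, i: int, j: int) -> float:
        a, b = self.columns.index(i), self.columns.index(j)
        return float(self.scores[a, b])

    def max_scores(self) -> np.ndarray:
        """Per-column maximum defined score over all partners (NaN-safe)."""
        with np.errstate(all="ignore"):
            allnan = np.all(np.isnan(self.scores), axis=1)
            out = np.full(len(self.columns), np.nan)
            if (~allnan).any():
                out[~allnan] = np.nanmax(self.scores[~allnan], axis=1)
        return out

    def n_positions_above(self, threshold: float) -> int:
        """Number of columns with at least one pair score >= threshold."""
        mx = self.max_scores()
        return int(np.sum(mx >= threshold))


def cma_matrix(
    aln: Alignment,
    w: SequenceWeights,
    numbering: NumberingMap | None = None,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    h_min: float = DEFAULT_H_MIN,
    statistic: Callable[..., float] | None = None,
) -> CorrelationResult:
    """Score all unordered column pairs; symmetric by construction.

    ``statistic``, if given, replaces the built-in normalized-MI kernel;
    it is called as ``statistic(codes_i, missing_i, codes_j, missing_j,
    weights, min_pairs, h_min)`` and must return a float or NaN.
    """
    m = aln.n_columns
    codes, missing = encode_alignment(aln)
    wv = w.values
    kernel = statistic or _pair_score
    scores = np.full((m, m), np.nan)
    for a in range(m):
        ca, ma = codes[:, a], missing[:, a]
        for b in range(a + 1, m):
            s = kernel(ca, ma, codes[:, b], missing[:, b], wv, min_pairs, h_min)
            scores[a, b] = scores[b, a] = s
    return CorrelationResult(
        scores=scores, columns=tuple(range(1, m + 1)), numbering=numbering
    )


@dataclass
class CoevolutionNetwork:
    """Thresholded co-evolution network over alignment columns."""

    edge_threshold: float
    edges: list[tuple[int, int, float]]  # (col_i, col_j, score), i < j
    numbering: NumberingMap | None = None

    @property
    def nodes(self) -> list[int]:
        out = sorted({c for i, j, _ in self.edges for c in (i, j)})
        return out

    def degree(self, col: int) -> int:
        return sum(1 for i, j, _ in self.edges if col in (i, j))

    def degrees(self) -> dict[int, int]:
        return {n: self.degree(n) for n in self.nodes}


def build_network(
    cr: CorrelationResult, edge_threshold: float = DEFAULT_EDGE_THRESHOLD
) -> CoevolutionNetwork:
    """Edges are column pairs with a defined score >= ``edge_threshold``."""
    if not 0 < edge_threshold <= 1:
        raise ValueError(f"edge_threshold must be in (0, 1], got {edge_threshold}")
    m = len(cr.columns)
    edges = []
    for a in range(m):
        for b in range(a + 1, m):
            s = cr.scores[a, b]
            if np.isfinite(s) and s >= edge_threshold:
                edges.append((cr.columns[a], cr.columns[b], float(s)))
    return CoevolutionNetwork(
        edge_threshold=edge_threshold, edges=edges, numbering=cr.numbering
    )


@dataclass
class SelectedPositions:
    """Specificity-determining-position candidates, in ascending order.

    ``positions`` are reference residue numbers when a numbering map is
    attached, raw 1-based columns otherwise; ``columns`` always hold
    the alignment columns.  ``max_score`` and ``n_partners`` record the
    selection evidence per position.
    """

    positions: list[int]
    columns: list[int]
    max_score: dict[int, float] = field(default_factory=dict)
    n_partners: dict[int, int] = field(default_factory=dict)


def select_positions(
    net: CoevolutionNetwork,
    cr: CorrelationResult,
    strong_threshold: float = DEFAULT_STRONG_THRESHOLD,
    min_partners: int = DEFAULT_MIN_PARTNERS,
) -> SelectedPositions:
    """Two-stage rule: max score > strong_threshold and degree >= min_partners."""
    if strong_threshold < net.edge_threshold:
        raise ValueError(
            "strong_threshold must be >= the network edge threshold "
            f"({strong_threshold} < {net.edge_threshold})"
        )
    degrees = net.degrees()
    chosen: list[tuple[int, int]] = []  # (label, column)
    max_score: dict[int, float] = {}
    n_partners: dict[int, int] = {}
    for col in net.nodes:
        a = cr.columns.index(col)
        with np.errstate(all="ignore"):
            row = cr.scores[a]
            mx = float(np.nanmax(row)) if np.isfinite(row).any() else float("nan")
        if np.isfinite(mx) and mx > strong_threshold and degrees[col] >= min_partners:
            lab = cr.label(col)
            chosen.append((lab, col))
            max_score[lab] = mx
            n_partners[lab] = degrees[col]
    chosen.sort()
    return SelectedPositions(
        positions=[lab for lab, _ in chosen],
        columns=[col for _, col in chosen],
        max_score=max_score,
        n_partners=n_partners,
    )


# ---------------------------------------------------------------------------
# plain-text serialization (reference-numbered headers)
# ---------------------------------------------------------------------------

def write_matrix_tsv(cr: CorrelationResult, path: str | Path) -> None:
    """Square score matrix with reference-numbered row/column headers."""
    labels = [cr.label(c) for c in cr.columns]
    with open(path, "w") as fh:
        fh.write("position\t" + "\t".join(str(l) for l in labels) + "\n")
        for a, lab in enumerate(labels):
            cells = (
                "" if not np.isfinite(cr.scores[a, b]) else f"{cr.scores[a, b]:.6f}"
                for b in range(len(labels))
            )
            fh.write(str(lab) + "\t" + "\t".join(cells) + "\n")


def read_matrix_tsv(path: str | Path) -> CorrelationResult:
    """Inverse of :func:`write_matrix_tsv`; labels become the columns."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        labels = tuple(int(h) for h in header)
        m = len(labels)
        scores = np.full((m, m), np.nan)
        for a, line in enumerate(fh):
            cells = line.rstrip("\n").split("\t")[1:]
            for b, cell in enumerate(cells):
                if cell:
                    scores[a, b] = float(cell)
    return CorrelationResult(scores=scores, columns=labels, numbering=None)


def write_edges_tsv(net: CoevolutionNetwork, path: str | Path,
                    cr: CorrelationResult | None = None) -> None:
    def lab(c):
        return cr.label(c) if cr is not None else c
    with open(path, "w") as fh:
        fh.write("position_i\tposition_j\tscore\n")
        for i, j, s in sorted(net.edges):
            fh.write(f"{lab(i)}\t{lab(j)}\t{s:.6f}\n")


def write_selection_tsv(sel: SelectedPositions, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tcolumn\tmax_score\tn_partners\n")
        for pos, col in zip(sel.positions, sel.columns):
            fh.write(
                f"{pos}\t{col}\t{sel.max_score[pos]:.6f}\t{sel.n_partners[pos]}\n"
            )


def read_selection_tsv(path: str | Path) -> SelectedPositions:
    positions, columns, mx, deg = [], [], {}, {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            p, c, m, d = line.rstrip("\n").split("\t")
            positions.append(int(p))
            columns.append(int(c))
            mx[int(p)] = float(m)
            deg[int(p)] = int(d)
    return SelectedPositions(positions=positions, columns=columns,
                             max_score=mx, n_partners=deg)
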