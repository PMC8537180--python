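"""Family curation: redundancy reduction, catalytic-residue filtering, trimming.

Three desk-scale curation rules applied before any correlation analysis:

1. greedy redundancy reduction at a pairwise-identity threshold (with a
   keep-list of annotated representatives that are re-added even when
   redundant),
2. removal of sequences lacking the catalytic acid (by default D/E at a
   user-supplied alignment column), and
3. removal of alignment columns whose gap content reaches a threshold.

Pairwise identity is matches in a global alignment divided by the length
of the shorter sequence, the short-sequence convention of common
clustering tools.  The alignment scoring (match 1, mismatch 0, linear
gap -1) is fixed so results are bit-stable.  Clustering is exact greedy
longest-first with all-pairs comparison — no k-mer prefilter — which is
plenty for families of a few thousand members and keeps the behavior
easy to verify against a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .errors import DimensionError
from .family_io import GAP, Alignment

DEFAULT_CATALYTIC_RESIDUES = frozenset({"D", "E"})


@dataclass
class CurationReport:
    """Bookkeeping for one curation stage (counts must be consistent)."""

    stage: str
    n_input: int
    n_kept: int
    kept_ids: list[str] = field(default_factory=list)
    removed_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.n_input != self.n_kept + len(self.removed_ids):
            raise ValueError(
                f"inconsistent report: {self.n_input} != "
                f"{self.n_kept} + {len(self.removed_ids)}"
            )

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)


def _make_aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-1,
        extend_gap_score=-1,
    )


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity normalized by the shorter sequence."""
    if not a or not b:
        return 0.0
    if aligner is None:
        aligner = _make_aligner()
    best = aligner.align(a, b)[0]
    identities = best.counts().identities
    return identities / min(len(a), len(b))


def greedy_redundancy_filter(
    seqs: list[tuple[str, str]],
    identity_threshold: float = 0.90,
    keep_list: set[str] | None = None,
) -> tuple[list[tuple[str, str]], CurationReport]:
    """Greedy longest-first clustering; returns representatives.

    Sequences are processed by descending length (ties broken by id,
    lexicographically).  A sequence joins the first existing
    representative with pairwise identity strictly above the threshold,
    otherwise it founds a new cluster.  Members of ``keep_list`` are
    always present in the output, appended after the representatives if
    they were absorbed into a cluster.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    keep_list = keep_list or set()
    ids = [sid for sid, _ in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    if not seqs:
        return [], CurationReport(stage="redundancy", n_input=0, n_kept=0)

    aligner = _make_aligner()
    order = sorted(seqs, key=lambda it: (-len(it[1]), it[0]))
    reps: list[tuple[str, str]] = []
    absorbed: list[str] = []
    for sid, seq in order:
        for _, rep_seq in reps:
            if pairwise_identity(seq, rep_seq, aligner) > identity_threshold:
                absorbed.append(sid)
                break
        else:
            reps.append((sid, seq))

    by_id = dict(seqs)
    readded = [sid for sid in absorbed if sid in keep_list]
    out = reps + [(sid, by_id[sid]) for sid in readded]
    removed = [sid for sid in absorbed if sid not in keep_list]
    report = CurationReport(
        stage="redundancy",
        n_input=len(seqs),
        n_kept=len(out),
        kept_ids=[sid for sid, _ in out],
        removed_ids=removed,
    )
    return out, report


def trim_gap_columns(
    aln: Alignment, max_gap_frac: float = 0.95
) -> tuple[Alignment, list[int]]:
    """Remove columns whose gap fraction is >= ``max_gap_frac``.

    Only '-' counts as a gap; 'X' is a residue of unknown type.  Returns
    the trimmed alignment and the removed 1-based column indices.  The
    operation is idempotent.
    """
    if not 0 < max_gap_frac <= 1:
        raise ValueError(f"max_gap_frac must be in (0, 1], got {max_gap_frac}")
    if aln.n_sequences == 0 or aln.n_columns == 0:
        return aln, []
    n = aln.n_sequences
    removed = []
    kept = []
    for col in range(1, aln.n_columns + 1):
        gap_frac = aln.column(col).count(GAP) / n
        (removed if gap_frac >= max_gap_frac else kept).append(col)
    if not removed:
        return aln, []
    return aln.subset_columns(kept), removed


def filter_missing_catalytic(
    aln: Alignment,
    catalytic_column: int,
    allowed_residues: frozenset[str] | set[str] = DEFAULT_CATALYTIC_RESIDUES,
) -> tuple[Alignment, CurationReport]:
    """Drop rows lacking the catalytic acid at the given 1-based column."""
    if not 1 <= catalytic_column <= aln.n_columns:
        raise IndexError(
            f"catalytic column {catalytic_column} out of range 1..{aln.n_columns}"
        )
    allowed = {r.upper() for r in allowed_residues}
    kept_ids, removed_ids = [], []
    for sid, row in aln.records():
        (kept_ids if row[catalytic_column - 1] in allowed else removed_ids).append(sid)
    report = CurationReport(
        stage="catalytic",
        n_input=aln.n_sequences,
        n_kept=len(kept_ids),
        kept_ids=kept_ids,
        removed_ids=removed_ids,
    )
    return aln.subset_rows(kept_ids), report


def curate(
    aln: Alignment,
    identity_threshold: float | None = 0.90,
    max_gap_frac: float = 0.95,
    catalytic_column: int | None = None,
    allowed_residues: frozenset[str] | set[str] = DEFAULT_CATALYTIC_RESIDUES,
    keep_list: set[str] | None = None,
) -> tuple[Alignment, list[CurationReport], list[int]]:
    """Full curation pipeline: redundancy -> catalytic filter -> trim.

    Redundancy runs on degapped rows and the surviving rows are taken
    from the original alignment, so column structure is preserved.
    Either filter can be skipped by passing ``None``.
    """
    reports: list[CurationReport] = []
    if identity_threshold is not None:
        degapped = [(sid, row.replace(GAP, "")) for sid, row in aln.records()]
        kept, rep = greedy_redundancy_filter(degapped, identity_threshold, keep_list)
        reports.append(rep)
        aln = aln.subset_rows([sid for sid, _ in kept])
    if catalytic_column is not None:
        aln, rep = filter_missing_catalytic(aln, catalytic_column, allowed_residues)
        reports.append(rep)
    aln, removed_cols = trim_gap_columns(aln, max_gap_frac)
    return aln, reports, removed_cols
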