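"""Alignment, numbering-map, and tree input/output.

The central container is :class:`Alignment`, an immutable gapped protein
multiple sequence alignment.  All user-facing column indices are 1-based,
and downstream modules refer to columns through a :class:`NumberingMap`
that translates alignment columns into residue numbers of a designated
reference sequence — the convention used throughout enzyme-family work,
where positions are quoted in the numbering of a well-characterized
member rather than in raw alignment coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentFormatError, DimensionError, LookupError_

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = frozenset(AMINO_ACIDS) | {GAP, UNKNOWN}

_FORMATS = ("fasta", "stockholm")


@dataclass(frozen=True)
class Alignment:
    """A validated, gapped protein multiple sequence alignment.

    Rows are uppercase strings over the 20 amino acids plus ``X``
    (unknown residue, treated as missing data by downstream counting)
    and ``-`` (gap).  Sequence ids are unique; every row has the same
    length.  Description lines are carried along verbatim but never
    interpreted.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    descriptions: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise DimensionError("ids and rows must have equal length")
        if not self.descriptions:
            object.__setattr__(self, "descriptions", tuple("" for _ in self.ids))
        if len(set(self.ids)) != len(self.ids):
            seen, dup = set(), None
            for i in self.ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise AlignmentFormatError(f"duplicate sequence id: {dup!r}")
        rows = tuple(r.upper() for r in self.rows)
        object.__setattr__(self, "rows", rows)
        if rows:
            width = len(rows[0])
            for sid, row in zip(self.ids, rows):
                if len(row) != width:
                    raise DimensionError(
                        f"row {sid!r} has length {len(row)}, expected {width}"
                    )
                bad = set(row) - ALPHABET
                if bad:
                    raise AlignmentFormatError(
                        f"record {sid!r} contains invalid characters: "
                        f"{''.join(sorted(bad))}"
                    )

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, sequence_id: str) -> str:
        try:
            return self.rows[self.ids.index(sequence_id)]
        except ValueError:
            raise LookupError_(f"unknown sequence id: {sequence_id!r}") from None

    def column(self, col: int) -> str:
        """Characters of 1-based column ``col``, top to bottom."""
        if not 1 <= col <= self.n_columns:
            raise IndexError(f"column {col} out of range 1..{self.n_columns}")
        return "".join(r[col - 1] for r in self.rows)

    def to_array(self) -> np.ndarray:
        """(n_sequences, n_columns) array of single characters."""
        if not self.rows:
            return np.empty((0, 0), dtype="<U1")
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype="S1"
        ).reshape(self.n_sequences, self.n_columns).astype("<U1")

    def records(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.rows))

    def subset_rows(self, keep_ids: Iterable[str]) -> "Alignment":
        keep = set(keep_ids)
        idx = [i for i, sid in enumerate(self.ids) if sid in keep]
        return Alignment(
            ids=tuple(self.ids[i] for i in idx),
            rows=tuple(self.rows[i] for i in idx),
            descriptions=tuple(self.descriptions[i] for i in idx),
        )

    def subset_columns(self, keep_cols: Iterable[int]) -> "Alignment":
        """Keep the given 1-based columns, in ascending order."""
        cols = sorted(set(keep_cols))
        for c in cols:
            if not 1 <= c <= self.n_columns:
                raise IndexError(f"column {c} out of range 1..{self.n_columns}")
        return Alignment(
            ids=self.ids,
            rows=tuple("".join(r[c - 1] for c in cols) for r in self.rows),
            descriptions=self.descriptions,
        )


@dataclass(frozen=True)
class NumberingMap:
    """Map from 1-based alignment columns to reference residue numbers.

    The k-th non-gap character of the reference row maps its column to
    residue number k.  Columns where the reference row is gapped are
    unmapped, so the mapping is partial and strictly increasing.
    """

    reference_id: str
    column_to_residue: dict[int, int] = field(default_factory=dict)

    def residue(self, col: int) -> int | None:
        return self.column_to_residue.get(col)

    def column(self, residue_number: int) -> int:
        for c, r in self.column_to_residue.items():
            if r == residue_number:
                return c
        raise LookupError_(
            f"residue number {residue_number} not mapped for "
            f"reference {self.reference_id!r}"
        )


def build_numbering_map(aln: Alignment, reference_id: str) -> NumberingMap:
    """Derive reference numbering from the reference row of ``aln``."""
    ref_row = aln.row(reference_id)
    mapping: dict[int, int] = {}
    k = 0
    for col0, ch in enumerate(ref_row):
        if ch != GAP:
            k += 1
            mapping[col0 + 1] = k
    return NumberingMap(reference_id=reference_id, column_to_residue=mapping)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Stockholm file into an :class:`Alignment`.

    Ragged rows raise :class:`DimensionError`; parse failures raise
    :class:`AlignmentFormatError` naming the offending record where the
    underlying parser allows it.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        records = list(SeqIO.parse(str(path), format))
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    return Alignment(
        ids=tuple(r.id for r in records),
        rows=tuple(str(r.seq) for r in records),
        descriptions=tuple(r.description for r in records),
    )


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write ``aln`` so that :func:`read_alignment` recovers an equal object."""
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    path = Path(path)
    records = [
        SeqRecord(Seq(row), id=sid, description=desc)
        for sid, row, desc in zip(aln.ids, aln.rows, aln.descriptions)
    ]
    if format == "stockholm":
        # Stockholm requires at least the header even when empty.
        msa = MultipleSeqAlignment(records)
        with open(path, "w") as fh:
            if records:
                AlignIO.write(msa, fh, "stockholm")
            else:
                fh.write("# STOCKHOLM 1.0\n//\n")
    else:
        SeqIO.write(records, str(path), "fasta")


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree, preserving leaf names, branch lengths, supports."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise AlignmentFormatError(f"cannot parse Newick file {path}: {exc}") from exc
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(Path(path)), schema="newick", unquoted_underscores=True)


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]
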