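"""Multiple-sequence-alignment ingestion, gap-column filtering, reference map.

Internal coordinates are 0-based half-open; every user-facing report uses
1-based residue numbering on the ungapped reference sequence (so the
family 4 motif-1 doublet reports as 41-42 and the family 1 doublet as
63-64).  The only gap symbol is ``'-'``; ``'X'`` counts as a residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import AlignIO

from udgcoev.curation import SequenceRecord, _VALID_RESIDUES

GAP = "-"


class AlignmentError(ValueError):
    pass


class Alignment:
    """Equal-length aligned sequence rows with an optional reference member."""

    def __init__(
        self,
        records: Iterable[SequenceRecord],
        reference_id: Optional[str] = None,
    ) -> None:
        self.records: list[SequenceRecord] = list(records)
        if not self.records:
            raise AlignmentError("alignment has no rows")
        L = len(self.records[0].residues)
        ids = set()
        for rec in self.records:
            if len(rec.residues) != L:
                raise AlignmentError(
                    f"record {rec.id!r} has length {len(rec.residues)}, expected {L}"
                )
            if rec.id in ids:
                raise AlignmentError(f"duplicate row id {rec.id!r}")
            ids.add(rec.id)
        if reference_id is not None and reference_id not in ids:
            raise AlignmentError(f"reference_id {reference_id!r} is not a member")
        self.reference_id = reference_id

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    @property
    def shape(self) -> tuple[int, int]:
        return self.n_rows, self.n_columns

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)

    def to_character_matrix(self) -> np.ndarray:
        """(n_rows, n_columns) array of single characters."""
        return np.array([list(r.residues) for r in self.records])

    def column_gap_fractions(self) -> np.ndarray:
        mat = self.to_character_matrix()
        return (mat == GAP).mean(axis=0)

    def select_columns(self, columns: Iterable[int]) -> "Alignment":
        cols = list(columns)
        recs = [
            _aligned_record(rec.id, "".join(rec.residues[c] for c in cols), rec.description)
            for rec in self.records
        ]
        return Alignment(recs, reference_id=self.reference_id)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.id}" + (f" {rec.description}" if rec.description else "") + "\n")
                fh.write(rec.residues + "\n")


def _aligned_record(seq_id: str, residues: str, description: str = "") -> SequenceRecord:
    """SequenceRecord that tolerates the gap character."""
    bad = set(residues) - _VALID_RESIDUES - {GAP}
    if bad:
        raise AlignmentError(f"record {seq_id!r}: invalid alignment symbol(s) {sorted(bad)}")
    rec = object.__new__(SequenceRecord)
    object.__setattr__(rec, "id", seq_id)
    object.__setattr__(rec, "residues", residues)
    object.__setattr__(rec, "description", description)
    return rec


@dataclass
class ColumnMap:
    """Map from kept alignment columns to 1-based reference residue numbers.

    ``ref_numbers[k]`` is None where the reference row is gapped at kept
    column ``kept_columns[k]``; such columns stay in the analysis but are
    reported without a residue number.
    """

    kept_columns: list[int]
    ref_numbers: list[Optional[int]]
    ref_residues: list[Optional[str]]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.kept_columns, self.kept_columns[1:])):
            raise ValueError("kept_columns must be strictly increasing")
        nums = [n for n in self.ref_numbers if n is not None]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError("ref_numbers must be strictly increasing over non-gap entries")

    def ref_number_of(self, column: int) -> Optional[int]:
        return self.ref_numbers[self.kept_columns.index(column)]

    def column_of(self, ref_number: int) -> int:
        return self.kept_columns[self.ref_numbers.index(ref_number)]

    def restrict(self, columns: Iterable[int]) -> "ColumnMap":
        keep = [i for i, c in enumerate(self.kept_columns) if c in set(columns)]
        return ColumnMap(
            [self.kept_columns[i] for i in keep],
            [self.ref_numbers[i] for i in keep],
            [self.ref_residues[i] for i in keep],
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("alignment_column\tref_number\tref_residue\n")
            for c, n, r in zip(self.kept_columns, self.ref_numbers, self.ref_residues):
                fh.write(f"{c}\t{'' if n is None else n}\t{'' if r is None else r}\n")


def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Clustal file.

    Ragged rows raise :class:`AlignmentError` naming the offending record.
    """
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentError(f"{path}: {exc}") from exc
    recs = [
        _aligned_record(rec.id, str(rec.seq).upper().replace(".", GAP))
        for rec in msa
    ]
    return Alignment(recs)


def map_to_reference(aln: Alignment, ref_id: str) -> ColumnMap:
    """Number every alignment column on the ungapped reference sequence.

    Column i maps to the count of non-gap reference residues in columns
    0..i (1-based) when the reference is non-gap at i, else to None.
    """
    ref = aln.row(ref_id)
    kept, nums, resi = [], [], []
    counter = 0
    for i, ch in enumerate(ref.residues):
        kept.append(i)
        if ch != GAP:
            counter += 1
            nums.append(counter)
            resi.append(ch)
        else:
            nums.append(None)
            resi.append(None)
    return ColumnMap(kept, nums, resi)


def filter_gap_columns(
    aln: Alignment, max_gap_fraction: float = 0.3
) -> tuple[Alignment, ColumnMap]:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    Returns the filtered alignment and a :class:`ColumnMap` recording the
    surviving columns with their reference numbering (identity numbering
    when no reference is set).
    """
    if not (0 <= max_gap_fraction <= 1):
        raise ValueError("max_gap_fraction must lie in [0, 1]")
    fractions = aln.column_gap_fractions()
    keep = [i for i, f in enumerate(fractions) if f <= max_gap_fraction]
    if not keep:
        raise AlignmentError("all columns exceed the gap-fraction threshold")
    filtered = aln.select_columns(keep)
    if aln.reference_id is not None:
        full = map_to_reference(aln, aln.reference_id)
        cmap = ColumnMap(
            keep,
            [full.ref_numbers[c] for c in keep],
            [full.ref_residues[c] for c in keep],
        )
    else:
        cmap = ColumnMap(keep, [c + 1 for c in keep], [None] * len(keep))
    return filtered, cmap
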