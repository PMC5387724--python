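"""Family curation: motif classification, redundancy clustering, reference pick.

UDG families carry short diagnostic motifs (family 1 UNG: GQDPY; family 4
UDGa: GE[A/G][V/P]G).  Raw sequence collections are sorted into families by
exact motif presence, redundancy-reduced by greedy single-linkage clustering
on global-alignment identity (75% identity / 85% coverage by default), and a
per-family reference sequence is chosen as the representative of the largest
cluster that still resembles the family's canonical structure sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed (names the offending record)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence entry.

    ``residues`` is an upper-case string over the 20-residue alphabet;
    'X' (unknown residue) is tolerated and flagged via :attr:`has_ambiguous`.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaParseError("sequence record with empty id")
        if not self.residues:
            raise FastaParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)}"
            )

    @property
    def has_ambiguous(self) -> bool:
        return "X" in self.residues

    def __len__(self) -> int:
        return len(self.residues)


class SequenceSet:
    """Ordered collection of :class:`SequenceRecord` with unique ids."""

    def __init__(self, records: Iterable[SequenceRecord] = ()) -> None:
        self._records: list[SequenceRecord] = []
        self._index: dict[str, int] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SequenceRecord) -> None:
        if rec.id in self._index:
            raise FastaParseError(f"duplicate sequence id {rec.id!r}")
        self._index[rec.id] = len(self._records)
        self._records.append(rec)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records)

    def __getitem__(self, key: int | str) -> SequenceRecord:
        if isinstance(key, str):
            return self._records[self._index[key]]
        return self._records[key]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self._records]


@dataclass(frozen=True)
class MotifPattern:
    """Ordered list of allowed-residue sets, e.g. {G},{E},{A,G},{V,P},{G}."""

    family_label: str
    pattern: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.pattern) < 3:
            raise ValueError("motif pattern must have length >= 3")
        if any(not s for s in self.pattern):
            raise ValueError("motif pattern contains an empty residue set")

    @classmethod
    def from_string(cls, family_label: str, text: str) -> "MotifPattern":
        """Parse a compact motif string such as ``GE[AG][VP]G``."""
        sets: list[frozenset[str]] = []
        i = 0
        while i < len(text):
            if text[i] == "[":
                j = text.index("]", i)
                sets.append(frozenset(text[i + 1 : j]))
                i = j + 1
            else:
                sets.append(frozenset(text[i]))
                i += 1
        return cls(family_label, tuple(sets))

    def matches(self, residues: str) -> bool:
        """True iff some contiguous window of ``residues`` fits the pattern."""
        k = len(self.pattern)
        for start in range(len(residues) - k + 1):
            if all(residues[start + p] in self.pattern[p] for p in range(k)):
                return True
        return False

    def __len__(self) -> int:
        return len(self.pattern)


# Diagnostic motif-1 patterns of the two high-activity UDG families.
FAMILY1_MOTIF = MotifPattern.from_string("family1", "GQDPY")
FAMILY4_MOTIF = MotifPattern.from_string("family4", "GE[AG][VP]G")


@dataclass
class ClusterSet:
    """Single-linkage clusters keyed by representative (founder) id."""

    clusters: list[tuple[str, list[str]]] = field(default_factory=list)
    identity_threshold: float = 0.75
    coverage_threshold: float = 0.85

    @property
    def representatives(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    def members_of(self, rep: str) -> list[str]:
        for r, members in self.clusters:
            if r == rep:
                return members
        raise KeyError(rep)

    def __len__(self) -> int:
        return len(self.clusters)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("representative_id\tmember_id\n")
            for rep, members in self.clusters:
                for m in members:
                    fh.write(f"{rep}\t{m}\n")


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a protein FASTA file into a :class:`SequenceSet`.

    Residues are upper-cased; duplicate ids and empty sequences are
    rejected with an error naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = SequenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        out.add(SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), description=desc))
    if len(out) == 0:
        raise FastaParseError(f"{path}: no FASTA records found")
    return out


def write_fasta(seqs: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in seqs:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def classify_by_motif(
    seqs: SequenceSet, patterns: Sequence[MotifPattern]
) -> dict[str, SequenceSet]:
    """Sort sequences into family bins by exact contiguous motif presence.

    Returns a mapping family_label -> SequenceSet plus two extra bins:
    ``"unclassified"`` (no motif) and ``"ambiguous"`` (>= 2 family motifs).
    The bins partition the input.
    """
    if not patterns:
        raise ValueError("patterns must be non-empty")
    bins: dict[str, SequenceSet] = {p.family_label: SequenceSet() for p in patterns}
    bins["unclassified"] = SequenceSet()
    bins["ambiguous"] = SequenceSet()
    for rec in seqs:
        hits = [p.family_label for p in patterns if p.matches(rec.residues)]
        if len(hits) == 1:
            bins[hits[0]].add(rec)
        elif len(hits) == 0:
            bins["unclassified"].add(rec)
        else:
            bins["ambiguous"].add(rec)
    return bins


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> tuple[float, float]:
    """Global-alignment identity and coverage between two sequences.

    identity = identical aligned columns / alignment length;
    coverage = columns where both sequences place a residue / length of the
    longer sequence.  Symmetric in its arguments.
    """
    aln = _ALIGNER.align(a.residues, b.residues)[0]
    sa, sb = str(aln[0]), str(aln[1])
    length = len(sa)
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    both = sum(1 for x, y in zip(sa, sb) if x != "-" and y != "-")
    identity = matches / length if length else 0.0
    coverage = both / max(len(a), len(b))
    return identity, coverage


def cluster_reduce(
    seqs: SequenceSet,
    identity_threshold: float = 0.75,
    coverage_threshold: float = 0.85,
) -> ClusterSet:
    """Greedy redundancy reduction at fixed identity/coverage thresholds.

    Sequences are processed longest-first (ties by input order); each joins
    the first existing cluster whose representative it meets both thresholds
    against, else founds its own cluster.  Representatives are founders.
    """
    if not (0 < identity_threshold <= 1) or not (0 < coverage_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    cs = ClusterSet(
        identity_threshold=identity_threshold, coverage_threshold=coverage_threshold
    )
    order = sorted(
        range(len(seqs)), key=lambda i: (-len(seqs[i]), i)
    )
    reps: list[SequenceRecord] = []
    for idx in order:
        rec = seqs[idx]
        placed = False
        for ci, rep in enumerate(reps):
            ident, cov = pairwise_identity(rec, rep)
            if ident >= identity_threshold and cov >= coverage_threshold:
                cs.clusters[ci][1].append(rec.id)
                placed = True
                break
        if not placed:
            reps.append(rec)
            cs.clusters.append((rec.id, [rec.id]))
    return cs


class NoReferenceError(RuntimeError):
    """No cluster representative resembles the canonical sequence."""


def select_reference(
    clusters: ClusterSet,
    seqs: SequenceSet,
    canonical: SequenceRecord,
    min_similarity: float = 0.25,
) -> SequenceRecord:
    """Pick the family reference sequence.

    The representative of the largest cluster whose identity to the
    family's canonical (structure-bearing) sequence exceeds
    ``min_similarity``; clusters are tried largest-first, ties broken by
    input order.
    """
    if len(clusters) == 0:
        raise ValueError("empty ClusterSet")
    order = sorted(
        range(len(clusters.clusters)),
        key=lambda i: (-len(clusters.clusters[i][1]), i),
    )
    for ci in order:
        rep_id = clusters.clusters[ci][0]
        rep = seqs[rep_id]
        ident, _ = pairwise_identity(rep, canonical)
        if ident > min_similarity:
            return rep
    raise NoReferenceError(
        "no cluster representative exceeds "
        f"{min_similarity:.0%} identity to the canonical sequence; "
        "choose a reference manually"
    )
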