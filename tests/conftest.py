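import numpy as np
import pytest

from udgcoev.alignment import Alignment, _aligned_record
from udgcoev.curation import SequenceRecord, SequenceSet


def make_alignment(rows, reference_id=None):
    """Alignment from a list of (id, residues) or plain residue strings."""
    recs = []
    for k, row in enumerate(rows):
        if isinstance(row, tuple):
            recs.append(_aligned_record(row[0], row[1]))
        else:
            recs.append(_aligned_record(f"s{k}", row))
    return Alignment(recs, reference_id=reference_id)


@pytest.fixture
def toy_alignment():
    """Gap-free 4x4 alignment with one perfectly coupled column pair (0, 1)."""
    return make_alignment(["ACDE", "ACDF", "CDDE", "CDEF"])


@pytest.fixture
def fasta_file(tmp_path):
    p = tmp_path / "seqs.fasta"
    p.write_text(">seq1 first\nACDEFG\n>seq2 second\nacdefh\n")
    return p


def seqset(*residue_strings, prefix="q"):
    return SequenceSet(
        SequenceRecord(id=f"{prefix}{i}", residues=r)
        for i, r in enumerate(residue_strings)
    )
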