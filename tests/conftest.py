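import numpy as np
import pytest

from toxdup.formats import Alignment, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_alignment():
    return Alignment.from_records(
        [
            SequenceRecord(id="s1", residues="ACDEF"),
            SequenceRecord(id="s2", residues="ACDEF"),
            SequenceRecord(id="s3", residues="ACDQF"),
            SequenceRecord(id="s4", residues="AC-EF"),
        ]
    )


def make_alignment(rows, ids=None):
    ids = ids or [f"s{i + 1}" for i in range(len(rows))]
    return Alignment.from_records(
        [SequenceRecord(id=i, residues=r) for i, r in zip(ids, rows)]
    )
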