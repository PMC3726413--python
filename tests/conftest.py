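import numpy as np
import pytest

from tfbsgroup.io_formats import SequenceRecord, SequenceSet


@pytest.fixture
def rng():
    return np.random.default_rng(20130717)


@pytest.fixture
def toy_seqs():
    """Two short sequences sharing an exact 5-mer at known positions."""
    return SequenceSet(
        [
            SequenceRecord("s0", "ACGTA"),
            SequenceRecord("s1", "ACGTA"),
        ]
    )


def make_seqs(strings):
    return SequenceSet(
        [SequenceRecord(f"s{i}", s) for i, s in enumerate(strings)]
    )
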