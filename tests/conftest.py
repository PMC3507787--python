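import numpy as np
import pytest

from neemkit import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_record(rng, rec_id, length, alphabet="ACGT"):
    return SequenceRecord(rec_id, "".join(rng.choice(list(alphabet), length)))


@pytest.fixture
def random_records(rng):
    def make(n, min_len=1, max_len=200, alphabet="ACGT"):
        return [
            random_record(rng, f"r{i}", int(rng.integers(min_len, max_len + 1)), alphabet)
            for i in range(n)
        ]

    return make
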