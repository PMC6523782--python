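import numpy as np
import pytest

from lncsense import SequenceRecord, build_vocabulary


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def vocab2():
    return build_vocabulary(2)


@pytest.fixture
def vocab1():
    return build_vocabulary(1)


def random_record(rng, n, rec_id="r", label=None):
    bases = "".join(np.array(list("ACTG"))[rng.integers(0, 4, size=n)])
    return SequenceRecord(id=rec_id, bases=bases, label=label)


@pytest.fixture
def labelled_records(rng):
    """40 random labelled records, 20 per class, lengths 200-400."""
    recs = []
    for i in range(40):
        n = int(rng.integers(200, 400))
        recs.append(random_record(rng, n, rec_id=f"rec{i:03d}", label=i % 2))
    return recs
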