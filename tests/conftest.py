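import numpy as np
import pytest

from contiguity import StudyList, clean_recall


@pytest.fixture
def study10():
    return StudyList("story", 10)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_seq(order, study, **kwargs):
    return clean_recall(order, study, **kwargs)
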