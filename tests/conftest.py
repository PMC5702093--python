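import numpy as np
import pytest

from psakit.records import AssessmentRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20130101)


@pytest.fixture
def independent_record():
    return AssessmentRecord.independent()


def make_record(**overrides) -> AssessmentRecord:
    return AssessmentRecord.independent(**overrides)
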