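import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20160329)


@pytest.fixture(scope="session")
def warm_kernel():
    """Trigger the JIT compile once so timings elsewhere are honest."""
    from segmse import SegmentSet, sample_entropy

    sample_entropy(SegmentSet([[0.0, 0.5, 1.0, 0.2, 0.7]]), tol=0.4)
    return True
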