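import numpy as np
import pytest

from summr.harmonize import HarmonizedSet
from summr.synthetic_data import SimConfig, as_harmonized_set, generate_univariable

# re-exported for the test modules
harmonized_from_study = as_harmonized_set


@pytest.fixture
def paper_like_study():
    return generate_univariable(SimConfig(seed=7))


@pytest.fixture
def paper_like_set(paper_like_study):
    return as_harmonized_set(paper_like_study)


@pytest.fixture
def tiny_set():
    """Five hand-sized instruments with heterogeneous ratios."""
    bx = np.array([0.10, 0.08, 0.12, 0.05, 0.20])
    sx = np.full(5, 0.01)
    by = np.array([0.05, 0.03, 0.07, 0.01, 0.09])
    sy = np.array([0.02, 0.015, 0.03, 0.01, 0.04])
    return HarmonizedSet.from_arrays(bx, sx, by, sy)
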