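import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from radsurv.features.quantize import QuantizedROI


def random_quantized(rng, max_shape=(6, 6, 3), max_ng=4) -> QuantizedROI:
    """Random small quantized ROI with a random (nonempty) mask."""
    shape = tuple(int(rng.integers(min(2, s), s + 1)) for s in max_shape)
    ng = int(rng.integers(1, max_ng + 1))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[int(rng.integers(mask.size))] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    return QuantizedROI(levels=levels, mask=mask, ng=int(levels.max()))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort_config():
    """A small but fully featured cohort for pipeline-level tests."""
    from radsurv.synthetic import CohortConfig

    return CohortConfig(
        n_subjects=16,
        volume_shape=(24, 24, 16),
        roi_semiaxes=(8.0, 7.0, 5.0),
        n_timepoints=20,
        censor_rate=0.25,
        seed=11,
    )
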