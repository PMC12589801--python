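import numpy as np
import pytest

from pbct_microdose import (ConditionSpec, DepthProfile, SpectrumShapeParams,
                            standard_beam)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def beam190():
    return standard_beam(190)


@pytest.fixture
def beam70():
    return standard_beam(70)


@pytest.fixture
def profile190(beam190):
    return DepthProfile.for_beam(beam190)


@pytest.fixture
def shape():
    return SpectrumShapeParams()


@pytest.fixture
def bp_condition(beam190):
    """A plain (boron-off) Bragg-peak condition for the 190 MeV beam."""
    return ConditionSpec(beam=beam190, depth=beam190.bragg_peak_depth,
                         n_events=20_000, seed=7)


def batch_se(values, n_batches=20):
    """Standard error of a spectrum statistic estimated by batching events."""
    values = np.asarray(values)
    batches = np.array_split(values, n_batches)
    from pbct_microdose import ydbar
    stats = [ydbar(b) for b in batches]
    return float(np.std(stats, ddof=1) / np.sqrt(n_batches))
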