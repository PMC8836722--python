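import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20230501)


@pytest.fixture
def random_segment_factory(rng):
    """Random 1200-sample (1 h at 3 s) segments with all three channels."""
    from icpkit.indices import TrendSeries

    def make(seed=None, n=1200, valid_fraction=1.0):
        r = np.random.default_rng(seed) if seed is not None else rng
        icp = 15.0 + 5.0 * r.standard_normal(n) + 3.0 * np.sin(np.arange(n) / 40.0)
        map_ = 85.0 + 6.0 * r.standard_normal(n) + 4.0 * np.sin(np.arange(n) / 25.0)
        amp = np.clip(1.5 + 0.5 * r.standard_normal(n) + 0.05 * icp, 0.0, None)
        valid = np.ones(n, dtype=bool)
        n_invalid = int(round((1.0 - valid_fraction) * n))
        if n_invalid:
            valid[r.choice(n, size=n_invalid, replace=False)] = False
        return TrendSeries(sample_interval_s=3.0, icp=icp, map=map_, amp=amp, valid=valid)

    return make
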