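"""Index-engine correctness: closed forms, oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icpkit.indices import (
    AllSegmentsUndefinedError,
    ChannelMissingError,
    HourlyIndices,
    TrendSeries,
    aggregate_patient,
    compute_hourly,
    cpp,
    cppopt,
    dicp,
    mean_icp,
    prx,
    rap,
    segment,
)

from . import oracles


def make_series(icp, map_=None, amp=None, valid=None, dt=3.0):
    icp = np.asarray(icp, dtype=float)
    if map_ is None:
        map_ = np.full_like(icp, 90.0)
    return TrendSeries(sample_interval_s=dt, icp=icp, map=map_, amp=amp, valid=valid)


class TestSegmentation:
    def test_72h_at_3s_gives_72_full_segments(self):
        s = make_series(np.zeros(86400))
        segs = segment(s)
        assert len(segs) == 72
        assert all(len(x) == 1200 and not x.partial for x in segs)

    def test_trailing_partial_segment_kept_and_flagged(self):
        segs = segment(make_series(np.zeros(1800)))
        assert len(segs) == 2
        assert not segs[0].partial and len(segs[0]) == 1200
        assert segs[1].partial and len(segs[1]) == 600

    def test_valid_fraction_reflects_invalid_samples(self):
        valid = np.ones(1200, bool)
        valid[:300] = False
        segs = segment(make_series(np.zeros(1200), valid=valid))
        assert len(segs) == 1
        assert segs[0].valid_fraction == pytest.approx(0.75)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            segment(make_series(np.empty(0)))


class TestMeanIcpAndCpp:
    def test_constant_and_alternating_means(self):
        assert mean_icp(make_series(np.full(1200, 15.0))) == pytest.approx(15.0)
        alt = np.tile([10.0, 20.0], 600)
        assert mean_icp(make_series(alt)) == pytest.approx(15.0)

    def test_below_validity_threshold_is_undefined_not_zero(self):
        valid = np.zeros(1200, bool)
        valid[:400] = True  # 1/3 valid < 0.5
        s = make_series(np.full(1200, 30.0), valid=valid)
        assert mean_icp(s) is None
        assert cpp(s) is None

    def test_cpp_constant_difference(self):
        s = make_series(np.full(1200, 20.0), np.full(1200, 90.0))
        assert cpp(s) == pytest.approx(70.0)
        same = make_series(np.full(1200, 50.0), np.full(1200, 50.0))
        assert cpp(same) == pytest.approx(0.0)

    def test_cpp_identity_on_random_segments(self, random_segment_factory):
        for seed in range(5):
            s = random_segment_factory(seed=seed, valid_fraction=0.9)
            v = s.valid
            expected = s.map[v].mean() - s.icp[v].mean()
            assert cpp(s) == pytest.approx(expected, rel=1e-12)


class TestPrx:
    def test_perfect_positive_and_negative_coupling(self, rng):
        map_ = 90.0 + 5.0 * rng.standard_normal(1200)
        up = make_series(0.5 * map_ + 3.0, map_)
        down = make_series(-map_ + 120.0, map_)
        assert prx(up) == pytest.approx(1.0)
        assert prx(down) == pytest.approx(-1.0)

    def test_zero_variance_channel_gives_undefined(self):
        s = make_series(np.full(1200, 15.0), np.full(1200, 90.0))
        assert prx(s) is None

    def test_independent_channels_give_small_prx(self):
        vals = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            s = make_series(15 + 2 * r.standard_normal(1200), 90 + 3 * r.standard_normal(1200))
            vals.append(prx(s))
        assert abs(np.mean(vals)) < 0.2

    def test_missing_map_channel_raises(self):
        s = TrendSeries(sample_interval_s=3.0, icp=np.zeros(1200))
        with pytest.raises(ChannelMissingError):
            prx(s)

    def test_full_hour_window_gives_single_correlation(self, random_segment_factory):
        s = random_segment_factory(seed=5)
        whole = prx(s, window_s=3600.0, step_s=3600.0)
        expected = np.corrcoef(s.map, s.icp)[0, 1]
        assert whole == pytest.approx(expected, rel=1e-12)


class TestRap:
    def test_affine_amp_icp_gives_one(self, rng):
        icp = 15.0 + 5.0 * rng.standard_normal(1200)
        s = make_series(icp, amp=0.1 * icp + 0.5)
        assert rap(s) == pytest.approx(1.0)

    def test_constant_amp_is_undefined_not_zero(self, rng):
        icp = 15.0 + 5.0 * rng.standard_normal(1200)
        s = make_series(icp, amp=np.full(1200, 2.0))
        assert rap(s) is None

    def test_missing_amp_raises_distinct_error(self, rng):
        s = make_series(15.0 + rng.standard_normal(1200))
        with pytest.raises(ChannelMissingError, match="RAP unavailable"):
            rap(s)


class TestDicp:
    def test_closed_forms_exact(self):
        at_threshold = make_series(np.full(1200, 20.0))
        assert dicp(at_threshold) == 0.0
        above = make_series(np.full(1200, 25.0))
        assert dicp(above) == pytest.approx(5.0, abs=1e-12)

    def test_zero_iff_never_above_threshold(self, random_segment_factory):
        s = random_segment_factory(seed=1)
        assert dicp(s, threshold=np.max(s.icp[s.valid]) + 1.0) == 0.0
        assert dicp(s, threshold=np.max(s.icp[s.valid])) == 0.0
        assert dicp(s, threshold=np.max(s.icp[s.valid]) - 0.5) > 0.0

    @given(st.integers(0, 2**31 - 1), st.floats(5.0, 40.0))
    def test_monotone_nonincreasing_in_threshold(self, seed, thr):
        r = np.random.default_rng(seed)
        s = make_series(20.0 + 8.0 * r.standard_normal(200))
        assert dicp(s, thr) >= dicp(s, thr + 1.0) >= 0.0

    @given(st.integers(0, 2**31 - 1), st.integers(1, 199))
    def test_additive_over_sample_partitions(self, seed, cut):
        r = np.random.default_rng(seed)
        valid = r.uniform(size=200) > 0.2
        s = make_series(20.0 + 8.0 * r.standard_normal(200), valid=valid)
        whole = dicp(s)
        parts = dicp(s.slice(0, cut)) + dicp(s.slice(cut, 200))
        assert parts == pytest.approx(whole, rel=1e-12, abs=1e-15)

    def test_invalid_samples_contribute_nothing(self):
        icp = np.full(1200, 20.0)
        icp[600] = 100.0  # a spike on an invalid sample must not count
        valid = np.ones(1200, bool)
        valid[600] = False
        assert dicp(make_series(icp, valid=valid)) == 0.0


class TestOracleEquivalence:
    def test_all_indices_match_naive_reimplementation(self, random_segment_factory):
        for seed in range(10):
            s = random_segment_factory(seed=seed, valid_fraction=0.92)
            assert mean_icp(s) == pytest.approx(oracles.naive_mean_icp(s), rel=1e-9)
            assert cpp(s) == pytest.approx(oracles.naive_cpp(s), rel=1e-9)
            assert prx(s) == pytest.approx(oracles.naive_prx(s), rel=1e-9)
            assert rap(s) == pytest.approx(oracles.naive_rap(s), rel=1e-9)
            assert dicp(s) == pytest.approx(oracles.naive_dicp_rectangle(s), rel=1e-9)

    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 50.0),
        st.floats(-100.0, 100.0),
        st.floats(0.1, 50.0),
        st.floats(-100.0, 100.0),
    )
    def test_correlation_indices_invariant_under_positive_affine_maps(
        self, seed, a1, b1, a2, b2
    ):
        r = np.random.default_rng(seed)
        icp = 15.0 + 4.0 * r.standard_normal(600)
        map_ = 85.0 + 5.0 * r.standard_normal(600)
        amp = 1.5 + 0.4 * r.standard_normal(600) + 0.05 * icp
        s = make_series(icp, map_, amp)
        t = make_series(icp, a1 * map_ + b1, a2 * amp + b2)
        assert prx(t) == pytest.approx(prx(s), abs=1e-9)
        assert rap(t) == pytest.approx(rap(s), abs=1e-9)


class TestAggregate:
    def _hourly(self, **kw):
        base = dict(
            segment_index=0,
            mean_icp=10.0,
            mean_cpp=70.0,
            prx=0.1,
            rap=0.2,
            dicp=1.0,
            valid_fraction=1.0,
        )
        base.update(kw)
        return HourlyIndices(**base)

    def test_single_segment_equals_segment_values(self):
        pi = aggregate_patient([self._hourly()])
        assert (pi.mean_icp, pi.mean_cpp, pi.mean_prx, pi.mean_rap) == (10.0, 70.0, 0.1, 0.2)
        assert pi.total_dicp == 1.0
        assert pi.n_segments == 1

    def test_prx_mean_and_dicp_sum(self):
        hourly = [
            self._hourly(segment_index=0, prx=0.2, dicp=4.449),
            self._hourly(segment_index=1, prx=0.4, dicp=4.449),
        ]
        pi = aggregate_patient(hourly)
        assert pi.mean_prx == pytest.approx(0.3)
        assert pi.total_dicp == pytest.approx(2 * 4.449)

    def test_dicp_total_reaches_published_scale(self):
        hourly = [self._hourly(segment_index=k, dicp=4.449) for k in range(72)]
        assert aggregate_patient(hourly).total_dicp == pytest.approx(320.3, abs=0.05)

    def test_undefined_segments_are_skipped_not_zeroed(self):
        hourly = [
            self._hourly(segment_index=0, prx=None),
            self._hourly(segment_index=1, prx=0.5),
        ]
        assert aggregate_patient(hourly).mean_prx == pytest.approx(0.5)

    def test_all_segments_undefined_raises_exclusion(self):
        h = self._hourly(mean_icp=None, mean_cpp=None, prx=None, rap=None, dicp=0.0)
        with pytest.raises(AllSegmentsUndefinedError):
            aggregate_patient([h])


class TestCppopt:
    def _hourly_from_curve(self, cpps, f, noise_sd=0.0, seed=0):
        r = np.random.default_rng(seed)
        return [
            HourlyIndices(
                segment_index=k,
                mean_icp=None,
                mean_cpp=float(c),
                prx=float(f(c) + noise_sd * r.standard_normal()),
                rap=None,
                dicp=0.0,
                valid_fraction=1.0,
            )
            for k, c in enumerate(cpps)
        ]

    def test_recovers_parabola_vertex(self):
        cpps = np.repeat(np.arange(50.0, 95.0, 5.0), 4) + 1.0
        hourly = self._hourly_from_curve(cpps, lambda c: 0.01 * (c - 70.0) ** 2 - 0.2, 0.01)
        res = cppopt(hourly)
        assert res.value == pytest.approx(70.0, abs=2.5)

    def test_monotone_relation_gives_vertex_out_of_range(self):
        cpps = np.repeat(np.arange(50.0, 95.0, 5.0), 4) + 1.0
        hourly = self._hourly_from_curve(cpps, lambda c: 0.01 * c)
        res = cppopt(hourly)
        assert res.value is None
        assert res.reason in ("vertex_out_of_range", "non_convex")

    def test_too_few_bins_undefined_with_reason(self):
        cpps = np.repeat([52.0, 57.0, 62.0], 4)
        hourly = self._hourly_from_curve(cpps, lambda c: 0.01 * (c - 57.0) ** 2)
        res = cppopt(hourly)
        assert res.value is None
        assert res.reason == "insufficient_bins"


def test_compute_hourly_counts_and_partial_flag(random_segment_factory):
    s = random_segment_factory(n=3000)  # 2.5 h at 3 s
    hourly = compute_hourly(s)
    assert [h.segment_index for h in hourly] == [0, 1, 2]
    assert [h.partial for h in hourly] == [False, False, True]
    assert all(h.dicp is not None for h in hourly)
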