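import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tvconn import (KernelSpec, SyntheticConfig, epoch_average, fisher_z,
                    inverse_fisher_z, kernel_weights, pointwise_slope,
                    simulate_subject, subperiod_fc, tvcc,
                    weighted_correlation)
from tvconn.tvcc import epoch_offsets


def longhand_weighted_r(x, y, w):
    """Independent oracle: expand every sum of the weighted-correlation
    formula term by term."""
    sw = sum(w)
    xb = sum(wi * xi for wi, xi in zip(w, x)) / sw
    yb = sum(wi * yi for wi, yi in zip(w, y)) / sw
    sxy = sum(wi * (xi - xb) * (yi - yb) for wi, xi, yi in zip(w, x, y))
    sxx = sum(wi * (xi - xb) ** 2 for wi, xi in zip(w, x))
    syy = sum(wi * (yi - yb) ** 2 for wi, yi in zip(w, y))
    return sxy / np.sqrt(sxx * syy)


class TestKernelWeights:
    def test_gaussian_values(self):
        u, w = kernel_weights(KernelSpec(h=24, shape="gaussian"))
        assert u.min() == -12 and u.max() == 12 and len(u) == 25
        assert w[u == 0] == 1.0
        # edge weight of the printed kernel: exp(-12^2/24) = exp(-6)
        assert w[u == 12][0] == pytest.approx(np.exp(-6.0), abs=1e-15)
        np.testing.assert_allclose(w, w[::-1])  # even function

    def test_rectangular_support(self):
        u, w = kernel_weights(KernelSpec(h=24, shape="rectangular"))
        assert np.all(w == 1.0) and len(w) == 25

    def test_seconds_constructor(self):
        spec = KernelSpec.from_seconds(16.0, 0.645)
        assert spec.h == pytest.approx(16.0 / 0.645)
        assert spec.half_width == 12

    @pytest.mark.parametrize("bad", [dict(h=2), dict(shape="hann")])
    def test_invalid_spec(self, bad):
        with pytest.raises(ValueError):
            KernelSpec(**bad)


class TestWeightedCorrelation:
    def test_affine_dependence(self, rng):
        x = rng.standard_normal(11)
        w = rng.uniform(0.1, 2.0, 11)
        assert weighted_correlation(x, 2 * x + 5, w) == pytest.approx(1.0)
        assert weighted_correlation(x, -x, w) == pytest.approx(-1.0)

    def test_matches_longhand_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(5, 31)
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            w = rng.uniform(0.05, 3.0, n)
            r = weighted_correlation(x, y, w)
            assert abs(r - longhand_weighted_r(x, y, w)) < 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_affine_invariance_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        w = rng.uniform(0.1, 1.0, n)
        r = weighted_correlation(x, y, w)
        r2 = weighted_correlation(3.5 * x - 1.0, 0.25 * y + 7.0, w)
        assert r2 == pytest.approx(r, abs=1e-12)
        r3 = weighted_correlation(-x, y, w)
        assert r3 == pytest.approx(-r, abs=1e-12)

    def test_degenerate_variance_is_nan(self):
        x = np.ones(5)
        y = np.arange(5.0)
        assert np.isnan(weighted_correlation(x, y, np.ones(5)))

    def test_too_few_positive_weights(self):
        with pytest.raises(ValueError, match="at least 3"):
            weighted_correlation(np.arange(5.0), np.arange(5.0),
                                 np.array([1.0, 1.0, 0, 0, 0]))


class TestTvcc:
    def test_identical_series_give_unit_correlation(self, rng):
        x = rng.standard_normal(100)
        res = tvcc(x, x, KernelSpec(h=24))
        np.testing.assert_allclose(res.r[res.valid_mask], 1.0, atol=1e-10)

    def test_rectangular_full_length_equals_pearson(self, rng):
        x = rng.standard_normal(60)
        y = rng.standard_normal(60)
        res = tvcc(x, y, KernelSpec(h=60, shape="rectangular"))
        full = np.corrcoef(x, y)[0, 1]
        hw = 30
        interior = [i for i in range(60) if i - hw <= 0 and i + hw >= 59]
        for i in interior:
            assert res.r[i] == pytest.approx(full, abs=1e-12)

    def test_scale_offset_invariance(self, rng):
        x = rng.standard_normal(80)
        y = rng.standard_normal(80)
        spec = KernelSpec(h=24)
        base = tvcc(x, y, spec).r
        same = tvcc(2.0 * x + 3.0, 0.5 * y - 1.0, spec).r
        flipped = tvcc(-2.0 * x, 0.5 * y, spec).r
        np.testing.assert_allclose(same, base, atol=1e-9)
        np.testing.assert_allclose(flipped, -base, atol=1e-9)

    def test_gaussian_approaches_rectangular_for_large_h(self, rng):
        # exp(-u^2/h) -> 1 on fixed support as h grows
        x = rng.standard_normal(120)
        y = x + rng.standard_normal(120)
        prev = np.inf
        hw_target = tvcc(x, y, KernelSpec(h=25, shape="rectangular")).r
        for h in (25, 250, 2500, 250000):
            # fixed 12-offset support each side for comparability across h
            g = _tvcc_fixed_support(x, y, h, hw=12)
            dist = np.nanmax(np.abs(g - hw_target))
            assert dist < prev + 1e-12
            prev = dist
        assert prev < 1e-3

    def test_matches_pointwise_weighted_correlation(self, rng):
        # the convolution path must agree with the direct per-sample formula
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        spec = KernelSpec(h=10)
        res = tvcc(x, y, spec)
        u, w = kernel_weights(spec)
        for t in [0, 3, 25, 49]:
            sel = (t + u >= 0) & (t + u < 50)
            direct = weighted_correlation(x[t + u[sel]], y[t + u[sel]], w[sel])
            assert res.r[t] == pytest.approx(direct, abs=1e-10)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            tvcc(np.arange(10.0), np.arange(10.0), KernelSpec(h=24))

    def test_null_series_mean_magnitude(self, rng):
        # for independent noise, windowed |r| concentrates near the sampling
        # scale of an ~n_eff-sample correlation, far from 0 and far from 1
        x = rng.standard_normal(5000)
        y = rng.standard_normal(5000)
        res = tvcc(x, y, KernelSpec(h=24))
        m = np.nanmean(np.abs(res.r))
        u, w = kernel_weights(KernelSpec(h=24))
        n_eff = w.sum() ** 2 / (w ** 2).sum()
        expected = np.sqrt(2.0 / (np.pi * (n_eff - 1)))  # E|r| ~ half-normal
        assert m == pytest.approx(expected, rel=0.15)


def _tvcc_fixed_support(x, y, h, hw):
    u = np.arange(-hw, hw + 1)
    w = np.exp(-(u.astype(float) ** 2) / h)
    out = np.full(x.size, np.nan)
    for t in range(x.size):
        sel = (t + u >= 0) & (t + u < x.size)
        out[t] = weighted_correlation(x[t + u[sel]], y[t + u[sel]], w[sel])
    return out


class TestFisherZ:
    def test_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5))
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_round_trip(self):
        r = np.linspace(-0.999, 0.999, 101)
        np.testing.assert_allclose(inverse_fisher_z(fisher_z(r)), r, atol=1e-10)

    def test_clipping_at_unity(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))
        assert fisher_z(-1.0) == -fisher_z(1.0)

    def test_monotonicity(self):
        r = np.linspace(-0.99, 0.99, 50)
        assert np.all(np.diff(fisher_z(r)) > 0)


class TestEpoching:
    def test_offset_grids(self, design):
        # [-10, 0) at tr 0.645: k in {-15..-1}, 15 samples
        assert list(epoch_offsets(0.645, (-10.0, 0.0))) == list(range(-15, 0))
        # [-10, +30): k in {-15..46}
        k = epoch_offsets(0.645, (-10.0, 30.0))
        assert k[0] == -15 and k[-1] == 46 and len(k) == 62
        # [0, 10) with onset on a sample: offsets 0..15, 16 samples
        assert len(epoch_offsets(0.645, (0.0, 10.0))) == 16

    def test_identical_cycles_average_to_one_segment(self, design):
        series = np.zeros(design.n_retained)
        offsets = epoch_offsets(design.tr, (-10.0, 30.0))
        template = np.sin(np.arange(offsets.size))
        for onset_idx in design.onset_indices():
            series[onset_idx + offsets] = template
        rel_times, mean = epoch_average(series, design)
        np.testing.assert_allclose(mean, template)
        np.testing.assert_allclose(rel_times, offsets * design.tr)

    def test_mean_of_three_cycles_longhand(self, design, rng):
        series = rng.standard_normal(design.n_retained)
        offsets = epoch_offsets(design.tr, (-10.0, 30.0))
        segments = [series[i + offsets] for i in design.onset_indices()]
        _, mean = epoch_average(series, design)
        np.testing.assert_allclose(mean, (segments[0] + segments[1] + segments[2]) / 3.0,
                                   atol=1e-14)

    def test_window_outside_series_names_cycle(self, design, rng):
        series = rng.standard_normal(design.n_retained)
        with pytest.raises(ValueError, match="cycle 3"):
            epoch_average(series, design, window=(-10.0, 80.0))


class TestPointwiseSlope:
    def test_exact_linear_recovery(self):
        t = np.arange(-15, 47) * 0.645
        v = 0.37 * t - 2.0
        slopes = pointwise_slope(t, v, fit_window_s=16.0)
        np.testing.assert_allclose(slopes, 0.37, atol=1e-12)

    def test_constant_gives_zero(self):
        t = np.arange(-15, 47) * 0.645
        slopes = pointwise_slope(t, np.full(t.size, 3.3))
        np.testing.assert_allclose(slopes, 0.0, atol=1e-12)

    def test_matches_normal_equation_oracle(self, rng):
        t = np.arange(-15, 47) * 0.645
        v = rng.standard_normal(t.size)
        slopes = pointwise_slope(t, v, fit_window_s=16.0)
        hw = int(np.floor(16.0 / 0.645 / 2))
        for i in [0, 1, 13, 30, 61]:
            lo, hi = max(0, i - hw), min(t.size, i + hw + 1)
            tt, vv = t[lo:hi], v[lo:hi]
            oracle = (((tt - tt.mean()) * (vv - vv.mean())).sum()
                      / ((tt - tt.mean()) ** 2).sum())
            assert slopes[i] == pytest.approx(oracle, abs=1e-12)

    def test_units_are_per_second(self):
        # same linear signal sampled twice as fast must give the same slope
        for tr in (0.5, 0.25):
            t = np.arange(0, 40) * tr
            s = pointwise_slope(t, 1.7 * t, fit_window_s=8.0)
            np.testing.assert_allclose(s, 1.7, atol=1e-10)


class TestSubperiodFc:
    def test_identical_series_hit_clip(self, design, rng):
        x = rng.standard_normal(design.n_retained)
        z = subperiod_fc(x, x, design)
        np.testing.assert_allclose(z, np.arctanh(1 - 1e-7))

    def test_constant_rho_calibration(self, design):
        # 200 simulated subjects at constant rho 0.5: each sub-period mean
        # within atanh(0.5) +/- 0.05
        from tvconn import constant_trajectory
        trajs = [constant_trajectory(("LMOG", "LFuG"), design, 0.5)]
        config = SyntheticConfig(n_subjects=1, seed=901, trajectories=trajs,
                                 activation_amplitude=(0.0, 0.0),
                                 drift_amplitude=0.0, rho_subject_sd=0.0)
        rows = []
        for i in range(200):
            series, _, _ = simulate_subject(config, i)
            x = series.column("LMOG")[design.n_discard:]
            y = series.column("LFuG")[design.n_discard:]
            rows.append(subperiod_fc(x, y, design))
        mean = np.asarray(rows).mean(axis=0)
        np.testing.assert_allclose(mean, np.arctanh(0.5), atol=0.05)

    def test_out_of_bounds_subperiod(self, design, rng):
        x = rng.standard_normal(design.n_retained)
        with pytest.raises(ValueError, match="outside"):
            subperiod_fc(x, x, design, boundaries=((-10, 0), (0, 10),
                                                   (10, 20), (20, 80)))
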