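"""Phase unwrapping, piecewise/running group delays, maximum synchrony."""

import itertools

import numpy as np
import pytest

from effr.group_delay import (
    DelaySeries,
    GroupDelayConfig,
    PhaseCurve,
    max_sync_rates,
    monotonic_mask,
    piecewise_fit,
    running_group_delay_3pt,
    segments_to_series,
    slopes_differ,
    unwrap_phase,
)


def delay_curve(rates, tau_ms, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    phase = 2 * np.pi * np.asarray(rates) * tau_ms * 1e-3
    return PhaseCurve(np.asarray(rates, float), phase + noise * rng.standard_normal(len(rates)))


class TestUnwrap:
    def test_small_steps_unchanged(self):
        c = unwrap_phase([10.0, 20.0, 30.0], [0.1, 0.2, 0.3])
        assert np.allclose(c.phase_rad, [0.1, 0.2, 0.3])

    def test_wraparound_correction(self):
        c = unwrap_phase([10.0, 20.0], [3.0, -3.0])
        assert np.allclose(c.phase_rad, [3.0, -3.0 + 2 * np.pi])

    def test_pure_delay_slope_recovery_oracle(self):
        """Brute-force oracle: for every rate the unwrapped value equals the
        true cumulative phase up to one shared 2-pi offset, provided the true
        adjacent steps stay below pi."""
        rng = np.random.default_rng(5)
        for tau in (2.0, 5.0, 11.0):
            rates = np.sort(rng.uniform(40, 40 + 140 / tau * 2, 20))
            while np.any(2 * np.pi * np.diff(rates) * tau * 1e-3 >= np.pi):
                rates = np.sort(rng.uniform(40, 40 + 140 / tau * 2, 20))
            true = 2 * np.pi * rates * tau * 1e-3
            wrapped = (true + np.pi) % (2 * np.pi) - np.pi
            un = unwrap_phase(rates, wrapped).phase_rad
            # candidate global offsets: the unwrapped curve may start one or
            # more full cycles below the true curve
            diffs = un - true
            assert np.allclose(diffs, diffs[0], atol=1e-9)
            assert abs(diffs[0] / (2 * np.pi) - round(diffs[0] / (2 * np.pi))) < 1e-9

    def test_needs_two_rates(self):
        with pytest.raises(ValueError):
            unwrap_phase([10.0], [0.0])


class TestMonotonicMask:
    def test_clean_curve_single_run(self):
        c = delay_curve(np.arange(100.0, 400.0, 20.0), 5.0)
        runs = monotonic_mask(c)
        assert runs == [slice(0, 15)]

    def test_split_on_large_phase_reduction(self):
        rates = np.arange(100.0, 300.0, 20.0)
        phase = np.zeros(rates.size)
        phase[5:] -= np.pi / 10  # one step of -pi/10 exceeds -pi/20
        runs = monotonic_mask(PhaseCurve(rates, phase))
        assert len(runs) == 2

    def test_small_reduction_tolerated(self):
        rates = np.arange(100.0, 300.0, 20.0)
        phase = np.zeros(rates.size)
        phase[5:] -= np.pi / 30  # within the -pi/20 tolerance
        runs = monotonic_mask(PhaseCurve(rates, phase))
        assert len(runs) == 1

    def test_split_on_wide_gap(self):
        rates = np.array([100.0, 120.0, 140.0, 260.0, 280.0, 300.0])  # 120-pps gap
        c = delay_curve(rates, 5.0)
        runs = monotonic_mask(c)
        assert runs == [slice(0, 3), slice(3, 6)]


class TestSlopeEquality:
    def test_matches_statsmodels_interaction(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        x1 = np.arange(10.0)
        x2 = np.arange(10.0, 22.0)
        y1 = 2.0 * x1 + rng.standard_normal(10)
        y2 = 2.6 * x2 + rng.standard_normal(12)
        _, p = slopes_differ(x1, y1, x2, y2)
        x = np.concatenate([x1, x2])
        seg = np.r_[np.zeros(10), np.ones(12)]
        X = sm.add_constant(np.column_stack([x, seg, x * seg]))
        res = sm.OLS(np.concatenate([y1, y2]), X).fit()
        assert p == pytest.approx(res.pvalues[3], rel=1e-6)


class TestPiecewise:
    def test_two_slope_exact_recovery(self):
        """tau = 10 ms over 15 rates then 2 ms over 16: breakpoint found
        exactly, slopes to numerical precision, segments fused to 2."""
        r1 = np.linspace(50, 148, 15)
        r2 = np.linspace(155, 260, 16)
        rates = np.concatenate([r1, r2])
        phase = np.concatenate(
            [
                2 * np.pi * r1 * 10e-3,
                2 * np.pi * r1[-1] * 10e-3 + 2 * np.pi * (r2 - r1[-1]) * 2e-3,
            ]
        )
        segs = piecewise_fit(PhaseCurve(rates, phase))
        assert len(segs) == 2
        # the pivot point lies on both lines, so either boundary is exact
        assert segs[0].index.stop in (14, 15)
        assert segs[0].tau_ms == pytest.approx(10.0, abs=1e-9)
        assert segs[1].tau_ms == pytest.approx(2.0, abs=1e-9)

    def test_single_line_fuses_to_one(self):
        c = delay_curve(np.arange(100.0, 400.0, 10.0), 5.0)
        segs = piecewise_fit(c)
        assert len(segs) == 1
        assert segs[0].tau_ms == pytest.approx(5.0, abs=1e-9)

    def test_sse_matches_brute_force_enumeration(self):
        """DP partition equals exhaustive enumeration on a small input."""
        rng = np.random.default_rng(7)
        n, k = 12, 3
        rates = np.linspace(100, 320, n)
        phase = np.cumsum(np.abs(rng.standard_normal(n)))
        cfg = GroupDelayConfig(n_segments=k, few_rates_threshold=0, fuse_p=2.0)
        # fuse_p = 2 makes every slope pair "different", disabling fusion so
        # the raw partition is exposed
        segs = piecewise_fit(PhaseCurve(rates, phase), cfg)
        dp_sse = sum(s.sse for s in segs)

        def sse(i, j):
            x, y = rates[i:j], phase[i:j]
            A = np.vstack([x, np.ones_like(x)]).T
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            return float(np.sum((y - A @ coef) ** 2))

        best = np.inf
        for cuts in itertools.combinations(range(3, n - 2), k - 1):
            bounds = [0, *cuts, n]
            if any(b - a < 3 for a, b in zip(bounds, bounds[1:])):
                continue
            best = min(best, sum(sse(a, b) for a, b in zip(bounds, bounds[1:])))
        assert dp_sse == pytest.approx(best, rel=1e-12)

    def test_partition_count_formula(self):
        # 31 points into 5 segments of >= 3 points each: C(20, 4) candidates
        from math import comb

        n, k, m = 31, 5, 3
        assert comb(n - k * m + k - 1, k - 1) == comb(20, 4) == 4845


class TestRunning:
    def test_29_windows_from_31_rates(self):
        from effr.synthetic_data import default_rate_list

        c = delay_curve(np.array(default_rate_list()), 5.0)
        series = running_group_delay_3pt(c)
        assert series.centers_pps.size == 29
        assert np.allclose(series.center_tau_ms, 5.0, atol=1e-9)
        assert np.allclose(series.tau_ms, 5.0, atol=1e-9)
        assert np.all(np.diff(series.rates_pps) == 1.0)  # 1-pps resolution

    def test_gap_windows_excluded(self):
        rates = np.array([100.0, 120.0, 140.0, 260.0, 280.0, 300.0])
        series = running_group_delay_3pt(delay_curve(rates, 5.0))
        # windows straddling the 120-pps gap are skipped: centers 120 and 280
        assert set(series.centers_pps) == {120.0, 280.0}

    def test_too_few_points_empty(self):
        series = running_group_delay_3pt(delay_curve(np.array([100.0, 120.0]), 5.0))
        assert series.rates_pps.size == 0


class TestMaxSync:
    def test_step_profile(self):
        """Delay profile stepping down with rate maps to the expected
        per-generator maximum synchrony rates."""
        rates = np.arange(43.0, 643.0)
        tau = np.select(
            [rates <= 90, rates <= 160, rates <= 270, rates <= 570],
            [13.0, 9.0, 5.0, 2.5],
            default=1.2,
        )
        ms = max_sync_rates(DelaySeries(rates, tau, "test"))
        assert ms["CTX"] == 90 and ms["TC"] == 160 and ms["IC"] == 270
        assert ms["SOC"] == 570 and ms["CN"] == 642

    def test_constant_5ms(self):
        rates = np.arange(100.0, 643.0)
        ms = max_sync_rates(DelaySeries(rates, np.full(rates.size, 5.0), "t"))
        assert ms["CN"] == ms["SOC"] == ms["IC"] == 642.0
        assert np.isnan(ms["TC"]) and np.isnan(ms["CTX"])

    def test_sub_1ms_delays_all_undefined(self):
        rates = np.arange(100.0, 200.0)
        with pytest.warns(UserWarning):
            ms = max_sync_rates(DelaySeries(rates, np.full(rates.size, 0.5), "t"))
        assert all(np.isnan(v) for v in ms.values())

    def test_monotone_non_increasing_cn_to_ctx(self):
        rng = np.random.default_rng(0)
        rates = np.arange(50.0, 650.0, 7.0)
        tau = np.abs(14 - rates / 50 + rng.standard_normal(rates.size))
        ms = max_sync_rates(DelaySeries(rates, tau, "t"))
        order = [ms[g] for g in ("CN", "SOC", "IC", "TC", "CTX")]
        vals = [v for v in order if not np.isnan(v)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
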