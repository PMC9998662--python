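import math

import numpy as np
import pytest

from filotrace.metrics import (DFSeries, fluorescence_variance,
                               fold_change_bins, instantaneous_speeds,
                               length_change_rates, motility_threshold,
                               normalize_tip_fluorescence, percent_motile,
                               summarize_motility, tip_roi_intensity)
from filotrace.simulate import SinusoidLength, simulate_length_series


def make_series(lengths=None, tips=None, fluor=None, valid=None, dt=5.0):
    n = len(lengths) if lengths is not None else len(tips)
    lengths = np.asarray(lengths if lengths is not None else np.full(n, 2.0), float)
    tips = np.asarray(tips if tips is not None else np.zeros((n, 2)), float)
    fluor = np.asarray(fluor if fluor is not None else np.ones(n), float)
    valid = np.asarray(valid if valid is not None else np.ones(n, bool))
    return DFSeries(df_id="df0", times_s=np.arange(n) * dt, length_um=lengths,
                    tip_xy_um=tips, tip_fluor=fluor,
                    tip_fluor_norm=fluor / np.nanmin(fluor[valid]), valid=valid)


class TestThreshold:
    def test_one_pixel_per_interval(self):
        assert motility_threshold(0.064, 5) == pytest.approx(0.0128)
        assert motility_threshold(0.064, 1) == pytest.approx(0.064)
        assert motility_threshold(0.128, 5) == pytest.approx(0.0256)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            motility_threshold(0.0, 5)


class TestInstantaneousSpeeds:
    def test_one_pixel_step(self):
        s = make_series(tips=[(0, 0), (0.064, 0)], lengths=[1, 1])
        np.testing.assert_allclose(instantaneous_speeds(s), [0.0128])

    def test_stationary_tip(self):
        s = make_series(tips=np.zeros((5, 2)), lengths=np.ones(5))
        np.testing.assert_allclose(instantaneous_speeds(s), np.zeros(4))

    def test_gap_omits_spanning_intervals(self):
        valid = [True, True, False, True, True]
        tips = [(i * 0.1, 0) for i in range(5)]
        s = make_series(tips=tips, lengths=np.ones(5), valid=valid)
        # brute-force pair enumeration: only (0,1) and (3,4) are valid pairs
        assert len(instantaneous_speeds(s)) == 2

    def test_too_short_raises(self):
        s = make_series(tips=np.zeros((3, 2)), lengths=np.ones(3),
                        valid=[True, False, True])
        with pytest.raises(ValueError):
            instantaneous_speeds(s)


def brute_force_summary(lengths, tips, valid, dt, thr):
    """Independent re-implementation with plain loops."""
    speeds, rates = [], []
    for i in range(len(lengths) - 1):
        if valid[i] and valid[i + 1]:
            dx = tips[i + 1][0] - tips[i][0]
            dy = tips[i + 1][1] - tips[i][1]
            speeds.append(math.hypot(dx, dy) / dt)
            rates.append((lengths[i + 1] - lengths[i]) / dt)
    avg = sum(speeds) / len(speeds)
    pct = 100.0 * sum(1 for v in speeds if v > thr) / len(speeds)
    pro = sorted(r for r in rates if r > thr)
    ret = sorted(r for r in rates if r < -thr)

    def med(vals):
        if not vals:
            return float("nan")
        m = len(vals) // 2
        return vals[m] if len(vals) % 2 else (vals[m - 1] + vals[m]) / 2

    lv = [L for L, v in zip(lengths, valid) if v]
    return dict(avg=avg, motile=avg > thr, pct=pct, pro=med(pro), ret=med(ret),
                avg_len=sum(lv) / len(lv), max_len=max(lv))


class TestSummarizeMotility:
    def test_prescribed_rates(self):
        # dL/dt = [0.02, 0.03, -0.02, 0.005] µm/s at 5 s sampling
        rates = [0.02, 0.03, -0.02, 0.005]
        lengths = np.concatenate([[2.0], 2.0 + np.cumsum(np.array(rates) * 5)])
        s = make_series(lengths=lengths, tips=np.zeros((5, 2)))
        out = summarize_motility(s, 0.0128)
        assert out.median_protrusion_rate_um_s == pytest.approx(0.025)
        assert out.median_retraction_rate_um_s == pytest.approx(-0.02)
        r = length_change_rates(s)
        pct_by_length = 100 * np.mean(np.abs(r) > 0.0128)
        assert pct_by_length == pytest.approx(75.0)

    def test_all_static(self):
        s = make_series(lengths=np.ones(5), tips=np.zeros((5, 2)))
        out = summarize_motility(s, 0.0128)
        assert out.pct_time_motile == 0.0 and not out.is_motile
        assert math.isnan(out.median_protrusion_rate_um_s)
        assert math.isnan(out.median_retraction_rate_um_s)

    def test_constant_growth(self):
        lengths = 2.0 + 0.02 * 5 * np.arange(6)
        s = make_series(lengths=lengths, tips=np.zeros((6, 2)))
        out = summarize_motility(s, 0.0128)
        assert out.median_protrusion_rate_um_s == pytest.approx(0.02)
        assert math.isnan(out.median_retraction_rate_um_s)

    def test_matches_brute_force_random(self, rng):
        thr = 0.0128
        for _ in range(30):
            n = rng.integers(5, 40)
            lengths = rng.uniform(1, 5, n)
            tips = rng.uniform(0, 10, (n, 2))
            valid = rng.random(n) > 0.15
            valid[:2] = True
            s = make_series(lengths=lengths, tips=tips, valid=valid)
            out = summarize_motility(s, thr)
            ref = brute_force_summary(lengths, tips, valid, 5.0, thr)
            assert out.avg_tip_speed_um_s == pytest.approx(ref["avg"])
            assert out.is_motile == ref["motile"]
            assert out.pct_time_motile == pytest.approx(ref["pct"])
            assert out.avg_length_um == pytest.approx(ref["avg_len"])
            assert out.max_length_um == pytest.approx(ref["max_len"])
            for got, want in [(out.median_protrusion_rate_um_s, ref["pro"]),
                              (out.median_retraction_rate_um_s, ref["ret"])]:
                assert (math.isnan(got) and math.isnan(want)) or \
                    got == pytest.approx(want)

    def test_time_reversal_swaps_rates(self, rng):
        n = 30
        lengths = rng.uniform(1, 5, n)
        tips = rng.uniform(0, 10, (n, 2))
        fwd = summarize_motility(make_series(lengths=lengths, tips=tips), 0.0128)
        rev = summarize_motility(make_series(lengths=lengths[::-1].copy(),
                                             tips=tips[::-1].copy()), 0.0128)
        assert rev.avg_tip_speed_um_s == pytest.approx(fwd.avg_tip_speed_um_s)
        assert rev.median_protrusion_rate_um_s == pytest.approx(
            -fwd.median_retraction_rate_um_s)
        assert rev.median_retraction_rate_um_s == pytest.approx(
            -fwd.median_protrusion_rate_um_s)

    def test_sinusoid_protrusion_rate_recovery(self):
        # analytic-series check: summary statistics computed on the exact
        # sampled sinusoid match a direct evaluation of thresholded dL/dt
        model = SinusoidLength(L0_um=2.0, amplitude_um=0.5, period_s=60.0)
        L = simulate_length_series(model, 600, 5.0, rng=0)
        s = make_series(lengths=L, tips=np.zeros((600, 2)))
        out = summarize_motility(s, 0.0128)
        r = np.diff(L) / 5.0
        expect = np.median(r[r > 0.0128])
        assert out.median_protrusion_rate_um_s == pytest.approx(expect, rel=0.05)


class TestPercentMotile:
    def test_counts(self):
        def S(motile):
            lengths = np.ones(3)
            tips = np.array([(0, 0), (0.2, 0), (0.4, 0)]) if motile \
                else np.zeros((3, 2))
            return summarize_motility(make_series(lengths=lengths, tips=tips),
                                      0.0128)
        assert percent_motile([S(True)] * 3 + [S(False)]) == pytest.approx(75.0)
        assert percent_motile([S(False)] * 2) == 0.0
        assert percent_motile([S(True)] * 2) == 100.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            percent_motile([])


class TestTipROI:
    def test_uniform_frame(self):
        frame = np.full((64, 64), 7.0)
        got = tip_roi_intensity(frame, (32, 32), 384, 0.064,
                                np.ones((64, 64), bool))
        assert got == pytest.approx(7.0)

    def test_disc_membership_matches_exhaustive_scan(self):
        r_px = 384 / 1000 / 0.064  # = 6 px
        frame = np.zeros((64, 64))
        cx, cy = 30.3, 27.8
        count = 0
        for row in range(64):
            for col in range(64):
                if (col - cx) ** 2 + (row - cy) ** 2 <= r_px ** 2:
                    frame[row, col] = 1.0
                    count += 1
        got = tip_roi_intensity(frame, (cx, cy), 384, 0.064)
        assert got == pytest.approx(1.0)  # mean over exactly the disc pixels
        # and the same disc averaged over a ramp equals the scan average
        ramp = np.arange(64 * 64, dtype=float).reshape(64, 64)
        expect = ramp[frame == 1.0].sum() / count
        assert tip_roi_intensity(ramp, (cx, cy), 384, 0.064) == pytest.approx(expect)

    def test_fully_masked_roi_is_nan(self):
        frame = np.ones((64, 64))
        got = tip_roi_intensity(frame, (32, 32), 384, 0.064,
                                np.zeros((64, 64), bool))
        assert math.isnan(got)

    def test_roi_outside_frame_raises(self):
        with pytest.raises(ValueError):
            tip_roi_intensity(np.ones((64, 64)), (500, 500), 384, 0.064)


class TestNormalization:
    def test_divides_by_minimum(self):
        np.testing.assert_allclose(normalize_tip_fluorescence([2, 4, 8]),
                                   [1, 2, 4])

    def test_constant_series(self):
        np.testing.assert_allclose(normalize_tip_fluorescence([5, 5, 5]),
                                   [1, 1, 1])

    def test_nan_gaps_ignored_for_minimum(self):
        out = normalize_tip_fluorescence([3, np.nan, 6])
        assert out[0] == pytest.approx(1.0)
        assert math.isnan(out[1])
        assert out[2] == pytest.approx(2.0)

    def test_idempotent_when_min_is_one(self, rng):
        x = normalize_tip_fluorescence(rng.uniform(1, 9, 25))
        np.testing.assert_allclose(normalize_tip_fluorescence(x), x)

    def test_non_positive_minimum_rejected(self):
        with pytest.raises(ValueError):
            normalize_tip_fluorescence([0.0, 2.0])


class TestVariance:
    def test_values(self):
        assert fluorescence_variance([4, 4, 4]) == 0.0
        assert fluorescence_variance([1, 3]) == pytest.approx(2.0)
        assert fluorescence_variance([1, 2, 1, 2]) == pytest.approx(1 / 3)

    def test_too_few_raises(self):
        with pytest.raises(ValueError):
            fluorescence_variance([1.0])


class TestFoldChangeBins:
    def test_constant_series_all_ones(self):
        t = np.arange(12) * 5.0
        v = np.full(12, 0.02)
        out = fold_change_bins(v, t, (0, 20), 20.0)
        np.testing.assert_allclose(out, np.ones_like(out))

    def test_doubling(self):
        t = np.arange(10) * 5.0
        v = np.array([0.01] * 5 + [0.02] * 5)
        out = fold_change_bins(v, t, (0, 25), 25.0)
        assert out[0] == pytest.approx(2.0)

    def test_empty_bin_is_nan(self):
        t = np.arange(10) * 5.0
        v = np.array([0.01] * 5 + [np.nan] * 3 + [0.02] * 2)
        out = fold_change_bins(v, t, (0, 25), 15.0)
        assert math.isnan(out[0]) and out[1] == pytest.approx(2.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            fold_change_bins(np.zeros(10), np.arange(10) * 5.0, (0, 25), 25.0)
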