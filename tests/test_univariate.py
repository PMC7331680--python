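"""ROI ERPs, pointwise t-tests, autocorrelation-matched cluster threshold,
N400 area, difference topographies."""

import numpy as np
import pytest

from n400kit import (
    DegenerateNullError,
    EffectSpec,
    EpochSet,
    NoiseSpec,
    ValidationError,
    difference_topomap,
    epoch_times,
    find_clusters,
    gb_cluster_threshold,
    lag1_autocorr,
    n400_area,
    pointwise_t,
    roi_erp,
    simulate_subject,
)
from n400kit.univariate import RoiSpec, _pooled_t, univariate_n400

ROI2 = RoiSpec(channels=("a", "b"), analysis_start=150.0)


def _epochs(voltages, channels=("a", "b"), srate=50.0, window=(-100.0, 900.0),
            rejected=None):
    n_tr = voltages.shape[0]
    return EpochSet(
        voltages=voltages,
        channels=channels,
        times=epoch_times(srate, window),
        srate=srate,
        condition=np.tile(["congruent", "incongruent"], n_tr // 2),
        pair_id=np.repeat(np.arange(n_tr // 2), 2),
        rejected=rejected,
    )


class TestRoiErp:
    def test_constant_trials_give_constant_erp_zero_sem(self):
        ep = _epochs(np.full((4, 2, 50), 3.0))
        erp = roi_erp(ep, ROI2)
        assert np.allclose(erp["congruent"].mean, 3.0)
        assert np.allclose(erp["congruent"].sem, 0.0)

    def test_two_trial_hand_arithmetic(self):
        v = np.zeros((4, 2, 50))
        v[0] = 0.0
        v[2] = 2.0  # the two congruent trials: 0 and 2 uV
        ep = _epochs(v)
        erp = roi_erp(ep, ROI2)
        assert np.allclose(erp["congruent"].mean, 1.0)
        assert np.allclose(erp["congruent"].sem, 1.0)

    def test_rejected_trials_excluded(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(8, 2, 50))
        rej = np.zeros(8, dtype=bool)
        rej[[0, 3]] = True
        ep = _epochs(v, rejected=rej)
        erp = roi_erp(ep, ROI2)
        keep_c = (ep.condition == "congruent") & ~rej
        manual = v[keep_c].mean(axis=1).mean(axis=0)
        assert np.allclose(erp["congruent"].mean, manual)

    def test_no_usable_trials_raises(self):
        ep = _epochs(np.zeros((2, 2, 50)), rejected=np.array([True, False]))
        with pytest.raises(ValidationError):
            roi_erp(ep, ROI2)


class TestPointwiseT:
    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(12, 2, 50))
        ep = _epochs(v)
        t1, _, _ = pointwise_t(ep, ROI2)
        swapped_cond = np.where(ep.condition == "congruent", "incongruent", "congruent")
        ep2 = EpochSet(v, ep.channels, ep.times, ep.srate, swapped_cond, ep.pair_id)
        t2, _, _ = pointwise_t(ep2, ROI2)
        assert np.allclose(t1, -t2)

    def test_huge_separation_gives_tiny_p(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(20, 2, 50)) * 0.1
        peak = np.argmin(np.abs(epoch_times(50.0, (-100, 900)) - 400.0))
        v[1::2, :, peak] += 10.0
        ep = _epochs(v)
        _, p, times = pointwise_t(ep, ROI2)
        assert p[np.argmin(np.abs(times - 400.0))] < 1e-6

    def test_calibrated_under_null(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(60, 2, 200))
        ep = _epochs(v, srate=200.0, window=(-100, 900))
        _, p, _ = pointwise_t(ep, ROI2)
        assert abs(np.mean(p < 0.05) - 0.05) < 0.04

    def test_starts_at_analysis_start(self):
        ep = _epochs(np.random.default_rng(4).normal(size=(8, 2, 50)))
        _, _, times = pointwise_t(ep, ROI2, start=150.0)
        assert times[0] >= 150.0


class TestAutocorr:
    def test_ar1_coefficient_recovered(self):
        rng = np.random.default_rng(5)
        n, phi = 20000, 0.9
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for t in range(1, n):
            x[t] = phi * x[t - 1] + np.sqrt(1 - phi**2) * rng.standard_normal()
        assert abs(lag1_autocorr(x) - phi) < 0.05

    def test_white_noise_near_zero(self):
        x = np.random.default_rng(6).standard_normal(10000)
        assert abs(lag1_autocorr(x)) < 0.05

    def test_alternating_series_is_minus_one_up_to_small_sample_factor(self):
        x = np.tile([1.0, -1.0], 50)
        # closed form: sum x_t x_{t+1} = -(n-1), sum x^2 = n
        assert lag1_autocorr(x) == pytest.approx(-(100 - 1) / 100)

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateNullError):
            lag1_autocorr(np.full(10, 2.0))


class TestClusterThreshold:
    def test_alpha_one_gives_threshold_one(self):
        assert gb_cluster_threshold(0.5, (10, 10), 50, alpha=1.0, n_sim=20, seed=0) == 1

    def test_phi_zero_matches_larger_brute_force_simulation(self):
        # same statistic computed with an independent 10x simulation
        thr = gb_cluster_threshold(0.0, (15, 15), 100, alpha=0.05, n_sim=400, seed=1)
        rng = np.random.default_rng(99)
        longest = np.empty(4000, dtype=int)
        for s in range(4000):
            a = rng.standard_normal((15, 100))
            b = rng.standard_normal((15, 100))
            _, p = _pooled_t(a, b)
            sig = p < 0.05
            best = cur = 0
            for v in sig:
                cur = cur + 1 if v else 0
                best = max(best, cur)
            longest[s] = best
        brute = 1
        while np.mean(longest >= brute) > 0.05:
            brute += 1
        assert abs(thr - brute) <= 1

    def test_threshold_non_decreasing_in_phi(self):
        thrs = [gb_cluster_threshold(phi, (20, 20), 150, n_sim=300, seed=7)
                for phi in (0.0, 0.5, 0.9)]
        assert thrs[0] <= thrs[1] <= thrs[2]

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValidationError):
            gb_cluster_threshold(1.5, (10, 10), 50)


class TestFindClusters:
    def test_no_significant_points_empty(self):
        times = np.arange(150.0, 900.0, 20.0)
        res = find_clusters(np.full(len(times), 0.5), times, min_len=3)
        assert res.clusters == [] and not res.significant

    def test_run_one_short_of_threshold_not_reported(self):
        times = np.arange(150.0, 900.0, 20.0)
        p = np.ones(len(times))
        p[5:9] = 0.01  # run of 4
        res = find_clusters(p, times, min_len=5)
        assert res.clusters == [] and not res.significant

    def test_long_run_reported_with_correct_bounds(self):
        times = np.arange(150.0, 900.0, 20.0)
        p = np.ones(len(times))
        p[10:25] = 0.01
        res = find_clusters(p, times, min_len=5)
        assert len(res.clusters) == 1
        start, end, length = res.clusters[0]
        assert (start, end, length) == (times[10], times[24], 15)
        assert res.significant


class TestN400Area:
    def test_constant_difference_times_window_length(self):
        times = np.arange(-100.0, 900.0, 2.0)
        diff = np.ones(len(times))
        assert n400_area(diff, times, (300.0, 800.0)) == pytest.approx(500.0)

    def test_zero_waveform_zero_area(self):
        times = np.arange(-100.0, 900.0, 2.0)
        assert n400_area(np.zeros(len(times)), times) == 0.0

    def test_triangular_bump_geometry(self):
        times = np.arange(-100.0, 900.0, 2.0)
        diff = np.clip(2.0 * (1 - np.abs(times - 550.0) / 250.0), 0, None)
        # triangle base 500 ms, height 2 uV -> area 500 uV.ms
        assert n400_area(diff, times, (300.0, 800.0)) == pytest.approx(500.0, rel=1e-3)

    def test_linear_and_additive_over_subwindows(self):
        rng = np.random.default_rng(8)
        times = np.arange(-100.0, 900.0, 2.0)
        d = rng.normal(size=len(times))
        a = n400_area(d, times, (300.0, 800.0))
        assert n400_area(3 * d, times, (300.0, 800.0)) == pytest.approx(3 * a)
        assert n400_area(d, times, (300.0, 500.0)) + n400_area(
            d, times, (500.0, 800.0)
        ) == pytest.approx(a)

    def test_window_out_of_range_rejected(self):
        times = np.arange(-100.0, 400.0, 2.0)
        with pytest.raises(ValidationError):
            n400_area(np.zeros(len(times)), times, (300.0, 800.0))


class TestTopomapAndFullAnalysis:
    def test_injected_effect_most_negative_near_center(self, montage):
        channels = tuple(montage.neighbourhood("Cz", 16))
        ep, _ = simulate_subject(
            40, montage=montage, channels=channels, srate=64.0, seed=9,
            effect=EffectSpec(amplitude=-8.0, topography_center="Cz",
                              topography_spread=0.35),
        )
        topo = difference_topomap(ep)
        # the window containing the peak (here 400 ms falls in 400-600 via
        # the bump's mass) should be most negative at/adjacent to Cz
        w = np.argmin(topo[0, :])  # window where Cz is most negative
        best = channels[int(np.argmin(topo[:, w]))]
        assert best in montage.neighbourhood("Cz", 5)

    def test_null_data_topomap_near_zero(self, montage, small_channels):
        ep, _ = simulate_subject(
            60, montage=montage, channels=small_channels, srate=32.0, seed=10,
            effect=EffectSpec(amplitude=0.0),
        )
        topo = difference_topomap(ep)
        sd = ep.voltages.std() / np.sqrt(60)
        assert np.abs(topo).max() < 4 * sd

    def test_full_univariate_analysis_detects_strong_effect(self, montage):
        roi = RoiSpec()
        channels = roi.channels + ("Fz", "Pz")
        ep, _ = simulate_subject(
            94, montage=montage, channels=channels, srate=64.0, seed=11,
            effect=EffectSpec(amplitude=-4.0),
        )
        out = univariate_n400(ep, n_sim=200, seed=12)
        assert out["clusters"].significant
        assert out["area_uVms"] > 0  # incongruent more negative
        lo, hi = 300.0, 800.0
        # cluster overlaps the injected effect's window
        assert any(s < hi and e > lo for s, e, _ in out["clusters"].clusters)
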