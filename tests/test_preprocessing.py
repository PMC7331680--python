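"""Signal conditioning: referencing, filtering, epoching, rejection,
spherical-spline interpolation."""

import numpy as np
import pytest

from n400kit import (
    ContinuousRecording,
    EpochSet,
    Montage,
    ValidationError,
    bandpass,
    baseline_correct,
    epoch,
    epoch_times,
    reject_artifacts,
    rereference,
    simulate_subject,
)
from n400kit.preprocessing import (
    PreprocConfig,
    _spline_predict,
    interpolate_bad_channels,
    preprocess,
    rejection_attribution,
)


def _epochs_from(voltages, channels, srate=50.0, window=(-100.0, 900.0)):
    times = epoch_times(srate, window)
    n_tr = voltages.shape[0]
    return EpochSet(
        voltages=voltages,
        channels=channels,
        times=times,
        srate=srate,
        condition=np.tile(["congruent", "incongruent"], n_tr // 2),
        pair_id=np.repeat(np.arange(n_tr // 2), 2),
    )


class TestRereference:
    def test_zero_mastoids_leave_data_unchanged(self):
        v = np.random.default_rng(0).normal(size=(2, 4, 50))
        v[:, 2:, :] = 0.0
        ep = _epochs_from(v, ("a", "b", "M1", "M2"))
        out = rereference(ep, ("M1", "M2"))
        assert np.allclose(out.voltages, ep.voltages)

    def test_mastoid_mean_is_zero_afterwards(self):
        v = np.random.default_rng(1).normal(size=(4, 5, 50))
        ep = _epochs_from(v, ("a", "b", "c", "M1", "M2"))
        out = rereference(ep, ("M1", "M2"))
        assert np.allclose(out.voltages[:, 3:, :].mean(axis=1), 0.0, atol=1e-12)

    def test_hand_computed_case(self):
        v = np.zeros((2, 3, 50))
        v[:, 0, :3] = [1.0, 2.0, 3.0]
        v[:, 1, :3] = [2.0, 4.0, 6.0]   # M1
        v[:, 2, :3] = [0.0, 0.0, 2.0]   # M2
        ep = _epochs_from(v, ("sig", "M1", "M2"))
        out = rereference(ep, ("M1", "M2"))
        assert np.allclose(out.voltages[0, 0, :3], [0.0, 0.0, -1.0])

    def test_idempotent(self):
        v = np.random.default_rng(2).normal(size=(2, 4, 50))
        ep = _epochs_from(v, ("a", "b", "M1", "M2"))
        once = rereference(ep, ("M1", "M2"))
        twice = rereference(once, ("M1", "M2"))
        assert np.allclose(once.voltages, twice.voltages, atol=1e-12)

    def test_missing_mastoid_raises(self):
        ep = _epochs_from(np.zeros((2, 2, 50)), ("a", "b"))
        with pytest.raises(KeyError):
            rereference(ep, ("M1", "M2"))


class TestBandpass:
    def _tapered_sine(self, freq, seconds=20.0, srate=512.0):
        # smooth onset/offset so the slow 0.1 Hz highpass transient does
        # not contaminate the steady-state gain measurement
        from scipy.signal.windows import tukey

        t = np.arange(0, seconds, 1 / srate)
        x = np.sin(2 * np.pi * freq * t) * tukey(len(t), 0.5)
        return ContinuousRecording(x[None, :], ("a",), srate, [])

    def test_passband_sine_preserved(self):
        rec = self._tapered_sine(10.0)
        out = bandpass(rec, 0.1, 40.0)
        n = out.voltages.shape[1]
        mid = slice(int(0.4 * n), int(0.6 * n))
        assert np.abs(out.voltages[0, mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_dc_offset_removed(self):
        rec = ContinuousRecording(np.full(5120, 50.0)[None, :], ("a",), 512.0, [])
        out = bandpass(rec, 0.1, 40.0)
        assert abs(out.voltages[0, 1024:-1024].mean()) < 1.0

    def test_stopband_attenuation_at_least_90_percent(self):
        rec = self._tapered_sine(80.0)
        out = bandpass(rec, 0.1, 40.0)
        n = out.voltages.shape[1]
        mid = slice(int(0.4 * n), int(0.6 * n))
        assert np.abs(out.voltages[0, mid]).max() < 0.1

    def test_invalid_band_rejected(self):
        rec = ContinuousRecording(np.zeros((1, 1024)), ("a",), 512.0, [])
        with pytest.raises(ValidationError):
            bandpass(rec, 40.0, 0.1)


class TestEpochingAndBaseline:
    def test_ramp_recording_cuts_ramp_segments(self):
        srate = 50.0
        n = 500
        v = np.arange(n, dtype=float)[None, :]
        events = [(100, "congruent", 0), (300, "incongruent", 0)]
        rec = ContinuousRecording(v, ("a",), srate, events)
        ep = epoch(rec, window=(-100, 900))
        # first sample is 5 samples (100 ms) before the event
        assert ep.voltages[0, 0, 0] == 95.0
        assert ep.voltages[1, 0, 0] == 295.0
        assert np.allclose(np.diff(ep.voltages[0, 0]), 1.0)

    def test_event_count_maps_to_trial_count(self, montage, small_channels):
        from n400kit import simulate_continuous

        sched = [(c, p) for p in range(5) for c in ("congruent", "incongruent")]
        rec = simulate_continuous(sched, montage=montage.subset(small_channels),
                                  srate=50.0, seed=0, window=(-100, 900))
        assert epoch(rec, (-100, 900)).n_trials == 10

    def test_constant_trial_becomes_zero(self):
        ep = _epochs_from(np.full((2, 2, 50), 7.0), ("a", "b"))
        out = baseline_correct(ep, (-100, 0))
        assert np.allclose(out.voltages, 0.0)

    def test_baseline_mean_zero_and_idempotent(self):
        v = np.random.default_rng(3).normal(size=(4, 3, 50))
        ep = _epochs_from(v, ("a", "b", "c"))
        out = baseline_correct(ep, (-100, 0))
        mask = out.time_mask(-100, 0)
        assert np.abs(out.voltages[:, :, mask].mean(axis=2)).max() < 1e-9
        again = baseline_correct(out, (-100, 0))
        assert np.allclose(out.voltages, again.voltages)

    def test_empty_baseline_window_rejected(self):
        ep = _epochs_from(np.zeros((2, 2, 50)), ("a", "b"))
        with pytest.raises(ValidationError):
            baseline_correct(ep, (-500, -400))


class TestRejection:
    def test_threshold_exceedance_flags_trial(self):
        v = np.zeros((4, 3, 50))
        v[1, 0, 10] = 250.0
        ep = _epochs_from(v, ("a", "b", "c"))
        out = reject_artifacts(ep, threshold=200.0, scope="all")
        assert list(out.rejected) == [False, True, False, False]

    def test_roi_scope_preserves_trials_clean_in_roi(self):
        v = np.zeros((4, 3, 50))
        v[1, 0, 10] = 250.0  # artifact on channel 'a' only
        ep = _epochs_from(v, ("a", "b", "c"))
        out = reject_artifacts(ep, threshold=200.0, scope=("b", "c"))
        assert not out.rejected.any()

    def test_roi_scope_never_rejects_more_than_all(self, montage, small_channels):
        ep, _ = simulate_subject(10, montage=montage, channels=small_channels,
                                 srate=50.0, window=(-100, 900), seed=4)
        all_mask = reject_artifacts(ep, 15.0, "all").rejected
        roi_mask = reject_artifacts(ep, 15.0, small_channels[:3]).rejected
        assert np.all(roi_mask <= all_mask)

    def test_empty_scope_rejected(self):
        ep = _epochs_from(np.zeros((2, 2, 50)), ("a", "b"))
        with pytest.raises(ValidationError):
            reject_artifacts(ep, 200.0, ())


class TestInterpolation:
    def test_clean_data_is_identity(self, montage):
        ep, _ = simulate_subject(5, montage=montage, srate=50.0, window=(-100, 900),
                                 seed=5)
        out, interpolated = interpolate_bad_channels(ep, montage)
        assert interpolated == []
        assert np.array_equal(out.voltages, ep.voltages)

    def test_railed_channel_is_interpolated_within_neighbour_range(self, montage):
        ep, _ = simulate_subject(10, montage=montage, srate=50.0, window=(-100, 900),
                                 seed=6)
        ci = ep.channel_index("Cz")
        v = ep.voltages.copy()
        v[: ep.n_trials // 5 + 1, ci, :] = 500.0  # railed on >20% of trials
        ep = EpochSet(v, ep.channels, ep.times, ep.srate, ep.condition, ep.pair_id)
        assert rejection_attribution(ep, 200.0)[ci] > 0.10
        out, interpolated = interpolate_bad_channels(ep, montage, fraction=0.10,
                                                     threshold=200.0)
        assert interpolated == ["Cz"]
        nb = [c for c in montage.neighbourhood("Cz", 7) if c != "Cz"]
        nb_idx = out.channel_indices(nb)
        lo = out.voltages[:, nb_idx, :].min(axis=1)
        hi = out.voltages[:, nb_idx, :].max(axis=1)
        span = hi - lo
        assert np.all(out.voltages[:, ci, :] >= lo - 0.75 * span - 1e-6)
        assert np.all(out.voltages[:, ci, :] <= hi + 0.75 * span + 1e-6)

    def test_spline_self_consistency(self, montage):
        # a field that is itself a spherical spline (built from known
        # coefficients on the good electrodes) is reconstructed exactly
        from n400kit.preprocessing import _g_matrix

        rng = np.random.default_rng(7)
        pos = montage.scalp_positions()
        bad = list(montage.scalp_names).index("Cz")
        good = np.array([i for i in range(64) if i != bad])
        c = rng.normal(size=(63, 5))
        c -= c.mean(axis=0)  # spline coefficients must sum to zero
        c0 = rng.normal(size=5)
        data_good = _g_matrix(np.clip(pos[good] @ pos[good].T, -1, 1)) @ c + c0
        truth = _g_matrix(np.clip(pos[[bad]] @ pos[good].T, -1, 1)) @ c + c0
        pred = _spline_predict(data_good, pos[good], pos[[bad]])
        assert np.allclose(pred, truth, atol=1e-3 * np.abs(truth).max() + 1e-6)

    def test_too_many_bad_channels_hard_error(self, montage, small_channels):
        ep, _ = simulate_subject(4, montage=montage, channels=small_channels,
                                 srate=50.0, window=(-100, 900), seed=8)
        v = ep.voltages.copy()
        v[:, :5, :] = 400.0
        ep = EpochSet(v, ep.channels, ep.times, ep.srate, ep.condition, ep.pair_id)
        with pytest.raises(RuntimeError, match="unreliable"):
            interpolate_bad_channels(ep, montage.subset(small_channels))


class TestPipeline:
    def test_end_to_end_on_continuous_simulation(self, montage):
        from n400kit import simulate_continuous

        names = tuple(montage.neighbourhood("Cz", 10)) + ("M1", "M2")
        sub = montage.subset(names)
        sched = [(c, p) for p in range(6) for c in ("congruent", "incongruent")]
        rec = simulate_continuous(sched, montage=sub, srate=256.0, seed=9,
                                  channels=names)
        ep, log = preprocess(rec, sub, PreprocConfig(reject_scope="all"))
        assert ep.n_trials == 12
        assert log["interpolated_channels"] == []
        mask = ep.time_mask(-100, 0)
        assert np.abs(ep.voltages[:, :, mask].mean(axis=2)).max() < 1e-9
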