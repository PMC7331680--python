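"""Synthetic EEG with a controllable N400-like condition effect.

The generator emulates the structure of a single-session sentence
experiment: 94 target-word pairs, each target appearing once in a congruent
and once in an incongruent context (188 trials), 64 scalp channels sampled
at 512 Hz, epochs spanning [-100, 1000) ms around target onset.

The condition effect is a separable spatio-temporal Gaussian bump added to
the incongruent trials only: a temporal Gaussian (peak latency, SD width)
times a spatial Gaussian over electrode positions (centre, spread).  A
negative amplitude makes incongruent trials more negative, matching the
N400 direction.  Sensor noise is spatially correlated 1/f ("pink") plus
white noise, identical in law for both conditions, so with amplitude 0 the
two conditions are exchangeable by construction.

Per-subject heterogeneity (cohorts) is modelled as random draws of the
effect's latency and topography centre around a base specification, plus a
"responder fraction" of subjects with a non-zero effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .epochs import CONDITIONS, ContinuousRecording, EpochSet, epoch_times
from .errors import ValidationError
from .montage import Montage

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "GroundTruth",
    "simulate_subject",
    "simulate_cohort",
    "simulate_continuous",
]


@dataclass(frozen=True)
class EffectSpec:
    """Spatio-temporal Gaussian condition effect.

    amplitude : µV, added to incongruent trials (negative = incongruent
        more negative).  0 yields exchangeable conditions.
    peak_latency : ms after target onset.
    temporal_width : Gaussian SD of the time course, ms.
    topography_center : channel name of the spatial peak.
    topography_spread : spatial Gaussian SD in unit-sphere (chord) units.
    latency_jitter_sd / center_jitter_sd : per-subject heterogeneity SDs
        (ms, and sphere units of centre displacement) used by
        :func:`simulate_cohort`.
    center_position : optional explicit 3-vector for the spatial peak,
        overriding ``topography_center`` (used for jittered cohorts, where
        the realized centre need not coincide with an electrode).
    """

    amplitude: float = -4.0
    peak_latency: float = 400.0
    temporal_width: float = 80.0
    topography_center: str = "Cz"
    topography_spread: float = 0.6
    latency_jitter_sd: float = 0.0
    center_jitter_sd: float = 0.0
    center_position: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.temporal_width <= 0:
            raise ValidationError("temporal_width must be > 0")
        if self.topography_spread <= 0:
            raise ValidationError("topography_spread must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor-noise model: spatially correlated pink + white noise.

    ``white_sd`` and ``pink_sd`` are per-channel SDs in µV;
    ``spatial_corr_scale`` is the Gaussian decay scale (chord distance on
    the unit sphere) of the inter-channel correlation.  Defaults give a
    single-trial SD of ~9 µV, large enough that a few-µV evoked effect is
    invisible in single trials but clear in the 94-trial average.
    """

    white_sd: float = 4.0
    pink_sd: float = 8.0
    spatial_corr_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.white_sd < 0 or self.pink_sd < 0:
            raise ValidationError("noise SDs must be >= 0")
        if self.spatial_corr_scale <= 0:
            raise ValidationError("spatial_corr_scale must be > 0")


@dataclass
class GroundTruth:
    """Realized per-subject effect parameters, for recovery tests."""

    amplitude: float
    peak_latency: float
    center_channel: str
    center_position: np.ndarray
    topography: np.ndarray  # per-channel spatial weight in [0, 1]
    subject_id: str = ""


def _spatial_mixer(positions: np.ndarray, scale: float) -> np.ndarray:
    """Cholesky factor of the Gaussian spatial correlation matrix."""
    d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    corr = np.exp(-d2 / (2.0 * scale**2))
    # small jitter keeps the matrix positive definite for dense layouts
    corr[np.diag_indices_from(corr)] += 1e-9
    L = np.linalg.cholesky(corr)
    # renormalise rows so per-channel variance is exactly 1
    return L / np.linalg.norm(L, axis=1, keepdims=True)


def _pink_noise(rng: np.random.Generator, shape: tuple, n_samples: int) -> np.ndarray:
    """Unit-SD 1/f noise along the last axis."""
    freqs = np.fft.rfftfreq(n_samples)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = rng.standard_normal(shape + (len(freqs),)) + 1j * rng.standard_normal(
        shape + (len(freqs),)
    )
    x = np.fft.irfft(spec * amp, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _effect_fields(
    effect: EffectSpec, montage: Montage, channels: tuple[str, ...], times: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatial weights (per channel), temporal bump, realized centre position."""
    if effect.center_position is not None:
        cpos = np.asarray(effect.center_position, dtype=float)
        cpos = cpos / np.linalg.norm(cpos)
    else:
        cpos = montage.position_of(effect.topography_center)
    pos = np.array([montage.position_of(c) for c in channels])
    d2 = np.sum((pos - cpos) ** 2, axis=1)
    weights = np.exp(-d2 / (2.0 * effect.topography_spread**2))
    bump = np.exp(-((times - effect.peak_latency) ** 2) / (2.0 * effect.temporal_width**2))
    return weights, bump, cpos


def simulate_subject(
    n_pairs: int,
    montage: Montage | None = None,
    effect: EffectSpec | None = None,
    noise: NoiseSpec | None = None,
    srate: float = 512.0,
    seed: int = 0,
    window: tuple[float, float] = (-100.0, 1000.0),
    channels: tuple[str, ...] | None = None,
    subject_id: str = "",
) -> tuple[EpochSet, GroundTruth]:
    """Simulate one subject's epoched session.

    Returns ``2 * n_pairs`` trials (each pair once per condition) plus the
    ground truth of the injected effect.  Deterministic given ``seed``.
    """
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    montage = montage if montage is not None else Montage.standard_64()
    effect = effect if effect is not None else EffectSpec()
    noise = noise if noise is not None else NoiseSpec()
    channels = tuple(channels) if channels is not None else montage.scalp_names

    times = epoch_times(srate, window)
    n_tr, n_ch, n_s = 2 * n_pairs, len(channels), len(times)
    rng = np.random.default_rng(seed)

    weights, bump, cpos = _effect_fields(effect, montage, channels, times)
    pos_all = np.array([montage.position_of(c) for c in channels])
    # nearest simulated channel to the realized centre
    d = np.linalg.norm(pos_all - cpos, axis=1)
    center_channel = channels[int(np.argmin(d))]

    raw = np.zeros((n_tr, n_ch, n_s))
    if noise.pink_sd > 0:
        raw += noise.pink_sd * _pink_noise(rng, (n_tr, n_ch), n_s)
    if noise.white_sd > 0:
        raw += noise.white_sd * rng.standard_normal((n_tr, n_ch, n_s))
    if noise.pink_sd > 0 or noise.white_sd > 0:
        L = _spatial_mixer(pos_all, noise.spatial_corr_scale)
        raw = np.einsum("cd,tds->tcs", L, raw)

    condition = np.array([CONDITIONS[i % 2] for i in range(n_tr)], dtype="U11")
    pair_id = np.repeat(np.arange(n_pairs), 2)
    incong = condition == "incongruent"
    raw[incong] += effect.amplitude * weights[None, :, None] * bump[None, None, :]

    epochs = EpochSet(
        voltages=raw,
        channels=channels,
        times=times,
        srate=srate,
        condition=condition,
        pair_id=pair_id,
        subject_id=subject_id,
    )
    truth = GroundTruth(
        amplitude=effect.amplitude,
        peak_latency=effect.peak_latency,
        center_channel=center_channel,
        center_position=cpos,
        topography=weights,
        subject_id=subject_id,
    )
    return epochs, truth


def simulate_cohort(
    n_subjects: int,
    n_pairs: int = 94,
    montage: Montage | None = None,
    base_effect: EffectSpec | None = None,
    noise: NoiseSpec | None = None,
    responder_fraction: float = 1.0,
    srate: float = 512.0,
    seed: int = 0,
    window: tuple[float, float] = (-100.0, 1000.0),
    channels: tuple[str, ...] | None = None,
) -> list[tuple[EpochSet, GroundTruth]]:
    """Simulate a heterogeneous cohort.

    Each subject's effect latency and topography centre are drawn around
    the base effect with its jitter SDs; ``responder_fraction`` sets
    the proportion of subjects with a non-zero amplitude (the rest get
    amplitude 0).  ``round(responder_fraction * n_subjects)`` subjects are
    responders, chosen at random but deterministically given ``seed``.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    if not 0.0 <= responder_fraction <= 1.0:
        raise ValidationError("responder_fraction must lie in [0, 1]")
    montage = montage if montage is not None else Montage.standard_64()
    base = base_effect if base_effect is not None else EffectSpec()

    rng = np.random.default_rng(seed)
    n_resp = int(round(responder_fraction * n_subjects))
    responders = np.zeros(n_subjects, dtype=bool)
    responders[rng.permutation(n_subjects)[:n_resp]] = True
    data_seeds = np.random.SeedSequence(seed).generate_state(n_subjects)

    base_pos = (
        np.asarray(base.center_position, float)
        if base.center_position is not None
        else montage.position_of(base.topography_center)
    )
    out = []
    for s in range(n_subjects):
        latency = base.peak_latency + rng.normal(0.0, base.latency_jitter_sd)
        cpos = base_pos + rng.normal(0.0, base.center_jitter_sd, size=3)
        cpos = cpos / np.linalg.norm(cpos)
        eff = replace(
            base,
            amplitude=base.amplitude if responders[s] else 0.0,
            peak_latency=float(latency),
            center_position=cpos,
        )
        sid = f"S{s + 1:02d}"
        out.append(
            simulate_subject(
                n_pairs,
                montage=montage,
                effect=eff,
                noise=noise,
                srate=srate,
                seed=int(data_seeds[s]),
                window=window,
                channels=channels,
                subject_id=sid,
            )
        )
    return out


def simulate_continuous(
    schedule,
    montage: Montage | None = None,
    effect: EffectSpec | None = None,
    noise: NoiseSpec | None = None,
    srate: float = 512.0,
    seed: int = 0,
    window: tuple[float, float] = (-100.0, 1000.0),
    gap_ms: float = 400.0,
    channels: tuple[str, ...] | None = None,
) -> ContinuousRecording:
    """Lay simulated epochs out on a continuous time axis with event markers.

    ``schedule`` is a sequence of ``(condition, pair_id)`` in presentation
    order (a :class:`~n400kit.design.TrialSequence` also works).  The
    per-trial data are generated exactly as :func:`simulate_subject` with
    the same seed, so cutting epochs back out of the recording reproduces
    the direct simulation trial-for-trial.
    """
    trials = _as_trial_list(schedule)
    if gap_ms < 0:
        raise ValidationError("gap_ms must be >= 0")
    pair_ids = sorted({pid for _, pid in trials})
    n_pairs = len(pair_ids)
    counts: dict = {}
    for cond, pid in trials:
        counts.setdefault(pid, set()).add(cond)
    for pid, conds in counts.items():
        if conds != set(CONDITIONS):
            raise ValidationError(f"schedule must present pair {pid} once per condition")

    epochs, _ = simulate_subject(
        n_pairs, montage=montage, effect=effect, noise=noise, srate=srate,
        seed=seed, window=window, channels=channels,
    )
    pid_index = {pid: i for i, pid in enumerate(pair_ids)}
    lookup = {
        (epochs.condition[t], int(epochs.pair_id[t])): t for t in range(epochs.n_trials)
    }

    n_s = len(epochs.times)
    n_pre = int(np.sum(epochs.times < 0))
    gap = int(round(gap_ms * srate / 1000.0))
    slot = n_s + gap
    total = slot * len(trials) + gap
    voltages = np.zeros((len(epochs.channels), total))
    events = []
    for k, (cond, pid) in enumerate(trials):
        t = lookup[(cond, pid_index[pid])]
        start = gap + k * slot
        voltages[:, start : start + n_s] = epochs.voltages[t]
        events.append((start + n_pre, str(cond), int(pid)))
    return ContinuousRecording(
        voltages=voltages, channels=epochs.channels, srate=srate, events=events
    )


def _as_trial_list(schedule) -> list:
    if hasattr(schedule, "labels") and hasattr(schedule, "pair_order"):
        return list(zip(schedule.labels, schedule.pair_order))
    return [(str(c), int(p)) for c, p in schedule]
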