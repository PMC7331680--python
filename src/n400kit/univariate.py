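"""Classic univariate N400 analysis.

The signal is averaged over a 9-electrode centro-parietal region of
interest (Cz and its surround), pointwise two-sample t-tests compare the
conditions from 150 ms onward, and multiple comparisons are controlled by
a minimum-cluster-length threshold calibrated on simulated null series
whose lag-1 autocorrelation matches the observed difference waveform
(Guthrie-Buchwald style).  The N400 magnitude is summarised as the
trapezoidal area of the congruent-minus-incongruent difference over
300-800 ms (positive when incongruent is more negative).

Only non-rejected trials enter these analyses (rejection is typically
scoped to the ROI channels to preserve data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .epochs import EpochSet
from .errors import DegenerateNullError, ValidationError
from .results import ClusterResult

__all__ = [
    "RoiSpec",
    "ErpWaveform",
    "roi_erp",
    "roi_trial_series",
    "pointwise_t",
    "lag1_autocorr",
    "gb_cluster_threshold",
    "find_clusters",
    "n400_area",
    "difference_topomap",
    "univariate_n400",
]

DEFAULT_ROI = ("Cz", "FC1", "FCz", "FC2", "C1", "C2", "CP1", "CPz", "CP2")


@dataclass(frozen=True)
class RoiSpec:
    """Region of interest and analysis windows for the N400."""

    channels: tuple[str, ...] = DEFAULT_ROI
    analysis_start: float = 150.0
    n400_window: tuple[float, float] = (300.0, 800.0)


@dataclass
class ErpWaveform:
    """Trial-averaged ROI waveform with its standard error."""

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_trials: int
    condition: str = ""


def roi_trial_series(epochs: EpochSet, roi: RoiSpec | None = None) -> dict:
    """Per-trial ROI-mean time series for each condition (accepted trials).

    Returns ``{condition: (n_trials, n_samples) array}``.
    """
    roi = roi if roi is not None else RoiSpec()
    idx = epochs.channel_indices(roi.channels)
    roi_mean = epochs.voltages[:, idx, :].mean(axis=1)
    out = {}
    for cond in ("congruent", "incongruent"):
        keep = (epochs.condition == cond) & ~epochs.rejected
        if not keep.any():
            raise ValidationError(f"no accepted trials in condition '{cond}'")
        out[cond] = roi_mean[keep]
    return out


def roi_erp(epochs: EpochSet, roi: RoiSpec | None = None) -> dict:
    """Per-condition ERP over the ROI: channel-mean then trial-mean, with
    the across-trial SEM of the channel-mean."""
    series = roi_trial_series(epochs, roi)
    out = {}
    for cond, x in series.items():
        n = x.shape[0]
        sem = x.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(x.shape[1])
        out[cond] = ErpWaveform(
            times=epochs.times.copy(), mean=x.mean(axis=0), sem=sem,
            n_trials=n, condition=cond,
        )
    return out


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classic pooled-variance two-sample t per column, two-tailed p.

    Columns where both groups have (near-)zero variance get t = 0, p = 1
    with a warning.
    """
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValidationError("need >= 2 usable trials per condition")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} timepoint(s) with degenerate variance; p set to 1")
        t = np.where(bad, 0.0, t)
        p = np.where(bad, 1.0, p)
    return t, p


def pointwise_t(
    epochs: EpochSet, roi: RoiSpec | None = None, start: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise two-sample t-tests on the ROI-mean from ``start`` ms onward.

    Returns ``(t_series, p_series, times)`` restricted to the analysis
    window.  The t statistic is congruent minus incongruent.
    """
    roi = roi if roi is not None else RoiSpec()
    start = start if start is not None else roi.analysis_start
    series = roi_trial_series(epochs, roi)
    mask = epochs.times >= start - 1e-9
    if not mask.any():
        raise ValidationError(f"no samples at or after {start} ms")
    t, p = _pooled_t(series["congruent"][:, mask], series["incongruent"][:, mask])
    return t, p, epochs.times[mask]


def lag1_autocorr(series: np.ndarray) -> float:
    """Sample lag-1 autocorrelation of a waveform."""
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValidationError("series must have length >= 3")
    x = x - x.mean()
    denom = float(np.sum(x * x))
    if denom == 0:
        raise DegenerateNullError("constant series has no defined autocorrelation")
    return float(np.sum(x[:-1] * x[1:]) / denom)


def gb_cluster_threshold(
    phi: float,
    n_per_condition: tuple[int, int],
    n_timepoints: int,
    alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int = 0,
) -> int:
    """Minimum significant cluster length from autocorrelation-matched nulls.

    Simulates ``n_sim`` null datasets of per-trial AR(1) Gaussian series
    (lag-1 coefficient ``phi``, stationary unit variance, trial counts
    matched to the data), runs the pointwise t-test on each, and records
    the longest run of p < 0.05.  The threshold is the smallest length L
    such that at most a fraction ``alpha`` of simulated longest runs
    reach L — an observed cluster of length >= L is then longer than 95%
    of the null series' longest clusters.
    """
    if not -1.0 < phi < 1.0:
        raise ValidationError("phi must lie in (-1, 1)")
    if n_sim < 1:
        raise ValidationError("n_sim must be >= 1")
    n_c, n_i = n_per_condition
    rng = np.random.default_rng(seed)
    n_trials = n_c + n_i
    innov_sd = np.sqrt(1.0 - phi * phi)
    x = np.empty((n_sim, n_trials, n_timepoints))
    x[:, :, 0] = rng.standard_normal((n_sim, n_trials))
    for t in range(1, n_timepoints):
        x[:, :, t] = phi * x[:, :, t - 1] + innov_sd * rng.standard_normal((n_sim, n_trials))
    longest = np.empty(n_sim, dtype=int)
    for s in range(n_sim):
        _, p = _pooled_t(x[s, :n_c], x[s, n_c:])
        longest[s] = _longest_run(p < 0.05)
    L = 1
    while np.mean(longest >= L) > alpha:
        L += 1
    return int(L)


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def find_clusters(
    p_series: np.ndarray,
    times: np.ndarray,
    min_len: int,
    alpha: float = 0.05,
    t_series: np.ndarray | None = None,
) -> ClusterResult:
    """Maximal runs of p < alpha at least ``min_len`` samples long."""
    p = np.asarray(p_series, dtype=float)
    times = np.asarray(times, dtype=float)
    mask = p < alpha
    padded = np.concatenate(([False], mask, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    clusters = [
        (float(times[a]), float(times[b - 1]), int(b - a))
        for a, b in zip(starts, ends)
        if b - a >= min_len
    ]
    return ClusterResult(
        times=times,
        stat_series=np.asarray(t_series) if t_series is not None else np.full_like(p, np.nan),
        p_series=p,
        min_cluster_len=int(min_len),
        clusters=clusters,
        significant=len(clusters) > 0,
    )


def n400_area(
    difference: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = (300.0, 800.0),
) -> float:
    """Trapezoidal area (µV·ms) of the congruent-minus-incongruent
    difference waveform over the window; positive when incongruent is
    more negative."""
    times = np.asarray(times, dtype=float)
    if window[0] < times[0] - 1e-9 or window[1] > times[-1] + 1e-9:
        raise ValidationError(f"window {window} outside waveform span")
    mask = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    return float(np.trapezoid(np.asarray(difference, float)[mask], times[mask]))


def difference_topomap(
    epochs: EpochSet,
    windows: tuple = ((200.0, 400.0), (400.0, 600.0), (600.0, 800.0), (800.0, 1000.0)),
) -> np.ndarray:
    """Per-channel mean of (incongruent - congruent) over time windows.

    Returns ``(n_channels, n_windows)``; computed from accepted trials.
    The maps are for display and are not thresholded.
    """
    keep_c = (epochs.condition == "congruent") & ~epochs.rejected
    keep_i = (epochs.condition == "incongruent") & ~epochs.rejected
    if not keep_c.any() or not keep_i.any():
        raise ValidationError("need accepted trials in both conditions")
    diff = epochs.voltages[keep_i].mean(axis=0) - epochs.voltages[keep_c].mean(axis=0)
    out = np.empty((len(epochs.channels), len(windows)))
    for w, (lo, hi) in enumerate(windows):
        mask = epochs.time_mask(lo, hi)
        if not mask.any():
            raise ValidationError(f"epochs do not cover the window [{lo}, {hi}) ms")
        out[:, w] = diff[:, mask].mean(axis=1)
    return out


def univariate_n400(
    epochs: EpochSet,
    roi: RoiSpec | None = None,
    alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int = 0,
) -> dict:
    """Full single-subject univariate analysis.

    Runs the ROI ERP, pointwise t-tests from the analysis start, the
    autocorrelation-matched cluster threshold, cluster detection, and the
    N400 area.  Returns a dict with keys ``erp``, ``clusters``
    (:class:`ClusterResult`), ``area_uVms``, ``autocorr`` and
    ``min_cluster_len``.
    """
    roi = roi if roi is not None else RoiSpec()
    erp = roi_erp(epochs, roi)
    diff = erp["congruent"].mean - erp["incongruent"].mean
    phi = lag1_autocorr(diff)
    t, p, times = pointwise_t(epochs, roi)
    series = roi_trial_series(epochs, roi)
    min_len = gb_cluster_threshold(
        phi,
        (series["congruent"].shape[0], series["incongruent"].shape[0]),
        n_timepoints=len(times),
        alpha=alpha,
        n_sim=n_sim,
        seed=seed,
    )
    clusters = find_clusters(p, times, min_len, alpha=alpha, t_series=t)
    area = n400_area(diff, epochs.times, roi.n400_window)
    return {
        "erp": erp,
        "clusters": clusters,
        "area_uVms": area,
        "autocorr": phi,
        "min_cluster_len": min_len,
    }
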