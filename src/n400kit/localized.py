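"""Time-resolved and time-x-space-resolved decoding.

Time-resolved: at each time point the classifier sees all scalp channels
over an 11-sample window (the centre sample plus 5 on each side); centres
whose window would exceed the epoch are skipped.  Family-wise inference
uses threshold-free cluster enhancement (TFCE) of the chance-centred
accuracy series and a max-statistic permutation correction computed over
all time points excluding the baseline.

Searchlight: the classifier sees a 5-electrode neighbourhood x 11-sample
window, repeated for every electrode and time point, yielding a
topographic accuracy map over time.  The maps are descriptive: no
significance testing is attached, and four 200-ms window averages
(200-1000 ms) summarise them for display.

Implementation note: all windowed Gram matrices are sliced from one
cumulative per-sample Gram tensor, so the SVM engine never touches the
feature arrays again after a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _svm
from .decoding import ClassifierSpec, _canonical_order, _flip_matrix, _loto_folds_any
from .epochs import EpochSet
from .errors import ValidationError
from .montage import Montage
from .results import AccuracyMap

__all__ = [
    "TfceSpec",
    "TimeResolvedResult",
    "time_resolved_decode",
    "time_resolved_inference",
    "tfce_series",
    "maxstat_significance",
    "searchlight_decode",
    "window_topographies",
    "DEFAULT_TOPO_WINDOWS",
]

DEFAULT_TOPO_WINDOWS = ((200.0, 400.0), (400.0, 600.0), (600.0, 800.0), (800.0, 1000.0))

_MAX_ITER = 200_000


@dataclass(frozen=True)
class TfceSpec:
    """TFCE parameters: extent exponent E, height exponent H, integration
    step dh (None = max statistic / 100), and whether the baseline is
    excluded from the analysis window."""

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    baseline_excluded: bool = True

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValidationError("E and H must be > 0")
        if self.dh is not None and self.dh <= 0:
            raise ValidationError("dh must be > 0")


def _cumulative_gram(v: np.ndarray) -> np.ndarray:
    """cum[:, :, s] = Gram of features restricted to samples [0, s)."""
    S = np.einsum("ics,jcs->ijs", v, v, optimize=True)
    out = np.zeros(S.shape[:2] + (S.shape[2] + 1,))
    np.cumsum(S, axis=2, out=out[:, :, 1:])
    return out


def _centres(n_samples: int, halfwidth: int) -> np.ndarray:
    if halfwidth < 0:
        raise ValidationError("halfwidth must be >= 0")
    if n_samples < 2 * halfwidth + 1:
        raise ValidationError(
            f"epoch of {n_samples} samples too short for halfwidth {halfwidth}"
        )
    return np.arange(halfwidth, n_samples - halfwidth)


def _windowed_accuracies(
    cum: np.ndarray,
    centres: np.ndarray,
    halfwidth: int,
    y: np.ndarray,
    runs: np.ndarray,
    clf: ClassifierSpec,
) -> np.ndarray:
    """(n_runs, n_centres) mean LOTO accuracies from a cumulative Gram."""
    out = np.empty((runs.shape[0], len(centres)))
    for k, c in enumerate(centres):
        K = cum[:, :, c + halfwidth + 1] - cum[:, :, c - halfwidth]
        K = np.ascontiguousarray(K)
        if clf.backend == "smo":
            folds = _svm.loto_batch(K, y, runs, clf.C, clf.tol, _MAX_ITER)
            out[:, k] = folds.mean(axis=1)
        else:
            for r, flip in enumerate(runs):
                yy = y * np.repeat(np.where(flip, -1.0, 1.0), 2)
                out[r, k] = float(np.mean(_loto_folds_any(K, yy, clf)))
    return out


def time_resolved_decode(
    epochs: EpochSet, clf: ClassifierSpec | None = None, halfwidth: int = 5
) -> AccuracyMap:
    """LOTO accuracy at each time point from an 11-sample window (all channels)."""
    clf = clf if clf is not None else ClassifierSpec()
    order, _, y = _canonical_order(epochs)
    cum = _cumulative_gram(epochs.voltages[order])
    centres = _centres(len(epochs.times), halfwidth)
    runs = np.zeros((1, len(y) // 2), dtype=np.uint8)
    acc = _windowed_accuracies(cum, centres, halfwidth, y, runs, clf)[0]
    return AccuracyMap(values=acc, times=epochs.times[centres])


def tfce_series(stats: np.ndarray, spec: TfceSpec | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a 1-D statistic series.

    ``TFCE(p) = sum over heights h in (0, s(p)] of e(h)^E * h^H * dh``
    where ``e(h)`` is the length of the contiguous supra-threshold run
    containing p.  The input should be chance-centred (accuracy - 0.5);
    only positive excursions score (one-sided).
    """
    spec = spec if spec is not None else TfceSpec()
    s = np.asarray(stats, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValidationError("statistic series must be finite")
    top = float(s.max(initial=0.0))
    if top <= 0:
        return np.zeros_like(s)
    dh = spec.dh if spec.dh is not None else top / 100.0
    n_steps = int(np.ceil(top / dh))
    out = np.zeros_like(s)
    for step in range(n_steps):
        h_lo = dh * step
        h = h_lo + 0.5 * dh  # midpoint rule
        mask = s > h_lo
        if not mask.any():
            break
        padded = np.concatenate(([False], mask, [False]))
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1])
        # each point integrates only up to its own height: the top cell
        # contributes a partial step min(dh, s - h_lo)
        weight = np.minimum(dh, s - h_lo)
        for a, b in zip(starts, ends):
            out[a:b] += (b - a) ** spec.E * h**spec.H * weight[a:b]
    return out


def maxstat_significance(
    observed_tfce: np.ndarray, null_tfce_maxima: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Timepoints whose TFCE exceeds 95% of the permutation maxima."""
    null = np.asarray(null_tfce_maxima, dtype=float)
    if null.size == 0:
        raise ValidationError("null maxima must be non-empty")
    obs = np.asarray(observed_tfce, dtype=float)
    # exact finite-permutation rule (see decode_significance): at 1000
    # permutations and alpha = 0.05 this is "larger than 95% of the null"
    need = int(np.ceil((1.0 - alpha) * (null.size + 1)))
    n_below = (null[None, :] < obs[:, None]).sum(axis=1)
    return n_below >= need


@dataclass
class TimeResolvedResult:
    """Time-resolved decoding with TFCE max-statistic inference.

    ``significant`` marks centres (within the analysis window) whose
    observed TFCE exceeds the null maxima's 95th percentile;
    ``significant_any`` is the subject-level detection flag.
    """

    map: AccuracyMap
    analysis_times: np.ndarray
    tfce_observed: np.ndarray
    null_tfce_maxima: np.ndarray
    significant: np.ndarray
    n_permutations: int

    @property
    def significant_any(self) -> bool:
        return bool(self.significant.any())


def time_resolved_inference(
    epochs: EpochSet,
    clf: ClassifierSpec | None = None,
    halfwidth: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
    tfce: TfceSpec | None = None,
    alpha: float = 0.05,
) -> TimeResolvedResult:
    """Time-resolved decoding with pairing-preserving permutation TFCE test.

    The same within-pair label flips are applied across all time points of
    a permutation, TFCE is applied per permutation to the chance-centred
    accuracy series over the analysis window (post-onset centres when the
    baseline is excluded), and the maximum TFCE per permutation forms the
    corrected null.
    """
    clf = clf if clf is not None else ClassifierSpec()
    tfce = tfce if tfce is not None else TfceSpec()
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    order, pids, y = _canonical_order(epochs)
    cum = _cumulative_gram(epochs.voltages[order])
    centres = _centres(len(epochs.times), halfwidth)
    flips = _flip_matrix(n_perm, len(pids), seed)
    runs = np.vstack([np.zeros((1, len(pids)), dtype=np.uint8), flips])
    acc = _windowed_accuracies(cum, centres, halfwidth, y, runs, clf)
    times = epochs.times[centres]
    window = times >= 0 if tfce.baseline_excluded else np.ones_like(times, dtype=bool)
    stats = acc[:, window] - 0.5
    tfce_obs = tfce_series(stats[0], tfce)
    null_max = np.array([tfce_series(stats[r], tfce).max(initial=0.0) for r in range(1, len(stats))])
    sig = maxstat_significance(tfce_obs, null_max, alpha)
    return TimeResolvedResult(
        map=AccuracyMap(values=acc[0], times=times),
        analysis_times=times[window],
        tfce_observed=tfce_obs,
        null_tfce_maxima=null_max,
        significant=sig,
        n_permutations=n_perm,
    )


def searchlight_decode(
    epochs: EpochSet,
    montage: Montage,
    clf: ClassifierSpec | None = None,
    n_channels: int = 5,
    halfwidth: int = 5,
) -> AccuracyMap:
    """Channel x time LOTO accuracy map over electrode neighbourhoods.

    For each electrode, features are its ``n_channels``-electrode
    neighbourhood over the 11-sample window.  The maps are exploratory:
    no significance testing is performed on them.
    """
    clf = clf if clf is not None else ClassifierSpec()
    order, _, y = _canonical_order(epochs)
    v = epochs.voltages[order]
    centres = _centres(len(epochs.times), halfwidth)
    runs = np.zeros((1, len(y) // 2), dtype=np.uint8)
    values = np.empty((len(epochs.channels), len(centres)))
    # neighbourhoods are taken within the recorded channel set
    sub = montage.subset(epochs.channels)
    for ci, ch in enumerate(epochs.channels):
        nb = sub.neighbourhood(ch, min(n_channels, sub.n_scalp))
        idx = epochs.channel_indices(nb)
        cum = _cumulative_gram(v[:, idx, :])
        values[ci] = _windowed_accuracies(cum, centres, halfwidth, y, runs, clf)[0]
    return AccuracyMap(values=values, times=epochs.times[centres], channels=epochs.channels)


def window_topographies(
    amap: AccuracyMap, windows: tuple = DEFAULT_TOPO_WINDOWS
) -> np.ndarray:
    """Per-channel mean accuracy over half-open time windows.

    Default: four 200-ms windows spanning 200-1000 ms.  Raises if any
    window contains no map centres.
    """
    if amap.channels is None:
        raise ValidationError("window topographies need a channel x time map")
    out = np.empty((len(amap.channels), len(windows)))
    for w, (lo, hi) in enumerate(windows):
        mask = (amap.times >= lo - 1e-9) & (amap.times < hi - 1e-9)
        if not mask.any():
            raise ValidationError(f"map does not cover the window [{lo}, {hi}) ms")
        out[:, w] = amap.values[:, mask].mean(axis=1)
    return out
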