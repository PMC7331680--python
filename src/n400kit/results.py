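"""Result containers shared by the decoding and ERP analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["DecodingResult", "ClusterResult", "AccuracyMap"]


@dataclass
class DecodingResult:
    """Outcome of a cross-validated decoding analysis on one subject.

    ``accuracy`` is the mean of ``fold_accuracies``.  When a permutation
    null was computed, ``null_accuracies`` holds its accuracies and
    ``p_rank`` / ``p_normal`` / ``effect_size`` / ``significant`` are
    filled in; otherwise they are None.
    """

    accuracy: float
    fold_accuracies: np.ndarray
    null_accuracies: np.ndarray | None = None
    p_rank: float | None = None
    p_normal: float | None = None
    effect_size: float | None = None
    significant: bool | None = None
    n_permutations: int = 0

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=float)
        if not np.all((self.fold_accuracies >= 0) & (self.fold_accuracies <= 1)):
            raise ValidationError("fold accuracies must lie in [0, 1]")
        if abs(self.accuracy - float(np.mean(self.fold_accuracies))) > 1e-9:
            raise ValidationError("accuracy must equal the mean of fold_accuracies")
        if self.null_accuracies is not None:
            self.null_accuracies = np.asarray(self.null_accuracies, dtype=float)
            if not np.all((self.null_accuracies >= 0) & (self.null_accuracies <= 1)):
                raise ValidationError("null accuracies must lie in [0, 1]")


@dataclass
class ClusterResult:
    """Pointwise statistics plus cluster-corrected significance.

    ``clusters`` is a list of ``(start_ms, end_ms, length_samples)`` for
    each run of below-alpha p-values at least ``min_cluster_len`` samples
    long; ``end_ms`` is the time of the last sample in the run.
    """

    times: np.ndarray
    stat_series: np.ndarray
    p_series: np.ndarray
    min_cluster_len: int
    clusters: list
    significant: bool

    def __post_init__(self) -> None:
        for (start, end, length) in self.clusters:
            if length < self.min_cluster_len:
                raise ValidationError("reported cluster shorter than min_cluster_len")
            if start < self.times[0] - 1e-9 or end > self.times[-1] + 1e-9:
                raise ValidationError("cluster bounds outside the analysed window")


@dataclass
class AccuracyMap:
    """Decoding accuracy as a function of time (1-D) or channel x time (2-D).

    ``times`` are the window-centre times (ms) of the valid centres;
    ``channels`` is None for the time-resolved (all-channel) variant.
    """

    values: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if not np.all((self.values >= 0) & (self.values <= 1)):
            raise ValidationError("accuracies must lie in [0, 1]")
        if self.channels is None:
            if self.values.shape != self.times.shape:
                raise ValidationError("1-D map values must match times")
        else:
            if self.values.shape != (len(self.channels), len(self.times)):
                raise ValidationError("2-D map must be channels x times")

    def peak_time(self, smooth: int = 3) -> float:
        """Latency (ms) of the accuracy maximum of a 1-D map.

        The curve is lightly smoothed (``smooth``-point moving average) and
        ties/plateaus at the maximum are resolved by their centroid, which
        makes the estimate robust when accuracy saturates around the peak.
        """
        if self.channels is not None:
            raise ValidationError("peak_time applies to 1-D (time-resolved) maps")
        v = self.values
        if smooth > 1:
            v = np.convolve(v, np.ones(smooth) / smooth, mode="same")
        top = v >= v.max() - 1e-12
        return float(self.times[top].mean())

    def peak_channel(self, time_window: tuple[float, float] | None = None) -> str:
        """Channel whose mean accuracy (optionally within a time window) is
        highest, for 2-D searchlight maps."""
        if self.channels is None:
            raise ValidationError("peak_channel applies to channel x time maps")
        if time_window is None:
            mask = np.ones(len(self.times), dtype=bool)
        else:
            mask = (self.times >= time_window[0]) & (self.times < time_window[1])
            if not mask.any():
                raise ValidationError(f"no map centres inside {time_window}")
        return self.channels[int(np.argmax(self.values[:, mask].mean(axis=1)))]
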