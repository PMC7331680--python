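"""Epoched-EEG containers and single-file HDF5 persistence.

Conventions
-----------
* Voltages are microvolts throughout.
* The epoch time axis is half-open: the default window ``[-100, 1000)`` ms
  around target-word onset contains the sample at 0 ms (the onset) and the
  first sample at or after -100 ms, but not the sample at +1000 ms.  At
  512 Hz this yields 563 samples per epoch.
* Every target pair contributes exactly two trials, one congruent and one
  incongruent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

__all__ = [
    "EpochSet",
    "ContinuousRecording",
    "epoch_times",
    "save_epochs",
    "load_epochs",
    "CONDITIONS",
]

CONDITIONS = ("congruent", "incongruent")


def epoch_times(srate: float, window: tuple[float, float] = (-100.0, 1000.0)) -> np.ndarray:
    """Sample times (ms) for an epoch window at a given sampling rate.

    The window is half-open on the right.  Sample times are integer
    multiples of the sampling period; time 0 (the event sample) is always
    included.  The first sample is the earliest multiple of the period that
    is >= ``window[0]``; the last is the greatest strictly below
    ``window[1]``.
    """
    if window[0] > 0 or window[1] <= 0:
        raise ValidationError(f"window must straddle 0 ms, got {window}")
    step = 1000.0 / srate
    n_pre = int(np.floor(-window[0] / step + 1e-9))
    n_post = int(np.ceil(window[1] / step - 1e-9))
    return (np.arange(-n_pre, n_post)) * step


@dataclass
class EpochSet:
    """Trials x channels x samples voltage array with trial metadata.

    Attributes
    ----------
    voltages
        ``(n_trials, n_channels, n_samples)`` float array, microvolts.
    channels
        Channel names, one per voltage row.
    times
        Per-sample times in ms relative to target onset; uniformly spaced
        at ``1000 / srate``.
    srate
        Sampling rate in Hz.
    condition
        Per-trial label, ``"congruent"`` or ``"incongruent"``.
    pair_id
        Per-trial integer naming the target-word pair; each id occurs
        exactly twice, once per condition.
    rejected
        Per-trial artifact mask (True = rejected).  Non-destructive:
        decoding ignores it, univariate analyses honour it.
    """

    voltages: np.ndarray
    channels: tuple[str, ...]
    times: np.ndarray
    srate: float
    condition: np.ndarray
    pair_id: np.ndarray
    rejected: np.ndarray = None  # type: ignore[assignment]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=np.float64)
        self.channels = tuple(self.channels)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.condition = np.asarray(self.condition, dtype="U11")
        self.pair_id = np.asarray(self.pair_id, dtype=np.int64)
        if self.rejected is None:
            self.rejected = np.zeros(self.voltages.shape[0], dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        v = self.voltages
        if v.ndim != 3:
            raise ValidationError("voltages must be trials x channels x samples")
        n_tr, n_ch, n_s = v.shape
        if len(self.channels) != n_ch:
            raise ValidationError("channels length must match voltages axis 1")
        if self.times.shape != (n_s,):
            raise ValidationError("times length must match voltages axis 2")
        for name, arr in (("condition", self.condition), ("pair_id", self.pair_id),
                          ("rejected", self.rejected)):
            if arr.shape != (n_tr,):
                raise ValidationError(f"{name} length must match number of trials")
        if not np.all(np.isfinite(v)):
            raise ValidationError("voltages must be finite")
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition labels: {sorted(bad)}")
        step = 1000.0 / self.srate
        if n_s > 1:
            diffs = np.diff(self.times)
            if np.any(diffs <= 0) or np.any(np.abs(diffs - step) > 1e-6 * step):
                raise ValidationError(
                    "times must be strictly increasing with uniform spacing 1000/srate"
                )
        # pairing invariant
        for pid in np.unique(self.pair_id):
            conds = self.condition[self.pair_id == pid]
            if len(conds) != 2:
                raise ValidationError(
                    f"pair_id must occur exactly twice (pair {pid} occurs {len(conds)} times)"
                )
            if set(conds) != set(CONDITIONS):
                raise ValidationError(
                    f"pair {pid} must have one trial per condition, got {list(conds)}"
                )

    # -- convenience ------------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.n_trials // 2

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel '{name}' not in epochs") from None

    def channel_indices(self, names) -> np.ndarray:
        return np.array([self.channel_index(n) for n in names], dtype=int)

    def time_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of samples with ``lo <= t < hi`` (ms, half-open)."""
        return (self.times >= lo - 1e-9) & (self.times < hi - 1e-9)

    def accepted(self) -> "EpochSet":
        """Copy restricted to non-rejected trials.

        Only valid when rejection did not break any pair; intended for
        inspection, not for decoding (which ignores the mask).
        """
        keep = ~self.rejected
        return replace(
            self,
            voltages=self.voltages[keep],
            condition=self.condition[keep],
            pair_id=self.pair_id[keep],
            rejected=self.rejected[keep],
        )

    def copy(self) -> "EpochSet":
        return replace(
            self,
            voltages=self.voltages.copy(),
            condition=self.condition.copy(),
            pair_id=self.pair_id.copy(),
            rejected=self.rejected.copy(),
        )


@dataclass
class ContinuousRecording:
    """Continuous multichannel recording with event markers.

    Events are ``(sample_index, condition, pair_id)`` triplets, sorted by
    sample index; each event must leave room for a full epoch window.
    """

    voltages: np.ndarray
    channels: tuple[str, ...]
    srate: float
    events: list  # of (int sample, str condition, int pair_id)

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=np.float64)
        self.channels = tuple(self.channels)
        if self.voltages.ndim != 2:
            raise ValidationError("continuous voltages must be channels x samples")
        if self.voltages.shape[0] != len(self.channels):
            raise ValidationError("channels length must match voltages axis 0")
        samples = [e[0] for e in self.events]
        if samples != sorted(samples):
            raise ValidationError("events must be sorted by sample index")

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel '{name}' not in recording") from None


# -- persistence ----------------------------------------------------------


def save_epochs(epochs: EpochSet, path) -> None:
    """Write an :class:`EpochSet` to a single HDF5 file.

    Voltages are stored as float32 (round-trip is lossless up to float32
    rounding); all metadata round-trips exactly, carried in a JSON block.
    """
    import h5py

    meta = {
        "srate": epochs.srate,
        "subject_id": epochs.subject_id,
        "channels": list(epochs.channels),
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("voltages", data=epochs.voltages.astype(np.float32))
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("condition", data=np.char.encode(epochs.condition, "ascii"))
        f.create_dataset("pair_id", data=epochs.pair_id)
        f.create_dataset("rejected", data=epochs.rejected)
        f.attrs["meta"] = json.dumps(meta)


def load_epochs(path) -> EpochSet:
    """Read an :class:`EpochSet` written by :func:`save_epochs`.

    Raises
    ------
    OSError
        If the file is missing or not readable as HDF5 (the message names
        the path).
    ValidationError
        If the stored metadata violates an :class:`EpochSet` invariant.
    """
    import h5py

    try:
        f = h5py.File(path, "r")
    except (OSError, FileNotFoundError) as exc:
        raise OSError(f"cannot read epochs file '{path}': {exc}") from exc
    with f:
        try:
            meta = json.loads(f.attrs["meta"])
            voltages = f["voltages"][()]
            times = f["times"][()]
            condition = np.char.decode(f["condition"][()], "ascii")
            pair_id = f["pair_id"][()]
            rejected = f["rejected"][()]
        except KeyError as exc:
            raise OSError(f"epochs file '{path}' is corrupt: missing {exc}") from exc
    return EpochSet(
        voltages=voltages,
        channels=tuple(meta["channels"]),
        times=times,
        srate=float(meta["srate"]),
        condition=condition,
        pair_id=pair_id,
        rejected=rejected,
        subject_id=str(meta["subject_id"]),
    )
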