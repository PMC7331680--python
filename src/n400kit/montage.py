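"""Electrode montages: 10-20 channel names, unit-sphere positions, and
nearest-neighbour queries used by the searchlight and by spherical-spline
interpolation.

The bundled default is an idealized 64-channel scalp layout with 10-20 style
names (Fp1 ... O2) plus two mastoid electrodes (M1, M2), with every position
normalised to the unit sphere.  Any montage can be substituted from a CSV
file with columns ``name,x,y,z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ValidationError

__all__ = ["Montage"]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class Montage:
    """A set of named electrodes on the unit sphere.

    Parameters
    ----------
    channel_names
        All electrode names, scalp channels first by convention.
    positions
        ``(n_channels, 3)`` array of unit-norm coordinates.
    mastoid_names
        Names of the two mastoid reference electrodes (may be absent from
        ``channel_names`` if the montage is scalp-only).
    eog_names
        Ocular channels; excluded from the scalp set.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray
    mastoid_names: tuple[str, ...] = ("M1", "M2")
    eog_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValidationError("positions must be an (n, 3) array")
        if pos.shape[0] != len(self.channel_names):
            raise ValidationError("positions and channel_names length mismatch")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            bad = self.channel_names[int(np.argmax(np.abs(norms - 1.0)))]
            raise ValidationError(
                f"positions must have unit norm within {_UNIT_TOL}; '{bad}' does not"
            )

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        path,
        mastoid_names: tuple[str, ...] = ("M1", "M2"),
        eog_names: tuple[str, ...] = (),
    ) -> "Montage":
        """Load a montage from a ``name,x,y,z`` CSV file.

        Positions are renormalised to the unit sphere so that slightly
        off-sphere digitised coordinates are accepted.
        """
        names: list[str] = []
        rows: list[list[float]] = []
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("name"):
                raise ValidationError(f"montage CSV {path} must start with a 'name,x,y,z' header")
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                parts = line.split(",")
                names.append(parts[0])
                rows.append([float(v) for v in parts[1:4]])
        pos = np.asarray(rows, dtype=float)
        pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        return cls(tuple(names), pos, mastoid_names=mastoid_names, eog_names=eog_names)

    @classmethod
    def standard_64(cls) -> "Montage":
        """The bundled idealized 64-channel 10-20 layout plus mastoids."""
        with resources.as_file(
            resources.files("n400kit.data").joinpath("montage64.csv")
        ) as p:
            return cls.from_csv(p)

    # -- queries ----------------------------------------------------------

    @property
    def scalp_names(self) -> tuple[str, ...]:
        excluded = set(self.mastoid_names) | set(self.eog_names)
        return tuple(n for n in self.channel_names if n not in excluded)

    @property
    def n_scalp(self) -> int:
        return len(self.scalp_names)

    def index_of(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel '{name}' not in montage") from None

    def position_of(self, name: str) -> np.ndarray:
        return self.positions[self.index_of(name)]

    def scalp_positions(self) -> np.ndarray:
        idx = [self.index_of(n) for n in self.scalp_names]
        return self.positions[idx]

    def neighbourhood(self, center: str, k: int) -> list[str]:
        """Return ``center`` plus its ``k - 1`` nearest scalp channels.

        Distance is Euclidean (chord) distance on the unit sphere, which
        orders channels identically to great-circle distance.  Exact ties
        are broken by channel-name lexicographic order, so the result is
        deterministic.
        """
        scalp = self.scalp_names
        if center not in scalp:
            raise KeyError(f"channel '{center}' is not a scalp channel of this montage")
        if not 1 <= k <= len(scalp):
            raise ValidationError(f"k must be in [1, {len(scalp)}], got {k}")
        cpos = self.position_of(center)
        dists = np.linalg.norm(self.scalp_positions() - cpos, axis=1)
        order = sorted(range(len(scalp)), key=lambda i: (dists[i], scalp[i]))
        return [scalp[i] for i in order[:k]]

    def subset(self, names: "list[str] | tuple[str, ...]") -> "Montage":
        """A montage restricted to ``names`` (order preserved)."""
        idx = [self.index_of(n) for n in names]
        return Montage(
            tuple(names),
            self.positions[idx],
            mastoid_names=tuple(n for n in self.mastoid_names if n in names),
            eog_names=tuple(n for n in self.eog_names if n in names),
        )
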