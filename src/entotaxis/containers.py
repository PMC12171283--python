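"""Core time-series containers shared across the analysis stages.

Coordinate conventions: the arena frame has the odor source at the origin
and x positive downwind.  Trajectories are stored in millimetres (the unit
of the raw tracking data); plume-model computations run in SI metres, and
the containers expose both views.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped planar positions of the searcher.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing.
    x, y : array of float
        Arena-frame coordinates in millimetres (source at the origin,
        x positive downwind).
    heading_deg : array of float, optional
        Body heading in degrees, if tracked.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("trajectory needs at least one sample")
        if not (t.size == x.size == y.size):
            raise ValueError("t, x, y must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(f"time not strictly increasing at row {bad}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if self.heading_deg is not None:
            h = np.asarray(self.heading_deg, dtype=float)
            if h.size != t.size:
                raise ValueError("heading length mismatch")
            object.__setattr__(self, "heading_deg", h)

    def __len__(self) -> int:
        return self.t.size

    @property
    def xy_mm(self) -> np.ndarray:
        """(n, 2) positions in millimetres."""
        return np.column_stack([self.x, self.y])

    @property
    def xy_m(self) -> np.ndarray:
        """(n, 2) positions in metres."""
        return self.xy_mm / 1000.0

    def position_at(self, times: np.ndarray) -> np.ndarray:
        """Linearly interpolated (n, 2) positions (mm) at ``times``."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        xi = np.interp(times, self.t, self.x)
        yi = np.interp(times, self.t, self.y)
        return np.column_stack([xi, yi])

    def translate(self, dx_mm: float, dy_mm: float) -> "Trajectory":
        return Trajectory(self.t, self.x + dx_mm, self.y + dy_mm,
                          self.heading_deg)


@dataclass(frozen=True)
class EncounterSeries:
    """Odor-detection history: encounter times within an observation window.

    The complement of the (instantaneous) detection times in
    ``[t_start, t_end]`` forms the non-detection intervals used by the
    likelihood.  Positions are the searcher's location at each encounter,
    in millimetres; amplitudes (mV) are optional and carried through from
    EAG peak detection.
    """

    times: np.ndarray
    t_start: float
    t_end: float
    positions_mm: np.ndarray | None = None
    amplitudes_mv: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1:
            raise ValueError("times must be 1-D")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("encounter times must be strictly increasing")
        if self.t_end < self.t_start:
            raise ValueError("t_end < t_start")
        if times.size and (times[0] < self.t_start or times[-1] > self.t_end):
            raise ValueError("encounter times outside observation window")
        object.__setattr__(self, "times", times)
        if self.positions_mm is not None:
            p = np.asarray(self.positions_mm, dtype=float).reshape(-1, 2)
            if p.shape[0] != times.size:
                raise ValueError("positions length mismatch")
            object.__setattr__(self, "positions_mm", p)
        if self.amplitudes_mv is not None:
            a = np.asarray(self.amplitudes_mv, dtype=float)
            if a.size != times.size:
                raise ValueError("amplitudes length mismatch")
            object.__setattr__(self, "amplitudes_mv", a)

    def __len__(self) -> int:
        return self.times.size

    def until(self, t: float) -> "EncounterSeries":
        """Restrict the history to encounters at or before time ``t``."""
        keep = self.times <= t
        return EncounterSeries(
            self.times[keep],
            self.t_start,
            min(self.t_end, t),
            None if self.positions_mm is None else self.positions_mm[keep],
            None if self.amplitudes_mv is None else self.amplitudes_mv[keep],
        )
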