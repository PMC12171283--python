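"""Behavioral metrics from fused trajectory + EAG streams.

Fuses the tracked trajectory (mm, arena frame, source at origin) with the
odor-encounter series onto a common time base, then computes translational
speed, the amplitude-velocity relation (does the animal surge when it
smells more?), wind-frame movement ratios (upwind / downwind / crosswind
time fractions), cast-like zigzag detection, localization outcome against
the success disc, and spatially binned intensity maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EncounterSeries, Trajectory

__all__ = [
    "FusedSeries",
    "LocalizationOutcome",
    "AmplitudeVelocitySummary",
    "WindFrameRatios",
    "CastSegment",
    "IntensityMap",
    "fuse",
    "translational_velocity",
    "amplitude_velocity_relation",
    "wind_frame_ratios",
    "detect_casts",
    "localization_outcome",
    "intensity_map",
]


@dataclass(frozen=True)
class FusedSeries:
    """Trajectory + encounter streams on a uniform time base.

    ``intensity`` / ``amplitude_mv`` carry the value of the most recent
    encounter at or before each sample (zero-order hold; 0 before the
    first encounter).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    speed: np.ndarray          # mm/s
    heading_deg: np.ndarray    # direction of motion, arena frame
    intensity: np.ndarray
    amplitude_mv: np.ndarray
    dt: float

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class LocalizationOutcome:
    success: bool
    time_to_source_s: float   # NaN on failure
    end_distance_mm: float


@dataclass(frozen=True)
class AmplitudeVelocitySummary:
    threshold_mv: float
    mean_speed_above: float
    mean_speed_below: float
    n_above: int
    n_below: int

    @property
    def empty_group(self) -> bool:
        return self.n_above == 0 or self.n_below == 0


@dataclass(frozen=True)
class WindFrameRatios:
    upwind: float
    downwind: float
    crosswind: float
    n_samples: int


@dataclass(frozen=True)
class CastSegment:
    t_start: float
    t_end: float
    n_reversals: int


@dataclass(frozen=True)
class IntensityMap:
    x_edges: np.ndarray
    y_edges: np.ndarray
    mean_intensity: np.ndarray  # NaN where never visited
    occupancy: np.ndarray


def _hold_values(sample_t: np.ndarray, event_t: np.ndarray,
                 event_v: np.ndarray) -> np.ndarray:
    """Zero-order hold of event values onto sample times (0 before first)."""
    out = np.zeros(sample_t.size)
    if event_t.size:
        idx = np.searchsorted(event_t, sample_t, side="right") - 1
        has = idx >= 0
        out[has] = event_v[idx[has]]
    return out


def _speed_heading(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                   smooth_window_s: float = 0.1
                   ) -> tuple[np.ndarray, np.ndarray]:
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    if smooth_window_s > 0 and t.size > 2:
        dt = float(np.median(np.diff(t)))
        n = max(1, int(round(smooth_window_s / dt)))
        if n > 1:
            k = np.ones(n) / n
            # edge-padded moving average keeps endpoints unbiased
            vx = np.convolve(np.pad(vx, (n // 2, n - 1 - n // 2), mode="edge"),
                             k, mode="valid")
            vy = np.convolve(np.pad(vy, (n // 2, n - 1 - n // 2), mode="edge"),
                             k, mode="valid")
    speed = np.hypot(vx, vy)
    heading = np.degrees(np.arctan2(vy, vx))
    return speed, heading


def fuse(traj: Trajectory, enc: EncounterSeries | None = None,
         dt_s: float = 0.01, smooth_window_s: float = 0.1) -> FusedSeries:
    """Resample the trajectory onto a uniform grid and attach encounters.

    Positions are linearly interpolated at ``dt_s`` (default 0.01 s, the
    camera frame period); encounter intensity and raw amplitude are held
    from the latest encounter at or before each sample.
    """
    if len(traj) < 2:
        raise ValueError("need at least two trajectory samples to fuse")
    t0, t1 = float(traj.t[0]), float(traj.t[-1])
    if enc is not None and len(enc):
        if enc.times[0] > t1 or enc.times[-1] < t0:
            raise ValueError("trajectory and encounter time ranges disjoint")
    n = int(np.floor((t1 - t0) / dt_s + 1e-9)) + 1
    t = t0 + dt_s * np.arange(n)
    pos = traj.position_at(t)
    speed, heading = _speed_heading(t, pos[:, 0], pos[:, 1], smooth_window_s)
    if enc is not None and len(enc):
        amps = (enc.amplitudes_mv if enc.amplitudes_mv is not None
                else np.ones(len(enc)))
        from .eag import normalize_intensity
        intens = normalize_intensity(amps, times=enc.times).intensity
        amplitude = _hold_values(t, enc.times, np.asarray(amps, dtype=float))
        intensity = _hold_values(t, enc.times, intens)
    else:
        amplitude = np.zeros(n)
        intensity = np.zeros(n)
    return FusedSeries(t=t, x=pos[:, 0], y=pos[:, 1], speed=speed,
                       heading_deg=heading, intensity=intensity,
                       amplitude_mv=amplitude, dt=dt_s)


def translational_velocity(fused: FusedSeries,
                           smooth_window_s: float = 0.1) -> np.ndarray:
    """Central-difference speed (mm/s), moving-average smoothed."""
    if len(fused) < 2:
        raise ValueError("need at least two samples")
    speed, _ = _speed_heading(fused.t, fused.x, fused.y, smooth_window_s)
    return speed


def amplitude_velocity_relation(fused: FusedSeries,
                                threshold_mv: float = 1.0
                                ) -> AmplitudeVelocitySummary:
    """Mean speed when the most recent EAG amplitude is above vs below
    ``threshold_mv`` (default 1 mV, where walking moths visibly surge)."""
    above = fused.amplitude_mv > threshold_mv
    n_above = int(np.sum(above))
    n_below = int(above.size - n_above)
    mean_above = float(np.mean(fused.speed[above])) if n_above else float("nan")
    mean_below = float(np.mean(fused.speed[~above])) if n_below else float("nan")
    return AmplitudeVelocitySummary(threshold_mv=threshold_mv,
                                    mean_speed_above=mean_above,
                                    mean_speed_below=mean_below,
                                    n_above=n_above, n_below=n_below)


def _angle_to_upwind(heading_deg: np.ndarray,
                     wind_axis: np.ndarray) -> np.ndarray:
    """Unsigned angle (deg, 0..180) between motion heading and upwind."""
    upwind = -np.asarray(wind_axis, dtype=float)
    upwind_deg = np.degrees(np.arctan2(upwind[1], upwind[0]))
    d = np.abs((heading_deg - upwind_deg + 180.0) % 360.0 - 180.0)
    return d


def wind_frame_ratios(fused: FusedSeries,
                      wind_axis: np.ndarray = (1.0, 0.0),
                      min_speed_mm_s: float = 2.0,
                      sector_half_width_deg: float = 45.0
                      ) -> WindFrameRatios:
    """Time fractions of upwind / downwind / crosswind movement.

    Samples moving slower than ``min_speed_mm_s`` are excluded
    (stationary jitter has no meaningful heading).  Upwind means motion
    within ``sector_half_width_deg`` of the into-wind direction; downwind
    the mirror sector; everything else is crosswind.  Fractions sum to 1.
    """
    moving = fused.speed > min_speed_mm_s
    if not np.any(moving):
        raise ValueError("no samples above the minimum-motion threshold")
    ang = _angle_to_upwind(fused.heading_deg[moving], wind_axis)
    n = ang.size
    up = float(np.sum(ang <= sector_half_width_deg)) / n
    down = float(np.sum(ang >= 180.0 - sector_half_width_deg)) / n
    return WindFrameRatios(upwind=up, downwind=down,
                           crosswind=1.0 - up - down, n_samples=n)


def detect_casts(fused: FusedSeries, wind_axis: np.ndarray = (1.0, 0.0),
                 window_s: float = 3.0, min_reversals: int = 2,
                 max_upwind_progress: float = 0.2,
                 min_speed_mm_s: float = 2.0
                 ) -> tuple[list[CastSegment], bool]:
    """Find cast-like zigzag segments: windows with repeated crosswind
    velocity reversals and little net upwind progress.

    Operational definition (all thresholds configurable): a sliding
    window of ``window_s`` is cast-like when the crosswind velocity
    reverses sign at least ``min_reversals`` times and the net upwind
    progress is below ``max_upwind_progress`` of the path length inside
    the window.  Returns the merged segments and a per-trial flag.
    """
    axis = np.asarray(wind_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    cross = np.array([-axis[1], axis[0]])
    pos = np.column_stack([fused.x, fused.y])
    v = np.gradient(pos, fused.t, axis=0)
    v_cross = v @ cross
    v_up = -(v @ axis)  # positive when moving upwind
    speed = fused.speed
    n_win = max(2, int(round(window_s / fused.dt)))
    segments: list[CastSegment] = []
    i = 0
    while i + n_win <= len(fused):
        sl = slice(i, i + n_win)
        moving = speed[sl] > min_speed_mm_s
        if np.sum(moving) > n_win // 2:
            vc = v_cross[sl][moving]
            signs = np.sign(vc[np.abs(vc) > 1e-9])
            reversals = int(np.sum(signs[1:] != signs[:-1])) if signs.size > 1 else 0
            path = float(np.sum(speed[sl]) * fused.dt)
            up_prog = float(np.sum(v_up[sl]) * fused.dt)
            if (reversals >= min_reversals and path > 0
                    and up_prog < max_upwind_progress * path):
                seg = CastSegment(t_start=float(fused.t[i]),
                                  t_end=float(fused.t[i + n_win - 1]),
                                  n_reversals=reversals)
                if segments and seg.t_start <= segments[-1].t_end:
                    last = segments[-1]
                    segments[-1] = CastSegment(last.t_start, seg.t_end,
                                               max(last.n_reversals,
                                                   seg.n_reversals))
                else:
                    segments.append(seg)
        i += max(1, n_win // 4)
    return segments, bool(segments)


def localization_outcome(traj: Trajectory,
                         source_mm: np.ndarray = (0.0, 0.0),
                         radius_mm: float = 10.0,
                         timeout_s: float = 180.0) -> LocalizationOutcome:
    """First passage into the success disc, or failure at timeout.

    Success means the trajectory enters the ``radius_mm`` disc around the
    source (default 10 mm) before ``timeout_s`` (default 180 s) measured
    from the first sample.
    """
    src = np.asarray(source_mm, dtype=float).reshape(2)
    dist = np.linalg.norm(traj.xy_mm - src, axis=1)
    rel_t = traj.t - traj.t[0]
    in_time = rel_t <= timeout_s
    hit = np.flatnonzero((dist <= radius_mm) & in_time)
    if hit.size:
        return LocalizationOutcome(success=True,
                                   time_to_source_s=float(rel_t[hit[0]]),
                                   end_distance_mm=float(dist[hit[0]]))
    last = int(np.flatnonzero(in_time)[-1]) if np.any(in_time) else 0
    return LocalizationOutcome(success=False, time_to_source_s=float("nan"),
                               end_distance_mm=float(dist[last]))


def intensity_map(fused: FusedSeries, bin_mm: float = 10.0,
                  x_range_mm: tuple[float, float] | None = None,
                  y_range_mm: tuple[float, float] | None = None
                  ) -> IntensityMap:
    """Arena-binned mean encounter intensity and occupancy.

    Bins never visited hold NaN intensity and zero occupancy.
    """
    def edges(vals, rng):
        if rng is None:
            lo = np.floor(np.min(vals) / bin_mm) * bin_mm
            hi = np.ceil(np.max(vals) / bin_mm) * bin_mm
            hi = hi if hi > lo else lo + bin_mm
        else:
            lo, hi = rng
        return np.arange(lo, hi + 0.5 * bin_mm, bin_mm)

    xe = edges(fused.x, x_range_mm)
    ye = edges(fused.y, y_range_mm)
    occ, _, _ = np.histogram2d(fused.x, fused.y, bins=[xe, ye])
    tot, _, _ = np.histogram2d(fused.x, fused.y, bins=[xe, ye],
                               weights=fused.intensity)
    with np.errstate(invalid="ignore"):
        mean = np.where(occ > 0, tot / np.maximum(occ, 1), np.nan)
    return IntensityMap(x_edges=xe, y_edges=ye, mean_intensity=mean,
                        occupancy=occ.astype(int))
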