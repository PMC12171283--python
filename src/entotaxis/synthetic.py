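"""Synthetic trajectories, encounter series, and EAG traces with ground
truth, emulating a walking male silk moth localizing a pulsed pheromone
source in wind.

The default scenario reproduces the standard free-walking assay: a source
at the arena origin emitting 1 Hz odor pulses (0.2 s on / 0.8 s off) into
a 0.6 m/s wind, the moth starting 150 mm downwind, success within a 10 mm
radius, 180 s timeout.  Encounters are drawn from the advection-diffusion
rate model (:mod:`entotaxis.plume`) by Poisson thinning; the agent is a
surge/cast state machine (straight fast upwind surges after each
encounter, growing crosswind zigzags otherwise) with the published
kinematic caps (mean speed 15 mm/s, max 32.8 mm/s, max turn rate
1.0 rad/s); the EAG synthesizer convolves encounters with a
fast-rise/slow-decay kernel under multiplicative adaptation (depression
per encounter, ~5 s recovery) plus noise and slow drift.

Every routine is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .containers import EncounterSeries, Trajectory
from .eag import EAGTrace
from .plume import PlumeParameters, encounter_rate

__all__ = [
    "BehaviorParams",
    "EAGKernelParams",
    "StimulusSchedule",
    "ScenarioConfig",
    "ScenarioTruth",
    "simulate_encounters",
    "simulate_moth",
    "synthesize_eag",
    "generate_scenario",
    "adaptation_fixed_point",
    "filtered_peak_lag",
    "survey_trajectory",
]


@dataclass(frozen=True)
class StimulusSchedule:
    """Pulsed odor release: 1 Hz, 0.2 s on / 0.8 s off by default."""

    rate_hz: float = 1.0
    on_s: float = 0.2

    @property
    def period_s(self) -> float:
        return 1.0 / self.rate_hz


@dataclass(frozen=True)
class BehaviorParams:
    """Surge / cast / loop controller parameters (mm, s, rad).

    The agent follows the walking-silkmoth behavioral program: a fresh
    odor encounter triggers a straight upwind SURGE; after the surge it
    CASTs (crosswind zigzag with growing half-period); without further
    contact it settles into LOOPing — an outward-growing orbit around
    the point where odor was last found, which systematically sweeps the
    surrounding area.  Surge triggering is gated by a peripheral
    adaptation state (depression per encounter, seconds-scale recovery):
    sustained rapid stimulation near the source suppresses fresh surges,
    so the moth stops over-shooting and lets the loop sweep find the
    source — the same adaptation the EAG synthesizer models.
    """

    mean_speed_mm_s: float = 15.0
    surge_speed_mm_s: float = 30.0
    loop_speed_mm_s: float = 20.0
    max_speed_mm_s: float = 32.8
    max_turn_rate_rad_s: float = 1.0
    surge_duration_s: float = 2.5
    surge_heading_jitter_rad: float = 0.08
    initial_heading_spread_rad: float = 0.25
    cast_duration_s: float = 1.0
    cast_half_period_s: float = 1.0
    cast_growth: float = 1.3
    cast_max_half_period_s: float = 4.0
    loop_radius0_mm: float = 20.0
    loop_pitch_mm: float = 15.0
    loop_radius_max_mm: float = 70.0
    anchor_fraction: float = 0.4
    adaptation_depression: float = 0.6
    adaptation_recovery_s: float = 5.0
    surge_threshold: float = 0.85

    def __post_init__(self) -> None:
        if self.mean_speed_mm_s > self.max_speed_mm_s \
                or self.surge_speed_mm_s > self.max_speed_mm_s \
                or self.loop_speed_mm_s > self.max_speed_mm_s:
            raise ValueError("commanded speeds exceed the maximum speed")
        for name in ("surge_duration_s", "cast_half_period_s",
                     "max_turn_rate_rad_s", "loop_radius0_mm",
                     "loop_pitch_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.adaptation_depression <= 1:
            raise ValueError("adaptation_depression must be in (0, 1]")


@dataclass(frozen=True)
class EAGKernelParams:
    """EAG response kernel and adaptation dynamics.

    The single-response kernel is a peak-normalized difference of
    exponentials (rise 2 ms, decay 150 ms by default; the onset-to-peak
    time is tau_r*tau_d/(tau_d-tau_r)*ln(tau_d/tau_r) ~ 8.7 ms, inside
    the <10 ms response-time envelope, with >100 ms recovery).  Successive responses are scaled
    by an adaptation state ``s``: after each encounter ``s <- s * rho``
    (``depression``), relaxing back to 1 with ``recovery_s`` (5 s).
    """

    rise_s: float = 0.002
    decay_s: float = 0.150
    base_amplitude_mv: float = 1.0
    depression: float = 0.7
    recovery_s: float = 5.0
    noise_sd_mv: float = 0.02
    drift_amplitude_mv: float = 0.05
    drift_period_s: float = 30.0
    polarity: float = -1.0   # physiological deflections are negative-going

    def __post_init__(self) -> None:
        for name in ("rise_s", "decay_s", "base_amplitude_mv", "recovery_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.depression <= 1:
            raise ValueError("depression must be in (0, 1]")
        if self.noise_sd_mv < 0 or self.drift_amplitude_mv < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def peak_lag_s(self) -> float:
        """Time from encounter to kernel peak."""
        tr, td = self.rise_s, self.decay_s
        return tr * td / (td - tr) * float(np.log(td / tr))


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic localization trial."""

    plume: PlumeParameters = field(default_factory=PlumeParameters)
    schedule: StimulusSchedule = field(default_factory=StimulusSchedule)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    kernel: EAGKernelParams = field(default_factory=EAGKernelParams)
    start_mm: tuple[float, float] = (150.0, 0.0)
    duration_s: float = 180.0
    success_radius_mm: float = 10.0
    control_dt_s: float = 0.01   # 100 Hz control / tracking rate
    gate_to_schedule: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["plume"]["wind_axis"] = list(map(float, self.plume.wind_axis))
        d["plume"]["r0"] = list(map(float, self.plume.r0))
        d["start_mm"] = list(self.start_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "plume" in d:
            p = dict(d["plume"])
            for k in ("wind_axis", "r0"):
                if k in p:
                    p[k] = np.asarray(p[k], dtype=float)
            d["plume"] = PlumeParameters(**p)
        for key, typ in (("schedule", StimulusSchedule),
                         ("behavior", BehaviorParams),
                         ("kernel", EAGKernelParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "start_mm" in d:
            d["start_mm"] = tuple(d["start_mm"])
        return cls(**d)


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth of a synthetic run, for recovery tests."""

    source_m: tuple[float, float]
    encounter_times: np.ndarray
    encounter_amplitudes_mv: np.ndarray
    seed: int
    config: dict

    def to_json_dict(self) -> dict:
        return {
            "source_m": list(self.source_m),
            "encounter_times_s": [float(t) for t in self.encounter_times],
            "encounter_amplitudes_mv":
                [float(a) for a in self.encounter_amplitudes_mv],
            "seed": self.seed,
            "config": self.config,
        }


def _schedule_open(t: np.ndarray, schedule: StimulusSchedule,
                   delay_s: np.ndarray | float) -> np.ndarray:
    """Whether a puff released ``delay_s`` earlier is passing the sensor."""
    phase = np.mod(t - delay_s, schedule.period_s)
    return (phase >= 0) & (phase < schedule.on_s)


def simulate_encounters(traj: Trajectory, plume: PlumeParameters,
                        seed: int, schedule: StimulusSchedule | None = None,
                        t_start: float | None = None,
                        t_end: float | None = None) -> np.ndarray:
    """Draw encounter times from the inhomogeneous Poisson rate
    R(r(t) | r0) along the trajectory, by thinning.

    When a ``schedule`` is given, encounters are additionally gated to
    puff-arrival windows delayed by the advection time (downwind
    distance / W); by default the process is ungated, matching the
    Poisson assumption of the likelihood.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    t0 = traj.t[0] if t_start is None else float(t_start)
    t1 = traj.t[-1] if t_end is None else float(t_end)
    sample_rates = encounter_rate(traj.xy_m, plume)
    r_max = 1.5 * float(np.max(sample_rates))
    if r_max <= 0:
        return np.empty(0)
    times = []
    t = t0
    while True:
        t = t + rng.exponential(1.0 / r_max)
        if t > t1:
            break
        pos_m = traj.position_at(t)[0] / 1000.0
        rate = float(encounter_rate(pos_m, plume))
        if schedule is not None and plume.W > 0:
            s = float((pos_m - plume.r0) @ plume.wind_axis)
            delay = max(s, 0.0) / plume.W
            if not _schedule_open(np.array([t]), schedule, delay)[0]:
                rate = 0.0
        if rng.random() < rate / r_max:
            times.append(t)
    return np.asarray(times)


def simulate_moth(config: ScenarioConfig, seed: int | None = None,
                  force_encounter_prob: float | None = None
                  ) -> tuple[Trajectory, EncounterSeries]:
    """Closed-loop surge/cast/loop agent driven by online encounter draws.

    The agent runs at the control rate (100 Hz).  Each step an encounter
    is drawn from the plume's rate model (per-step Bernoulli with
    p = 1 - exp(-R dt), the discrete equivalent of Poisson thinning).
    A fresh encounter — one arriving with the adaptation state above
    ``surge_threshold`` — triggers a straight fast upwind SURGE; the
    surge decays into a crosswind CAST and then into a LOOP, an
    outward-growing orbit (constant sweep pitch) anchored part-way back
    along the last surge.  Adapted encounters re-anchor the loop at the
    contact point instead of surging.  Turn rate and speed respect the
    published caps at every step; the run stops at the success radius or
    the timeout.

    ``force_encounter_prob`` overrides the per-step encounter probability
    (degenerate controls: 1.0 with no depression forces continuous
    surging; 0.0 yields pure casting/looping).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    b = config.behavior
    plume = config.plume
    dt = config.control_dt_s
    n_max = int(round(config.duration_s / dt)) + 1
    upwind = -plume.wind_axis
    up_ang = float(np.arctan2(upwind[1], upwind[0]))
    cross_ang = up_ang + np.pi / 2.0
    src_mm = plume.r0 * 1000.0

    pos = np.array(config.start_mm, dtype=float)
    heading = up_ang + rng.uniform(-b.initial_heading_spread_rad,
                                   b.initial_heading_spread_rad)
    target = heading
    mode = "cast"
    surge_left = 0.0
    cast_sign = 1.0 if rng.random() < 0.5 else -1.0
    cast_half = b.cast_half_period_s
    cast_left = 0.5 * cast_half   # first excursion halved, recentered
    cast_time_left = b.cast_duration_s
    loop_dir = 1.0
    loop_r = b.loop_radius0_mm
    anchor = pos.copy()
    surge_start = pos.copy()
    s_ad = 1.0   # peripheral adaptation state
    speed = b.mean_speed_mm_s

    ts = np.empty(n_max)
    xs = np.empty(n_max)
    ys = np.empty(n_max)
    enc_t: list[float] = []
    enc_pos: list[np.ndarray] = []
    n = 0
    for i in range(n_max):
        t = i * dt
        ts[n], xs[n], ys[n] = t, pos[0], pos[1]
        n += 1
        if np.linalg.norm(pos - src_mm) <= config.success_radius_mm:
            break
        s_ad = 1.0 - (1.0 - s_ad) * np.exp(-dt / b.adaptation_recovery_s)
        if force_encounter_prob is not None:
            p_enc = force_encounter_prob
        else:
            rate = float(encounter_rate(pos / 1000.0, plume))
            if config.gate_to_schedule and plume.W > 0:
                s_down = float((pos / 1000.0 - plume.r0) @ plume.wind_axis)
                delay = max(s_down, 0.0) / plume.W
                if not _schedule_open(np.array([t]), config.schedule,
                                      delay)[0]:
                    rate = 0.0
            p_enc = -np.expm1(-rate * dt)
        if rng.random() < p_enc:
            enc_t.append(t)
            enc_pos.append(pos.copy())
            fresh = s_ad >= b.surge_threshold
            s_ad *= b.adaptation_depression
            if fresh:
                target = up_ang + b.surge_heading_jitter_rad \
                    * rng.standard_normal()
                mode = "surge"
                surge_left = b.surge_duration_s
                cast_half = b.cast_half_period_s
                cast_left = 0.5 * cast_half
                surge_start = pos.copy()
            else:
                # adapted contact: recenter the local search here
                anchor = pos.copy()
                loop_r = b.loop_radius0_mm
        if mode == "surge":
            speed = b.surge_speed_mm_s
            surge_left -= dt
            if surge_left <= 0:
                mode = "cast"
                cast_time_left = b.cast_duration_s
                cast_sign = 1.0 if rng.random() < 0.5 else -1.0
                anchor = surge_start + b.anchor_fraction * (pos - surge_start)
        elif mode == "cast":
            target = cross_ang if cast_sign > 0 else cross_ang + np.pi
            speed = b.mean_speed_mm_s
            cast_left -= dt
            cast_time_left -= dt
            if cast_left <= 0:
                cast_sign = -cast_sign
                cast_half = min(cast_half * b.cast_growth,
                                b.cast_max_half_period_s)
                cast_left = cast_half
            if cast_time_left <= 0:
                mode = "loop"
                loop_dir = 1.0 if rng.random() < 0.5 else -1.0
                loop_r = b.loop_radius0_mm
        if mode == "loop":
            # grow the orbit radius at constant sweep pitch per lap
            speed = b.loop_speed_mm_s
            loop_r = min(np.sqrt(loop_r ** 2 + 2 * b.loop_pitch_mm
                                 * speed / (2 * np.pi) * dt),
                         b.loop_radius_max_mm)
            dvec = pos - anchor
            dr = float(np.hypot(dvec[0], dvec[1]))
            radial = np.arctan2(dvec[1], dvec[0]) if dr > 1e-6 else heading
            err = np.clip((dr - loop_r) / 20.0, -1.0, 1.0)
            target = radial + loop_dir * (np.pi / 2 + err * np.pi / 4)
        ang_err = (target - heading + np.pi) % (2 * np.pi) - np.pi
        if mode == "cast" and not enc_t and ang_err != 0.0:
            # appetitive (pre-stimulus) zigzag: reversals swing through
            # the downwind side, never through the upwind heading
            rel_h = (heading - up_ang) % (2 * np.pi)
            lo, hi = sorted([0.0, ang_err])
            # upwind lies at relative angle 0 (mod 2pi): the swept arc
            # [heading, heading+err] contains it iff 2pi*k - rel_h in
            # (lo, hi) for some integer k
            crosses_up = any(lo < k * 2 * np.pi - rel_h < hi
                             for k in (-1, 0, 1))
            if crosses_up:
                ang_err -= np.sign(ang_err) * 2 * np.pi
        heading += np.clip(ang_err, -b.max_turn_rate_rad_s * dt,
                           b.max_turn_rate_rad_s * dt)
        v = min(speed, b.max_speed_mm_s)
        pos = pos + v * dt * np.array([np.cos(heading), np.sin(heading)])
        pos = np.clip(pos, -750.0, 750.0)   # arena walls (1.5 x 1.5 m)

    traj = Trajectory(ts[:n], xs[:n], ys[:n])
    enc = EncounterSeries(np.asarray(enc_t), float(ts[0]), float(ts[n - 1]),
                          positions_mm=(np.asarray(enc_pos).reshape(-1, 2)
                                        if enc_t else None))
    return traj, enc


def survey_trajectory(extent_mm: float = 30.0, spacing_mm: float = 8.0,
                      speed_mm_s: float = 40.0, duration_s: float = 60.0,
                      dt_s: float = 0.05,
                      center_mm: tuple[float, float] = (0.0, 0.0)
                      ) -> Trajectory:
    """Space-filling boustrophedon (raster) trajectory for source-recovery
    tests: parallel sweeps across a square around ``center_mm``, repeated
    until ``duration_s``.

    Not a moth — a calibration path that samples the rate field densely
    and evenly, the way one would validate the estimator with a scanned
    sensor.
    """
    ys = np.arange(-extent_mm, extent_mm + 1e-9, spacing_mm)
    pts = []
    d = 1
    for y in ys:
        pts.append((d * -extent_mm, y))
        pts.append((d * extent_mm, y))
        d = -d
    pts = np.asarray(pts, dtype=float) + np.asarray(center_mm, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.arange(0.0, duration_s + 1e-9, dt_s)
    dist = (speed_mm_s * t) % s[-1]
    return Trajectory(t, np.interp(dist, s, pts[:, 0]),
                      np.interp(dist, s, pts[:, 1]))


def filtered_peak_lag(kernel: EAGKernelParams, cutoff_hz: float = 10.0,
                      fs: float = 1000.0, order: int = 4) -> float:
    """Latency from odor arrival to the peak of the low-pass-filtered
    response kernel (s).

    Peak detection on a filtered trace reports the lagged peak; for a
    characterized kernel this systematic latency can be computed once
    (the in-vivo analogue is a static single-puff calibration) and
    subtracted via ``detect_encounters(..., peak_lag_s=...)``.
    """
    from scipy import signal as sp_signal
    n = int(round(2.0 * fs))
    t = np.arange(n) / fs
    g = np.exp(-t / kernel.decay_s) - np.exp(-t / kernel.rise_s)
    pad = np.zeros(n)  # kernel centered so filtfilt edges stay clean
    x = np.concatenate([pad, g / np.max(g), pad])
    sos = sp_signal.butter(order, cutoff_hz, btype="low", fs=fs,
                           output="sos")
    y = sp_signal.sosfiltfilt(sos, x)
    return float((np.argmax(y) - n) / fs)


def adaptation_fixed_point(k: EAGKernelParams, interval_s: float) -> float:
    """Fixed point of the depression/recovery recursion under periodic
    stimulation at the given interval.

    The state obeys ``s_{k+1} = 1 - (1 - s_k * rho) * exp(-dt/tau)``; its
    fixed point is ``(1 - e) / (1 - rho * e)`` with
    ``e = exp(-dt/tau)``.
    """
    e = float(np.exp(-interval_s / k.recovery_s))
    return (1.0 - e) / (1.0 - k.depression * e)


def _encounter_amplitudes(times: np.ndarray,
                          k: EAGKernelParams) -> np.ndarray:
    """Adaptation-state amplitudes A_i = A0 * s_i along the encounter
    sequence (s starts at 1, depresses by rho per encounter, relaxes to 1
    with the recovery constant)."""
    amps = np.empty(times.size)
    s = 1.0
    for i, t in enumerate(times):
        if i > 0:
            dt = t - times[i - 1]
            s = 1.0 - (1.0 - s) * np.exp(-dt / k.recovery_s)
        amps[i] = k.base_amplitude_mv * s
        s = s * k.depression
    return amps


def synthesize_eag(encounter_times: np.ndarray,
                   kernel: EAGKernelParams,
                   duration_s: float,
                   seed: int,
                   fs: float = 1000.0,
                   source_m: tuple[float, float] = (0.0, 0.0),
                   config_echo: dict | None = None
                   ) -> tuple[EAGTrace, ScenarioTruth]:
    """Render an EAG trace from encounter times: adapted response kernels
    plus Gaussian noise and slow sinusoidal baseline drift, at 1 kHz.

    Returns the trace and the ground truth (true encounter times and the
    per-encounter amplitudes the adaptation model assigned).
    """
    times = np.asarray(encounter_times, dtype=float)
    if times.size and (times.min() < 0 or times.max() > duration_s):
        raise ValueError("encounter times outside [0, duration]")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    amps = _encounter_amplitudes(times, kernel)

    # peak-normalized difference-of-exponentials kernel, truncated at 8
    # decay constants (amplitude < 4e-4 of peak beyond that)
    klen = int(round(8 * kernel.decay_s * fs))
    kt = np.arange(klen) / fs
    g = np.exp(-kt / kernel.decay_s) - np.exp(-kt / kernel.rise_s)
    g /= np.max(g)

    clean = np.zeros(n)
    for ti, ai in zip(times, amps):
        i0 = int(round(ti * fs))
        i1 = min(i0 + klen, n)
        clean[i0:i1] += ai * g[: i1 - i0]

    noise = rng.normal(0.0, kernel.noise_sd_mv, n) \
        if kernel.noise_sd_mv > 0 else np.zeros(n)
    drift = kernel.drift_amplitude_mv * np.sin(
        2 * np.pi * t / kernel.drift_period_s + rng.uniform(0, 2 * np.pi)) \
        if kernel.drift_amplitude_mv > 0 else np.zeros(n)
    v = kernel.polarity * clean + noise + drift
    trace = EAGTrace(t=t, v=v, fs=fs)
    truth = ScenarioTruth(source_m=tuple(map(float, source_m)),
                          encounter_times=times,
                          encounter_amplitudes_mv=amps,
                          seed=seed,
                          config=config_echo or {})
    return trace, truth


def generate_scenario(config: ScenarioConfig,
                      out_dir: str | Path | None = None
                      ) -> dict:
    """Run a full synthetic trial and (optionally) write it to disk.

    Returns a dict with the Trajectory, EAGTrace, EncounterSeries and
    ScenarioTruth; when ``out_dir`` is given, also writes
    ``trajectory.csv``, ``eag.csv`` and ``truth.json`` (byte-identical
    for identical config + seed).
    """
    traj, enc = simulate_moth(config)
    trace, truth = synthesize_eag(
        enc.times, config.kernel, duration_s=float(traj.t[-1]),
        seed=config.seed + 1_000_003, source_m=tuple(config.plume.r0),
        config_echo=config.to_dict())
    result = {"trajectory": traj, "eag": trace, "encounters": enc,
              "truth": truth}
    if out_dir is not None:
        from . import io as eio
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        eio.write_trajectory(out / "trajectory.csv", traj)
        eio.write_eag(out / "eag.csv", trace)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        result["paths"] = {"trajectory": out / "trajectory.csv",
                           "eag": out / "eag.csv",
                           "truth": out / "truth.json"}
    return result
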