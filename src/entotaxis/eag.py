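"""Electroantennogram (EAG) conditioning and response metrics.

The EAG is the summed extracellular potential of the antennal olfactory
receptor neurons; its deflection amplitude tracks the received odor
intensity.  Physiological EAG deflections are negative-going, so all
analysis here first rectifies the trace into a *response-polarity* signal
(``polarity = -1`` by default flips negative-down deflections into
positive amplitudes; set ``polarity = +1`` for positive-going recordings).

The processing chain mirrors a standard walking-insect preparation:
zero-phase low-pass filtering at 10 Hz, peak detection for encounter
timing, onset-to-peak response time (Tr) and peak-to-baseline recovery
time (Td), per-trial min-max intensity normalization, and the
near-source adaptation ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EncounterSeries, Trajectory

__all__ = [
    "EAGTrace",
    "EAGResponseMetrics",
    "IntensitySeries",
    "lowpass",
    "detect_encounters",
    "response_metrics",
    "normalize_intensity",
    "near_source_ratio",
    "periodic_attenuation_profile",
]

DEFAULT_POLARITY = -1.0  # negative-going deflections


@dataclass(frozen=True)
class EAGTrace:
    """Uniformly sampled EAG voltage trace (mV), nominally 1 kHz."""

    t: np.ndarray
    v: np.ndarray
    fs: float = 1000.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if t.size != v.size or t.size < 2:
            raise ValueError("t and v must match and have >=2 samples")
        dt = np.diff(t)
        nominal = 1.0 / self.fs
        if np.any(np.abs(dt - nominal) > 1e-6 * nominal + 1e-9):
            bad = int(np.argmax(np.abs(dt - nominal)))
            raise ValueError(
                f"non-uniform sampling near t={t[bad]:.4f}s "
                f"(gap {dt[bad]*1e3:.3f} ms, expected {nominal*1e3:.3f} ms)")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class EAGResponseMetrics:
    """Single-response profile: Tr (onset to peak), Td (peak back to
    baseline), amplitude (peak deviation from pre-onset baseline, mV).
    ``Td`` is NaN when the trace ends before the response recovers."""

    Tr: float
    Td: float
    amplitude: float


@dataclass(frozen=True)
class IntensitySeries:
    """Per-encounter amplitudes with min-max normalized intensity."""

    times: np.ndarray
    raw_amplitude: np.ndarray
    intensity: np.ndarray


def lowpass(trace: EAGTrace, cutoff_hz: float = 10.0,
            order: int = 4) -> EAGTrace:
    """Zero-phase Butterworth low-pass (forward-backward) at ``cutoff_hz``.

    The effective magnitude response is the squared Butterworth response
    (8th-order roll-off for the default 4th-order design) with no phase
    distortion, so response peaks are not delayed by the filter.
    """
    if cutoff_hz >= trace.fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz >= Nyquist {trace.fs / 2} Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trace.fs,
                        output="sos")
    vf = signal.sosfiltfilt(sos, trace.v)
    return EAGTrace(t=trace.t, v=vf, fs=trace.fs)


def _response_signal(trace: EAGTrace, polarity: float) -> np.ndarray:
    return polarity * trace.v


def detect_encounters(trace: EAGTrace,
                      min_prominence_mv: float | None = None,
                      min_separation_s: float = 0.3,
                      polarity: float = DEFAULT_POLARITY,
                      peak_lag_s: float = 0.0) -> EncounterSeries:
    """Detect odor-encounter timings as EAG response peaks.

    Local maxima of the response-polarity signal with prominence at least
    ``min_prominence_mv`` and separation at least ``min_separation_s``
    (largest peaks kept first).  When no prominence is given it defaults
    to 5x the median absolute deviation of the trace, a robust noise
    estimate as long as responses are sparse.  A flat or sub-threshold
    trace yields an empty series, not an error.

    ``peak_lag_s`` is the known response latency from odor arrival to the
    (filtered) EAG peak — obtainable from a static single-puff
    characterization of the preparation, or from
    :func:`entotaxis.synthetic.filtered_peak_lag` for synthetic kernels —
    and is subtracted from the reported times so they estimate odor
    arrival rather than the lagged peak.
    """
    if min_separation_s <= 0:
        raise ValueError("min_separation_s must be positive")
    s = _response_signal(trace, polarity)
    if min_prominence_mv is None:
        mad = float(np.median(np.abs(s - np.median(s))))
        min_prominence_mv = 5.0 * mad
    if min_prominence_mv <= 0:  # exactly flat trace
        return EncounterSeries(np.empty(0), float(trace.t[0]),
                               float(trace.t[-1]),
                               amplitudes_mv=np.empty(0))
    distance = max(1, int(round(min_separation_s * trace.fs)))
    peaks, props = signal.find_peaks(s, prominence=min_prominence_mv,
                                     distance=distance)
    amps = props["prominences"]
    times = trace.t[peaks] - peak_lag_s
    t_start = min(float(trace.t[0]), float(times[0]) if times.size else
                  float(trace.t[0]))
    return EncounterSeries(times=times, t_start=t_start,
                           t_end=float(trace.t[-1]), amplitudes_mv=amps)


def response_metrics(trace: EAGTrace, stim_onset_s: float,
                     search_window_s: float = 0.5,
                     baseline_window_s: float = 0.2,
                     recovery_band: float = 0.05,
                     min_amplitude_mv: float = 0.05,
                     polarity: float = DEFAULT_POLARITY,
                     ) -> EAGResponseMetrics | None:
    """Tr/Td/amplitude of the response to a stimulus at ``stim_onset_s``.

    Baseline is the median of the ``baseline_window_s`` before onset; the
    peak is the response-signal maximum within ``search_window_s`` after
    onset.  Td is the first return to within ``recovery_band`` x amplitude
    of baseline after the peak.  Returns ``None`` (a no-response result)
    when the peak deviation stays below ``min_amplitude_mv``.
    """
    s = _response_signal(trace, polarity)
    t = trace.t
    if not (t[0] <= stim_onset_s <= t[-1]):
        raise ValueError("stimulus onset outside trace")
    pre = s[(t >= stim_onset_s - baseline_window_s) & (t < stim_onset_s)]
    baseline = float(np.median(pre)) if pre.size else float(s[t >= stim_onset_s][0])
    win = (t >= stim_onset_s) & (t <= stim_onset_s + search_window_s)
    if not np.any(win):
        return None
    sw, tw = s[win], t[win]
    ipk = int(np.argmax(sw))
    amplitude = float(sw[ipk] - baseline)
    if amplitude < min_amplitude_mv:
        return None
    Tr = float(tw[ipk] - stim_onset_s)
    t_peak = float(tw[ipk])
    after = t > t_peak
    recovered = np.abs(s[after] - baseline) <= recovery_band * amplitude
    if np.any(recovered):
        Td = float(t[after][np.argmax(recovered)] - t_peak)
    else:
        Td = float("nan")
    return EAGResponseMetrics(Tr=Tr, Td=Td, amplitude=amplitude)


def normalize_intensity(amplitudes_mv: np.ndarray,
                        times: np.ndarray | None = None) -> IntensitySeries:
    """Min-max normalize per-encounter amplitudes to [0, 1] per trial.

    Degenerate rule: with a single amplitude, or all amplitudes equal,
    every intensity is 1 (the trial's strongest response).
    """
    amps = np.asarray(amplitudes_mv, dtype=float)
    if amps.size == 0:
        raise ValueError("no amplitudes to normalize")
    if times is None:
        times = np.arange(amps.size, dtype=float)
    times = np.asarray(times, dtype=float)
    lo, hi = float(np.min(amps)), float(np.max(amps))
    if hi > lo:
        intensity = (amps - lo) / (hi - lo)
    else:
        intensity = np.ones_like(amps)
    return IntensitySeries(times=times, raw_amplitude=amps,
                           intensity=intensity)


def near_source_ratio(intens: IntensitySeries, traj: Trajectory,
                      source_mm: np.ndarray = (0.0, 0.0)) -> float:
    """Amplitude of the encounter nearest the source over the trial's
    maximum amplitude.

    A value near 1 means the antenna still responded maximally close to
    the source; values well below 1 indicate adaptation (or reduced drive)
    near the source.  Scale-invariant in the raw trace.
    """
    if intens.raw_amplitude.size == 0:
        raise ValueError("no encounters")
    src = np.asarray(source_mm, dtype=float).reshape(2)
    pos = traj.position_at(intens.times)
    dist = np.linalg.norm(pos - src, axis=1)
    nearest = float(intens.raw_amplitude[int(np.argmin(dist))])
    return nearest / float(np.max(intens.raw_amplitude))


def periodic_attenuation_profile(trace: EAGTrace, stim_times: np.ndarray,
                                 window_s: float = 0.5,
                                 polarity: float = DEFAULT_POLARITY,
                                 **metric_kw) -> np.ndarray:
    """Per-stimulus response amplitude under periodic stimulation.

    Applies :func:`response_metrics` in consecutive windows of
    ``window_s`` after each stimulus.  Windows that would overlap the next
    stimulus are an error (shrink ``window_s``).  Stimuli with no
    detectable response contribute NaN.
    """
    stim_times = np.asarray(stim_times, dtype=float)
    if np.any(np.diff(stim_times) < 0):
        raise ValueError("stim_times must be sorted")
    if stim_times.size > 1 and np.any(np.diff(stim_times) < window_s):
        raise ValueError("analysis windows overlap; reduce window_s")
    amps = np.full(stim_times.size, np.nan)
    for i, t0 in enumerate(stim_times):
        m = response_metrics(trace, t0, search_window_s=window_s,
                             polarity=polarity, **metric_kw)
        if m is not None:
            amps[i] = m.amplitude
    return amps
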