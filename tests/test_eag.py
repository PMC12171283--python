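"""EAG conditioning, peak detection, response metrics, intensity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from entotaxis import (
    EAGKernelParams,
    EAGTrace,
    Trajectory,
    detect_encounters,
    lowpass,
    near_source_ratio,
    normalize_intensity,
    periodic_attenuation_profile,
    response_metrics,
    synthesize_eag,
)
from entotaxis.synthetic import filtered_peak_lag

FS = 1000.0


def make_trace(v, fs=FS):
    return EAGTrace(t=np.arange(v.size) / fs, v=v, fs=fs)


NOISELESS = EAGKernelParams(noise_sd_mv=0.0, drift_amplitude_mv=0.0)


class TestEAGTrace:
    def test_nonuniform_sampling_rejected(self):
        t = np.arange(100) / FS
        t[50] += 0.002
        with pytest.raises(ValueError):
            EAGTrace(t=t, v=np.zeros(100), fs=FS)

    def test_duration(self):
        tr = make_trace(np.zeros(2001))
        assert tr.duration == pytest.approx(2.0)


class TestLowpass:
    def test_dc_passes_unchanged(self):
        tr = make_trace(np.full(2000, 1.7))
        out = lowpass(tr, 10.0)
        assert out.v == pytest.approx(tr.v, abs=1e-9)

    def test_50hz_attenuated_40db(self):
        t = np.arange(4000) / FS
        tr = make_trace(np.sin(2 * np.pi * 50 * t))
        out = lowpass(tr, 10.0)
        mid = out.v[500:-500]
        assert np.max(np.abs(mid)) < 10 ** (-40 / 20)

    def test_recovers_slow_component(self):
        t = np.arange(4000) / FS
        slow = np.sin(2 * np.pi * 1.0 * t)
        tr = make_trace(slow + 0.5 * np.sin(2 * np.pi * 100 * t))
        out = lowpass(tr, 10.0)
        r = np.corrcoef(out.v, slow)[0, 1]
        assert r > 0.99

    def test_idempotent_on_bandlimited_signal(self):
        t = np.arange(4000) / FS
        tr = make_trace(np.sin(2 * np.pi * 1.0 * t))
        once = lowpass(tr, 10.0)
        twice = lowpass(once, 10.0)
        rms = np.sqrt(np.mean(once.v ** 2))
        assert np.sqrt(np.mean((twice.v - once.v) ** 2)) < 0.01 * rms

    def test_cutoff_above_nyquist_rejected(self):
        tr = make_trace(np.zeros(100))
        with pytest.raises(ValueError):
            lowpass(tr, 600.0)


class TestDetectEncounters:
    def test_two_kernels_recovered_within_20ms(self):
        truth = np.array([1.0, 2.0])
        k = EAGKernelParams(noise_sd_mv=0.05)  # SNR 20
        trace, _ = synthesize_eag(truth, k, 4.0, seed=11)
        lag = filtered_peak_lag(k)
        enc = detect_encounters(lowpass(trace), peak_lag_s=lag)
        assert len(enc) == 2
        assert np.max(np.abs(enc.times - truth)) <= 0.020

    def test_pure_noise_rarely_detects(self):
        false_alarms = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            trace = make_trace(rng.normal(0.0, 0.02, 5000))
            filt = lowpass(trace)
            enc = detect_encounters(filt, min_prominence_mv=0.1)
            if len(enc):
                false_alarms += 1
        assert false_alarms <= 5

    def test_ten_pulses_at_1hz_all_found(self):
        truth = np.arange(10) + 0.5
        trace, _ = synthesize_eag(truth, NOISELESS, 11.0, seed=0)
        enc = detect_encounters(lowpass(trace),
                                peak_lag_s=filtered_peak_lag(NOISELESS))
        assert len(enc) == 10

    def test_flat_trace_yields_empty_series(self):
        enc = detect_encounters(make_trace(np.zeros(2000)))
        assert len(enc) == 0


class TestResponseMetrics:
    def test_fast_rise_slow_recovery_profile(self):
        """Default kernel: onset-to-peak within 10 ms, recovery beyond
        100 ms — the canonical single-puff antennal response shape."""
        trace, _ = synthesize_eag(np.array([1.0]), NOISELESS, 3.0, seed=0)
        m = response_metrics(trace, 1.0)
        assert m is not None
        assert m.Tr <= 0.010
        assert m.Td > 0.100

    def test_amplitude_recovered_within_1pct(self):
        trace, _ = synthesize_eag(np.array([1.0]), NOISELESS, 3.0, seed=0)
        m = response_metrics(trace, 1.0)
        assert m.amplitude == pytest.approx(1.0, rel=0.01)

    def test_flat_trace_gives_no_response(self):
        assert response_metrics(make_trace(np.zeros(2000)), 1.0) is None


class TestNormalizeIntensity:
    def test_minmax_mapping(self):
        out = normalize_intensity(np.array([1.0, 2.0, 3.0]))
        assert out.intensity == pytest.approx([0.0, 0.5, 1.0])

    def test_all_equal_maps_to_one(self):
        out = normalize_intensity(np.array([2.0, 2.0]))
        assert out.intensity == pytest.approx([1.0, 1.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_intensity(np.array([]))

    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_and_rank_preserving(self, amps):
        amps = np.asarray(amps)
        out = normalize_intensity(amps)
        assert np.all(out.intensity >= 0) and np.all(out.intensity <= 1)
        assert np.array_equal(np.argsort(amps, kind="stable"),
                              np.argsort(out.intensity, kind="stable"))


class TestNearSourceRatio:
    def _traj(self):
        # walks from 100 mm downwind to the source over 10 s
        t = np.linspace(0, 10, 101)
        return Trajectory(t, 100.0 - 10.0 * t, np.zeros_like(t))

    def test_constant_amplitudes_give_one(self):
        intens = normalize_intensity(np.array([1.0, 1.0, 1.0]),
                                     times=np.array([1.0, 5.0, 9.0]))
        assert near_source_ratio(intens, self._traj()) == 1.0

    def test_halved_near_source(self):
        # 1 mV encounter nearest the source, 2 mV maximum
        intens = normalize_intensity(np.array([2.0, 1.0]),
                                     times=np.array([1.0, 9.0]))
        assert near_source_ratio(intens, self._traj()) == pytest.approx(0.5)

    def test_scale_invariance(self):
        amps = np.array([2.0, 1.5, 0.7])
        times = np.array([1.0, 5.0, 9.0])
        r1 = near_source_ratio(normalize_intensity(amps, times=times),
                               self._traj())
        r2 = near_source_ratio(normalize_intensity(amps * 7.3, times=times),
                               self._traj())
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_no_encounters_rejected(self):
        with pytest.raises(ValueError):
            intens = normalize_intensity(np.array([1.0]),
                                         times=np.array([1.0]))
            object.__setattr__(intens, "raw_amplitude", np.empty(0))
            near_source_ratio(intens, self._traj())


class TestPeriodicAttenuation:
    def test_1hz_train_non_increasing(self):
        stim = np.arange(10) + 0.5
        trace, _ = synthesize_eag(stim, NOISELESS, 11.0, seed=0)
        amps = periodic_attenuation_profile(trace, stim)
        assert not np.any(np.isnan(amps))
        assert np.all(np.diff(amps) < 0)

    def test_single_pulse_matches_response_metrics(self):
        trace, _ = synthesize_eag(np.array([1.0]), NOISELESS, 3.0, seed=0)
        amps = periodic_attenuation_profile(trace, np.array([1.0]))
        m = response_metrics(trace, 1.0)
        assert amps.size == 1
        assert amps[0] == pytest.approx(m.amplitude, rel=1e-9)

    def test_long_gap_recovers_most_amplitude(self):
        # 10 s gap (twice the recovery constant): second response within
        # 15% of the first
        stim = np.array([1.0, 11.0])
        trace, _ = synthesize_eag(stim, NOISELESS, 13.0, seed=0)
        amps = periodic_attenuation_profile(trace, stim)
        assert amps[1] >= 0.85 * amps[0]

    def test_overlapping_windows_rejected(self):
        trace, _ = synthesize_eag(np.array([1.0]), NOISELESS, 3.0, seed=0)
        with pytest.raises(ValueError):
            periodic_attenuation_profile(trace, np.array([1.0, 1.2]),
                                         window_s=0.5)
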