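"""Trace analysis: baselines, averaging, windowed measures, direct-response
classification/subtraction, event detection and windowing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from optomap.core import SweepRecord
from optomap.events import (QuantalEventSet, average_sweeps, baseline_subtract,
                            classify_response, detect_events, event_rates,
                            normalize_to_power, peak_amplitude, remove_direct,
                            window_events, windowed_mean_amplitude)
from optomap.exceptions import (IncompatibleSweepsError, InvalidParameterError,
                                WindowError)
from optomap.synthgen import epsc_peak_time, make_epsc_kernel

from conftest import kernel_sweep


class TestBaselineAndAveraging:
    def test_constant_trace_becomes_zero(self):
        s = SweepRecord(np.full(1000, -12.0), 0.1, 50.0)
        assert np.allclose(baseline_subtract(s).samples, 0.0)

    def test_offset_kernel_recovers_kernel(self):
        k = make_epsc_kernel(80, 0.5, 5, 60, 0.1, 150)
        s = SweepRecord(k - 30.0, 0.1, 50.0)
        assert np.allclose(baseline_subtract(s).samples, k, atol=1e-9)

    def test_baseline_window_must_precede_stimulus(self):
        s = SweepRecord(np.zeros(1000), 0.1, 50.0)
        with pytest.raises(WindowError):
            baseline_subtract(s, (40.0, 60.0))
        with pytest.raises(WindowError):
            baseline_subtract(SweepRecord(np.zeros(100), 0.1, 10.0),
                              (-5.0, 5.0))

    def test_averaging_identical_sweeps_is_idempotent(self):
        s = kernel_sweep()
        avg = average_sweeps([s, s])
        assert np.array_equal(avg.samples, s.samples)

    def test_opposite_sweeps_cancel(self):
        s = kernel_sweep()
        neg = s.with_samples(-s.samples)
        assert np.allclose(average_sweeps([s, neg]).samples, 0.0)

    def test_mismatched_sweeps_rejected(self):
        a = kernel_sweep()
        b = kernel_sweep(dt=0.2)
        with pytest.raises(IncompatibleSweepsError):
            average_sweeps([a, b])
        c = kernel_sweep(grid_index=(0, 1))
        with pytest.raises(IncompatibleSweepsError):
            average_sweeps([a, c])

    def test_residual_shrinks_like_root_n(self, rng):
        """Averaging N noisy copies shrinks residual RMS roughly as 1/sqrt(N)."""
        k = make_epsc_kernel(50, 0.5, 5, 20, 0.1, 100)

        def rms(n):
            sweeps = [SweepRecord(k + rng.normal(0, 4, k.size), 0.1, 10.0)
                      for _ in range(n)]
            return np.sqrt(np.mean((average_sweeps(sweeps).samples - k) ** 2))

        ratio = np.mean([rms(4) / rms(64) for _ in range(5)])
        assert ratio == pytest.approx(4.0, rel=0.25)


class TestWindowedMeasures:
    def test_peak_of_known_kernel(self):
        s = kernel_sweep(amp=100, onset_after_stim=7.0)
        assert peak_amplitude(s, (5, 80)) == pytest.approx(100, abs=0.5)

    def test_kernel_outside_window_measures_noise_floor(self):
        s = kernel_sweep(amp=100, onset_after_stim=90.0)
        assert peak_amplitude(s, (5, 80)) == pytest.approx(0.0, abs=1e-6)

    def test_peak_takes_max_not_sum_and_respects_window(self):
        tr = make_epsc_kernel(60, 0.5, 5, 20, 0.1, 200) + \
            make_epsc_kernel(80, 0.5, 5, 50, 0.1, 200)
        s = SweepRecord(tr, 0.1, 10.0, stim_kind="laser", power=10.0)
        assert peak_amplitude(s, (5, 80)) == pytest.approx(80, rel=0.02)
        # the 2-30 ms window excludes the late (polysynaptic-like) component
        assert peak_amplitude(s, (2, 30)) == pytest.approx(60, rel=0.02)

    def test_empty_window_raises(self):
        s = kernel_sweep()
        with pytest.raises(WindowError):
            peak_amplitude(s, (30, 30))
        with pytest.raises(WindowError):
            peak_amplitude(s, (5, 10_000))

    def test_mean_amplitude_of_zero_and_rect_pulse(self):
        z = SweepRecord(np.zeros(1500), 0.1, 10.0)
        assert windowed_mean_amplitude(z, (2, 30)) == 0.0
        tr = np.zeros(1500)
        tr[int(12 / 0.1):int(40 / 0.1)] = -50.0
        s = SweepRecord(tr, 0.1, 10.0)
        assert windowed_mean_amplitude(s, (2, 30)) == pytest.approx(50.0)

    def test_mean_amplitude_matches_quadrature(self):
        """Windowed mean equals the analytic integral of |kernel| / width."""
        tr_, td_, onset, amp = 0.5, 5.0, 12.0, 90.0
        s = kernel_sweep(amp=amp, tau_rise=tr_, tau_decay=td_,
                         onset_after_stim=2.0, dt=0.01)
        tpk = epsc_peak_time(tr_, td_)
        gmax = np.exp(-tpk / td_) - np.exp(-tpk / tr_)

        def f(t):
            if t < onset:
                return 0.0
            return amp * (np.exp(-(t - onset) / td_)
                          - np.exp(-(t - onset) / tr_)) / gmax

        integral, _ = quad(f, 12.0, 40.0, limit=200)
        assert windowed_mean_amplitude(s, (2, 30)) == pytest.approx(
            integral / 28.0, rel=0.01)

    def test_peak_invariant_to_offset_after_baseline_subtraction(self, rng):
        s = kernel_sweep(amp=70, noise_sd=2.0, rng=rng)
        shifted = s.with_samples(s.samples + 25.0)
        a = peak_amplitude(baseline_subtract(s), (5, 80))
        b = peak_amplitude(baseline_subtract(shifted), (5, 80))
        assert a == pytest.approx(b, abs=1e-9)

    def test_normalize_to_power(self):
        assert normalize_to_power(172.0, 172.0 / 2.2) == pytest.approx(2.2)
        assert normalize_to_power(0.0, 3.0) == 0.0
        assert normalize_to_power(100.0, 4.0) == \
            normalize_to_power(100.0, 2.0) / 2
        with pytest.raises(InvalidParameterError):
            normalize_to_power(10.0, 0.0)


def _direct_trace(rng, direct_amp=150.0, syn_amp=0.0, noise_sd=2.0,
                  syn_onset=12.0):
    tr = make_epsc_kernel(direct_amp, 0.2, 10, 12.0, 0.1, 150)
    if syn_amp:
        tr = tr + make_epsc_kernel(syn_amp, 0.5, 5, 10 + syn_onset, 0.1, 150)
    if noise_sd:
        tr = tr + rng.normal(0, noise_sd, tr.size)
    return baseline_subtract(
        SweepRecord(tr, 0.1, 10.0, stim_kind="uncage", power=30.0))


class TestClassification:
    def test_fast_early_response_is_direct(self, rng):
        r = classify_response(_direct_trace(rng), amp_threshold=6.0)
        assert r.classification == "direct"
        assert r.onset_latency < 5.0

    def test_slow_late_response_is_synaptic(self, rng):
        s = kernel_sweep(amp=60, onset_after_stim=8.0, noise_sd=2.0, rng=rng)
        r = classify_response(baseline_subtract(s), amp_threshold=6.0)
        assert r.classification == "synaptic"

    def test_direct_plus_synaptic_is_mixed(self, rng):
        r = classify_response(_direct_trace(rng, syn_amp=60.0),
                              amp_threshold=6.0)
        assert r.classification == "mixed"

    def test_subthreshold_response_is_none(self, rng):
        s = SweepRecord(rng.normal(0, 1.0, 1500), 0.1, 10.0)
        r = classify_response(baseline_subtract(s), amp_threshold=30.0)
        assert r.classification == "none"

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(c=st.floats(min_value=1.0, max_value=10.0))
    def test_scaling_up_never_turns_direct_into_synaptic(self, c):
        rng = np.random.default_rng(0)
        base = _direct_trace(rng, noise_sd=0.0)
        scaled = base.with_samples(base.samples * c)
        r = classify_response(scaled, amp_threshold=6.0)
        assert r.classification != "synaptic"


class TestRemoveDirect:
    def test_synaptic_response_returned_unchanged(self, rng):
        s = kernel_sweep(amp=60, onset_after_stim=8.0, noise_sd=2.0, rng=rng)
        r = classify_response(baseline_subtract(s), amp_threshold=6.0)
        assert remove_direct(r) is r

    def test_mixed_correction_recovers_synaptic_peak(self, rng):
        errs = []
        for _ in range(30):
            r = classify_response(_direct_trace(rng, syn_amp=60.0),
                                  amp_threshold=6.0)
            rc = remove_direct(r)
            assert rc.classification == "synaptic"
            errs.append(peak_amplitude(rc.trace, (5, 80), smooth_ms=1.0) - 60)
        assert np.max(np.abs(errs)) < 6.0  # within 10 % of 60 pA

    def test_pure_direct_is_excluded_with_small_residual(self, rng):
        r = classify_response(_direct_trace(rng), amp_threshold=6.0)
        rc = remove_direct(r)
        assert rc.excluded
        assert peak_amplitude(rc.trace, (2, 80), smooth_ms=1.0) < 0.05 * 150

    def test_never_increases_pure_synaptic_peak(self, rng):
        for _ in range(10):
            s = kernel_sweep(amp=40, onset_after_stim=9.0, noise_sd=2.0, rng=rng)
            r = classify_response(baseline_subtract(s), amp_threshold=6.0)
            before = peak_amplitude(r.trace, (5, 80))
            after = peak_amplitude(remove_direct(r).trace, (5, 80))
            assert after <= before + 1e-12


class TestEventDetection:
    def test_flat_trace_yields_no_events(self):
        s = SweepRecord(np.zeros(20000), 0.1, 1100.0)
        assert len(detect_events(s)) == 0

    def test_noise_only_trace_has_negligible_false_positives(self, rng):
        s = SweepRecord(rng.normal(0, 2.0, 150000), 0.1, 1100.0)
        # threshold is 3 sigma of the raw trace applied to the smoothed
        # trace (~6.7 sigma there): expect essentially zero crossings in 15 s
        assert len(detect_events(s)) <= 1

    def test_injected_events_are_recovered_with_amplitudes(self, rng):
        tr = np.zeros(30000)
        t_true = np.arange(10) * 280.0 + 100.0
        for t in t_true:
            tr += make_epsc_kernel(15.0, 0.5, 5.0, t, 0.1, 3000.0)
        s = SweepRecord(tr + rng.normal(0, 2.0, tr.size), 0.1, 1500.0)
        ev = detect_events(s)
        assert len(ev) >= 9
        se = 2.0 / np.sqrt(len(ev))
        assert np.mean(ev.amplitudes) == pytest.approx(15.0, abs=2 * se + 1.0)

    def test_events_closer_than_min_iei_merge(self):
        tr = make_epsc_kernel(20, 0.5, 5, 100.0, 0.1, 300) + \
            make_epsc_kernel(20, 0.5, 5, 101.0, 0.1, 300)
        s = SweepRecord(tr, 0.1, 50.0)
        ev = detect_events(s, min_iei=2.0, noise_sd=1.0)
        assert len(ev) == 1


class TestWindowingAndRates:
    @pytest.mark.parametrize("t, label", [
        (-500.0, "spontaneous"), (-1000.0, "spontaneous"), (-1000.1, "other"),
        (0.0, "other"), (49.9, "other"), (50.0, "evoked"), (100.0, "evoked"),
        (349.9, "evoked"), (350.0, "other"), (400.0, "other")])
    def test_half_open_window_labels(self, t, label):
        ev = QuantalEventSet(times=[t], amplitudes=[10.0])
        assert window_events(ev).labels[0] == label

    def test_three_evoked_events_in_one_sweep_is_ten_hz(self):
        ev = QuantalEventSet(times=[60.0, 100.0, 300.0],
                             amplitudes=[10, 11, 12], n_sweeps=1)
        rates = event_rates(window_events(ev))
        assert rates["evoked_hz"] == pytest.approx(10.0)
        assert rates["spont_hz"] == 0.0
        assert np.isnan(rates["spont_amp_pA"])

    def test_zero_sweeps_rejected(self):
        ev = QuantalEventSet(times=[], amplitudes=[], n_sweeps=0)
        with pytest.raises(InvalidParameterError):
            event_rates(ev)
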