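"""Sweep-level analysis: averaging, peak measurement, direct-response
classification and subtraction, quantal event detection and windowing.

All amplitudes returned are positive magnitudes of inward (negative)
current.  Analysis windows are half-open ``[start, end)`` in ms and, unless
stated otherwise, relative to the stimulus onset of the sweep.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .core import SweepRecord
from .exceptions import (IncompatibleSweepsError, InvalidParameterError,
                         WindowError)

__all__ = [
    "EvokedResponse", "QuantalEventSet",
    "baseline_subtract", "average_sweeps", "peak_amplitude",
    "windowed_mean_amplitude", "noise_sd_estimate", "onset_latency",
    "rise_time_20_80", "classify_response", "remove_direct",
    "detect_events", "window_events", "event_rates", "normalize_to_power",
]

log = logging.getLogger(__name__)

#: Event windows relative to the flash, half-open [start, end) ms.
SPONT_WINDOW = (-1000.0, 0.0)
EVOKED_WINDOW = (50.0, 350.0)


# ---------------------------------------------------------------------------
# evoked-response containers

@dataclass
class EvokedResponse:
    """An averaged, baseline-subtracted response at one stimulation site."""

    trace: SweepRecord
    amplitude: float = 0.0            # pA, positive magnitude
    onset_latency: Optional[float] = None  # ms after stimulus
    classification: str = "none"      # none | synaptic | direct | mixed | unusable
    analysis_window: tuple = (5.0, 80.0)
    grid_index: Optional[tuple] = None
    excluded: bool = False            # True for pure-direct / unusable pixels
    info: dict = field(default_factory=dict)


@dataclass
class QuantalEventSet:
    """Detected event times/amplitudes, optionally window-labelled.

    Times are in ms relative to the flash.  Labels are ``"spontaneous"``
    (time in [-1000, 0)), ``"evoked"`` (time in [50, 350)) or ``"other"``.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    labels: np.ndarray = None
    n_sweeps: int = 1
    spont_window: tuple = SPONT_WINDOW
    evoked_window: tuple = EVOKED_WINDOW
    sweep_ids: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.labels is None:
            self.labels = np.full(self.times.size, "other", dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)

    def __len__(self):
        return self.times.size

    @classmethod
    def concatenate(cls, sets: list) -> "QuantalEventSet":
        """Pool events over sweeps; ``n_sweeps`` is the sum."""
        if not sets:
            raise InvalidParameterError("nothing to concatenate")
        first = sets[0]
        return cls(
            times=np.concatenate([s.times for s in sets]),
            amplitudes=np.concatenate([s.amplitudes for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            n_sweeps=sum(s.n_sweeps for s in sets),
            spont_window=first.spont_window, evoked_window=first.evoked_window)


# ---------------------------------------------------------------------------
# basic trace algebra

def _window_slice(sweep: SweepRecord, window: tuple, relative: bool = True):
    """Sample slice for a half-open [start, end) ms window.

    ``relative=True`` interprets the window relative to stim_onset.
    """
    w0, w1 = window
    if relative:
        w0, w1 = sweep.stim_onset + w0, sweep.stim_onset + w1
    if w1 <= w0:
        raise WindowError(f"empty window ({w0}, {w1}) ms")
    if w0 < 0 or w1 > sweep.duration + 1e-9:
        raise WindowError(
            f"window [{w0}, {w1}) ms outside trace [0, {sweep.duration}) ms")
    i0 = int(math.ceil(w0 / sweep.dt - 1e-9))
    i1 = int(math.ceil(w1 / sweep.dt - 1e-9))
    i1 = min(i1, sweep.n_samples)
    if i1 <= i0:
        raise WindowError("window contains no samples")
    return slice(i0, i1)


def baseline_subtract(sweep: SweepRecord,
                      baseline_window: Optional[tuple] = None) -> SweepRecord:
    """Zero the mean of the pre-stimulus baseline window.

    ``baseline_window`` is absolute (ms from sweep start) and defaults to
    everything before the stimulus.  It must precede the stimulus onset.
    """
    if baseline_window is None:
        baseline_window = (0.0, sweep.stim_onset)
    w0, w1 = baseline_window
    if w1 > sweep.stim_onset + 1e-9:
        raise WindowError("baseline window must precede the stimulus onset")
    sl = _window_slice(sweep, baseline_window, relative=False)
    return sweep.with_samples(sweep.samples - sweep.samples[sl].mean())


def average_sweeps(sweeps: list) -> SweepRecord:
    """Pointwise arithmetic mean of repeated sweeps.

    All sweeps must share dt, length, stimulus onset and grid index.
    """
    if not sweeps:
        raise IncompatibleSweepsError("no sweeps to average")
    ref = sweeps[0]
    for s in sweeps[1:]:
        if (s.dt != ref.dt or s.n_samples != ref.n_samples
                or s.stim_onset != ref.stim_onset
                or s.grid_index != ref.grid_index):
            raise IncompatibleSweepsError(
                "sweeps differ in dt, length, stim_onset or grid_index")
    mean = np.mean([s.samples for s in sweeps], axis=0)
    return replace(ref, samples=mean, sweep_id=None)


def _boxcar(x: np.ndarray, width_samples: int) -> np.ndarray:
    if width_samples <= 1:
        return x
    k = np.ones(width_samples) / width_samples
    return np.convolve(x, k, mode="same")


def peak_amplitude(resp: SweepRecord, window: tuple = (5.0, 80.0),
                   smooth_ms: float = 0.0) -> float:
    """Peak magnitude of the (baseline-subtracted) current in the window.

    The window is relative to stimulus onset.  ``smooth_ms > 0`` applies a
    boxcar of that width before taking the maximum, which suppresses the
    upward bias of max-picking on noisy traces; leave it 0 for clean or
    averaged traces.  The discrete maximum is refined by parabolic
    interpolation through its neighbours, so the estimate varies smoothly
    rather than snapping to the sample grid.
    """
    sl = _window_slice(resp, window)
    x = _boxcar(resp.samples, int(round(smooth_ms / resp.dt))) if smooth_ms > 0 \
        else resp.samples
    seg = np.abs(x[sl])
    i = int(np.argmax(seg))
    peak = float(seg[i])
    if 0 < i < seg.size - 1:
        y0, y1, y2 = seg[i - 1], seg[i], seg[i + 1]
        den = y0 - 2.0 * y1 + y2
        if den < -1e-12:  # strict local maximum: quadratic vertex
            peak = float(y1 - (y0 - y2) ** 2 / (8.0 * den))
    return peak


def windowed_mean_amplitude(resp: SweepRecord, window: tuple = (2.0, 30.0)) -> float:
    """Mean rectified current over the window (action-potential maps)."""
    sl = _window_slice(resp, window)
    return float(np.mean(np.abs(resp.samples[sl])))


def normalize_to_power(amp: float, power: float) -> float:
    """Amplitude per unit stimulus power (pA/mW)."""
    if power is None or power <= 0:
        raise InvalidParameterError(f"power must be positive, got {power}")
    return amp / power


# ---------------------------------------------------------------------------
# noise, onset, kinetics

def noise_sd_estimate(samples: np.ndarray) -> float:
    """Robust (MAD-based) noise SD in pA."""
    x = np.asarray(samples, dtype=float)
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def onset_latency(resp: SweepRecord, k: float = 3.0, sustain_ms: float = 0.5,
                  noise_sd: Optional[float] = None) -> Optional[float]:
    """First time (ms after stimulus) the trace stays beyond ``k * noise_sd``
    for at least ``sustain_ms``; None if it never does.

    The sustained-crossing rule makes the latency robust to single-sample
    noise.  Noise SD defaults to a MAD estimate from the pre-stimulus
    baseline.
    """
    i_stim = int(round(resp.stim_onset / resp.dt))
    if noise_sd is None:
        base = resp.samples[:max(i_stim, 1)]
        noise_sd = noise_sd_estimate(base)
    thr = max(k * noise_sd, 1e-9)
    n_sust = max(int(round(sustain_ms / resp.dt)), 1)
    above = np.abs(resp.samples[i_stim:]) > thr
    if above.size < n_sust:
        return None
    # first index where `n_sust` consecutive samples are above threshold
    run = np.convolve(above.astype(int), np.ones(n_sust, dtype=int), mode="valid")
    hits = np.nonzero(run == n_sust)[0]
    if hits.size == 0:
        return None
    return float(hits[0] * resp.dt)


def _first_peak_index(resp: SweepRecord, start_idx: int, min_height: float) -> int:
    """Index of the first local maximum of |current| above ``min_height``."""
    absx = np.abs(resp.samples)
    peaks, _ = find_peaks(absx[start_idx:], height=min_height)
    if peaks.size == 0:
        return start_idx + int(np.argmax(absx[start_idx:]))
    return start_idx + int(peaks[0])


def rise_time_20_80(resp: SweepRecord, peak_idx: int, onset_idx: int) -> float:
    """20-80 % rise time (ms) of the rising phase up to ``peak_idx``."""
    seg = np.abs(resp.samples[onset_idx:peak_idx + 1])
    if seg.size < 2:
        return 0.0
    pk = seg[-1]
    t = np.arange(seg.size) * resp.dt

    def crossing(level):
        above = np.nonzero(seg >= level)[0]
        if above.size == 0:
            return t[-1]
        i = above[0]
        if i == 0:
            return t[0]
        # linear interpolation between the bracketing samples
        f = (level - seg[i - 1]) / (seg[i] - seg[i - 1])
        return t[i - 1] + f * resp.dt

    return float(crossing(0.8 * pk) - crossing(0.2 * pk))


# ---------------------------------------------------------------------------
# direct-response classification and subtraction

def _second_component_onset(resp: SweepRecord, peak_idx: int,
                            amp_threshold: float) -> Optional[int]:
    """Onset index of a slower second component after the direct peak.

    Looks for a second local maximum of the (smoothed) rectified current
    with prominence above ``amp_threshold`` after ``peak_idx``; the
    synaptic onset is taken at the valley between the two peaks, which
    bounds the segment over which the direct decay can be fitted cleanly.
    Returns None when no second component exists.
    """
    absx = _boxcar(np.abs(resp.samples), max(int(round(1.0 / resp.dt)), 1))
    dist = max(int(round(2.0 / resp.dt)), 1)
    # search beyond the smoothing width so the (smeared) direct peak itself
    # cannot register as a second component
    start = peak_idx + dist
    if start >= absx.size:
        return None
    peaks, _ = find_peaks(absx[start:], height=amp_threshold,
                          prominence=amp_threshold, distance=dist)
    if peaks.size == 0:
        return None
    p2 = start + int(peaks[0])
    valley = peak_idx + int(np.argmin(absx[peak_idx:p2 + 1]))
    return valley


def classify_response(resp: SweepRecord, amp_threshold: float,
                      direct_latency: float = 5.0,
                      direct_rise_max: float = 1.0,
                      analysis_window: tuple = (5.0, 80.0),
                      grid_index: Optional[tuple] = None) -> EvokedResponse:
    """Classify a baseline-subtracted averaged response.

    * ``none`` — peak below ``amp_threshold``;
    * ``direct`` — onset earlier than ``direct_latency`` (5 ms rule) with a
      20-80 % rise time under ``direct_rise_max`` (uncaging onto the
      recorded neuron itself is near-instantaneous);
    * ``mixed`` — direct criteria met plus a slower synaptic component
      above threshold after ``direct_latency``;
    * ``synaptic`` — everything else above threshold.
    """
    i_stim = int(round(resp.stim_onset / resp.dt))
    amp_full = float(np.max(np.abs(resp.samples[i_stim:])))
    if amp_full < amp_threshold:
        return EvokedResponse(trace=resp, amplitude=amp_full,
                              classification="none",
                              analysis_window=analysis_window,
                              grid_index=grid_index)
    onset = onset_latency(resp)
    if onset is None:
        return EvokedResponse(trace=resp, amplitude=amp_full,
                              classification="none",
                              analysis_window=analysis_window,
                              grid_index=grid_index)
    onset_idx = i_stim + int(round(onset / resp.dt))
    cls = "synaptic"
    info: dict = {}
    if onset < direct_latency:
        pk = _first_peak_index(resp, onset_idx, 0.5 * amp_threshold)
        rise = rise_time_20_80(resp, pk, onset_idx)
        info["first_peak_idx"] = pk
        info["rise_20_80_ms"] = rise
        if rise < direct_rise_max:
            second = _second_component_onset(resp, pk, amp_threshold)
            if second is not None and (second - i_stim) * resp.dt >= direct_latency:
                cls = "mixed"
                info["second_onset_idx"] = second
            else:
                cls = "direct"
    amp = peak_amplitude(resp, analysis_window)
    return EvokedResponse(trace=resp, amplitude=amp, onset_latency=onset,
                          classification=cls, analysis_window=analysis_window,
                          grid_index=grid_index, info=info)


def _double_exp(s, a1, tau1, a2, tau2):
    return a1 * np.exp(-s / tau1) + a2 * np.exp(-s / tau2)


def _peel_initial_guess(s: np.ndarray, y: np.ndarray) -> tuple:
    """Log-linear peel: slow tail fit first, fast residual second."""
    half = s.size // 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tail_s, tail_y = s[half:], y[half:]
        ok = tail_y > 0
        if ok.sum() >= 2:
            b, a = np.polyfit(tail_s[ok], np.log(tail_y[ok]), 1)
            tau2 = -1.0 / b if b < 0 else 10.0
            a2 = math.exp(a)
        else:
            tau2, a2 = 10.0, max(float(y[0]) * 0.3, 1e-6)
        resid = y - a2 * np.exp(-s / np.clip(tau2, 0.05, 500.0))
        ok = resid[:half] > 0
        if ok.sum() >= 2:
            b, a = np.polyfit(s[:half][ok], np.log(resid[:half][ok]), 1)
            tau1 = -1.0 / b if b < 0 else 1.0
            a1 = math.exp(a)
        else:
            tau1, a1 = 1.0, max(float(y[0]) * 0.7, 1e-6)
    tau1 = float(np.clip(tau1, 0.06, 400.0))
    tau2 = float(np.clip(tau2, 0.06, 500.0))
    return a1, tau1, a2, tau2


def remove_direct(resp: EvokedResponse, max_iter: int = 2000) -> EvokedResponse:
    """Subtract the direct-response component by a double-exponential
    decay fit.

    The decay of the direct component is fitted from its peak up to the
    onset of the synaptic component (or the end of the analysis window for
    a pure direct response), extrapolated over the full window and
    subtracted.  The unmodelled rising phase (before the direct peak, all
    earlier than 5 ms and hence outside the synaptic analysis window) is
    zeroed.  Pure direct responses are additionally flagged ``excluded``:
    they carry no synaptic signal and are deleted from maps rather than
    corrected.  Synaptic or sub-threshold responses are returned unchanged.

    A non-converging fit returns classification ``"unusable"`` with
    ``excluded=True`` (the pixel is dropped from maps).
    """
    if resp.classification not in ("direct", "mixed"):
        return resp
    trace = resp.trace
    i_stim = int(round(trace.stim_onset / trace.dt))
    pk = resp.info.get("first_peak_idx")
    if pk is None:
        onset_idx = i_stim + int(round((resp.onset_latency or 0.0) / trace.dt))
        pk = _first_peak_index(trace, onset_idx, 0.5 * resp.amplitude)
    w_end_idx = i_stim + int(round(resp.analysis_window[1] / trace.dt))
    w_end_idx = min(w_end_idx, trace.n_samples)
    if resp.classification == "mixed" and "second_onset_idx" in resp.info:
        fit_end = resp.info["second_onset_idx"]
    else:
        fit_end = w_end_idx
    fit_end = max(fit_end, pk + 5)
    s = (np.arange(pk, fit_end) - pk) * trace.dt
    y = -trace.samples[pk:fit_end]  # decay of an inward current, positive
    try:
        p0 = _peel_initial_guess(s, y)
        popt, _ = curve_fit(
            _double_exp, s, y, p0=p0,
            bounds=([-np.inf, 0.05, -np.inf, 0.05],
                    [np.inf, 500.0, np.inf, 500.0]),
            maxfev=max_iter)
    except (RuntimeError, ValueError) as exc:
        log.warning("direct-response fit failed (%s); pixel flagged unusable", exc)
        return replace(resp, classification="unusable", excluded=True)
    corrected = trace.samples.copy()
    s_full = (np.arange(pk, trace.n_samples) - pk) * trace.dt
    corrected[pk:] += _double_exp(s_full, *popt)
    onset_idx = i_stim + int(round((resp.onset_latency or 0.0) / trace.dt))
    corrected[onset_idx:pk] = 0.0   # unmodelled direct rising phase
    new_trace = trace.with_samples(corrected)
    amp = peak_amplitude(new_trace, resp.analysis_window)
    if resp.classification == "mixed":
        return EvokedResponse(trace=new_trace, amplitude=amp,
                              onset_latency=resp.onset_latency,
                              classification="synaptic",
                              analysis_window=resp.analysis_window,
                              grid_index=resp.grid_index,
                              info={**resp.info, "direct_fit": tuple(popt),
                                    "direct_corrected": True})
    return EvokedResponse(trace=new_trace, amplitude=amp,
                          onset_latency=resp.onset_latency,
                          classification="direct", excluded=True,
                          analysis_window=resp.analysis_window,
                          grid_index=resp.grid_index,
                          info={**resp.info, "direct_fit": tuple(popt)})


# ---------------------------------------------------------------------------
# quantal event detection

def detect_events(trace: SweepRecord, k_sigma: float = 3.0, min_iei: float = 2.0,
                  smooth_ms: float = 0.5, prominence_frac: float = 0.6,
                  noise_sd: Optional[float] = None) -> QuantalEventSet:
    """Threshold-crossing event detection on a quantal-release sweep.

    The trace is median-centred and lightly boxcar-smoothed; events are
    local minima whose magnitude exceeds ``k_sigma`` times the raw-trace
    noise SD (MAD estimate, robust to sparse events), separated by at least
    ``min_iei`` ms (closer minima merge into the larger event).  Amplitude
    is the peak magnitude relative to the local pre-event baseline (median
    of the smoothed trace 6-1.5 ms before the peak).  Event times are
    relative to the stimulus (flash) onset.
    """
    x = trace.samples - np.median(trace.samples)
    if noise_sd is None:
        noise_sd = noise_sd_estimate(x)
    thr = max(k_sigma * noise_sd, 1e-9)
    xs = _boxcar(x, int(round(smooth_ms / trace.dt)))
    dist = max(int(round(min_iei / trace.dt)), 1)
    # a prominence floor keeps noise ripple on an event's decay from
    # splitting it into spurious detections; a fraction of the threshold
    # suffices (it only needs to exceed the smoothed-noise ripple) and a
    # full-threshold prominence would suppress events riding on the decay
    # of a predecessor at high evoked rates
    peaks, _ = find_peaks(-xs, height=thr, prominence=prominence_frac * thr,
                          distance=dist)
    amps = np.empty(peaks.size)
    i_pre0 = int(round(6.0 / trace.dt))
    i_pre1 = int(round(1.5 / trace.dt))
    for j, p in enumerate(peaks):
        lo = max(p - i_pre0, 0)
        hi = max(p - i_pre1, 0)
        base = np.median(xs[lo:hi]) if hi > lo else 0.0
        amps[j] = base - xs[p]
    times = peaks * trace.dt - trace.stim_onset
    return QuantalEventSet(times=times, amplitudes=amps, n_sweeps=1)


def window_events(events: QuantalEventSet, t_flash: float = 0.0,
                  spont_window: tuple = SPONT_WINDOW,
                  evoked_window: tuple = EVOKED_WINDOW) -> QuantalEventSet:
    """Label events by half-open windows relative to the flash.

    ``spontaneous``: time in [-1000, 0); ``evoked``: time in [50, 350);
    everything else ``other``.  ``t_flash`` shifts event times first if
    they are not already flash-relative.
    """
    t = events.times - t_flash
    labels = np.full(t.size, "other", dtype=object)
    labels[(t >= spont_window[0]) & (t < spont_window[1])] = "spontaneous"
    labels[(t >= evoked_window[0]) & (t < evoked_window[1])] = "evoked"
    return QuantalEventSet(times=t, amplitudes=events.amplitudes, labels=labels,
                           n_sweeps=events.n_sweeps,
                           spont_window=spont_window, evoked_window=evoked_window,
                           sweep_ids=events.sweep_ids)


def event_rates(events: QuantalEventSet) -> dict:
    """Per-cell quantal statistics from a labelled, pooled event set.

    Rates are counts divided by ``n_sweeps`` times the window duration
    (1.0 s spontaneous, 0.3 s evoked).  Amplitudes are means over the
    labelled events; NaN when no event fell in a window.
    """
    if events.n_sweeps < 1:
        raise InvalidParameterError("need at least one sweep")
    spont_dur = (events.spont_window[1] - events.spont_window[0]) / 1000.0
    evoked_dur = (events.evoked_window[1] - events.evoked_window[0]) / 1000.0
    sp = events.labels == "spontaneous"
    ev = events.labels == "evoked"
    return {
        "spont_hz": float(sp.sum() / (events.n_sweeps * spont_dur)),
        "evoked_hz": float(ev.sum() / (events.n_sweeps * evoked_dur)),
        "spont_amp_pA": float(events.amplitudes[sp].mean()) if sp.any() else float("nan"),
        "evoked_amp_pA": float(events.amplitudes[ev].mean()) if ev.any() else float("nan"),
        "n_spont": int(sp.sum()),
        "n_evoked": int(ev.sum()),
        "n_sweeps": int(events.n_sweeps),
    }
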