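"""Synthetic optogenetic-mapping and quantal-release experiments.

This module generates complete, ground-truthed stand-ins for the raw
recordings of a callosal-input mapping study: paired neighbouring WT/KO
L2/3 neurons driven by one shared presynaptic axon field, photostimulated
over a grid (sCRACM, action-potential maps, LSPS) or in bulk (LED), plus
Sr2+ asynchronous quantal-release sweeps.

Generative model
----------------
* EPSC waveform: difference of exponentials, peak-normalised, inward
  (negative) current.
* Spatial innervation: an isotropic 2-D Gaussian amplitude field over the
  grid, centred ``field_offset_y`` um pia-ward of the soma (callosal input
  is strongest at the proximal apical dendrite).
* Trial-to-trial release: binomial(``n_sites``, ``p_release``) vesicles per
  stimulus with lognormal quantal sizes.  The two members of a pair share
  the presynaptic draws (they are driven by the same axons); the genotype
  acts as a multiplicative postsynaptic scale ``ko_scale`` on synaptic (not
  direct) current, so in the noiseless limit the per-sweep KO/WT amplitude
  ratio equals ``ko_scale`` exactly.
* Direct (non-synaptic) uncaging responses: only at spots within 50 um of
  the soma, onset ``direct_onset`` (< 5 ms), sub-millisecond rise; possible
  in LSPS and AP-map modes, never in sCRACM (TTX/4-AP leaves synaptic
  terminal release only).
* Sr2+ sweeps: homogeneous Poisson spontaneous events over the whole sweep
  plus an inhomogeneous Poisson evoked component with rate
  ``evoked_rate0 * exp(-(t - t_flash)/evoked_tau)`` after the flash.
* Recording noise: additive white Gaussian, ``noise_sd`` pA.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SynthConfig.seed``, so identical configs produce bit-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .core import CellRecording, GridGeometry, SweepRecord
from .exceptions import InvalidParameterError

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "make_epsc_kernel",
    "epsc_peak_time",
    "simulate_grid_experiment",
    "simulate_sr_sweep",
    "simulate_sr_experiment",
    "evoked_rate0_for_window_rate",
    "sample_release_amplitudes",
]

#: Mode-specific defaults: grid geometry, sweep timing, repeat count, and
#: whether direct (non-synaptic) contamination is possible.
MODE_DEFAULTS = {
    "sCRACM": dict(grid_rows=12, grid_cols=12, x_spacing=50.0, y_spacing=50.0,
                   sweep_len=150.0, stim_onset=10.0, n_repeats=3),
    "AP_map": dict(grid_rows=8, grid_cols=8, x_spacing=75.0, y_spacing=100.0,
                   sweep_len=150.0, stim_onset=10.0, n_repeats=3),
    "LSPS": dict(grid_rows=16, grid_cols=16, x_spacing=50.0, y_spacing=60.0,
                 sweep_len=150.0, stim_onset=10.0, n_repeats=3),
    "LED_bulk": dict(grid_rows=1, grid_cols=1, x_spacing=50.0, y_spacing=50.0,
                     sweep_len=150.0, stim_onset=10.0, n_repeats=5),
    "Sr2+": dict(sweep_len=1500.0, stim_onset=1100.0),
}

DIRECT_CAPABLE_MODES = ("LSPS", "AP_map")


@dataclass
class SynthConfig:
    """All knobs of the synthetic experiment.

    Defaults are the study conditions: 12x12 sCRACM grid at 50 um spacing,
    quantal amplitude 12 pA (spontaneous) / 15 pA (evoked), spontaneous
    rate 1.3 Hz, evoked-window rate 8.3 Hz, genotype effect ko_scale=0.6
    (a 40 % reduction), 15 pairs.
    """

    seed: int = 0
    dt: float = 0.1                 # ms per sample (10 kHz)
    sweep_len: float = 150.0        # ms
    stim_onset: float = 10.0        # ms
    grid_rows: int = 12
    grid_cols: int = 12
    x_spacing: float = 50.0         # um
    y_spacing: float = 50.0         # um
    tau_rise: float = 0.5           # ms, EPSC kernel
    tau_decay: float = 5.0          # ms
    noise_sd: float = 2.0           # pA, recording noise
    n_sites: int = 10               # release sites per spot
    p_release: float = 0.5
    quantal_amp_mean: float = 12.0  # pA, lognormal quantal size
    quantal_amp_cv: float = 0.3
    ko_scale: float = 0.6           # multiplicative genotype effect
    direct_frac: float = 0.5        # P(direct response) at peri-somatic spots
    direct_onset: float = 2.0       # ms (< 5)
    direct_tau_rise: float = 0.2    # ms, << tau_rise
    direct_tau_decay: float = 10.0  # ms
    direct_amp_mean: float = 150.0  # pA
    direct_radius: float = 50.0     # um from soma
    led_power: float = 2.0          # mW
    spont_rate: float = 1.3         # Hz, Sr2+ spontaneous events
    evoked_rate0: float = 22.6      # Hz at the flash; decays with evoked_tau
    evoked_tau: float = 150.0       # ms
    evoked_amp_mean: float = 15.0   # pA, evoked quantal size
    n_pairs: int = 15
    n_repeats: int = 3              # stimuli per grid spot
    n_sr_sweeps: int = 12           # flashes per cell in Sr2+ mode
    # innervation field (soma-relative um)
    field_sigma: float = 100.0
    field_peak_amp: float = 60.0    # pA mean peak at the field centre
    field_offset_y: float = 100.0   # field centre, pia-ward of soma
    pair_amp_cv: float = 0.4        # pair-to-pair lognormal scatter of field amp
    bulk_gain: float = 5.0          # LED-bulk amplitude = bulk_gain * field_peak_amp
    syn_latency: float = 7.0        # ms, synaptic onset after stimulus
    syn_latency_jitter: float = 1.0 # ms, +/- uniform per spot

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if not (0 < self.p_release <= 1):
            raise InvalidParameterError("p_release must be in (0, 1]")
        if self.ko_scale <= 0:
            raise InvalidParameterError("ko_scale must be positive")
        if not (self.tau_decay > self.tau_rise > 0):
            raise InvalidParameterError("need tau_decay > tau_rise > 0")
        if not (self.direct_tau_decay > self.direct_tau_rise > 0):
            raise InvalidParameterError("need direct_tau_decay > direct_tau_rise > 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")
        if self.spont_rate < 0 or self.evoked_rate0 < 0:
            raise InvalidParameterError("event rates must be non-negative")
        if self.n_sites < 1:
            raise InvalidParameterError("n_sites must be >= 1")
        if self.direct_onset >= 5.0:
            raise InvalidParameterError("direct_onset must be < 5 ms")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "SynthConfig":
        """Config with the grid geometry / timing defaults of ``mode``."""
        if mode not in MODE_DEFAULTS:
            raise InvalidParameterError(f"unknown mode {mode!r}")
        kw = dict(MODE_DEFAULTS[mode])
        kw.update(overrides)
        return cls(**kw)

    @property
    def grid(self) -> GridGeometry:
        return GridGeometry(self.grid_rows, self.grid_cols,
                            self.x_spacing, self.y_spacing)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover.

    ``cells[cell_id]`` holds the per-spot true synaptic and direct peak
    amplitudes (row-major nested lists); ``sweeps[sweep_id]`` holds the
    per-sweep realised amplitudes; ``sr_events[sweep_id]`` the true event
    times (ms, relative to the flash) and amplitudes.
    """

    ko_scale: float
    config: dict = field(default_factory=dict)
    cells: dict = field(default_factory=dict)
    sweeps: dict = field(default_factory=dict)
    sr_events: dict = field(default_factory=dict)

    @property
    def true_ratio(self) -> float:
        """True KO/WT synaptic amplitude ratio (the genotype effect)."""
        return self.ko_scale


def _lognormal_params(mean: float, cv: float) -> tuple:
    """(mu, sigma) of a lognormal with given mean and coefficient of variation."""
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def epsc_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time-to-peak (ms after onset) of the difference-of-exponentials kernel.

    Closed form: ``t* = tau_r*tau_d/(tau_d - tau_r) * ln(tau_d/tau_r)``.
    """
    return tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)


def make_epsc_kernel(amp: float, tau_rise: float, tau_decay: float,
                     onset: float, dt: float, sweep_len: float) -> np.ndarray:
    """Difference-of-exponentials EPSC trace, peak magnitude ``amp``.

    The trace is zero before ``onset`` and deflects negative (inward
    current).  Normalised so the analytic peak magnitude equals ``amp``.
    """
    if dt <= 0 or tau_rise <= 0 or tau_decay <= 0:
        raise InvalidParameterError("dt and time constants must be positive")
    if tau_decay <= tau_rise:
        raise InvalidParameterError("need tau_decay > tau_rise")
    n = int(round(sweep_len / dt))
    trace = np.zeros(n)
    if amp == 0:
        return trace
    t = np.arange(n) * dt
    s = t - onset
    m = s >= 0
    g = np.exp(-s[m] / tau_decay) - np.exp(-s[m] / tau_rise)
    tpk = epsc_peak_time(tau_rise, tau_decay)
    gmax = math.exp(-tpk / tau_decay) - math.exp(-tpk / tau_rise)
    trace[m] = -amp * g / gmax
    return trace


def sample_release_amplitudes(rng: np.random.Generator, n_trials: int,
                              n_sites: int, p_release: float,
                              quantal_mean: float, quantal_cv: float) -> np.ndarray:
    """Per-trial evoked amplitudes under the binomial quantal model.

    Each trial releases ``k ~ Binomial(n_sites, p_release)`` vesicles whose
    lognormal sizes (mean ``quantal_mean``, CV ``quantal_cv``) sum to the
    trial amplitude.  With ``quantal_cv = 0`` the classical closed form
    ``CV = sqrt((1-p)/(N p))`` holds in the large-trial limit.
    """
    ks = rng.binomial(n_sites, p_release, size=n_trials)
    total = int(ks.sum())
    if quantal_cv > 0:
        mu, sig = _lognormal_params(quantal_mean, quantal_cv)
        sizes = rng.lognormal(mu, sig, size=total)
    else:
        sizes = np.full(total, quantal_mean)
    amps = np.zeros(n_trials)
    edges = np.concatenate([[0], np.cumsum(ks)])
    for i in range(n_trials):
        amps[i] = sizes[edges[i]:edges[i + 1]].sum()
    return amps


def _innervation_field(config: SynthConfig) -> np.ndarray:
    """Mean synaptic peak amplitude (pA) per grid spot, soma-relative."""
    g = config.grid
    vals = np.zeros((g.rows, g.cols))
    for r in range(g.rows):
        for c in range(g.cols):
            x, y = g.relative_coords(r, c)
            d2 = x * x + (y - config.field_offset_y) ** 2
            vals[r, c] = config.field_peak_amp * math.exp(
                -d2 / (2.0 * config.field_sigma ** 2))
    return vals


def simulate_grid_experiment(config: SynthConfig, mode: str = "sCRACM"):
    """Paired WT/KO grid-mapping (or LED-bulk) experiment.

    Returns ``(cells, ground_truth)`` where ``cells`` is a flat list of
    ``2 * n_pairs`` :class:`CellRecording` objects.  Stimulation order is a
    seeded pseudorandom permutation of the grid spots per repeat (shared by
    both members of a pair, which are recorded simultaneously).
    """
    if mode not in ("sCRACM", "AP_map", "LSPS", "LED_bulk"):
        raise InvalidParameterError(f"unknown grid mode {mode!r}")
    if config.n_pairs < 1:
        raise InvalidParameterError("n_pairs must be >= 1")
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    bulk = mode == "LED_bulk"
    allow_direct = mode in DIRECT_CAPABLE_MODES
    stim_kind = "LED" if bulk else ("uncage" if mode == "LSPS" else "laser")

    gt = GroundTruth(ko_scale=config.ko_scale, config=config.to_dict())
    cells = []
    for p in range(config.n_pairs):
        pair_id = f"pair{p:03d}"
        # pair-to-pair biological scatter of overall input strength
        if config.pair_amp_cv > 0:
            mu, sig = _lognormal_params(1.0, config.pair_amp_cv)
            pair_scale = rng.lognormal(mu, sig)
        else:
            pair_scale = 1.0
        # slice-frame soma position (arbitrary translation; maps must undo it)
        soma = (float(rng.uniform(-200, 200)), float(rng.uniform(-300, -100)))
        if bulk:
            field_amp = np.array([[config.bulk_gain * config.field_peak_amp]])
        else:
            field_amp = _innervation_field(config)
        field_amp = field_amp * pair_scale
        # synaptic latency per spot (presynaptic property -> shared in pair)
        lat = config.syn_latency + rng.uniform(
            -config.syn_latency_jitter, config.syn_latency_jitter, size=field_amp.shape)
        # direct-response sites, drawn independently per cell (dendrite-specific)
        direct_amp = {gen: np.zeros_like(field_amp) for gen in ("WT", "KO")}
        if allow_direct and config.direct_frac > 0:
            for gen in ("WT", "KO"):
                for (r, c) in grid.all_indices():
                    x, y = grid.relative_coords(r, c)
                    if math.hypot(x, y) <= config.direct_radius and \
                            rng.random() < config.direct_frac:
                        mu, sig = _lognormal_params(config.direct_amp_mean, 0.3)
                        direct_amp[gen][r, c] = rng.lognormal(mu, sig)

        pair_cells = {}
        for gen in ("WT", "KO"):
            cell_id = f"{pair_id}_{gen}"
            pair_cells[gen] = CellRecording(
                cell_id=cell_id, genotype=gen, pair_id=pair_id, mode=mode,
                dt=config.dt, stim_onset=config.stim_onset, soma_pos=soma,
                grid=None if bulk else grid, led_power=config.led_power,
                metadata={"seed": config.seed})
            scale = config.ko_scale if gen == "KO" else 1.0
            gt.cells[cell_id] = {
                "genotype": gen, "pair_id": pair_id,
                "true_syn": (field_amp * scale).tolist(),
                "true_direct": direct_amp[gen].tolist(),
            }

        spots = list(grid.all_indices())
        counter = {g: 0 for g in ("WT", "KO")}
        for rep in range(config.n_repeats):
            order = rng.permutation(len(spots))
            for si in order:
                r, c = spots[si]
                mean_amp = field_amp[r, c]
                # shared presynaptic release draw for the pair
                q = mean_amp / (config.n_sites * config.p_release)
                trial_amp = float(sample_release_amplitudes(
                    rng, 1, config.n_sites, config.p_release,
                    q if q > 0 else 1.0, config.quantal_amp_cv)[0]) if q > 0 else 0.0
                for gen in ("WT", "KO"):
                    cell = pair_cells[gen]
                    scale = config.ko_scale if gen == "KO" else 1.0
                    syn_amp = trial_amp * scale
                    trace = make_epsc_kernel(
                        syn_amp, config.tau_rise, config.tau_decay,
                        config.stim_onset + lat[r, c], config.dt, config.sweep_len)
                    d_amp = direct_amp[gen][r, c]
                    if d_amp > 0:
                        trace = trace + make_epsc_kernel(
                            d_amp, config.direct_tau_rise, config.direct_tau_decay,
                            config.stim_onset + config.direct_onset,
                            config.dt, config.sweep_len)
                    if config.noise_sd > 0:
                        trace = trace + rng.normal(0, config.noise_sd, trace.size)
                    sid = f"{cell.cell_id}_s{counter[gen]:04d}"
                    counter[gen] += 1
                    cell.sweeps.append(SweepRecord(
                        samples=trace, dt=config.dt, stim_onset=config.stim_onset,
                        stim_kind=stim_kind, grid_index=None if bulk else (r, c),
                        power=config.led_power, sweep_id=sid))
                    gt.sweeps[sid] = {
                        "cell_id": cell.cell_id, "grid_index": None if bulk else [r, c],
                        "syn_amp": syn_amp, "direct_amp": float(d_amp),
                        "repeat": rep,
                    }
        cells.extend(pair_cells.values())
    return cells, gt


def _sample_sr_event_times(rng: np.random.Generator, config: SynthConfig,
                           evoked_rate0: Optional[float] = None) -> np.ndarray:
    """Event times (ms from sweep start) for one Sr2+ sweep.

    Spontaneous: homogeneous Poisson at ``spont_rate`` over the whole sweep.
    Evoked: inhomogeneous Poisson, rate ``r0 * exp(-(t - t_flash)/tau)`` for
    t > t_flash, sampled by inverse transform of the truncated exponential.
    """
    T, t0 = config.sweep_len, config.stim_onset
    r0 = config.evoked_rate0 if evoked_rate0 is None else evoked_rate0
    n_spont = rng.poisson(config.spont_rate * T / 1000.0)
    t_spont = rng.uniform(0, T, size=n_spont)
    tau = config.evoked_tau
    span = T - t0
    frac = 1.0 - math.exp(-span / tau)
    lam = r0 / 1000.0 * tau * frac   # expected evoked count
    n_ev = rng.poisson(lam)
    u = rng.uniform(0, 1, size=n_ev)
    t_ev = t0 - tau * np.log(1.0 - u * frac)
    return np.sort(np.concatenate([t_spont, t_ev]))


def simulate_sr_sweep(config: SynthConfig, rng: Optional[np.random.Generator] = None,
                      evoked_rate0: Optional[float] = None):
    """One Sr2+ sweep: ``(SweepRecord, events)``.

    ``events`` is a list of ``(time_ms_rel_flash, amplitude_pA)`` ground-truth
    pairs.  Spontaneous events carry lognormal amplitudes with mean
    ``quantal_amp_mean``; evoked (post-flash) events with mean
    ``evoked_amp_mean``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = _sample_sr_event_times(rng, config, evoked_rate0)
    trace = np.zeros(int(round(config.sweep_len / config.dt)))
    events = []
    for t in times:
        mean = config.evoked_amp_mean if t > config.stim_onset else config.quantal_amp_mean
        if config.quantal_amp_cv > 0:
            mu, sig = _lognormal_params(mean, config.quantal_amp_cv)
            amp = float(rng.lognormal(mu, sig))
        else:
            amp = mean
        trace += make_epsc_kernel(amp, config.tau_rise, config.tau_decay,
                                  float(t), config.dt, config.sweep_len)
        events.append((float(t - config.stim_onset), amp))
    if config.noise_sd > 0:
        trace = trace + rng.normal(0, config.noise_sd, trace.size)
    sweep = SweepRecord(samples=trace, dt=config.dt, stim_onset=config.stim_onset,
                        stim_kind="LED", power=config.led_power)
    return sweep, events


def simulate_sr_experiment(config: SynthConfig):
    """Paired Sr2+ quantal-release experiment.

    Each cell receives ``n_sr_sweeps`` LED flashes.  The genotype effect is
    on the evoked event rate (``evoked_rate0 * ko_scale`` for KO cells);
    spontaneous rate and quantal amplitudes are genotype-independent, as a
    change in release-site number or release probability predicts.
    """
    if config.n_pairs < 1:
        raise InvalidParameterError("n_pairs must be >= 1")
    if config.sweep_len < config.stim_onset + 350.0:
        raise InvalidParameterError(
            "Sr2+ sweeps need >= 350 ms after the flash; increase sweep_len")
    rng = np.random.default_rng(config.seed)
    gt = GroundTruth(ko_scale=config.ko_scale, config=config.to_dict())
    cells = []
    for p in range(config.n_pairs):
        pair_id = f"pair{p:03d}"
        soma = (float(rng.uniform(-200, 200)), float(rng.uniform(-300, -100)))
        for gen in ("WT", "KO"):
            cell_id = f"{pair_id}_{gen}"
            cell = CellRecording(
                cell_id=cell_id, genotype=gen, pair_id=pair_id, mode="Sr2+",
                dt=config.dt, stim_onset=config.stim_onset, soma_pos=soma,
                led_power=config.led_power, metadata={"seed": config.seed})
            r0 = config.evoked_rate0 * (config.ko_scale if gen == "KO" else 1.0)
            gt.cells[cell_id] = {"genotype": gen, "pair_id": pair_id,
                                 "evoked_rate0": r0, "spont_rate": config.spont_rate}
            for k in range(config.n_sr_sweeps):
                sweep, events = simulate_sr_sweep(config, rng, evoked_rate0=r0)
                sid = f"{cell_id}_s{k:04d}"
                sweep.sweep_id = sid
                cell.sweeps.append(sweep)
                gt.sweeps[sid] = {"cell_id": cell_id, "grid_index": None,
                                  "n_events": len(events)}
                gt.sr_events[sid] = [[t, a] for t, a in events]
            cells.append(cell)
    return cells, gt


def evoked_rate0_for_window_rate(target_hz: float, config: SynthConfig,
                                 window: tuple = (50.0, 350.0)) -> float:
    """Initial evoked rate ``r0`` so the *total* mean event rate in the
    post-flash ``window`` (spontaneous + evoked) equals ``target_hz``.

    Integral of the decaying rate over [w0, w1]:
    ``r0 * tau * (exp(-w0/tau) - exp(-w1/tau)) / 1000`` events.
    """
    w0, w1 = window
    dur_s = (w1 - w0) / 1000.0
    integral = config.evoked_tau / 1000.0 * (
        math.exp(-w0 / config.evoked_tau) - math.exp(-w1 / config.evoked_tau))
    excess = (target_hz - config.spont_rate) * dur_s
    if excess < 0:
        raise InvalidParameterError("target rate below the spontaneous rate")
    return excess / integral
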