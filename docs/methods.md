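# Methods

This note documents the models, estimators and numerical choices behind
`optomap`, and what the synthetic-data tests do and do not demonstrate
about real recordings.

## Signal model

Membrane current is stored signed (pA) at uniform sampling, inward current
negative; reported amplitudes are positive magnitudes. The EPSC waveform is
a peak-normalised difference of exponentials,

    I(t) = −A · [e^{−(t−t₀)/τ_d} − e^{−(t−t₀)/τ_r}] / g(t*),

with analytic time-to-peak t* = τ_r τ_d/(τ_d−τ_r) · ln(τ_d/τ_r). Defaults
τ_r = 0.5 ms, τ_d = 5 ms (AMPAR kinetics); direct uncaging responses use
τ_r = 0.2 ms, τ_d = 10 ms with 2 ms onset. The default sampling interval is
0.1 ms (10 kHz), which resolves sub-millisecond rise times; recording noise
is additive white Gaussian with SD 2 pA, a typical whole-cell baseline.

## Synthetic experiments

The generator emulates the statistical structure of paired optogenetic
mapping experiments; its defaults are the study conditions.

* **Spatial innervation.** An isotropic 2-D Gaussian amplitude field
  (σ = 100 µm, peak 60 pA) centred 100 µm pia-ward of the soma, matching
  input that is strongest at the proximal apical dendrite. Grid geometries:
  sCRACM 12×12 at 50 µm; LSPS 16×16 at 50×60 µm; action-potential maps 8×8
  at 75×100 µm. Stimulation order is a seeded pseudorandom permutation of
  spots per repeat, 3 repeats per spot (5 sweeps for bulk LED).
* **Release model.** Per stimulus, k ~ Binomial(N = 10, p = 0.5) vesicles
  with lognormal quantal sizes (mean 12 pA, CV 0.3) sum to the trial
  amplitude, scaled so its expectation equals the local field value. A
  double-patch experiment records two neighbouring neurons under
  identical stimulation; the generator accordingly shares the presynaptic
  draws between pair members, and the genotype acts as a multiplicative
  postsynaptic scale (`ko_scale`, default 0.6) on synaptic — never direct —
  current. In the noiseless limit the per-sweep KO/WT ratio therefore
  equals `ko_scale` exactly, which is the anchor for parameter-recovery
  tests. Pair-to-pair heterogeneity is a lognormal scale with CV 0.4.
  N and p are free parameters of the model, not measured values.
* **Direct responses** occur only at spots within 50 µm of the soma
  (probability 0.5 per eligible spot, amplitude ~150 pA), only in LSPS and
  AP-map modes; sCRACM in TTX/4-AP has none by construction. This makes the
  < 5 ms onset classification rule discriminative by design.
* **Sr²⁺ sweeps.** Spontaneous events are homogeneous Poisson (1.3 Hz) over
  the whole sweep; evoked events follow an inhomogeneous Poisson rate
  r₀·e^{−(t−t_flash)/τ} with τ = 150 ms and r₀ = 22.6 Hz, chosen in closed
  form so the total mean rate in the 50–350 ms window is 8.3 Hz.
  Spontaneous amplitudes average 12 pA, evoked 15 pA. The genotype scales
  the evoked *rate* (frequency, not amplitude, changes with synapse number
  or release probability). Flashes come every 30 s in the emulated
  paradigm; 12 flashes per cell by default.

What the generator does **not** emulate: dendritic filtering and space-clamp
error, series-resistance artefacts, polysynaptic recruitment, opsin
desensitisation, electrode drift, or correlated (non-white) noise. Passing
parameter-recovery tests therefore demonstrates correctness of the
estimators under the stated stochastic model, not robustness to every
failure mode of real recordings.

## Estimators

* **Amplitude.** Responses are averaged across repeats first, then
  baseline-subtracted (pre-stimulus window) and measured: peak magnitude in
  a half-open window after stimulus onset (5–80 ms for sCRACM/LSPS/LED,
  5–150 ms for slow NMDAR-EPSCs) or the rectified 2–30 ms mean for
  action-potential maps (excluding polysynaptic contamination). On noisy
  averages the peak is read after a ~1 ms boxcar (≈1 kHz filtering, the
  conventional bandwidth for EPSC peak measurement) and refined by
  parabolic interpolation through the discrete maximum; without the
  sub-sample refinement the estimate snaps to the sample grid, which
  introduces a quasi-discrete component into paired differences and
  distorts the downstream normality gate.
* **Onset latency** is the first time the trace stays beyond 3× the
  baseline noise SD for ≥ 0.5 ms — robust to single-sample noise.
* **Direct-response handling.** A response is *direct* if onset < 5 ms and
  the 20–80 % rise time is < 1 ms ("visibly faster" operationalised; the
  threshold is configurable); *mixed* if a second, slower supra-threshold
  component follows. The second component is located as the next prominent
  local maximum of the rectified smoothed trace, with the synaptic onset at
  the intervening valley. The direct decay is fitted from its peak to that
  valley (or the window end for pure direct) with
  A₁e^{−t/τ₁} + A₂e^{−t/τ₂}, initialised by log-linear peeling, bounds
  τ ∈ (0.05, 500] ms, Levenberg–Marquardt/TRF via `scipy.optimize.curve_fit`
  (≤ 2000 function evaluations ≈ 500 iterations); the fit is extrapolated
  across the analysis window and subtracted. The unmodelled rising phase
  (entirely earlier than the 5 ms window start) is zeroed. Pure direct
  pixels are excluded from maps rather than corrected; non-converging fits
  flag the pixel unusable (also excluded).
* **Event detection** re-implements standard mEPSC threshold detection:
  median-centred trace, noise SD via 1.4826·MAD (robust to sparse events),
  0.5 ms boxcar smoothing, local minima exceeding k·SD (k = 3) with a
  prominence floor of 0.6× the threshold and a 2 ms refractory (`min_iei`;
  closer minima merge into the larger event). The prominence floor is what
  keeps noise ripple on an event's decay from splitting it, while staying
  low enough not to suppress events riding on a predecessor's decay at high
  evoked rates; 0.6 balances the two failure modes across 0.5–15 Hz.
  Amplitudes are measured against a local pre-event baseline (median of the
  smoothed trace 6–1.5 ms before the peak). Residual biases are the
  refractory merge loss (≈ e^{−rate·2 ms}) and sub-threshold misses; both
  stay under 5 % at the default amplitudes (≥ 4× noise SD).
* **Windows.** All event windows are half-open in ms relative to the flash:
  spontaneous [−1000, 0), evoked [50, 350). Rates divide pooled counts by
  n_sweeps × window duration (1.0 s / 0.3 s).

## Maps

Pixel values refer to pixel centres; x is lateral, y vertical with pia-ward
positive; aligned frames put the soma (or home-barrel centre) at the
origin. Group averaging uses soma-aligned, power-normalised (default on),
half-interpolated maps; per-cell statistics (region means, vertical
profiles) use the un-interpolated maps. Bilinear resampling is a single
primitive shared by pixel halving and barrel alignment, with conservative
mask propagation: an output pixel whose stencil touches any masked input
pixel is masked, so interpolation never fabricates values where direct
responses were deleted. Barrel alignment mirrors (optional medial–lateral
flip), stretches per axis about the home-barrel centre to the reference
barrel size, translates the centre to the origin, and resamples onto the
nominal-spacing lattice through the origin — the common frame for group
averaging; with reference = home this is a pure translation and
grid-commensurate values round-trip exactly. Group pixels sampled by fewer
than `min_n` = 8 neurons are masked ("black pixels").

## Statistics

Each dataset is screened with D'Agostino-Pearson (`scipy.stats.normaltest`)
and Anderson-Darling (`scipy.stats.anderson`, interpolated p-value, which
makes the gate exact at any α) at α = 0.05 per test; only datasets passing
both receive parametric tests. Below n = 8 the omnibus tests are
uninformative and the rank test is used directly, as it is for
zero-variance differences. Paired data use paired *t* / Wilcoxon matched
pairs, independent groups unpaired *t* / Mann-Whitney, all two-sided. A
sign-flip permutation test (10⁴ flips, add-one-corrected) serves as an
assumption-free cross-check of the gated procedure. The two-way interaction
ANOVA is a classical fixed-effects OLS fit (statsmodels, type-II sums of
squares) with Šidák-adjusted pairwise cell comparisons on request; for
vertical profiles, per-row paired comparisons plus this interaction ANOVA
stand in for random-effects profile models, whose structure is deliberately
out of scope. CV is computed on raw (not power-normalised) single-cell
trial amplitudes — power is constant within a cell — and requires ≥ 3
trials and a positive mean.

## Calibration and problem sizes

The packaged checks run, per replicate, a complete paired bulk-LED
experiment (15 pairs × 2 cells × 5 sweeps at 10 kHz) — the design whose
group sizes the percent-change examples use. Ratio recovery averages 20
replicate experiments; type-I calibration of the gated test uses 1000
null replicates (rejection rate ≈ 0.054); detector calibration uses 1000
Sr²⁺ sweeps per rate regime. These sizes give sampling error comfortably
below the tolerances they are checked against while keeping the whole
suite in the low minutes on one CPU.

## Known limitations

Fixed-effects ANOVA replaces the mixed-effects profile analysis; event
detection is threshold-based (no template matching or deconvolution), so
heavily overlapping quantal events at rates well above ~15 Hz in-window
are undercounted; the double-exponential subtraction assumes the direct
decay is bi-exponential and the synaptic onset separable (> ~2 ms after
the direct peak); barrel rectangles are user-supplied metadata, not
segmented from images; datasets are plain text (CSV + JSON), with an NWB
adapter left as an extension point.
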