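# Methods

This note records the models implemented in `spinelab`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions that matter when reproducing results.

## FLIM-FRET decay model and binding fraction

TCSPC decays are modeled as a two-component mixture: free donor with
lifetime τ_D and FRET-quenched bound donor with lifetime τ_AD < τ_D, each
an exponential convolved with a Gaussian instrument response of width τ_G
and offset t0:

F(t) = F0 [ P_D H(t; t0, τ_D, τ_G) + P_AD H(t; t0, τ_AD, τ_G) ],
H(t) = ½ exp(τ_G²/2τ² − (t−t0)/τ) erfc((τ_G² − τ(t−t0)) / (√2 τ τ_G)).

τ_D is fixed at 2.6 ns, the fluorescence lifetime of free eGFP, so the fit
estimates (P_AD, τ_AD, t0, τ_G) plus amplitude.

**Numerical stability.** The erfc prefactor exp(τ_G²/2τ²) overflows for
small τ. Writing z for the erfc argument, the identity
erfc(z) = erfcx(z)·exp(−z²) collapses the full exponent to
−(t−t0)²/(2τ_G²) whenever z ≥ 0; for z < 0 the direct prefactor exponent
is itself negative. `decay_component` branches on sign(z) and is verified
against direct numerical quadrature of the convolution integral.

**Fitting objective.** TCSPC bin counts are Poisson, so the fit maximizes
the Poisson likelihood of the binned counts. The amplitude enters the
expected counts linearly and its Poisson-optimal value at fixed shape is
total counts / Σ shape, so it is profiled out analytically; L-BFGS-B then
optimizes the remaining four parameters under box bounds: P_AD ∈ [0, 1]
(box bounds rather than a logit transform, so the estimator can land on
the P_AD = 0 boundary exactly in null-binding data), τ_AD ∈ (0.1 ns, τ_D),
τ_G ∈ (0.02, 1) ns, t0 within the first half of the record. Weighted least
squares (variance = max(counts, 1)) is available as a diagnostic fallback
(`objective="wls"`). Initialization is deterministic: P_AD = 0.2,
τ_AD = τ_D/2, τ_G = 0.15 ns, t0 at the histogram's rising-edge
half-maximum. Non-convergence raises a warning and is flagged in the
result, never silent.

**Bin handling.** The model is evaluated at bin centers by default; bins
(25 ns / 256 ≈ 0.1 ns) are narrow relative to both lifetimes. Exact
Simpson bin integration is available behind `bin_integration=True`.
Laser-period wrap-around (incomplete decay) is not modeled; the simulator
uses a 25-ns period (≈ 9.6 τ_D), which leaves < 10⁻⁴ of the decay mass
beyond the record, so truncation bias on the mean arrival time is ≈ 2 ps.
With shorter periods (< 5 τ_D) the unmodeled wrap-around would bias both
estimators; that regime is a known limitation.

**Moment estimator.** Per-pixel and per-ROI binding fractions come from
the mean photon arrival time ⟨t⟩ (count-weighted mean of bin centers).
With the whole-image t0 from the pooled fit, ⟨τ⟩ = ⟨t⟩ − t0 and

P_AD = τ_D(τ_D − ⟨τ⟩) / [(τ_D − τ_AD)(τ_D + τ_AD − ⟨τ⟩)].

This inversion is exact under the convention that P_D, P_AD are amplitude
fractions and each component's photon yield is proportional to amplitude ×
lifetime — the partition the synthetic generator implements (component
choice probability P_AD τ_AD / (P_D τ_D + P_AD τ_AD)). That convention is
the key correctness decision tying the estimator to the generator; under a
photon-fraction convention the closed form would not invert exactly.
Noise can push the estimate outside [0, 1]; out-of-range values are
returned with a warning and clipped only on request (silent clipping would
bias averages toward the interior).

**Photon floors.** Whole-image fit ≥ 10⁴ photons, per-pixel lifetime map
≥ 10 photons, ROI per frame ≥ 100 photons; all configurable. Frames or
pixels below the floor are masked (NaN), not dropped.

**QC.** Cells whose average baseline binding fraction exceeds 0.45 are
excluded from analysis (`qc_filter_cells`), matching the inclusion rule
for sensor-expressing cells.

## Volume time courses

ΔF/F₀ = (F − F₀)/F₀ with F₀ the mean of the first `baseline_n` points;
`baseline_n` defaults to 7 when at least 7 pre-stimulus points exist, and
at minimum 5 — the conventional five-to-seven-point baseline. Phase
windows (minutes from uncaging onset, t = 0 at the first pulse) are closed
on both ends, matching the "1 to 3 min" phrasing; an empty window raises
rather than returning 0.

**Expansion correction.** The expansion factor is determined from nuclei
areas before/after gel expansion. Dividing mean areas literally yields an
area ratio, but a "fourfold" expansion conventionally refers to the linear
scale; both conventions are implemented (`convention="area"`, the literal
ratio; `convention="linear"`, its square root) and the caller must choose
— the package never infers the convention from the data. Correcting a
length (e.g. a vesicle diameter) requires the linear factor.

## Uncaging-locked sweeps

The trace is segmented into consecutive 16-frame sweeps at 0.128 s/frame
(2.048-s uncaging period). The nominal 7.8-Hz frame rate implies 0.1282 s;
the 0.128-s rounding is adopted so that 16 frames equal the 2.048-s pulse
interval exactly and the post-pulse latencies are the printed
0.128–0.384 s. The pulse is taken to fall between frames 2 and 3 of each
sweep (frame indices are 1-based in user-facing arguments, 0-based
internally); sub-frame pulse latency is not modeled. Each sweep is
normalized to the mean of its own first two frames, which cancels the
slowly accumulating volume/release background; a non-positive per-sweep
baseline flags the sweep invalid rather than dropping it silently. With 7
baseline sweeps, uncaging pulse k lands in sweep 7 + k, so the default
pulse range 2–18 averages sweeps 9–25; the range is configurable (release
events can remain visible through pulse 22). Dispersion is reported as
SEM. The peak response is the mean of the three frames after the pulse.
Channel contrasts use a two-tailed paired t-test from scipy; a
zero-variance difference vector is reported as degenerate (or as t = 0,
p = 1 when the difference is identically zero) instead of a spurious
p = 0.

## TIRF events

The reference detector finds local maxima above a robust threshold
(median + k × 1.4826·MAD, default k = 4) with a matching prominence
requirement — prominence rejects noise bumps riding on the decay tail of a
previous event — and a minimum separation (default 0.5 s). The detector is
plumbing for synthetic data, not a reimplementation of any production
event-detection software. Frequencies are counts in half-open windows
[start, end) divided by window length; release-time histograms use
left-closed bins whose width must divide the window (default 10-s bins
over the 60-s stimulation span, giving 6 bins), and events exactly at the
window end are excluded — the standard half-open convention, stated
explicitly. Event kinetics are an explicit choice: 10–90 % interpolated
rise time and a mono-exponential least-squares decay constant; flat or
non-convergent decays are flagged. The electrical protocol is 30 bursts at
0.5 Hz of 20 × 1-ms impulses at 83 Hz (600 pulses, 60 s); uncaging is 30
single 6-ms pulses at 0.5 Hz.

Frequency windows default to basal = the full 60-s unstimulated movie and
stimulated = the 60-s span starting 4 s into the stimulated movie.
Frequencies are computed per recording, with per-cell grouping left to the
caller.

## Synthetic generators

All generators take an explicit seed, derive everything from it, and
return a manifest (`GroundTruth`) that, with the seed, fully determines
the output. There is no hidden global random state.

* **Photon histograms** — exact-count sampling (out-of-range arrivals are
  redrawn) under the amplitude × lifetime component partition above.
* **FLIM series** — spatially uniform P_AD inside the ROI, free donor
  outside, fixed photon budget per pixel. No optical PSF, no morphology.
* **Spine movies** — 7 baseline sweeps + 30 uncaging sweeps at
  0.128 s/frame. The volume transient is a saturating rise (τ = 20 s)
  decaying (τ = 60 s) to a sustained plateau (defaults: peak +100 %,
  plateau +40 % ΔF/F₀). Release transients (SEP mode only) are an
  instantaneous step with mono-exponential decay — a proxy for diffusion
  and re-acidification; the experiment does not constrain this shape, so
  it is declared, not inferred. Defaults: per-pulse amplitude 0.15 ΔF/F₀,
  decay τ = 1.0 s, per-pulse success probability 0.5 (not quantified
  experimentally; 0.5 makes roughly half the sweeps carry an event).
  Gamillus mode shares the volume channel and adds no release component.
  Noise is multiplicative Gaussian with variance proportional to signal
  (a shot-noise proxy appropriate for ROI-summed traces; fractional SD
  4 % at baseline), while FLIM data are Poisson at the photon level — the
  two noise regimes of the respective acquisitions.
* **Event trains** — inhomogeneous Poisson, basal rate outside the
  stimulation window and stimulated rate inside. Defaults basal 0.01 Hz,
  stimulated 0.05 Hz: sparse dense-core-vesicle release rates at which a
  paired design over 20 recordings resolves the step.

What passing tests show: the estimators are unbiased and correctly
calibrated **under the generative assumptions** (two-lifetime mixture,
Gaussian IRF, amplitude × lifetime photon yield, step-plus-exponential
release, Poisson events). Real recordings add autofluorescence and
background decay components, detector afterpulsing, bleaching, spine
motion and focus drift, and correlated noise — none of which are emulated,
so recovery accuracies measured here are upper bounds on real-data
performance.

## Problem sizes

The test suite and acceptance script run at the study's stated design
sizes where they are stated (20 seeds × 3×10⁵ photons for decay recovery;
13 spines per reporter scenario; 20 paired TIRF recordings; 100 trains
for rate calibration) and at small image geometries (≈ 10×10 pixel ROIs,
a few hundred photons per pixel) for the imaging paths, which keeps the
full suite under a minute while leaving every statistical check at its
design n.

## Known limitations

* No laser-period wrap-around in the decay model; short-period data are
  out of scope.
* Two decay components only; no background/scatter component, no phasor
  analysis.
* The sweep analysis assumes complete, regularly sampled traces (no
  dropped frames) and does not classify which sweeps contain true events.
* The event detector is intentionally simple; it assumes a stationary
  baseline and well-separated transients.
* The per-sweep measured release amplitude is compressed relative to the
  true per-event amplitude by within-window decay, sub-unity release
  probability, and division by the accumulated baseline; tests therefore
  compare against the accordingly adjusted expectation, not the raw
  amplitude parameter.
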