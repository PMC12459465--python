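# spinelab

Quantitative analysis of single-spine structural plasticity experiments:
FLIM-FRET binding-fraction estimation for a TrkB activation sensor,
ΔF/F₀ spine-volume time courses, uncaging-locked sweep analysis of fast
reporter release, and TIRF release-event statistics — together with a
synthetic-data generator that emulates each data regime so every stage can
be validated against known ground truth.

## Who this is for

Labs doing two-photon glutamate-uncaging experiments on dendritic spines
routinely combine several bespoke analyses: fitting TCSPC fluorescence
decays to read out FRET sensors, normalizing spine fluorescence to
pre-stimulus baselines, aligning fast reporter transients to uncaging
pulses, and counting exocytosis events in TIRF movies. `spinelab` packages
those analyses as tested, composable library functions with a thin CLI.

## The models

**FLIM-FRET binding fraction.** A donor decay with free and FRET-quenched
populations is modeled as

```
F(t) = F0 [ P_D · H(t; t0, τ_D, τ_G) + P_AD · H(t; t0, τ_AD, τ_G) ]
H(t)  = ½ exp(τ_G²/2τ² − (t−t0)/τ) · erfc((τ_G² − τ(t−t0)) / (√2 τ τ_G))
```

with `τ_D = 2.6 ns` (free eGFP) held fixed, `P_AD` the bound fraction, and
`τ_G` the Gaussian pulse-response width. `H` is evaluated through the
scaled complementary error function so it never overflows. Fits maximize
the Poisson likelihood of the binned counts. Images and ROI time courses
use the faster moment estimator: the mean photon arrival time `⟨t⟩` gives
the mean lifetime `⟨τ⟩ = ⟨t⟩ − t0`, and

```
P_AD = τ_D (τ_D − ⟨τ⟩) / [ (τ_D − τ_AD)(τ_D + τ_AD − ⟨τ⟩) ]
```

which exactly inverts the photon-weighted mixture mean
`⟨τ⟩ = (P_D τ_D² + P_AD τ_AD²)/(P_D τ_D + P_AD τ_AD)`. Traces are reported
as `P_AD − P_AD0` (baseline-subtracted); cells whose baseline binding
fraction exceeds 0.45 are excluded by the QC filter.

**Volume time courses.** `ΔF/F₀ = (F − F₀)/F₀` with `F₀` the mean of the
first 5–7 pre-stimulus points, summarized over named phase windows
(transient 1–3 min; sustained 9–11, 12–15 or 15–20 min).

**Uncaging-locked sweeps.** The stimulated-spine trace is cut into
16-frame sweeps (2.048 s at 0.128 s/frame; pulse between frames 2 and 3),
each sweep is normalized to its own first two frames, sweeps for pulses
2–18 (rows 9–25 after 7 baseline sweeps) are averaged, and the response is
the mean ΔF/F₀ of the three post-pulse frames (0.128–0.384 s latency).
Reporter vs. volume channels are compared with a paired t-test.

**TIRF events.** Release events are Poisson-like and sparse; the module
estimates basal vs. stimulated frequencies, bins release times (10-s bins
over the 60-s stimulation span), measures 10–90 % rise times and
mono-exponential decay constants, and encodes the stimulation schedule
(30 bursts of 20×1-ms impulses at 83 Hz, delivered at 0.5 Hz).

## Worked example

Simulate 13 spines with a pH-sensitive release reporter and ask whether
the per-pulse reporter response exceeds the volume-channel response:

```python
import numpy as np
from spinelab import synthetic, sweeps

scenario = synthetic.SpineScenario(reporter_mode="SEP")
spines, truth = synthetic.simulate_spine_movie(scenario, n_spines=13, seed=1)

peaks = {"reporter": [], "volume": []}
for channels in spines:
    for name in peaks:
        mat = sweeps.normalize_sweeps(sweeps.segment_sweeps(channels[name]))
        mean, sem = sweeps.average_sweeps(mat, pulse_range=(2, 18))
        peaks[name].append(sweeps.peak_response(mean))

res = sweeps.paired_channel_comparison(
    np.array(peaks["reporter"]), np.array(peaks["volume"])
)
print(f"mean reporter peak : {np.mean(peaks['reporter']):.4f} dF/F0")
print(f"mean volume peak   : {np.mean(peaks['volume']):.4f} dF/F0")
print(f"paired t({res.n - 1}) = {res.statistic:.2f}, p = {res.pvalue:.2e}")
```

Output:

```
mean reporter peak : 0.0432 dF/F0
mean volume peak   : 0.0055 dF/F0
paired t(12) = 12.85, p = 2.25e-08
```

The reporter channel carries a clear uncaging-locked response on top of
the slow volume signal (the per-pulse transients fire with probability 0.5
and decay within a sweep, so the measured mean peak sits below the 0.15
single-event amplitude), while the volume channel shows only the small
within-sweep volume drift. Running the same analysis with
`reporter_mode="Gamillus"` (pH-stable reporter) gives a non-significant
paired difference — the control that distinguishes release from
accumulation.

The same analyses are available from the shell:

```sh
spinelab simulate --scenario SEP --n-spines 13 --seed 1 --out sim/
spinelab sweeps --traces sim/traces.csv --pulses 2:18 --out out/
spinelab run --seed 0 --out demo/        # full synthetic demo pipeline
```

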