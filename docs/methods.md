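# Methods

This note documents the models, estimators and numerical choices behind
`sst_ersp`, in the order the pipeline runs them: task simulation, synthetic
ROI EEG, time-frequency decomposition, cluster statistics, and clinical
correlation analyses. It also states what the synthetic generator does and
does not emulate, and therefore what a passing test does and does not show
about real recordings.

## 1. Anticipated-response stop signal task

One trial: a 2000 ms fixation screen ("READY"), a "GET SET" cue with a
button press, a 1400 ms delay, then a car that moves for 1000 ms. On **go**
trials the button must be released 700–800 ms after motion onset (releases
< 700 ms are "Too early!", > 800 ms or never "Too late!"). On **stop**
trials the car halts at the stop signal delay (SSD) and the button must be
held to the end of the trial. Blocks mix go and stop trials 2:1; since 40
is not divisible by 3, blocks alternate 13 and 14 stop trials (54 stop /
106 go over a 4 × 40 session — the closest integer realization). A practice
phase (10 go, 10 stop, 20 mixed) is simulated, flagged, and excluded from
every summary.

**Staircase.** Each block starts at SSD = 500 ms. A successful stop moves
the SSD 50 ms later (harder), a failed stop 50 ms earlier (easier), clamped
to the 300–700 ms range in which the stop cue can appear. This one-up
one-down rule converges on the SSD at which stopping succeeds half the
time.

**Subject model.** A horse race between an anticipatory go process and a
stop process: the planned release latency (motion-locked) and the stop
process latency SSRT_i are independent truncated-normal (> 0) draws, and
the stop wins iff `ssd + ssrt_i <= planned_release`. Defaults
(go 798 ± 25 ms, stop 250 ± 35 ms, omission rate 0) reproduce the
group-level behavioral profile of the cohort the package models: mean
GO-RT ≈ 798 ms, mean SSD ≈ 548 ms, means-method SSRT
(`mean GO-RT − mean SSD`) ≈ 250 ms, go success rate ≈ 0.5.

**A deliberate bias.** The staircase's long-run success fraction is exactly
0.5 only in its stationary regime. Because every block restarts at 500 ms —
one step below the 548 ms equilibrium implied by the subject defaults — and
contains only 13–14 stop trials, each block carries a small warm-up excess
of successes. The exact Markov-chain expectation of the session mean
P(inhibit) under the defaults is 0.536; the unit tests check the simulator
against that dynamic-programming oracle rather than against an idealized
0.5. Empirical cohorts performing this task report P(inhibit) ≈ 0.54, which
is the same phenomenon.

**Summaries.** GO-RT averages go-trial releases only (omissions are
classified go_late and excluded; failed-stop releases never enter GO-RT —
the means method needs realized go latencies). SSD averages over all stop
trials. The identity `SSRT = mean GO-RT − mean SSD` holds on every row of
the summary table by construction, including the across-block mean.

## 2. Synthetic ROI source signals

The generator targets the data contract *after* recording, artifact
rejection and source localization: clean single-trial current-source
density traces per region of interest (right superior / middle / inferior
frontal gyri) at 1000 Hz. It emulates:

- **1/f background**: Gaussian noise shaped to `power ∝ 1/f^χ` (default
  χ = 1, clamped below 1 Hz), scaled analytically — not empirically — to the
  requested RMS so trials stay strictly Gaussian.
- **Band-limited oscillators** (e.g. a 10 ± 2 Hz alpha bump) as
  raised-cosine-edged filtered noise.
- **Injected ERD/ERS**: an effect multiplies the amplitude of the
  band-passed component of the composite signal by `10^(delta_db/20)`
  inside its time window, so measured *power* changes by exactly `delta_db`
  (dB is defined on power). Gains ramp on/off with 50 ms cosine ramps placed
  *outside* the nominal window: the in-window gain is exact and spectral
  splatter is controlled. Effects are locked to motion onset or to the stop
  signal, and can be restricted to one group.

It does **not** emulate: sensor-level data, volume conduction / inverse-
solution mixing between ROIs, tic or ocular artifacts, non-Gaussian or
non-stationary backgrounds, or feedback-driven behavioral strategy shifts.
Passing tests therefore demonstrate that the *analysis chain* is correct
and calibrated on data satisfying its assumptions — not that those
assumptions hold in any particular recording.

**Epochs.** Motion-locked epochs default to −500…+1000 ms (all trials),
stop-locked to −500…+800 ms (stop trials only). The baseline segment is the
last 200 ms of fixation of the same trial, stored twice: verbatim (the
contract) and with 500 ms of surrounding context, so that baseline wavelet
power can be computed free of convolution edge artifacts even at 3 Hz
(longest kernel half-length 478 ms).

**Cohorts.** `build_cohort` gives every subject a behavioral session,
per-trial ROI EEG and a clinical row (ages 10–17; tic/urge/OCD/ADHD scale
scores drawn around the modeled cohort's summary statistics, zero tic
scores for controls). A linkage option draws one effect's `delta_db` per
patient jointly with a clinical score: both load on standardized age and
their age-independent residuals are bivariate normal with the requested
correlation, so the population age-adjusted (partial) correlation equals
the target exactly. This enables end-to-end recovery tests of the
power-vs-severity analysis.

## 3. Time-frequency decomposition

95 complex Morlet wavelets, 3–50 Hz in 0.5 Hz steps; Gaussian-windowed
complex exponentials with `σ_t = cycles/(2πf)`, truncated at ±3 σ_t and
normalized to unit energy (white noise then yields flat expected power
across rows). The cycle count rises linearly from 3 at 3 Hz to 10 at
50 Hz — a standard resolution trade-off; it is a configuration knob
(constant or per-frequency alternatives) because results depend on it.
Convolution is frequency-domain multiplication with explicit edge
bookkeeping: output samples closer to an epoch edge than a kernel
half-length are flagged, analysis windows must avoid them, and the time
axis may be decimated after convolution (default every 5th sample).

dB normalization is per trial and per frequency:
`dB(f,t,trial) = 10·log10(P(f,t,trial) / mean_t' P_baseline(f,t',trial))`.
Per-trial baselines (rather than condition averages) keep trials
exchangeable units, which the trial-pooled permutation statistic below
requires; a trial-averaged baseline remains available as an option. The
normalization is exactly invertible given the stored baseline.

**Effect recovery estimator.** A wavelet centered near a band edge also
responds to power outside the band, so the raw in-band dB change
underestimates an injected effect. The package measures effects through an
explicit model: for each row, the expected in-band response fraction
`frac(f)` is computed from the kernel's actual discrete spectrum weighted
by a model PSD, and the plateau power ratio `m(f)` (trial means of linear
power, window inset by 2 temporal SDs; group-vs-group ratios preferred, as
per-trial baseline noise then cancels) is inverted through
`m = (1 − frac) + frac·10^(δ/10)`. Row estimates are combined with `frac²`
weights. The model assumes a *single* effect: with simultaneous effects in
adjacent bands the out-of-band term is itself scaled and recovery is
biased; recovery tests therefore inject one band per dataset. At 200
trials/group the estimator's empirical spread is ≈ 0.2 dB.

## 4. Cluster-based permutation statistics

dB power from both groups is pooled into a master array (frequency × time ×
trials) with per-trial group labels — a fixed-effects-over-trials design,
exactly as the master-array construction implies; a subject-level summary
test is out of scope. Per pixel, a pooled-variance two-sample t
(df = nA + nB − 2, variance floored at 1e−24 for constant pixels) compares
groups. Pixels with |t| above the two-tailed p = 0.05 critical value form
8-connected clusters (the default connectivity of the 2-D
connected-component routine this procedure is built around), each scored by
its mass Σ|t|.

The null distribution shuffles the trial-to-group labels (default 1000
permutations, seeded) and records each permutation's **maximum** cluster
mass, 0 if nothing survives — the standard familywise-valid summary; the
observed clusters are then compared against the 100·(1 − 0.05/3) = 98.33rd
percentile of that distribution (conventionally reported as "98.3"; the
threshold itself is computed at the exact percentile with linear
interpolation). Corrected p per cluster is the fraction of null masses at
or above its mass. Trials are shuffled freely across subjects, mirroring
the trial-pooled design. Permutation-Z maps
((observed − null mean)/null SD) are emitted as diagnostics only; masses
and thresholds use t throughout. Monte-Carlo calibration on exchangeable
null data (500 datasets, 30 × 50 × 80 arrays) gives a familywise
false-positive rate of 0.022 against the nominal 0.017.

For correlation analyses, a significant-cluster mask extracts each
patient's mean dB over the masked pixels of their trial-averaged map —
signed dB, so deeper desynchronization gives a more negative scalar.

## 5. Clinical statistics

Descriptives are mean, SD (n − 1) and median (even-n midpoint; the bundled
reference table's tic-severity median is 22.5, conventionally reported
rounded). "Age-adjusted correlation" is implemented as the first-order
partial Pearson correlation — Pearson on the least-squares residuals of
both variables after regressing on age plus intercept — with
`t = r·sqrt((n − k − 2)/(1 − r²))` for the p value; the residual route
equals the closed-form recursion to 1e−10 and matches an independent
implementation. FDR is Benjamini–Hochberg across exactly the three scales
entering the analysis (tic severity, obsessive-compulsive, ADHD), and the
power-vs-severity analysis runs only when a significant case-control
cluster exists. The behavioral correlation (SSRT vs self-rated tic
suppressibility) is a plain Pearson r; by construction better
suppressibility with faster stopping is negative.

## 6. Problem sizes, determinism, limitations

Every stochastic component draws from `numpy` Generators seeded through
`SeedSequence` chains, so sessions, cohorts, permutations and whole
pipeline runs are bit-reproducible given a seed, and stage outputs are
cached on disk so the permutation stage can be re-run with different
correction parameters without re-simulation.

Simulation sizes used by the validation suite were chosen to estimate each
quantity with standard errors comfortably inside its tolerance band: 200
sessions for staircase/SSRT calibration (SE ≈ 0.002 on P(inhibit)); 500
null datasets × 500 permutations at 30 × 50 × 80 for type-I calibration
(SE ≈ 0.006 on a rate of 0.017); 200 trials/group for effect recovery
(SE ≈ 0.2 dB); 500 cohorts of n = 14 for correlation recovery
(SE ≈ 0.01 on r). The shipped demo configuration runs one ROI with
8 + 7 subjects (about one minute on one CPU).

Known limitations: fixed-effects pooling of trials ignores between-subject
variance, so group inferences generalize to these subjects' trial
populations, not to new subjects; the leakage-corrected recovery assumes an
isolated band effect and the generator's model PSD; the staircase warm-up
bias above is inherent to the modeled task geometry; no mixed-model block
analysis is provided (the per-block behavioral table such a model would
consume is emitted instead).
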