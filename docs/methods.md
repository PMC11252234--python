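# Methods

This note documents the models, the numerical conventions and the design
choices behind `imepmap`, in the spirit of a statistical package's methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Signal model of the synthetic generator

A stimulus-locked sweep is modelled as

    x(t) = b(t) + g * e(t) * u(t)

where `b` is background EMG, `u` an independent burst carrier, `e` the burst
envelope and `g` the site gain.

**Background.** Voluntary background EMG during a strong isometric
contraction is emulated as stationary Gaussian noise, zero-phase Butterworth
filtered to the recording band (default 20–1000 Hz at 2 kHz sampling; when
the upper edge reaches Nyquist only the high-pass is applied) and scaled to
an exact target RMS (`background_rms`, default 50 µV). This is a surrogate,
not a physiological model: real contraction EMG contains motor-unit
structure, slow force drift and occasional artifacts, none of which are
simulated. Passing tests therefore demonstrate correctness of the analysis
chain under a stationary band-limited background, not robustness to every
failure mode of real recordings. No quantitative value for background
amplitude at strong contraction was available to calibrate against, so
`background_rms` is a free parameter; all downstream statistics are relative
(percent of baseline), which makes its exact value immaterial (scale
invariance is asserted by a property test).

**Burst.** An iMEP manifests as a transient *increase in EMG level*, so the
burst is a multiplicative envelope (rectangular by default, Hann optional)
applied to an independent band-limited noise carrier and *added* to the
background, with the carrier scaled so the burst RMS is `gain` times the
background RMS. The envelope is normalised by its own RMS so Hann and
rectangular envelopes deposit the same energy. A deterministic added
waveform would be wrong here: rectified-area statistics respond to EMG
level, not to phase-locked shape.

**Spatial tuning.** Site gain follows an isotropic Gaussian field
`g_i = g_peak * exp(-||x_i - c||^2 / (2 w^2))` with true centre `c`
(default 2.3 mm lateral, 13.25 mm anterior of the grid centre) and width
`w = 15` mm. The defaults are calibrated so that, at the peak,
`relative_area ≈ 100 * sqrt(1 + g_peak^2) ≈ 345%` and at the grid centre
(the hotspot site) ≈ 185%, matching the magnitudes such studies report;
`g_peak = 3.3`.

**Between-participant variability.** Each participant receives (i) a rigid
translation of the grid (hotspot placement scatter, SD 5 mm in-plane,
1.7 mm out-of-plane), which moves the tuning centre with it; (ii) a
log-normal gain factor (sigma 0.3); (iii) task-specific burst onset and
duration drawn once per participant from the configured (mean, SD) pairs —
onsets 19.8 ± 2.5, 20.4 ± 3.9, 20.8 ± 3.1 ms and durations 23.9 ± 15.2,
21.3 ± 13.7, 25.1 ± 16.6 ms for the unilateral, bilateral-homologous and
bilateral-antagonistic tasks respectively — truncated to [12, 30] ms and
[8, 36] ms so bursts stay inside the detection search window. The quoted
SDs are between-participant spreads, which is why they are drawn per
participant and held fixed within one; `simulate_trial` itself is
deterministic given (config, gain, seed, timing).

**Seeding.** Every random quantity derives from the single study seed via
`numpy.random.SeedSequence` with a structured spawn key
(`[seed, stream, participant, task, site, trial]`), so any subset of the
study is reproducible in isolation and equal configs give bit-identical
studies.

## 2. Detection chain

Sweeps are DC-corrected by the raw prestimulus mean, full-wave rectified,
and characterised by the prestimulus window (default 100 ms, 200 samples at
2 kHz; sample SD, n−1 denominator). The detection threshold is
`prestim mean + 1 SD`. Onset = first sample in the post-stimulus search
window starting a run of ≥ 5 ms strictly above threshold; offset = first
later sample starting a run of > 5 ms strictly below it, clamped to the
window end if the EMG never settles (the run may extend past the window's
end but not past the sweep). The default search window is 10–60 ms:
the lower edge blanks the stimulus artifact (an optional simulated artifact
spike exists to exercise this), the upper edge bounds plausible iMEP
latencies. The vectorised implementation is held sample-exact against a
naive run-scan oracle in the test suite.

**Averaged vs per-trial detection.** The default mode detects once on the
point-wise mean of a site's rectified sweeps (one area per site, as grid
studies report), with per-trial detection retained as an option and used
for the persistence statistic (fraction of trials with a detectable burst).

**Threshold baseline in averaged mode — a deliberate choice.** The SD
entering the threshold is the *pooled single-sweep* prestimulus SD, not the
SD of the averaged trace. A threshold set at mean + 1 SD *of the detection
trace's own noise* sits at its ~84th percentile regardless of how many
trials are averaged, so the chance that 11 consecutive samples fall below
it is only ~0.15 per position and the offset rule triggers, on average,
~25 samples (12 ms) late — a bias we measured in simulation before fixing
the convention. Judging the averaged waveform against the single-sweep
horizontal line (the line a human rater draws on raw rectified EMG) removes
this bias: onset and duration recover the generative values to well within
2 ms at burst gains ≥ 3 (asserted by the validation suite at n = 200
trials). Relative areas are unaffected (the baseline *mean* is identical
either way).

**Degenerate cases.** A zero prestimulus mean makes the relative area
undefined and raises a dedicated error; undetected sites report area 0 and
enter the CoG with weight 0; ties in site ranking break by site id. A
data-quality check warns (never excludes) when the mean background EMG
drifts between task conditions by more than 20%.

## 3. Centre of gravity

`x_CoG = sum_i a_i x_i / sum_i a_i`, computed per axis over the stored 3-D
site coordinates. The weights are the *relative* areas (percent): the
processing chain defines only the relative area, and because the CoG is
invariant to uniform weight rescaling the choice matters only when
baselines differ across sites; raw µV·ms areas are stored on each result
and can be used instead. The CoG is an unconstrained Euclidean average (no
cortical-surface projection; coordinates are assumed already expressed in a
common space — spatial normalisation is a preprocessing requirement, not
part of this package). The weighted mean always lies in the convex hull of
the positively weighted sites; tests assert the axis-aligned bounding-box
consequence of this on random weightings, plus exact agreement with a
per-axis loop oracle.

## 4. Bayesian two-group comparison

The comparison of CoG and hotspot coordinate distributions uses the robust
two-group model: `y_ki ~ t(nu, mu_k, sigma_k)` with shared normality `nu`,
priors `mu_k ~ N(pooled mean, 1000 * pooled SD)`,
`sigma_k ~ U(pooled SD/1000, pooled SD*1000)`, `nu - 1 ~ Exp(mean 29)`.
Groups are treated as independent samples (the comparison is between
distributions of centroids, not a paired contrast).

**Sampler.** The posterior is sampled with an affine-invariant ensemble
(emcee) in transformed coordinates `(mu1, mu2, log sigma1, log sigma2,
log(nu-1))` with the Jacobian added, using differential-evolution moves
(80% DE, 20% snooker). Defaults: 4 independent ensembles of 16 walkers,
1000 warmup draws per chain (minimum 300 ensemble steps), thinning factor 6
(approximately the measured integrated autocorrelation time), 100,000
retained draws in total. Each walker is treated as a chain for
rank-normalised split-R̂ and ESS (arviz); R̂ > 1.05 flags the result as
non-converged and warns. At default settings R̂ ≈ 1.00 and the ESS of the
mean difference exceeds 10^4.

**Decision rule.** The separation accuracy is defined as
`max(P(dmu > 0), P(dmu < 0))` over posterior draws — the probability mass
of the difference of means on its dominant side. (The phrase "ability to
separate the groups" admits other operationalisations; a
posterior-predictive alternative — the probability that a new observation
from one group exceeds one from the other — is available via
`fit(accuracy_method="classification")`. The posterior-sign definition is
the default because it reduces to 0.5 for exchangeable groups and 1.0 for
disjoint ones, which is what the tier thresholds presuppose.) Tiers follow the stated
cut-offs literally: ns < 0.80 ≤ `*` < 0.90 ≤ `**` ≤ 0.95 < `***`. The
claimed correspondence of 80% accuracy to p = 0.05 is not asserted
anywhere; instead the suite *reports* the empirical null tier rate across
seeds without asserting its level. No multiple-comparison correction is
applied across tasks or axes. Per-axis comparisons are the default
(distributions are compared coordinate by coordinate); a joint 3-D
statistic would be a different analysis and is not implemented.

## 5. Task-modulation mixed model

`relative_area ~ C(task) + background_emg` with a participant random
intercept (statsmodels MixedLM). Background EMG is continuous and therefore
cannot be a grouping factor; it enters as a fixed covariate by default,
with a participant-level random slope on background available behind a
flag. The omnibus TASK test is the likelihood-ratio chi-square between ML
fits with and without the task factor; a Wald chi-square/F on the task
coefficients from the REML fit is reported alongside (statsmodels provides
no Satterthwaite denominator df, so the F is referenced to its chi-square
limit). The analysis is run twice, at each participant's maximum-area site
and at the hotspot site. A zero-variance response short-circuits to
(statistic 0, p 1). Calibration under the model's own generative
assumptions (n = 20 participants, 500 replicates) keeps the type-I rate
within [0.02, 0.09] at alpha = 0.05, with power > 0.8 for a one-SD task
effect — both asserted in the validation suite.

## 6. Problem sizes and tolerances in the test suite

The validation suite runs the full study geometry (20 participants x 3
tasks x 9 sites x 10 trials) through the complete pipeline once, with MCMC
reduced to 6,000 retained draws for the nine per-axis comparisons (the
decision rule needs ~10^3 independent draws; tier assertions there are far
from the thresholds). Timing-recovery checks use 200 trials per scenario
with a ±2 ms tolerance (four sample periods at 2 kHz). Monte-Carlo
tolerances on posterior summaries are set to 3 standard errors of the
corresponding estimator unless the quantity is deterministic given the
seed, in which case equality is exact.

## 7. Known limitations

- The background surrogate is stationary and Gaussian; motor-unit
  synchronisation, fatigue drift and movement artifacts are not emulated.
- The detector's offset rule inherits the 5-ms run convention; bursts with
  < 5 ms internal dips are merged, bursts shorter than 5 ms are invisible
  by design.
- Hotspots enter the group comparison as single points, not as CoGs over
  the same grid, mirroring how such data are collected; any systematic
  hotspot mislocalisation propagates directly into the shift estimates.
- The mixed model assumes a single variance component (or one random slope);
  richer covariance structures are out of scope, and conclusions about the
  model's operating characteristics are asserted on simulated data only.
- MNI normalisation, coil physics and cortical-surface rendering are out of
  scope; coordinates are taken as given.
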