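# Methods

## Respirometry signal model

A recording is a 1-Hz multichannel series (CO₂ ppm, activity analog, chamber
temperature) with two empty-chamber baseline windows flanking the fly
segment. The analyzer baseline is assumed to drift linearly over the tens of
minutes of a recording; the drift line is anchored at the two points (center
of pre-window, mean pre ppm) and (center of post-window, mean post ppm).
This two-point construction guarantees the corrected series has exactly zero
mean over each baseline window and is idempotent (a second fit returns the
zero line). A least-squares fit over all baseline samples is available via
`drift_method="regression"`; the two differ only when noise within a window
is asymmetric. Corrected values may be negative (noise around zero excess);
they are retained, because clipping at zero would bias window means upward.

### Unit conversions

- ppm → flux: `V̇CO₂ (µL/h) = ppm × flow (mL/min) × 0.06`. Linear, so the
  whole chain commutes with averaging and scaling.
- flux → power: oxyjoule relation `(16 + 5.164·RQ) J per mL O₂` with
  `V̇O₂ = V̇CO₂ / RQ`. At RQ = 1 (ad-libitum carbohydrate feeding) this is
  21.164 J/mL, i.e. 5.87889 µW per µL CO₂/h. RQ and hence the coefficient
  are single config constants; substituting e.g. 20.1 J/mL is a one-line
  change and rescales all MR values proportionally.
- mass correction: `power / mass^0.856` (interspecific exponent for
  tracheate arthropods). Mass is a per-recording constant, so correction
  commutes with time-averaging.

### Activity index and windowing

The activity analog is reduced to the absolute difference sum
ADS[k] = Σ|Δactivity| (offset-invariant, not gain-invariant; the analog's
gain is assumed comparable across recordings). The activity index of a
window of N samples is `ADS range / N × 60` — the mean absolute first
difference per minute, which is invariant to recording duration. The
alternative reading `range / (N × 60)` differs only by the constant 3600 and
would not change any slope test verdict, only the slope's units.

Segments are consecutive, non-overlapping 300-s windows of the fly segment;
a trailing partial window is dropped. Within `segment_metrics` the
per-window index is computed by partitioning the fly segment's cumulative
ADS channel at the window boundaries (the diff entering a window's first
sample belongs to that window; the segment's leading sample contributes 0).
This bookkeeping makes window indices add up exactly over the recording and
makes the pipeline an exact inverse of the trace generator (below): on
noise-free synthetic data the regression recovers the generating
coupling and resting power to machine precision, which the tests assert at
1e-6 relative error.

### Standard metabolic rate

No universal operational definition exists; the package uses the
conventional lowest running average restricted to quiescence: slide a 300-s
window in 1-s steps, keep windows whose activity index lies in the lowest
20% quantile for that recording, and take the minimum mean MR among them.
Window length and quantile are config keys and are recorded in the output;
if no window qualifies the global minimum is returned with a fallback flag.
The estimator equals the true resting power exactly whenever a fully
quiescent window exists, and otherwise upper-bounds it.

### Homeostasis regression

Segments are pooled across flies within a group (no per-fly random effect —
the analysis mirrors a pooled scatter of 5-minute points with a single
fitted line; a mixed model is out of scope). OLS of mean MR on activity
index; two-sided t-test of the slope and a 95% CI. Homeostasis is declared
"lost" only for a significantly **positive** slope (p < α, default 0.05): a
negative slope is physiologically implausible and is not evidence against
homeostasis. The test's type-I error is calibrated by simulation at ~5%
under zero coupling (30 segments per replicate).

## Synthetic trace generator

`gen_resp_trace` emulates what the pipeline consumes, not chamber physics:
no washout kinetics, no temperature dependence of MR, no discontinuous
gas-exchange cycles, no analyzer 1/f noise (noise is i.i.d. Gaussian, SD
0.05 ppm by default — half the 0.1-ppm resolution of the CO₂ analyzer
class emulated). Passing tests therefore validate the estimators'
arithmetic and statistical calibration, not robustness to those real-data
features.

Activity is a two-state telegraph process: bout onsets at
`bout_rate_per_min` (default 0.5/min) while resting, geometric bout lengths
with mean `bout_mean_s` (default 30 s), and uniform jitter of the analog
only while active — this bout structure is what gives the ADS range its
meaning. Instantaneous power is `smr_uW + activity_coupling_uW × 60·|Δa|`,
back-converted to ppm through the exact inverse of the conversion chain and
added to a drifting baseline. Defaults (SMR 15 µW, mass 1.2 mg, 1800-s
recording with 120-s baselines, baseline 2 ppm, drift 10⁻³ ppm/s) are
plausible for a female fly at 25 °C; the fraction of time active (~20%)
and coupling values are chosen for testability since no public reference
values exist. Ground truth is embedded in the trace metadata sidecar so
recovery tests never re-derive it.

## Survival machinery

Kaplan–Meier estimation and both rank tests are computed with lifelines
(Gehan–Breslow–Wilcoxon = risk-set sums weighted by number at risk); the
test suite verifies both statistics against an independent brute-force
risk-set enumeration (exact equality on tables of ≤ 30 flies, censoring and
ties included) and KM against the empirical survivor function when
censoring is absent. Tied death times decrement simultaneously; no
jittering. Time units (days for lifespan, hours for starvation) are a
property of the table, not the code.

Multiple comparisons default to Bonferroni (most conservative, assumption
free); Holm is available. Median lifespan is the smallest time with
S(t) ≤ 0.5 and is flagged undefined if the curve never reaches 0.5.
"Maximum lifespan" has no standard definition, so every summary is tagged:
`top_decile_mean` (default; mean death age of the longest-lived 10% of
dying flies, falling back to `last_death` with a flag below 10 deaths),
`last_death`, or `percentile_90` (linear interpolation).

The double-mutant additivity rule: *non-additive* when both singles differ
from control (corrected log-rank p < α) while the double differs from
neither single; *additive-consistent* when the double differs from both
singles and its median lifespan exceeds theirs; otherwise *inconclusive*.
The family for correction is the five pairwise comparisons involved.

Synthetic cohorts use a Gompertz hazard a·e^{bt} sampled by inverse CDF
(t = ln(1 − (b/a)·ln U)/b; b = 0 gives the exponential). Default
parameters (a = 1.3×10⁻³/day, b = 0.1/day; extended-lifespan group
a = 4.7×10⁻⁴) give medians near 40 and 50 days, typical for flies at 29 °C.
Censoring is administrative (optional fixed study end) plus independent
random loss at a uniform time before death, mimicking vial-change losses.

## Phenotype statistics

The dispatch rule follows common practice: Shapiro–Wilk per group; the
parametric branch (unpaired t-test / one-way ANOVA) runs only if **all**
groups pass at `alpha_norm` (a single failing group switches the whole
comparison to Mann–Whitney / Kruskal–Wallis — the conservative reading).
Variance homogeneity is not tested; Welch's correction is off by default to
mirror the plain unpaired t-test, and available by flag. The gate decision
and per-group normality p-values are always part of the result. Two-factor
designs get a two-way ANOVA (type-II, interaction reported as the headline)
with Sidak-adjusted pairwise t-tests of the first factor within each level
of the second, m = the total number of such comparisons
(p_adj = 1 − (1−p)^m, always between p and Bonferroni's m·p).

Climbing sessions reduce to one scalar: mean over the 5 trials of the mean
normalized fly height at the 4-s mark; invariant to fly and trial order.

## Numerical and testing choices

- All generators take an explicit integer seed; identical (spec, seed) give
  bit-identical output. Pipeline runs with the same resolved config are
  byte-identical; the resolved config is serialized next to every output
  and writes are atomic (temp file + rename).
- Problem sizes in the validation suite (30 segments per replicate; 500
  replicate regressions for slope bias and power; 1000 for the null
  rejection rate; cohorts of 100/arm for test calibration, 5000 for
  sampler sup-norm checks) were chosen so each Monte-Carlo estimate's
  standard error is comfortably below the band it is checked against.
- The exponential-median check of the cohort sampler compares the median
  of several replicate sample medians (n = 2000 each) against ln 2/a,
  because a single sample median carries ~1.9 days of sampling noise at
  that n — the aggregate tests the sampler's calibration rather than one
  draw's luck.
- Degenerate inputs fail loudly: empty baseline windows, non-finite ppm
  (with index), non-unit time steps (with index), zero-variance activity
  regressor, groups without death events, duplicate comparison pairs,
  incomplete two-factor layouts.

## Known limitations

Chamber washout deconvolution, temperature compensation, O₂-channel
analysis, mixed-effects regression, Cox models and parametric survival fits
are out of scope. The activity index is not gain-invariant across
recordings; the generators produce statistical shapes, not biology — diet,
temperature and genotype act only through the parameters you set.
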