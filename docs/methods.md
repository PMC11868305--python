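# Methods

## The designs being modelled

Two study geometries are built in. The *within-participant* geometry
(`EXP1_DESIGN`, `EXP2_DESIGN`) crosses encoding level (deep vs. shallow
orienting task, within participants) with delay group (0.5 / 2 / 24 h,
between participants; 30 or 24 participants per group). Every participant
studies 40 words (20 per level), takes an immediate old/new test on 10
targets per level plus 40 distractors, and a delayed test on the remaining
10 targets per level plus 40 fresh distractors — disjoint item sets, so no
item is retrieved twice and testing effects cannot contaminate the delayed
measurement. The *between-participants* geometry (`EXP3_DESIGN`) assigns
each participant one encoding level, with delays 0.5 / 2 / 6 h and 20
participants per level × delay cell (20 targets per phase).

The immediate test is always at t = 0 and is pooled across delay groups when
cells are summarised, which is why the immediate cell's n is the whole
sample while delayed cells are one group each.

## Signal-detection scoring

Equal-variance SDT throughout: d′ = z(H) − z(FA), c = −½[z(H) + z(FA)],
with z the inverse standard normal CDF (evaluated by `scipy.stats.norm.ppf`,
accurate to well below 1e−10). Both variances are fixed at 1; the d′ and c
formulas presuppose this.

Rates are corrected with the log-linear rule (add 0.5 to each count, 1 to
each trial count). The default applies it to *every* cell (the
recommendation associated with the rule, which keeps the correction a
smooth, order-preserving map); an `loglinear_extremes_only` mode corrects
only rates of exactly 0 or 1, for sensitivity analysis. The report records
which mode was used.

Screening follows the studies' rules, made operational as:

- *chance level*: immediate d′ ≤ 0 at either level. "≤" rather than "=" —
  corrected scores are continuous and never hit 0 exactly.
- *rate outlier*: an immediate hit or false-alarm rate more than 2.5 sample
  SDs from that rate's sample mean, pooled across levels (per rate, over all
  participants). The pooling choice is logged; with fewer than 3
  participants the screen is skipped with a warning, and a zero-SD rate
  flags nobody.

In the within-participant designs the 40 distractors of a test phase are
shared between levels, so the two levels' false-alarm rates are identical by
construction; distractor rows carry `lop_condition = "shared"` and count
toward both levels.

## Retention functions and the slope test

Four two-parameter laws for d′ as a function of delay t in hours:
linear y = a − bt, power y = a(t+1)^(−b), exponential y = ae^(−bt),
logarithmic y = a − b·ln(t+1). All four predict y = a at t = 0, so a is the
initial degree of learning and b the forgetting slope (units differ by
form). Delays default to the nominal values; observed mean delays are
available as an alternative convention (`with_actual_delays`) — fits differ
only past the reported precision.

**Fitting.** Weighted least squares, Σᵢ wᵢ(yᵢ − f(tᵢ))², with wᵢ = 1 for
participant-level points and wᵢ = nᵢ for cell means. The two are
mathematically identical in (a, b) because the within-cell scatter is
orthogonal to any function of t; a property test verifies the identity to
1e−8. The linear and logarithmic forms are solved exactly (they are linear
in (a, b)); the power and exponential forms profile the intercept in closed
form (a(b) = Σwyu/Σwu² with u the slope basis) and minimise over b with a
deterministic multi-start: starts on a log-spaced grid 0.01…4, mirrored
negative starts and 0, each refined by Brent's method. b is unconstrained in
sign — a negative fitted slope (performance improving with delay) is a
model-health signal, not an error. Standard errors come from the
Gauss-Newton covariance σ̂²(JᵀWJ)⁻¹ with σ̂² = RSS_total/(N − 2); a
resampling alternative was not implemented because the SEs are descriptive
here and not part of any test decision.

**Constrained fits.** The slope-equality question is answered by refitting
one condition (by default shallow) with b fixed at the other condition's
estimate; only a remains and has the closed form above for all four laws.

**Likelihood-ratio test.** For Gaussian errors with profiled variance,
−2ΔlnL = N·ln(RSS_c/RSS_u) on 1 df. N is the trial-level (participant ×
phase) count behind the cells, and both RSS totals include the within-cell
sum of squares, reconstructed from cell summaries as Σ (n−1)·n·SE² (since
SE = SD/√n). A constrained RSS below the unconstrained one is impossible at
the optimum and raises rather than returning a negative χ².

Calibration caveat: the LR machinery is calibrated (~5% size) when the
constraint value is a constant. Fixing b at the *other condition's
estimate*, as the study procedure does, imports that estimate's sampling
noise and makes the test anti-conservative; the Monte-Carlo test in the
suite verifies the calibrated case and this caveat is the reason the
procedure's χ² should be read descriptively near the threshold.

**Model selection.** Gaussian-likelihood information criteria on the
trial-level total RSS: AIC = N·ln(2πRSS/N) + N + 2k and
BIC = … + k·ln N with k = 3 (a, b, σ); R² = 1 − RSS/TSS with TSS about the
weighted grand mean (within-cell SS included in both). With N and k equal
across the four laws, AIC, BIC and R² are all monotone in RSS, so their
rankings agree; `fit_all_functions` asserts this and flags any disagreement.
The absolute AIC/BIC values depend on residual detail that published
summaries cannot pin down, so only rankings and R² (to ~±0.02) are treated
as reproducible.

## ANOVA, post hocs, Bayes factors

**Split-plot (mixed) ANOVA** is computed from explicit projection sums of
squares: the between stratum tests delay group against subjects-within-
groups (L·Σnⱼ(ȳⱼ−ȳ)² vs. L·Σ(ȳₛ−ȳⱼ)²); the within stratum tests level as
R(level | subjects) and the interaction as R(level×group | subjects, level)
against the remaining within residual. These comparisons respect
marginality (Type II); with balanced groups they equal Type I, verified in
the tests, and a balanced hand-computed oracle matches to 1e−10.
Sphericity corrections are unnecessary — the within factor has exactly two
levels in every design, so sphericity holds trivially. Identically-zero
effects on degenerate (zero-residual) data are reported as F = 0 rather
than 0/0.

**Factorial ANOVA** (fully between) delegates to statsmodels
`anova_lm(typ=2)`; an explicit regression-projection oracle checks the
unbalanced case in the tests. Partial η² = SS_effect/(SS_effect +
SS_error-of-that-stratum) on every table.

**Post hocs.** Bonferroni pairwise t-tests (adjusted p = min(1, m·p)) on
the between factor, using the subjects-within-groups MS of the mixed model
(per-subject means, error MS/L) or the pooled within-group variance;
Tukey-Kramer HSD from scipy's studentized-range distribution for the
between-participants design. Cohen's d divides the mean difference by the
square root of the error MS used — the pooled-error variant, one of several
conventions; the choice is recorded here.

**Bayes factors** use the BIC approximation BF₀₁ ≈ exp[(BIC_alt −
BIC_null)/2] (unit-information prior), not default-prior JZS integrals:
reproducing a specific prior family is out of scope and the claims the
approximation supports are categorical (Kass-Raftery bins at 1, 3, 20,
150). Each effect is compared with/without, respecting marginality; in the
mixed design the level and interaction comparisons carry subject dummies in
both models, while the delay-group comparison is made on subject means
(subject dummies would absorb a between-subjects factor). Output is
labelled "BIC-approximate".

**RT analysis** log-transforms each target-trial RT (natural log of ms) and
feeds per-participant × level means into the same ANOVA machinery. The RTs
attached to recognition rows stand in for the level-specific orienting-task
latencies (deep vs. shallow differ in log-mean); shared distractor rows get
the level-averaged distribution and are excluded from the RT contrast.

## The generative simulator

What it emulates: bi-normal evidence with an *absolute* criterion
(response "old" iff evidence > cᵢ); latent discriminability following the
level's retention law, floored at 0 (the screening rule treats d′ = 0 as
chance, so negative true discriminability is not meaningful here);
participant heterogeneity as a shared intercept deviation δᵢ ~ N(0, sd_a²)
(shared across levels, giving the within-design correlation a split-plot
analysis expects) and criterion cᵢ ~ N(c̄, sd_c²); inattentive participants
(probability p) who flip a fair coin on every trial and should trip the
chance-level screen; truncated lognormal RTs. Item-to-phase assignment is
random; Latin-square rotation of materials is not simulated, and no
word-level psycholinguistic structure exists.

Note on the criterion statistic: with an absolute evidence criterion c, the
SDT criterion estimate converges to c − d′/2 (it measures bias relative to
the evidence midpoint), while the distractor "old" rate converges to
1 − Φ(c). Both limits are tested.

Defaults are set once from the first experiment's published summaries:
a_deep = 2.6, a_shallow = 2.1 (immediate d′), b_deep = 0.36,
b_shallow = 0.44 (power-fit slopes), RT log-means 7.91/7.58 (≈ 2.9 s and
2.1 s medians) with σ = 0.4 and the 5-s response window. The published
summaries report no trial-level variance components, so sd_a = 0.45,
criterion mean 1.25 with SD 0.3, and p_inattentive = 0.04 (matching the
observed ~4/90 exclusion rate) are calibration choices: sd_a + binomial
measurement noise at 10 targets/40 distractors per cell reproduces immediate
SEs ≈ 0.06-0.07 at n ≈ 86, and criterion 1.25 puts false-alarm rates near
0.10 with near-unbiased midpoint behaviour at immediate d′ ≈ 2.5.

Two sampling paths share this model: the per-trial table (one row per test
trial) and a vectorised score-level path that draws binomial hit/false-alarm
counts directly (the within-design levels share one distractor draw per
phase, as in the trial path). A test checks the two paths agree in
distribution; the score-level path powers the Monte-Carlo studies.

What passing simulation tests do **not** show about real data: the
simulator is the analysis model plus simple noise, so recovery and
calibration results certify the pipeline's internals, not the adequacy of
equal-variance SDT, the absence of item effects, or the retention law's
truth for any real population.

## Calibration results computed by the suite

- *Interaction size.* Under a null-interaction world (flat retention, level
  effect preserved, chance-level screening applied), the split-plot
  interaction test's rejection rate over 2000 simulated studies of the
  within-participant geometry is checked against the 3.5-6.5% band around
  the nominal 5%.
- *Slope recovery.* Median |b̂ − b| over 200 simulated studies per group
  size falls as participants per group double (15 → 30 → 60). It does not
  fall to zero: with 10 targets per cell the corrected d′ is a nonlinearly
  biased estimate of latent discriminability (ceiling compression at the
  immediate test), and the fitted slope inherits an attenuation of ≈ 0.03
  at b = 0.4 that more participants cannot remove. This is a real property
  of the published measurement design, worth knowing when interpreting
  fitted slopes.

Problem sizes (2000 null simulations, 200 recovery studies per size, 500
replicates for the LR-calibration check) are the package's standard
settings, chosen to give Monte-Carlo SEs comfortably inside the asserted
bands.

## Known limitations

- Exact published F, p, η² and Bayes-factor values require the raw
  participant data and are not reproduction targets; the printed retention
  parameters and χ² statistics are, and reproduce to within the rounding of
  the published summaries. The χ² statistic is the most rounding-sensitive
  quantity: perturbing the two-decimal cell means and SEs within ±0.005
  moves the first experiment's χ² with an SD of ≈ 0.17, so the refit value
  of 2.43 sits within one rounding-propagation SD of the printed 2.25.
- The between-participants experiment's six excluded participants are not
  attributed to delay groups in the published summary, so its summary-level
  refits default to the pre-exclusion 20 per cell with a logged caveat;
  user-supplied weights are accepted.
- No ROC/confidence-rating modelling, no mixed-effects (random-slope)
  retention fitting, no additional retention laws (hyperbolic,
  exponential-power); single-function fits visibly misfit the fast-early /
  slow-late shape of forgetting, which is part of why model ranking, not
  absolute fit, is the supported conclusion.
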