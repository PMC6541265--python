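# Methods

## Data model and coding rules

The unit record is one outcome measure of one intervention arm of one study:
`(study_id, available_data, measure, intervention, n_t, n_c, n_total, r)`,
where `available_data` encodes which statistics the primary article reported
(post means/SDs, ANOVA F, t/p, Cohen's d, pre–post change scores, or
nothing usable) and `r` is the correlation-scale effect, signed so that
positive always means the intervention helped (symptom scales are flipped at
transcription).

Three coding rules prepare a table for analysis:

* articles reporting only an overall N have it split equally over groups,
  with an odd participant assigned to the treatment group (a deterministic
  convention; the alternative assignment changes no reported value at the
  sample sizes involved);
* sibling articles that report arms of one underlying study are merged under
  a single study id (the packaged default merges the four Mongrain-family
  articles);
* rows whose statistics cannot yield an effect size are excluded, each with
  a log line. The packaged tables carry no raw summary statistics from which
  such rows could be rescued, so exclusion is the only path for them.

Shipped fixtures are guarded by sha256 checksums against transcription
drift. Round-tripping read→write→read is value-exact; byte-exactness is not
promised because the source tables format zero correlations inconsistently.

## Effect sizes

Conversions follow the standard two-group formulas: pooled-SD Cohen's d from
means and SDs (post-test or change scores); d = ±√(F·(n_t+n_c)/(n_t·n_c))
for a two-group one-way F; d = t·√(1/n_t+1/n_c); p-values are inverted
through the central t distribution (two-sided) and routed through the t
path. The pre–post-controlled d_ppc2 standardizes the difference of group
change scores by the pooled pre-test SD with the Hedges small-sample factor
1 − 3/(4(n_t+n_c−2)−1); its variance (Morris 2008) requires the pre–post
correlation ρ_pp, which primary studies essentially never report, so the
function demands an explicit imputation rather than assuming one. d→r uses
a = (n_t+n_c)²/(n_t·n_c), so unequal groups shrink r; the equal-n inverse
d = 2r/√(1−r²) is used when reporting adjusted estimates on the d scale.
No Hedges correction is applied on the post-only path by default (exposed as
an option): the packaged tables' r values correspond to uncorrected
conversion at these sample sizes.

## Within-study aggregation

A study contributes one effect. All of its rows — outcomes × arms, plus rows
of merged sibling articles — enter one composite with an imputed uniform
within-study correlation ρ = .50 (the conventional default when primary
articles report no outcome intercorrelations; configurable). Two composites
are implemented:

* **Schmidt–Hunter composite correlation** (pipeline default):
  r_comp = r̄·√(m/(1+(m−1)ρ)) — the correlation of treatment with the *sum*
  of the m standardized outcomes. Averaging outcomes cancels
  measure-specific error, so the composite exceeds the average correlation
  whenever ρ < 1 and equals it at ρ = 1. The formula can exceed 1 when the
  inputs are inconsistent with the assumed ρ; that is raised as an error.
* **Mean composite** (`method="mean"`): the average correlation, with the
  variance of a mean of correlated estimates — the composite's precision
  grows with m, but sublinearly.

The study's effective sample size is the *mean* per-comparison N over its
rows (`n_mode="mean"`), and its weight derives solely from
var(z) = 1/(n̄−3). This deliberately conservative choice treats a study's
arms as replicate comparisons at its characteristic size rather than summing
them into a larger virtual sample: multi-arm studies share controls, and
their outcome composites share participants, so summing would overstate
precision. An arm-summing alternative (`n_mode="arms"`, treatment arms
summed, control counted once) is provided for sensitivity analysis. The
combination of composite aggregation with mean-N weighting is the
convention under which the packaged study sets reproduce their published
results; the estimator sweep (`smallmeta.pipeline.estimator_sweep`)
documents how the estimates move under the alternatives.

## Pooling and heterogeneity

Pooling is on the Fisher-z scale throughout, with back-transformation for
reporting. The random-effects model is z_i ~ N(θ_i, v_i), θ_i ~ N(μ, τ²).
τ² is estimated by DerSimonian–Laird by default; Paule–Mandel (bisection on
the generalized Q equation) and REML (Fisher-scoring fixed point) are
options, both verified against an independent reference implementation.
Confidence intervals are plain Wald on z (no Knapp–Hartung adjustment, which
matches the interval widths of the replicated analyses). Q uses
fixed-effect weights, df = k−1, and I² = max(0, (Q−df)/Q)·100.

## Small-study diagnostics

* **Egger test** (default variant): OLS of the standardized effect z_i/se_i
  on precision 1/se_i; the intercept's t statistic has k−2 df. The
  weighted meta-regression variant is available.
* **Trim and fill**: L0 estimator (R0 optional) on the z scale; the excess
  side is chosen from the sign of the Egger intercept; trimming iterates to
  convergence of k0 with a fixed-effect center, mirrors are imputed, and
  observed + filled studies are pooled with the chosen τ² estimator.
  Observed studies are never removed from the final pool. `side` names the
  side with the observed *excess* (mirrors are imputed opposite).
* **Cumulative meta-analysis**: nested prefixes, most precise first; the
  first row is the single most precise study, the last equals the full pool.
* **TOP10**: fixed-effect pool of the ⌈k/10⌉ most precise studies; ties in
  precision break by study id; below k = 10 the single most precise study is
  used, with a warning.
* **Limit meta-analysis**: the extended random-effects model
  E[z_i] = β + α·√(v_i+τ²), fitted by the generalized radial regression
  z_i√w_i = α + β√w_i with w_i = 1/(v_i+τ̂²) and τ̂² from the pooling step.
  The reported adjustment is the model expectation at infinite precision,
  β + α·τ̂ ("beta0"); β alone ("betalim") and a random-effects pool of the
  shrunken estimates ("mulim") are exposed. The CI uses the OLS covariance
  of the radial fit scaled by RSS/(k−2) with a normal quantile — the
  construction that matches the replicated analyses' printed intervals.
  The small-study test statistic Q−Q′ (df 1) and residual heterogeneity Q′
  (df k−2) come from the fixed-weight Egger regression, so Q = (Q−Q′) + Q′
  exactly. At τ̂² = 0 the shrinkage factors √(τ̂²/(v_i+τ̂²)) are all zero
  and the adjustment reduces to the regression limit β; the result carries a
  note. (Returning the unadjusted pooled estimate instead would silently
  drop the correction precisely when selection fails to inflate Q —
  simulation shows this destroys coverage of a true null.)

## Outliers and sensitivity

The primary screen flags study effects beyond 1.5×IQR outside the quartiles
(linear-interpolation quartiles, R type 7). It operates on the
*pre-composite* study mean correlations: the composite rescaling grows with
the number of outcomes, so screening composite values would let a study's
measure count, not its effect, decide outlier status — concretely, it would
flag two additional small negative studies in the Bolier depression set
whose raw effects are unremarkable. A studentized-deleted-residual screen
(leave-one-out random-effects fits, |t| > 1.96) is provided as the
corroborating method and agrees on the packaged sets. Flagged studies
trigger a paired re-run of the full chain with and without them. In the
Sin & Lyubomirsky well-being set the IQR fence falls within .01 of one
borderline study (r = .72, n = 12), which the screen flags; at 2-decimal
transcription precision its status is genuinely marginal.

## Synthetic data

The generator emulates the structure the analysis assumes: θ_i ~ N(μ_z, τ²);
group sizes log-normal (median 20, σ = 0.6, floor 5 — an all-small-studies
literature like the packaged sets, where the median per-comparison N is a
few dozen); per arm, m correlated outcome estimates with covariance
v·[(1−ρ)I + ρJ], v = 1/(n_total−3); defaults μ_z = .10, τ = .15, m = 3,
ρ = .50, one arm, no selection. Selection for significance redraws each
selected study until its pooled z is significantly *positive* (two-sided
α = .05), which induces right-side funnel asymmetry while keeping k fixed;
a truncation mode that drops non-significant selected studies (variable k)
is also provided. Redraw keeps test statistics well-defined at fixed k and
is the default.

What passing simulations do and do not show: the generator draws exact
normal z estimates at the assumed variances — it validates estimator logic,
not robustness to non-normal outcomes, unit-of-analysis errors, or
correlations that differ from the imputed ρ. With τ > 0 the redraw
mechanism selects on *true* effects as well as noise, so the
infinite-precision limit of the selected population is itself positive
(≈ τ·√(2/π) at μ = 0); no adjustment method can then recover zero, which is
why the coverage property is evaluated at τ = 0, where selection acts on
sampling error alone.

## Numerical conventions and edge cases

τ̂² is floored at zero in all estimators; PM brackets its root to 1e−10;
REML iterates its fixed point to 1e−10 with a DL start. Egger and limit
meta-analysis require k ≥ 3, the outlier screens k ≥ 4, pooling k ≥ 2.
Trim-and-fill caps k0 at k−2 and raises after 50 non-converging iterations
(with the k0 trace). Composite correlations outside (−1, 1) raise rather
than clip. All analyses are deterministic given their inputs; the generator
is bit-reproducible given a seed.

## Known limitations

* The within-study correlation ρ = .50 is an imputation, not an estimate;
  the composite (and hence every downstream number) moves with it.
* Weighting by 1/(n̄−3) ignores the precision differences between composite
  sizes; it is the convention of the replicated analyses, not an efficiency
  claim.
* Limit meta-analysis models a *smooth* small-study trend; under hard
  selection at a significance threshold its beta0 adjustment removes most
  but not all bias, and with a wide study-size spread the residual bias can
  exceed its confidence width.
* Selection models (Copas, step-function weights) and p-based corrections
  are out of scope, as are moderator/meta-regression analyses.
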