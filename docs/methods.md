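# Methods

`polyhazard` implements a survival-analysis framework for turning GWAS
results into individualized, age-specific absolute disease risk. It was
built around the Alzheimer-disease use case (APOE plus 31 GWAS SNPs) but
the machinery is disease-agnostic.

## Model

The hazard of onset at age `t` for an individual with polygenic hazard
score `s` is assumed proportional:

    h(t | s) = h0(t) * exp(s),      s = sum_j beta_j g_ij (+ APOE terms),

where `g_ij` are effect-allele dosages in `[0, 2]` and `beta_j` are log
hazard ratios estimated jointly in a Cox model on the age axis. Age, not
time-on-study, is the time scale; subjects enter the risk set at their
study-entry age (left truncation) and leave at onset (event) or last
clinical visit (censoring). Individuals with onset before age 60 are
excluded by the ascertainment rules, mirroring late-onset disease cohorts.

### Score derivation (three stages)

1. **Prescreen.** Candidate variants are GWAS summary-statistic hits at
   `p < 1e-5` (configurable; optionally restricted to risk-increasing
   effects — both behaviours exist because published descriptions are
   ambiguous about direction filtering).
2. **Stepwise Cox selection.** Forward selection controlled for sex, the
   two APOE allele dosages and five genetic principal components. At each
   step every remaining candidate is added to the joint model and the
   model's residual criterion is recomputed; the best candidate is kept if
   it improves the criterion beyond the halting threshold.

   *Criterion choice.* The criterion is the sum of squared **deviance**
   residuals, the variance-normalised transform of the Martingale
   residuals (`d_i = sign(M_i) sqrt(-2[M_i + delta_i ln(delta_i - M_i)])`).
   During development we found that the naive sum of squared Martingale
   residuals is not a usable selection loss: on simulated case-control
   cohorts a strongly causal SNP (Wald z ~ 10) *increases* it, because a
   more discriminating model spreads the expected event counts and the
   quadratic loss penalises that spread more than it rewards the improved
   event assignment. The deviance form's stepwise reduction tracks the
   likelihood-ratio statistic, so causal variants reliably lower it
   (observed gains ~50-60 versus ~1 for null SNPs in the same
   simulations). The literal squared-Martingale sum remains available as
   `criterion="martingale_ssr"` for sensitivity analyses.

   *Halting.* A step is accepted when the relative criterion reduction
   exceeds `tol`. The default `tol="auto"` sets the per-step threshold to
   the Bonferroni-adjusted chi-square(1) quantile
   `chi2.isf(alpha / n_remaining, 1)` relative to the current criterion
   (`alpha = 0.05`): that is the reduction a pure-noise candidate would
   achieve with probability `alpha`, so under an all-null candidate pool
   selection halts immediately ~95% of the time. A fixed relative
   tolerance does not transfer across cohort sizes (noise gains follow a
   chi-square law while the criterion scales with the event count), which
   is why the adaptive gate is the default; fixed floats are accepted.
3. **Bootstrap averaging.** The *fixed* selected model is refit on `B`
   (default 1000) resamples of individuals drawn with replacement; the
   reported `beta` is the mean over convergent resamples and `se` their
   standard deviation. Selection is not re-run per resample (the selected
   set is treated as frozen); conditional p-values come from the
   full-data joint fit's Wald tests and are reported both raw and in
   -log10 form.

### Cox engine

A self-contained partial-likelihood engine (Newton iteration with
analytic gradient and Hessian, step-halving on likelihood decrease,
convergence at gradient sup-norm `< 1e-8` or 100 iterations) supports
Efron (default) and Breslow tie handling and left truncation. Risk-set
sums are computed with sorted suffix cumulative sums, so a fit costs
`O(n log n + n p^2)` per iteration, which is what makes stepwise
selection over dozens of candidates and 1000-fold bootstrapping
tractable. Monotone likelihood (perfect separation) is detected by the
flat-likelihood signature — diverging coefficients or standard errors two
orders of magnitude above the coefficient — and flagged, never silently
returned. The baseline cumulative hazard uses the Breslow estimator;
Martingale residuals are truncation-adjusted
(`M_i = delta_i - [H0(exit_i) - H0(entry_i)] e^{beta x_i}`), are bounded
above by 1 and sum to ~0 at the MLE. The engine reproduces lifelines'
`CoxPHFitter` to ~1e-5 on tied, truncated data (cross-checked in tests;
lifelines is never used as the implementation).

### Reference score distribution

The population distribution `f(s)` is composed from per-variant
effect-allele frequencies under Hardy-Weinberg and linkage equilibrium:
SNP dosages are `Binomial(2, f_j)`, the APOE locus is sampled as an
ordered pair of three alleles (e2/e3/e4) so the e2 + e4 dosage can never
exceed 2. Exact enumeration is available up to 12 SNPs (`3^k` support
points crossed with 9 ordered APOE pairs); Monte Carlo (default `1e6`
draws) otherwise, with the analytic mean used for centering in both
cases. The distribution is centered at its population mean so `s = 0` is
the mean genetic profile, and it stores an e4-carrier flag per support
point so APOE-stratified quantities condition on carrier status without
changing scale. Percentiles use `100 * CDF(s)` with the midpoint
convention at atoms.

## Calibration to population incidence

Case-control cohorts cannot supply a baseline hazard, so the score-zero
baseline `h0*(t)` is solved from published age-specific incidence.
Published "percent per year" values are read as one-year conditional
probabilities `q` and converted to hazards `h = -ln(1 - q)`; log-linear
interpolation runs between knots, flat extension below the first knot and
log-linear extrapolation above the last.

The solver marches over an age grid (cells of `dt = 0.25` y from 5 y
before the first knot to 100 y) maintaining per-support-point survival
`S(t | s_k)`. For each cell it solves the implicit fixed point

    h0 * E[ e^s | survivors at the cell midpoint under h0 ] = h_pop(mid)

by fixed-point iteration to `1e-15`, then advances the survival state.
Matching at cell midpoints makes the scheme second order in `dt`
(halving `dt` moves reported incidence cells by < 0.5%, asserted in
tests); the reconstruction residual is ~1e-16 by construction and stored
as a diagnostic. The survivor expectation shrinks with age as high-score
individuals are depleted — exactly the mechanism that makes a case-control
baseline unusable — and the calibration inverts it.

Derived quantities (all under the piecewise-constant-hazard convention,
cumulative hazard piecewise linear between cell edges):

- annualized incidence `100 (1 - exp(-e^s [H0(a+1) - H0(a)]))`, capped at
  100 per 100 person-years;
- survivor curves `S(t | s, alive at a0) = exp(-e^s [H0(t) - H0(a0)])`;
- expected onset age: the smallest age where cumulative risk reaches `q`
  (default 0.5), linearly interpolated on the grid, `inf` when the level
  is never reached;
- incidence tables over percentiles x ages. Percentile columns evaluate
  the single score at that quantile of the reference distribution
  (`fixed_quantile`, the default; on the hazard scale the ratio between
  two percentile columns is then exactly `e^{s_p1 - s_p2}` at every age).
  The `survivor_quantile` mode instead re-takes the quantile within the
  survivor-reweighted distribution at each age, so column ratios shrink
  with age; published per-percentile tables are reproduced by the default
  mode, and the survivor-conditioned variant exists because some published
  in-text values appear to use additional conditioning that is not fully
  specified. APOE carrier / non-carrier columns are survivor-weighted mean
  incidences within the conditioned distributions.

## Synthetic cohorts

The simulator generates the world the framework assumes, nothing more:
independent HWE dosages, a 3-allele APOE locus (default European allele
frequencies e2/e3/e4 = 0.08/0.78/0.14 with the published log hazard
ratios -0.47/+1.03 as defaults), a Gompertz baseline
`lambda e^{gamma (t - 60)}` anchored to the packaged US incidence
endpoints (`lambda = 8e-4`/yr at 60; `gamma = ln(12.10/0.08)/35 ~ 0.1434`/yr),
proportional score effects centered at the population mean (so `lambda`
is the baseline at the mean genetic profile), uniform last-visit censoring
on a configurable follow-up window (default 70-95 y, giving realistic
~15% case fractions in a population pool), independent of genotype, fixed
entry at 60 y, sex as a null Bernoulli(0.55) covariate and five null
standard-normal principal components. Ascertainment removes exits before
60 and, in case-control mode, samples exact case/control counts without
replacement. Onset ages are drawn by closed-form inversion of the
Gompertz cumulative hazard, so simulated times are exact, not discretised.

What a green test on this generator does *not* establish: robustness to
linkage disequilibrium between variants, imputation error, informative
censoring, competing mortality, secular changes in incidence, or
non-European allele-frequency structure — none of which are modelled.

## Numerical and design choices

- Ties: Efron by default (accepted default for age-banded event times),
  Breslow by flag. Entry ages are honoured whenever present; without
  them entry is treated as `-inf` (no truncation).
- The published weight table ships without effect alleles or frequencies
  (they were not printed); scoring real genotypes against it therefore
  needs a user-supplied allele map and frequency panel. Allele mismatches
  are resolved by dosage flip `g -> 2 - g` only when the complementary
  allele matches, otherwise an error names the variant; missing dosages
  are mean-imputed as `2f` (unbiased under HWE).
- Validation procedures (`stratify_km`, `onset_correlation`,
  `progression_trend`, `decile_hr`) consume frozen weights and scores and
  expose no fitting entry points, enforcing train/test discipline. The
  "predicted onset age" of a percentile bin is the model onset age at
  cumulative risk `q = 0.5` (configurable) at the bin's median score;
  progression analyses bin on predicted annualized incidence at baseline
  age, not on the raw score.
- Every stochastic routine takes an explicit seed; identical seeds yield
  bitwise-identical cohorts, bootstrap tables and pipeline outputs.

## Known limitations

- No LD modelling anywhere: candidate SNPs are treated as independent in
  both selection and the reference distribution, as in the original
  framework. Correlated candidates will split or shadow each other's
  effects.
- The bootstrap averages a fixed selected model; selection uncertainty is
  not propagated (re-selection per resample is deliberately out of the
  default path).
- Incidence calibration trusts the published population rates; no
  uncertainty in the baseline table is propagated.
- The framework is sex-agnostic because published incidence was not
  sex-stratified, and competing mortality is not modelled, so late-age
  absolute risks are risks of onset in a world without death from other
  causes.
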