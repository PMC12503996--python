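# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `deltami`.

## Data-generating model

`simulate_trial` draws a two-arm trial of `n` participants. Arm is
Bernoulli(0.5); baseline age is Uniform(`age_low`, `age_high`) (defaults
20–40 years). Weekly outcomes for weeks −1…24 follow

    Y_it = α* + β*_age AGE_it + β*_0 I(t<1) + β*_A A_i I(t>0)
           + c0_i + c1_i t + η_it

with AGE_it = baseline age + t/52 (literal weekly aging; the in-trial drift
of ≤ 24/52 years moves the mean by ~23 steps/day against an error SD of
2000, so this choice is cosmetic but reproducible), c0_i ~ N(0, σ²_c0),
c1_i ~ N(0, σ²_c1) independent, and η_i a 26-dimensional zero-mean Gaussian
with corr(η_t1, η_t2) = exp(−|t1−t2|/`decay`) and common SD σ_e
(`decay` = 52 weeks).

Defaults are the published simulation-study conditions: n = 130,
α* = 10 000, β*_age = −50 /year, β*_0 = −4000, β*_A = 0 (null) or 1000
(alternative), σ_c0 = σ_c1 = 50, σ_e = 2000 steps/day, giving the ~8500
steps/day post-baseline grand mean.

Two deliberate readings of ambiguous points:

* **Treatment-effect timing.** The generating equation is written with a
  constant arm effect at every week, but randomization happens after the
  run-in, and applying the effect during the run-in makes the
  baseline-constrained analysis LMM absorb most of it into random
  intercepts (measured: power 21.5% instead of ~85% at effect 1000). The
  generator therefore applies β*_A post-baseline only, which reproduces the
  published power and near-zero bias.
* **Run-in collapsing.** Weeks −1 and 0 are generated, then
  `collapse_runin` replaces them by a single week-0 record holding their
  mean — the "average steps per day during the run-in" that both analysis
  models use as the baseline covariate. Using week 0 alone is available by
  skipping the collapse of week −1 (`simulate_trial(..., collapse=False)`
  plus custom handling).

RNG discipline: one `numpy` Generator per replication, consumed in a fixed
documented order (covariates, then c0/c1, then the η block); replication r
of a study uses the substream `SeedSequence([master_seed, r])`, so
aggregates are independent of execution order.

## Missingness engine

Post-baseline cells are masked by per-week independent Bernoulli draws with
logit

    η_it = α_m + β_ma A_i + β_mt t + β_m0 v(Y_i0) + β_ml v(Y_ilt)
           + β_mla v(Y_ilt) A_i + β_my v(Y_it) + β_mya v(Y_it) A_i
           + I(t ≥ 13) β_mr v(Ȳ_i,21–24)

where Y_ilt is the most recent observed value before week t (sequentially
updated; the never-masked week-0 value is always eligible) and v(·)
mean-centres value-scale covariates at their generating-model marginal
means (run-in: α* + 30 β*_age + β*_0 ≈ 4500; post-baseline:
α* + 30 β*_age + β*_A/2 ≈ 8500). Without centring, coefficients of ±0.001
per step/day applied to raw ~8500-step values saturate the logistic; with
centring the printed coefficient scales produce moderate missingness.
Week 0 is never masked (it is a covariate in both analysis models and the
fallback last-observed value). MCAR scenarios bypass the logistic model via
a direct per-cell probability `mcar_p`.

Because the exact published supplementary forms are not available, the
intercept α_m is *calibrated*: `calibrate_intercept` bisects α_m until the
simulated overall missingness matches the published value, using one large
common-random-numbers dataset (20 × n participants) so the objective is
monotone and noise-free across bisection steps. This anchors every
mechanism to its published pmiss; the value-coefficient slopes are taken at
the printed values. Consequence (measured, not tuned): the MAR scenarios
reproduce the published biases within Monte-Carlo error, while the MNAR
scenario breaks in the published direction but more strongly (LMM type I
~22% vs the published 14.4%) — the breakage magnitude depends on details of
the supplementary form that the main text does not determine.

## Analysis models

**LM.** OLS of the observed week-21–24 mean on intercept, baseline age,
run-in value and arm (statsmodels). Participants with all four primary
weeks missing are dropped; otherwise the response is the mean of the
observed subset.

**LMM.** Fixed effects: baseline age, separate run-in and post-baseline
levels, cubic time, and 24 week-specific treatment coefficients (no
assumption about the effect's time course; the estimand averages the four
week-21–24 coefficients). Random effects: independent intercept and slope.
Residuals: AR(1) with parameter ρ across integer week lags; missing weeks
are handled by marginalisation (lags exponentiate, ρ^{|Δt|}), never by
re-indexing. No installed Python package fits random effects plus AR(1)
residuals, so the marginal likelihood is implemented directly:

* The AR(1) correlation of a Markov process restricted to its observed
  times whitens by the innovation transform
  (x_j − ρ^{gap} x_{j−1})/√(1 − ρ^{2·gap}); the two random effects enter as
  a rank-2 Woodbury update of the whitened Gram matrices. One likelihood
  evaluation is elementwise arithmetic plus a few matrix products (no
  per-participant factorizations); it matches a dense multivariate-normal
  oracle to ~1e−11 and is tested to 1e−8.
* Fixed effects and σ²_res are profiled out analytically; the optimizer
  searches (log σ_b0/σ_res, log σ_b1/σ_res, atanh ρ) with L-BFGS-B
  (bounds ±10 on log scales, |atanh ρ| ≤ 6; ftol 1e−9, gtol 1e−5 — looser
  tolerances were checked to move the criterion by < 1e−7 relative and the
  contrast by < 0.01 steps/day while running 3× faster).
* Starts: a data-driven start (OLS-residual lag-1 autocorrelation for ρ,
  small random-effect scales), plus a near-iid second start. On observed
  trial data the single data-driven start suffices (a 30-dataset check
  found only sub-0.01-se differences from adding the second start), so
  `starts="auto"` runs the second start only on failure. Completed and
  delta-shifted datasets are different: imputation and constant shifts can
  put the "large random intercept + weak AR(1)" and "small intercept +
  strong AR(1)" decompositions in close competition, and the wrong mode
  changes the contrast SE enough to flip test decisions; pooled
  completed-data fits therefore always run both starts.
* REML is the default (ML available); Wald z-tests use |z| > 1.96, the
  conventional 5% critical value. No small-sample df corrections.

Polynomial time columns are scaled by 1/24 internally and unscaled on
output to keep the 30-column normal equations well conditioned.

## Imputation

MICE with type-1 predictive mean matching: Bayesian-draw coefficients for
the missing rows' predictions, point-estimate predictions for the donors,
donor pool of 5, imputed value copied from a uniformly drawn closest
donor. Sweeps run in increasing week order, 5 iterations, initialised by
sampling observed values within column. Predictors for week t: age, run-in
value, last-before-t observed value (computed against the *original* mask,
since it encodes the observed history that drives missingness), and the
current working values of all other weekly columns; the randomized arm is
excluded by default (matching the described predictor set) behind an
`include_arm` flag. If a column's observed rows cannot support the
regression, other-week predictors are pruned farthest-in-time-first.
Rubin's rules pool the per-completion LMM contrasts:
T = W̄ + (1 + 1/M)B, with B = 0 when M = 1.

## Sensitivity sweep and metrics

δ_max = λ σ̂_res from the observed-data LMM fit (λ = 2); grid
{−1, −1+2/S, …, 1}, S = 8. The shift δ·δ_max is added to originally-masked
cells of the final completed datasets in both arms (`shift_arms="treated"`
restricts to the intervention arm); it is not propagated through the
chained-equation sweeps — the shift is read as a modification of the
imputed values, and a propagation mode is left as future work. By default
the same M completed datasets are reused across the grid (common random
numbers): the statistical target is unchanged and the per-δ contrast is
far less noisy than re-imputing S+1 times; the literal re-run mode is
available (`reuse_imputations=False`).

SIR half-width: the largest h ∈ {2/S, …, 1} such that the observed-data
test rejects and every |δ| ≤ h test rejects in the same direction; 0
otherwise. SIC half-width: the largest h such that every |δ| ≤ h decision
(reject up / reject down / fail to reject) matches the observed-data
decision; 0 when no δ beyond 0 agrees. Both metrics live on the grid, and
SIR = SIC whenever the observed test rejects.

## Replication driver

`run_replications` aggregates per-scenario bias (±2 SE), two-sided
rejection %, % of replications whose decision differs from the
no-imputation LMM, mean pmiss, pSIR (fraction of replications with a
positive SIR), and mean SIR/SIC half-widths. Fit failures are excluded and
counted; more than 1% failures aborts the scenario. Presets cover the
published scenario grids (`table1_row*`, `table2_row*`, `k1`–`k8`), with
MCAR rows masked directly at the printed rate and MAR/MNAR rows calibrated
to it.

## Problem sizes

Monte-Carlo scale is chosen for a single-CPU workflow: the acceptance
script uses 4000 replications for the cross-sectional type-I rate, 1200 for
LMM-based type-I/bias quantities, 1500 for the M = 1 imputation bias and
700 for power (each LMM fit ≈ 0.05–0.15 s); the test suite uses 300–400
replications for the same checks and 30–60 replications for full δ-sweep
metrics (a sweep is (S+1)·M = 90 mixed-model fits per replication). All
comparisons against published values use ≥3 Monte-Carlo SE bands at the
chosen scale; the published tables themselves used 10 000 replications,
which the driver reproduces by raising `reps`.

## Known limitations

* The missingness mechanism is a documented reconstruction (per-week
  independent logistic with centred value covariates), not the exact
  supplementary specification; mechanism-dependent quantities match in
  direction and order, not always in magnitude (see above).
* PMM settings (donor count, sweeps) follow the canonical chained-equation
  defaults; the published supplement may differ.
* The imputation model ignores the re-randomized stage-2 assignment, as the
  trial's own analysis plan argues it has little effect on missingness.
* Monotone-dropout mechanisms, reference-based controlled imputation,
  binary outcomes and pattern-specific δ_max are out of scope.
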