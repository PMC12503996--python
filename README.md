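# deltami

Delta-based controlled multiple-imputation sensitivity analysis for
clinical trials with a repeatedly measured continuous outcome.

## The problem

Trials that collect a weekly outcome (here: average daily step counts over a
two-week run-in and 24 post-baseline weeks, in a two-arm 1:1 randomized
mobile-health trial of n ≈ 130 participants) inevitably lose outcome values.
A linear mixed model (LMM) of all observed weekly values gives valid
inference when data are missing at random (MAR) given everything in the
model, but nobody ever knows that missingness is not MNAR — dependent on the
unobserved values themselves. `deltami` implements the machinery to (a) show
what MCAR/MAR/MNAR missingness does to the two standard analyses, and (b)
run *SD-sensitivity* analyses: delta-based controlled multiple imputation
that systematically shifts imputed values to probe departures from MAR,
summarised by two interval metrics (SIR/SIC, below).

## Models

**Estimand.** The treatment-policy effect θ_A: the average difference
between arms in mean steps/day over weeks 21–24.

**Cross-sectional LM.** Y_i = α + β_age AGE_i + β_r Y_i0 + β_A A_i + ε_i,
where Y_i is the observed mean of weeks 21–24, Y_i0 the run-in average and
A_i the randomized arm; θ̂_A = β̂_A.

**Longitudinal LMM.** For t = 0, …, 24

    Y_it = β_age AGE_i + β_0 I(t=0) + β_1 I(t>0) + β_t t + β_t2 t² + β_t3 t³
           + β_At A_i I(t>0) + b_i + b1_i t + ε_it

with week-specific treatment coefficients β_At, independent Gaussian random
intercept/slope (b_i, b1_i) and AR(1)-correlated residuals, fit by
ML/REML on the observed data; θ̂_A = (β̂_A,21 + β̂_A,22 + β̂_A,23 + β̂_A,24)/4
with a Wald z-test at |z| > 1.96.

**Sensitivity sweep.** MICE with predictive mean matching produces M
completed datasets; every imputed value is shifted by δ·δ_max for δ on the
symmetric grid {−1, −1+2/S, …, 1} (S = 8 by default), with
δ_max = λ·σ̂_res (λ = 2), σ̂_res the residual SD of the observed-data LMM
fit. Each shifted completion set is analysed with the LMM and pooled by
Rubin's rules (T = W̄ + (1+1/M)B). Two per-dataset metrics summarise the
sweep: the **SIR** half-width (largest symmetric δ-interval on which every
sensitivity test and the observed-data test reject in the same direction)
and the **SIC** half-width (largest symmetric δ-interval of decision
concordance with the observed-data test).

## Worked example

```python
import numpy as np
import deltami as dm

gen = dm.GenConfig()                       # n=130, null policy effect
table = dm.simulate_trial(gen, seed=42)    # collapsed weeks 0..24
miss = dm.MissConfig(alpha_m=-2.5, beta_ma=1.5)   # arm-dependent MAR
masked = dm.apply_missingness(table, miss, seed=8, gen=gen)
print(f"pmiss = {dm.compute_pmiss(masked):.3f}")

fit = dm.fit_lmm(masked)                   # observed-data LMM
c = fit.contrast_
print(f"theta_hat = {c.theta_hat:.1f}  se = {c.se:.1f}  z = {c.z:.2f}")

res = dm.run_sensitivity(masked, S=8, M=10, seed=5)
print([round(r.theta_hat, 1) for r in res.per_delta])
print(f"SIR half-width = {res.sir_half_width}, SIC half-width = {res.sic_half_width}")
```

prints

```
pmiss = 0.165
theta_hat = 430.0  se = 318.7  z = 1.35
[-144.1, 10.2, 163.5, 307.1, 417.2, 560.1, 690.2, 822.5, 954.2]
SIR half-width = 0.0, SIC half-width = 0.5
```

The observed-data test does not reject (z = 1.35), so there is no
sensitivity interval of rejection. The per-δ estimates rise monotonically —
arm-1 participants are masked more often (β_ma > 0), so a common positive
shift of imputed values moves the contrast up — and the decisions agree with
the observed analysis for all |δ| ≤ 1/2 (the tests at δ ≥ 3/4 reject
upward), giving SIC half-width 0.5.

A command-line interface mirrors the pipeline
(`deltami simulate | mask | analyze | impute | sensitivity | experiment`);
`deltami experiment --scenario k1 --out summary.csv` reproduces a row of the
simulation studies.

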