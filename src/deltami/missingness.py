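"""Parametric missingness mechanisms for the trial table (MCAR/MAR/MNAR).

Post-baseline outcomes (weeks 1..24) are masked by per-week independent
Bernoulli draws whose probability follows a logistic model.  For participant
i at week t the linear predictor is

    eta_it = alpha_m + beta_ma*A_i + beta_mt*t
             + beta_m0*v(Y_i0) + beta_ml*v(Y_ilt) + beta_mla*v(Y_ilt)*A_i
             + beta_my*v(Y_it) + beta_mya*v(Y_it)*A_i
             + I(t >= 13) * beta_mr * v((Y_i21+Y_i22+Y_i23+Y_i24)/4)

where Y_ilt is the most recent observed outcome before week t (the never-
masked week-0 run-in average is always eligible), and v(.) optionally
mean-centres value-scale covariates at their generating-model marginal means
(without centring, coefficient magnitudes of ~0.001 per step/day applied to
raw values of ~8500 saturate the logistic).  Weeks 13-24 ("stage 2", after
the trial's potential re-randomization) may additionally depend on the
week-21..24 average through beta_mr.

Terms in Y_it and the stage-2 average read outcome values regardless of their
own missingness status, which is what makes those mechanisms MNAR with
respect to any analysis of the observed data; mechanisms with
beta_my = beta_mya = beta_mr = 0 depend only on observed history and are MAR
for the longitudinal analysis model.

MCAR scenarios bypass the logistic model entirely via ``mcar_p``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .simulate import GenConfig, simulate_trial

POST_WEEKS = np.arange(1, 25)
STAGE2_START = 13
PRIMARY_WEEKS = (21, 22, 23, 24)


@dataclass
class MissConfig:
    alpha_m: float = 0.0       # logit intercept
    beta_ma: float = 0.0       # arm
    beta_m0: float = 0.0       # run-in value, per step/day
    beta_mt: float = 0.0       # week
    beta_ml: float = 0.0       # last-observed value
    beta_mla: float = 0.0      # last-observed x arm
    beta_my: float = 0.0       # current value (MNAR)
    beta_mya: float = 0.0      # current value x arm (MNAR)
    beta_mr: float = 0.0       # stage-2 weeks-21..24 average (MNAR)
    center_values: bool = True
    mcar_p: float | None = None  # direct per-week missing probability

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if name in ("center_values", "mcar_p"):
                continue
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.mcar_p is not None and not 0.0 <= self.mcar_p <= 1.0:
            raise ValueError("mcar_p must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MissConfig":
        return cls(**d)

    def is_mnar(self) -> bool:
        """True if the predictor reads any unobserved-eligible value."""
        return any((self.beta_my, self.beta_mya, self.beta_mr))


def marginal_centers(gen: GenConfig) -> dict:
    """Generating-model marginal means used to centre value covariates.

    ``y0``: mean of the collapsed run-in average; ``post``: mean post-baseline
    outcome (the within-trial age drift of <=24/52 years is ignored — it moves
    the mean by ~23 steps/day against an SD of ~2000).  Both include the
    marginal arm effect betaA*/2.
    """
    mean_age = 0.5 * (gen.age_low + gen.age_high)
    base = gen.alpha_star + gen.beta_age_star * mean_age
    return {"y0": base + gen.beta0_star,                  # run-in: pre-randomization
            "post": base + 0.5 * gen.betaA_star}


def linear_predictor(arm, week, y0, y_last, y_current, y_stage2_mean,
                     config: MissConfig, centers: dict | None = None):
    """Logit of the missing probability for one cell (vectorised over pids)."""
    week = np.asarray(week)
    if np.any(week < 1):
        raise ValueError("linear_predictor applies to post-baseline weeks only")
    if config.center_values:
        if centers is None:
            centers = {"y0": 0.0, "post": 0.0}
        v0 = np.asarray(y0) - centers["y0"]
        vl = np.asarray(y_last) - centers["post"]
        vy = np.asarray(y_current) - centers["post"]
        vr = np.asarray(y_stage2_mean) - centers["post"]
    else:
        v0, vl, vy, vr = (np.asarray(a) for a in (y0, y_last, y_current, y_stage2_mean))
    arm = np.asarray(arm)
    eta = (config.alpha_m
           + config.beta_ma * arm
           + config.beta_mt * week
           + config.beta_m0 * v0
           + config.beta_ml * vl
           + config.beta_mla * vl * arm
           + config.beta_my * vy
           + config.beta_mya * vy * arm)
    eta = eta + np.where(week >= STAGE2_START, config.beta_mr * vr, 0.0)
    return eta


def apply_missingness(table: pd.DataFrame, config: MissConfig, seed,
                      gen: GenConfig | None = None) -> pd.DataFrame:
    """Mask post-baseline outcomes of a collapsed trial table.

    Weeks are processed in increasing order so the last-observed covariate is
    updated sequentially; week 0 is never masked.  ``gen`` supplies the
    centring means when ``config.center_values`` (defaults to the standard
    ``GenConfig()``).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if (table["week"] < 0).any():
        raise ValueError("table must be collapsed to weeks 0..24 (run collapse_runin)")
    wide = table.pivot(index="pid", columns="week", values="y")
    if 0 not in wide.columns or wide[0].isna().any():
        raise ValueError("week 0 must be present for every pid")

    pids = wide.index.to_numpy()
    n = len(pids)
    arm = table.drop_duplicates("pid").set_index("pid").loc[pids, "arm"].to_numpy()
    Y = wide[list(range(0, 25))].to_numpy()  # true values, n x 25

    if config.mcar_p is not None:
        miss = rng.random((n, 24)) < config.mcar_p
    else:
        centers = marginal_centers(gen if gen is not None else GenConfig())
        stage2_mean = Y[:, list(PRIMARY_WEEKS)].mean(axis=1)
        y0 = Y[:, 0]
        last = Y[:, 0].copy()
        miss = np.zeros((n, 24), dtype=bool)
        u = rng.random((n, 24))
        for j, t in enumerate(POST_WEEKS):
            eta = linear_predictor(arm, np.full(n, t), y0, last, Y[:, t],
                                   stage2_mean, config, centers)
            miss[:, j] = u[:, j] < expit(eta)
            last = np.where(miss[:, j], last, Y[:, t])

    mask_df = pd.DataFrame(miss, index=pids, columns=POST_WEEKS)
    out = table.copy()
    post = out["week"] >= 1
    cell_missing = mask_df.stack().reindex(
        pd.MultiIndex.from_arrays([out.loc[post, "pid"], out.loc[post, "week"]])
    ).to_numpy()
    out.loc[post, "observed"] = np.where(cell_missing, 0, out.loc[post, "observed"])
    return out


def compute_pmiss(table: pd.DataFrame) -> float:
    """Fraction of week-1..24 cells flagged missing."""
    post = table[table["week"] >= 1]
    if post.empty:
        raise ValueError("table has no post-baseline weeks")
    return float((post["observed"] == 0).mean())


def calibrate_intercept(config: MissConfig, target_pmiss: float, gen: GenConfig,
                        reps: int = 4, seed: int = 0, tol: float = 2e-3,
                        lo: float = -12.0, hi: float = 12.0,
                        max_iter: int = 40) -> float:
    """Find alpha_m so the simulated mean pmiss matches ``target_pmiss``.

    Monotone bisection (expit is increasing in alpha_m); all other
    coefficients fixed.  Uses common random numbers — one simulated dataset of
    ``reps * gen.n`` participants and one set of uniform draws — so the
    objective is monotone and noise-free across iterations.
    """
    if not 0.0 < target_pmiss < 1.0:
        raise ValueError("target_pmiss must be in (0, 1)")
    if config.mcar_p is not None:
        raise ValueError("mcar_p is set; nothing to calibrate")

    from dataclasses import replace
    big = replace(gen, n=max(2, reps * gen.n))
    table = simulate_trial(big, seed, collapse=True)
    mask_seed = np.random.SeedSequence([int(seed), 1_000_003]).generate_state(1)[0] % (2**31)

    def pmiss_at(a: float) -> float:
        c = replace(config, alpha_m=a)
        masked = apply_missingness(table, c, int(mask_seed), gen=big)
        return compute_pmiss(masked)

    p_lo, p_hi = pmiss_at(lo), pmiss_at(hi)
    if not (p_lo <= target_pmiss <= p_hi):
        raise RuntimeError(
            f"search range [{lo}, {hi}] does not bracket target "
            f"(pmiss range [{p_lo:.4f}, {p_hi:.4f}])")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = pmiss_at(mid)
        if abs(p - target_pmiss) < tol:
            return mid
        if p < target_pmiss:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
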