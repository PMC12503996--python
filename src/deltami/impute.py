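"""Multiple imputation by chained equations with predictive mean matching.

The imputer works on the wide layout (one row per participant; columns AGE,
arm, y0..y24) produced by :func:`pivot_wide`.  Each incomplete weekly column
is imputed in increasing week order, repeatedly, by type-1 predictive mean
matching: a Bayesian linear regression of the column on its predictors is
fit on the rows where the column is observed; predictions for the missing
rows use a posterior draw of the coefficients while predictions for observed
rows use the point estimates; each missing row then copies the actual value
of a donor drawn uniformly from the ``donors`` observed rows with the
closest predictions.  Imputed values therefore always lie in the observed
support of the column.

The predictor set for week t is AGE, the run-in value y0, the last outcome
observed (in the original data) before week t, and the current working
values of every other weekly column — optionally the randomized arm too.
The last-observed predictor is computed against the *original* missingness
mask once, not against working imputations: it encodes the observed history
that is believed to drive missingness.

Rubin's rules combine the per-imputation policy-effect estimates:
T = mean within-imputation variance + (1 + 1/M) * between variance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .models import ContrastResult, MixedModelAnalysis, wald_test
from .models import _LmmData

WEEK_COLS = [f"y{w}" for w in range(0, 25)]
POST_COLS = WEEK_COLS[1:]


@dataclass
class ImputeConfig:
    M: int = 10           # number of imputations
    donors: int = 5       # PMM donor-pool size
    iterations: int = 5   # chained-equation sweeps
    include_arm: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.M < 1 or self.donors < 1 or self.iterations < 1:
            raise ValueError("M, donors and iterations must all be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ImputeConfig":
        return cls(**d)


@dataclass
class CompletedSet:
    """M completed wide tables plus the original missing-cell mask."""
    tables: list            # list of wide DataFrames, no missing cells
    mask: pd.DataFrame      # bool, pid x weekly columns, True = was missing

    @property
    def M(self) -> int:
        return len(self.tables)

    def n_masked(self) -> int:
        return int(self.mask.to_numpy().sum())

    def to_csv(self, directory, prefix: str = "imputation") -> list:
        """Write one CSV per completed table plus the missing-cell mask.

        Completed tables are written as ``<prefix>_<m>.csv`` with columns
        ``pid,age,arm,y0,...,y24``; the mask as ``<prefix>_mask.csv`` with
        one ``pid,week`` row per originally missing cell.
        """
        import os
        paths = []
        for m, comp in enumerate(self.tables, start=1):
            path = os.path.join(directory, f"{prefix}_{m}.csv")
            comp.rename_axis("pid").to_csv(path)
            paths.append(path)
        cells = self.mask.rename_axis("pid").stack()
        cells = cells[cells].reset_index()[["pid", "level_1"]]
        cells["week"] = cells.pop("level_1").str.lstrip("y").astype(int)
        mask_path = os.path.join(directory, f"{prefix}_mask.csv")
        cells.to_csv(mask_path, index=False)
        paths.append(mask_path)
        return paths


@dataclass
class MIResult:
    """Rubin-pooled policy-effect estimate."""
    theta_hat: float
    within: float           # mean within-imputation variance
    between: float          # between-imputation variance
    total_var: float        # within + (1 + 1/M) * between
    estimates: np.ndarray   # per-imputation estimates
    contrast: ContrastResult

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def pivot_wide(table: pd.DataFrame):
    """Reshape a collapsed trial table to wide; returns (wide, mask).

    ``wide`` has columns age, arm, y0..y24 indexed by pid and carries the
    internally retained values even in masked cells; ``mask`` marks the cells
    with observed == 0.
    """
    if table.duplicated(["pid", "week"]).any():
        raise ValueError("duplicate (pid, week) rows")
    wide_y = table.pivot(index="pid", columns="week", values="y")
    wide_o = table.pivot(index="pid", columns="week", values="observed")
    weeks = list(range(0, 25))
    if any(w not in wide_y.columns for w in weeks):
        raise ValueError("weeks 0..24 must be present for every pid")
    base = table[table["week"] == 0].set_index("pid")
    wide = pd.DataFrame({"age": base["age"], "arm": base["arm"]},
                        index=wide_y.index)
    for w in weeks:
        wide[f"y{w}"] = wide_y[w]
    mask = pd.DataFrame(False, index=wide.index, columns=WEEK_COLS)
    for w in weeks:
        mask[f"y{w}"] = wide_o[w] == 0
    return wide, mask


def wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Completed wide table back to the long trial-table layout (all observed)."""
    weeks = np.arange(0, 25)
    n = len(wide)
    return pd.DataFrame({
        "pid": np.repeat(wide.index.to_numpy(), 25),
        "week": np.tile(weeks, n),
        "age": (wide["age"].to_numpy(float)[:, None] + weeks / 52.0).ravel(),
        "arm": np.repeat(wide["arm"].to_numpy(int), 25),
        "y": wide[WEEK_COLS].to_numpy(float).ravel(),
        "observed": 1,
    })


def pmm_impute_variable(target: np.ndarray, predictors: np.ndarray,
                        miss: np.ndarray, donors: int,
                        rng: np.random.Generator,
                        prune_order=None) -> np.ndarray:
    """Impute the masked entries of one column by type-1 PMM.

    ``target`` is the full column (working values in masked rows are
    ignored), ``predictors`` the design without intercept, ``miss`` the
    boolean mask of rows to impute.  ``prune_order`` optionally lists
    predictor column indices in drop-first order, applied while the observed
    rows cannot support the regression (rows < predictors + donors + 1).
    Returns the imputed values for the masked rows.
    """
    miss = np.asarray(miss, bool)
    obs = ~miss
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("no observed rows for target column")
    keep = list(range(predictors.shape[1]))
    if prune_order is not None:
        for j in prune_order:
            if n_obs >= len(keep) + donors + 2:
                break
            keep.remove(j)
    X = np.column_stack([np.ones(len(target)), predictors[:, keep]])
    Xo, yo = X[obs], np.asarray(target, float)[obs]
    p = X.shape[1]

    beta_hat, _, rank, _ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta_hat
    dof = max(n_obs - rank, 1)
    rss = float(resid @ resid)
    sigma2_star = rss / rng.chisquare(dof)
    xtx_inv = np.linalg.pinv(Xo.T @ Xo)
    cov = sigma2_star * xtx_inv
    # symmetrise then factor via eigh for robustness to near-singularity
    w, V = np.linalg.eigh(0.5 * (cov + cov.T))
    L = V * np.sqrt(np.clip(w, 0.0, None))
    beta_star = beta_hat + L @ rng.standard_normal(p)

    pred_obs = Xo @ beta_hat
    pred_mis = X[miss] @ beta_star
    k = min(donors, n_obs)
    d = np.abs(pred_obs[None, :] - pred_mis[:, None])
    pool = np.argpartition(d, k - 1, axis=1)[:, :k]
    choice = pool[np.arange(len(pred_mis)), rng.integers(0, k, size=len(pred_mis))]
    return yo[choice]


def _last_observed_matrix(wide: pd.DataFrame, mask: pd.DataFrame) -> np.ndarray:
    """lastobs[i, t-1] = latest originally observed value before week t."""
    n = len(wide)
    vals = wide[WEEK_COLS].to_numpy(float)
    observed = ~mask[WEEK_COLS].to_numpy(bool)
    out = np.empty((n, 24))
    last = vals[:, 0].copy()  # week 0 is never masked
    for t in range(1, 25):
        out[:, t - 1] = last
        last = np.where(observed[:, t], vals[:, t], last)
    return out


def mice_chain(wide: pd.DataFrame, mask: pd.DataFrame,
               config: ImputeConfig, rng=None) -> CompletedSet:
    """Run the chained-equation sweeps for each of the M imputations."""
    if mask[ "y0"].any():
        raise ValueError("week 0 must be fully observed")
    if wide[["age", "arm"]].isna().any().any():
        raise ValueError("age and arm must be fully observed")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    maskv = mask[WEEK_COLS].to_numpy(bool)
    vals = wide[WEEK_COLS].to_numpy(float)
    lastobs = _last_observed_matrix(wide, mask)
    age = wide["age"].to_numpy(float)
    arm = wide["arm"].to_numpy(float)
    incomplete = [t for t in range(1, 25) if maskv[:, t].any()]

    substreams = rng.spawn(config.M)
    tables = []
    for m in range(config.M):
        sub = substreams[m]
        work = vals.copy()
        for t in incomplete:
            obs_vals = vals[~maskv[:, t], t]
            if len(obs_vals) == 0:
                raise ValueError(f"week {t} has no observed values")
            work[maskv[:, t], t] = sub.choice(obs_vals, size=maskv[:, t].sum())
        for _ in range(config.iterations):
            for t in incomplete:
                others = [w for w in range(1, 25) if w != t]
                cols = [age, vals[:, 0], lastobs[:, t - 1]]
                if config.include_arm:
                    cols.append(arm)
                n_fixed = len(cols)
                cols += [work[:, w] for w in others]
                X = np.column_stack(cols)
                # other-week predictors, farthest in time dropped first
                order = np.argsort([-abs(w - t) for w in others])
                prune = [n_fixed + int(i) for i in order]
                work[maskv[:, t], t] = pmm_impute_variable(
                    work[:, t], X, maskv[:, t], config.donors, sub,
                    prune_order=prune)
        comp = wide.copy()
        comp[WEEK_COLS] = work
        tables.append(comp)
    return CompletedSet(tables=tables, mask=mask.copy())


class MICEImputer(BaseEstimator):
    """scikit-learn style front end over :func:`mice_chain`.

    ``transform`` accepts a long trial table and returns a
    :class:`CompletedSet` of M completed wide tables.
    """

    def __init__(self, M: int = 10, donors: int = 5, iterations: int = 5,
                 include_arm: bool = False, random_state=None):
        self.M = M
        self.donors = donors
        self.iterations = iterations
        self.include_arm = include_arm
        self.random_state = random_state

    def _config(self) -> ImputeConfig:
        seed = self.random_state if not isinstance(
            self.random_state, np.random.Generator) else None
        return ImputeConfig(M=self.M, donors=self.donors,
                            iterations=self.iterations,
                            include_arm=self.include_arm, seed=seed)

    def fit(self, table: pd.DataFrame, y=None) -> "MICEImputer":
        return self

    def transform(self, table: pd.DataFrame) -> CompletedSet:
        wide, mask = pivot_wide(table)
        rng = (self.random_state
               if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        return mice_chain(wide, mask, self._config(), rng)

    def fit_transform(self, table: pd.DataFrame, y=None) -> CompletedSet:
        return self.fit(table).transform(table)


def rubin_pool(estimates, variances, level: float = 0.05) -> MIResult:
    """Pool per-imputation estimates and variances by Rubin's rules."""
    estimates = np.asarray(estimates, float)
    variances = np.asarray(variances, float)
    if estimates.size == 0 or estimates.shape != variances.shape:
        raise ValueError("estimates and variances must be equal-length, non-empty")
    M = estimates.size
    theta = float(estimates.mean())
    within = float(variances.mean())
    between = float(estimates.var(ddof=1)) if M > 1 else 0.0
    total = within + (1.0 + 1.0 / M) * between
    if total > 0:
        contrast = wald_test(theta, float(np.sqrt(total)), level)
    else:
        contrast = ContrastResult(theta, 0.0, float("nan"), False, 0)
    return MIResult(theta, within, between, total, estimates, contrast)


def fit_completed(completed: CompletedSet, method: str = "reml",
                  level: float = 0.05, x0=None, starts=2, **kwargs) -> MIResult:
    """Fit the mixed model on every completed table and pool by Rubin's rules.

    Completed (and delta-shifted) datasets can put the random-intercept and
    AR(1) variance decompositions in close competition, so both optimizer
    starts are used by default.  ``x0`` optionally adds a warm start for the
    first fit; subsequent fits chain from the previous optimum (the M
    completed datasets differ only in the imputed cells).
    """
    est, var = [], []
    theta = x0
    for comp in completed.tables:
        data = _LmmData.from_arrays(
            comp.index.to_numpy(), comp["age"].to_numpy(float),
            comp["arm"].to_numpy(int), comp[WEEK_COLS].to_numpy(float))
        fit = MixedModelAnalysis(method=method, level=level, starts=starts,
                                 **kwargs).fit(data, x0=theta)
        theta = fit.theta_
        est.append(fit.contrast_.theta_hat)
        var.append(fit.contrast_.se ** 2)
    return rubin_pool(est, var, level)


def mi_analyze(table: pd.DataFrame, config: ImputeConfig | None = None,
               rng=None, method: str = "reml", level: float = 0.05) -> MIResult:
    """The full multiple-imputation pipeline on one trial table.

    Imputes M completed datasets, fits the longitudinal mixed model and the
    policy contrast on each, and pools with Rubin's rules.  With no masked
    cells the result collapses to the observed-data analysis (between
    variance 0) for any M.
    """
    config = config or ImputeConfig()
    wide, mask = pivot_wide(table)
    if not mask.to_numpy().any():
        fit = MixedModelAnalysis(method=method, level=level).fit(table)
        c = fit.contrast_
        return rubin_pool([c.theta_hat], [c.se ** 2], level)
    completed = mice_chain(wide, mask, config, rng)
    return fit_completed(completed, method=method, level=level)
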