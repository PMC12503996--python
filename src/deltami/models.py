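"""Analysis models for the trial table and the policy-effect contrast.

Two analysis routes are provided:

* :class:`LinearModelAnalysis` — the cross-sectional linear model of the
  primary outcome (the mean of observed weeks 21-24) on intercept, baseline
  age, the run-in value Y0 and the randomized arm, fit by OLS.

* :class:`MixedModelAnalysis` — the longitudinal linear mixed model of all
  weekly outcomes

      Y_it = beta_age*AGE_i + beta_0*I(t=0) + beta_1*I(t>0)
             + beta_t*t + beta_t2*t^2 + beta_t3*t^3
             + betaA_t*A_i*I(t>0) + b_i + b1_i*t + eps_it

  with week-specific treatment coefficients betaA_t (t = 1..24), independent
  Gaussian random intercept b_i and slope b1_i, and AR(1)-correlated residuals
  (corr(eps_t1, eps_t2) = rho^{|t1-t2|}).  Estimation maximises the observed-
  data marginal likelihood (ML or REML); the fixed effects and the residual
  variance are profiled out by generalized least squares, leaving a
  3-parameter search over (log sigma_b0/sigma_res, log sigma_b1/sigma_res,
  atanh rho).  Missing weeks are handled by marginalisation: the per-pid
  covariance is evaluated on the observed weeks with lags exponentiated as
  rho^{|dt|}.

The policy effect is the contrast theta_A = (betaA_21 + betaA_22 + betaA_23
+ betaA_24)/4, the average treatment difference over the primary-outcome
window, tested by a Wald z-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

ANALYSIS_WEEKS = np.arange(0, 25)
PRIMARY_WEEKS = (21, 22, 23, 24)
_T_SCALE = 24.0  # internal scaling of the polynomial time columns


@dataclass
class ContrastResult:
    """Policy-effect estimate with its Wald test decisions."""
    theta_hat: float
    se: float
    z: float
    reject_two_sided: bool
    onesided_direction: int  # sign of effect if |z| > crit, else 0

    def to_dict(self) -> dict:
        return {"theta_hat": self.theta_hat, "se": self.se, "z": self.z,
                "reject_two_sided": self.reject_two_sided,
                "direction": self.onesided_direction}


def wald_test(estimate: float, se: float, level: float = 0.05) -> ContrastResult:
    """Asymptotic z-test of a zero null.

    At the default 5% level the critical value is the conventional 1.96; for
    other levels the exact normal quantile is used.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    crit = 1.96 if level == 0.05 else float(stats.norm.ppf(1 - level / 2))
    z = estimate / se
    reject = abs(z) > crit
    direction = int(np.sign(z)) if reject else 0
    return ContrastResult(float(estimate), float(se), float(z), bool(reject), direction)


def _contrast_from(names, params, cov, level: float = 0.05) -> ContrastResult:
    """theta = c'beta with weights 1/4 on the week-21..24 arm coefficients."""
    c = np.zeros(len(names))
    for w in PRIMARY_WEEKS:
        c[names.index(f"arm_w{w}")] = 0.25
    theta = float(c @ params)
    var = float(c @ cov @ c)
    se = float(np.sqrt(max(var, 0.0)))
    if se <= 0:
        return ContrastResult(theta, se, float("nan"), False, 0)
    return wald_test(theta, se, level)


# ---------------------------------------------------------------------------
# cross-sectional linear model
# ---------------------------------------------------------------------------

class LinearModelAnalysis(BaseEstimator):
    """OLS of the primary outcome on intercept, age, run-in value and arm.

    The response per participant is the mean of the *observed* week-21..24
    values; a participant enters only if at least one of those weeks is
    observed.  Fitted attributes follow scikit-learn conventions.
    """

    def __init__(self, level: float = 0.05):
        self.level = level

    def fit(self, table: pd.DataFrame) -> "LinearModelAnalysis":
        base = table[table["week"] == 0].set_index("pid")
        prim = table[table["week"].isin(PRIMARY_WEEKS) & (table["observed"] == 1)]
        resp = prim.groupby("pid")["y"].mean()
        pids = resp.index
        if len(pids) < 4:
            raise ValueError("fewer than 4 participants with an observable response")
        X = pd.DataFrame({
            "const": 1.0,
            "age": base.loc[pids, "age"].to_numpy(),
            "y0": base.loc[pids, "y"].to_numpy(),
            "arm": base.loc[pids, "arm"].to_numpy(float),
        }, index=pids)
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError("collinear design")
        res = sm.OLS(resp.to_numpy(), X.to_numpy()).fit()
        self.names_ = list(X.columns)
        self.params_ = pd.Series(res.params, index=self.names_)
        self.cov_params_ = pd.DataFrame(res.cov_params(), index=self.names_,
                                        columns=self.names_)
        self.resid_sd_ = float(np.sqrt(res.mse_resid))
        self.n_used_ = int(len(pids))
        i = self.names_.index("arm")
        self.contrast_ = wald_test(res.params[i], res.bse[i], self.level)
        return self

    def report(self) -> dict:
        """Flat coefficient -> (estimate, se) mapping plus the contrast."""
        se = np.sqrt(np.diag(self.cov_params_.to_numpy()))
        out = {name: {"estimate": float(self.params_[name]), "se": float(s)}
               for name, s in zip(self.names_, se)}
        out["contrast"] = self.contrast_.to_dict()
        return out


def fit_lm(table: pd.DataFrame, level: float = 0.05) -> LinearModelAnalysis:
    """Functional wrapper over :class:`LinearModelAnalysis`."""
    return LinearModelAnalysis(level=level).fit(table)


# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------

def lmm_fixed_effect_names() -> list[str]:
    return (["age", "I_t0", "I_post", "t", "t2", "t3"]
            + [f"arm_w{w}" for w in range(1, 25)])


def lmm_design_matrix(weeks, age: float, arm: int, scale_time: bool = False) -> np.ndarray:
    """Fixed-effect design rows for one participant at the given weeks."""
    weeks = np.asarray(weeks, dtype=float)
    ts = weeks / _T_SCALE if scale_time else weeks
    cols = [np.full_like(weeks, age),
            (weeks == 0).astype(float),
            (weeks > 0).astype(float),
            ts, ts**2, ts**3]
    for w in range(1, 25):
        cols.append(float(arm) * (weeks == w).astype(float))
    return np.column_stack(cols)


def _design_batch(age: np.ndarray, arm: np.ndarray) -> np.ndarray:
    """Scaled-time design rows for all participants on the 0..24 grid."""
    weeks = ANALYSIS_WEEKS.astype(float)
    n, T = len(age), len(weeks)
    ts = weeks / _T_SCALE
    X = np.zeros((n, T, 30))
    X[:, :, 0] = age[:, None]
    X[:, :, 1] = (weeks == 0)[None, :]
    X[:, :, 2] = (weeks > 0)[None, :]
    X[:, :, 3] = ts[None, :]
    X[:, :, 4] = (ts**2)[None, :]
    X[:, :, 5] = (ts**3)[None, :]
    for w in range(1, 25):
        X[:, w, 5 + w] = arm
    return X


def lmm_marginal_covariance(weeks, sigma_b0: float, sigma_b1: float,
                            sigma_res: float, rho: float) -> np.ndarray:
    """Marginal covariance of the observed weeks for one participant.

    V = Z diag(sigma_b0^2, sigma_b1^2) Z' + sigma_res^2 * R(rho) with
    Z = [1, t] and R_{jk} = rho^{|w_j - w_k|}.
    """
    if abs(rho) >= 1:
        raise ValueError("rho must be in (-1, 1)")
    weeks = np.asarray(weeks, dtype=float)
    lag = np.abs(weeks[:, None] - weeks[None, :])
    V = (sigma_b0**2
         + sigma_b1**2 * np.outer(weeks, weeks)
         + sigma_res**2 * rho**lag)
    return V


def lmm_loglik(beta, sigma_b0, sigma_b1, sigma_res, rho,
               table: pd.DataFrame) -> float:
    """Observed-data Gaussian log-likelihood at the given parameters.

    Sums, over participants, the multivariate-normal log-density of the
    observed outcomes given the fixed-effect mean and the marginal covariance
    restricted to the observed weeks.
    """
    beta = np.asarray(beta, dtype=float)
    total = 0.0
    for _, g in table[table["observed"] == 1].groupby("pid"):
        weeks = g["week"].to_numpy()
        y = g["y"].to_numpy()
        age = float(g.loc[g["week"].idxmin(), "age"])
        arm = int(g["arm"].iloc[0])
        X = lmm_design_matrix(weeks, age, arm)
        V = lmm_marginal_covariance(weeks, sigma_b0, sigma_b1, sigma_res, rho)
        r = y - X @ beta
        cf = linalg.cho_factor(V, lower=True)
        w = linalg.cho_solve(cf, r)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        total += -0.5 * (len(y) * np.log(2 * np.pi) + logdet + r @ w)
    return float(total)


class _LmmData:
    """Compacted per-participant arrays for fast repeated likelihood evaluation.

    Each participant's observed rows are gathered to the leading slots of a
    fixed-width layout (padded with zeros), with the integer week gaps
    between consecutive observed rows stored alongside.  The AR(1) residual
    correlation of a Markov process restricted to its observed times whitens
    by the one-step innovation transform (x_j - rho^gap * x_{j-1}) /
    sqrt(1 - rho^{2 gap}), and the random intercept/slope enter the marginal
    covariance as a rank-2 update handled by the Woodbury identity — so each
    likelihood evaluation is elementwise arithmetic plus a handful of matrix
    products, with no per-participant factorizations.
    """

    def __init__(self, table: pd.DataFrame):
        if (table["week"] < 0).any():
            raise ValueError("collapse the run-in before fitting (weeks 0..24)")
        wide_y = table.pivot(index="pid", columns="week", values="y")
        wide_o = table.pivot(index="pid", columns="week", values="observed")
        missing_weeks = [w for w in ANALYSIS_WEEKS if w not in wide_y.columns]
        if missing_weeks:
            raise ValueError(f"table lacks weeks {missing_weeks}")
        wide_y = wide_y[list(ANALYSIS_WEEKS)]
        wide_o = wide_o[list(ANALYSIS_WEEKS)].fillna(0)
        base = table[table["week"] == 0].set_index("pid")
        self._init_arrays(
            pids=wide_y.index.to_numpy(),
            age=base.loc[wide_y.index, "age"].to_numpy(float),
            arm=base.loc[wide_y.index, "arm"].to_numpy(int),
            Y=np.nan_to_num(wide_y.to_numpy(float), nan=0.0),
            obs=wide_o.to_numpy(float) > 0)

    @classmethod
    def from_arrays(cls, pids, age, arm, Y, obs=None) -> "_LmmData":
        """Build directly from wide arrays (fast path for completed data)."""
        self = cls.__new__(cls)
        if obs is None:
            obs = np.ones_like(np.asarray(Y, float), dtype=bool)
        self._init_arrays(np.asarray(pids), np.asarray(age, float),
                          np.asarray(arm, int), np.asarray(Y, float), obs)
        return self

    def _init_arrays(self, pids, age, arm, Y, obs) -> None:
        weeks = ANALYSIS_WEEKS.astype(float)
        n, T = obs.shape
        if (obs[:, 1:].sum(axis=1) > 0).sum() < 4 or len(np.unique(arm)) < 2:
            raise ValueError("need observed post-baseline data in both arms")
        self.pids = pids
        X = _design_batch(age, arm)
        y = Y * obs
        rhs = np.concatenate([y[:, :, None], X * obs[:, :, None]], axis=2)

        # gather observed slots to the left, preserving week order
        order = np.argsort(~obs, axis=1, kind="stable")
        k = obs.sum(axis=1)
        slot = np.arange(T)[None, :]
        self.valid = slot < k[:, None]                       # n x 25
        self.pair_valid = (slot[:, 1:] < k[:, None])         # n x 24
        self.weeks_c = np.take_along_axis(
            np.broadcast_to(weeks, obs.shape), order, axis=1) * self.valid
        self.rhs_c = np.take_along_axis(rhs, order[:, :, None], axis=1)
        gaps = np.diff(self.weeks_c, axis=1)
        self.gaps = np.where(self.pair_valid, gaps, 1.0)

        self.N = int(obs.sum())
        self.p = X.shape[2]
        self.arm = arm
        self.u1 = self.valid.astype(float)        # random-intercept loadings
        self.u2 = self.weeks_c * self.valid       # random-slope loadings
        self._rho_key = None

    def whiten(self, v: np.ndarray, a, s) -> np.ndarray:
        """Innovation transform of compacted columns v (n x 25 [x c])."""
        out = np.empty_like(v)
        aa, ss = (a, s) if v.ndim == 2 else (a[:, :, None], s[:, :, None])
        out[:, 0] = v[:, 0]
        out[:, 1:] = (v[:, 1:] - aa * v[:, :-1]) / ss
        return out

    def rho_block(self, rho: float):
        """rho-dependent pieces of the likelihood, cached on exact rho.

        The AR(1) whitening and every Gram product that does not involve the
        random-effect scales depends on rho alone, so successive likelihood
        evaluations at the same rho (e.g. coordinate-wise finite-difference
        steps) reuse it.
        """
        if self._rho_key == rho:
            return self._rho_cache
        # gaps are integer-valued, so rho**gaps is well defined for rho < 0
        a = np.where(self.pair_valid, rho ** self.gaps, 0.0)
        s2 = 1.0 - a * a
        if np.any(s2 <= 0):
            return None
        s = np.sqrt(s2)
        Wr = self.whiten(self.rhs_c, a, s)                  # n x 25 x (1+p)
        W1 = self.whiten(self.u1, a, s)                     # n x 25
        W2 = self.whiten(self.u2, a, s)
        n, T, c = Wr.shape
        flat = Wr.reshape(n * T, c)
        A = flat.T @ flat                                   # joint Gram [y X]
        WrT = Wr.transpose(0, 2, 1)
        B1 = (WrT @ W1[:, :, None])[:, :, 0]                # n x (1+p)
        B2 = (WrT @ W2[:, :, None])[:, :, 0]
        u11 = np.sum(W1 * W1, axis=1)
        u12 = np.sum(W1 * W2, axis=1)
        u22 = np.sum(W2 * W2, axis=1)
        logdet_ar = float(np.sum(np.log(s2[self.pair_valid])))
        self._rho_key = rho
        self._rho_cache = (A, B1, B2, u11, u12, u22, logdet_ar)
        return self._rho_cache


def _profiled_crit(theta, data: _LmmData, reml: bool):
    """-2 * profiled (restricted) log-likelihood plus pieces for the fit.

    theta = (log g0, log g1, atanh rho) with g = sigma_b / sigma_res; the
    fixed effects are profiled by GLS and sigma_res^2 analytically.  The
    random intercept/slope enter through the rank-2 Woodbury identity on the
    AR(1)-whitened Gram blocks.
    """
    g0, g1 = np.exp(theta[0]), np.exp(theta[1])
    rho = np.tanh(theta[2])
    block = data.rho_block(rho)
    if block is None:
        return np.inf, None
    A, B1, B2, u11, u12, u22, logdet_ar = block

    m11 = 1.0 + g0**2 * u11
    m12 = g0 * g1 * u12
    m22 = 1.0 + g1**2 * u22
    det = m11 * m22 - m12**2
    if np.any(det <= 0):
        return np.inf, None
    b1 = g0 * B1
    b2 = g1 * B2
    t1 = (b1 * (m22 / det)[:, None]).T @ b1
    t2 = (b1 * (m12 / det)[:, None]).T @ b2
    t3 = (b2 * (m11 / det)[:, None]).T @ b2
    G = A - (t1 - t2 - t2.T + t3)                           # [y X]' C^-1 [y X]

    logdet = logdet_ar + float(np.sum(np.log(det)))
    yy, Xty, XtX = G[0, 0], G[0, 1:], G[1:, 1:]
    try:
        cf = linalg.cho_factor(XtX, lower=True)
    except linalg.LinAlgError:
        return np.inf, None
    beta = linalg.cho_solve(cf, Xty)
    rss = float(yy - Xty @ beta)
    if not np.isfinite(rss) or rss <= 0:
        return np.inf, None
    N, p = data.N, data.p
    dof = N - p if reml else N
    sigma2 = max(rss / dof, 1e-300)
    crit = dof * (np.log(2 * np.pi * sigma2) + 1.0) + logdet
    if reml:
        crit += 2.0 * np.sum(np.log(np.diag(cf[0])))
    return crit, (beta, sigma2, XtX, cf)


class MixedModelAnalysis(BaseEstimator):
    """ML/REML fit of the longitudinal mixed model with AR(1) residuals.

    Parameters
    ----------
    method : {"reml", "ml"}
        Estimation criterion (REML default).
    starts : {"auto", 1, 2}
        "auto" runs a data-driven start (residual-autocorrelation based) and
        falls back to a second, near-iid start only if the first fails;
        2 always runs both and keeps the better optimum.
    """

    def __init__(self, method: str = "reml", level: float = 0.05,
                 starts="auto", gtol: float = 1e-5, maxiter: int = 200):
        self.method = method
        self.level = level
        self.starts = starts
        self.gtol = gtol
        self.maxiter = maxiter

    # -- initial values ----------------------------------------------------
    @staticmethod
    def _moment_start(data: _LmmData) -> np.ndarray:
        # OLS residual lag-1 autocorrelation as the starting rho
        y = data.rhs_c[:, :, 0]
        X = data.rhs_c[:, :, 1:]
        Xf = X.reshape(-1, data.p)
        beta, *_ = np.linalg.lstsq(Xf, y.ravel(), rcond=None)
        r = (y - X @ beta) * data.valid
        pair = data.pair_valid & (data.gaps == 1.0)
        a, b = r[:, 1:][pair], r[:, :-1][pair]
        den = float(np.sqrt(np.sum(a**2) * np.sum(b**2)))
        rho0 = np.clip(float(np.sum(a * b)) / den if den > 0 else 0.5, -0.95, 0.995)
        return np.array([np.log(0.05), np.log(0.05), np.arctanh(rho0)])

    _IID_START = np.array([np.log(0.3), np.log(0.05), np.arctanh(0.2)])

    def fit(self, table, x0=None) -> "MixedModelAnalysis":
        """Fit to a long trial table (or a prebuilt internal data block).

        ``x0`` optionally warm-starts the variance-parameter search, e.g.
        with the ``theta_`` of a fit to a closely related dataset.
        """
        data = table if isinstance(table, _LmmData) else _LmmData(table)
        reml = self.method.lower() == "reml"
        if self.method.lower() not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")

        def objective(theta):
            return _profiled_crit(theta, data, reml)[0]

        bounds = [(-10.0, 3.0), (-10.0, 3.0), (-6.0, 6.0)]
        starts = [np.asarray(x0, float) if x0 is not None
                  else self._moment_start(data)]
        if self.starts == 2:
            starts.append(self._IID_START)
        best = None
        for k, x0 in enumerate(starts):
            res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"maxiter": self.maxiter,
                                             "ftol": 1e-9, "gtol": self.gtol})
            if best is None or res.fun < best.fun:
                best = res
            if (self.starts == "auto" and k == 0
                    and not (res.success and np.isfinite(res.fun))):
                starts.append(self._IID_START)
        self.converged_ = bool(best.success and np.isfinite(best.fun))

        crit, parts = _profiled_crit(best.x, data, reml)
        if parts is None:
            raise RuntimeError("likelihood undefined at optimum")
        beta_s, sigma2, XtX, cf = parts
        # undo the internal time scaling of the polynomial columns
        scale = np.ones(data.p)
        scale[3:6] = 1.0 / np.array([_T_SCALE, _T_SCALE**2, _T_SCALE**3])
        beta = beta_s * scale
        cov = sigma2 * linalg.cho_solve(cf, np.eye(data.p))
        cov = cov * np.outer(scale, scale)

        names = lmm_fixed_effect_names()
        self.names_ = names
        self.fixed_effects_ = pd.Series(beta, index=names)
        self.cov_fixed_ = pd.DataFrame(cov, index=names, columns=names)
        self.sigma_res_ = float(np.sqrt(sigma2))
        self.sigma_b0_ = float(np.exp(best.x[0]) * self.sigma_res_)
        self.sigma_b1_ = float(np.exp(best.x[1]) * self.sigma_res_)
        self.rho_ = float(np.tanh(best.x[2]))
        self.theta_ = best.x.copy()
        self.loglik_ = -0.5 * float(crit)
        self.n_obs_ = data.N
        self.contrast_ = _contrast_from(names, beta, cov, self.level)
        return self

    def report(self) -> dict:
        """Flat coefficient -> (estimate, se) mapping, variance components
        and the policy contrast."""
        se = np.sqrt(np.diag(self.cov_fixed_.to_numpy()))
        out = {name: {"estimate": float(self.fixed_effects_[name]),
                      "se": float(s)}
               for name, s in zip(self.names_, se)}
        out["variance_components"] = {
            "sigma_b0": self.sigma_b0_, "sigma_b1": self.sigma_b1_,
            "sigma_res": self.sigma_res_, "rho": self.rho_}
        out["loglik"] = self.loglik_
        out["converged"] = self.converged_
        out["contrast"] = self.contrast_.to_dict()
        return out


def fit_lmm(table: pd.DataFrame, method: str = "reml", **kwargs) -> MixedModelAnalysis:
    """Functional wrapper over :class:`MixedModelAnalysis`."""
    return MixedModelAnalysis(method=method, **kwargs).fit(table)


def policy_contrast(fit: MixedModelAnalysis, level: float = 0.05) -> ContrastResult:
    """theta_A = mean of the week-21..24 treatment coefficients, with Wald test."""
    if not getattr(fit, "converged_", False):
        raise ValueError("fit did not converge")
    return _contrast_from(fit.names_, fit.fixed_effects_.to_numpy(),
                          fit.cov_fixed_.to_numpy(), level)
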