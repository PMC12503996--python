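"""Longitudinal step-count trial simulator.

Generates SIU-like weekly step-count data for a two-arm trial from a linear
mixed model with a Gaussian random intercept and slope per participant and
within-participant errors that are exponentially ("spatially") correlated in
time:

    Y_it = alpha* + beta_age* * AGE_it + beta0* * I(t < 1)
           + betaA* * A_i + c0_i + c1_i * t + eta_it,   t = -1, ..., 24

where A_i ~ Bernoulli(0.5) is the randomized arm, baseline age is
Uniform(age_low, age_high), c0_i ~ N(0, sigma_c0^2), c1_i ~ N(0, sigma_c1^2)
and eta_i is a 26-dimensional zero-mean Gaussian with
corr(eta_t1, eta_t2) = exp(-|t1 - t2| / decay) and common SD sigma_e.

Weeks -1 and 0 form the run-in; :func:`collapse_runin` replaces them by a
single week-0 record holding their average, which is the baseline outcome Y_i0
used by the analysis models.

The exchange object (a "trial table") is a long-format pandas DataFrame with
columns ``pid, week, age, arm, y, observed``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

TABLE_COLUMNS = ["pid", "week", "age", "arm", "y", "observed"]

#: week range generated by the simulator (run-in weeks -1 and 0 included)
GEN_WEEKS = np.arange(-1, 25)


@dataclass
class GenConfig:
    """Parameters of the data-generating mixed model.

    Defaults are the trial-sized null configuration used throughout the
    simulation studies: n=130 participants, grand post-baseline mean
    ~8500 steps/day, run-in offset -4000 steps/day, small random
    intercept/slope SDs and error SD 2000 steps/day.
    """

    n: int = 130
    alpha_star: float = 10_000.0     # intercept, steps/day
    beta_age_star: float = -50.0     # steps/day per year of age
    beta0_star: float = -4_000.0     # run-in offset, steps/day
    betaA_star: float = 0.0          # constant treatment policy effect, steps/day
    sigma_c0: float = 50.0           # SD of random intercept
    sigma_c1: float = 50.0           # SD of random slope (per week)
    sigma_e: float = 2_000.0         # error SD, steps/day
    decay: float = 52.0              # spatial-correlation time constant, weeks
    age_low: float = 20.0
    age_high: float = 40.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        for name in ("sigma_c0", "sigma_c1", "sigma_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.decay <= 0:
            raise ValueError("decay must be > 0")
        if not self.age_low < self.age_high:
            raise ValueError("age_low must be < age_high")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GenConfig":
        return cls(**d)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_covariates(config: GenConfig, seed) -> pd.DataFrame:
    """Draw the per-participant skeleton: pid, randomized arm, baseline age.

    Arm is Bernoulli(0.5); baseline age is Uniform(age_low, age_high).
    Deterministic given ``seed`` (an int or a numpy Generator).
    """
    rng = _as_rng(seed)
    arm = rng.integers(0, 2, size=config.n)
    age0 = rng.uniform(config.age_low, config.age_high, size=config.n)
    return pd.DataFrame({"pid": np.arange(config.n), "arm": arm, "age0": age0})


def spatial_covariance(weeks, sigma_e: float, decay: float = 52.0) -> np.ndarray:
    """Covariance of the within-participant error over ``weeks``.

    Entry (j, k) is sigma_e^2 * exp(-|w_j - w_k| / decay); symmetric PSD.
    """
    weeks = np.asarray(weeks, dtype=float)
    if len(np.unique(weeks)) != len(weeks):
        raise ValueError("weeks must be distinct")
    if sigma_e < 0:
        raise ValueError("sigma_e must be >= 0")
    lag = np.abs(weeks[:, None] - weeks[None, :])
    return sigma_e**2 * np.exp(-lag / decay)


def _fixed_surface(config: GenConfig, age_t: np.ndarray, arm: np.ndarray,
                   weeks: np.ndarray) -> np.ndarray:
    """Fixed-effect mean surface of the generator (n x T).

    The constant treatment policy effect applies to post-baseline weeks only:
    randomization happens after the run-in, so arms coincide during weeks
    -1 and 0.
    """
    runin = (weeks < 1).astype(float)
    return (config.alpha_star
            + config.beta_age_star * age_t
            + config.beta0_star * runin[None, :]
            + config.betaA_star * arm[:, None] * (1.0 - runin)[None, :])


def simulate_outcomes(config: GenConfig, skeleton: pd.DataFrame, seed) -> pd.DataFrame:
    """Generate the full trial table for weeks -1..24 from a skeleton.

    Substream order within the generator stream: c0/c1 draws, then the
    correlated errors (one standard-normal block, whitened jointly), so the
    same seed yields a bitwise-identical table.
    """
    for col in ("pid", "arm", "age0"):
        if col not in skeleton.columns:
            raise ValueError(f"skeleton missing column {col!r}")
    rng = _as_rng(seed)
    n = len(skeleton)
    weeks = GEN_WEEKS
    T = len(weeks)

    c0 = rng.normal(0.0, config.sigma_c0, size=n)
    c1 = rng.normal(0.0, config.sigma_c1, size=n)
    cov = spatial_covariance(weeks, config.sigma_e, config.decay)
    if config.sigma_e > 0:
        L = np.linalg.cholesky(cov)
        eta = rng.standard_normal((n, T)) @ L.T
    else:
        eta = np.zeros((n, T))

    age0 = skeleton["age0"].to_numpy(float)
    arm = skeleton["arm"].to_numpy(int)
    # age in years at the end of week t: baseline age + t/52
    age_t = age0[:, None] + weeks[None, :] / 52.0
    y = (_fixed_surface(config, age_t, arm, weeks)
         + c0[:, None] + c1[:, None] * weeks[None, :] + eta)

    pid = np.repeat(skeleton["pid"].to_numpy(), T)
    table = pd.DataFrame({
        "pid": pid,
        "week": np.tile(weeks, n),
        "age": age_t.ravel(),
        "arm": np.repeat(arm, T),
        "y": y.ravel(),
        "observed": np.ones(n * T, dtype=int),
    })
    return table


def simulate_trial(config: GenConfig, seed, collapse: bool = True) -> pd.DataFrame:
    """Covariates + outcomes in one call; optionally collapse the run-in."""
    rng = _as_rng(seed)
    skeleton = simulate_covariates(config, rng)
    table = simulate_outcomes(config, skeleton, rng)
    return collapse_runin(table) if collapse else table


def collapse_runin(table: pd.DataFrame) -> pd.DataFrame:
    """Replace weeks -1 and 0 by a single week-0 record holding their mean.

    The week-0 value after collapsing is the run-in average Y_i0; it is always
    flagged observed. All other rows are unchanged.
    """
    weeks = set(table["week"].unique())
    if -1 not in weeks or 0 not in weeks:
        raise ValueError("table must contain run-in weeks -1 and 0 for every pid")
    wide = table.pivot(index="pid", columns="week", values="y")
    if wide[[-1, 0]].isna().any().any():
        raise ValueError("run-in weeks absent for some pid")
    runin_mean = wide[[-1, 0]].mean(axis=1)

    out = table[table["week"] >= 0].copy()
    at0 = out["week"] == 0
    out.loc[at0, "y"] = out.loc[at0, "pid"].map(runin_mean).to_numpy()
    out.loc[at0, "observed"] = 1
    return out.reset_index(drop=True)


def write_table(table: pd.DataFrame, path) -> None:
    """Write a trial table as CSV; masked y cells are written empty."""
    out = table.copy()
    out.loc[out["observed"] == 0, "y"] = np.nan
    out.to_csv(path, index=False, columns=TABLE_COLUMNS)


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table CSV missing columns {missing}")
    return table[TABLE_COLUMNS]
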