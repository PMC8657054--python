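"""A-priori power for the omnibus full-vs-null test.

The question: with n persons whose traits are bivariate standard normal with
correlation r, what is the chance that the full second-order polynomial model
beats the intercept-only model at level alpha when the population surface
explains a fraction R^2 of the outcome variance?

Monte-Carlo answer: draw traits, build the five design terms, scale a
coefficient pattern so the population R^2 hits the target exactly (using the
closed-form covariance of the polynomial terms under bivariate normality), add
unit Gaussian noise, and apply the same likelihood-ratio gate the pipeline
uses.  Analytic oracle: both the chi-square LR statistic and the omnibus F are
monotone functions of the residual-sum-of-squares ratio, so exact power comes
from the noncentral-F distribution with noncentrality n R^2 / (1 - R^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PowerConfig",
    "PowerResult",
    "design_covariance",
    "scale_pattern",
    "simulate_power",
    "analytic_power",
]

DF1 = 5  # slopes of the full polynomial


@dataclass
class PowerConfig:
    n: int
    R2_target: float
    r_EN: float = -0.31
    alpha: float = 0.05
    reps: int = 10_000
    seed: int | None = None
    # relative sizes of (b1, b2, b3, b4, b5) before rescaling; the omnibus
    # noncentrality depends only on the total R^2, not on the pattern
    coefficient_pattern: tuple[float, ...] = (-1.0, 1.0, 0.0, 0.0, 0.0)
    statistic: str = "lr"  # "lr" (pipeline gate) or "f"

    def __post_init__(self) -> None:
        if not 0.0 < self.R2_target < 1.0:
            raise ValueError("R2_target must lie in (0, 1)")
        if abs(self.r_EN) >= 1.0:
            raise ValueError("|r_EN| must be below 1")
        if self.reps < 100:
            raise ValueError("need at least 100 replicates")
        if self.statistic not in ("lr", "f"):
            raise ValueError("statistic must be 'lr' or 'f'")


@dataclass
class PowerResult:
    power: float
    mc_se: float
    analytic: float
    reps: int
    config: PowerConfig = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "power": self.power,
            "mc_se": self.mc_se,
            "analytic": self.analytic,
            "reps": self.reps,
        }


def design_covariance(rho: float) -> np.ndarray:
    """Covariance of (E, N, E^2, EN, N^2) under standard bivariate normality.

    Third central moments of a centered Gaussian vanish, so the linear and
    quadratic blocks are uncorrelated; the quadratic block follows from
    Isserlis' theorem: var(E^2) = 2, cov(E^2, EN) = 2 rho,
    cov(E^2, N^2) = 2 rho^2, var(EN) = 1 + rho^2.
    """
    S = np.zeros((5, 5))
    S[:2, :2] = [[1.0, rho], [rho, 1.0]]
    S[2:, 2:] = [
        [2.0, 2.0 * rho, 2.0 * rho**2],
        [2.0 * rho, 1.0 + rho**2, 2.0 * rho],
        [2.0 * rho**2, 2.0 * rho, 2.0],
    ]
    return S


def scale_pattern(pattern: np.ndarray, rho: float, R2: float) -> np.ndarray:
    """Scale a coefficient pattern so the population R^2 equals the target
    (unit residual variance)."""
    pattern = np.asarray(pattern, dtype=float)
    v = float(pattern @ design_covariance(rho) @ pattern)
    if v <= 0:
        raise ValueError("coefficient pattern carries no signal variance")
    return pattern * np.sqrt(R2 / (1.0 - R2) / v)


def analytic_power(
    n: int, R2: float, df1: int = DF1, alpha: float = 0.05, statistic: str = "f"
) -> float:
    """Exact power of the omnibus test from the noncentral-F distribution.

    Noncentrality lambda = n R^2 / (1 - R^2), numerator df ``df1``, denominator
    df n - df1 - 1.  For the chi-square LR gate the critical region is mapped
    through the monotone identity LR = n log(1 + df1 F / df2), so the same
    distribution gives its exact power.
    """
    df2 = n - df1 - 1
    if df2 <= 0:
        raise ValueError(f"invalid degrees of freedom: n={n}, df1={df1}")
    lam = n * R2 / (1.0 - R2)
    if statistic == "f":
        crit = stats.f.isf(alpha, df1, df2)
    elif statistic == "lr":
        chi_crit = stats.chi2.isf(alpha, df1)
        crit = (df2 / df1) * (np.exp(chi_crit / n) - 1.0)
    else:
        raise ValueError("statistic must be 'lr' or 'f'")
    if R2 == 0:
        return float(alpha) if statistic == "f" else float(stats.f.sf(crit, df1, df2))
    return float(stats.ncf.sf(crit, df1, df2, lam))


def simulate_power(config: PowerConfig, chunk: int = 250) -> PowerResult:
    """Monte-Carlo rejection rate of the omnibus full-vs-null test.

    Replicates are processed in vectorized chunks: batched normal-equation
    solves give each replicate's full-model residual sum of squares.
    """
    rng = np.random.default_rng(config.seed)
    n, rho = config.n, config.r_EN
    beta = scale_pattern(np.asarray(config.coefficient_pattern), rho, config.R2_target)
    df2 = n - DF1 - 1
    if config.statistic == "lr":
        crit = stats.chi2.isf(config.alpha, DF1)
    else:
        crit = stats.f.isf(config.alpha, DF1, df2)

    rejections = 0
    done = 0
    while done < config.reps:
        m = min(chunk, config.reps - done)
        z1 = rng.standard_normal((m, n))
        z2 = rng.standard_normal((m, n))
        E = z1
        N = rho * z1 + np.sqrt(1.0 - rho**2) * z2
        D = np.stack([E, N, E * E, E * N, N * N], axis=2)
        y = D @ beta + rng.standard_normal((m, n))
        X = np.concatenate([np.ones((m, n, 1)), D], axis=2)
        XtX = np.einsum("mni,mnj->mij", X, X)
        Xty = np.einsum("mni,mn->mi", X, y)
        bhat = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        yty = np.einsum("mn,mn->m", y, y)
        rss1 = yty - np.einsum("mi,mi->m", bhat, Xty)
        ybar = y.mean(axis=1)
        rss0 = yty - n * ybar**2
        if config.statistic == "lr":
            stat = n * np.log(rss0 / rss1)
        else:
            stat = ((rss0 - rss1) / DF1) / (rss1 / df2)
        rejections += int(np.sum(stat > crit))
        done += m

    power = rejections / config.reps
    mc_se = float(np.sqrt(max(power * (1 - power), 1e-12) / config.reps))
    analytic = analytic_power(n, config.R2_target, DF1, config.alpha, config.statistic)
    return PowerResult(
        power=float(power), mc_se=mc_se, analytic=analytic, reps=config.reps, config=config
    )
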