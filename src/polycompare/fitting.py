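"""Constrained Gaussian maximum-likelihood estimation of catalogue models.

Each candidate is estimated by maximizing the conditional Gaussian likelihood
of the outcome given the design terms, subject to the spec's fixed zeros,
linear equalities and linear inequalities.  The profile over the residual
variance reduces the problem to inequality-constrained least squares on the
subspace defined by the equality constraints, solved exactly by active-set
enumeration of the KKT systems; when the unconstrained optimum already
satisfies every inequality it is returned directly, so unconstrained fits
match ordinary least squares to numerical precision.

Missing-data contract (the FIML arrangement the analysis assumes): traits and
the baseline outcome are completely observed; persons missing only the
follow-up outcome contribute no conditional-likelihood term but are retained in
``n_obs``, the sample size used downstream in the small-sample AICc
correction.  With zero missingness the fit coincides with complete-case OLS
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import null_space

from .catalog import COEF_NAMES, ModelSpec
from .preprocess import PreparedData

__all__ = ["FitResult", "fit", "fit_catalog", "lr_gate", "adjusted_r2", "GateResult"]

DESIGN_COLUMNS = ("E", "N", "E2", "EN", "N2")

_ACTIVE_TOL = 1e-7


@dataclass
class FitResult:
    spec_name: str
    beta: dict[str, float]  # b0..b5 and, when longitudinal, c_cov
    sigma2: float
    ll: float
    K: int
    n_obs: int
    n_complete: int
    converged: bool
    active_constraints: list[str] = field(default_factory=list)
    r2: float = np.nan
    adj_r2: float = np.nan
    message: str = ""

    @property
    def b(self) -> np.ndarray:
        return np.array([self.beta[c] for c in COEF_NAMES])

    def to_dict(self) -> dict:
        out = {
            "spec": self.spec_name,
            "beta": self.beta,
            "sigma2": self.sigma2,
            "LL": self.ll,
            "K": self.K,
            "n_obs": self.n_obs,
            "n_complete": self.n_complete,
            "converged": self.converged,
            "active_constraints": self.active_constraints,
            "R2": self.r2,
            "adj_R2": self.adj_r2,
        }
        return out


@dataclass
class GateResult:
    statistic: float
    df: int
    p: float
    proceed: bool


class SufficientStats:
    """Cross-products of the complete-case design; makes per-spec fits O(p^3)."""

    def __init__(self, prepared: PreparedData, outcome: str, covariate: str | None):
        df = prepared.frame
        mask = df[outcome].notna().to_numpy()
        cols = [np.ones(int(mask.sum()))]
        cols += [df.loc[mask, c].to_numpy(dtype=float) for c in DESIGN_COLUMNS]
        if covariate is not None:
            cols.append(df.loc[mask, covariate].to_numpy(dtype=float))
        X = np.column_stack(cols)
        y = df.loc[mask, outcome].to_numpy(dtype=float)
        self.covariate = covariate
        self.n_obs = len(df)
        self.n_complete = int(mask.sum())
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ybar = float(y.mean())
        self.p = X.shape[1]
        self.X = X
        self.y = y


def adjusted_r2(r2: float, n_complete: int, p_slopes: int) -> float:
    """Adjusted R^2 with p = free slope count (intercept and sigma^2 excluded).

    Undefined (NaN) when n_complete <= p + 1.
    """
    if n_complete <= p_slopes + 1:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n_complete - 1) / (n_complete - p_slopes - 1)


def _constraint_system(spec: ModelSpec, p: int):
    """Equality matrix E (E beta = e) and inequality matrix G (G beta <= h) over p columns."""
    E_rows, e_vals = [], []
    for coef in sorted(spec.zero_set):
        row = np.zeros(p)
        row[COEF_NAMES.index(coef)] = 1.0
        E_rows.append(row)
        e_vals.append(0.0)
    for eq in spec.equalities:
        row = np.zeros(p)
        row[:6] = eq.weights
        E_rows.append(row)
        e_vals.append(eq.const)
    G_rows, h_vals, labels = [], [], []
    for iq in spec.inequalities:
        row = np.zeros(p)
        row[:6] = iq.weights
        G_rows.append(row)
        h_vals.append(iq.const)
        labels.append(iq.label or "ineq")
    E = np.array(E_rows) if E_rows else np.zeros((0, p))
    G = np.array(G_rows) if G_rows else np.zeros((0, p))
    return E, np.array(e_vals), G, np.array(h_vals), labels


def _qp_active_set(
    A: np.ndarray, b: np.ndarray, G: np.ndarray, h: np.ndarray, tol: float = 1e-9
) -> tuple[np.ndarray, bool, str]:
    """Exact minimizer of 0.5 t'At - b't subject to G t <= h.

    The catalogue never imposes more than a handful of inequalities, so the
    convex QP is solved by enumerating candidate active sets: for each subset
    of constraints held at equality the KKT system is solved directly and the
    point is accepted when it is primal feasible with nonnegative multipliers.
    Deterministic, no line searches to stall.
    """
    from itertools import combinations

    m, k = G.shape
    best: tuple[float, np.ndarray] | None = None
    scale = 1.0 + np.abs(h)
    for size in range(m + 1):
        for subset in combinations(range(m), size):
            Gs = G[list(subset)]
            hs = h[list(subset)]
            if size and np.linalg.matrix_rank(Gs) < size:
                continue
            kkt = np.block(
                [[A, Gs.T], [Gs, np.zeros((size, size))]]
            ) if size else A
            rhs = np.concatenate([b, hs]) if size else b
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            theta, lam = sol[:k], sol[k:]
            if size and np.any(lam < -tol):
                continue
            if np.any(G @ theta > h + tol * scale):
                continue
            obj = 0.5 * theta @ A @ theta - b @ theta
            if best is None or obj < best[0] - 1e-12:
                best = (obj, theta)
    if best is None:  # pragma: no cover - convex feasible QPs always yield a KKT point
        return np.zeros(k), False, "no KKT point found"
    return best[1], True, "active-set QP solution"


def _fit_from_stats(spec: ModelSpec, ss: SufficientStats) -> FitResult:
    p = ss.p
    E, e_vals, G, h, labels = _constraint_system(spec, p)

    # parameterize the equality-feasible affine set as beta = beta_part + Z theta
    if E.shape[0]:
        Z = null_space(E)
        beta_part = np.linalg.lstsq(E, e_vals, rcond=None)[0]
    else:
        Z = np.eye(p)
        beta_part = np.zeros(p)

    A = Z.T @ ss.XtX @ Z
    b_vec = Z.T @ (ss.Xty - ss.XtX @ beta_part)
    theta0 = np.linalg.solve(A, b_vec)

    GZ = G @ Z if G.shape[0] else np.zeros((0, Z.shape[1]))
    h_adj = h - G @ beta_part if G.shape[0] else h

    converged = True
    message = "unconstrained optimum feasible"
    if GZ.shape[0] and np.any(GZ @ theta0 > h_adj + 1e-10):
        theta0, converged, message = _qp_active_set(A, b_vec, GZ, h_adj)

    beta = beta_part + Z @ theta0
    rss = ss.yty - 2.0 * beta @ ss.Xty + beta @ ss.XtX @ beta
    rss = max(rss, 1e-300)
    n_c = ss.n_complete
    sigma2 = rss / n_c
    ll = -0.5 * n_c * (np.log(2.0 * np.pi * sigma2) + 1.0)

    tss = ss.yty - n_c * ss.ybar**2
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    adj = adjusted_r2(r2, n_c, spec.K - 2)

    active = []
    if G.shape[0]:
        slack = h - G @ beta
        scale = 1.0 + np.abs(h)
        active = [labels[i] for i in range(len(labels)) if slack[i] < _ACTIVE_TOL * scale[i]]

    beta_dict = {c: float(beta[i]) for i, c in enumerate(COEF_NAMES)}
    if ss.covariate is not None:
        beta_dict["c_cov"] = float(beta[6])
    return FitResult(
        spec_name=spec.name,
        beta=beta_dict,
        sigma2=float(sigma2),
        ll=float(ll),
        K=spec.K,
        n_obs=ss.n_obs,
        n_complete=n_c,
        converged=converged,
        active_constraints=active,
        r2=float(r2),
        adj_r2=float(adj),
        message=message,
    )


def fit(
    spec: ModelSpec,
    prepared: PreparedData,
    outcome: str = "L1",
    covariate: str | None = None,
) -> FitResult:
    """Estimate one catalogue model.

    ``outcome`` is L1 (cross-sectional) or L2 (longitudinal); the longitudinal
    analysis must pass ``covariate="L1"`` so the baseline outcome enters with a
    freely estimated slope, matching ``spec.longitudinal``.
    """
    if outcome == "L2" and covariate is None:
        raise ValueError("longitudinal outcome requires the baseline covariate L1")
    if spec.longitudinal != (covariate is not None):
        raise ValueError(
            f"spec '{spec.name}' longitudinal={spec.longitudinal} but covariate={covariate!r}"
        )
    ss = SufficientStats(prepared, outcome, covariate)
    if np.linalg.matrix_rank(ss.XtX) < ss.p:
        raise ValueError(f"singular design while fitting '{spec.name}'")
    return _fit_from_stats(spec, ss)


def fit_catalog(
    specs: list[ModelSpec],
    prepared: PreparedData,
    outcome: str = "L1",
    covariate: str | None = None,
) -> list[FitResult]:
    """Fit every spec on shared sufficient statistics (one pass over the data)."""
    ss = SufficientStats(prepared, outcome, covariate)
    if np.linalg.matrix_rank(ss.XtX) < ss.p:
        raise ValueError("singular design matrix")
    return [_fit_from_stats(s, ss) for s in specs]


def lr_gate(full_fit: FitResult, null_fit: FitResult, alpha: float = 0.05) -> GateResult:
    """Chi-square likelihood-ratio gate: proceed only if the full model beats the null.

    The analysis continues to catalogue comparison only when the full
    polynomial explains significantly more outcome variance than the
    intercept-only model.
    """
    statistic = 2.0 * (full_fit.ll - null_fit.ll)
    if statistic < -1e-6:
        raise RuntimeError(
            f"negative LR statistic {statistic:.3g}: null LL exceeds full LL"
        )
    statistic = max(statistic, 0.0)
    df = full_fit.K - null_fit.K
    p = float(stats.chi2.sf(statistic, df))
    return GateResult(statistic=float(statistic), df=df, p=p, proceed=p < alpha)
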