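"""Response-surface interpretation of a fitted full polynomial.

Classic response-surface analysis of a second-order polynomial in two
predictors re-expresses the coefficients along the two diagonals of the
predictor plane: a1 = b1 + b2 and a2 = b3 + b4 + b5 give the slope and
curvature along the line of congruence E = N, a3 = b1 - b2 and a4 = b3 - b4 + b5
along the line of incongruence E = -N.  Grid predictions are restricted to the
region where trait combinations were actually observed (the convex hull of the
(E, N) points); outside it the surface carries no interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .catalog import COEF_NAMES, ModelSpec
from .preprocess import PreparedData, RangeBox

__all__ = [
    "SurfaceCoefficients",
    "SurfaceGrid",
    "rsa_coefficients",
    "predict_grid",
    "classify_shape",
    "stationary_point",
]

_CURV_TOL = 1e-8


def _beta_array(beta) -> np.ndarray:
    if hasattr(beta, "beta"):  # FitResult
        beta = beta.beta
    if isinstance(beta, dict):
        return np.array([float(beta.get(c, 0.0)) for c in COEF_NAMES])
    return np.asarray(beta, dtype=float)[:6]


@dataclass(frozen=True)
class SurfaceCoefficients:
    a1: float  # slope along E = N
    a2: float  # curvature along E = N
    a3: float  # slope along E = -N
    a4: float  # curvature along E = -N


def rsa_coefficients(beta) -> SurfaceCoefficients:
    b = _beta_array(beta)
    return SurfaceCoefficients(
        a1=float(b[1] + b[2]),
        a2=float(b[3] + b[4] + b[5]),
        a3=float(b[1] - b[2]),
        a4=float(b[3] - b[4] + b[5]),
    )


def evaluate_surface(beta, e: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Exact polynomial evaluation b0 + b1 e + b2 n + b3 e^2 + b4 e n + b5 n^2."""
    b = _beta_array(beta)
    return b[0] + b[1] * e + b[2] * n + b[3] * e * e + b[4] * e * n + b[5] * n * n


@dataclass
class SurfaceGrid:
    frame: pd.DataFrame  # columns e, n, prediction, in_region
    resolution: int

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def predict_grid(
    beta,
    range_box: RangeBox,
    resolution: int = 50,
    points: np.ndarray | None = None,
) -> SurfaceGrid:
    """Predictions on a regular grid over the range box.

    ``points`` (k x 2 array of observed centered (E, N) values) defines the
    data-region mask as the convex hull of the observations; without points
    every grid node inside the box counts as in-region.
    """
    if resolution < 2:
        raise ValueError("grid resolution must be at least 2")
    e = np.linspace(range_box.e_lo, range_box.e_hi, resolution)
    n = np.linspace(range_box.n_lo, range_box.n_hi, resolution)
    ee, nn = np.meshgrid(e, n, indexing="ij")
    pred = evaluate_surface(beta, ee, nn)
    if points is not None and len(points) >= 3:
        tri = Delaunay(np.asarray(points, dtype=float))
        mask = tri.find_simplex(np.column_stack([ee.ravel(), nn.ravel()])) >= 0
    else:
        mask = np.ones(ee.size, dtype=bool)
    frame = pd.DataFrame(
        {
            "e": ee.ravel(),
            "n": nn.ravel(),
            "prediction": pred.ravel(),
            "in_region": mask,
        }
    )
    return SurfaceGrid(frame=frame, resolution=resolution)


def stationary_point(beta) -> tuple[float, float] | None:
    """Vertex of the quadratic surface, or None when curvature is (near) singular."""
    b = _beta_array(beta)
    H = np.array([[2 * b[3], b[4]], [b[4], 2 * b[5]]])
    if abs(np.linalg.det(H)) < _CURV_TOL:
        return None
    e0, n0 = np.linalg.solve(H, [-b[1], -b[2]])
    return float(e0), float(n0)


def _trait_label(slope_corners: np.ndarray, curv: float, tol: float) -> str:
    if np.all(slope_corners <= tol):
        direction = -1.0  # non-increasing
    elif np.all(slope_corners >= -tol):
        direction = 1.0  # non-decreasing
    else:
        return "non-monotone"
    if abs(curv) < tol:
        return "linear"
    # curvature opposing the slope direction flattens the effect at the
    # steep end -> saturating; reinforcing it -> exponential
    return "saturating" if np.sign(curv) != direction else "exponential"


def classify_shape(
    beta,
    range_box: RangeBox,
    prepared: PreparedData | None = None,
    tol: float = 1e-10,
) -> dict:
    """Label each trait's effect over the range box and the interaction sign.

    A trait is monotone when its partial slope keeps one sign across the box
    corners (the slope is linear in (e, n), so corner signs decide the box).
    For a non-monotone trait the observed persons are split by the sign of the
    slope at their own (E, N) location, enabling statements like "the effect is
    positive for x% of the sample".
    """
    b = _beta_array(beta)
    corners = np.array(range_box.corners)
    e_c, n_c = corners[:, 0], corners[:, 1]
    slope_e = b[1] + 2 * b[3] * e_c + b[4] * n_c
    slope_n = b[2] + b[4] * e_c + 2 * b[5] * n_c
    out = {
        "E": _trait_label(slope_e, 2 * b[3], tol),
        "N": _trait_label(slope_n, 2 * b[5], tol),
        "interaction": "none" if abs(b[4]) < tol else ("positive" if b[4] > 0 else "negative"),
    }
    if prepared is not None:
        ev = prepared.frame["E"].to_numpy()
        nv = prepared.frame["N"].to_numpy()
        se = b[1] + 2 * b[3] * ev + b[4] * nv
        sn = b[2] + b[4] * ev + 2 * b[5] * nv
        out["E_positive_slope_fraction"] = float(np.mean(se > 0))
        out["N_positive_slope_fraction"] = float(np.mean(sn > 0))
    sp = stationary_point(b)
    if sp is not None:
        out["stationary_point"] = sp
    return out


def claimed_monotonicity(spec: ModelSpec) -> dict[str, str | None]:
    """Monotone directions a spec's constraints guarantee over the range box.

    Shape specs (and the composite interaction surfaces) are non-increasing in
    extraversion and/or non-decreasing in neuroticism wherever the trait
    enters the model.
    """
    e_dir = "nonincreasing" if (spec.e_shape or spec.interaction) else None
    n_dir = "nondecreasing" if (spec.n_shape or spec.interaction) else None
    return {"E": e_dir, "N": n_dir}
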