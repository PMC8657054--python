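"""The catalogue of competing hypothesis models.

Every candidate is a constrained version of the full second-order polynomial

    L = b0 + b1*E + b2*N + b3*E^2 + b4*E*N + b5*N^2

where E and N are the centered traits.  A hypothesis about the *shape* of a
trait's effect (linear / saturating / exponential, in the monotone sense) or
about a specific interaction pattern (mutual compensation, optimal
constellation) becomes a system of fixed-zero coefficients, linear equalities
and linear inequalities on (b0..b5).  Shape constraints are anchored at the
observed range of the centered traits so that the claimed monotone behaviour
holds over the whole region where data actually live:

* linear E effect:       b3 = 0,  b1 <= 0
* saturating E effect:   b3 >= 0, b1 + 2*b3*e_hi <= 0   (decreasing, flattens at high E)
* exponential E effect:  b3 <= 0, b1 + 2*b3*e_lo <= 0   (decreasing, steepens at high E)
* linear N effect:       b5 = 0,  b2 >= 0
* exponential N effect:  b5 >= 0, b2 + 2*b5*n_lo >= 0   (increasing, steepens at high N)
* saturating N effect:   b5 <= 0, b2 + 2*b5*n_hi >= 0   (increasing, flattens at high N)

All main-effect-shape models fix the interaction b4 = 0; single-trait models
additionally zero the other trait's coefficients.  The two interaction
hypotheses are one-parameter composite surfaces:

* mutual compensation:   b0 + c*(E - e_hi)*(N - n_lo), c <= 0 -- loneliness sits
  at baseline whenever E is maximal or N minimal, rising only in the E-/N+ corner
* optimal constellation: b0 + c*(E - e_lo)*(N - n_hi), c >= 0 -- loneliness drops
  below baseline only in the E+/N- corner

With the null and full models and the full 3x3 grid of shape combinations the
set contains exactly 19 candidates.  Directional inequality constraints count
their parameter as free in K; equalities and fixed zeros do not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import linprog

from .preprocess import RangeBox

__all__ = [
    "COEF_NAMES",
    "LinearRestriction",
    "ModelSpec",
    "build_catalog",
    "shape_predicate",
    "nesting",
    "catalog_nesting",
    "catalog_to_json",
    "FULL_MODEL",
    "NULL_MODEL",
]

COEF_NAMES = ("b0", "b1", "b2", "b3", "b4", "b5")

NULL_MODEL = "Null Model"
FULL_MODEL = "Full Model"

_SHAPES = ("linear", "saturating", "exponential")

_NUMTOL = 1e-8


@dataclass(frozen=True)
class LinearRestriction:
    """A linear restriction w . (b0..b5) (= | <=) const."""

    weights: tuple[float, ...]
    const: float = 0.0
    label: str = ""

    def value(self, beta: np.ndarray) -> float:
        return float(np.dot(self.weights, beta))


def _restriction(coefs: dict[str, float], const: float = 0.0, label: str = "") -> LinearRestriction:
    w = [0.0] * 6
    for name, val in coefs.items():
        w[COEF_NAMES.index(name)] = float(val)
    return LinearRestriction(tuple(w), const, label)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model as a constraint system on the full polynomial.

    ``zero_set`` lists coefficients fixed at zero; ``equalities`` and
    ``inequalities`` (each ``w . b (= | <=) const``) encode the remaining
    structure.  ``e_shape``/``n_shape`` record the claimed main-effect shape
    (None when the trait is absent or the model is not a shape model);
    ``interaction`` is the claimed sign of b4 for the composite models.
    """

    name: str
    zero_set: frozenset[str]
    equalities: tuple[LinearRestriction, ...] = ()
    inequalities: tuple[LinearRestriction, ...] = ()
    longitudinal: bool = False
    range_dependent: bool = False
    e_shape: str | None = None
    n_shape: str | None = None
    interaction: str | None = None

    @property
    def K(self) -> int:
        """Free parameters: unconstrained b's, + T1-outcome slope, + sigma^2."""
        free_b = 6 - len(self.zero_set) - len(self.equalities)
        return free_b + (1 if self.longitudinal else 0) + 1

    def feasible(self, beta: np.ndarray, tol: float = _NUMTOL) -> bool:
        ok, _ = shape_predicate(self, beta, tol=tol)
        return ok


def _e_constraints(shape: str, box: RangeBox) -> tuple[set[str], list[LinearRestriction]]:
    zero: set[str] = set()
    ineq: list[LinearRestriction] = []
    if shape == "linear":
        zero.add("b3")
        ineq.append(_restriction({"b1": 1.0}, label="b1 <= 0"))
    elif shape == "saturating":
        ineq.append(_restriction({"b3": -1.0}, label="b3 >= 0"))
        ineq.append(_restriction({"b1": 1.0, "b3": 2.0 * box.e_hi}, label="slope_E(e_hi) <= 0"))
    elif shape == "exponential":
        ineq.append(_restriction({"b3": 1.0}, label="b3 <= 0"))
        ineq.append(_restriction({"b1": 1.0, "b3": 2.0 * box.e_lo}, label="slope_E(e_lo) <= 0"))
    else:  # pragma: no cover
        raise ValueError(shape)
    return zero, ineq


def _n_constraints(shape: str, box: RangeBox) -> tuple[set[str], list[LinearRestriction]]:
    zero: set[str] = set()
    ineq: list[LinearRestriction] = []
    if shape == "linear":
        zero.add("b5")
        ineq.append(_restriction({"b2": -1.0}, label="b2 >= 0"))
    elif shape == "exponential":
        ineq.append(_restriction({"b5": -1.0}, label="b5 >= 0"))
        ineq.append(_restriction({"b2": -1.0, "b5": -2.0 * box.n_lo}, label="slope_N(n_lo) >= 0"))
    elif shape == "saturating":
        ineq.append(_restriction({"b5": 1.0}, label="b5 <= 0"))
        ineq.append(_restriction({"b2": -1.0, "b5": -2.0 * box.n_hi}, label="slope_N(n_hi) >= 0"))
    else:  # pragma: no cover
        raise ValueError(shape)
    return zero, ineq


_SHAPE_WORD = {"linear": "Linear", "saturating": "Saturating", "exponential": "Exponential"}


def build_catalog(range_box: RangeBox, longitudinal: bool = False) -> list[ModelSpec]:
    """Build the complete 19-model candidate set for a given data range.

    When ``longitudinal`` each spec additionally frees the slope of the
    baseline outcome (K grows by one); the constraint systems are unchanged.
    """
    box = range_box  # validated by RangeBox itself
    specs: list[ModelSpec] = []

    def add(name: str, zero: set[str], eq=(), ineq=(), **kw) -> None:
        specs.append(
            ModelSpec(
                name=name,
                zero_set=frozenset(zero),
                equalities=tuple(eq),
                inequalities=tuple(ineq),
                longitudinal=longitudinal,
                **kw,
            )
        )

    add(NULL_MODEL, {"b1", "b2", "b3", "b4", "b5"})

    # single-trait shape models
    for shape in _SHAPES:
        zero, ineq = _e_constraints(shape, box)
        word = _SHAPE_WORD[shape]
        name = (
            "Linear Main Effect of Extraversion Model"
            if shape == "linear"
            else f"{word} Effect of Extraversion Model"
        )
        add(name, zero | {"b2", "b4", "b5"}, ineq=ineq, e_shape=shape)
    for shape in _SHAPES:
        zero, ineq = _n_constraints(shape, box)
        word = _SHAPE_WORD[shape]
        name = (
            "Linear Main Effect of Neuroticism Model"
            if shape == "linear"
            else f"{word} Effect of Neuroticism Model"
        )
        add(name, zero | {"b1", "b3", "b4"}, ineq=ineq, n_shape=shape)

    # 3x3 grid of two-trait shape combinations
    for es in _SHAPES:
        for ns in _SHAPES:
            ze, ie = _e_constraints(es, box)
            zn, inn = _n_constraints(ns, box)
            if es == "linear" and ns == "linear":
                name = "Linear Main Effects Model"
            else:
                name = (
                    f"{_SHAPE_WORD[es]} Extraversion and "
                    f"{_SHAPE_WORD[ns]} Neuroticism Effects Model"
                )
            add(name, ze | zn | {"b4"}, ineq=ie + inn, e_shape=es, n_shape=ns)

    # composite one-parameter interaction surfaces: b0 + c*(E - e_a)*(N - n_a)
    add(
        "Mutual Compensation Model",
        {"b3", "b5"},
        eq=(
            _restriction({"b1": 1.0, "b4": box.n_lo}, label="b1 = -b4*n_lo"),
            _restriction({"b2": 1.0, "b4": box.e_hi}, label="b2 = -b4*e_hi"),
        ),
        ineq=(_restriction({"b4": 1.0}, label="b4 <= 0"),),
        range_dependent=True,
        interaction="negative",
    )
    add(
        "Optimal Constellation Model",
        {"b3", "b5"},
        eq=(
            _restriction({"b1": 1.0, "b4": box.n_hi}, label="b1 = -b4*n_hi"),
            _restriction({"b2": 1.0, "b4": box.e_lo}, label="b2 = -b4*e_lo"),
        ),
        ineq=(_restriction({"b4": -1.0}, label="b4 >= 0"),),
        range_dependent=True,
        interaction="positive",
    )

    add(FULL_MODEL, set())

    assert len(specs) == 19
    assert len({s.name for s in specs}) == 19
    return specs


def _beta_array(beta) -> np.ndarray:
    if isinstance(beta, dict):
        return np.array([float(beta.get(c, 0.0)) for c in COEF_NAMES])
    return np.asarray(beta, dtype=float)[:6]


def shape_predicate(
    spec: ModelSpec, beta, tol: float = _NUMTOL
) -> tuple[bool, dict[str, float]]:
    """Check a coefficient vector against a spec's constraint system.

    Returns (satisfied, margins).  For equalities the margin is
    ``-(|w.b - c|)``; for inequalities it is the slack ``c - w.b``.  A margin
    below ``-tol`` means the constraint is violated.  For monotone-shape specs
    this is equivalent to sign conditions on the partial derivatives of the
    surface at the relevant corner of the range box.
    """
    b = _beta_array(beta)
    margins: dict[str, float] = {}
    ok = True
    for coef in sorted(spec.zero_set):
        m = -abs(b[COEF_NAMES.index(coef)])
        margins[f"{coef} = 0"] = m
        ok &= m >= -tol
    for eq in spec.equalities:
        m = -abs(eq.value(b) - eq.const)
        margins[eq.label or "eq"] = m
        ok &= m >= -tol
    for iq in spec.inequalities:
        m = iq.const - iq.value(b)
        margins[iq.label or "ineq"] = m
        ok &= m >= -tol
    return bool(ok), margins


def _lp_constraint_matrices(spec: ModelSpec):
    """Equality/inequality matrices over (b0..b5) describing a spec's feasible set."""
    A_eq, b_eq = [], []
    for coef in spec.zero_set:
        row = [0.0] * 6
        row[COEF_NAMES.index(coef)] = 1.0
        A_eq.append(row)
        b_eq.append(0.0)
    for eq in spec.equalities:
        A_eq.append(list(eq.weights))
        b_eq.append(eq.const)
    A_ub = [list(iq.weights) for iq in spec.inequalities]
    b_ub = [iq.const for iq in spec.inequalities]
    return A_eq, b_eq, A_ub, b_ub


def _extreme_value(w, const, A_eq, b_eq, A_ub, b_ub, maximize: bool):
    c = [-x for x in w] if maximize else list(w)
    res = linprog(
        c,
        A_ub=A_ub or None,
        b_ub=b_ub or None,
        A_eq=A_eq or None,
        b_eq=b_eq or None,
        bounds=[(None, None)] * 6,
        method="highs",
    )
    if res.status == 3:  # unbounded
        return np.inf if maximize else -np.inf
    if not res.success:  # pragma: no cover - feasible sets always contain 0
        raise RuntimeError(f"LP failed: {res.message}")
    return -res.fun if maximize else res.fun


def is_nested(a: ModelSpec, b: ModelSpec, tol: float = 1e-7) -> bool:
    """True when A's feasible coefficient set is contained in B's.

    Decided by linear programming: every restriction of B must be implied over
    the feasible set of A (each of B's equalities attains a single value on A's
    set equal to its constant; each of B's inequalities has a bounded maximum
    not exceeding its constant).
    """
    A_eq, b_eq, A_ub, b_ub = _lp_constraint_matrices(a)
    for coef in b.zero_set:
        w = [0.0] * 6
        w[COEF_NAMES.index(coef)] = 1.0
        hi = _extreme_value(w, 0.0, A_eq, b_eq, A_ub, b_ub, maximize=True)
        lo = _extreme_value(w, 0.0, A_eq, b_eq, A_ub, b_ub, maximize=False)
        if abs(hi) > tol or abs(lo) > tol:
            return False
    for eq in b.equalities:
        hi = _extreme_value(eq.weights, eq.const, A_eq, b_eq, A_ub, b_ub, maximize=True)
        lo = _extreme_value(eq.weights, eq.const, A_eq, b_eq, A_ub, b_ub, maximize=False)
        if abs(hi - eq.const) > tol or abs(lo - eq.const) > tol:
            return False
    for iq in b.inequalities:
        hi = _extreme_value(iq.weights, iq.const, A_eq, b_eq, A_ub, b_ub, maximize=True)
        if hi > iq.const + tol:
            return False
    return True


def nesting(catalog: list[ModelSpec]) -> set[tuple[str, str]]:
    """Ordered pairs (A, B): A is a strict special case of B.  Transitively closed."""
    pairs: set[tuple[str, str]] = set()
    for a in catalog:
        for b in catalog:
            if a.name != b.name and is_nested(a, b):
                pairs.add((a.name, b.name))
    # transitive closure (the LP relation already is, but keep the invariant explicit)
    changed = True
    while changed:
        changed = False
        for x, y in list(pairs):
            for y2, z in list(pairs):
                if y2 == y and (x, z) not in pairs and x != z:
                    pairs.add((x, z))
                    changed = True
    return pairs


# The nesting relation depends only on the constraint structure, not on the
# numeric range-box anchors (verified by a test on two distinct boxes), so
# repeated pipeline runs reuse a structurally computed relation.
_CANONICAL_BOX = RangeBox(-2.1, 1.9, -2.4, 2.6)


@lru_cache(maxsize=4)
def catalog_nesting(longitudinal: bool = False) -> frozenset[tuple[str, str]]:
    return frozenset(nesting(build_catalog(_CANONICAL_BOX, longitudinal=longitudinal)))


def catalog_to_json(catalog: list[ModelSpec]) -> str:
    """Serialize the catalogue (names, zero sets, numeric constraints, K)."""
    payload = []
    for s in catalog:
        payload.append(
            {
                "name": s.name,
                "K": s.K,
                "zero_set": sorted(s.zero_set),
                "equalities": [
                    {"weights": list(e.weights), "const": e.const, "label": e.label}
                    for e in s.equalities
                ],
                "inequalities": [
                    {"weights": list(i.weights), "const": i.const, "label": i.label}
                    for i in s.inequalities
                ],
                "longitudinal": s.longitudinal,
                "range_dependent": s.range_dependent,
            }
        )
    return json.dumps(payload, indent=2)
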