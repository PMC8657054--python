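"""Structure of the 19-model candidate set and its nesting relation."""

import numpy as np
import pytest
from scipy.optimize import linprog

from polycompare import RangeBox, build_catalog, shape_predicate
from polycompare.catalog import (
    FULL_MODEL,
    NULL_MODEL,
    _lp_constraint_matrices,
    nesting,
)
from polycompare.surface import claimed_monotonicity, evaluate_surface

BOX = RangeBox(-2.0, 2.0, -2.5, 2.5)

EXPECTED_K = {
    NULL_MODEL: 2,
    "Linear Main Effect of Extraversion Model": 3,
    "Linear Main Effect of Neuroticism Model": 3,
    "Saturating Effect of Extraversion Model": 4,
    "Exponential Effect of Extraversion Model": 4,
    "Saturating Effect of Neuroticism Model": 4,
    "Exponential Effect of Neuroticism Model": 4,
    "Linear Main Effects Model": 4,
    "Linear Extraversion and Exponential Neuroticism Effects Model": 5,
    "Linear Extraversion and Saturating Neuroticism Effects Model": 5,
    "Saturating Extraversion and Linear Neuroticism Effects Model": 5,
    "Exponential Extraversion and Linear Neuroticism Effects Model": 5,
    "Saturating Extraversion and Exponential Neuroticism Effects Model": 6,
    "Saturating Extraversion and Saturating Neuroticism Effects Model": 6,
    "Exponential Extraversion and Exponential Neuroticism Effects Model": 6,
    "Exponential Extraversion and Saturating Neuroticism Effects Model": 6,
    "Mutual Compensation Model": 3,
    "Optimal Constellation Model": 3,
    FULL_MODEL: 7,
}

# constraint-satisfying coefficient vectors used for grid monotonicity checks
SATISFYING = {
    "linear_e": {"b1": -0.4},
    "saturating_e": {"b1": -0.5, "b3": 0.06},
    "exponential_e": {"b1": -0.3, "b3": -0.05},
    "linear_n": {"b2": 0.4},
    "exponential_n": {"b2": 0.4, "b5": 0.05},
    "saturating_n": {"b2": 0.5, "b5": -0.06},
}


@pytest.fixture(scope="module")
def catalog():
    return build_catalog(BOX)


def test_catalog_has_nineteen_uniquely_named_models(catalog):
    assert len(catalog) == 19
    assert len({s.name for s in catalog}) == 19


def test_free_parameter_counts(catalog):
    assert {s.name: s.K for s in catalog} == EXPECTED_K


def test_longitudinal_catalog_frees_baseline_slope():
    longi = build_catalog(BOX, longitudinal=True)
    assert {s.name: s.K for s in longi} == {k: v + 1 for k, v in EXPECTED_K.items()}


def test_degenerate_range_box_is_rejected():
    with pytest.raises(ValueError):
        RangeBox(1.0, 1.0, -2.0, 2.0)


class TestShapePredicate:
    def test_saturating_e_slope_condition_at_high_end(self, catalog):
        spec = next(s for s in catalog if s.name == "Saturating Effect of Extraversion Model")
        ok, _ = shape_predicate(spec, {"b1": -0.5, "b3": 0.1})  # slope at e_hi=2: -0.1
        assert ok
        bad, margins = shape_predicate(spec, {"b1": -0.5, "b3": 0.2})  # slope +0.3
        assert not bad
        assert margins["slope_E(e_hi) <= 0"] < 0

    def test_full_model_is_unconstrained(self, catalog):
        spec = next(s for s in catalog if s.name == FULL_MODEL)
        ok, _ = shape_predicate(spec, {"b1": 9.0, "b2": -9.0, "b3": 5, "b4": -5, "b5": 5})
        assert ok

    def test_composite_equalities_enforced(self, catalog):
        spec = next(s for s in catalog if s.name == "Mutual Compensation Model")
        c = -0.2
        beta = {"b1": -c * BOX.n_lo, "b2": -c * BOX.e_hi, "b4": c}
        assert shape_predicate(spec, beta)[0]
        beta["b1"] += 0.01
        assert not shape_predicate(spec, beta)[0]


class TestNesting:
    def test_expected_pairs(self, nesting_cs):
        assert ("Null Model", "Linear Main Effects Model") in nesting_cs
        assert ("Linear Main Effects Model", "Full Model") in nesting_cs
        assert (
            "Linear Main Effect of Extraversion Model",
            "Linear Main Effect of Neuroticism Model",
        ) not in nesting_cs

    def test_every_model_nested_in_full(self, catalog, nesting_cs):
        for s in catalog:
            if s.name != FULL_MODEL:
                assert (s.name, FULL_MODEL) in nesting_cs

    def test_null_nested_in_every_main_effects_model(self, catalog, nesting_cs):
        for s in catalog:
            if s.name != NULL_MODEL:
                assert (NULL_MODEL, s.name) in nesting_cs

    def test_relation_is_invariant_to_range_box_anchors(self):
        other = RangeBox(-1.2, 3.1, -0.9, 1.8)
        assert nesting(build_catalog(BOX)) == nesting(build_catalog(other))


def test_every_feasible_region_has_an_interior_point(catalog):
    """Optimization is well-posed: strict slack is attainable in every spec."""
    for spec in catalog:
        A_eq, b_eq, A_ub, b_ub = _lp_constraint_matrices(spec)
        if not A_ub:
            continue
        # maximize the minimal slack t: A_ub b + t <= b_ub, bounded box
        n_ub = len(A_ub)
        c = [0.0] * 6 + [-1.0]
        A = [row + [1.0] for row in A_ub]
        res = linprog(
            c,
            A_ub=A,
            b_ub=b_ub,
            A_eq=[row + [0.0] for row in A_eq] or None,
            b_eq=b_eq if A_eq else None,
            bounds=[(-10, 10)] * 6 + [(0, 10)],
            method="highs",
        )
        assert res.success and -res.fun > 1e-6, spec.name


def _coefficients_for(spec):
    beta = {}
    if spec.e_shape:
        beta.update(SATISFYING[f"{spec.e_shape}_e"])
    if spec.n_shape:
        beta.update(SATISFYING[f"{spec.n_shape}_n"])
    if spec.interaction == "negative":
        c = -0.2
        beta = {"b1": -c * BOX.n_lo, "b2": -c * BOX.e_hi, "b4": c}
    if spec.interaction == "positive":
        c = 0.2
        beta = {"b1": -c * BOX.n_hi, "b2": -c * BOX.e_lo, "b4": c}
    return beta


def test_shape_constraints_guarantee_grid_monotonicity(catalog):
    """On a 50x50 grid, predicate-passing coefficients yield surfaces
    non-increasing in E and/or non-decreasing in N, as each spec claims."""
    e = np.linspace(BOX.e_lo, BOX.e_hi, 50)
    n = np.linspace(BOX.n_lo, BOX.n_hi, 50)
    ee, nn = np.meshgrid(e, n, indexing="ij")
    for spec in catalog:
        claims = claimed_monotonicity(spec)
        if not (claims["E"] or claims["N"]):
            continue
        beta = _coefficients_for(spec)
        ok, margins = shape_predicate(spec, beta)
        assert ok, (spec.name, margins)
        surf = evaluate_surface(beta, ee, nn)
        if claims["E"]:
            assert np.all(np.diff(surf, axis=0) <= 1e-10), spec.name
        if claims["N"]:
            assert np.all(np.diff(surf, axis=1) >= -1e-10), spec.name
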