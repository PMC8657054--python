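"""Constrained ML estimation: oracles, closed forms, missing-data contract."""

import numpy as np
import pytest

from polycompare import SynthConfig, adjusted_r2, build_catalog, build_design, fit, fit_catalog, generate, lr_gate
from polycompare.catalog import FULL_MODEL, NULL_MODEL


def _spec(catalog, name):
    return next(s for s in catalog if s.name == name)


def test_unconstrained_full_fit_equals_ols_oracle(lme_prepared, catalog_cs):
    """The full-model fit must reproduce the normal-equation solution."""
    result = fit(_spec(catalog_cs, FULL_MODEL), lme_prepared)
    f = lme_prepared.frame
    X = np.column_stack([np.ones(len(f)), f[["E", "N", "E2", "EN", "N2"]].to_numpy()])
    y = f["L1"].to_numpy()
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert np.allclose(result.b, beta_ols, atol=1e-6)
    assert result.converged


def test_null_fit_closed_form(lme_prepared, catalog_cs):
    result = fit(_spec(catalog_cs, NULL_MODEL), lme_prepared)
    y = lme_prepared.frame["L1"].to_numpy()
    assert result.beta["b0"] == pytest.approx(y.mean(), abs=1e-9)
    assert result.sigma2 == pytest.approx(y.var(), rel=1e-9)  # ML divisor n
    assert result.K == 2


def test_constraint_inactivity_matches_unconstrained(lme_prepared, catalog_cs):
    """When the OLS optimum satisfies a spec's constraints, the constrained
    fit coincides with it."""
    spec = _spec(catalog_cs, "Linear Main Effects Model")
    result = fit(spec, lme_prepared)
    f = lme_prepared.frame
    X = np.column_stack([np.ones(len(f)), f[["E", "N"]].to_numpy()])
    y = f["L1"].to_numpy()
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    if beta_ols[1] <= 0 <= beta_ols[2]:  # generated under b1<0, b2>0: holds
        assert result.beta["b1"] == pytest.approx(beta_ols[1], abs=1e-6)
        assert result.beta["b2"] == pytest.approx(beta_ols[2], abs=1e-6)
        assert result.active_constraints == []


def test_active_constraint_is_reported_and_k_unchanged(catalog_cs, lme_prepared):
    """Data pushing a sign-constrained slope past zero leaves the estimate on
    the boundary with the constraint reported active; K is not reduced."""
    spec = _spec(catalog_cs, "Linear Main Effect of Neuroticism Model")  # b2 >= 0
    prep = build_design(
        generate(SynthConfig(n=300, model="Linear Main Effect of Neuroticism Model",
                             coefficients={"b2": -0.4}, seed=3, clip=False)),
        rescale=False,
    )
    # generating slope violates the spec's direction, so the fit lands on b2=0
    result = fit(spec, prep)
    assert result.beta["b2"] == pytest.approx(0.0, abs=1e-8)
    assert "b2 >= 0" in result.active_constraints
    assert result.K == spec.K


def test_nested_ll_monotonicity_across_catalog(lme_prepared, catalog_cs, nesting_cs):
    fits = {f.spec_name: f for f in fit_catalog(catalog_cs, lme_prepared)}
    for a, b in nesting_cs:
        assert fits[a].ll <= fits[b].ll + 1e-6, (a, b)


def test_fiml_reduction_no_missingness_equals_complete_case_ols():
    cohort = generate(SynthConfig(n=250, seed=31, t2_missing_rate=0.0, t1_t2_stability=0.6))
    prep = build_design(cohort)
    catalog = build_catalog(prep.range_box, longitudinal=True)
    result = fit(_spec(catalog, FULL_MODEL), prep, outcome="L2", covariate="L1")
    f = prep.frame
    X = np.column_stack(
        [np.ones(len(f)), f[["E", "N", "E2", "EN", "N2", "L1"]].to_numpy()]
    )
    beta_ols, *_ = np.linalg.lstsq(X, f["L2"].to_numpy(), rcond=None)
    est = np.array([result.beta[c] for c in ("b0", "b1", "b2", "b3", "b4", "b5")] + [result.beta["c_cov"]])
    assert np.allclose(est, beta_ols, atol=1e-6)
    assert result.n_obs == result.n_complete == 250


def test_missing_t2_rows_counted_in_n_obs_not_in_likelihood():
    cohort = generate(SynthConfig(n=300, seed=37, t2_missing_rate=0.4))
    prep = build_design(cohort)
    catalog = build_catalog(prep.range_box, longitudinal=True)
    result = fit(_spec(catalog, FULL_MODEL), prep, outcome="L2", covariate="L1")
    n_complete = int(prep.frame["L2"].notna().sum())
    assert result.n_obs == 300
    assert result.n_complete == n_complete < 300


def test_longitudinal_outcome_requires_covariate(lme_prepared, catalog_cs):
    with pytest.raises(ValueError):
        fit(_spec(catalog_cs, FULL_MODEL), lme_prepared, outcome="L2")


def test_saturating_e_parameter_recovery():
    """Constraint-satisfying generating coefficients are recovered within
    Monte-Carlo error at n=2000."""
    reps, errs1, errs3 = 12, [], []
    rng = np.random.default_rng(41)
    for _ in range(reps):
        cfg = SynthConfig(
            n=2000, model="Saturating Effect of Extraversion Model",
            coefficients={"b1": -0.4, "b3": 0.05}, clip=False,
            seed=int(rng.integers(2**31 - 1)),
        )
        prep = build_design(generate(cfg), rescale=False)
        catalog = build_catalog(prep.range_box)
        res = fit(_spec(catalog, "Saturating Effect of Extraversion Model"), prep)
        errs1.append(res.beta["b1"] + 0.4)
        errs3.append(res.beta["b3"] - 0.05)
    for errs in (errs1, errs3):
        se = np.std(errs, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(errs)) < 3 * se + 0.01


class TestLrGate:
    def test_identical_fits_give_zero_statistic(self, lme_prepared, catalog_cs):
        null = fit(_spec(catalog_cs, NULL_MODEL), lme_prepared)
        gate = lr_gate(null, null)
        assert gate.statistic == 0.0 and not gate.proceed

    def test_strong_effects_pass_the_gate(self, lme_prepared, catalog_cs):
        full = fit(_spec(catalog_cs, FULL_MODEL), lme_prepared)
        null = fit(_spec(catalog_cs, NULL_MODEL), lme_prepared)
        gate = lr_gate(full, null)
        assert gate.df == 5 and gate.proceed

    def test_inconsistent_lls_raise(self, lme_prepared, catalog_cs):
        full = fit(_spec(catalog_cs, FULL_MODEL), lme_prepared)
        null = fit(_spec(catalog_cs, NULL_MODEL), lme_prepared)
        with pytest.raises(RuntimeError):
            lr_gate(null, full)


@pytest.mark.parametrize(
    "r2,n,p,expected",
    [
        (1.0, 50, 5, 1.0),  # perfect fit
        (0.0, 50, 5, pytest.approx(-0.1136, abs=1e-3)),  # never above zero at R2=0
        (0.5, 100, 5, pytest.approx(0.4734, abs=1e-4)),
    ],
)
def test_adjusted_r2_formula(r2, n, p, expected):
    assert adjusted_r2(r2, n, p) == expected


def test_adjusted_r2_undefined_for_tiny_samples():
    assert np.isnan(adjusted_r2(0.5, 6, 5))
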