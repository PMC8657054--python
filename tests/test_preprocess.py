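"""Rescaling, centering, design construction and influence screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polycompare import (
    Cohort,
    SynthConfig,
    build_design,
    center,
    flag_influential,
    generate,
    poms_rescale,
)
from polycompare.fitting import SufficientStats


@pytest.mark.parametrize(
    "x,bounds,expected",
    [
        (1.0, (1, 5), 1.0),  # scale minimum maps to target minimum
        (5.0, (1, 5), 7.0),  # scale maximum maps to target maximum
        (3.0, (1, 5), 4.0),  # midpoint maps to midpoint
        (4.0, (1, 7), 4.0),  # identity on an already-1-7 scale
    ],
)
def test_poms_maps_instrument_range_onto_target(x, bounds, expected):
    assert poms_rescale(x, bounds) == pytest.approx(expected)


def test_poms_is_linear_and_order_preserving(rng):
    x = np.sort(rng.uniform(1, 5, 50))
    y = poms_rescale(x, (1, 5))
    assert np.all(np.diff(y) >= 0)
    # linearity: the map is affine, so second differences of an affine input vanish
    assert np.allclose(np.diff(y) / np.diff(x), 1.5)


def test_poms_rejects_out_of_bounds_naming_rows():
    with pytest.raises(ValueError, match=r"rows \[2\]"):
        poms_rescale(np.array([2.0, 3.0, 9.0]), (1, 5))


@pytest.mark.parametrize(
    "values,expected",
    [([2.0, 4.0], [-1.0, 1.0]), ([3.0, 3.0, 3.0], [0.0, 0.0, 0.0])],
)
def test_center_examples(values, expected):
    centered, mean = center(np.array(values))
    assert np.allclose(centered, expected)
    assert mean == pytest.approx(np.mean(values))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(-50, 50), min_size=2, max_size=40))
def test_center_output_mean_is_zero(values):
    centered, _ = center(np.array(values))
    assert abs(np.nanmean(centered)) < 1e-10


def test_center_refuses_all_missing():
    with pytest.raises(ValueError):
        center(np.array([np.nan, np.nan]))


def _toy_cohort(n=40, bounds=(1.0, 5.0), seed=0):
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    df = pd.DataFrame(
        {
            "E_raw": rng.uniform(lo, hi, n),
            "N_raw": rng.uniform(lo, hi, n),
            "L1": rng.uniform(lo, hi, n),
        }
    )
    b = {k: bounds for k in ("E_raw", "N_raw", "L1", "L2")}
    return Cohort.from_frame(df, bounds=b)


def test_build_design_rescales_then_centers_then_derives():
    cohort = _toy_cohort(bounds=(1.0, 5.0))
    prep = build_design(cohort)
    f = prep.frame
    assert abs(f["E"].mean()) < 1e-10 and abs(f["N"].mean()) < 1e-10
    assert np.allclose(f["E2"], f["E"] ** 2)
    assert np.allclose(f["EN"], f["E"] * f["N"])
    assert np.allclose(f["N2"], f["N"] ** 2)
    # outcome rescaled onto 1-7, never centered
    assert f["L1"].between(1, 7).all()
    box = prep.range_box
    assert box.e_hi > box.e_lo and box.n_hi > box.n_lo


def test_build_design_refuses_degenerate_cohort():
    with pytest.raises(ValueError, match="refusing"):
        build_design(_toy_cohort(n=5))


def test_rows_missing_baseline_outcome_are_dropped_with_count():
    df = pd.DataFrame(
        {"E_raw": [2, 3, 4, 2], "N_raw": [2, 2, 3, 3], "L1": [1, np.nan, 2, 3]}
    )
    cohort = Cohort.from_frame(df, bounds={k: (1, 5) for k in ("E_raw", "N_raw", "L1", "L2")})
    assert cohort.n == 3
    assert cohort.meta["n_dropped_missing_outcome"] == 1


def test_poms_rescaling_is_affine_invariant_for_fit_quality():
    """R^2 of the full polynomial is unchanged by POMS + centering of traits."""
    cohort = generate(SynthConfig(n=300, seed=11))
    prep_scaled = build_design(cohort, rescale=True)
    prep_raw = build_design(cohort, rescale=False)

    def full_r2(prep):
        ss = SufficientStats(prep, "L1", None)
        beta = np.linalg.solve(ss.XtX, ss.Xty)
        rss = ss.yty - beta @ ss.Xty
        tss = ss.yty - ss.n_complete * ss.ybar**2
        return 1 - rss / tss

    assert full_r2(prep_scaled) == pytest.approx(full_r2(prep_raw), abs=1e-10)


class TestInfluence:
    def test_hat_values_sum_to_design_columns(self, lme_prepared):
        report = flag_influential(lme_prepared)
        assert report.table["hat"].between(0, 1).all()
        assert report.table["hat"].sum() == pytest.approx(6.0, abs=1e-8)

    def test_planted_extreme_outlier_is_flagged(self):
        cohort = generate(SynthConfig(n=300, seed=5, clip=False))
        data = cohort.data.copy()
        # park one person at an extreme trait corner and shift their outcome by
        # ten residual standard deviations
        data.loc[0, ["E_raw", "N_raw"]] = [data["E_raw"].max() + 3, data["N_raw"].max() + 3]
        data.loc[0, "L1"] = data["L1"].mean() + 10 * 0.8
        cohort.data = data
        report = flag_influential(build_design(cohort, rescale=False))
        assert bool(report.table.loc[report.table["row"] == 0, "flagged"].iloc[0])

    def test_clean_gaussian_data_flags_under_five_percent(self):
        cohort = generate(SynthConfig(n=300, seed=17, clip=False))
        report = flag_influential(build_design(cohort, rescale=False))
        assert report.table["flagged"].mean() < 0.05

    def test_interior_duplicate_has_low_leverage(self):
        cohort = generate(SynthConfig(n=200, seed=23))
        data = cohort.data.copy()
        data.loc[1, ["E_raw", "N_raw"]] = [cohort.data["E_raw"].mean(), cohort.data["N_raw"].mean()]
        cohort.data = data
        report = flag_influential(build_design(cohort))
        assert report.table.loc[1, "hat"] < report.cutoffs["hat"]
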