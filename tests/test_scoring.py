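"""Phenotype-axis fitting, score calibration, and vertex heatmap fields."""

import numpy as np
import pandas as pd
import pytest

import morphoscore as ms
from morphoscore.errors import (
    DegenerateAxisError,
    DegenerateReferenceError,
    InsufficientDataError,
    ShapeMismatchError,
    SingularDesignError,
)


def _pc_cohort(n_per_group, m, g_vector, noise_sd, seed, age_trend=None):
    """Simulate PC scores for two groups with a known group displacement."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    groups = np.repeat([0.0, 1.0], n_per_group)
    ages = rng.uniform(3, 20, n)
    sexes = rng.integers(0, 2, n).astype(float)
    y = np.outer(groups, g_vector) + rng.normal(0, noise_sd, (n, m))
    if age_trend is not None:
        a = ages - ages.mean()
        y = y + np.outer(a**3, age_trend)
    return y, ages, sexes, groups


def test_axis_recovers_injected_group_vector():
    rng = np.random.default_rng(0)
    g = rng.standard_normal(12)
    y, ages, sexes, groups = _pc_cohort(100, 12, g, np.linalg.norm(g) / 10, 1)
    axis = ms.fit_phenotype_axis(y, ages, sexes, groups)
    cos = axis.group_vector_pc @ g / (axis.norm_v * np.linalg.norm(g))
    assert cos >= 0.99


def test_axis_degenerate_when_groups_identical():
    rng = np.random.default_rng(2)
    n = 40
    groups = np.repeat([0.0, 1.0], n // 2)
    ages = rng.uniform(3, 20, n)
    sexes = rng.integers(0, 2, n).astype(float)
    y = np.tile(rng.standard_normal(6), (n, 1))  # same shape for everyone
    with pytest.raises(DegenerateAxisError):
        ms.fit_phenotype_axis(y, ages, sexes, groups)


def test_axis_unaffected_by_shared_age_trend():
    """A cubic age trend common to both groups is regressed away."""
    rng = np.random.default_rng(3)
    g = rng.standard_normal(8)
    trend = rng.standard_normal(8) * 0.01
    y0, ages, sexes, groups = _pc_cohort(150, 8, g, 0.1, 4)
    axis_plain = ms.fit_phenotype_axis(y0, ages, sexes, groups)
    y1, *_ = _pc_cohort(150, 8, g, 0.1, 4, age_trend=trend)
    axis_trend = ms.fit_phenotype_axis(y1, ages, sexes, groups)
    cos = axis_plain.group_vector_pc @ axis_trend.group_vector_pc / (
        axis_plain.norm_v * axis_trend.norm_v
    )
    assert cos >= 0.99


def test_axis_singular_design_names_column():
    rng = np.random.default_rng(5)
    n = 30
    groups = np.repeat([0.0, 1.0], n // 2)
    ages = rng.uniform(3, 20, n)
    sexes = np.zeros(n)  # constant -> collinear with intercept
    y = np.outer(groups, rng.standard_normal(4)) + rng.normal(0, 0.1, (n, 4))
    with pytest.raises(SingularDesignError) as err:
        ms.fit_phenotype_axis(y, ages, sexes, groups)
    assert err.value.column == "sex"


@pytest.fixture(scope="module")
def fitted_axis():
    rng = np.random.default_rng(6)
    g = rng.standard_normal(10)
    y, ages, sexes, groups = _pc_cohort(80, 10, g, 0.05, 7)
    return ms.fit_phenotype_axis(y, ages, sexes, groups)


def test_score_calibration_exact(fitted_axis):
    """Predicted normative shape scores 0; +v scores 1; +w (w ⊥ v) scores 0."""
    axis = fitted_axis
    age, sex = 8.3, 1
    pred = axis.predict_normative_pc(age, sex)
    raw, normalized = ms.score_scan(pred, age, sex, axis)
    assert normalized == pytest.approx(0.0, abs=1e-10)
    _, s_plus = ms.score_scan(pred + axis.group_vector_pc, age, sex, axis)
    assert s_plus == pytest.approx(1.0, abs=1e-10)
    rng = np.random.default_rng(8)
    w = rng.standard_normal(axis.n_components)
    w -= (w @ axis.group_vector_pc) / axis.norm_v**2 * axis.group_vector_pc
    _, s_orth = ms.score_scan(pred + w, age, sex, axis)
    assert s_orth == pytest.approx(0.0, abs=1e-10)
    # raw and normalized differ by exactly one factor of ||v||
    raw2, norm2 = ms.score_scan(pred + axis.group_vector_pc, age, sex, axis)
    assert raw2 == pytest.approx(norm2 * axis.norm_v, rel=1e-12)


def test_score_scan_dimension_mismatch(fitted_axis):
    with pytest.raises(ShapeMismatchError):
        ms.score_scan(np.zeros(3), 5.0, 0, fitted_axis)


def test_group_means_approach_calibrated_values(small_study):
    """Mean score ~1 for affected controls, ~0 for normative controls."""
    meta = small_study["metadata"]
    scored = ms.score_cohort(
        small_study["scores_pc"], meta, small_study["axis"]
    )
    ach = scored[scored["group"] == ms.GROUP_ACHONDRO]["normalized_score"]
    norm = scored[scored["group"] == ms.GROUP_NORMATIVE]["normalized_score"]
    # fitting and scoring on the same controls makes these exact in-sample
    assert ach.mean() == pytest.approx(1.0, abs=1e-8)
    assert norm.mean() == pytest.approx(0.0, abs=1e-8)


def _score_table(values, groups):
    return pd.DataFrame(
        {
            "scan_id": [f"s{i}" for i in range(len(values))],
            "group": groups,
            "normalized_score": values,
            "age_years": np.linspace(4, 12, len(values)),
        }
    )


def test_standardize_reference_mean_zero_sd_one():
    rng = np.random.default_rng(9)
    values = rng.normal(1.0, 0.4, 30)
    table = _score_table(values, [ms.GROUP_ACHONDRO] * 30)
    out = ms.standardize_scores(table)
    ref = out["sd_standardized_score"]
    assert ref.mean() == pytest.approx(0.0, abs=1e-12)
    assert ref.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_standardize_affine_invariance():
    rng = np.random.default_rng(10)
    values = rng.normal(0.5, 0.3, 25)
    groups = [ms.GROUP_ACHONDRO] * 15 + [ms.GROUP_TREATED] * 10
    out1 = ms.standardize_scores(_score_table(values, groups))
    out2 = ms.standardize_scores(_score_table(3.2 * values - 1.7, groups))
    np.testing.assert_allclose(
        out1["sd_standardized_score"], out2["sd_standardized_score"], atol=1e-10
    )


def test_standardize_single_nonreference_row_passes_through():
    values = np.array([1.0, 1.4, 0.8, 2.0])
    groups = [ms.GROUP_ACHONDRO] * 3 + [ms.GROUP_TREATED]
    out = ms.standardize_scores(_score_table(values, groups))
    assert np.isfinite(out["sd_standardized_score"].iloc[-1])


def test_standardize_degenerate_reference():
    table = _score_table(np.ones(5), [ms.GROUP_ACHONDRO] * 5)
    with pytest.raises(DegenerateReferenceError):
        ms.standardize_scores(table)
    with pytest.raises(InsufficientDataError):
        ms.standardize_scores(_score_table([1.0], [ms.GROUP_ACHONDRO]))


def _treated_table(n, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "normalized_score": rng.normal(1.0, 0.1, n),
            "age_years": rng.uniform(5, 11, n),
        }
    )


def test_age_standardize_recovers_injected_trend():
    rng = np.random.default_rng(11)
    ages = rng.uniform(3, 20, 96)
    slope = 0.1
    scores = 1.0 + slope * (ages - ages.mean()) + rng.normal(0, 1e-3, 96)
    treated = _treated_table(20, 12)
    treated["normalized_score"] += slope * (treated["age_years"] - ages.mean())
    out, test = ms.age_standardize(treated, scores, ages)
    assert test.significant
    import statsmodels.api as sm

    se = sm.OLS(scores, sm.add_constant(ages)).fit().bse[1]
    assert abs(test.slope - slope) < 2 * se
    resid_fit = ms.control_age_fit(
        out["age_standardized_score"], out["age_years"], alpha=0.05
    )
    assert abs(resid_fit.slope) < 0.01  # residualized scores ~flat in age


def test_age_standardize_alpha_extremes():
    rng = np.random.default_rng(13)
    ages = rng.uniform(3, 20, 50)
    scores = rng.normal(1.0, 0.1, 50)
    treated = _treated_table(10, 14)
    _, forced = ms.age_standardize(treated, scores, ages, alpha=1.0)
    assert forced.significant
    out, forbidden = ms.age_standardize(treated, scores, ages, alpha=0.0)
    assert not forbidden.significant
    np.testing.assert_array_equal(
        out["age_standardized_score"], out["normalized_score"]
    )


def test_age_standardize_constant_ages_raises():
    with pytest.raises(SingularDesignError):
        ms.age_standardize(
            _treated_table(5, 15), np.ones(10), np.full(10, 7.0)
        )


def test_vertex_scores_calibration(small_study):
    space, axis = small_study["space"], small_study["axis"]
    age, sex = 6.0, 0
    pred_pc = axis.predict_normative_pc(age, sex)
    pred = ms.reconstruct(
        np.concatenate([pred_pc, np.zeros(len(space.eigenvalues) - len(pred_pc))]),
        space,
    )
    field_zero = ms.vertex_scores(pred, age, sex, axis, space)
    np.testing.assert_allclose(field_zero, 0.0, atol=1e-8)
    plus = pred + axis.group_vector_landmark
    field_one = ms.vertex_scores(plus, age, sex, axis, space)
    vnorm = np.linalg.norm(axis.group_vector_landmark, axis=1)
    active = vnorm > 1e-3 * axis.norm_v / np.sqrt(len(vnorm))
    np.testing.assert_allclose(field_one[active], 1.0, atol=1e-8)


@pytest.mark.parametrize("scan_index", [0, 25, 70])
def test_vertex_score_aggregation_identity(small_study, scan_index):
    """||v_j||^2-weighted mean of vertex scores equals the global score."""
    space, axis = small_study["space"], small_study["axis"]
    meta = small_study["metadata"]
    coords = small_study["aligned"].coordinates[scan_index]
    age = meta.loc[scan_index, "age_years"]
    sex = meta.loc[scan_index, "sex"]
    field = ms.vertex_scores(coords, age, sex, axis, space)
    weights = (axis.group_vector_landmark**2).sum(axis=1)
    aggregated = (weights * field).sum() / weights.sum()
    _, global_score = ms.score_scan(
        ms.project(coords, space), age, sex, axis
    )
    assert aggregated == pytest.approx(global_score, abs=1e-8)


def test_vertex_score_change_properties():
    rng = np.random.default_rng(16)
    a, b, c = rng.standard_normal((3, 40))
    np.testing.assert_array_equal(ms.vertex_score_change(a, a), np.zeros(40))
    np.testing.assert_allclose(
        ms.vertex_score_change(a, b), -ms.vertex_score_change(b, a)
    )
    np.testing.assert_allclose(
        ms.vertex_score_change(a, c),
        ms.vertex_score_change(a, b) + ms.vertex_score_change(b, c),
        atol=1e-12,
    )
    with pytest.raises(ShapeMismatchError):
        ms.vertex_score_change(a, np.zeros(5))
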