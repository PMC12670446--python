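"""Regression-derived phenotype axis and severity scoring.

The phenotype axis is the direction in shape space that separates an
affected group from a normative group after accounting for age and sex:
each retained PC score is regressed on an intercept, a cubic polynomial in
(centered) age, sex, and a group indicator; the vector v of group
coefficients across PCs spans the age/sex-adjusted normative and affected
shape means.

A scan's score is its scalar projection onto v — computed on the residual
r after subtracting the model's prediction for a *normative* individual of
the same age and sex — divided once more by the norm of v:

    normalized_score = (r . v) / ||v||**2

so the normative mean maps to 0 and the affected-group mean displacement
maps to 1.  Scores may further be expressed in SDs of a reference group
(here the untreated affected controls) and, when the controls show a
significant score-on-age trend, residualized on age using the control
regression.

Per-vertex heatmap fields use the same projection locally: the vertex score
at landmark j is the projection of the scan's displacement d_j (from the
predicted normative shape) onto the local axis direction v_j, normalized by
||v_j||**2.  The ||v_j||**2-weighted mean of vertex scores equals the global
normalized score, so the heatmap decomposes the global score spatially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    DegenerateAxisError,
    DegenerateReferenceError,
    InsufficientDataError,
    ShapeMismatchError,
    SingularDesignError,
)
from .shape_space import ShapeSpace
from .superimposition import as_points

# canonical group labels used in metadata tables
GROUP_NORMATIVE = "normative"
GROUP_ACHONDRO = "achondroplasia"
GROUP_TREATED = "treated"

#: relative threshold below which a vertex has no local axis signal
VERTEX_EPS = 1e-3

_DESIGN_COLUMNS = ("intercept", "age", "age^2", "age^3", "sex", "group")


@dataclass
class PhenotypeAxis:
    """Fitted group-contrast axis with its supporting regression.

    ``regression_coeffs`` is (6, m): rows follow ``_DESIGN_COLUMNS`` order,
    columns are retained PCs.  ``group_vector_pc`` is the "group" row;
    ``group_vector_landmark`` is the same vector expanded in the landmark
    basis (k, 3), consistent to machine precision.
    """

    group_vector_pc: np.ndarray
    group_vector_landmark: np.ndarray | None
    norm_v: float
    regression_coeffs: np.ndarray
    age_center: float
    fit_sample_counts: dict

    @property
    def n_components(self) -> int:
        return self.group_vector_pc.shape[0]

    def predict_normative_pc(self, age: float, sex: float) -> np.ndarray:
        """Model-predicted PC scores for a normative individual (group = 0)."""
        a = age - self.age_center
        row = np.array([1.0, a, a**2, a**3, float(sex), 0.0])
        return row @ self.regression_coeffs


@dataclass
class AgeEffectTest:
    """Linear regression of control scores on age."""

    slope: float
    intercept: float
    t_stat: float
    p_value: float
    significant: bool
    control_mean_age: float
    n: int


def _design_matrix(ages, sexes, groups, age_center: float) -> np.ndarray:
    a = np.asarray(ages, dtype=float) - age_center
    return np.column_stack(
        [
            np.ones_like(a),
            a,
            a**2,
            a**3,
            np.asarray(sexes, dtype=float),
            np.asarray(groups, dtype=float),
        ]
    )


def _check_full_rank(design: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank == design.shape[1]:
        return
    # identify the first column that fails to increase the rank
    for j in range(1, design.shape[1] + 1):
        if np.linalg.matrix_rank(design[:, :j]) < j:
            name = _DESIGN_COLUMNS[j - 1]
            raise SingularDesignError(
                f"design matrix is rank deficient at column '{name}'",
                column=name,
            )
    raise SingularDesignError("design matrix is rank deficient")


def fit_phenotype_axis(
    scores_pc,
    ages,
    sexes,
    groups,
    space: ShapeSpace | None = None,
) -> PhenotypeAxis:
    """Fit the group-contrast axis from control samples.

    Parameters
    ----------
    scores_pc : (n, m) array
        Retained-PC scores of the control scans (normative + affected;
        treated scans are excluded from this fit).
    ages, sexes, groups : length-n arrays
        Age in years; sex coded 0/1; group coded 0 = normative,
        1 = affected.  Age is centered at its pooled mean before powers.
    space : ShapeSpace, optional
        When given, the axis is also expanded into landmark space.
    """
    y = np.asarray(scores_pc, dtype=float)
    groups = np.asarray(groups, dtype=float)
    if y.ndim != 2:
        raise ShapeMismatchError(f"scores_pc must be (n, m), got {y.shape}")
    if not (np.any(groups == 0) and np.any(groups == 1)):
        raise InsufficientDataError("both groups must be present to fit the axis")
    ages = np.asarray(ages, dtype=float)
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    age_center = float(ages.mean())
    design = _design_matrix(ages, sexes, groups, age_center)
    _check_full_rank(design)
    coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
    v = coeffs[5]
    norm_v = float(np.linalg.norm(v))
    response_scale = float(np.linalg.norm(y) / np.sqrt(y.size)) if y.size else 0.0
    if norm_v <= 1e-10 * max(1.0, response_scale):
        raise DegenerateAxisError(
            "group coefficient vector has zero norm; groups are indistinguishable"
        )
    v_landmark = None
    if space is not None:
        m = v.shape[0]
        v_landmark = (v @ space.components[:m]).reshape(-1, 3)
    counts = {
        "normative": int((groups == 0).sum()),
        "affected": int((groups == 1).sum()),
    }
    return PhenotypeAxis(
        group_vector_pc=v,
        group_vector_landmark=v_landmark,
        norm_v=norm_v,
        regression_coeffs=coeffs,
        age_center=age_center,
        fit_sample_counts=counts,
    )


def score_scan(scan_pc_scores, age, sex, axis: PhenotypeAxis) -> tuple[float, float]:
    """Raw and normalized phenotype score of one scan.

    The residual r is the scan's PC score minus the predicted normative
    score at its age and sex; raw = (r.v)/||v||, normalized = (r.v)/||v||^2.
    """
    s = np.asarray(scan_pc_scores, dtype=float)
    if s.shape != axis.group_vector_pc.shape:
        raise ShapeMismatchError(
            f"scan has {s.shape} PC scores, axis expects "
            f"{axis.group_vector_pc.shape}"
        )
    r = s - axis.predict_normative_pc(age, sex)
    dot = float(r @ axis.group_vector_pc)
    return dot / axis.norm_v, dot / axis.norm_v**2


def score_cohort(scores_pc, metadata: pd.DataFrame, axis: PhenotypeAxis) -> pd.DataFrame:
    """Score every scan in a cohort; returns metadata + score columns."""
    scores_pc = np.asarray(scores_pc, dtype=float)
    if len(scores_pc) != len(metadata):
        raise ShapeMismatchError("scores_pc and metadata length mismatch")
    out = metadata.reset_index(drop=True).copy()
    raw = np.empty(len(out))
    normalized = np.empty(len(out))
    for i, row in out.iterrows():
        raw[i], normalized[i] = score_scan(
            scores_pc[i], row["age_years"], row["sex"], axis
        )
    out["raw_projection"] = raw
    out["normalized_score"] = normalized
    return out


def standardize_scores(
    score_table: pd.DataFrame,
    reference_group: str = GROUP_ACHONDRO,
    group_col: str = "group",
    score_col: str = "normalized_score",
) -> pd.DataFrame:
    """Express scores in SDs of a reference group (mean 0, SD 1 there)."""
    ref = score_table[score_table[group_col] == reference_group][score_col]
    if len(ref) < 2:
        raise InsufficientDataError(
            f"reference group '{reference_group}' needs >= 2 members, has {len(ref)}"
        )
    sd = float(ref.std(ddof=1))
    if sd == 0.0:
        raise DegenerateReferenceError("reference group scores have zero SD")
    out = score_table.copy()
    out["sd_standardized_score"] = (out[score_col] - float(ref.mean())) / sd
    return out


def control_age_fit(control_scores, control_ages, alpha: float = 0.05) -> AgeEffectTest:
    """OLS of control score on age; flags significance at ``alpha``."""
    scores = np.asarray(control_scores, dtype=float)
    ages = np.asarray(control_ages, dtype=float)
    if len(scores) < 3:
        raise InsufficientDataError("age regression needs >= 3 controls")
    if np.ptp(ages) == 0:
        raise SingularDesignError(
            "control ages are constant; age slope unidentifiable", column="age"
        )
    fit = sm.OLS(scores, sm.add_constant(ages)).fit()
    slope = float(fit.params[1])
    p = float(fit.pvalues[1])
    return AgeEffectTest(
        slope=slope,
        intercept=float(fit.params[0]),
        t_stat=float(fit.tvalues[1]),
        p_value=p,
        significant=bool(p < alpha),
        control_mean_age=float(ages.mean()),
        n=len(scores),
    )


def age_standardize(
    treated_scores: pd.DataFrame,
    control_scores,
    control_ages,
    alpha: float = 0.05,
    score_col: str = "normalized_score",
    age_col: str = "age_years",
) -> tuple[pd.DataFrame, AgeEffectTest]:
    """Residualize treated scores on age using the control age trend.

    The age effect is estimated on untreated controls only.  If it is
    significant at ``alpha``, treated scores are corrected by subtracting
    ``slope * (age - control mean age)``; otherwise they pass through
    unchanged and the (non-significant) test result is reported alongside.
    """
    test = control_age_fit(control_scores, control_ages, alpha=alpha)
    out = treated_scores.copy()
    if test.significant:
        out["age_standardized_score"] = out[score_col] - test.slope * (
            out[age_col] - test.control_mean_age
        )
    else:
        out["age_standardized_score"] = out[score_col]
    return out, test


def vertex_scores(
    scan_config_aligned,
    age,
    sex,
    axis: PhenotypeAxis,
    space: ShapeSpace,
    eps: float = VERTEX_EPS,
) -> np.ndarray:
    """Per-vertex phenotype score field for one aligned scan.

    At landmark j, with d_j the scan's displacement from the predicted
    normative shape and v_j the local axis direction:

        score_j = (d_j . v_j) / ||v_j||**2   if ||v_j|| > eps * ||v|| / sqrt(k)
        score_j = 0                          otherwise (no local signal).
    """
    pts = as_points(scan_config_aligned)
    if axis.group_vector_landmark is not None:
        v = axis.group_vector_landmark
    else:
        m = axis.n_components
        v = (axis.group_vector_pc @ space.components[:m]).reshape(-1, 3)
    if pts.shape != v.shape:
        raise ShapeMismatchError(
            f"scan has {pts.shape[0]} landmarks, axis has {v.shape[0]}"
        )
    pred_pc = axis.predict_normative_pc(age, sex)
    pred = (
        space.consensus.reshape(-1)
        + pred_pc @ space.components[: len(pred_pc)]
    ).reshape(-1, 3)
    d = pts - pred
    vnorm2 = (v**2).sum(axis=1)
    k = pts.shape[0]
    threshold2 = (eps * axis.norm_v / np.sqrt(k)) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(vnorm2 > threshold2, (d * v).sum(axis=1) / vnorm2, 0.0)
    return scores


def vertex_score_change(first_visit_field, last_visit_field) -> np.ndarray:
    """Elementwise change in vertex score; negative = toward normative."""
    first = np.asarray(first_visit_field, dtype=float)
    last = np.asarray(last_visit_field, dtype=float)
    if first.shape != last.shape:
        raise ShapeMismatchError(
            f"field shapes differ: {first.shape} vs {last.shape}"
        )
    return last - first
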