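"""Synthetic bilateral 3D landmark cohorts with known ground truth.

The generator emulates the statistical structure of a facial-phenotyping
treatment study: a large cross-sectional normative cohort, a cross-sectional
affected (achondroplasia-like) cohort, and a small longitudinal treated
cohort followed over several visits, some of whose members start on placebo
and receive the drug roughly a year later.

Every scan is built additively in landmark space from a bilaterally
symmetric template:

    scan = template + growth(age) + sex_effect + group_axis [affected only]
         + subject_offset + slope * max(years_from_first_dose, 0) * group_axis
         + measurement noise

and is then pushed through a random similarity transform (rotation,
translation, positive scale) to simulate acquisition, which the Procrustes
stage must undo.  Because the treatment effect acts along the group axis
with a coefficient linear in time, the true phenotype score of a treated
scan is exactly ``1 + subject_term + slope * years`` — linear in time, the
regime the longitudinal mixed model assumes.

The template is a half-ellipsoid point cloud with jitter rather than an
anatomical face: the analysis requires only homology and bilateral
structure, and a geometric template keeps the generator dependency-free and
exactly reproducible from a seed.  The sagittal plane is x = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigurationError
from .scoring import GROUP_ACHONDRO, GROUP_NORMATIVE, GROUP_TREATED
from .superimposition import (
    BilateralMap,
    LandmarkConfiguration,
    centroid_size,
    opa_rotation,
    reflect_relabel,
)

PROTOCOL_DRUG = "drug"
PROTOCOL_PLACEBO_FIRST = "placebo_first"

#: years between a placebo-first subject's first visit and their first dose
PLACEBO_LEAD_YEARS = 1.0

#: spatial kernel width (template length units) for smooth effect fields
DEFAULT_SMOOTHNESS = 0.5

METADATA_COLUMNS = [
    "scan_id", "subject_id", "group", "sex", "age_years",
    "protocol", "years_from_first_dose", "true_score",
]


@dataclass
class CohortSpec:
    """Study-design parameters for one simulated cohort.

    Defaults mirror the design shape of the study being emulated: 200
    normative scans (scaled down from a few-thousand-strong normative
    database), 96 affected controls, and 14 treated subjects followed for
    7 visits at 0.75-year spacing (~4.5 years of follow-up), with 4 of the
    14 on the placebo-first protocol.  Treated subjects start around age 5.
    Effect magnitudes are dimensionless RMS displacements relative to a
    template of roughly unit radius.
    """

    n_pairs: int = 25
    n_midline: int = 10
    n_normative: int = 200
    n_achondro: int = 96
    n_treated: int = 14
    visits_per_treated: int = 7
    visit_spacing_years: float = 0.75
    protocol_split: float = 4 / 14
    age_range_years: tuple[float, float] = (3.0, 20.0)
    group_effect_scale: float = 0.1
    sex_effect_scale: float = 0.03
    growth_coeffs: tuple[float, float, float] = (0.01, 5e-4, 2e-5)
    subject_sd: float = 0.05
    treatment_slope: float = -0.05
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_pairs, self.n_midline, self.n_normative,
            self.n_achondro, self.n_treated, self.visits_per_treated,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be >= 0")
        if self.n_pairs + self.n_midline < 4:
            raise ConfigurationError("need n_pairs + n_midline >= 4 landmarks")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ConfigurationError("noise_sd and subject_sd must be >= 0")
        if not 0.0 <= self.protocol_split <= 1.0:
            raise ConfigurationError("protocol_split must be in [0, 1]")
        if self.group_effect_scale < 0 or self.sex_effect_scale < 0:
            raise ConfigurationError("effect scales must be >= 0")

    @property
    def n_landmarks(self) -> int:
        return 2 * self.n_pairs + self.n_midline

    @property
    def age_center(self) -> float:
        lo, hi = self.age_range_years
        return 0.5 * (lo + hi)


@dataclass
class SyntheticTruth:
    """Ground truth injected by :func:`simulate_cohort`."""

    group_axis_true: np.ndarray
    treatment_slope_true: float
    per_subject_offsets: dict = field(default_factory=dict)
    template: LandmarkConfiguration | None = None
    bilateral_map: BilateralMap | None = None


def make_template(n_pairs: int, n_midline: int, seed=None) -> tuple[LandmarkConfiguration, BilateralMap]:
    """Bilaterally symmetric half-ellipsoid template point cloud.

    Landmarks 0..n_pairs-1 are left-side points (x < 0), the next n_pairs
    their exact mirror images, and the final n_midline lie on the x = 0
    plane exactly.  Deterministic given the seed.
    """
    if n_pairs < 0 or n_midline < 0:
        raise ConfigurationError("landmark counts must be >= 0")
    if 2 * n_pairs + n_midline < 4:
        raise ConfigurationError("need at least 4 landmarks in total")
    rng = np.random.default_rng(seed)
    axes = np.array([0.8, 1.0, 1.2])
    right = np.empty((n_pairs, 3))
    for i in range(n_pairs):
        d = rng.standard_normal(3)
        d[0] = 0.15 + abs(d[0])  # keep paired points clear of the midline
        d /= np.linalg.norm(d)
        right[i] = axes * d * (1.0 + 0.1 * rng.uniform(-1.0, 1.0))
    left = right * np.array([-1.0, 1.0, 1.0])
    mid = np.empty((n_midline, 3))
    for i in range(n_midline):
        d = rng.standard_normal(3)
        d[0] = 0.0
        norm = np.linalg.norm(d)
        d = d / norm if norm > 0 else np.array([0.0, 1.0, 0.0])
        mid[i] = axes * d * (1.0 + 0.1 * rng.uniform(-1.0, 1.0))
        mid[i, 0] = 0.0
    points = np.vstack([left, right, mid])
    bmap = BilateralMap(
        pairs=[(i, n_pairs + i) for i in range(n_pairs)],
        midline=list(range(2 * n_pairs, 2 * n_pairs + n_midline)),
    )
    return LandmarkConfiguration(points, scan_id="template"), bmap


def _similarity_basis(points: np.ndarray) -> np.ndarray:
    """Orthonormal basis of infinitesimal similarity motions at a shape.

    Columns span the (up to 7-dimensional) tangent space of translations,
    rotations and uniform scaling in flattened (3k) landmark space.  A
    displacement field with no component in this span is a pure shape
    change — Procrustes superimposition can neither create nor absorb it.
    """
    x = points - points.mean(axis=0)
    k = x.shape[0]
    cols = []
    for i in range(3):
        t = np.zeros((k, 3))
        t[:, i] = 1.0
        cols.append(t.reshape(-1))
    skews = (
        np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 0]]),
        np.array([[0.0, 0, -1], [0, 0, 0], [1, 0, 0]]),
        np.array([[0.0, 0, 0], [0, 0, -1], [0, 1, 0]]),
    )
    for a in skews:
        cols.append((x @ a.T).reshape(-1))
    cols.append(x.reshape(-1))
    b = np.column_stack(cols)
    u, s, _ = np.linalg.svd(b, full_matrices=False)
    return u[:, s > 1e-10 * s[0]]


def make_effect_field(
    template,
    bilateral_map: BilateralMap,
    smoothness: float = DEFAULT_SMOOTHNESS,
    scale: float = 1.0,
    seed=None,
) -> np.ndarray:
    """Smooth, bilaterally symmetric random displacement field.

    Gaussian noise per landmark is smoothed with a distance kernel
    exp(-d²/2·smoothness²) so nearby landmarks move coherently, symmetrized
    under the bilateral map (group effects must not create asymmetry), and
    normalized to RMS per-landmark displacement ``scale``.

    The field's similarity components (net translation, rotation and
    scaling at the template) are projected out before normalization: a
    smooth field is otherwise dominated by near-rigid motion, which
    Procrustes alignment removes by construction and which therefore
    cannot represent a group shape difference.  The similarity subspace is
    invariant under the bilateral reflection, so the projection preserves
    symmetry.
    """
    if scale < 0:
        raise ConfigurationError("scale must be >= 0")
    if smoothness <= 0:
        raise ConfigurationError("smoothness must be > 0")
    pts = template.points if isinstance(template, LandmarkConfiguration) else np.asarray(template)
    k = pts.shape[0]
    if scale == 0.0:
        return np.zeros((k, 3))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((k, 3))
    kernel = np.exp(-cdist(pts, pts, "sqeuclidean") / (2.0 * smoothness**2))
    f = kernel @ noise
    f = 0.5 * (f + reflect_relabel(f, bilateral_map))
    basis = _similarity_basis(pts)
    flat = f.reshape(-1)
    flat = flat - basis @ (basis.T @ flat)
    f = flat.reshape(k, 3)
    rms = np.linalg.norm(f) / np.sqrt(k)
    if rms == 0.0:
        raise ConfigurationError("effect field vanished; cannot normalize")
    return f * (scale / rms)


def _quat_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion."""
    q = rng.standard_normal(4)
    w, x, y, z = q / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _acquire(points: np.ndarray, rng) -> np.ndarray:
    """Random similarity transform simulating acquisition pose and units."""
    rot = _quat_rotation(rng)
    scale = rng.uniform(0.5, 2.0)
    translation = rng.uniform(-10.0, 10.0, size=3)
    return scale * points @ rot + translation


def simulate_cohort(spec: CohortSpec):
    """Simulate a full cohort; returns (samples, metadata, truth).

    ``samples`` is a list of :class:`LandmarkConfiguration` in acquisition
    pose; ``metadata`` a DataFrame with one row per scan (columns
    ``METADATA_COLUMNS``, including the noiseless true phenotype score);
    ``truth`` the injected effect fields.  Identical spec (including seed)
    gives an identical cohort.
    """
    root = np.random.SeedSequence(spec.seed)
    (
        ss_template, ss_axis, ss_sex, ss_growth, ss_subjects, ss_scans,
    ) = root.spawn(6)
    template, bmap = make_template(spec.n_pairs, spec.n_midline, seed=ss_template)
    axis = make_effect_field(
        template, bmap, scale=spec.group_effect_scale, seed=ss_axis
    )
    sex_field = make_effect_field(
        template, bmap, scale=spec.sex_effect_scale, seed=ss_sex
    )
    growth_seeds = ss_growth.spawn(3)
    growth_fields = [
        make_effect_field(template, bmap, scale=1.0, seed=s)
        for s in growth_seeds
    ]
    rng_subj = np.random.default_rng(ss_subjects)
    rng_scan = np.random.default_rng(ss_scans)

    k = spec.n_landmarks
    axis_flat = axis.reshape(-1)
    axis_norm2 = float(axis_flat @ axis_flat)

    def growth(age: float) -> np.ndarray:
        a = age - spec.age_center
        g = np.zeros((k, 3))
        for power, (coeff, fld) in enumerate(
            zip(spec.growth_coeffs, growth_fields), start=1
        ):
            g += coeff * a**power * fld
        return g

    samples: list[LandmarkConfiguration] = []
    rows: list[dict] = []
    offsets: dict[str, np.ndarray] = {}
    lo, hi = spec.age_range_years

    def emit(subject_id, group, sex, age, protocol, years, offset, visit):
        affected = group in (GROUP_ACHONDRO, GROUP_TREATED)
        pos_years = max(years, 0.0) if years is not None else 0.0
        pts = template.points + growth(age) + sex * sex_field + offset
        if affected:
            pts = pts + axis
        if group == GROUP_TREATED and pos_years > 0:
            pts = pts + spec.treatment_slope * pos_years * axis
        if spec.noise_sd > 0:
            pts = pts + rng_scan.normal(0.0, spec.noise_sd, size=(k, 3))
        true_score = 0.0
        if axis_norm2 > 0:
            true_score = float(offset.reshape(-1) @ axis_flat) / axis_norm2
            if affected:
                true_score += 1.0
            if group == GROUP_TREATED:
                true_score += spec.treatment_slope * pos_years
        scan_id = f"{subject_id}_v{visit}"
        samples.append(
            LandmarkConfiguration(_acquire(pts, rng_scan), scan_id=scan_id)
        )
        rows.append(
            {
                "scan_id": scan_id,
                "subject_id": subject_id,
                "group": group,
                "sex": int(sex),
                "age_years": float(age),
                "protocol": protocol,
                "years_from_first_dose": (
                    float(years) if years is not None else np.nan
                ),
                "true_score": true_score,
            }
        )

    def subject_offset(subject_id: str) -> np.ndarray:
        off = (
            rng_subj.standard_normal((k, 3)) * spec.subject_sd
            if spec.subject_sd > 0
            else np.zeros((k, 3))
        )
        offsets[subject_id] = off
        return off

    for group, count in (
        (GROUP_NORMATIVE, spec.n_normative),
        (GROUP_ACHONDRO, spec.n_achondro),
    ):
        for i in range(count):
            subject_id = f"{group}_{i:04d}"
            off = subject_offset(subject_id)
            age = rng_subj.uniform(lo, hi)
            sex = int(rng_subj.integers(0, 2))
            emit(subject_id, group, sex, age, None, None, off, visit=0)

    n_placebo = int(round(spec.n_treated * spec.protocol_split))
    placebo_idx = set(
        rng_subj.permutation(spec.n_treated)[:n_placebo].tolist()
    )
    for i in range(spec.n_treated):
        subject_id = f"{GROUP_TREATED}_{i:04d}"
        off = subject_offset(subject_id)
        first_age = max(lo, rng_subj.normal(5.0, 1.0))
        sex = int(rng_subj.integers(0, 2))
        placebo = i in placebo_idx
        protocol = PROTOCOL_PLACEBO_FIRST if placebo else PROTOCOL_DRUG
        lead = PLACEBO_LEAD_YEARS if placebo else 0.0
        for v in range(spec.visits_per_treated):
            t = v * spec.visit_spacing_years
            emit(
                subject_id, GROUP_TREATED, sex, first_age + t,
                protocol, t - lead, off, visit=v,
            )

    metadata = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    truth = SyntheticTruth(
        group_axis_true=axis,
        treatment_slope_true=spec.treatment_slope,
        per_subject_offsets=offsets,
        template=template,
        bilateral_map=bmap,
    )
    return samples, metadata, truth


def axis_recovery_cosine(axis_landmark_field, consensus, truth: SyntheticTruth) -> float:
    """Cosine similarity between a fitted axis and the injected group axis.

    The fitted axis lives in the GPA consensus frame, which differs from
    the template frame by an arbitrary rotation (and the unit-size
    rescaling); the consensus is superimposed on the unit-scaled template
    and the same rotation applied to the axis field before comparing.
    Cosine similarity itself is scale-free.
    """
    field = np.asarray(axis_landmark_field, dtype=float)
    tpl = truth.template.points
    tpl_unit = (tpl - tpl.mean(axis=0)) / centroid_size(tpl)
    rot, _ = opa_rotation(np.asarray(consensus, dtype=float), tpl_unit)
    v = (field @ rot).reshape(-1)
    g = truth.group_axis_true.reshape(-1)
    return float(v @ g / (np.linalg.norm(v) * np.linalg.norm(g)))


# ---------------------------------------------------------------------------
# score-level reduction for longitudinal calibration studies
# ---------------------------------------------------------------------------

def score_intercept_sd(spec: CohortSpec) -> float:
    """SD of the per-subject score intercept implied by the landmark model.

    An i.i.d. Gaussian landmark offset with per-coordinate SD ``subject_sd``
    projects onto the normalized group axis with SD
    ``subject_sd / (group_effect_scale * sqrt(k))``.
    """
    if spec.group_effect_scale <= 0:
        raise ConfigurationError("score scale undefined when group effect is 0")
    return spec.subject_sd / (spec.group_effect_scale * np.sqrt(spec.n_landmarks))


def score_residual_sd(spec: CohortSpec) -> float:
    """Per-visit score noise SD implied by the landmark measurement noise."""
    if spec.group_effect_scale <= 0:
        raise ConfigurationError("score scale undefined when group effect is 0")
    return spec.noise_sd / (spec.group_effect_scale * np.sqrt(spec.n_landmarks))


def simulate_treated_scores(spec: CohortSpec, seed=None) -> pd.DataFrame:
    """Treated-cohort score table drawn from the score-level model.

    Because treatment and individual offsets act along the group axis, the
    landmark model reduces exactly, in score units, to

        score = 1 + b_subject + slope * max(years, 0) + e

    with b ~ N(0, :func:`score_intercept_sd`²) and per-visit noise
    e ~ N(0, :func:`score_residual_sd`²).  This reduction lets slope-
    recovery and error-calibration studies run thousands of replicates
    without re-running the geometric pipeline each time.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    b_sd = score_intercept_sd(spec)
    e_sd = score_residual_sd(spec)
    n_placebo = int(round(spec.n_treated * spec.protocol_split))
    placebo_idx = set(rng.permutation(spec.n_treated)[:n_placebo].tolist())
    rows = []
    for i in range(spec.n_treated):
        subject_id = f"{GROUP_TREATED}_{i:04d}"
        b = rng.normal(0.0, b_sd)
        placebo = i in placebo_idx
        lead = PLACEBO_LEAD_YEARS if placebo else 0.0
        first_age = max(spec.age_range_years[0], rng.normal(5.0, 1.0))
        for v in range(spec.visits_per_treated):
            t = v * spec.visit_spacing_years
            years = t - lead
            score = (
                1.0 + b
                + spec.treatment_slope * max(years, 0.0)
                + rng.normal(0.0, e_sd)
            )
            rows.append(
                {
                    "scan_id": f"{subject_id}_v{v}",
                    "subject_id": subject_id,
                    "group": GROUP_TREATED,
                    "age_years": first_age + t,
                    "protocol": (
                        PROTOCOL_PLACEBO_FIRST if placebo else PROTOCOL_DRUG
                    ),
                    "years_from_first_dose": years,
                    "normalized_score": score,
                }
            )
    return pd.DataFrame(rows)
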