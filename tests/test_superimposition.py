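"""Procrustes alignment, GPA and bilateral symmetrization."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import morphoscore as ms
from morphoscore.errors import (
    ConfigurationError,
    DegenerateConfigurationError,
    InsufficientDataError,
    ShapeMismatchError,
)

from conftest import random_similarity


def test_centroid_size_unit_tetrahedron():
    """Hand-computed: centroid (1/4,1/4,1/4), summed squared deviations 9/4."""
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    assert ms.centroid_size(pts) == pytest.approx(1.5, abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_centroid_size_homogeneity_and_translation(seed):
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((17, 3))
    size = ms.centroid_size(pts)
    c = rng.uniform(0.1, 5.0)
    assert ms.centroid_size(c * pts) == pytest.approx(c * size, rel=1e-12)
    assert ms.centroid_size(pts + rng.uniform(-9, 9, 3)) == pytest.approx(
        size, rel=1e-12
    )


def test_centroid_size_degenerate_raises():
    with pytest.raises(DegenerateConfigurationError):
        ms.centroid_size(np.ones((5, 3)))


@pytest.mark.parametrize("seed", range(5))
def test_opa_recovers_similarity_transform(seed):
    rng = np.random.default_rng(seed)
    target = rng.standard_normal((20, 3))
    mobile = random_similarity(target, rng)
    aligned, residual = ms.opa_align(mobile, target)
    assert residual < 1e-10
    np.testing.assert_allclose(aligned, target, atol=1e-10)


def test_opa_identity():
    rng = np.random.default_rng(3)
    pts = rng.standard_normal((12, 3))
    aligned, residual = ms.opa_align(pts, pts)
    assert residual == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(aligned, pts, atol=1e-12)


def test_opa_never_mirror_matches():
    """A mirrored asymmetric shape must not be silently reflected back."""
    rng = np.random.default_rng(9)
    target = rng.standard_normal((15, 3))
    mirrored = target * np.array([-1.0, 1.0, 1.0])
    _, residual = ms.opa_align(mirrored, target)
    assert residual > 1e-2  # a reflection would give ~0


@pytest.mark.parametrize("seed", [10, 11, 12])
def test_opa_matches_bruteforce_minimization(seed):
    """Independent oracle: numerical optimization over rotation + log-scale."""
    rng = np.random.default_rng(seed)
    mobile = rng.standard_normal((4, 3))
    target = rng.standard_normal((4, 3))
    _, residual = ms.opa_align(mobile, target)

    xc = mobile - mobile.mean(axis=0)
    yc = target - target.mean(axis=0)

    def objective(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        return np.linalg.norm(np.exp(params[3]) * xc @ rot - yc)

    best = np.inf
    for start_seed in range(8):
        srng = np.random.default_rng(start_seed)
        x0 = np.append(srng.uniform(-np.pi, np.pi, 3), 0.0)
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    assert residual == pytest.approx(best, abs=1e-6)


def test_opa_shape_mismatch_raises():
    with pytest.raises(ShapeMismatchError):
        ms.opa_align(np.zeros((4, 3)) + np.eye(4, 3), np.eye(5, 3))


def test_gpa_similarity_copies_collapse_to_consensus():
    rng = np.random.default_rng(4)
    shape = rng.standard_normal((30, 3))
    copies = [random_similarity(shape, rng) for _ in range(10)]
    aligned = ms.gpa(copies)
    assert aligned.converged
    for coords in aligned.coordinates:
        assert np.linalg.norm(coords - aligned.consensus) < 1e-8
    # the consensus is the shape itself (GPA consensus of copies of one shape)
    assert ms.procrustes_distance(aligned.consensus, shape) < 1e-10


def test_gpa_two_configs_equidistant_consensus():
    rng = np.random.default_rng(5)
    a = rng.standard_normal((25, 3))
    b = a + 0.1 * rng.standard_normal((25, 3))
    aligned = ms.gpa([a, b])
    residuals = [
        np.linalg.norm(c - aligned.consensus) for c in aligned.coordinates
    ]
    assert residuals[0] == pytest.approx(residuals[1], abs=1e-8)


def test_gpa_order_permutation_preserves_pairwise_distances():
    rng = np.random.default_rng(6)
    base = rng.standard_normal((20, 3))
    configs = [
        random_similarity(base + 0.05 * rng.standard_normal((20, 3)), rng)
        for _ in range(8)
    ]
    order = rng.permutation(8)
    aligned_a = ms.gpa(configs)
    aligned_b = ms.gpa([configs[i] for i in order])

    def pairwise(coords):
        n = len(coords)
        return np.array(
            [
                np.linalg.norm(coords[i] - coords[j])
                for i in range(n)
                for j in range(i + 1, n)
            ]
        )

    dist_a = pairwise(aligned_a.coordinates)
    inverse = np.argsort(order)
    dist_b = pairwise(aligned_b.coordinates[inverse])
    np.testing.assert_allclose(dist_a, dist_b, atol=1e-8)


def test_gpa_invariants_unit_size_centered():
    rng = np.random.default_rng(7)
    configs = [rng.standard_normal((12, 3)) for _ in range(6)]
    aligned = ms.gpa(configs)
    assert ms.centroid_size(aligned.consensus) == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(aligned.consensus.mean(axis=0), 0, atol=1e-12)
    for coords in aligned.coordinates:
        assert ms.centroid_size(coords) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(coords.mean(axis=0), 0, atol=1e-12)


def test_gpa_alignment_invariant_to_input_pose():
    """Shape distances are unchanged when inputs arrive in arbitrary pose."""
    rng = np.random.default_rng(8)
    base = rng.standard_normal((15, 3))
    configs = [base + 0.05 * rng.standard_normal((15, 3)) for _ in range(5)]
    moved = [random_similarity(c, rng) for c in configs]
    dist_a = [
        ms.procrustes_distance(a, b)
        for a in ms.gpa(configs).coordinates
        for b in ms.gpa(configs).coordinates
    ]
    dist_b = [
        ms.procrustes_distance(a, b)
        for a in ms.gpa(moved).coordinates
        for b in ms.gpa(moved).coordinates
    ]
    np.testing.assert_allclose(dist_a, dist_b, atol=1e-8)


def test_gpa_too_few_configs_raises():
    with pytest.raises(InsufficientDataError):
        ms.gpa([np.eye(4, 3)])


def test_reflect_relabel_symmetric_template_is_fixed_point(template60):
    template, bmap = template60
    out = ms.reflect_relabel(template, bmap)
    np.testing.assert_array_equal(out.points, template.points)


def test_reflect_relabel_involution_and_isometry(template60):
    _, bmap = template60
    rng = np.random.default_rng(13)
    pts = rng.standard_normal((bmap.n_landmarks, 3))
    once = ms.reflect_relabel(pts, bmap)
    twice = ms.reflect_relabel(once, bmap)
    np.testing.assert_array_equal(twice, pts)
    assert not np.allclose(once, pts)  # asymmetric input changes
    assert ms.centroid_size(once) == pytest.approx(
        ms.centroid_size(pts), rel=1e-14
    )


def test_reflect_relabel_invalid_map_raises():
    bad = ms.BilateralMap(pairs=[(0, 1)], midline=[1])  # index 1 twice
    with pytest.raises(ConfigurationError):
        ms.reflect_relabel(np.zeros((3, 3)), bad)


def test_symmetrize_fixed_point_on_symmetric_input(template60):
    template, bmap = template60
    out = ms.symmetrize(template, bmap)
    np.testing.assert_allclose(out.points, template.points, atol=1e-10)


@pytest.mark.parametrize("seed", range(4))
def test_symmetrize_idempotent_and_output_symmetric(template60, seed):
    template, bmap = template60
    rng = np.random.default_rng(seed)
    pts = template.points + 0.2 * rng.standard_normal(template.points.shape)
    once = ms.symmetrize(pts, bmap)
    twice = ms.symmetrize(once, bmap)
    assert np.abs(twice - once).max() < 1e-8
    # the output is bilaterally symmetric: its mirror aligns onto itself
    reflected = ms.reflect_relabel(once, bmap)
    _, residual = ms.opa_align(reflected, once)
    assert residual < 1e-6


def test_symmetrization_does_not_increase_distance_to_symmetric_mean(template60):
    """On average, removing asymmetry moves shapes toward a symmetric
    population consensus."""
    template, bmap = template60
    rng = np.random.default_rng(21)
    before, after = [], []
    for _ in range(20):
        noisy = template.points + 0.1 * rng.standard_normal(template.points.shape)
        before.append(ms.procrustes_distance(noisy, template))
        after.append(ms.procrustes_distance(ms.symmetrize(noisy, bmap), template))
    assert np.mean(after) <= np.mean(before)
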