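"""Procrustes superimposition and bilateral symmetrization of 3D landmarks.

A landmark configuration is an ordered set of k homologous 3D points; point j
corresponds anatomically across every scan in a study.  This module provides
the standard geometric-morphometrics machinery to place configurations in a
common shape coordinate frame:

* :func:`centroid_size` — the standard size measure (root summed squared
  distances to the centroid);
* :func:`opa_align` — ordinary Procrustes analysis: optimal translation,
  proper rotation and positive scaling of one configuration onto another;
* :func:`gpa` — generalized Procrustes analysis: iterative alignment of many
  configurations to an evolving consensus, all kept at unit centroid size;
* :func:`reflect_relabel` / :func:`symmetrize` — bilateral symmetrization:
  a configuration is mirrored about the sagittal plane, its left/right labels
  swapped, the mirrored copy superimposed on the original, and the two
  averaged.  The result has no bilateral asymmetry component.

Conventions
-----------
The sagittal (mirror) plane is fixed at x = 0: generators and readers must
place the face's midline there.  Rotations are always proper (det = +1);
reflection symmetry is handled exclusively through label-aware mirroring, so
an asymmetric shape can never be silently matched to its mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateConfigurationError,
    InsufficientDataError,
    ShapeMismatchError,
)

#: Convergence tolerance on the consensus RMS movement inside GPA.
GPA_TOL = 1e-8
#: Iteration cap for GPA; non-convergence sets a flag, it does not raise.
GPA_MAX_ITER = 100

_MIRROR = np.array([-1.0, 1.0, 1.0])


@dataclass
class LandmarkConfiguration:
    """One scan's ordered set of k 3D landmarks."""

    points: np.ndarray
    scan_id: str | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ConfigurationError(
                f"points must be (k, 3), got {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ConfigurationError("points contain non-finite values")
        self.points = pts

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class BilateralMap:
    """Left/right landmark pairing plus midline indices.

    The pairs and midline indices must partition ``range(k)``; applying the
    induced permutation twice is the identity by construction.
    """

    pairs: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]

    def __init__(self, pairs, midline):
        object.__setattr__(self, "pairs", tuple((int(a), int(b)) for a, b in pairs))
        object.__setattr__(self, "midline", tuple(int(i) for i in midline))

    @property
    def n_landmarks(self) -> int:
        return 2 * len(self.pairs) + len(self.midline)

    def validate(self, k: int) -> None:
        seen = [i for pair in self.pairs for i in pair] + list(self.midline)
        if sorted(seen) != list(range(k)):
            raise ConfigurationError(
                f"bilateral map does not partition 0..{k - 1}: "
                f"covers {len(set(seen))} of {k} indices"
            )

    def permutation(self, k: int) -> np.ndarray:
        """Index permutation swapping each (left, right) pair; an involution."""
        self.validate(k)
        perm = np.arange(k)
        for left, right in self.pairs:
            perm[left] = right
            perm[right] = left
        return perm


@dataclass
class AlignedSet:
    """Output of GPA: unit-size configurations in a common frame.

    ``coordinates`` is (n, k, 3); every configuration and the consensus are
    centered at the origin with centroid size 1.
    """

    coordinates: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    converged: bool
    scan_ids: list = field(default_factory=list)

    @property
    def configurations(self) -> list[LandmarkConfiguration]:
        ids = self.scan_ids or [None] * len(self.coordinates)
        return [
            LandmarkConfiguration(p, scan_id=i)
            for p, i in zip(self.coordinates, ids)
        ]

    @property
    def n_samples(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coordinates.shape[1]


def as_points(config) -> np.ndarray:
    """Coerce a LandmarkConfiguration or array-like to a (k, 3) float array."""
    if isinstance(config, LandmarkConfiguration):
        return config.points
    pts = np.asarray(config, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ConfigurationError(f"expected (k, 3) points, got {pts.shape}")
    return pts


def centroid_size(config) -> float:
    """Root summed squared distances of the points to their centroid."""
    pts = as_points(config)
    size = float(np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum()))
    if size == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide; size is 0")
    return size


def _optimal_rotation(h: np.ndarray) -> np.ndarray:
    """Proper rotation R maximizing trace(R^T H) for cross-covariance H.

    Works on a single (3, 3) matrix or a stacked (n, 3, 3) batch.
    """
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(u @ vt)
    d = np.ones(h.shape[:-2] + (3,))
    d[..., -1] = np.sign(det)
    return (u * d[..., None, :]) @ vt


def opa_rotation(mobile, target) -> tuple[np.ndarray, float]:
    """Optimal proper rotation and scale carrying centered mobile onto target.

    Returns ``(R, s)`` such that ``s * (mobile - mean) @ R`` best matches
    ``target - mean`` in least squares.
    """
    x = as_points(mobile)
    y = as_points(target)
    if x.shape != y.shape:
        raise ShapeMismatchError(f"landmark counts differ: {x.shape} vs {y.shape}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.array([1.0, 1.0, sign])
    rot = (u * d) @ vt
    denom = float((xc**2).sum())
    if denom == 0.0:
        raise DegenerateConfigurationError("mobile configuration is degenerate")
    scale = float((s * d).sum()) / denom
    return rot, scale


def opa_align(mobile, target, scale: bool = True) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes superimposition of ``mobile`` onto ``target``.

    Applies the optimal translation, proper rotation (det = +1, never a
    reflection) and, if ``scale``, positive scaling minimizing the summed
    squared distance to ``target``.  Returns the aligned copy and the
    residual distance (root of the minimized sum).
    """
    x = as_points(mobile)
    y = as_points(target)
    rot, s = opa_rotation(x, y)
    if not scale:
        s = 1.0
    aligned = s * (x - x.mean(axis=0)) @ rot + y.mean(axis=0)
    residual = float(np.linalg.norm(aligned - y))
    return aligned, residual


def procrustes_distance(a, b) -> float:
    """Full Procrustes distance between two shapes (unit-size, rotation-free)."""
    x = as_points(a)
    y = as_points(b)
    xs = (x - x.mean(axis=0)) / centroid_size(x)
    ys = (y - y.mean(axis=0)) / centroid_size(y)
    _, residual = opa_align(xs, ys)
    return residual


def gpa(configs, tol: float = GPA_TOL, max_iter: int = GPA_MAX_ITER) -> AlignedSet:
    """Generalized Procrustes analysis of two or more configurations.

    Every configuration is centered and scaled to unit centroid size, then
    iteratively rotated to the running consensus (the mean shape, itself
    re-centered and rescaled to unit size each round) until the consensus
    RMS movement drops below ``tol`` or ``max_iter`` is reached.  Because
    all shapes are held at unit size throughout, the optimal similarity
    alignment to the consensus reduces to a rotation.
    """
    if len(configs) < 2:
        raise InsufficientDataError("GPA needs at least 2 configurations")
    pts = [as_points(c) for c in configs]
    k = pts[0].shape[0]
    if any(p.shape[0] != k for p in pts):
        raise ShapeMismatchError("configurations have differing landmark counts")
    scan_ids = [
        c.scan_id if isinstance(c, LandmarkConfiguration) else None for c in configs
    ]
    sizes = np.array([centroid_size(p) for p in pts])
    x = np.stack([(p - p.mean(axis=0)) / s for p, s in zip(pts, sizes)])

    def _unit(shape: np.ndarray) -> np.ndarray:
        shape = shape - shape.mean(axis=0)
        return shape / np.sqrt((shape**2).sum())

    consensus = x[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        h = np.einsum("nki,kj->nij", x, consensus)
        rot = _optimal_rotation(h)
        x = np.einsum("nki,nij->nkj", x, rot)
        new = _unit(x.mean(axis=0))
        movement = np.linalg.norm(new - consensus) / np.sqrt(k)
        consensus = new
        if movement < tol:
            converged = True
            break
    # final rotation pass so every shape is aligned to the *final* consensus
    h = np.einsum("nki,kj->nij", x, consensus)
    x = np.einsum("nki,nij->nkj", x, _optimal_rotation(h))
    return AlignedSet(
        coordinates=x,
        consensus=consensus,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
        scan_ids=scan_ids,
    )


def reflect_relabel(config, bilateral_map: BilateralMap):
    """Mirror a configuration about x = 0 and swap left/right labels.

    Midline labels are unchanged.  Applying the operation twice is the
    identity; centroid size is preserved exactly (reflection is an isometry).
    Returns the same type as the input (configuration in, configuration out).
    """
    pts = as_points(config)
    perm = bilateral_map.permutation(pts.shape[0])
    reflected = (pts * _MIRROR)[perm]
    if isinstance(config, LandmarkConfiguration):
        return LandmarkConfiguration(reflected, scan_id=config.scan_id)
    return reflected


def symmetrize(
    config,
    bilateral_map: BilateralMap,
    tol: float = 1e-12,
    max_iter: int = 30,
):
    """Bilaterally symmetrize a configuration.

    The mirrored, label-swapped copy is superimposed on the original by
    ordinary Procrustes analysis and the two are averaged pointwise.  A
    single align-and-average step is not an exact projection onto the
    symmetric subspace (alignment and averaging do not commute, leaving a
    residual that is second order in the asymmetry), so the step is
    iterated to its fixed point; convergence is quadratic and reaches
    machine precision in a handful of rounds.  The result is therefore a
    fixed point of the operation (idempotent) and is itself bilaterally
    symmetric.
    """
    pts = as_points(config)
    sym = pts
    scale = centroid_size(pts)
    for _ in range(max_iter):
        reflected = as_points(reflect_relabel(sym, bilateral_map))
        aligned, _ = opa_align(reflected, sym)
        new = 0.5 * (sym + aligned)
        change = np.abs(new - sym).max()
        sym = new
        if change < tol * scale:
            break
    if isinstance(config, LandmarkConfiguration):
        return LandmarkConfiguration(sym, scan_id=config.scan_id)
    return sym
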