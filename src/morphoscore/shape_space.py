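"""Shape-space PCA and parallel analysis for component retention.

After generalized Procrustes alignment every scan is a point in a 3k-
dimensional coordinate space (k landmarks, flattened).  PCA of the aligned
coordinates gives the major modes of shape variation; downstream statistics
(phenotype-axis regression, Hotelling tests) operate on the leading PC
scores.  The number of components to retain is chosen by Horn-style
parallel analysis: a component is kept only while its eigenvalue exceeds
the chosen percentile of eigenvalues obtained from structureless reference
data of the same dimensions.

PCA is run on the aligned coordinates directly, without a prior projection
to Procrustes tangent space; for the small shape variation typical of
within-species facial data the difference is numerically minor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .superimposition import AlignedSet, LandmarkConfiguration, as_points

PA_PERMUTATIONS = 100
PA_PERCENTILE = 95.0


@dataclass
class ShapeSpace:
    """PCA coordinate system for aligned shapes.

    Attributes
    ----------
    consensus : (k, 3) array
        Mean aligned shape; the origin of the PC coordinate system.
    components : (m, 3k) array
        Orthonormal basis vectors in flattened landmark space, ordered by
        decreasing eigenvalue.
    eigenvalues : (m,) array
        Sample variances (n−1 denominator) along each component.
    n_retained : int
        Number of components retained for downstream statistics.
    """

    consensus: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    n_retained: int
    n_samples: int

    @property
    def n_landmarks(self) -> int:
        return self.consensus.shape[0]

    @property
    def variance_explained_cum(self) -> np.ndarray:
        """Cumulative fraction of total variance per component count."""
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return np.cumsum(self.eigenvalues) / total


def _as_matrix(data) -> np.ndarray:
    """Coerce AlignedSet / list of configurations / array to (n, 3k)."""
    if isinstance(data, AlignedSet):
        x = data.coordinates
    elif isinstance(data, np.ndarray):
        x = data
    else:
        x = np.stack([as_points(c) for c in data])
    if x.ndim == 3:
        x = x.reshape(x.shape[0], -1)
    return np.asarray(x, dtype=float)


def fit_pca(data, n_retained: int | None = None) -> ShapeSpace:
    """PCA of aligned, flattened landmark coordinates.

    Centers on the sample mean (the consensus of the aligned data),
    eigendecomposes the sample covariance via SVD, and keeps at most
    min(N−1, 3k) components.  ``n_retained`` defaults to all of them;
    use :func:`parallel_analysis` to choose a data-driven cut.
    """
    x = _as_matrix(data)
    n, p = x.shape
    if n < 2:
        raise InsufficientDataError("PCA needs at least 2 samples")
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    m = min(n - 1, p)
    eigenvalues = (s[:m] ** 2) / (n - 1)
    components = vt[:m]
    if n_retained is None:
        n_retained = m
    if not 0 <= n_retained <= m:
        raise ValueError(f"n_retained must be in [0, {m}], got {n_retained}")
    return ShapeSpace(
        consensus=mean.reshape(-1, 3),
        components=components,
        eigenvalues=eigenvalues,
        n_retained=n_retained,
        n_samples=n,
    )


def _eigenvalues(xc: np.ndarray) -> np.ndarray:
    s = np.linalg.svd(xc, compute_uv=False)
    return s**2 / (xc.shape[0] - 1)


def parallel_analysis(
    data,
    n_permutations: int = PA_PERMUTATIONS,
    percentile: float = PA_PERCENTILE,
    seed=None,
    method: str = "permutation",
) -> int:
    """Horn-style parallel analysis: how many PCs rise above chance?

    Reference eigenvalue spectra are generated either by independently
    permuting each variable across samples (``method="permutation"``,
    preserving every marginal distribution) or from Gaussian noise with
    matching per-variable SDs (``method="normal"``).  The retained count is
    the largest m such that observed eigenvalues 1..m *all* exceed the given
    percentile of the reference eigenvalue at the same rank.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    if method not in ("permutation", "normal"):
        raise ValueError(f"unknown method {method!r}")
    x = _as_matrix(data)
    n, p = x.shape
    if n < 2:
        raise InsufficientDataError("parallel analysis needs at least 2 samples")
    rng = np.random.default_rng(seed)
    xc = x - x.mean(axis=0)
    observed = _eigenvalues(xc)
    m = min(n - 1, p)
    null = np.empty((n_permutations, m))
    col_sd = x.std(axis=0, ddof=1)
    for i in range(n_permutations):
        if method == "permutation":
            ref = rng.permuted(x, axis=0)
        else:
            ref = rng.standard_normal((n, p)) * col_sd
        null[i] = _eigenvalues(ref - ref.mean(axis=0))[:m]
    threshold = np.percentile(null, percentile, axis=0)
    passing = observed[:m] > threshold
    retained = 0
    for ok in passing:
        if not ok:
            break
        retained += 1
    return retained


def fit_shape_space(
    data,
    n_permutations: int = PA_PERMUTATIONS,
    percentile: float = PA_PERCENTILE,
    seed=None,
    method: str = "permutation",
) -> ShapeSpace:
    """Convenience: PCA plus parallel-analysis retention in one call."""
    space = fit_pca(data)
    space.n_retained = parallel_analysis(
        data, n_permutations=n_permutations, percentile=percentile,
        seed=seed, method=method,
    )
    return space


def _flatten(shape, space: ShapeSpace) -> np.ndarray:
    if isinstance(shape, LandmarkConfiguration):
        shape = shape.points
    x = np.asarray(shape, dtype=float)
    if x.ndim == 2:
        x = x.reshape(-1)
    if x.shape[-1] != space.components.shape[1]:
        raise ValueError(
            f"shape has {x.shape[-1]} coordinates, space expects "
            f"{space.components.shape[1]}"
        )
    return x


def project(shape, space: ShapeSpace, n_components: int | None = None) -> np.ndarray:
    """PC scores of an aligned shape on the leading components.

    ``n_components`` defaults to the space's retained count.
    """
    if n_components is None:
        n_components = space.n_retained
    if not 0 <= n_components <= len(space.eigenvalues):
        raise ValueError(
            f"n_components must be in [0, {len(space.eigenvalues)}], "
            f"got {n_components}"
        )
    x = _flatten(shape, space)
    return (x - space.consensus.reshape(-1)) @ space.components[:n_components].T


def reconstruct(scores, space: ShapeSpace) -> np.ndarray:
    """Map PC scores back to a (k, 3) landmark configuration."""
    scores = np.atleast_1d(np.asarray(scores, dtype=float))
    flat = space.consensus.reshape(-1) + scores @ space.components[: len(scores)]
    return flat.reshape(-1, 3)
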