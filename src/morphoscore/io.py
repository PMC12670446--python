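"""Readers and writers for landmark data and pipeline artifacts.

Formats
-------
* Landmarks: wide CSV (one row per scan, columns ``x1,y1,z1,...,xk,yk,zk``,
  index column ``scan_id``), vertex-only PLY (vertex order = landmark
  order; read via trimesh), or OBJ vertex lines.
* Bilateral map: CSV with columns ``left,right``; a row with equal indices
  marks a midline landmark.
* Metadata / scores: plain CSV.
* AlignedSet / ShapeSpace / PhenotypeAxis: NumPy ``.npz`` archives with a
  version tag (layouts below).
* Heatmaps: ASCII PLY point clouds carrying a per-vertex float ``quality``
  property (the vertex score) and a red–blue diverging vertex color
  (0-centered; reds = more affected-like, blues = more normative-like).

NPZ layouts (all carry ``format_version``):
  aligned:   coordinates (n,k,3), consensus (k,3), centroid_sizes (n,),
             iterations, converged, scan_ids (n,)
  space:     consensus (k,3), components (m,3k), eigenvalues (m,),
             n_retained, n_samples
  axis:      group_vector_pc (m,), group_vector_landmark (k,3),
             regression_coeffs (6,m), age_center, norm_v
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import PhenotypeAxis
from .shape_space import ShapeSpace
from .superimposition import AlignedSet, BilateralMap, LandmarkConfiguration

FORMAT_VERSION = "morphoscore-1"


# -- landmark configurations -------------------------------------------------

def write_landmarks_csv(path, samples) -> None:
    """Wide CSV: one row per scan, columns x1,y1,z1,...; index scan_id."""
    rows = {}
    for i, s in enumerate(samples):
        scan_id = s.scan_id if s.scan_id is not None else f"scan_{i:05d}"
        rows[scan_id] = s.points.reshape(-1)
    k = len(next(iter(rows.values()))) // 3
    columns = [f"{c}{j}" for j in range(1, k + 1) for c in ("x", "y", "z")]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    df.index.name = "scan_id"
    df.to_csv(path)


def read_landmarks_csv(path) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path, index_col="scan_id")
    return [
        LandmarkConfiguration(
            row.to_numpy(dtype=float).reshape(-1, 3), scan_id=str(idx)
        )
        for idx, row in df.iterrows()
    ]


def read_ply_points(path) -> np.ndarray:
    """Vertex coordinates of a PLY file, in file order."""
    import trimesh

    geom = trimesh.load(str(path), process=False)
    return np.asarray(geom.vertices, dtype=float)


def read_obj_points(path) -> np.ndarray:
    """Vertex (``v``) lines of an OBJ file, in file order."""
    pts = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("v "):
                pts.append([float(t) for t in line.split()[1:4]])
    return np.asarray(pts, dtype=float)


def read_landmark_file(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return read_ply_points(path)
    if path.suffix.lower() == ".obj":
        return read_obj_points(path)
    raise ValueError(f"unsupported landmark format: {path.suffix}")


def write_ply(path, points, scalar=None, colors=None, color_limit=None) -> None:
    """ASCII vertex-only PLY, optionally with a scalar field and colors.

    ``scalar`` is stored as a float ``quality`` property.  When ``colors``
    is omitted and a scalar is given, a red–blue diverging map centered at
    0 is applied (reds positive / affected-like, blues negative /
    normative-like); ``color_limit`` sets the symmetric saturation value
    (default: max |scalar|).
    """
    pts = np.asarray(points, dtype=float)
    if scalar is not None:
        scalar = np.asarray(scalar, dtype=float)
        if colors is None:
            from matplotlib import colormaps

            limit = color_limit or float(np.abs(scalar).max()) or 1.0
            normed = np.clip(scalar / (2.0 * limit) + 0.5, 0.0, 1.0)
            colors = (colormaps["coolwarm"](normed)[:, :3] * 255).astype(np.uint8)
    header = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(pts)}",
        "property float x",
        "property float y",
        "property float z",
    ]
    if scalar is not None:
        header.append("property float quality")
    if colors is not None:
        header += [
            "property uchar red",
            "property uchar green",
            "property uchar blue",
        ]
    header.append("end_header")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for i, p in enumerate(pts):
            parts = [f"{v:.8g}" for v in p]
            if scalar is not None:
                parts.append(f"{scalar[i]:.8g}")
            if colors is not None:
                parts += [str(int(c)) for c in colors[i]]
            fh.write(" ".join(parts) + "\n")


# -- bilateral map -----------------------------------------------------------

def write_bilateral_map(path, bmap: BilateralMap) -> None:
    rows = [{"left": a, "right": b} for a, b in bmap.pairs]
    rows += [{"left": i, "right": i} for i in bmap.midline]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_bilateral_map(path) -> BilateralMap:
    df = pd.read_csv(path)
    pairs = [
        (int(r.left), int(r.right))
        for r in df.itertuples()
        if r.left != r.right
    ]
    midline = [int(r.left) for r in df.itertuples() if r.left == r.right]
    return BilateralMap(pairs=pairs, midline=midline)


# -- npz artifacts -----------------------------------------------------------

def save_aligned(path, aligned: AlignedSet) -> None:
    np.savez_compressed(
        path,
        format_version=FORMAT_VERSION,
        coordinates=aligned.coordinates,
        consensus=aligned.consensus,
        centroid_sizes=aligned.centroid_sizes,
        iterations=aligned.iterations,
        converged=aligned.converged,
        scan_ids=np.array(
            [s if s is not None else "" for s in aligned.scan_ids]
        ),
    )


def load_aligned(path) -> AlignedSet:
    with np.load(path, allow_pickle=False) as z:
        return AlignedSet(
            coordinates=z["coordinates"],
            consensus=z["consensus"],
            centroid_sizes=z["centroid_sizes"],
            iterations=int(z["iterations"]),
            converged=bool(z["converged"]),
            scan_ids=[s or None for s in z["scan_ids"].tolist()],
        )


def save_shape_space(path, space: ShapeSpace) -> None:
    np.savez_compressed(
        path,
        format_version=FORMAT_VERSION,
        consensus=space.consensus,
        components=space.components,
        eigenvalues=space.eigenvalues,
        n_retained=space.n_retained,
        n_samples=space.n_samples,
    )


def load_shape_space(path) -> ShapeSpace:
    with np.load(path, allow_pickle=False) as z:
        return ShapeSpace(
            consensus=z["consensus"],
            components=z["components"],
            eigenvalues=z["eigenvalues"],
            n_retained=int(z["n_retained"]),
            n_samples=int(z["n_samples"]),
        )


def save_axis(path, axis: PhenotypeAxis) -> None:
    np.savez_compressed(
        path,
        format_version=FORMAT_VERSION,
        group_vector_pc=axis.group_vector_pc,
        group_vector_landmark=(
            axis.group_vector_landmark
            if axis.group_vector_landmark is not None
            else np.zeros((0, 3))
        ),
        regression_coeffs=axis.regression_coeffs,
        age_center=axis.age_center,
        norm_v=axis.norm_v,
        count_normative=axis.fit_sample_counts.get("normative", 0),
        count_affected=axis.fit_sample_counts.get("affected", 0),
    )


def load_axis(path) -> PhenotypeAxis:
    with np.load(path, allow_pickle=False) as z:
        v_land = z["group_vector_landmark"]
        return PhenotypeAxis(
            group_vector_pc=z["group_vector_pc"],
            group_vector_landmark=v_land if v_land.size else None,
            norm_v=float(z["norm_v"]),
            regression_coeffs=z["regression_coeffs"],
            age_center=float(z["age_center"]),
            fit_sample_counts={
                "normative": int(z["count_normative"]),
                "affected": int(z["count_affected"]),
            },
        )
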