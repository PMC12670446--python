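import numpy as np
import pandas as pd
import pytest

import morphoscore as ms


def random_similarity(points: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply a random rotation, translation and positive scale."""
    q = rng.standard_normal(4)
    w, x, y, z = q / np.linalg.norm(q)
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    scale = rng.uniform(0.5, 2.0)
    translation = rng.uniform(-10.0, 10.0, size=3)
    return scale * points @ rot + translation


@pytest.fixture(scope="session")
def template60():
    """A 60-landmark symmetric template with its bilateral map."""
    return ms.make_template(n_pairs=25, n_midline=10, seed=11)


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study run through align -> PCA -> axis fit.

    Session-scoped: several test modules reuse it for scoring and
    heatmap checks.
    """
    spec = ms.CohortSpec(
        n_normative=60, n_achondro=40, n_treated=5, visits_per_treated=4,
        seed=42,
    )
    samples, metadata, truth = ms.simulate_cohort(spec)
    symmetrized = [ms.symmetrize(s, truth.bilateral_map) for s in samples]
    aligned = ms.gpa(symmetrized)
    space = ms.fit_pca(aligned)
    space.n_retained = max(ms.parallel_analysis(aligned, seed=0), 1)
    scores_pc = np.stack([ms.project(p, space) for p in aligned.coordinates])
    is_control = metadata["group"].isin(
        [ms.GROUP_NORMATIVE, ms.GROUP_ACHONDRO]
    ).to_numpy()
    ctrl = metadata[is_control]
    axis = ms.fit_phenotype_axis(
        scores_pc[is_control],
        ctrl["age_years"].to_numpy(),
        ctrl["sex"].to_numpy(),
        (ctrl["group"] == ms.GROUP_ACHONDRO).astype(float).to_numpy(),
        space=space,
    )
    return {
        "spec": spec,
        "metadata": metadata,
        "truth": truth,
        "aligned": aligned,
        "space": space,
        "scores_pc": scores_pc,
        "axis": axis,
    }
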