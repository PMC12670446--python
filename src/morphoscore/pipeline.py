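"""End-to-end study orchestration.

Runs the full analysis in the order the method is defined: obtain landmark
configurations (simulated or loaded), bilaterally symmetrize each scan,
generalized-Procrustes align the pooled sample, fit the shape-space PCA
with parallel-analysis retention, fit the phenotype axis on the control
groups (treated scans are pooled into the PCA but excluded from the axis
regression), score every scan, standardize against the affected controls,
test and apply the control age correction, run the paired Hotelling test
on first-vs-last treated visits and the longitudinal mixed model, and
write per-subject heatmap pairs.

Every stage writes its artifact into the output directory so any stage can
be re-run independently; a manifest and a run log (seed, package versions,
stage timings) are always produced.  The whole run is deterministic under
a fixed seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, StageError
from .inference import fit_score_lmm, paired_hotelling
from .io import (
    read_bilateral_map,
    read_landmarks_csv,
    save_aligned,
    save_axis,
    save_shape_space,
    write_bilateral_map,
    write_landmarks_csv,
    write_ply,
)
from .scoring import (
    GROUP_ACHONDRO,
    GROUP_NORMATIVE,
    GROUP_TREATED,
    age_standardize,
    fit_phenotype_axis,
    score_cohort,
    standardize_scores,
    vertex_score_change,
    vertex_scores,
)
from .shape_space import fit_pca, parallel_analysis, project
from .superimposition import gpa, symmetrize
from .synthetic_cohort import CohortSpec, simulate_cohort

logger = logging.getLogger("morphoscore")

#: dimensionality cap used for the paired Hotelling test ("auto" mode)
HOTELLING_DIM_CAP = 13


@dataclass
class StudyConfig:
    """Configuration for one study run.

    Exactly one input source must be given: a :class:`CohortSpec` for
    simulation, or paths to a landmarks CSV + metadata CSV + bilateral map
    CSV.  ``hotelling_dims`` is an integer or ``"auto"``
    (min(13, n_pairs − 1)).  ``seed`` drives simulation and the
    parallel-analysis permutations and is recorded in every output.
    """

    cohort: CohortSpec | None = None
    landmarks_path: str | None = None
    metadata_path: str | None = None
    bilateral_map_path: str | None = None
    n_permutations: int = 100
    percentile: float = 95.0
    pa_method: str = "permutation"
    alpha: float = 0.05
    hotelling_dims: int | str = "auto"
    seed: int = 0
    out_dir: str = "study_out"

    def __post_init__(self):
        simulated = self.cohort is not None
        loaded = self.landmarks_path is not None
        if simulated == loaded:
            raise ConfigurationError(
                "provide exactly one of: a cohort spec, or data paths"
            )
        if loaded and (self.metadata_path is None or self.bilateral_map_path is None):
            raise ConfigurationError(
                "loading data requires metadata_path and bilateral_map_path"
            )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw and raw["cohort"] is not None:
            cohort = raw["cohort"]
            if "age_range_years" in cohort:
                cohort["age_range_years"] = tuple(cohort["age_range_years"])
            if "growth_coeffs" in cohort:
                cohort["growth_coeffs"] = tuple(cohort["growth_coeffs"])
            raw["cohort"] = CohortSpec(**cohort)
        return cls(**raw)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_study(config: StudyConfig) -> dict:
    """Execute every stage of the study; returns the report dictionary.

    On a stage failure a :class:`StageError` naming the stage is raised
    after a manifest of the artifacts completed so far has been written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    timings: dict[str, float] = {}
    report: dict = {"seed": config.seed, "version": __version__}
    state: dict = {}

    def _write_manifest():
        (out / "manifest.json").write_text(
            json.dumps({"artifacts": manifest, "timings": timings}, indent=2)
        )

    def run_stage(name, fn):
        logger.info("stage %s ...", name)
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            _write_manifest()
            raise StageError(name, str(exc)) from exc
        timings[name] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", name, timings[name])

    def stage_input():
        if config.cohort is not None:
            spec = replace(config.cohort, seed=config.seed)
            samples, metadata, truth = simulate_cohort(spec)
            state["truth"] = truth
            state["bmap"] = truth.bilateral_map
            write_landmarks_csv(out / "landmarks.csv", samples)
            write_bilateral_map(out / "bilateral_map.csv", state["bmap"])
            manifest.extend(["landmarks.csv", "bilateral_map.csv"])
        else:
            samples = read_landmarks_csv(config.landmarks_path)
            metadata = pd.read_csv(config.metadata_path)
            state["bmap"] = read_bilateral_map(config.bilateral_map_path)
        metadata.to_csv(out / "metadata.csv", index=False)
        manifest.append("metadata.csv")
        state["samples"] = samples
        state["metadata"] = metadata.reset_index(drop=True)

    def stage_symmetrize():
        state["symmetrized"] = [
            symmetrize(s, state["bmap"]) for s in state["samples"]
        ]

    def stage_align():
        aligned = gpa(state["symmetrized"])
        save_aligned(out / "aligned.npz", aligned)
        manifest.append("aligned.npz")
        state["aligned"] = aligned
        report["gpa"] = {
            "iterations": aligned.iterations,
            "converged": aligned.converged,
            "n_samples": aligned.n_samples,
            "n_landmarks": aligned.n_landmarks,
        }

    def stage_space():
        aligned = state["aligned"]
        pa_seed = np.random.SeedSequence(config.seed).spawn(1)[0]
        space = fit_pca(aligned)
        n_ret = parallel_analysis(
            aligned,
            n_permutations=config.n_permutations,
            percentile=config.percentile,
            seed=pa_seed,
            method=config.pa_method,
        )
        space.n_retained = max(n_ret, 1)  # downstream scoring needs >= 1 PC
        save_shape_space(out / "shapespace.npz", space)
        manifest.append("shapespace.npz")
        state["space"] = space
        report["shape_space"] = {
            "n_retained": space.n_retained,
            "variance_explained_pct": float(
                100.0 * space.variance_explained_cum[space.n_retained - 1]
            ),
        }

    def stage_axis():
        space = state["space"]
        meta = state["metadata"]
        scores_pc = np.stack(
            [
                project(p, space)
                for p in state["aligned"].coordinates
            ]
        )
        state["scores_pc"] = scores_pc
        is_control = meta["group"].isin([GROUP_NORMATIVE, GROUP_ACHONDRO])
        ctrl = meta[is_control]
        axis = fit_phenotype_axis(
            scores_pc[is_control.to_numpy()],
            ctrl["age_years"].to_numpy(),
            ctrl["sex"].to_numpy(),
            (ctrl["group"] == GROUP_ACHONDRO).astype(float).to_numpy(),
            space=space,
        )
        save_axis(out / "axis.npz", axis)
        manifest.append("axis.npz")
        state["axis"] = axis
        report["axis"] = {
            "norm_v": axis.norm_v,
            "fit_sample_counts": axis.fit_sample_counts,
        }

    def stage_scores():
        meta = state["metadata"]
        axis = state["axis"]
        scored = score_cohort(state["scores_pc"], meta, axis)
        scored = standardize_scores(scored)
        controls = scored[scored["group"] == GROUP_ACHONDRO]
        treated = scored[scored["group"] == GROUP_TREATED]
        if len(treated) and len(controls) >= 3:
            treated_std, age_test = age_standardize(
                treated,
                controls["normalized_score"].to_numpy(),
                controls["age_years"].to_numpy(),
                alpha=config.alpha,
            )
            scored.loc[treated_std.index, "age_standardized_score"] = (
                treated_std["age_standardized_score"]
            )
            report["control_age_effect"] = {
                "slope": age_test.slope,
                "t": age_test.t_stat,
                "p_value": age_test.p_value,
                "significant": age_test.significant,
            }
        scored.to_csv(out / "scores.csv", index=False)
        manifest.append("scores.csv")
        state["scores"] = scored
        by_group = scored.groupby("group")["normalized_score"].mean()
        report["mean_normalized_score"] = by_group.to_dict()

    def _first_last(meta):
        """Row indices of each treated subject's first and last visit."""
        treated = meta[meta["group"] == GROUP_TREATED]
        firsts, lasts = [], []
        for _, sub in treated.groupby("subject_id"):
            sub = sub.sort_values("age_years")
            firsts.append(sub.index[0])
            lasts.append(sub.index[-1])
        return firsts, lasts

    def stage_hotelling():
        meta = state["metadata"]
        space = state["space"]
        firsts, lasts = _first_last(meta)
        if len(firsts) < 2:
            report["hotelling"] = None
            return
        n_pairs = len(firsts)
        if config.hotelling_dims == "auto":
            dims = min(HOTELLING_DIM_CAP, n_pairs - 1)
        else:
            dims = int(config.hotelling_dims)
        dims = min(dims, len(space.eigenvalues))
        coords = state["aligned"].coordinates
        first_pc = np.stack([project(coords[i], space, dims) for i in firsts])
        last_pc = np.stack([project(coords[i], space, dims) for i in lasts])
        result = paired_hotelling(first_pc, last_pc, n_dims=dims)
        report["hotelling"] = result.as_dict()

    def stage_lmm():
        scored = state["scores"]
        treated = scored[scored["group"] == GROUP_TREATED]
        if treated["subject_id"].nunique() < 2:
            report["lmm"] = None
            return
        score_col = (
            "age_standardized_score"
            if "age_standardized_score" in treated.columns
            else "normalized_score"
        )
        result = fit_score_lmm(treated, score_col=score_col)
        report["lmm"] = result.as_dict()
        report["lmm"]["score_column"] = score_col

    def stage_heatmaps():
        meta = state["metadata"]
        space = state["space"]
        axis = state["axis"]
        coords = state["aligned"].coordinates
        heat_dir = out / "heatmaps"
        heat_dir.mkdir(exist_ok=True)
        firsts, lasts = _first_last(meta)
        for i_first, i_last in zip(firsts, lasts):
            subject = meta.loc[i_first, "subject_id"]
            fields = {}
            for tag, idx in (("first", i_first), ("last", i_last)):
                fields[tag] = vertex_scores(
                    coords[idx],
                    meta.loc[idx, "age_years"],
                    meta.loc[idx, "sex"],
                    axis,
                    space,
                )
            change = vertex_score_change(fields["first"], fields["last"])
            write_ply(
                heat_dir / f"{subject}_first.ply", coords[i_first],
                scalar=fields["first"],
            )
            write_ply(
                heat_dir / f"{subject}_change.ply", coords[i_last],
                scalar=change,
            )
            manifest.extend(
                [f"heatmaps/{subject}_first.ply", f"heatmaps/{subject}_change.ply"]
            )

    def stage_report():
        (out / "inference.json").write_text(
            json.dumps(report, indent=2, default=_json_default)
        )
        run_log = {
            "seed": config.seed,
            "morphoscore_version": __version__,
            "numpy_version": np.__version__,
            "stage_timings_s": timings,
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
        manifest.extend(["inference.json", "run_log.json"])
        _write_manifest()
        manifest.append("manifest.json")

    run_stage("input", stage_input)
    run_stage("symmetrize", stage_symmetrize)
    run_stage("align", stage_align)
    run_stage("shape_space", stage_space)
    run_stage("axis", stage_axis)
    run_stage("scores", stage_scores)
    run_stage("hotelling", stage_hotelling)
    run_stage("lmm", stage_lmm)
    run_stage("heatmaps", stage_heatmaps)
    run_stage("report", stage_report)
    return report
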