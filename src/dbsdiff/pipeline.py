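"""End-to-end orchestration of the pre/post synthetic study.

``run_study`` ties the stages together: phantom generation → per-session
simulation (noise, artifact, motion) → motion correction → quality metrics
→ tensor scalars → ROI statistics → ball-and-stick fit → tractography →
connectivity tables.  Every stochastic stage draws its RNG seed from the
master seed combined with the stage name, so stages are independently
reproducible and a rerun with the same master seed is bit-identical.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import __version__
from .connectivity import (
    compare_connection_maps,
    connectivity_metrics,
    connectivity_table,
    percent_change,
)
from .dwi import DWIVolume, save_session
from .gradients import make_scheme
from .phantom import Phantom, apply_motion, build_study_phantom, simulate_dwi
from .preprocess import MotionReport, register_to_b0, summarize_motion
from .quality import QualityReport, quality_report
from .rigid import RigidTransform, random_rigid_transforms
from .roistats import (
    analyze_rois,
    classify_affected,
    cohort_summary,
    extract_roi_samples,
    results_table,
)
from .tensor import fit_tensor, scalar_map
from .tract import BallStickOptions, TrackingParams, fit_ball_and_stick, track


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed (< 2³¹) from the master seed and stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class TractSpec:
    name: str
    seed_roi: str
    target_roi: str


DEFAULT_TRACTS = (
    TractSpec("nigrostriatal", "ns_seed", "ns_target"),
    TractSpec("dentatorubrothalamic", "drt_seed", "drt_target"),
    TractSpec("hyperdirect", "hd_seed", "hd_target"),
)


@dataclass
class StudyConfig:
    """Everything that determines one synthetic pre/post study.

    The two sessions differ only through the post-session noise level,
    motion, and artifact — the controllable encoding of the 3 T anesthetized
    pre-operative versus 1.5 T awake implanted post-operative contrast.
    """

    sigma_pre: float = 5.0
    sigma_post: float = 40.0
    with_artifact: bool = True
    artifact_attenuation: float = 0.1
    motion_max_translation_mm: float = 1.0
    motion_max_rotation_deg: float = 1.0
    register: bool = True
    n_directions: int = 32
    b_value: float = 800.0
    scalars: tuple[str, ...] = ("fa", "md", "rd")
    tracts: tuple[TractSpec, ...] = DEFAULT_TRACTS
    tracking: TrackingParams = field(default_factory=lambda: TrackingParams(samples=500))
    mcmc: BallStickOptions = field(default_factory=BallStickOptions)
    fit_mask: str = "brain"          # "brain" or "wm" (dilated white matter)
    alpha: float = 0.05
    master_seed: int = 0
    out_dir: str | Path | None = None

    @classmethod
    def fast(cls, **overrides) -> "StudyConfig":
        """A reduced configuration for quick runs: fewer tracking samples,
        shorter chains, no injected motion and registration off; the fiber
        model is fitted on the dilated white-matter mask only."""
        defaults = dict(
            register=False,
            motion_max_translation_mm=0.0,
            motion_max_rotation_deg=0.0,
            tracking=TrackingParams(samples=100),
            mcmc=BallStickOptions(burn_in=200, n_samples=50, thin=1),
            fit_mask="wm",
        )
        defaults.update(overrides)
        return cls(**defaults)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs written so far are kept."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage


@dataclass
class StudyResult:
    config: StudyConfig
    phantom: Phantom
    sessions: dict[str, DWIVolume]
    motion_reports: dict[str, MotionReport]
    quality_reports: dict[str, QualityReport]
    scalar_maps: dict[tuple[str, str], object]     # (session, kind) → ScalarMap
    roi_results: list
    roi_table: pd.DataFrame
    cohort: dict
    tract_results: dict[tuple[str, str], object]   # (tract, session) → TractographyResult
    connectivity: pd.DataFrame
    manifest: dict


def _default_motion(config: StudyConfig, n_volumes: int, b0_index: int, seed: int):
    rng = np.random.default_rng(seed)
    transforms = random_rigid_transforms(
        n_volumes, config.motion_max_translation_mm, config.motion_max_rotation_deg, rng
    )
    transforms[b0_index] = RigidTransform.identity()
    return transforms


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full pre/post workflow deterministically under the master seed."""
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "versions": {"numpy": np.__version__},
        "master_seed": config.master_seed,
        "stage_seeds": {},
        "warnings": [],
        "parameters": {
            "sigma_pre": config.sigma_pre,
            "sigma_post": config.sigma_post,
            "artifact_attenuation": config.artifact_attenuation
            if config.with_artifact else None,
            "tracking_samples": config.tracking.samples,
            "step_mm": config.tracking.step_mm,
            "curvature": config.tracking.curvature,
            "alpha": config.alpha,
        },
    }

    def seed_for(stage: str) -> int:
        s = stage_seed(config.master_seed, stage)
        manifest["stage_seeds"][stage] = s
        return s

    caught: list[str] = []

    def run_stage(name, fn):
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                result = fn()
            caught.extend(f"{name}: {w.message}" for w in wlist)
            return result
        except Exception as exc:  # noqa: BLE001 — annotate stage and re-raise
            raise PipelineStageError(name, exc) from exc

    # ---- generate ---------------------------------------------------------
    def gen():
        phantom = build_study_phantom(
            artifact_attenuation=config.artifact_attenuation,
            with_artifact=config.with_artifact,
            sigma_pre=config.sigma_pre,
            sigma_post=config.sigma_post,
        )
        scheme = make_scheme(config.n_directions, config.b_value)
        pre = simulate_dwi(phantom, scheme, config.sigma_pre,
                           seed=seed_for("simulate-pre"), session="pre")
        use_artifact = config.with_artifact and phantom.artifact_mask.any()
        # signal dropout enters before the noise: susceptibility artifact
        # kills signal at acquisition, thermal noise is unchanged
        post = simulate_dwi(
            phantom, scheme, config.sigma_post,
            seed=seed_for("simulate-post"), session="post",
            dropout_mask=phantom.artifact_mask if use_artifact else None,
            dropout_attenuation=config.artifact_attenuation,
        )
        truth: dict = {}
        if config.motion_max_translation_mm > 0 or config.motion_max_rotation_deg > 0:
            transforms = _default_motion(
                config, post.n_volumes, post.b0_index, seed_for("motion-post")
            )
            post = apply_motion(post, transforms)
            truth["true_motion"] = post.meta["true_motion"]
        return phantom, pre, post, truth

    phantom, pre, post, truth = run_stage("generate", gen)
    if out_dir is not None:
        save_session(pre, out_dir / "pre")
        save_session(post, out_dir / "post", truth=truth)

    # ---- preprocess -------------------------------------------------------
    motion_reports: dict[str, MotionReport] = {}
    sessions = {"pre": pre, "post": post}
    if config.register:
        def preprocess():
            out = {}
            for name, dwi in sessions.items():
                corrected, report = register_to_b0(dwi)
                out[name] = (corrected, report)
            return out
        corrected = run_stage("preprocess", preprocess)
        sessions = {k: v[0] for k, v in corrected.items()}
        motion_reports = {k: v[1] for k, v in corrected.items()}
        if out_dir is not None:
            for name, rep in motion_reports.items():
                rep.save(out_dir / f"motion_{name}.csv",
                         out_dir / f"motion_{name}.json")

    # ---- quality ----------------------------------------------------------
    def quality():
        return {name: quality_report(dwi) for name, dwi in sessions.items()}

    quality_reports = run_stage("quality", quality)
    if out_dir is not None:
        for name, rep in quality_reports.items():
            rep.save(out_dir / f"quality_{name}.csv", out_dir / f"quality_{name}.json")

    # ---- tensor scalars ---------------------------------------------------
    def scalars():
        maps = {}
        for name, dwi in sessions.items():
            tf = fit_tensor(dwi)
            for kind in config.scalars:
                maps[(name, kind)] = scalar_map(tf, kind, session=name)
        return maps

    maps = run_stage("tensor", scalars)
    if out_dir is not None:
        for (name, kind), m in maps.items():
            m.save(out_dir / f"{name}_{kind}.nii.gz")

    # ---- ROI statistics ---------------------------------------------------
    def roistats():
        affected, frac = classify_affected(
            phantom.roi_labels, phantom.artifact_mask, phantom.spec.roi_defs
        )
        results = []
        for kind in config.scalars:
            samples = extract_roi_samples(
                maps[("pre", kind)], maps[("post", kind)],
                phantom.roi_labels, phantom.spec.roi_defs, affected,
            )
            results.extend(analyze_rois(samples, alpha=config.alpha))
        table = results_table(results)
        summary = cohort_summary(results)
        summary["fraction_rois_affected"] = frac
        return results, table, summary

    roi_results, roi_table, cohort = run_stage("roistats", roistats)
    if out_dir is not None:
        roi_table.to_csv(out_dir / "roi_comparisons.csv", index=False)
        with open(out_dir / "cohort_summary.json", "w") as fh:
            json.dump(cohort, fh, indent=2)

    # ---- tractography + connectivity --------------------------------------
    tract_results: dict[tuple[str, str], object] = {}
    conn_df = pd.DataFrame()
    if config.tracts:
        def fit_models():
            models = {}
            for name, dwi in sessions.items():
                if config.fit_mask == "wm":
                    fmask = ndimage.binary_dilation(dwi.mask("wm"), iterations=2)
                    fmask &= dwi.brain_mask
                else:
                    fmask = dwi.brain_mask
                models[name] = fit_ball_and_stick(
                    dwi, mask=fmask, options=config.mcmc,
                    seed=seed_for(f"bedpost-{name}"),
                )
            return models

        models = run_stage("fit-ball-and-stick", fit_models)

        def tracking():
            rows = []
            for tspec in config.tracts:
                seed_m = phantom.roi_mask(phantom.spec.roi_defs[tspec.seed_roi])
                target_m = phantom.roi_mask(phantom.spec.roi_defs[tspec.target_roi])
                row: dict = {"tract": tspec.name}
                for name in ("pre", "post"):
                    res = track(
                        models[name], seed_m, target_m,
                        params=config.tracking,
                        termination_mask=sessions[name].brain_mask,
                        seed=seed_for(f"track-{tspec.name}-{name}"),
                    )
                    tract_results[(tspec.name, name)] = res
                    met = connectivity_metrics(res, tract=tspec.name, session=name)
                    row[f"index_{name}"] = met.index
                    row[f"density_{name}"] = met.density
                row["index_percent_change"] = percent_change(
                    row["index_pre"], row["index_post"]
                )
                row["density_percent_change"] = percent_change(
                    row["density_pre"], row["density_post"]
                )
                p, similar = compare_connection_maps(
                    tract_results[(tspec.name, "pre")],
                    tract_results[(tspec.name, "post")],
                    target_m,
                )
                row["welch_p"] = p
                rows.append(row)
            return connectivity_table(rows)

        conn_df = run_stage("connectivity", tracking)
        if out_dir is not None:
            from .dwi import save_nifti

            tdir = out_dir / "tracts"
            tdir.mkdir(exist_ok=True)
            for (tname, sname), res in tract_results.items():
                save_nifti(res.success_counts, pre.voxel_size,
                           tdir / f"{tname}_{sname}_success.nii.gz", dtype=np.uint32)
                save_nifti(res.visitation, pre.voxel_size,
                           tdir / f"{tname}_{sname}_visitation.nii.gz", dtype=np.uint32)
            conn_df.to_csv(out_dir / "connectivity.csv", index=False)

    # ---- manifest ---------------------------------------------------------
    manifest["warnings"] = caught
    if motion_reports:
        manifest["motion"] = summarize_motion(
            motion_reports["post"], motion_reports["pre"]
        ) if len(motion_reports) == 2 else {}
    manifest["quality"] = {
        name: {"snr": rep.snr, "cnr": rep.cnr} for name, rep in quality_reports.items()
    }
    if out_dir is not None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    return StudyResult(
        config=config,
        phantom=phantom,
        sessions=sessions,
        motion_reports=motion_reports,
        quality_reports=quality_reports,
        scalar_maps=maps,
        roi_results=roi_results,
        roi_table=roi_table,
        cohort=cohort,
        tract_results=tract_results,
        connectivity=conn_df,
        manifest=manifest,
    )
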