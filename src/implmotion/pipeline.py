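"""End-to-end displacement workflow for one or many valgus/varus scan pairs.

Stages, in order: segmentation masks (supplied as files — the socket where
external deep-learning predictions plug in — or grown from seeds), mask
post-processing (largest component, margin carving around the implant),
marching-cubes meshing, ICP rough alignment of the implant, double-contour
sampling in the valgus scan, point-to-image refinement against the varus
scan for implant and tibia, and finally the implant-relative-to-bone
motion with its three displacement parameters (rScrew, MTPM, mTRE).

The implant is registered first, then the tibia; all intermediate
artifacts (transforms, meshes, heatmap PLY, outcome JSON, machine-readable
run log) can be written to a per-pair working directory for auditability.
A non-converged registration is flagged in the result and the log, never
silently accepted.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics, segment, stats
from .kinematics import DisplacementOutcome, heatmap_colors
from .register import RegistrationOptions, RegistrationResult, register_object
from .surface import TriMesh, extract_mesh, save_mesh
from .volio import (
    ImageVolume,
    LabelVolume,
    RigidTransform,
    LABEL_IMPLANT,
    LABEL_CORTICAL,
    read_volume,
    write_transform,
)

__all__ = [
    "PipelineConfig",
    "PairMasks",
    "PipelineError",
    "PairResult",
    "run_pair",
    "run_pair_files",
    "run_batch",
]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one workflow run.

    ``segmentation_mode`` is ``"masks-supplied"`` (default; external
    segmentations enter as ordinary mask files) or ``"region-grow"``
    (seeded thresholding reproducing the semi-automatic arm; requires the
    seed and threshold fields).  ``margin_radius_mm`` defaults to the 3 mm
    safety margin carved out of the bone around the implant.
    """

    segmentation_mode: str = "masks-supplied"
    implant_seed_valgus: tuple[int, int, int] | None = None
    implant_seed_varus: tuple[int, int, int] | None = None
    bone_seed: tuple[int, int, int] | None = None
    implant_low: float | None = None
    implant_high: float = np.inf
    bone_low: float | None = None
    bone_high: float = np.inf
    margin_radius_mm: float = 3.0
    contour_offset_mm: float = 0.3
    registration: RegistrationOptions = field(default_factory=RegistrationOptions)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.segmentation_mode not in ("masks-supplied", "region-grow"):
            raise ValueError(f"unknown segmentation_mode {self.segmentation_mode!r}")


@dataclass
class PairMasks:
    """The three masks one pair needs: implant in both scans, bone in valgus."""

    implant_valgus: LabelVolume
    implant_varus: LabelVolume
    bone_valgus: LabelVolume


@dataclass
class PairResult:
    """Everything one pair produces."""

    outcome: DisplacementOutcome
    t_implant: RigidTransform
    t_bone: RigidTransform
    t_relative: RigidTransform
    implant_registration: RegistrationResult
    bone_registration: RegistrationResult
    implant_mesh: TriMesh
    log: dict


def _binary(mask: LabelVolume, label: int) -> LabelVolume:
    return LabelVolume(
        grid=(mask.grid == label).astype(np.int16), spacing=mask.spacing, origin=mask.origin
    )


def _segment_pair(valgus: ImageVolume, varus: ImageVolume, config: PipelineConfig) -> PairMasks:
    if config.implant_low is None or config.bone_low is None:
        raise PipelineError("segmentation", "region-grow mode requires implant_low and bone_low")
    for name, seed in (
        ("implant_seed_valgus", config.implant_seed_valgus),
        ("implant_seed_varus", config.implant_seed_varus),
        ("bone_seed", config.bone_seed),
    ):
        if seed is None:
            raise PipelineError("segmentation", f"region-grow mode requires {name}")
    implant_valgus = segment.region_grow(
        valgus, config.implant_seed_valgus, config.implant_low, config.implant_high
    )
    implant_varus = segment.region_grow(
        varus, config.implant_seed_varus, config.implant_low, config.implant_high
    )
    bone_valgus = segment.region_grow(valgus, config.bone_seed, config.bone_low, config.bone_high)
    return PairMasks(implant_valgus, implant_varus, bone_valgus)


def run_pair(
    valgus: ImageVolume,
    varus: ImageVolume,
    config: PipelineConfig | None = None,
    masks: PairMasks | None = None,
    out_dir: str | Path | None = None,
) -> PairResult:
    """Run the full workflow on one scan pair.

    In mask-supplied mode ``masks`` must be given; label code 1 marks the
    implant and any nonzero bone code marks bone (code 2, cortical, is
    used when present).  Artifacts are written under ``out_dir`` when
    given.
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}

    def timed(stage: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        timings[stage] = time.perf_counter() - t0
        return result

    if config.segmentation_mode == "region-grow":
        masks = timed("segmentation", _segment_pair, valgus, varus, config)
    elif masks is None:
        raise PipelineError("segmentation", "masks-supplied mode requires a PairMasks object")

    # Post-processing: largest component per class, then carve the margin.
    def postprocess() -> tuple[LabelVolume, LabelVolume, LabelVolume]:
        implant_v = segment.largest_component(_binary(masks.implant_valgus, LABEL_IMPLANT))
        implant_r = segment.largest_component(_binary(masks.implant_varus, LABEL_IMPLANT))
        bone_label = (
            LABEL_CORTICAL if (masks.bone_valgus.grid == LABEL_CORTICAL).any() else 1
        )
        bone = segment.largest_component(_binary(masks.bone_valgus, bone_label))
        bone = segment.carve_margin(bone, implant_v, radius_mm=config.margin_radius_mm)
        return implant_v, implant_r, bone

    implant_mask_v, implant_mask_r, bone_mask = timed("postprocess", postprocess)

    implant_mesh = timed("mesh_implant", extract_mesh, implant_mask_v, 1)
    implant_mesh_varus = timed("mesh_implant_varus", extract_mesh, implant_mask_r, 1)
    bone_mesh = timed("mesh_bone", extract_mesh, bone_mask, 1)

    reg_implant = timed(
        "register_implant",
        register_object,
        implant_mesh,
        valgus,
        varus,
        target_mesh_for_init=implant_mesh_varus,
        options=config.registration,
        offset_mm=config.contour_offset_mm,
    )
    reg_bone = timed(
        "register_bone",
        register_object,
        bone_mesh,
        valgus,
        varus,
        target_mesh_for_init=None,
        options=config.registration,
        offset_mm=config.contour_offset_mm,
    )

    t_rel = kinematics.relative_motion(reg_implant.transform, reg_bone.transform)
    outcome = kinematics.displacement_outcome(t_rel, implant_mesh.vertices)

    log = {
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "implant": {
            "correlation": reg_implant.final_correlation,
            "iterations": reg_implant.iterations_used,
            "converged": reg_implant.converged,
        },
        "bone": {
            "correlation": reg_bone.final_correlation,
            "iterations": reg_bone.iterations_used,
            "converged": reg_bone.converged,
        },
        "outcome": {
            "rscrew_deg": outcome.rscrew_deg,
            "mtpm_mm": outcome.mtpm_mm,
            "mtre_mm": outcome.mtre_mm,
        },
    }
    result = PairResult(
        outcome=outcome,
        t_implant=reg_implant.transform,
        t_bone=reg_bone.transform,
        t_relative=t_rel,
        implant_registration=reg_implant,
        bone_registration=reg_bone,
        implant_mesh=implant_mesh,
        log=log,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PairResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_transform(result.t_implant, out / "transform_implant.txt")
    write_transform(result.t_bone, out / "transform_bone.txt")
    write_transform(result.t_relative, out / "transform_relative.txt")
    save_mesh(result.implant_mesh, out / "implant.ply")
    colors = heatmap_colors(result.outcome.per_vertex_mm)
    save_mesh(result.implant_mesh, out / "implant_heatmap.ply", vertex_colors=colors)
    with open(out / "outcome.json", "w") as fh:
        json.dump(result.log["outcome"], fh, indent=2)
    with open(out / "run_log.json", "w") as fh:
        json.dump(result.log, fh, indent=2)


def run_pair_files(
    valgus_path: str | Path,
    varus_path: str | Path,
    implant_valgus_mask: str | Path,
    implant_varus_mask: str | Path,
    bone_valgus_mask: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PairResult:
    """File-based entry point: read volumes and masks, then run the pair."""
    for p in (valgus_path, varus_path, implant_valgus_mask, implant_varus_mask, bone_valgus_mask):
        if not Path(p).exists():
            raise PipelineError("inputs", f"missing input file: {p}")
    valgus = read_volume(valgus_path)
    varus = read_volume(varus_path)
    masks = PairMasks(
        implant_valgus=read_volume(implant_valgus_mask, as_labels=True),
        implant_varus=read_volume(implant_varus_mask, as_labels=True),
        bone_valgus=read_volume(bone_valgus_mask, as_labels=True),
    )
    return run_pair(valgus, varus, config=config, masks=masks, out_dir=out_dir)


def run_batch(
    manifest: pd.DataFrame,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every pair in a manifest and summarise per group.

    ``manifest`` columns: ``pair_id``, ``valgus_path``, ``varus_path``,
    ``implant_valgus_mask``, ``implant_varus_mask``, ``bone_valgus_mask``
    and ``group``.  Per-pair failures are recorded in the results table
    (column ``error``) and the batch continues.  Returns ``(results,
    summary)`` where the summary holds the median and bootstrap 95% CI of
    each parameter per group (R = 1000 resamples, seeded by
    ``config.seed``), plus Mann-Whitney p-values between group pairs.
    """
    config = config or PipelineConfig()
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    rows = []
    for _, row in manifest.iterrows():
        pair_out = None if out_dir is None else Path(out_dir) / str(row["pair_id"])
        record = {"pair_id": row["pair_id"], "group": row.get("group", ""), "error": ""}
        try:
            result = run_pair_files(
                row["valgus_path"],
                row["varus_path"],
                row["implant_valgus_mask"],
                row["implant_varus_mask"],
                row["bone_valgus_mask"],
                config=config,
                out_dir=pair_out,
            )
            record.update(
                rscrew_deg=result.outcome.rscrew_deg,
                mtpm_mm=result.outcome.mtpm_mm,
                mtre_mm=result.outcome.mtre_mm,
                implant_converged=result.implant_registration.converged,
                bone_converged=result.bone_registration.converged,
            )
        except Exception as exc:  # record and continue
            record["error"] = str(exc)
        rows.append(record)
    results = pd.DataFrame(rows)

    params = ["rscrew_deg", "mtpm_mm", "mtre_mm"]
    ok = results[results["error"] == ""]
    summary_rows = []
    for group, sub in ok.groupby("group"):
        for param in params:
            ci = stats.bootstrap_median_ci(sub[param].to_numpy(), reps=1000, seed=config.seed)
            summary_rows.append(
                {
                    "group": group,
                    "parameter": param,
                    "median": ci.estimate,
                    "ci_low": ci.ci_low,
                    "ci_high": ci.ci_high,
                }
            )
    groups = sorted(ok["group"].unique())
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            for param in params:
                p = stats.mann_whitney_u(
                    ok.loc[ok["group"] == ga, param].to_numpy(),
                    ok.loc[ok["group"] == gb, param].to_numpy(),
                )
                summary_rows.append(
                    {"group": f"{ga} vs {gb}", "parameter": param, "p_value": p}
                )
    summary = pd.DataFrame(summary_rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        results.to_csv(Path(out_dir) / "results.csv", index=False)
        summary.to_csv(Path(out_dir) / "summary.csv", index=False)
    return results, summary
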