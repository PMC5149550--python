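"""End-to-end study pipeline: movement -> perception -> gaze -> summary.

``run_pipeline`` composes the analysis stages over a study bundle (in
memory or on disk) and writes movement scores, heat maps, the perception
report, the movement-perception association, the gaze report and one
machine-readable ``summary.json``.  The run is idempotent for fixed
inputs: identical inputs produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from PIL import Image

from . import gaze as _gaze
from . import io as _io
from . import motion as _motion
from . import perception as _perception
from .stats import TestResult
from .synthetic import StudyBundle

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]

logger = logging.getLogger("fiblab.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline.

    ``tau`` is the fixed pixel-change threshold (0-255); ``crop_width``
    the central crop applied to real camera frames (skipped when the
    frames are already narrower); ``tolerance`` the AOI reassignment
    distance in pixels; ``alpha`` the significance level quoted in the
    summary; ``kernel_sigma`` and ``coverage_quantile`` control the
    fixation heat and focus maps.
    """

    tau: int = 25
    crop_width: int | None = 801
    tolerance: float = 15.0
    alpha: float = 0.05
    colormap: str = "afmhot"
    kernel_sigma: float = 4.0
    coverage_quantile: float = 0.75
    seed: int = 0
    threshold_after_averaging: bool = False
    render_heatmaps: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.tau <= 255:
            raise ValueError("tau must lie in 0-255")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, TestResult):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def _movement_stage(bundle: StudyBundle, config: PipelineConfig, out: Path,
                    study_dir: Path | None) -> pd.DataFrame:
    clips = bundle.clips
    if clips is None:
        if study_dir is None or not (study_dir / "clips").is_dir():
            if bundle.movement is not None:
                logger.info("motion: no clip media, reusing stored movement scores")
                return bundle.movement
            raise StageError("motion", "bundle has neither clip media nor movement scores")
        clips = [
            _io.read_frames(study_dir / "clips" / meta["clip_id"], clip_id=meta["clip_id"])
            for meta in bundle.manifest["clips"]
        ]
        for clip, meta in zip(clips, bundle.manifest["clips"]):
            clip.condition = meta.get("condition")
    child_by_clip = {m["clip_id"]: m.get("child_id") for m in bundle.manifest["clips"]}
    rows = []
    heat_dir = out / "heatmaps"
    heat_dir.mkdir(parents=True, exist_ok=True)
    for clip in clips:
        if config.crop_width is not None and config.crop_width < clip.width:
            clip = _motion.crop_central(clip, config.crop_width)
        hm = _motion.movement_heatmap(
            clip, config.tau, threshold_after_averaging=config.threshold_after_averaging
        )
        per_region = _motion.region_scores(hm, bundle.bounds)
        rows.append(
            {
                "clip_id": clip.clip_id,
                "child_id": child_by_clip.get(clip.clip_id),
                "condition": clip.condition,
                "total": _motion.total_movement(hm),
                **per_region,
            }
        )
        pd.DataFrame(hm.values).to_csv(heat_dir / f"{clip.clip_id}.csv", index=False, header=False)
        if config.render_heatmaps:
            rgb = _motion.render_heatmap(hm, config.colormap)
            Image.fromarray(rgb).save(heat_dir / f"{clip.clip_id}.png")
    movement = pd.DataFrame(rows)
    _io.write_movement(movement, out / "movement_scores.csv")
    return movement


def _perception_stage(bundle: StudyBundle, movement: pd.DataFrame, out: Path) -> dict:
    ratings = bundle.ratings
    clip_scores = _perception.percent_lie_per_clip(ratings)
    clip_scores.to_csv(out / "clip_scores.csv", index=False)
    judge_scores = _perception.judge_condition_scores(ratings)
    report = _perception.condition_analysis(judge_scores)
    cues = _perception.cue_region_frequencies(ratings)
    association = _perception.movement_perception_association(clip_scores, movement)
    per_region = {}
    for region in ("head", "trunk", "legs"):
        if region in movement.columns:
            per_region[region] = _perception.movement_perception_association(
                clip_scores, movement, region
            )
    movement_tests = _perception.condition_movement_tests(movement)
    result = {
        "condition_analysis": report,
        "cue_region_frequencies": cues,
        "association": {"total": association, **per_region},
        "movement_tests": movement_tests,
    }
    with open(out / "perception_report.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(result), fh, indent=2, sort_keys=True)
    return result


def _gaze_stage(bundle: StudyBundle, config: PipelineConfig, out: Path) -> dict:
    conditions = {m["clip_id"]: m["condition"] for m in bundle.manifest["clips"]}
    table = _gaze.gaze_durations(
        bundle.fixations, bundle.aois, conditions, config.tolerance
    )
    table.durations.to_csv(out / "gaze_durations.csv", index=False)
    report = _gaze.gaze_region_analysis(table)
    screen = tuple(bundle.manifest.get("frame_size", [80, 108]))
    fx = bundle.fixations
    for cond in sorted(set(conditions.values())):
        cond_clips = {c for c, cc in conditions.items() if cc == cond}
        sub = fx[fx["clip_id"].isin(cond_clips)]
        heat = _gaze.fixation_heatmap(sub, screen, config.kernel_sigma)
        Image.fromarray((heat * 255).astype("uint8"), mode="L").save(
            out / f"fixation_heatmap_{cond}.png"
        )
        mask = _gaze.focus_map(heat, config.coverage_quantile)
        Image.fromarray((mask * 255).astype("uint8"), mode="L").save(
            out / f"focus_map_{cond}.png"
        )
    with open(out / "gaze_report.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report


def run_pipeline(
    study: StudyBundle | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "fiblab_out",
) -> Path:
    """Run movement, perception and gaze analyses over a study.

    ``study`` is a :class:`StudyBundle` or a path to a study directory in
    the documented layout.  Stages degrade gracefully: without ratings the
    perception stage is skipped, without fixations the gaze stage is
    skipped (each with a warning).  Writes ``summary.json`` and returns
    the output directory.
    """
    config = config or PipelineConfig()
    study_dir: Path | None = None
    if not isinstance(study, StudyBundle):
        study_dir = Path(study)
        bundle = _io.read_study(study_dir)
    else:
        bundle = study
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    summary: dict = {
        "config": dataclasses.asdict(config),
        "n_clips": bundle.n_clips,
        "n_children": bundle.manifest.get("n_children"),
        "stages": {},
    }

    logger.info("motion: scoring %d clips (tau=%d)", bundle.n_clips, config.tau)
    try:
        movement = _movement_stage(bundle, config, out, study_dir)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("motion", str(exc)) from exc
    summary["stages"]["motion"] = {
        "n_clips_scored": int(len(movement)),
        "mean_total_movement": float(movement["total"].mean()),
    }

    if bundle.ratings is None:
        logger.warning("perception: no ratings table, stage skipped")
        summary["stages"]["perception"] = {"skipped": True}
    else:
        try:
            perception = _perception_stage(bundle, movement, out)
        except Exception as exc:  # noqa: BLE001
            raise StageError("perception", str(exc)) from exc
        summary["stages"]["perception"] = _jsonable(perception)

    if bundle.fixations is None or bundle.aois is None:
        logger.warning("gaze: no fixations or AOIs, stage skipped")
        summary["stages"]["gaze"] = {"skipped": True}
    else:
        try:
            gaze_report = _gaze_stage(bundle, config, out)
        except Exception as exc:  # noqa: BLE001
            raise StageError("gaze", str(exc)) from exc
        summary["stages"]["gaze"] = _jsonable(gaze_report)

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out / "summary.json")
    return out
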