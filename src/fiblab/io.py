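"""Readers and writers for the study's file formats.

Everything tabular is plain CSV (comma-separated, UTF-8, header row,
``.`` decimal separator); clip media are PNG frame directories
(``frame_000001.png`` ...) or any video container a local imageio plugin
can decode; the study manifest is JSON.  Every writer's output round-trips
losslessly through its paired reader.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image

from .gaze import Aoi, AoiSet
from .motion import FrameSequence, RegionBounds, to_grayscale
from .synthetic import StudyBundle

__all__ = [
    "read_frames",
    "write_frames",
    "write_ratings",
    "read_ratings",
    "write_fixations",
    "read_fixations",
    "write_movement",
    "read_movement",
    "write_aois",
    "read_aois",
    "write_bounds",
    "read_bounds",
    "write_study",
    "read_study",
]

logger = logging.getLogger("fiblab.io")

FRAME_PATTERN = re.compile(r"\.(png|tif|tiff|bmp|jpg|jpeg)$", re.IGNORECASE)


class FormatError(ValueError):
    """Raised when an input file or directory cannot be parsed."""


def _numeric_key(name: str) -> tuple:
    """Sort key ordering embedded integers numerically (frame_10 after frame_2)."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def read_frames(path: str | Path, clip_id: str | None = None) -> FrameSequence:
    """Load a clip from a frame directory or a video file as gray levels.

    Directories are read file by file in numeric-aware name order; frames
    are converted to gray with the BT.601 luma weights.  Mixed frame
    dimensions raise a :class:`FormatError` naming the offending file.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if FRAME_PATTERN.search(p.name)),
            key=lambda p: _numeric_key(p.name),
        )
        if not files:
            raise FormatError(f"no image frames found in {path}")
        frames = []
        shape = None
        for f in files:
            try:
                img = to_grayscale(iio.imread(f))
            except Exception as exc:  # noqa: BLE001 - report the file
                raise FormatError(f"cannot read frame {f}: {exc}") from exc
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise FormatError(
                    f"frame {f} has shape {img.shape}, expected {shape}"
                )
            frames.append(img)
        return FrameSequence(np.stack(frames), clip_id=clip_id or path.name)
    if not path.exists():
        raise FormatError(f"no such clip: {path}")
    try:
        frames = [to_grayscale(frame) for frame in iio.imiter(path)]
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot decode video {path}: {exc}") from exc
    if len(frames) < 2:
        raise FormatError(f"video {path} holds fewer than two frames")
    return FrameSequence(np.stack(frames), clip_id=clip_id or path.stem)


def write_frames(seq: FrameSequence, out_dir: str | Path) -> Path:
    """Write a clip as a directory of numbered PNG frames."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i in range(seq.n_frames):
        Image.fromarray(seq.frames[i], mode="L").save(
            out_dir / f"frame_{i + 1:06d}.png"
        )
    return out_dir


RATING_COLUMNS = [
    "judge_id", "clip_id", "condition", "response_lie",
    "cue_face", "cue_shoulders", "cue_legs", "cue_feet", "cue_other",
]
FIXATION_COLUMNS = ["judge_id", "clip_id", "onset_s", "duration_s", "x_px", "y_px"]


def write_ratings(ratings: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in RATING_COLUMNS if c in ratings.columns]
    ratings[cols].to_csv(path, index=False)
    return path


def read_ratings(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"judge_id", "clip_id", "condition", "response_lie"} - set(df.columns)
    if missing:
        raise FormatError(f"ratings CSV {path} missing columns {sorted(missing)}")
    return df


def write_fixations(fixations: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    fixations[FIXATION_COLUMNS].to_csv(path, index=False)
    return path


def read_fixations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FIXATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"fixations CSV {path} missing columns {sorted(missing)}")
    return df


def write_movement(movement: pd.DataFrame, path: str | Path) -> Path:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    movement.to_csv(path, index=False)
    return Path(path)


def read_movement(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"clip_id", "condition", "total"} - set(df.columns)
    if missing:
        raise FormatError(f"movement CSV {path} missing columns {sorted(missing)}")
    return df


def write_aois(aois: Mapping[str, AoiSet], path: str | Path) -> Path:
    rows = []
    for clip_id in sorted(aois):
        aset = aois[clip_id]
        for a in aset.aois:
            l, t, r, b = a.rect
            rows.append(
                {
                    "clip_id": clip_id,
                    "label": a.label,
                    "left": l,
                    "top": t,
                    "right": r,
                    "bottom": b,
                    "screen_w": aset.screen_size[0],
                    "screen_h": aset.screen_size[1],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_aois(path: str | Path) -> dict[str, AoiSet]:
    df = pd.read_csv(path)
    out: dict[str, AoiSet] = {}
    for clip_id, group in df.groupby("clip_id", sort=True):
        aois = [
            Aoi(r.label, (r.left, r.top, r.right, r.bottom))
            for r in group.itertuples()
        ]
        screen = (int(group["screen_w"].iloc[0]), int(group["screen_h"].iloc[0]))
        out[str(clip_id)] = AoiSet(clip_id=str(clip_id), aois=aois, screen_size=screen)
    return out


def write_bounds(bounds: RegionBounds, path: str | Path) -> Path:
    row = {
        "head_trunk_row": bounds.head_trunk_row,
        "trunk_legs_row": bounds.trunk_legs_row,
        "legs_feet_row": "" if bounds.legs_feet_row is None else bounds.legs_feet_row,
    }
    pd.DataFrame([row]).to_csv(path, index=False)
    return Path(path)


def read_bounds(path: str | Path) -> RegionBounds:
    df = pd.read_csv(path)
    row = df.iloc[0]
    lf = row.get("legs_feet_row")
    legs_feet = None if pd.isna(lf) or lf == "" else int(lf)
    return RegionBounds(int(row["head_trunk_row"]), int(row["trunk_legs_row"]), legs_feet)


def write_study(bundle: StudyBundle, out_dir: str | Path, *, write_clips: bool = True) -> Path:
    """Write a study bundle to disk in the documented layout.

    ``manifest.json`` plus ``ratings.csv``, ``fixations.csv``,
    ``movement_scores.csv``, ``aois.csv``, ``bounds.csv`` and (optionally)
    one PNG frame directory per clip under ``clips/``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    if bundle.ratings is not None:
        write_ratings(bundle.ratings, out / "ratings.csv")
    if bundle.fixations is not None:
        write_fixations(bundle.fixations, out / "fixations.csv")
    if bundle.movement is not None:
        write_movement(bundle.movement, out / "movement_scores.csv")
    if bundle.aois:
        write_aois(bundle.aois, out / "aois.csv")
    write_bounds(bundle.bounds, out / "bounds.csv")
    if write_clips and bundle.clips:
        for clip in bundle.clips:
            write_frames(clip, out / "clips" / clip.clip_id)
    return out


def read_study(study_dir: str | Path, *, load_clips: bool = False) -> StudyBundle:
    """Load a study bundle written by :func:`write_study`.

    Clip frames are only loaded into memory with ``load_clips=True``;
    otherwise stages read them lazily from ``clips/``.
    """
    study_dir = Path(study_dir)
    manifest_path = study_dir / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"no manifest.json in {study_dir}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    known = {c["clip_id"] for c in manifest.get("clips", [])}

    def _optional(path: Path, reader):
        return reader(path) if path.exists() else None

    ratings = _optional(study_dir / "ratings.csv", read_ratings)
    fixations = _optional(study_dir / "fixations.csv", read_fixations)
    movement = _optional(study_dir / "movement_scores.csv", read_movement)
    aois = _optional(study_dir / "aois.csv", read_aois)
    bounds_path = study_dir / "bounds.csv"
    if bounds_path.exists():
        bounds = read_bounds(bounds_path)
    else:
        r0, r1, r2 = manifest.get("region_rows", [30, 65, 95])
        bounds = RegionBounds(r0, r1)
    for name, df in (("ratings", ratings), ("fixations", fixations)):
        if df is not None and known:
            unknown = set(df["clip_id"]) - known
            if unknown:
                raise FormatError(
                    f"{name} reference clips absent from the manifest: {sorted(unknown)[:5]}"
                )
    clips = None
    clip_dir = study_dir / "clips"
    if load_clips and clip_dir.is_dir():
        clips = [
            read_frames(clip_dir / c["clip_id"], clip_id=c["clip_id"])
            for c in manifest.get("clips", [])
        ]
        for clip, meta in zip(clips, manifest.get("clips", [])):
            clip.condition = meta.get("condition")
    return StudyBundle(
        manifest=manifest,
        bounds=bounds,
        clips=clips,
        movement=movement,
        ratings=ratings,
        fixations=fixations,
        aois=aois,
    )
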