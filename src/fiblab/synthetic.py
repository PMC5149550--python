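"""Synthetic deception-study generator.

Builds complete, fully seeded studies with the structure the downstream
analyses assume: schematic video clips of a standing figure whose body
regions jitter with condition-dependent amplitude, judge rating tables
whose lie responses are driven by clip movement (plus condition-level
cues not captured by movement), and fixation streams concentrated on the
head region.  Every generator is a pure function of its parameters and
seed, so all pipeline stages can be exercised and calibrated without any
recorded data.

The default study emulates the design this package targets: 30 children
each filmed in one truthful (``Tc``) and two lying (``Ly1``, ``Ly2``)
conditions — 90 clips — rated by 20 judges.  Movement amplitudes make the
second lie attempt visibly more agitated than the truthful baseline while
the first attempt is statistically indistinguishable from it; judge
responses separate both lying conditions from truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gaze import Aoi, AoiSet, FixationEvent
from .motion import FrameSequence, MovementScore, RegionBounds, movement_heatmap, region_scores, total_movement

__all__ = [
    "FigureSpec",
    "ConditionProfile",
    "JudgeModel",
    "GazeModel",
    "StudyBundle",
    "CONDITIONS",
    "default_profiles",
    "default_aois",
    "generate_clip",
    "generate_ratings",
    "generate_fixations",
    "generate_study",
]

#: The three elicitation conditions, in design order.
CONDITIONS = ("Tc", "Ly1", "Ly2")

#: Body regions carrying movement, top to bottom.
BODY_REGIONS = ("head", "trunk", "legs", "feet")

#: Cue regions offered by the rating questionnaire.
CUE_REGIONS = ("face", "shoulders", "legs", "feet", "other")


@dataclass(frozen=True)
class FigureSpec:
    """Geometry and gray levels of the schematic standing figure.

    The default frame is an 80 x 108 scale model of an 801 x 1080 cropped
    recording: a dark figure (head disc, trunk rectangle, two leg bars,
    two foot bars) against a light uniform wall.  ``region_rows`` are the
    head/trunk, trunk/legs and legs/feet boundary rows used both for
    movement region scores and for the default areas of interest.

    ``noise_sigma`` optionally adds Gaussian sensor noise (gray levels) to
    every frame; the default of 0 keeps zero-jitter clips exactly static.
    """

    frame_height: int = 108
    frame_width: int = 80
    region_rows: tuple[int, int, int] = (30, 65, 95)
    head_center: tuple[int, int] = (40, 16)  # (x, y)
    head_radius: int = 10
    trunk_rect: tuple[int, int, int, int] = (28, 30, 52, 65)  # l, t, r, b half-open
    leg_rects: tuple[tuple[int, int, int, int], ...] = (
        (32, 65, 38, 95),
        (42, 65, 48, 95),
    )
    foot_rects: tuple[tuple[int, int, int, int], ...] = (
        (29, 95, 39, 104),
        (41, 95, 51, 104),
    )
    foreground_level: int = 60
    background_level: int = 230
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        r0, r1, r2 = self.region_rows
        if not 0 < r0 < r1 < r2 < self.frame_height:
            raise ValueError(f"region_rows must satisfy 0 < {r0} < {r1} < {r2} < height")
        if self.foreground_level == self.background_level:
            raise ValueError("foreground and background gray levels must differ")
        for level in (self.foreground_level, self.background_level):
            if not 0 <= level <= 255:
                raise ValueError("gray levels must lie in 0-255")
        for rect in (self.trunk_rect, *self.leg_rects, *self.foot_rects):
            l, t, r, b = rect
            if not (0 <= l < r <= self.frame_width and 0 <= t < b <= self.frame_height):
                raise ValueError(f"body rect {rect} outside the frame")
        cx, cy = self.head_center
        rad = self.head_radius
        if not (rad <= cx < self.frame_width - rad and rad <= cy < self.frame_height - rad):
            raise ValueError("head disc outside the frame")

    def part_pixels(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """(rows, cols) index arrays per body region at the rest position."""
        yy, xx = np.mgrid[0 : self.frame_height, 0 : self.frame_width]
        cx, cy = self.head_center
        head = (xx - cx) ** 2 + (yy - cy) ** 2 <= self.head_radius**2
        parts: dict[str, tuple[np.ndarray, np.ndarray]] = {"head": np.nonzero(head)}

        def rect_ix(rects: Sequence[tuple[int, int, int, int]]):
            mask = np.zeros((self.frame_height, self.frame_width), dtype=bool)
            for l, t, r, b in rects:
                mask[t:b, l:r] = True
            return np.nonzero(mask)

        parts["trunk"] = rect_ix([self.trunk_rect])
        parts["legs"] = rect_ix(self.leg_rects)
        parts["feet"] = rect_ix(self.foot_rects)
        return parts

    def bounds(self, include_feet: bool = False) -> RegionBounds:
        """Region bounds for movement scoring (3-region by default)."""
        r0, r1, r2 = self.region_rows
        return RegionBounds(r0, r1, r2 if include_feet else None)


@dataclass(frozen=True)
class ConditionProfile:
    """Per-region jitter amplitude (max displacement in px/frame) of one condition."""

    condition: str
    jitter_amplitude: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(BODY_REGIONS) - set(self.jitter_amplitude)
        if missing:
            raise ValueError(f"amplitudes missing for regions: {sorted(missing)}")
        if any(a < 0 for a in self.jitter_amplitude.values()):
            raise ValueError("jitter amplitudes must be >= 0")
        object.__setattr__(
            self, "jitter_amplitude", MappingProxyType(dict(self.jitter_amplitude))
        )

    def scaled(self, factor: float) -> "ConditionProfile":
        return ConditionProfile(
            self.condition,
            {k: v * factor for k, v in self.jitter_amplitude.items()},
        )


def default_profiles() -> dict[str, ConditionProfile]:
    """Default condition profiles.

    The truthful baseline and the first lie attempt share identical
    amplitudes (the first attempt is behaviorally indistinguishable from
    truth at the movement level), while the second attempt roughly doubles
    them everywhere — the "ironic effect" of a more self-conscious lie.
    """
    base = {"head": 2.0, "trunk": 1.2, "legs": 0.8, "feet": 0.8}
    agitated = {"head": 3.5, "trunk": 2.1, "legs": 1.4, "feet": 1.5}
    return {
        "Tc": ConditionProfile("Tc", base),
        "Ly1": ConditionProfile("Ly1", dict(base)),
        "Ly2": ConditionProfile("Ly2", agitated),
    }


@dataclass(frozen=True)
class JudgeModel:
    """Bernoulli judge responses, logistic in the clip's movement score.

    ``p(lie) = logistic(intercept + slope * movement + condition_effect)``.
    The movement term encodes "more movement looks more deceptive"; the
    per-condition offsets encode cues judges pick up that the movement
    score does not carry (facial behavior, hesitation), which is what lets
    rating accuracy separate the first lie attempt from truth even when
    their movement distributions coincide.  With ``slope = 0`` and zero
    offsets the expected percent-lie is identical (and equal to
    ``logistic(intercept)``) across conditions.

    ``cue_probs`` are the probabilities that a judge who answered "lie"
    flags each questionnaire cue region (multi-select, independent draws).
    """

    intercept: float = -1.40
    slope: float = 0.20
    n_judges: int = 20
    condition_effects: Mapping[str, float] = field(
        default_factory=lambda: {"Tc": -0.30, "Ly1": 0.68, "Ly2": -0.05}
    )
    cue_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "face": 0.76,
            "feet": 0.33,
            "legs": 0.30,
            "shoulders": 0.17,
            "other": 0.13,
        }
    )

    def __post_init__(self) -> None:
        if self.n_judges < 1:
            raise ValueError("n_judges must be positive")
        object.__setattr__(
            self, "condition_effects", MappingProxyType(dict(self.condition_effects))
        )
        object.__setattr__(self, "cue_probs", MappingProxyType(dict(self.cue_probs)))

    @classmethod
    def null(cls, n_judges: int = 20) -> "JudgeModel":
        """A judge model with no movement or condition signal: p(lie) = 0.5."""
        return cls(
            intercept=0.0,
            slope=0.0,
            n_judges=n_judges,
            condition_effects={c: 0.0 for c in CONDITIONS},
        )


@dataclass(frozen=True)
class GazeModel:
    """Where synthetic judges look and for how long.

    Fixation regions are multinomial draws over the areas of interest
    (defaults dominated by the head, emulating the strong face preference
    of human judges); positions are uniform inside the chosen AOI
    rectangle; durations are gamma distributed (shape 2, scale 0.15 s,
    i.e. mean 0.3 s — a typical fixation length).
    """

    region_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "head": 0.75,
            "trunk": 0.15,
            "legs": 0.06,
            "feet": 0.03,
            "noise": 0.01,
        }
    )
    duration_shape: float = 2.0
    duration_scale: float = 0.15
    n_fixations_per_clip: int = 20

    def __post_init__(self) -> None:
        w = dict(self.region_weights)
        if any(v < 0 for v in w.values()):
            raise ValueError("region weights must be >= 0")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("region weights must sum to 1")
        if self.duration_shape <= 0 or self.duration_scale <= 0:
            raise ValueError("duration parameters must be positive")
        if self.n_fixations_per_clip < 0:
            raise ValueError("n_fixations_per_clip must be >= 0")
        object.__setattr__(self, "region_weights", MappingProxyType(w))


@dataclass
class StudyBundle:
    """A complete synthetic (or loaded) study.

    Holds the manifest, the rendered clips, the derived movement-score
    table (``clip_id, child_id, condition, total, head, trunk, legs``),
    the judge rating table, the fixation table and the per-clip areas of
    interest, plus the region bounds used for movement scoring.
    """

    manifest: dict
    bounds: RegionBounds
    clips: list[FrameSequence] | None = None
    movement: pd.DataFrame | None = None
    ratings: pd.DataFrame | None = None
    fixations: pd.DataFrame | None = None
    aois: dict[str, AoiSet] | None = None

    @property
    def clip_ids(self) -> list[str]:
        return [c["clip_id"] for c in self.manifest["clips"]]

    @property
    def n_clips(self) -> int:
        return len(self.manifest["clips"])


def _clamped_offset(d: float, lo: int, hi: int) -> int:
    """Round a displacement and clamp it so the part stays inside the frame."""
    return int(min(max(round(d), lo), hi))


def generate_clip(
    spec: FigureSpec,
    profile: ConditionProfile,
    n_frames: int = 50,
    seed: int = 0,
    clip_id: str = "clip",
) -> FrameSequence:
    """Render one clip of the jittering schematic figure.

    Each frame displaces every body region independently by uniform jitter
    in ``[-amplitude, +amplitude]`` (rounded to whole pixels) around the
    rest position; a displacement that would push a part outside the frame
    is clamped to the frame bounds.  Identical arguments and seed give a
    bit-identical sequence.
    """
    if n_frames < 2:
        raise ValueError("a clip needs at least two frames")
    rng = np.random.default_rng(seed)
    parts = spec.part_pixels()
    h, w = spec.frame_height, spec.frame_width
    # Legal offset range per part so clamping preserves the part's shape.
    limits = {}
    for name, (ys, xs) in parts.items():
        limits[name] = (
            (-int(ys.min()), h - 1 - int(ys.max())),
            (-int(xs.min()), w - 1 - int(xs.max())),
        )
    frames = np.full((n_frames, h, w), spec.background_level, dtype=np.uint8)
    for t in range(n_frames):
        frame = frames[t]
        for name in BODY_REGIONS:
            amp = profile.jitter_amplitude[name]
            dy, dx = rng.uniform(-amp, amp, size=2)
            (ylo, yhi), (xlo, xhi) = limits[name]
            oy = _clamped_offset(dy, ylo, yhi)
            ox = _clamped_offset(dx, xlo, xhi)
            ys, xs = parts[name]
            frame[ys + oy, xs + ox] = spec.foreground_level
        if spec.noise_sigma > 0:
            noisy = frame + rng.normal(0.0, spec.noise_sigma, size=frame.shape)
            frames[t] = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    return FrameSequence(frames, clip_id=clip_id, condition=profile.condition)


def generate_ratings(
    movement_scores: pd.DataFrame | Sequence[MovementScore],
    model: JudgeModel,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the judge rating table for a set of scored clips.

    ``movement_scores`` is a DataFrame with ``clip_id``, ``condition`` and
    ``total`` columns (or a sequence of :class:`MovementScore`).  Every
    judge x clip response is an independent Bernoulli draw with
    ``p = logistic(intercept + slope * total + condition_effect)``; cue
    regions are flagged (independently, per ``cue_probs``) only on "lie"
    responses.  Returns one row per judge x clip with the documented CSV
    schema.
    """
    if not isinstance(movement_scores, pd.DataFrame):
        movement_scores = pd.DataFrame(
            [
                {"clip_id": s.clip_id, "condition": s.condition, "total": s.total}
                for s in movement_scores
            ]
        )
    required = {"clip_id", "condition", "total"}
    if not required.issubset(movement_scores.columns):
        raise ValueError(f"movement scores need columns {sorted(required)}")
    totals = movement_scores["total"].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(totals)):
        raise ValueError("movement scores contain non-finite values")
    conditions = movement_scores["condition"].to_numpy()
    offsets = np.array(
        [model.condition_effects.get(str(c), 0.0) for c in conditions]
    )
    with np.errstate(over="ignore"):
        logits = model.intercept + model.slope * totals + offsets
    p = np.clip(1.0 / (1.0 + np.exp(-logits)), 0.0, 1.0)

    rng = np.random.default_rng(seed)
    n_clips = totals.size
    lie = rng.random((model.n_judges, n_clips)) < p[None, :]
    records: dict[str, np.ndarray | list] = {
        "judge_id": np.repeat([f"j{j:02d}" for j in range(1, model.n_judges + 1)], n_clips),
        "clip_id": np.tile(movement_scores["clip_id"].to_numpy(), model.n_judges),
        "condition": np.tile(conditions, model.n_judges),
        "response_lie": lie.ravel().astype(int),
    }
    for region in CUE_REGIONS:
        prob = model.cue_probs.get(region, 0.0)
        flags = (rng.random((model.n_judges, n_clips)) < prob) & lie
        records[f"cue_{region}"] = flags.ravel().astype(int)
    return pd.DataFrame(records)


def generate_fixations(
    model: GazeModel,
    aois: AoiSet,
    seed: int = 0,
    judge_id: str = "j01",
) -> list[FixationEvent]:
    """Simulate one judge's fixation stream over one clip.

    Each fixation's region is drawn from ``region_weights``, its position
    uniformly inside that AOI's rectangle, and its duration from the gamma
    law; onsets accumulate durations plus short saccade gaps.
    """
    if not aois.aois:
        raise ValueError("AoiSet is empty")
    labels = list(model.region_weights.keys())
    weights = np.array([model.region_weights[k] for k in labels])
    by_label = {a.label: a for a in aois.aois}
    missing = [k for k, w in zip(labels, weights) if w > 0 and k not in by_label]
    if missing:
        raise ValueError(f"region weights refer to AOIs absent from the set: {missing}")
    rng = np.random.default_rng(seed)
    n = model.n_fixations_per_clip
    if n == 0:
        return []
    choices = rng.choice(len(labels), size=n, p=weights / weights.sum())
    durations = rng.gamma(model.duration_shape, model.duration_scale, size=n)
    gaps = rng.uniform(0.02, 0.05, size=n)
    events: list[FixationEvent] = []
    onset = 0.0
    for i in range(n):
        aoi = by_label[labels[choices[i]]]
        l, t, r, b = aoi.rect
        x = rng.uniform(l, r)
        y = rng.uniform(t, b)
        events.append(
            FixationEvent(
                judge_id=judge_id,
                clip_id=aois.clip_id,
                onset=onset,
                duration=float(durations[i]),
                x=float(x),
                y=float(y),
            )
        )
        onset += float(durations[i] + gaps[i])
    return events


def default_aois(spec: FigureSpec, clip_id: str) -> AoiSet:
    """Stacked body AOIs derived from the figure geometry, plus a noise corner.

    The four body AOIs are full-body-width bands following ``region_rows``
    (head band starts just above the figure); the noise AOI sits in the
    lower-left screen corner, away from the body columns.
    """
    r0, r1, r2 = spec.region_rows
    xs = [spec.trunk_rect[0], spec.trunk_rect[2]]
    for l, _, r, _ in (*spec.leg_rects, *spec.foot_rects):
        xs.extend([l, r])
    cx, cy = spec.head_center
    xs.extend([cx - spec.head_radius, cx + spec.head_radius + 1])
    left = max(0, min(xs) - 4)
    right = min(spec.frame_width, max(xs) + 4)
    bottom = min(spec.frame_height, max(r[3] for r in spec.foot_rects) + 2)
    aois = [
        Aoi("head", (left, max(0, cy - spec.head_radius - 4), right, r0)),
        Aoi("trunk", (left, r0, right, r1)),
        Aoi("legs", (left, r1, right, r2)),
        Aoi("feet", (left, r2, right, bottom)),
        Aoi("noise", (0, spec.frame_height - 16, max(2, left - 6), spec.frame_height)),
    ]
    return AoiSet(clip_id=clip_id, aois=aois, screen_size=(spec.frame_width, spec.frame_height))


def generate_study(
    n_children: int = 30,
    spec: FigureSpec | None = None,
    profiles: Mapping[str, ConditionProfile] | None = None,
    judge_model: JudgeModel | None = None,
    gaze_model: GazeModel | None = None,
    seed: int = 0,
    *,
    n_frames: int = 50,
    tau: int = 25,
    child_variability: float = 0.3,
    with_gaze: bool = True,
    keep_clips: bool = True,
) -> StudyBundle:
    """Generate a complete study: clips, movement scores, ratings, fixations.

    Each of ``n_children`` children contributes one clip per condition
    (``n_children x 3`` clips).  A per-child expressiveness factor, uniform
    in ``1 +/- child_variability``, scales that child's jitter amplitudes in
    all conditions, creating realistic between-child movement spread while
    preserving within-child condition contrasts.  Movement scores are
    computed from the rendered frames with the package's own
    frame-differencing analysis and then drive the judge model.  Everything
    is reproducible from ``seed``.
    """
    if n_children < 1:
        raise ValueError("n_children must be >= 1")
    spec = spec or FigureSpec()
    profiles = profiles if profiles is not None else default_profiles()
    missing = set(CONDITIONS) - set(profiles)
    if missing:
        raise ValueError(f"missing condition profiles: {sorted(missing)}")
    judge_model = judge_model or JudgeModel()
    gaze_model = gaze_model or GazeModel()

    master = np.random.default_rng(seed)
    child_scales = master.uniform(1.0 - child_variability, 1.0 + child_variability, n_children)
    clip_seeds = master.integers(0, 2**31, size=(n_children, len(CONDITIONS)))
    ratings_seed = int(master.integers(0, 2**31))
    fixation_seed_base = int(master.integers(0, 2**20))

    bounds = spec.bounds()
    clips: list[FrameSequence] = []
    manifest_clips: list[dict] = []
    movement_rows: list[dict] = []
    aois: dict[str, AoiSet] = {}
    for i in range(n_children):
        child_id = f"ch{i + 1:02d}"
        for j, cond in enumerate(CONDITIONS):
            clip_id = f"{child_id}_{cond}"
            prof = profiles[cond].scaled(float(child_scales[i]))
            clip = generate_clip(spec, prof, n_frames, int(clip_seeds[i, j]), clip_id)
            hm = movement_heatmap(clip, tau)
            per_region = region_scores(hm, bounds)
            movement_rows.append(
                {
                    "clip_id": clip_id,
                    "child_id": child_id,
                    "condition": cond,
                    "total": total_movement(hm),
                    **per_region,
                }
            )
            manifest_clips.append(
                {"clip_id": clip_id, "child_id": child_id, "condition": cond}
            )
            aois[clip_id] = default_aois(spec, clip_id)
            if keep_clips:
                clips.append(clip)
    movement = pd.DataFrame(movement_rows)
    ratings = generate_ratings(movement, judge_model, ratings_seed)

    fixations: pd.DataFrame | None = None
    if with_gaze:
        fix_records: list[FixationEvent] = []
        for j in range(1, judge_model.n_judges + 1):
            judge_id = f"j{j:02d}"
            for k, clip_id in enumerate(m["clip_id"] for m in manifest_clips):
                fix_seed = fixation_seed_base + j * 100_003 + k
                fix_records.extend(
                    generate_fixations(gaze_model, aois[clip_id], fix_seed, judge_id)
                )
        fixations = pd.DataFrame(
            {
                "judge_id": [f.judge_id for f in fix_records],
                "clip_id": [f.clip_id for f in fix_records],
                "onset_s": [f.onset for f in fix_records],
                "duration_s": [f.duration for f in fix_records],
                "x_px": [f.x for f in fix_records],
                "y_px": [f.y for f in fix_records],
            }
        )

    manifest = {
        "n_children": n_children,
        "conditions": list(CONDITIONS),
        "n_judges": judge_model.n_judges,
        "seed": seed,
        "n_frames": n_frames,
        "tau": tau,
        "child_variability": child_variability,
        "frame_size": [spec.frame_width, spec.frame_height],
        "region_rows": list(spec.region_rows),
        "clips": manifest_clips,
    }
    return StudyBundle(
        manifest=manifest,
        bounds=bounds,
        clips=clips if keep_clips else None,
        movement=movement,
        ratings=ratings,
        fixations=fixations,
        aois=aois,
    )
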