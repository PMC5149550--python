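"""Area-of-interest gaze analysis.

Fixation events are binned into rectangular body areas of interest (AOIs:
head, trunk, legs, feet) drawn on each clip, with a tolerance-based
reassignment of near misses standing in for the manual correction an
analyst would perform: a fixation landing within ``tolerance`` pixels of
the nearest body AOI is assigned to it.  A fifth AOI in the lower-left
screen corner collects noise (stray fixations on the experimenter's
hands) and is excluded from all statistics.

Durations are aggregated per judge x condition x region, contrasted with
the head-vs-rest F test, and rendered as duration-weighted Gaussian
fixation heat maps and their inverse "focus maps".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import stats as _stats

__all__ = [
    "Aoi",
    "AoiSet",
    "FixationEvent",
    "GazeDurationTable",
    "BODY_AOI_ORDER",
    "assign_fixation",
    "gaze_durations",
    "gaze_region_analysis",
    "fixation_heatmap",
    "focus_map",
]

logger = logging.getLogger("fiblab.gaze")

#: Fixed tie-break priority when a fixation is equally close to several AOIs.
BODY_AOI_ORDER = ("head", "trunk", "legs", "feet")

#: Default reassignment tolerance in pixels.
DEFAULT_TOLERANCE = 15.0


@dataclass(frozen=True)
class Aoi:
    """One labeled screen rectangle, half-open on its right/bottom edges."""

    label: str
    rect: tuple[float, float, float, float]  # left, top, right, bottom

    def __post_init__(self) -> None:
        l, t, r, b = self.rect
        if not (l < r and t < b):
            raise ValueError(f"degenerate AOI rect {self.rect}")

    def contains(self, x: float, y: float) -> bool:
        l, t, r, b = self.rect
        return l <= x < r and t <= y < b

    def distance(self, x: float, y: float) -> float:
        """Euclidean distance from a point to the rectangle (0 inside)."""
        l, t, r, b = self.rect
        dx = l - x if x < l else (x - r if x >= r else 0.0)
        dy = t - y if y < t else (y - b if y >= b else 0.0)
        return float(np.hypot(max(dx, 0.0), max(dy, 0.0)))

    @property
    def center(self) -> tuple[float, float]:
        l, t, r, b = self.rect
        return ((l + r) / 2.0, (t + b) / 2.0)


@dataclass
class AoiSet:
    """The AOIs drawn on one clip: four stacked body areas plus noise."""

    clip_id: str
    aois: list[Aoi]
    screen_size: tuple[int, int]  # (width, height)

    def __post_init__(self) -> None:
        w, h = self.screen_size
        labels = [a.label for a in self.aois]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate AOI labels")
        for a in self.aois:
            l, t, r, b = a.rect
            if not (0 <= l and 0 <= t and r <= w and b <= h):
                raise ValueError(f"AOI {a.label} {a.rect} outside the {w}x{h} screen")
        body = self.body_aois()
        for i, a in enumerate(body):
            for b2 in body[i + 1 :]:
                if _rects_overlap(a.rect, b2.rect):
                    raise ValueError(f"body AOIs {a.label} and {b2.label} overlap")

    def body_aois(self) -> list[Aoi]:
        by_label = {a.label: a for a in self.aois}
        return [by_label[k] for k in BODY_AOI_ORDER if k in by_label]

    def noise_aoi(self) -> Aoi | None:
        for a in self.aois:
            if a.label == "noise":
                return a
        return None


def _rects_overlap(a, b) -> bool:
    al, at, ar, ab = a
    bl, bt, br, bb = b
    return al < br and bl < ar and at < bb and bt < ab


@dataclass(frozen=True)
class FixationEvent:
    """One fixation: who looked, at which clip, when, for how long, where."""

    judge_id: str
    clip_id: str
    onset: float
    duration: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("fixation duration must be positive")


def assign_fixation(
    f: FixationEvent | tuple[float, float],
    aois: AoiSet,
    tolerance: float = DEFAULT_TOLERANCE,
) -> str | None:
    """Assign a fixation to a body AOI, the noise AOI, or ``None``.

    Containment in a body AOI wins outright.  Otherwise, if the nearest
    body AOI lies within ``tolerance`` pixels the fixation is reassigned to
    it (ties broken by nearest AOI center, then by the fixed order
    head > trunk > legs > feet).  Failing that, containment in the noise
    AOI yields ``"noise"``; anything else is unassigned.  With
    ``tolerance = 0`` the rule reduces to pure rectangle containment.
    """
    if isinstance(f, FixationEvent):
        x, y = f.x, f.y
    else:
        x, y = f
    body = aois.body_aois()
    for a in body:
        if a.contains(x, y):
            return a.label
    if tolerance > 0 and body:
        best: Aoi | None = None
        best_key: tuple[float, float, int] | None = None
        for rank, a in enumerate(body):
            d = a.distance(x, y)
            if d <= tolerance:
                cx, cy = a.center
                key = (d, float(np.hypot(x - cx, y - cy)), rank)
                if best_key is None or key < best_key:
                    best, best_key = a, key
        if best is not None:
            return best.label
    noise = aois.noise_aoi()
    if noise is not None and noise.contains(x, y):
        return "noise"
    return None


@dataclass
class GazeDurationTable:
    """Total assigned fixation duration per judge x condition x region.

    ``durations`` is a tidy DataFrame (``judge_id, condition, region,
    duration_s``) complete over the judge x condition x body-region grid
    (absent combinations hold 0).  ``qc`` tallies noise and unassigned
    duration separately per judge x condition.
    """

    durations: pd.DataFrame
    qc: pd.DataFrame

    def pivot(self, condition: str | None = None) -> pd.DataFrame:
        """Judge x region wide table, optionally restricted to one condition."""
        d = self.durations
        if condition is not None:
            d = d[d["condition"] == condition]
            return d.pivot_table(
                index="judge_id", columns="region", values="duration_s", aggfunc="sum"
            )[list(BODY_AOI_ORDER)]
        return d.pivot_table(
            index="judge_id", columns="region", values="duration_s", aggfunc="sum"
        )[list(BODY_AOI_ORDER)]


def gaze_durations(
    fixations: pd.DataFrame | Iterable[FixationEvent],
    aois: Mapping[str, AoiSet],
    clip_conditions: Mapping[str, str],
    tolerance: float = DEFAULT_TOLERANCE,
) -> GazeDurationTable:
    """Aggregate fixation durations into a judge x condition x region table.

    Fixations outside the screen are dropped with a warning; clips without
    an AOI set are skipped with a warning; noise and unassigned time is
    tallied separately for quality control and excluded from the body
    table.
    """
    if not isinstance(fixations, pd.DataFrame):
        fixations = pd.DataFrame(
            {
                "judge_id": [f.judge_id for f in fixations],
                "clip_id": [f.clip_id for f in fixations],
                "onset_s": [f.onset for f in fixations],
                "duration_s": [f.duration for f in fixations],
                "x_px": [f.x for f in fixations],
                "y_px": [f.y for f in fixations],
            }
        )
    body_rows: dict[tuple[str, str, str], float] = {}
    qc_rows: dict[tuple[str, str], dict[str, float]] = {}
    judges: set[str] = set()
    conditions_seen: set[str] = set()
    n_dropped = 0
    for clip_id, group in fixations.groupby("clip_id", sort=True):
        if clip_id not in aois:
            logger.warning("no AOI set for clip %s; skipping %d fixations", clip_id, len(group))
            continue
        if clip_id not in clip_conditions:
            logger.warning("no condition label for clip %s; skipping", clip_id)
            continue
        aset = aois[clip_id]
        cond = clip_conditions[clip_id]
        conditions_seen.add(cond)
        w, h = aset.screen_size
        for judge_id, x, y, dur in zip(
            group["judge_id"], group["x_px"], group["y_px"], group["duration_s"]
        ):
            judges.add(judge_id)
            if not (0 <= x < w and 0 <= y < h):
                n_dropped += 1
                continue
            label = assign_fixation((x, y), aset, tolerance)
            qc = qc_rows.setdefault((judge_id, cond), {"noise_s": 0.0, "unassigned_s": 0.0})
            if label in BODY_AOI_ORDER:
                key = (judge_id, cond, label)
                body_rows[key] = body_rows.get(key, 0.0) + float(dur)
            elif label == "noise":
                qc["noise_s"] += float(dur)
            else:
                qc["unassigned_s"] += float(dur)
    if n_dropped:
        logger.warning("dropped %d out-of-screen fixations", n_dropped)
    # complete grid: every judge x condition x region present, zeros filled
    records = [
        {
            "judge_id": j,
            "condition": c,
            "region": r,
            "duration_s": body_rows.get((j, c, r), 0.0),
        }
        for j in sorted(judges)
        for c in sorted(conditions_seen)
        for r in BODY_AOI_ORDER
    ]
    qc = pd.DataFrame(
        [
            {"judge_id": j, "condition": c, **vals}
            for (j, c), vals in sorted(qc_rows.items())
        ]
    )
    return GazeDurationTable(durations=pd.DataFrame(records), qc=qc)


def gaze_region_analysis(table: GazeDurationTable) -> dict:
    """Head-vs-rest contrast plus per-region descriptive summary.

    Returns a report with the overall contrast (durations summed over
    conditions per judge), one contrast per condition, and a region x
    condition table of across-judge means and SDs of the per-judge
    duration totals.
    """
    overall = table.pivot()
    conditions = sorted(table.durations["condition"].unique())
    per_condition = {
        c: _stats.head_vs_rest_contrast(table.pivot(c)) for c in conditions
    }
    summary_rows = []
    for region in BODY_AOI_ORDER:
        row: dict[str, object] = {"region": region}
        for c in conditions:
            vals = table.pivot(c)[region]
            row[f"{c}_mean"] = float(vals.mean())
            row[f"{c}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        summary_rows.append(row)
    return {
        "overall": _stats.head_vs_rest_contrast(overall),
        "per_condition": per_condition,
        "summary": pd.DataFrame(summary_rows),
    }


def fixation_heatmap(
    fixations: pd.DataFrame | Iterable[FixationEvent],
    screen_size: tuple[int, int],
    kernel_sigma: float,
    *,
    normalize: bool = True,
) -> np.ndarray:
    """Duration-weighted Gaussian fixation density image.

    Each fixation contributes an isotropic Gaussian kernel of unit mass
    scaled by its duration, centered at its position.  The result is
    min-max normalized unless ``normalize=False`` (useful for checking
    that the un-normalized mass equals the summed durations).  An empty
    fixation list yields an all-zero image.
    """
    if kernel_sigma <= 0:
        raise ValueError("kernel_sigma must be positive")
    w, h = screen_size
    img = np.zeros((h, w), dtype=np.float64)
    if isinstance(fixations, pd.DataFrame):
        xs = fixations["x_px"].to_numpy(dtype=np.float64)
        ys = fixations["y_px"].to_numpy(dtype=np.float64)
        durs = fixations["duration_s"].to_numpy(dtype=np.float64)
    else:
        fx = list(fixations)
        xs = np.array([f.x for f in fx])
        ys = np.array([f.y for f in fx])
        durs = np.array([f.duration for f in fx])
    if xs.size == 0:
        return img
    xi = np.clip(np.rint(xs), 0, w - 1).astype(int)
    yi = np.clip(np.rint(ys), 0, h - 1).astype(int)
    np.add.at(img, (yi, xi), durs)
    img = gaussian_filter(img, sigma=kernel_sigma, mode="constant", truncate=6.0)
    if normalize:
        peak = img.max()
        if peak > 0:
            img = img / peak
    return img


def focus_map(heat: np.ndarray, coverage_quantile: float) -> np.ndarray:
    """Binary mask revealing only the most-fixated screen regions.

    Pixels with intensity below the ``coverage_quantile`` quantile of the
    heat image are masked (``False``, rendered black); the rest are
    revealed (``True``).
    """
    if not 0.0 < coverage_quantile < 1.0:
        raise ValueError("coverage_quantile must lie strictly between 0 and 1")
    heat = np.asarray(heat, dtype=np.float64)
    # order-statistic quantile: q -> 0 masks nothing, q -> 1 keeps the peak
    thresh = np.quantile(heat, coverage_quantile, method="lower")
    return heat >= thresh
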