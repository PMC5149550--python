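"""Frame-differencing movement quantification.

The movement measure used throughout this package is deliberately simple:
for every pair of consecutive gray-level frames the absolute per-pixel
change is computed, changes below a fixed threshold are zeroed (this
suppresses low-level flicker such as in-camera illumination compensation),
and the thresholded change grids are averaged per pixel over the whole
clip.  The resulting *movement heat map* is the source of every movement
score: the clip's total movement is the mean of the map, and per-region
scores are means over horizontal body bands (head / trunk / legs, with an
optional feet band).

All arithmetic is carried out in signed integers (differencing) and
float64 (averaging), so there is no unsigned wrap-around and no overflow
on long sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameSequence",
    "MovementHeatMap",
    "RegionBounds",
    "MovementScore",
    "to_grayscale",
    "crop_central",
    "frame_difference",
    "threshold_changes",
    "movement_heatmap",
    "total_movement",
    "region_scores",
    "render_heatmap",
]

#: ITU-R BT.601 luma weights used for RGB -> gray conversion.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

#: Fixed pixel-change threshold used by default (absolute change range 0-255).
DEFAULT_TAU = 25


@dataclass
class FrameSequence:
    """An ordered stack of gray-level frames belonging to one clip.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)`` with integer gray
        levels in 0-255.  At least two frames are required, since a single
        frame carries no movement information.
    clip_id
        Identifier of the clip the frames belong to.
    condition
        Elicitation condition label (``"Tc"``, ``"Ly1"``, ``"Ly2"``) or
        ``None`` when unknown.
    """

    frames: np.ndarray
    clip_id: str = "clip"
    condition: str | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError(
                f"frames must be a (n_frames, height, width) stack, got ndim={f.ndim}"
            )
        if f.shape[0] < 2:
            raise ValueError("a frame sequence needs at least two frames")
        if f.min() < 0 or f.max() > 255:
            raise ValueError("gray levels must lie in 0-255")
        self.frames = f.astype(np.uint8, copy=False)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


@dataclass
class MovementHeatMap:
    """Per-pixel average thresholded absolute change over one clip."""

    values: np.ndarray
    threshold_used: int
    n_frame_pairs: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("heat map values must be a 2-D grid")
        if v.min() < 0 or v.max() > 255:
            raise ValueError("heat map values must lie in 0-255")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RegionBounds:
    """Horizontal body-band boundaries (0-based row indices, half-open).

    ``head`` is rows ``[0, head_trunk_row)``, ``trunk`` is
    ``[head_trunk_row, trunk_legs_row)`` and ``legs`` runs to the bottom of
    the frame, unless ``legs_feet_row`` is given, in which case ``legs``
    stops there and ``feet`` covers the remainder.
    """

    head_trunk_row: int
    trunk_legs_row: int
    legs_feet_row: int | None = None

    def __post_init__(self) -> None:
        rows = [self.head_trunk_row, self.trunk_legs_row]
        if self.legs_feet_row is not None:
            rows.append(self.legs_feet_row)
        if rows[0] <= 0 or any(b <= a for a, b in zip(rows, rows[1:])):
            raise ValueError(f"region rows must be strictly increasing and > 0: {rows}")

    def region_slices(self, height: int) -> dict[str, tuple[int, int]]:
        """Row bands per region label for a frame of the given height."""
        last = self.legs_feet_row if self.legs_feet_row is not None else self.trunk_legs_row
        if last >= height:
            raise ValueError(
                f"region rows {self} do not fit a frame of height {height}"
            )
        bands = {
            "head": (0, self.head_trunk_row),
            "trunk": (self.head_trunk_row, self.trunk_legs_row),
        }
        if self.legs_feet_row is None:
            bands["legs"] = (self.trunk_legs_row, height)
        else:
            bands["legs"] = (self.trunk_legs_row, self.legs_feet_row)
            bands["feet"] = (self.legs_feet_row, height)
        return bands


@dataclass
class MovementScore:
    """Movement summary of one clip: overall mean plus per-region means."""

    clip_id: str
    condition: str | None
    total: float
    per_region: dict[str, float] = field(default_factory=dict)


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an RGB frame to gray levels with BT.601 luma weights.

    ``gray = round(0.299 R + 0.587 G + 0.114 B)`` clamped to 0-255.
    Already-gray (2-D) input passes through unchanged.
    """
    a = np.asarray(frame)
    if a.ndim == 2:
        return a.astype(np.uint8, copy=False)
    if a.ndim == 3 and a.shape[-1] in (3, 4):
        rgb = a[..., :3].astype(np.float64)
        gray = rgb @ np.asarray(GRAY_WEIGHTS)
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise ValueError(f"expected a 2-D gray or 3-channel RGB frame, got shape {a.shape}")


def crop_central(seq: FrameSequence, target_width: int) -> FrameSequence:
    """Keep ``target_width`` horizontally centered columns of every frame.

    All rows are kept.  When the number of discarded columns is odd, the
    extra column is dropped on the right.
    """
    if target_width > seq.width:
        raise ValueError(
            f"target_width {target_width} exceeds frame width {seq.width}"
        )
    if target_width == seq.width:
        return seq
    left = (seq.width - target_width) // 2
    return FrameSequence(
        seq.frames[:, :, left : left + target_width],
        clip_id=seq.clip_id,
        condition=seq.condition,
    )


def frame_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pixel absolute gray-level change between two frames.

    Computed in signed arithmetic, so e.g. ``|10 - 250| = 240`` rather than
    an unsigned wrap-around.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    return np.abs(b.astype(np.int16) - a.astype(np.int16))


def threshold_changes(diff: np.ndarray, tau: int = DEFAULT_TAU) -> np.ndarray:
    """Zero all change values *smaller than* ``tau``; values >= tau are kept.

    The boundary value ``tau`` itself is retained.
    """
    if not 0 <= tau <= 255:
        raise ValueError(f"tau must lie in 0-255, got {tau}")
    diff = np.asarray(diff)
    return np.where(diff < tau, 0, diff)


def movement_heatmap(
    seq: FrameSequence,
    tau: int = DEFAULT_TAU,
    *,
    threshold_after_averaging: bool = False,
) -> MovementHeatMap:
    """Average thresholded absolute change per pixel over a whole clip.

    By default the threshold is applied to each of the ``n_frames - 1``
    frame-pair difference grids *before* averaging; this is what suppresses
    per-frame flicker.  ``threshold_after_averaging=True`` instead averages
    the raw differences and thresholds the mean map once, for comparison.
    """
    frames = seq.frames.astype(np.int16)
    diffs = np.abs(frames[1:] - frames[:-1])
    if not threshold_after_averaging:
        diffs = np.where(diffs < _checked_tau(tau), 0, diffs)
        values = diffs.mean(axis=0, dtype=np.float64)
    else:
        values = diffs.mean(axis=0, dtype=np.float64)
        values = np.where(values < _checked_tau(tau), 0.0, values)
    return MovementHeatMap(values, threshold_used=tau, n_frame_pairs=seq.n_frames - 1)


def _checked_tau(tau: int) -> int:
    if not 0 <= tau <= 255:
        raise ValueError(f"tau must lie in 0-255, got {tau}")
    return tau


def total_movement(hm: MovementHeatMap) -> float:
    """Overall movement of a clip: the mean over all heat-map pixels."""
    return float(np.mean(hm.values))


def region_scores(hm: MovementHeatMap, bounds: RegionBounds) -> dict[str, float]:
    """Mean heat-map value per horizontal body band.

    Bands span the full frame width and are half-open in rows, so the
    pixel-count-weighted mean of the region scores equals the total score.
    """
    height = hm.values.shape[0]
    return {
        label: float(np.mean(hm.values[r0:r1, :]))
        for label, (r0, r1) in bounds.region_slices(height).items()
    }


def score_clip(
    seq: FrameSequence,
    bounds: RegionBounds,
    tau: int = DEFAULT_TAU,
) -> MovementScore:
    """Convenience wrapper: heat map -> total + per-region movement score."""
    hm = movement_heatmap(seq, tau)
    return MovementScore(
        clip_id=seq.clip_id,
        condition=seq.condition,
        total=total_movement(hm),
        per_region=region_scores(hm, bounds),
    )


def render_heatmap(hm: MovementHeatMap, colormap_name: str = "afmhot") -> np.ndarray:
    """Render a heat map as an RGB image through a hot-style colormap.

    The map is min-max normalized first; an all-zero (or constant) map
    renders at the colormap's low end, which for ``"afmhot"`` is black.
    Returns a ``(height, width, 3)`` uint8 array.
    """
    import matplotlib

    v = hm.values
    vmin, vmax = float(v.min()), float(v.max())
    norm = np.zeros_like(v) if vmax <= vmin else (v - vmin) / (vmax - vmin)
    cmap = matplotlib.colormaps[colormap_name]
    rgba = cmap(norm)
    return np.clip(np.rint(rgba[..., :3] * 255), 0, 255).astype(np.uint8)
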