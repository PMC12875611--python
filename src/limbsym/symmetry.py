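"""Dorsoventral mirror-symmetry scoring of sectioned limbs.

The procedure quantifies how mirror-symmetric the tissue layout of a limb
cross-section is about its dorsoventral midline:

1. the midpoint of user-supplied dorsal and ventral end points defines the
   axis of symmetry, and the section is rotated so that axis is vertical;
2. a window of fixed physical width (default 400 μm) is cut so external
   curvature of the section does not confound the measure;
3. the ventral half of the window is flipped onto the dorsal half;
4. for each tissue class a binary mask is built on both halves (exact class
   match on label rasters, per-channel color tolerance on RGB rasters) and

   ``score_c = matching_c / total_c``

   where ``matching_c`` counts pixels matching the class on *both* halves
   and ``total_c`` counts pixels matching it on *either* half — i.e. a
   per-class Jaccard index of the two mirror halves; a perfect mirror
   scores exactly 1.0.  A ``sum`` denominator (|dorsal| + |ventral|,
   Dice-like) is available for sensitivity checks.
5. "combined" pools matching and total counts over all classes.

An optional grid search refines the rotation angle by maximising the
epidermis-class (class 5) score, formalising the manual step of aligning
the outer contour symmetrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi

from .io import ClassPalette, LabelImage, RGBImage

__all__ = [
    "AxisSpec",
    "WindowSpec",
    "ToleranceSpec",
    "SymmetryWindow",
    "SymmetryResult",
    "place_axis",
    "refine_angle",
    "extract_window",
    "class_mask",
    "score_window",
    "score_sample",
]

_CLASS_INDICES = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class AxisSpec:
    """The symmetry axis: endpoint pair plus the rotation making it vertical.

    ``rotation_deg`` is the in-plane rotation applied to the raster so the
    dorsoventral segment becomes a single column with dorsal on top;
    ``mirror_row`` is the row of the axis midpoint in the rotated frame of
    the raster the axis was placed on (recomputed per raster when windows
    are cut, so the spec survives re-use across equally sized rasters).
    """

    dorsal_point: tuple[float, float]
    ventral_point: tuple[float, float]
    rotation_deg: float
    mirror_row: float


@dataclass(frozen=True)
class WindowSpec:
    """An angle-aligned crop of fixed physical width (default 400 μm).

    ``center_col`` is the column of the window center in the rotated frame;
    ``None`` centers the window on the symmetry axis.  The pixel width is
    derived from the scale and forced even so the mirror line sits between
    rows, never on one.
    """

    center_col: int | None = None
    width_um: float = 400.0

    def __post_init__(self) -> None:
        if not self.width_um > 0:
            raise ValueError("width_um must be positive")

    def width_px(self, scale_um_per_px: float) -> int:
        w = 2 * round(self.width_um / (2.0 * scale_um_per_px))
        if w < 2:
            raise ValueError(
                f"window width {self.width_um} μm spans fewer than 2 px at "
                f"{scale_um_per_px} μm/px"
            )
        return int(w)


@dataclass(frozen=True)
class ToleranceSpec:
    """Per-channel RGB tolerance: colors match when all three channel
    differences are within ``per_channel``.  Ignored on label rasters."""

    per_channel: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.per_channel <= 255:
            raise ValueError("tolerance must be in 0..255")


@dataclass
class SymmetryWindow:
    """Two aligned half-rasters: position (i, j) in one half is the mirror
    partner of (i, j) in the other (the ventral half is stored pre-flipped)."""

    dorsal: np.ndarray
    ventral_flipped: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dorsal.shape != self.ventral_flipped.shape:
            raise ValueError("halves must have identical dimensions")

    def swapped(self) -> "SymmetryWindow":
        return SymmetryWindow(self.ventral_flipped, self.dorsal, dict(self.provenance))


@dataclass
class SymmetryResult:
    """Per-class and combined symmetry scores for one window."""

    matching: dict[int, int]
    total: dict[int, int]
    scores: dict[int, float | None]
    combined: float
    denominator: str = "union"
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rotation geometry

def _rotation(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([[math.cos(a), math.sin(a)], [-math.sin(a), math.cos(a)]])


def _rotated_frame(shape: tuple[int, int], deg: float):
    """Rotation matrix, input/output centers and output shape with resize."""
    h, w = shape
    rot = _rotation(deg)
    c_in = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    corners = np.array([[0, 0], [0, w - 1], [h - 1, 0], [h - 1, w - 1]], dtype=float)
    rc = (corners - c_in) @ rot.T
    out_h = int(math.ceil(rc[:, 0].max() - rc[:, 0].min())) + 1
    out_w = int(math.ceil(rc[:, 1].max() - rc[:, 1].min())) + 1
    c_out = np.array([(out_h - 1) / 2.0, (out_w - 1) / 2.0])
    return rot, c_in, c_out, (out_h, out_w)


def _rotate_point(p, rot, c_in, c_out) -> np.ndarray:
    return rot @ (np.asarray(p, dtype=float) - c_in) + c_out


def _rotate_raster(arr: np.ndarray, deg: float, order: int, cval: float) -> np.ndarray:
    """Rotate about the raster center, enlarging the canvas to fit."""
    if deg % 360.0 == 0.0:
        return arr.copy()
    rot, c_in, c_out, out_shape = _rotated_frame(arr.shape[:2], deg)
    inv = rot.T
    offset = c_in - inv @ c_out
    if arr.ndim == 2:
        return ndi.affine_transform(
            arr, inv, offset=offset, output_shape=out_shape, order=order,
            mode="constant", cval=cval,
        )
    out = np.empty(out_shape + (arr.shape[2],), dtype=arr.dtype)
    for ch in range(arr.shape[2]):
        out[:, :, ch] = ndi.affine_transform(
            arr[:, :, ch].astype(float), inv, offset=offset,
            output_shape=out_shape, order=order, mode="constant", cval=cval,
        ).astype(arr.dtype)
    return out


# ---------------------------------------------------------------------------
# operations

def place_axis(
    img: LabelImage | RGBImage,
    dorsal_point: Sequence[float],
    ventral_point: Sequence[float],
) -> AxisSpec:
    """Define the symmetry axis from the dorsal and ventral end points."""
    h, w = img.shape
    d = np.asarray(dorsal_point, dtype=float)
    v = np.asarray(ventral_point, dtype=float)
    for name, p in (("dorsal", d), ("ventral", v)):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise ValueError(f"{name}_point {tuple(p)} is outside the raster")
    if np.allclose(d, v):
        raise ValueError("dorsal and ventral points must not coincide")
    dr, dc = v - d
    deg = math.degrees(math.atan2(dc, dr))
    rot, c_in, c_out, _ = _rotated_frame((h, w), deg)
    rd = _rotate_point(d, rot, c_in, c_out)
    rv = _rotate_point(v, rot, c_in, c_out)
    mirror_row = float((rd[0] + rv[0]) / 2.0)
    return AxisSpec(tuple(d), tuple(v), deg, mirror_row)


def extract_window(
    img: LabelImage | RGBImage,
    axis: AxisSpec,
    window: WindowSpec = WindowSpec(),
) -> SymmetryWindow:
    """Rotate, split at the mirror line, flip the ventral half, crop.

    Label rasters are rotated with nearest-neighbour interpolation (no
    invented classes, background fill); RGB rasters bilinearly.  When the
    mirror line falls on a row, that center row belongs to neither half;
    both halves are cropped to the lesser half-height.
    """
    if isinstance(img, LabelImage):
        arr = _rotate_raster(
            img.labels, axis.rotation_deg, order=0,
            cval=img.palette.background_index,
        )
    else:
        arr = _rotate_raster(img.pixels, axis.rotation_deg, order=1, cval=0)
    rot, c_in, c_out, _ = _rotated_frame(img.shape, axis.rotation_deg)
    rd = _rotate_point(axis.dorsal_point, rot, c_in, c_out)
    rv = _rotate_point(axis.ventral_point, rot, c_in, c_out)
    if rd[0] > rv[0]:
        raise ValueError("dorsal point must lie above the ventral point after rotation")
    m = (rd[0] + rv[0]) / 2.0
    axis_col = (rd[1] + rv[1]) / 2.0

    width_px = window.width_px(img.scale_um_per_px)
    center_col = window.center_col if window.center_col is not None else round(axis_col)
    c0 = int(center_col) - width_px // 2
    c1 = c0 + width_px
    out_h, out_w = arr.shape[:2]
    if c0 < 0 or c1 > out_w:
        raise ValueError(
            f"window columns [{c0}, {c1}) fall outside the rotated raster "
            f"(width {out_w})"
        )

    if abs(m - round(m)) < 1e-9:  # mirror line on a row: exclude it
        top_end = int(round(m)) - 1
        bot_start = int(round(m)) + 1
    else:
        top_end = int(math.floor(m))
        bot_start = top_end + 1
    half_h = min(top_end + 1, out_h - bot_start)
    if half_h < 1:
        raise ValueError("mirror line leaves no rows on one side of the window")

    dorsal = arr[top_end - half_h + 1 : top_end + 1, c0:c1]
    ventral = arr[bot_start : bot_start + half_h, c0:c1][::-1]
    return SymmetryWindow(
        dorsal.copy(),
        ventral.copy(),
        provenance={
            "mirror_row": float(m),
            "axis_col": float(axis_col),
            "center_col": int(center_col),
            "width_px": int(width_px),
            "rotation_deg": float(axis.rotation_deg),
        },
    )


def class_mask(
    half: np.ndarray,
    target: int | Sequence[int],
    tol: ToleranceSpec | int = ToleranceSpec(),
) -> np.ndarray:
    """Binary mask of pixels matching a class (label raster) or a color
    within per-channel tolerance (RGB raster)."""
    if isinstance(tol, int):
        tol = ToleranceSpec(tol)
    if half.ndim == 2:
        return half == int(target)
    diff = np.abs(half.astype(np.int16) - np.asarray(target, dtype=np.int16))
    return np.all(diff <= tol.per_channel, axis=-1)


def score_window(
    win: SymmetryWindow,
    palette: ClassPalette,
    tol: ToleranceSpec | int = ToleranceSpec(),
    denominator: str = "union",
) -> SymmetryResult:
    """Per-class and combined symmetry scores for one window.

    matching_c = |mask_dorsal ∧ mask_ventral|; total_c = |mask_dorsal ∨
    mask_ventral| (``union``, the default) or |mask_dorsal| +
    |mask_ventral| (``sum``).  Classes absent from both halves get no
    score; combined pools counts over scored classes, hence lies between
    the min and max per-class score (mediant property) and is symmetric in
    the two halves.
    """
    if denominator not in ("union", "sum"):
        raise ValueError(f"denominator must be 'union' or 'sum', got {denominator!r}")
    if win.dorsal.size == 0:
        raise ValueError("empty window")
    matching: dict[int, int] = {}
    total: dict[int, int] = {}
    scores: dict[int, float | None] = {}
    for c in _CLASS_INDICES:
        target = c if win.dorsal.ndim == 2 else palette.color(c)
        md = class_mask(win.dorsal, target, tol)
        mv = class_mask(win.ventral_flipped, target, tol)
        m = int(np.count_nonzero(md & mv))
        if denominator == "union":
            t = int(np.count_nonzero(md | mv))
        else:
            # literal "both sides" total; a perfect mirror scores 0.5
            t = int(np.count_nonzero(md)) + int(np.count_nonzero(mv))
        matching[c] = m
        total[c] = t
        scores[c] = (m / t) if t > 0 else None
    grand_total = sum(t for t in total.values() if t > 0)
    if grand_total == 0:
        raise ValueError("window contains no pixels matching any class")
    combined = sum(matching[c] for c in total if total[c] > 0) / grand_total
    return SymmetryResult(
        matching=matching,
        total=total,
        scores=scores,
        combined=float(combined),
        denominator=denominator,
        provenance=dict(win.provenance),
    )


def refine_angle(
    labels: LabelImage,
    axis: AxisSpec,
    window: WindowSpec = WindowSpec(),
    search_deg: float = 5.0,
    step_deg: float = 0.5,
) -> AxisSpec:
    """Grid-search a rotation offset maximising epidermal (class 5) symmetry.

    Formalises the manual alignment of the outer contour: candidate offsets
    in [−search, +search] on a grid of ``step_deg`` are scored by the
    class-5 symmetry of the window; ties prefer the smallest |offset|, then
    negative before positive.  ``search_deg = 0`` returns the axis unchanged.
    """
    if search_deg < 0:
        raise ValueError("search_deg must be >= 0")
    if step_deg <= 0:
        raise ValueError("step_deg must be > 0")
    if search_deg == 0:
        return axis
    n = int(math.floor(search_deg / step_deg + 1e-9))
    offsets = [0.0]
    for k in range(1, n + 1):
        offsets.extend([-k * step_deg, k * step_deg])

    best_offset: float | None = None
    best_score = -1.0
    for off in offsets:
        cand = replace(axis, rotation_deg=axis.rotation_deg + off)
        win = extract_window(labels, cand, window)
        md = class_mask(win.dorsal, 5)
        mv = class_mask(win.ventral_flipped, 5)
        t = int(np.count_nonzero(md | mv))
        if t == 0:
            continue
        s = int(np.count_nonzero(md & mv)) / t
        if s > best_score:
            best_score = s
            best_offset = off
    if best_offset is None:
        raise ValueError("no epidermal contour in window")
    return replace(axis, rotation_deg=axis.rotation_deg + best_offset)


def score_sample(
    labels: LabelImage | RGBImage,
    axis: AxisSpec,
    windows: Iterable[WindowSpec],
    tol: ToleranceSpec | int = ToleranceSpec(),
    denominator: str = "union",
    sample_id: str = "",
    palette: ClassPalette | None = None,
) -> list[SymmetryResult]:
    """Score every requested window of one sample; results carry the sample
    id so downstream tables can group windows cut from the same limb."""
    windows = list(windows)
    if not windows:
        raise ValueError("at least one window is required")
    palette = palette or getattr(labels, "palette", None)
    results = []
    for i, w in enumerate(windows):
        win = extract_window(labels, axis, w)
        res = score_window(win, palette, tol, denominator)
        res.provenance.update({"sample_id": sample_id, "window_id": i})
        results.append(res)
    return results
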