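"""Synthetic transverse limb sections with a tunable dorsoventral asymmetry.

Every downstream stage (pixel classification, window extraction, symmetry
scoring, group statistics) is exercised on these generated sections, so the
generator is first-class, tested code.

A section is a smooth mirror-symmetric blob outlined by an epidermis ring
(class 5) enclosing other connective tissue (class 4) in which elliptical
cartilage elements (class 2) and muscle bundles (class 3) are embedded on a
background (class 1).  Internal symmetry is imposed constructively: the
dorsal half layout is generated and mirrored to the ventral half, then a
fraction ``asymmetry`` of the ventral elements is re-randomised
independently.  ``asymmetry = 0`` therefore gives a raster that is exactly
invariant under reflection about its dorsoventral mid-row, and
``asymmetry = 1`` gives independent dorsal and ventral layouts.  The outer
contour is always mirror-symmetric so that external shape never confounds
internal-tissue symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse

from .io import DEFAULT_PALETTE, ClassPalette, LabelImage, RGBImage

__all__ = [
    "SectionSpec",
    "StainModel",
    "CohortSample",
    "generate_label_section",
    "render_staining",
    "make_cohort",
    "contour_axis_points",
]

_MAX_PLACEMENT_TRIES = 500


@dataclass(frozen=True)
class SectionSpec:
    """Parameters of one generated section.

    Element counts are per dorsal half; the ventral half receives their
    mirror images (or independent re-draws, governed by ``asymmetry``).
    Canvas default is 512×512 px at 4 μm/px so a 400 μm scoring window
    spans 100 columns.
    """

    height_px: int = 512
    width_px: int = 512
    scale_um_per_px: float = 4.0
    n_cartilage: int = 2
    n_muscle: int = 3
    epidermis_thickness_px: int = 6
    asymmetry: float = 0.0
    seed: int = 0
    palette: ClassPalette = field(default_factory=lambda: DEFAULT_PALETTE)

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError("canvas dimensions must be positive")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be positive")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError(f"asymmetry must be in [0, 1], got {self.asymmetry}")
        if self.n_cartilage < 0 or self.n_muscle < 0:
            raise ValueError("element counts must be >= 0")
        if self.epidermis_thickness_px < 1:
            raise ValueError("epidermis_thickness_px must be >= 1")


@dataclass(frozen=True)
class StainModel:
    """Trichrome-like rendering model.

    Each rendered pixel is ``class mean color × sample multiplier + noise``
    clipped to 0..255.  The single scalar multiplier per sample models the
    slide-to-slide staining-intensity variation that motivates training one
    classifier per sample; the Gaussian pixel noise models local texture.
    """

    mean_colors: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: {i: DEFAULT_PALETTE.color(i) for i in range(1, 6)}
    )
    multiplier_range: tuple[float, float] = (0.7, 1.3)
    noise_sd: float = 4.0

    def __post_init__(self) -> None:
        colors = [tuple(c) for c in self.mean_colors.values()]
        if len(set(colors)) != len(colors):
            raise ValueError("stain mean colors must be pairwise distinct")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.multiplier_range
        if not (lo > 0 and hi >= lo):
            raise ValueError("multiplier_range must satisfy 0 < lo <= hi")


def _symmetric_contour(spec: SectionSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth blob from low-order radial harmonics, exactly mirror-symmetric.

    Only cos(kθ) terms are used; cos is even in θ so the radius is an even
    function of the dorsoventral offset and the rasterised mask is
    bit-exactly invariant under reflection about the mid-row.
    """
    h, w = spec.height_px, spec.width_px
    rc, cc = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    dy = rows - rc
    dx = cols - cc
    theta = np.arctan2(dy, dx)
    r0 = 0.38 * min(h, w)
    amps = rng.uniform(-0.05, 0.05, size=4)
    radius = np.full_like(theta, r0)
    for k, a in zip((2, 3, 4, 5), amps):
        radius = radius + r0 * a * np.cos(k * theta)
    return np.hypot(dy, dx) <= radius


def _draw_element(
    rng: np.random.Generator,
    interior: np.ndarray,
    top_row_max: int,
    radius_frac: tuple[float, float],
    shape: tuple[int, int],
) -> np.ndarray:
    """Place one ellipse fully inside the dorsal part of ``interior``."""
    h, w = shape
    scale = min(h, w)
    for _ in range(_MAX_PLACEMENT_TRIES):
        rr0 = rng.uniform(0, top_row_max)
        cc0 = rng.uniform(0, w - 1)
        r_rad = rng.uniform(*radius_frac) * scale
        c_rad = rng.uniform(*radius_frac) * scale
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(rr0, cc0, r_rad, c_rad, shape=shape, rotation=rot)
        if rr.size == 0:
            continue
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        if mask[top_row_max + 1 :, :].any():
            continue
        if not interior[mask].all():
            continue
        return mask
    raise ValueError(
        "elements cannot fit inside contour: reduce element count/size or "
        "epidermis thickness"
    )


def generate_label_section(spec: SectionSpec) -> LabelImage:
    """Generate one ground-truth label section; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    contour = _symmetric_contour(spec, rng)
    inner = ndi.binary_erosion(
        contour, iterations=spec.epidermis_thickness_px, border_value=0
    )
    ring = contour & ~inner
    # elements stay clear of the epidermis by a 2 px margin
    interior = ndi.binary_erosion(inner, iterations=2, border_value=0)
    top_row_max = int(np.floor((h - 1) / 2.0))

    labels = np.full((h, w), spec.palette.background_index, dtype=np.uint8)
    labels[inner] = 4

    for class_index, count, radius_frac in (
        (2, spec.n_cartilage, (0.035, 0.065)),
        (3, spec.n_muscle, (0.045, 0.085)),
    ):
        for _ in range(count):
            dorsal = _draw_element(rng, interior, top_row_max, radius_frac, (h, w))
            if rng.random() < spec.asymmetry:
                ventral = _draw_element(rng, interior, top_row_max, radius_frac, (h, w))[
                    ::-1, :
                ]
            else:
                ventral = dorsal[::-1, :]
            labels[dorsal | ventral] = class_index

    labels[ring] = 5
    return LabelImage(labels, spec.palette, spec.scale_um_per_px)


def contour_axis_points(
    labels: LabelImage, col: int | None = None
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Dorsal/ventral end points: extreme non-background rows at one column.

    Defaults to the central column.  On a mirror-symmetric section the two
    points are mirror partners, so the axis midpoint is the exact mid-row.
    """
    if col is None:
        col = labels.shape[1] // 2
    fg = labels.labels[:, col] != labels.palette.background_index
    rows = np.flatnonzero(fg)
    if rows.size == 0:
        raise ValueError(f"no tissue found at column {col}")
    return (int(rows[0]), col), (int(rows[-1]), col)


def render_staining(
    labels: LabelImage,
    stain: StainModel | None = None,
    seed: int = 0,
    multiplier: float | None = None,
) -> RGBImage:
    """Render a label section to a noisy trichrome-like RGB image.

    With ``noise_sd = 0`` and multiplier 1 the render reproduces the stain
    mean colors exactly.
    """
    stain = stain or StainModel()
    rng = np.random.default_rng(seed)
    if multiplier is None:
        multiplier = float(rng.uniform(*stain.multiplier_range))
    lut = np.zeros((6, 3), dtype=np.float64)
    for idx, col in stain.mean_colors.items():
        lut[idx] = col
    img = lut[labels.labels] * multiplier
    if stain.noise_sd > 0:
        img = img + rng.normal(0.0, stain.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return RGBImage(img, labels.scale_um_per_px)


@dataclass
class CohortSample:
    """One generated sample: ground truth, render, and its provenance."""

    sample_id: str
    group: str
    asymmetry: float
    layout_seed: int
    stain_seed: int
    multiplier: float
    labels: LabelImage
    rgb: RGBImage
    dorsal_point: tuple[int, int]
    ventral_point: tuple[int, int]


def make_cohort(
    spec_template: SectionSpec,
    group_asymmetries: list[float],
    n_per_group: int,
    seed: int,
    stain: StainModel | None = None,
    group_names: list[str] | None = None,
) -> list[CohortSample]:
    """Generate a seeded cohort of sections across asymmetry groups.

    Each sample receives a fresh layout seed and a fresh stain draw (hence
    its own intensity multiplier), all derived reproducibly from the master
    seed.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    stain = stain or StainModel()
    if group_names is None:
        group_names = [f"asym{a:g}" for a in group_asymmetries]
    if len(group_names) != len(group_asymmetries):
        raise ValueError("group_names must match group_asymmetries in length")
    master = np.random.default_rng(seed)
    cohort: list[CohortSample] = []
    for gname, asym in zip(group_names, group_asymmetries):
        for i in range(n_per_group):
            layout_seed = int(master.integers(0, 2**31 - 1))
            stain_seed = int(master.integers(0, 2**31 - 1))
            spec = SectionSpec(
                height_px=spec_template.height_px,
                width_px=spec_template.width_px,
                scale_um_per_px=spec_template.scale_um_per_px,
                n_cartilage=spec_template.n_cartilage,
                n_muscle=spec_template.n_muscle,
                epidermis_thickness_px=spec_template.epidermis_thickness_px,
                asymmetry=asym,
                seed=layout_seed,
                palette=spec_template.palette,
            )
            labels = generate_label_section(spec)
            # same first draw as render_staining's internal rng
            mult = float(np.random.default_rng(stain_seed).uniform(*stain.multiplier_range))
            rgb = render_staining(labels, stain, seed=stain_seed)
            dorsal, ventral = contour_axis_points(labels)
            cohort.append(
                CohortSample(
                    sample_id=f"{gname}_{i:02d}",
                    group=gname,
                    asymmetry=asym,
                    layout_seed=layout_seed,
                    stain_seed=stain_seed,
                    multiplier=mult,
                    labels=labels,
                    rgb=rgb,
                    dorsal_point=dorsal,
                    ventral_point=ventral,
                )
            )
    return cohort
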