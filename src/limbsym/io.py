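"""Raster and configuration I/O shared by the whole pipeline.

Conventions fixed repo-wide: coordinates are row-major, 0-based, origin at
the top-left; rows increase ventrally, so the top of an image is dorsal.
Label images carry class indices 1..5 tied to a :class:`ClassPalette`;
background is a first-class class (class 1), not a mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = [
    "ClassPalette",
    "RGBImage",
    "LabelImage",
    "SectionConfig",
    "DEFAULT_PALETTE",
    "read_rgb",
    "write_rgb",
    "read_label",
    "write_label",
    "read_config",
    "write_config",
]


@dataclass(frozen=True)
class ClassPalette:
    """Ordered mapping of tissue class index -> (name, display color).

    The five-class scheme is: 1 background, 2 cartilage, 3 muscle,
    4 other connective tissue, 5 epidermis.
    """

    entries: tuple[tuple[int, str, tuple[int, int, int]], ...]
    background_index: int = 1

    def __post_init__(self) -> None:
        if len(self.entries) != 5:
            raise ValueError(f"palette must have exactly 5 entries, got {len(self.entries)}")
        indices = [e[0] for e in self.entries]
        if sorted(indices) != [1, 2, 3, 4, 5]:
            raise ValueError(f"class indices must be exactly 1..5, got {indices}")
        colors = [tuple(e[2]) for e in self.entries]
        if len(set(colors)) != len(colors):
            raise ValueError("palette colors must be pairwise distinct")
        for c in colors:
            if len(c) != 3 or any(not (0 <= v <= 255) for v in c):
                raise ValueError(f"invalid RGB color {c}")
        if self.background_index not in indices:
            raise ValueError("background_index must be a declared class index")

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(e[0] for e in self.entries)

    def color(self, class_index: int) -> tuple[int, int, int]:
        for idx, _, col in self.entries:
            if idx == class_index:
                return tuple(col)
        raise KeyError(f"class index {class_index} not in palette")

    def name(self, class_index: int) -> str:
        for idx, name, _ in self.entries:
            if idx == class_index:
                return name
        raise KeyError(f"class index {class_index} not in palette")

    def color_to_index(self) -> dict[tuple[int, int, int], int]:
        return {tuple(col): idx for idx, _, col in self.entries}

    def to_jsonable(self) -> list:
        return [[idx, name, list(col)] for idx, name, col in self.entries]

    @classmethod
    def from_jsonable(cls, data: Sequence) -> "ClassPalette":
        return cls(tuple((int(i), str(n), tuple(int(v) for v in c)) for i, n, c in data))


#: Default display palette. Background is near-white as in a cleared
#: trichrome slide; cartilage blue, muscle red, connective pale green,
#: epidermis purple. Exact values are arbitrary but must stay distinct.
DEFAULT_PALETTE = ClassPalette(
    (
        (1, "background", (255, 255, 255)),
        (2, "cartilage", (60, 100, 220)),
        (3, "muscle", (200, 50, 60)),
        (4, "connective", (130, 200, 180)),
        (5, "epidermis", (150, 80, 160)),
    )
)


@dataclass
class RGBImage:
    """H×W×3 8-bit raster with a physical scale in μm per pixel."""

    pixels: np.ndarray
    scale_um_per_px: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H×W×3, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LabelImage:
    """H×W raster of class indices tied to a palette."""

    labels: np.ndarray
    palette: ClassPalette
    scale_um_per_px: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {self.labels.shape}")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be positive")
        present = np.unique(self.labels)
        declared = set(self.palette.indices)
        bad = [int(v) for v in present if int(v) not in declared]
        if bad:
            raise ValueError(f"labels contain undeclared class indices {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def to_rgb(self) -> RGBImage:
        """Render each class as its palette color."""
        out = np.zeros(self.labels.shape + (3,), dtype=np.uint8)
        for idx, _, col in self.palette.entries:
            out[self.labels == idx] = col
        return RGBImage(out, self.scale_um_per_px)


@dataclass
class SectionConfig:
    """JSON sidecar: physical scale and the manually placed axis endpoints."""

    scale_um_per_px: float
    dorsal_point: tuple[float, float] | None = None
    ventral_point: tuple[float, float] | None = None
    palette: ClassPalette = field(default_factory=lambda: DEFAULT_PALETTE)


def _open_raster(path: str | Path) -> Image.Image:
    try:
        return Image.open(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc


def read_rgb(path: str | Path, scale_um_per_px: float) -> RGBImage:
    """Read a PNG or TIFF color raster.

    Alpha channels are dropped; anything that is not 3- or 4-channel color
    (e.g. grayscale) is rejected so scale/channel mistakes fail loudly.
    """
    img = _open_raster(path)
    if img.mode == "RGBA":
        img = img.convert("RGB")
    if img.mode != "RGB":
        raise ValueError(
            f"unsupported channel count: {path!r} has mode {img.mode!r}, expected RGB(A)"
        )
    return RGBImage(np.asarray(img, dtype=np.uint8), scale_um_per_px)


def write_rgb(path: str | Path, img: RGBImage) -> None:
    """Write a lossless PNG/TIFF; round-trips bit-exactly with read_rgb."""
    Image.fromarray(img.pixels, mode="RGB").save(path)


def read_label(
    path: str | Path, palette: ClassPalette, scale_um_per_px: float
) -> LabelImage:
    """Read an indexed or RGB label image; colors must match the palette exactly."""
    img = _open_raster(path)
    rgb = np.asarray(img.convert("RGB"), dtype=np.uint8)
    lut = palette.color_to_index()
    labels = np.zeros(rgb.shape[:2], dtype=np.uint8)
    matched = np.zeros(rgb.shape[:2], dtype=bool)
    for col, idx in lut.items():
        m = np.all(rgb == np.asarray(col, dtype=np.uint8), axis=-1)
        labels[m] = idx
        matched |= m
    if not matched.all():
        r, c = np.argwhere(~matched)[0]
        offending = tuple(int(v) for v in rgb[r, c])
        raise ValueError(
            f"color {offending} at (row={r}, col={c}) is not in the palette"
        )
    return LabelImage(labels, palette, scale_um_per_px)


def write_label(path: str | Path, label_img: LabelImage) -> None:
    """Write a paletted PNG whose palette slots hold the exact class colors."""
    pil = Image.fromarray(label_img.labels, mode="P")
    flat = [0, 0, 0] * 256
    for idx, _, col in label_img.palette.entries:
        flat[3 * idx : 3 * idx + 3] = list(col)
    pil.putpalette(flat)
    pil.save(path, format="PNG")


def write_config(path: str | Path, cfg: SectionConfig) -> None:
    data = {
        "scale_um_per_px": cfg.scale_um_per_px,
        "dorsal_point": list(cfg.dorsal_point) if cfg.dorsal_point else None,
        "ventral_point": list(cfg.ventral_point) if cfg.ventral_point else None,
        "palette": cfg.palette.to_jsonable(),
    }
    Path(path).write_text(json.dumps(data, indent=1))


def read_config(path: str | Path) -> SectionConfig:
    data = json.loads(Path(path).read_text())
    return SectionConfig(
        scale_um_per_px=float(data["scale_um_per_px"]),
        dorsal_point=tuple(data["dorsal_point"]) if data.get("dorsal_point") else None,
        ventral_point=tuple(data["ventral_point"]) if data.get("ventral_point") else None,
        palette=ClassPalette.from_jsonable(data["palette"])
        if data.get("palette")
        else DEFAULT_PALETTE,
    )
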