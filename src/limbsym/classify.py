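"""Per-sample trainable pixel classification of stained sections.

The workflow mirrors interactive trainable-segmentation tools: the user
scribbles a few pixels per tissue class on each section, a multi-scale
feature stack is computed from the RGB image, a seeded random-forest is fit
on exactly the annotated pixels, and every pixel is then assigned one of
the five classes.  One classifier per sample is the default because
staining intensity varies from slide to slide; annotations may be shared
across sections cut from the same limb.

Feature bank (per channel): raw intensity, plus Gaussian-smoothed
intensity, gradient magnitude and Laplacian at each requested scale, so
``F = 3 × (1 + 3·n_scales)``.  Boundaries are handled by reflection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from sklearn.ensemble import RandomForestClassifier

from .io import DEFAULT_PALETTE, ClassPalette, LabelImage, RGBImage

__all__ = [
    "AnnotationSet",
    "FeatureStack",
    "PixelClassifier",
    "DEFAULT_SCALES",
    "extract_features",
    "train",
    "classify",
    "sample_annotations",
    "save_model",
    "load_model",
]

DEFAULT_SCALES: tuple[float, ...] = (1.0, 2.0, 4.0)

_MODEL_FORMAT_VERSION = 1


@dataclass
class AnnotationSet:
    """Sparse scribble annotations: (row, col, class_index) strokes."""

    strokes: np.ndarray  # (n, 3) int array
    source_image: str = ""

    def __post_init__(self) -> None:
        self.strokes = np.asarray(self.strokes, dtype=np.int64).reshape(-1, 3)
        classes = np.unique(self.strokes[:, 2])
        bad = [int(c) for c in classes if not 1 <= c <= 5]
        if bad:
            raise ValueError(f"annotation class indices must be in 1..5, got {bad}")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.strokes[:, 2])

    def counts(self) -> dict[int, int]:
        cls, n = np.unique(self.strokes[:, 2], return_counts=True)
        return {int(c): int(k) for c, k in zip(cls, n)}

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.strokes, columns=["row", "col", "class_index"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, source_image: str = "") -> "AnnotationSet":
        df = pd.read_csv(path)
        return cls(df[["row", "col", "class_index"]].to_numpy(), source_image)


@dataclass
class FeatureStack:
    """H×W×F real-valued feature raster with named features."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    scales: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("feature stack must be H×W×F")
        if self.values.shape[2] != len(self.feature_names):
            raise ValueError("feature_names must match the stack depth")
        if not np.isfinite(self.values).all():
            raise ValueError("feature stack contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[2]


def extract_features(
    img: RGBImage, scales: tuple[float, ...] | list[float] = DEFAULT_SCALES
) -> FeatureStack:
    """Multi-scale color/edge/texture features per channel.

    For each channel: the raw intensity, then per scale σ the
    Gaussian-smoothed intensity, the Gaussian gradient magnitude and the
    Gaussian Laplacian (all computed with reflective boundaries).
    """
    scales = tuple(float(s) for s in scales)
    if len(scales) == 0:
        raise ValueError("at least one scale is required")
    if any(s <= 0 for s in scales):
        raise ValueError(f"scales must be positive, got {scales}")
    x = img.pixels.astype(np.float64)
    planes: list[np.ndarray] = []
    names: list[str] = []
    # DC response of the truncated LoG kernel; subtracted so a constant
    # signal yields an exactly zero Laplacian feature
    lap_dc = {
        s: float(ndi.gaussian_laplace(np.ones((1, 1)), s, mode="reflect")[0, 0])
        for s in scales
    }
    for ch, ch_name in enumerate("RGB"):
        planes.append(x[:, :, ch])
        names.append(f"{ch_name}_raw")
    for s in scales:
        for ch, ch_name in enumerate("RGB"):
            c = x[:, :, ch]
            planes.append(ndi.gaussian_filter(c, s, mode="reflect"))
            names.append(f"{ch_name}_gauss_{s:g}")
            planes.append(ndi.gaussian_gradient_magnitude(c, s, mode="reflect"))
            names.append(f"{ch_name}_gradmag_{s:g}")
            smoothed = ndi.gaussian_filter(c, s, mode="reflect")
            planes.append(
                ndi.gaussian_laplace(c, s, mode="reflect") - lap_dc[s] * smoothed
            )
            names.append(f"{ch_name}_laplace_{s:g}")
    return FeatureStack(np.stack(planes, axis=-1), tuple(names), scales)


@dataclass
class PixelClassifier:
    """A trained per-sample discriminative model over feature vectors."""

    model: RandomForestClassifier
    classes: tuple[int, ...]
    feature_names: tuple[str, ...]
    annotation_counts: dict[int, int] = field(default_factory=dict)
    seed: int = 0


def train(
    features: FeatureStack, ann: AnnotationSet, seed: int = 0, n_trees: int = 100
) -> PixelClassifier:
    """Fit a seeded random forest on exactly the annotated pixels.

    Requires at least two distinct classes and at least one annotated pixel
    for every class that appears.
    """
    counts = ann.counts()
    if len(counts) < 2:
        raise ValueError(
            f"need annotations for >= 2 distinct classes, got {sorted(counts)}"
        )
    zero = [c for c, n in counts.items() if n == 0]
    if zero:
        raise ValueError(f"classes with zero annotations: {zero}")
    h, w, _ = features.values.shape
    rows, cols = ann.strokes[:, 0], ann.strokes[:, 1]
    if (rows < 0).any() or (rows >= h).any() or (cols < 0).any() or (cols >= w).any():
        raise ValueError("annotation coordinates fall outside the image")
    X = features.values[rows, cols, :]
    y = ann.strokes[:, 2]
    model = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    model.fit(X, y)
    return PixelClassifier(
        model=model,
        classes=tuple(int(c) for c in model.classes_),
        feature_names=features.feature_names,
        annotation_counts=counts,
        seed=seed,
    )


def classify(
    clf: PixelClassifier,
    features: FeatureStack,
    palette: ClassPalette | None = None,
    scale_um_per_px: float = 1.0,
) -> LabelImage:
    """Assign every pixel one trained class; ties go to the lowest index.

    ``model.classes_`` is sorted ascending, and argmax over the probability
    matrix returns the first maximum, so equal votes resolve to the lowest
    class index deterministically.
    """
    if features.feature_names != clf.feature_names:
        raise ValueError(
            "feature layout mismatch between training and classification: "
            f"{clf.feature_names} vs {features.feature_names}"
        )
    h, w, f = features.values.shape
    proba = clf.model.predict_proba(features.values.reshape(-1, f))
    pred = np.asarray(clf.classes, dtype=np.uint8)[np.argmax(proba, axis=1)]
    return LabelImage(pred.reshape(h, w), palette or DEFAULT_PALETTE, scale_um_per_px)


def sample_annotations(
    truth: LabelImage, n_per_class: int, seed: int = 0
) -> AnnotationSet:
    """Draw seeded scribbles from a ground-truth label image.

    Emulates the user's sparse per-class annotations on synthetic sections;
    classes absent from the image are simply not annotated.
    """
    rng = np.random.default_rng(seed)
    strokes = []
    for c in np.unique(truth.labels):
        rr, cc = np.nonzero(truth.labels == c)
        k = min(n_per_class, rr.size)
        pick = rng.choice(rr.size, size=k, replace=False)
        for i in pick:
            strokes.append((int(rr[i]), int(cc[i]), int(c)))
    return AnnotationSet(np.asarray(strokes, dtype=np.int64))


def save_model(clf: PixelClassifier, path: str | Path) -> None:
    """Serialise a trained classifier to one file with a version header."""
    joblib.dump(
        {
            "format_version": _MODEL_FORMAT_VERSION,
            "model": clf.model,
            "classes": clf.classes,
            "feature_names": clf.feature_names,
            "annotation_counts": clf.annotation_counts,
            "seed": clf.seed,
        },
        path,
    )


def load_model(path: str | Path) -> PixelClassifier:
    data = joblib.load(path)
    version = data.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {version!r}")
    return PixelClassifier(
        model=data["model"],
        classes=tuple(data["classes"]),
        feature_names=tuple(data["feature_names"]),
        annotation_counts=dict(data["annotation_counts"]),
        seed=int(data["seed"]),
    )
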