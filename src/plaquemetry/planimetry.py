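"""Planimetry of two-tone disclosed-plaque images.

The disclosing agent stains new plaque pink and dense/mature plaque
purple; both dyes absorb green light, so the green channel carries the
best plaque/enamel contrast and anchors the feature bank. Segmentation
uses a trainable pixel classifier (random forest over a fixed, versioned
feature bank) into three classes — non-plaque, light/pink plaque,
dark/purple plaque — trained from sparse pixel annotations.

Indices per ROI (all percent of ROI pixel count):

    PLANIdark  = 100 * dark pixels / ROI pixels
    PLANItot   = 100 * (dark + light pixels) / ROI pixels
    PLANIlight = PLANItot - PLANIdark        (held exactly, by construction)
    relPLANIdark  = PLANIdark  / PLANItot * 100   (undefined when PLANItot = 0)
    relPLANIlight = PLANIlight / PLANItot * 100

A single three-class model is fitted rather than two binary passes, which
rules out dark-not-subset-of-total inconsistencies; a two-pass mode that
reproduces the original two-run arithmetic is available and yields the
same indices through the subtraction identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import remove_small_objects
from sklearn.ensemble import RandomForestClassifier

from .core import ValidationError

log = logging.getLogger(__name__)

CLASS_NON_PLAQUE = 0
CLASS_LIGHT_PINK = 1
CLASS_DARK_PURPLE = 2
CLASS_NAMES = {CLASS_NON_PLAQUE: "non_plaque", CLASS_LIGHT_PINK: "light_pink", CLASS_DARK_PURPLE: "dark_purple"}

MIN_LABELS_PER_CLASS = 50
MIN_COMPONENT_PX = 5

GAUSSIAN_SIGMAS = (1, 2, 4, 8)
MEDIAN_RADII = (2, 5)


@dataclass
class DisclosedImage:
    """One disclosed buccal tooth-surface screenshot with its ROI pixel mask."""

    rgb: np.ndarray  # H x W x 3, uint8
    roi_pixel_mask: np.ndarray  # H x W bool
    tooth_id: str | None = None

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        self.roi_pixel_mask = np.asarray(self.roi_pixel_mask, dtype=bool)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValidationError("rgb must be H x W x 3")
        if self.roi_pixel_mask.shape != self.rgb.shape[:2]:
            raise ValidationError("roi_pixel_mask shape must match image")
        if not self.roi_pixel_mask.any():
            raise ValidationError("empty ROI pixel mask")


@dataclass
class PlanimetricIndices:
    plani_tot: float
    plani_dark: float
    plani_light: float
    rel_dark: float  # NaN when undefined (PLANItot = 0)
    rel_light: float

    def __post_init__(self) -> None:
        if not (0 <= self.plani_dark <= self.plani_tot <= 100 + 1e-9):
            raise ValidationError("need 0 <= PLANIdark <= PLANItot <= 100")
        if self.plani_light != self.plani_tot - self.plani_dark:
            raise ValidationError("PLANIlight must equal PLANItot - PLANIdark exactly")

    @property
    def rel_defined(self) -> bool:
        return not np.isnan(self.rel_dark)


def green_channel_gray(img: DisclosedImage) -> np.ndarray:
    """The green channel as an 8-bit grayscale raster.

    Pink and purple dyes absorb green, so plaque appears dark against the
    bright enamel.
    """
    return img.rgb[:, :, 1].astype(np.uint8)


def feature_stack(rgb: np.ndarray) -> np.ndarray:
    """Fixed per-pixel feature bank (H x W x F, float32).

    Raw R/G/B; the green-channel gray; Gaussian blurs of it at sigma 1, 2,
    4, 8 px; Sobel gradient magnitude; differences of Gaussians (1-2,
    2-4, 4-8); local median and local variance at radii 2 and 5 px.
    """
    rgb = np.asarray(rgb, dtype=np.float32)
    g = rgb[:, :, 1]
    feats = [rgb[:, :, 0], g, rgb[:, :, 2]]
    blurs = [ndimage.gaussian_filter(g, s) for s in GAUSSIAN_SIGMAS]
    feats.extend(blurs)
    gx = ndimage.sobel(g, axis=0)
    gy = ndimage.sobel(g, axis=1)
    feats.append(np.hypot(gx, gy))
    for a, b in zip(blurs, blurs[1:]):
        feats.append(a - b)
    for r in MEDIAN_RADII:
        size = 2 * r + 1
        feats.append(ndimage.median_filter(g, size=size))
        mean = ndimage.uniform_filter(g, size=size)
        mean_sq = ndimage.uniform_filter(g * g, size=size)
        feats.append(np.maximum(mean_sq - mean * mean, 0.0))
    return np.stack(feats, axis=-1)


@dataclass
class PixelClassifier:
    """Trainable three-class pixel classifier (random forest on the feature bank)."""

    model: RandomForestClassifier
    seed: int
    n_per_class: dict[int, int] = field(default_factory=dict)

    def predict(self, rgb: np.ndarray) -> np.ndarray:
        feats = feature_stack(rgb)
        h, w, f = feats.shape
        pred = self.model.predict(feats.reshape(-1, f))
        return pred.reshape(h, w).astype(np.uint8)


def train_classifier(
    images: list[DisclosedImage],
    labels: list[np.ndarray],
    seed: int = 0,
    n_trees: int = 100,
) -> PixelClassifier:
    """Fit the pixel classifier from sparse annotations.

    ``labels`` hold, per image, -1 for unannotated pixels and a class id
    (0 non-plaque, 1 light/pink, 2 dark/purple) where annotated. At least
    50 annotated pixels are required per class. Deterministic for a fixed
    seed and training set.
    """
    xs, ys = [], []
    for img, lab in zip(images, labels):
        lab = np.asarray(lab)
        if lab.shape != img.rgb.shape[:2]:
            raise ValidationError("label raster shape must match image")
        feats = feature_stack(img.rgb)
        sel = lab >= 0
        xs.append(feats[sel])
        ys.append(lab[sel])
    x = np.concatenate(xs)
    y = np.concatenate(ys).astype(int)
    counts = {c: int(np.sum(y == c)) for c in (CLASS_NON_PLAQUE, CLASS_LIGHT_PINK, CLASS_DARK_PURPLE)}
    for c, n in counts.items():
        if n < MIN_LABELS_PER_CLASS:
            raise ValidationError(
                f"class {CLASS_NAMES[c]} has {n} labelled pixels (need >= {MIN_LABELS_PER_CLASS})"
            )
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(x, y)
    return PixelClassifier(model=model, seed=seed, n_per_class=counts)


def segment(
    img: DisclosedImage, clf: PixelClassifier, min_component_px: int = MIN_COMPONENT_PX
) -> np.ndarray:
    """Per-pixel class raster; non-ROI pixels are non-plaque.

    Connected plaque components smaller than ``min_component_px`` are
    removed (speck filter).
    """
    pred = clf.predict(img.rgb)
    pred[~img.roi_pixel_mask] = CLASS_NON_PLAQUE
    if min_component_px > 1:
        plaque = pred > CLASS_NON_PLAQUE
        kept = remove_small_objects(plaque, max_size=min_component_px - 1)
        pred[plaque & ~kept] = CLASS_NON_PLAQUE
    return pred


def planimetric_indices(seg: np.ndarray, roi_pixel_mask: np.ndarray) -> PlanimetricIndices:
    """Coverage indices from a segmented raster.

    Relative values are undefined (NaN, flagged) at PLANItot = 0 rather
    than forced to zero, to avoid biasing downstream correlations.
    """
    roi = np.asarray(roi_pixel_mask, dtype=bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValidationError("empty ROI pixel mask")
    s = np.asarray(seg)[roi]
    n_dark = int(np.sum(s == CLASS_DARK_PURPLE))
    n_light = int(np.sum(s == CLASS_LIGHT_PINK))
    plani_dark = 100.0 * n_dark / n_roi
    plani_tot = 100.0 * (n_dark + n_light) / n_roi
    plani_light = plani_tot - plani_dark  # subtraction identity, bit-exact
    if plani_tot > 0:
        rel_dark = plani_dark / plani_tot * 100.0
        rel_light = 100.0 - rel_dark
    else:
        log.warning("PLANItot = 0: relative planimetric values undefined")
        rel_dark = rel_light = float("nan")
    return PlanimetricIndices(
        plani_tot=plani_tot,
        plani_dark=plani_dark,
        plani_light=plani_light,
        rel_dark=rel_dark,
        rel_light=rel_light,
    )


def indices_two_pass(seg: np.ndarray, roi_pixel_mask: np.ndarray) -> PlanimetricIndices:
    """Two-pass arithmetic: measure dark and total separately, light by subtraction.

    Reproduces the original two-run procedure exactly; on a three-class
    segmentation it coincides with :func:`planimetric_indices` because the
    classes partition the ROI.
    """
    roi = np.asarray(roi_pixel_mask, dtype=bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValidationError("empty ROI pixel mask")
    s = np.asarray(seg)[roi]
    plani_dark = 100.0 * int(np.sum(s == CLASS_DARK_PURPLE)) / n_roi
    plani_tot = 100.0 * int(np.sum(s > CLASS_NON_PLAQUE)) / n_roi
    plani_light = plani_tot - plani_dark
    if plani_tot > 0:
        rel_dark = plani_dark / plani_tot * 100.0
        rel_light = 100.0 - rel_dark
    else:
        rel_dark = rel_light = float("nan")
    return PlanimetricIndices(plani_tot, plani_dark, plani_light, rel_dark, rel_light)


def iou_per_class(seg: np.ndarray, truth: np.ndarray, roi_pixel_mask: np.ndarray) -> dict[str, float]:
    """Intersection-over-union per class inside the ROI (evaluation helper)."""
    roi = np.asarray(roi_pixel_mask, dtype=bool)
    out = {}
    for c, name in CLASS_NAMES.items():
        a = (np.asarray(seg) == c) & roi
        b = (np.asarray(truth) == c) & roi
        union = np.sum(a | b)
        out[name] = float(np.sum(a & b) / union) if union else float("nan")
    return out
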