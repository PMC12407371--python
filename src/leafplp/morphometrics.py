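"""Leaf-shape morphometrics from scaled photographs.

A leaf is photographed flat on a white sheet with a known scale
(pixels per cm).  From the segmented blade we measure the condition
vector used throughout the pipeline: area A (cm^2), perimeter P (cm),
area-to-perimeter ratio A/P (cm), caliper thickness T (um, supplied
separately) and skewness S (unitless, third standardized moment of the
pixel distribution projected on the blade's major principal axis).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .errors import (
    InvalidArgumentError,
    SegmentationEmptyError,
    UndefinedMomentError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LeafImage",
    "LeafMask",
    "LeafFeatures",
    "segment_leaf",
    "measure_area",
    "measure_perimeter",
    "measure_skewness",
    "extract_features",
    "read_image",
]


@dataclass
class LeafImage:
    """An 8-bit grayscale raster with a physical scale.

    ``ground_truth`` is populated by the synthetic renderer (true mask,
    area, perimeter, skewness at pixel resolution); it is ``None`` for
    real photographs.
    """

    pixels: np.ndarray
    px_per_cm: float
    ground_truth: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InvalidArgumentError("image must be a non-empty 2-D raster")
        if not self.px_per_cm > 0:
            raise InvalidArgumentError("px_per_cm must be positive")


@dataclass
class LeafMask:
    """Binary foreground mask carrying the source image's scale."""

    mask: np.ndarray
    px_per_cm: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise InvalidArgumentError("mask must be 2-D")
        if not self.mask.any():
            raise SegmentationEmptyError("mask has no foreground pixels")
        if not self.px_per_cm > 0:
            raise InvalidArgumentError("px_per_cm must be positive")


_FEATURE_NAMES = ("area", "perimeter", "ap_ratio", "thickness", "skewness")


@dataclass(frozen=True)
class LeafFeatures:
    """The five-element condition vector c = (A, P, A/P, T, S)."""

    area: float  # cm^2
    perimeter: float  # cm
    ap_ratio: float  # cm
    thickness: float  # um
    skewness: float  # unitless

    def __post_init__(self):
        if not (self.area > 0 and self.perimeter > 0 and self.thickness > 0):
            raise InvalidArgumentError("area, perimeter and thickness must be positive")
        if abs(self.ap_ratio - self.area / self.perimeter) > 1e-9 * self.area:
            raise InvalidArgumentError("ap_ratio must equal area/perimeter")

    @classmethod
    def from_measurements(
        cls, area: float, perimeter: float, thickness: float, skewness: float
    ) -> "LeafFeatures":
        """Build a feature vector, deriving A/P from A and P."""
        return cls(area, perimeter, area / perimeter, thickness, skewness)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.area, self.perimeter, self.ap_ratio, self.thickness, self.skewness],
            dtype=float,
        )

    names = _FEATURE_NAMES


def segment_leaf(image: LeafImage, threshold_policy: str = "dark") -> LeafMask:
    """Segment the blade from a high-contrast leaf-on-white-paper photograph.

    Otsu's global threshold splits the histogram; ``threshold_policy``
    selects whether the blade is the dark ("dark", default) or the
    bright ("bright") side.  The largest connected component is kept and
    its holes filled, so specular spots on the blade do not puncture the
    mask.
    """
    px = np.asarray(image.pixels, dtype=float)
    if np.ptp(px) == 0:
        raise SegmentationEmptyError("image has a single gray level; nothing to segment")
    if threshold_policy == "bright":
        # reflect intensities so the same dark-side rule applies; a pure
        # contrast inversion then yields the identical mask
        px = (px.min() + px.max()) - px
    elif threshold_policy != "dark":
        raise InvalidArgumentError(f"unknown threshold policy {threshold_policy!r}")
    thr = filters.threshold_otsu(px)
    fg = px < thr
    if not fg.any():
        raise SegmentationEmptyError("threshold produced an empty foreground")

    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    fg = labels == counts.argmax()
    fg = ndimage.binary_fill_holes(fg)

    touched = sum(
        int(edge.any()) for edge in (fg[0, :], fg[-1, :], fg[:, 0], fg[:, -1])
    )
    if touched >= 3:
        warnings.warn("foreground touches 3+ image borders; check framing/scale", stacklevel=2)
    return LeafMask(fg, image.px_per_cm)


def measure_area(mask: LeafMask) -> float:
    """Blade area in cm^2: foreground pixel count / (px_per_cm)^2."""
    return float(mask.mask.sum()) / mask.px_per_cm**2


def measure_perimeter(mask: LeafMask) -> float:
    """Blade perimeter in cm via sub-pixel contour tracing.

    The mask is lightly smoothed (Gaussian, sigma = 1 px) and its
    0.5-level marching-squares contour traced; summing the polyline's
    Euclidean segment lengths weights diagonal steps by sqrt(2).  The
    smoothing suppresses the staircase over-estimate that raw
    pixel-edge counting (or an unsmoothed contour) suffers on smooth
    boundaries, at the cost of slightly rounding sharp corners.
    """
    smoothed = ndimage.gaussian_filter(mask.mask.astype(float), 1.0)
    contours = measure.find_contours(smoothed, 0.5)
    if not contours:
        raise SegmentationEmptyError("mask has no traceable boundary")
    # after hole-filling a single outer contour dominates; sum all for safety
    total = 0.0
    for c in contours:
        seg = np.diff(c, axis=0)
        total += float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    return total / mask.px_per_cm


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Unit major principal axis of centered pixel coordinates.

    Orientation is fixed deterministically (positive column component,
    tie-broken by positive row component) so the sign of odd moments is
    reproducible and negates under mirror reflection.
    """
    cov = np.cov(coords.T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    if axis[1] < 0 or (axis[1] == 0 and axis[0] < 0):
        axis = -axis
    return axis


def measure_skewness(mask: LeafMask) -> float:
    """Third standardized moment along the mask's major principal axis.

    Positive values mean pixel mass is concentrated toward the
    axis-negative end with a tail toward the axis-positive end, the
    usual sign convention for sample skewness.
    """
    coords = np.argwhere(mask.mask).astype(float)
    if len(coords) < 2:
        raise UndefinedMomentError("skewness undefined for a <2-pixel mask")
    centered = coords - coords.mean(axis=0)
    axis = _principal_axis(coords)
    t = centered @ axis
    var = float(np.mean(t**2))
    if var <= 0:
        raise UndefinedMomentError("degenerate mask: zero variance along major axis")
    return float(np.mean(t**3) / var**1.5)


def extract_features(
    image: LeafImage, thickness: float, threshold_policy: str = "dark"
) -> LeafFeatures:
    """Full morphometric pipeline: segment, then measure A, P, A/P, S.

    ``thickness`` is the caliper reading in micrometers, measured on a
    vein-free blade region; it is passed through unchanged.
    """
    if not thickness > 0:
        raise InvalidArgumentError("thickness must be positive (um)")
    mask = segment_leaf(image, threshold_policy)
    area = measure_area(mask)
    perimeter = measure_perimeter(mask)
    skew = measure_skewness(mask)
    return LeafFeatures.from_measurements(area, perimeter, thickness, skew)


def read_image(path, px_per_cm: float) -> LeafImage:
    """Load a PNG/TIFF photograph as a grayscale LeafImage."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    return LeafImage(arr.astype(np.uint8), px_per_cm)
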