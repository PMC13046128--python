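"""Per-channel image processing for spinal-cord cross-sections.

The processing chain turns a confocal z-stack of one fluorescence channel
into a clean binary mask of candidate cells:

    max projection -> gray-matter masking -> rolling-ball background
    subtraction -> maximum-entropy threshold -> despeckle + closing

The order matters: the threshold is computed on background-subtracted,
in-mask pixels only, so masking and subtraction must precede it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import closing, disk, opening

U16_MAX = 65535


class DegenerateHistogramError(ValueError):
    """Raised when an image is constant inside the mask and no threshold exists."""


@dataclass
class ChannelStack:
    """One marker's z-stack with pixel calibration.

    Parameters
    ----------
    voxels : ndarray, shape (z, y, x)
        Intensity values in the unsigned 16-bit range.
    pixel_size : float
        Lateral calibration in micrometres per pixel.
    marker : str
        Fluorescence marker label (e.g. ``"ChAT"``).
    """

    voxels: np.ndarray
    pixel_size: float
    marker: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a (z, y, x) array with >= 1 plane")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]


@dataclass
class SectionGeometry:
    """Spatial reference frame of one cross-section.

    ``gray_mask`` delineates the butterfly-shaped gray matter, ``canal_mask``
    the central canal; ``canal_centroid`` is the (x, y) origin of the polar
    coordinate system.  ``dorsal_up`` records the mounting orientation: when
    True, dorsal is toward smaller row indices.
    """

    gray_mask: np.ndarray
    canal_mask: np.ndarray
    canal_centroid: tuple[float, float]
    dorsal_up: bool = True
    # cached ray-boundary lookup, built lazily by geometry.RadialBoundary
    _boundary_cache: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gray_mask = np.asarray(self.gray_mask).astype(bool)
        self.canal_mask = np.asarray(self.canal_mask).astype(bool)
        if self.gray_mask.shape != self.canal_mask.shape:
            raise ValueError("gray and canal masks must share a shape")


def max_project(stack: ChannelStack | np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a z-stack along the z axis."""
    voxels = stack.voxels if isinstance(stack, ChannelStack) else np.asarray(stack)
    if voxels.ndim != 3 or voxels.shape[0] < 1:
        raise ValueError("expected a non-empty (z, y, x) stack")
    return voxels.max(axis=0)


def apply_mask(image: np.ndarray, gray_mask: np.ndarray) -> np.ndarray:
    """Zero out pixels outside the gray-matter mask; in-mask pixels unchanged."""
    image = np.asarray(image)
    gray_mask = np.asarray(gray_mask).astype(bool)
    if image.shape != gray_mask.shape:
        raise ValueError("image and mask shapes differ")
    return np.where(gray_mask, image, 0)


def subtract_background(image: np.ndarray, radius_px: int = 20) -> np.ndarray:
    """Rolling-ball style background subtraction.

    The smoothly varying background is estimated by a grayscale morphological
    opening with a disk structuring element of the given radius (the flat-ball
    approximation of the rolling ball) and subtracted, clamped at zero.  A
    fast sequence decomposition of the disk footprint is used; the estimate is
    clamped at the image so the subtraction never goes negative.

    Bright features narrower than the disk survive essentially intact: the
    structuring element cannot fit inside them, so the opening flattens them
    into the background estimate.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    footprint = disk(radius_px, decomposition="sequence")
    background = np.minimum(opening(image, footprint), image)
    return image - background


def threshold_max_entropy(
    image: np.ndarray,
    gray_mask: np.ndarray | None = None,
    n_bins: int = 256,
) -> float:
    """Maximum-entropy (Kapur-Sahoo-Wong) threshold of in-mask pixels.

    A 256-bin histogram is built over the observed in-mask intensity range
    (so 16-bit input reproduces the 8-bit histogram dialect of the common
    macro implementation).  The returned threshold is the intensity at the
    upper edge of the selected background bin; candidate splits leaving
    either side empty are not considered, and ties are broken toward the
    lower threshold.

    Pixels outside ``gray_mask`` never influence the result.
    """
    image = np.asarray(image)
    if gray_mask is not None:
        gray_mask = np.asarray(gray_mask).astype(bool)
        if gray_mask.shape != image.shape:
            raise ValueError("image and mask shapes differ")
        values = image[gray_mask]
    else:
        values = image.ravel()
    if values.size == 0:
        raise DegenerateHistogramError("empty mask")
    vmin = float(values.min())
    vmax = float(values.max())
    if vmin == vmax:
        raise DegenerateHistogramError("constant image inside mask")

    hist, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    p = hist / hist.sum()
    cum = np.cumsum(p)

    # entropy contribution of each occupied bin; empty bins contribute 0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cum_plogp = np.cumsum(plogp)

    best_t = -1
    best_obj = -np.inf
    total_plogp = cum_plogp[-1]
    for t in range(n_bins - 1):
        p0 = cum[t]
        p1 = 1.0 - p0
        if p0 <= 0 or p1 <= 0:
            continue
        h0 = np.log(p0) - cum_plogp[t] / p0
        h1 = np.log(p1) - (total_plogp - cum_plogp[t]) / p1
        obj = h0 + h1
        if obj > best_obj + 1e-12:
            best_obj = obj
            best_t = t
    if best_t < 0:
        raise DegenerateHistogramError("no valid threshold candidate")
    return float(edges[best_t + 1])


def binarize_clean(image: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold and clean: despeckle (3x3 median) then 3x3 closing, once.

    Pixels strictly above the threshold are foreground.  The median pass
    removes isolated noise pixels; the closing fills single-pixel holes and
    hairline gaps.
    """
    binary = np.asarray(image) > threshold
    binary = ndi.median_filter(binary.astype(np.uint8), size=3).astype(bool)
    binary = closing(binary, footprint=np.ones((3, 3), dtype=bool))
    return binary


def segment_channel(
    stack: ChannelStack,
    geometry: SectionGeometry,
    rolling_ball_radius_px: int = 20,
    manual_threshold: float | None = None,
) -> np.ndarray:
    """Full per-channel chain from z-stack to clean binary mask.

    ``manual_threshold`` overrides the automatic maximum-entropy value, for
    operator-adjusted thresholding.
    """
    projected = max_project(stack)
    masked = apply_mask(projected, geometry.gray_mask)
    subtracted = subtract_background(masked, rolling_ball_radius_px)
    if manual_threshold is None:
        thr = threshold_max_entropy(subtracted, geometry.gray_mask)
    else:
        thr = manual_threshold
    return binarize_clean(subtracted, thr) & geometry.gray_mask
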