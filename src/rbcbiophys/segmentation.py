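"""Image-processing chain from a raw micrograph to labeled single-cell regions.

The chain mirrors the device's on-phone analysis: convert to 8-bit grayscale,
auto-adjust intensity, threshold to a binary mask, fill the holes left by the
bright biconcave centre of each cell, label connected components, and reject
merged ("stacked") cells by a size/shape rule.  Cells are darker than the
background in this imaging mode; the polarity is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "FrameRole",
    "ImageFrame",
    "CellRegion",
    "StackedCellParams",
    "to_grayscale",
    "adjust_intensity",
    "binarize",
    "fill_holes",
    "label_regions",
    "remove_stacked",
    "segment_frame",
    "region_circularity",
]

#: ITU-R BT.601 luma weights, the standard RGB -> gray conversion.
REC601_WEIGHTS = (0.299, 0.587, 0.114)


class FrameRole(str, Enum):
    PRE_STRESS = "pre_stress"
    POST_STRESS = "post_stress"


@dataclass
class ImageFrame:
    """One 8-bit grayscale raster plus its physical pixel scale.

    Every geometric quantity downstream (areas in µm², diameters in µm) is
    derived from ``pixel_scale``.
    """

    pixels: np.ndarray
    pixel_scale: float  # µm per pixel
    role: FrameRole = FrameRole.PRE_STRESS

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("ImageFrame expects a 2-D raster")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be positive")
        self.role = FrameRole(self.role)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def physical_extent(self) -> tuple[float, float]:
        """(height, width) of the field in µm."""
        h, w = self.pixels.shape
        return h * self.pixel_scale, w * self.pixel_scale


@dataclass
class CellRegion:
    """One segmented cell: pixel set plus the measurements the pipeline needs.

    ``perimeter_px`` uses the estimator selected in :func:`label_regions`
    (Crofton 4-direction by default).  ``solidity`` (area / convex area) is
    cached because the stacked-cell rule consumes it.
    """

    label_id: int
    coords: np.ndarray  # (n, 2) array of (row, col) pixel indices
    area_px: int
    perimeter_px: float
    centroid: tuple[float, float]  # (row, col), sub-pixel
    solidity: float
    touches_border: bool = False
    rejected_stacked: bool = False

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("a region must contain at least one pixel")

    def centroid_um(self, pixel_scale: float) -> tuple[float, float]:
        return self.centroid[0] * pixel_scale, self.centroid[1] * pixel_scale


def region_circularity(region: CellRegion) -> float:
    """Scale-free circularity 4π·area/perimeter² from pixel measurements."""
    if region.perimeter_px <= 0:
        return 0.0
    return 4.0 * np.pi * region.area_px / region.perimeter_px**2


def to_grayscale(
    raw: np.ndarray,
    pixel_scale: float,
    role: FrameRole | str = FrameRole.PRE_STRESS,
    weights: Sequence[float] = REC601_WEIGHTS,
) -> ImageFrame:
    """Convert an 8-bit raster (single- or 3-channel) to a grayscale frame.

    Single-channel input passes through unchanged; RGB is collapsed with the
    given luma weights (ITU-R BT.601 by default) and rounded to nearest.
    """
    raw = np.asarray(raw)
    if raw.dtype != np.uint8:
        raise ValueError(f"unsupported bit depth {raw.dtype}; expected 8-bit input")
    if raw.ndim == 2:
        gray = raw
    elif raw.ndim == 3 and raw.shape[2] in (3, 4):
        w = np.asarray(weights, dtype=float)
        if w.size != 3:
            raise ValueError("channel weights must have length 3")
        gray = np.rint(raw[..., :3].astype(float) @ w).clip(0, 255).astype(np.uint8)
    else:
        raise ValueError(f"unsupported raster shape {raw.shape}")
    return ImageFrame(gray, pixel_scale=pixel_scale, role=role)


def adjust_intensity(
    frame: ImageFrame, p_low: float = 1.0, p_high: float = 99.0
) -> ImageFrame:
    """Percentile-based linear contrast stretch to the full 8-bit range.

    Intensities at the ``p_low`` percentile map to 0 and at ``p_high`` to 255;
    the map is monotone, so pixel ordering is preserved.  A constant image is
    returned unchanged with a warning.
    """
    px = frame.pixels.astype(float)
    lo, hi = np.percentile(px, [p_low, p_high])
    if hi <= lo:
        warnings.warn("constant image: intensity adjustment skipped", stacklevel=2)
        return ImageFrame(frame.pixels.copy(), frame.pixel_scale, frame.role)
    out = np.rint((px - lo) * (255.0 / (hi - lo))).clip(0, 255).astype(np.uint8)
    return ImageFrame(out, frame.pixel_scale, frame.role)


def binarize(
    frame: ImageFrame,
    method: Literal["otsu", "fixed"] = "otsu",
    threshold: int | None = None,
    invert: bool = False,
) -> np.ndarray:
    """Threshold a grayscale frame to a boolean cell mask.

    Default polarity: cells are *darker* than the background, so foreground is
    ``pixels <= t`` with ``t`` chosen by Otsu's between-class-variance
    criterion.  ``invert=True`` flips the polarity; ``method="fixed"`` uses the
    supplied ``threshold``.
    """
    px = frame.pixels
    if method == "otsu":
        if px.min() == px.max():
            warnings.warn("constant image: empty foreground mask", stacklevel=2)
            return np.zeros(px.shape, dtype=bool)
        t = threshold_otsu(px)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed-threshold mode requires a threshold value")
        t = threshold
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = (px > t) if invert else (px <= t)
    if not mask.any():
        warnings.warn("empty foreground after thresholding", stacklevel=2)
    return mask


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background holes not connected to the image border.

    Background connectivity is 4-connected (the dual of the 8-connected
    foreground), avoiding the usual topological paradox.  Idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    # cross-shaped structure == 4-connected background flood
    return ndi.binary_fill_holes(mask, structure=ndi.generate_binary_structure(2, 1))


def label_regions(
    mask: np.ndarray,
    perimeter_estimator: Literal["crofton", "chain"] = "crofton",
) -> list[CellRegion]:
    """Label 8-connected components and measure area, perimeter and centroid.

    Perimeter uses the Crofton 4-direction estimator by default (the chain-code
    estimator is available as ``"chain"``); the choice is shared with all
    circularity computations so that large rasterized discs approach
    circularity 1.  Regions touching the image border are flagged.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled = measure.label(mask, connectivity=2)
    h, w = mask.shape
    regions: list[CellRegion] = []
    for rp in measure.regionprops(labeled):
        if perimeter_estimator == "crofton":
            perim = float(measure.perimeter_crofton(rp.image, directions=4))
        elif perimeter_estimator == "chain":
            perim = float(rp.perimeter)
        else:
            raise ValueError(f"unknown perimeter estimator {perimeter_estimator!r}")
        minr, minc, maxr, maxc = rp.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        regions.append(
            CellRegion(
                label_id=int(rp.label),
                coords=np.asarray(rp.coords),
                area_px=int(rp.area),
                perimeter_px=perim,
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                solidity=float(rp.solidity),
                touches_border=bool(touches),
            )
        )
    return regions


@dataclass
class StackedCellParams:
    """Rejection rule for merged (stacked/rouleaux) cell regions.

    A region is rejected when any enabled clause fires:
    area_px > k_area · median(area_px), solidity < s_min, or
    circularity < c_min.  With fewer than 3 regions the median-area clause is
    skipped (a median over 1–2 blobs is meaningless); shape clauses still apply.
    """

    k_area: float = 1.8
    s_min: float = 0.85
    c_min: float = 0.6
    use_area: bool = True
    use_solidity: bool = True
    use_circularity: bool = True


def remove_stacked(
    regions: Sequence[CellRegion],
    params: StackedCellParams | None = None,
) -> tuple[list[CellRegion], list[CellRegion]]:
    """Partition regions into (kept, rejected) by the stacked-cell rule.

    The shape clauses are pointwise, hence idempotent.  The median-area clause
    is idempotent on unimodal cell populations (removing outliers barely moves
    the median); a strongly bimodal area distribution can shift the median on
    re-application, which is outside the rule's intended regime.
    """
    params = params or StackedCellParams()
    regions = list(regions)
    if not regions:
        return [], []
    areas = np.array([r.area_px for r in regions], dtype=float)
    median_area = float(np.median(areas)) if len(regions) >= 3 else None
    kept: list[CellRegion] = []
    rejected: list[CellRegion] = []
    for r in regions:
        bad = False
        if params.use_area and median_area is not None:
            bad = bad or r.area_px > params.k_area * median_area
        if params.use_solidity:
            bad = bad or r.solidity < params.s_min
        if params.use_circularity:
            bad = bad or region_circularity(r) < params.c_min
        r.rejected_stacked = bool(bad)
        (rejected if bad else kept).append(r)
    return kept, rejected


def segment_frame(
    frame: ImageFrame,
    *,
    method: Literal["otsu", "fixed"] = "otsu",
    threshold: int | None = None,
    invert: bool = False,
    p_low: float = 1.0,
    p_high: float = 99.0,
    stacked_params: StackedCellParams | None = None,
    perimeter_estimator: Literal["crofton", "chain"] = "crofton",
    exclude_border: bool = True,
    min_area_px: int = 9,
) -> tuple[list[CellRegion], list[CellRegion]]:
    """Full chain: adjust → binarize → fill holes → label → remove stacked.

    Returns (kept, discarded); discarded collects stacked-rejected and, when
    ``exclude_border`` (default), border-touching regions.  Specks below
    ``min_area_px`` are dropped silently as noise.
    """
    adj = adjust_intensity(frame, p_low=p_low, p_high=p_high)
    mask = binarize(adj, method=method, threshold=threshold, invert=invert)
    mask = fill_holes(mask)
    regions = [
        r for r in label_regions(mask, perimeter_estimator) if r.area_px >= min_area_px
    ]
    border = [r for r in regions if r.touches_border] if exclude_border else []
    interior = [r for r in regions if not (exclude_border and r.touches_border)]
    kept, stacked = remove_stacked(interior, stacked_params)
    return kept, stacked + border
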