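"""Per-cell shape descriptors and population summaries.

Implements the device's parameter set: mean diameter √(area/π), circularity
4π·area/perimeter² (1 for a perfect circle), axis ratio MaxFeret/MinFeret
(caliper widths of the pixel-corner convex hull), and per-population means
with "distribution widths".  Distribution width follows the hematology RDW
convention: 100·SD/mean (coefficient of variation, sample SD with n−1); plain
SD is available via ``width_mode="sd"``.

The 8-dimensional population parameter vector, in fixed order, is
(diameter_mean, diameter_dw, circularity_mean, circularity_dw,
axis_ratio_mean, axis_ratio_dw, dr_mean, dr_dw).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .segmentation import CellRegion

__all__ = [
    "CellMorphometry",
    "PopulationSummary",
    "PARAM_VECTOR_KEYS",
    "mean_diameter",
    "circularity",
    "feret_extremes",
    "measure_region",
    "measure_regions",
    "summarize",
]

#: Fixed key order of the 8-parameter population vector.
PARAM_VECTOR_KEYS = (
    "diameter_mean",
    "diameter_dw",
    "circularity_mean",
    "circularity_dw",
    "axis_ratio_mean",
    "axis_ratio_dw",
    "dr_mean",
    "dr_dw",
)


def mean_diameter(area: float | np.ndarray) -> float | np.ndarray:
    """Diameter of the equal-area circle: √(area/π).  ``area`` in µm²."""
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be positive")
    out = np.sqrt(area / np.pi)
    return float(out) if out.ndim == 0 else out


def circularity(area: float | np.ndarray, perimeter: float | np.ndarray) -> float | np.ndarray:
    """4π·area/perimeter²; equals 1 for a perfect circle."""
    area = np.asarray(area, dtype=float)
    perimeter = np.asarray(perimeter, dtype=float)
    if np.any(area <= 0) or np.any(perimeter <= 0):
        raise ValueError("area and perimeter must be positive")
    out = 4.0 * np.pi * area / perimeter**2
    return float(out) if out.ndim == 0 else out


def _hull_points(coords: np.ndarray) -> np.ndarray:
    """Convex-hull vertices of the pixel *corner* cloud of a region.

    Using corners (not centers) gives a single pixel a finite 1-px footprint,
    avoiding the zero-width degeneracy.
    """
    coords = np.asarray(coords, dtype=float)
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    pts = (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def feret_extremes(region: CellRegion, pixel_scale: float = 1.0) -> tuple[float, float]:
    """(max, min) caliper widths of the pixel-corner convex hull, in µm.

    Max Feret is the hull diameter (largest vertex-pair distance); min Feret
    is the smallest width over hull edges (rotating-calipers minimal width).
    A single-pixel region returns (pixel_scale, pixel_scale) by convention.
    """
    if region.area_px == 1:
        return pixel_scale, pixel_scale
    v = _hull_points(region.coords)
    # max feret: brute-force over hull vertex pairs (hulls are tiny)
    d2 = np.sum((v[:, None, :] - v[None, :, :]) ** 2, axis=-1)
    max_f = float(np.sqrt(d2.max()))
    # min feret: for each hull edge, the farthest vertex distance to the edge line
    nv = len(v)
    min_f = np.inf
    for i in range(nv):
        p, q = v[i], v[(i + 1) % nv]
        edge = q - p
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        rel = v - p
        dist = np.abs(edge[0] * rel[:, 1] - edge[1] * rel[:, 0]) / norm
        min_f = min(min_f, float(dist.max()))
    return max_f * pixel_scale, min_f * pixel_scale


@dataclass
class CellMorphometry:
    """Shape descriptors of one cell in physical units."""

    cell_id: int
    area: float  # µm²
    perimeter: float  # µm
    mean_diameter: float  # µm
    axis_ratio: float  # ≥ 1
    circularity: float  # (0, ~1]; may exceed 1 by the perimeter-estimator tolerance

    def __post_init__(self) -> None:
        if abs(self.mean_diameter - np.sqrt(self.area / np.pi)) > 1e-9:
            raise ValueError("mean_diameter inconsistent with area")
        if self.axis_ratio < 1:
            raise ValueError("axis_ratio must be ≥ 1")
        if self.circularity <= 0:
            raise ValueError("circularity must be positive")


def measure_region(region: CellRegion, pixel_scale: float) -> CellMorphometry:
    """Physical-unit morphometry of one segmented region."""
    area = region.area_px * pixel_scale**2
    perim = region.perimeter_px * pixel_scale
    max_f, min_f = feret_extremes(region, pixel_scale)
    return CellMorphometry(
        cell_id=region.label_id,
        area=area,
        perimeter=perim,
        mean_diameter=mean_diameter(area),
        axis_ratio=max(max_f / min_f, 1.0),
        circularity=circularity(area, perim),
    )


def measure_regions(
    regions: Sequence[CellRegion], pixel_scale: float
) -> list[CellMorphometry]:
    return [measure_region(r, pixel_scale) for r in regions]


@dataclass
class PopulationSummary:
    """The 8-parameter population vector plus count and concentration."""

    n_cells: int
    diameter_mean: float
    diameter_dw: float
    circularity_mean: float
    circularity_dw: float
    axis_ratio_mean: float
    axis_ratio_dw: float
    dr_mean: float
    dr_dw: float
    concentration: float | None = None  # cells / mL

    def vector(self) -> np.ndarray:
        """The 8 statistics in the fixed ``PARAM_VECTOR_KEYS`` order."""
        return np.array([getattr(self, k) for k in PARAM_VECTOR_KEYS], dtype=float)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in PARAM_VECTOR_KEYS}
        d["n_cells"] = self.n_cells
        d["concentration_per_ml"] = self.concentration
        return d


def _width(values: np.ndarray, mode: Literal["cv", "sd"]) -> float:
    if len(values) < 2:
        return 0.0
    sd = float(np.std(values, ddof=1))
    if mode == "sd":
        return sd
    mean = float(np.mean(values))
    if mean == 0:
        raise ValueError("distribution width undefined for zero mean")
    return 100.0 * sd / mean


def summarize(
    cells: Sequence[CellMorphometry],
    drs: Sequence[float] | None = None,
    volume_ml: float | None = None,
    width_mode: Literal["cv", "sd"] = "cv",
) -> PopulationSummary:
    """Population means and distribution widths of the per-cell descriptors.

    ``drs`` supplies the matched-pair deformation indices (its length may
    differ from ``cells``: stacked or unmatched cells drop out of pairing);
    when omitted, the mechanical entries are NaN.  ``volume_ml`` converts the
    count to a concentration.
    """
    if not cells:
        raise ValueError("summarize requires at least one cell")
    diam = np.array([c.mean_diameter for c in cells])
    circ = np.array([c.circularity for c in cells])
    axr = np.array([c.axis_ratio for c in cells])
    if any(np.mean(v) == 0 for v in (diam, circ, axr)) and width_mode == "cv":
        raise ValueError("distribution width undefined for zero mean")
    if drs is not None and len(drs) > 0:
        dr_arr = np.asarray(drs, dtype=float)
        dr_mean, dr_dw = float(np.mean(dr_arr)), _width(dr_arr, width_mode)
    else:
        dr_mean, dr_dw = float("nan"), float("nan")
    return PopulationSummary(
        n_cells=len(cells),
        diameter_mean=float(np.mean(diam)),
        diameter_dw=_width(diam, width_mode),
        circularity_mean=float(np.mean(circ)),
        circularity_dw=_width(circ, width_mode),
        axis_ratio_mean=float(np.mean(axr)),
        axis_ratio_dw=_width(axr, width_mode),
        dr_mean=dr_mean,
        dr_dw=dr_dw,
        concentration=(len(cells) / volume_ml) if volume_ml else None,
    )


def chamber_volume_ml(
    field_width_um: float,
    field_height_um: float,
    depth_um: float = 20.0,
    dilution: float = 1.0,
) -> float:
    """Imaged sample volume in mL: field area × chamber depth ÷ dilution.

    Default depth 20 µm (the chip chamber height); ``dilution`` > 1 scales the
    volume down to report the concentration of the undiluted sample.
    """
    um3_per_ml = 1e12
    return field_width_um * field_height_um * depth_um / um3_per_ml / dilution


def morphometry_to_frame(cells: Sequence[CellMorphometry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "area_um2": [c.area for c in cells],
            "perimeter_um": [c.perimeter for c in cells],
            "mean_diameter_um": [c.mean_diameter for c in cells],
            "axis_ratio": [c.axis_ratio for c in cells],
            "circularity": [c.circularity for c in cells],
        }
    )
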