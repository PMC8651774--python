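"""Reading and writing the pipeline's file formats.

Images: 8-bit grayscale or RGB PNG/TIFF in, 8-bit grayscale PNG/TIFF out;
labeled masks as 16-bit TIFF.  Tables: per-region and per-pair CSVs with
documented column names; configs as YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .segmentation import CellRegion, FrameRole, ImageFrame, to_grayscale

__all__ = [
    "load_frame",
    "save_frame",
    "save_labeled_mask",
    "regions_to_frame",
    "save_regions_csv",
]

REGION_CSV_COLUMNS = (
    "label_id",
    "area_px",
    "perimeter_px",
    "centroid_row",
    "centroid_col",
    "solidity",
    "touches_border",
    "rejected_stacked",
)


def load_frame(
    path: str | Path,
    pixel_scale: float,
    role: FrameRole | str = FrameRole.PRE_STRESS,
) -> ImageFrame:
    """Read a PNG/TIFF micrograph; RGB input is collapsed to 8-bit grayscale."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(path)
    else:
        raw = np.asarray(Image.open(path))
    if raw.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported bit depth {raw.dtype}; expected 8-bit")
    return to_grayscale(raw, pixel_scale=pixel_scale, role=role)


def save_frame(path: str | Path, frame: ImageFrame) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, frame.pixels)
    else:
        Image.fromarray(frame.pixels).save(path)


def save_labeled_mask(path: str | Path, shape: tuple[int, int], regions: Sequence[CellRegion]) -> None:
    """Write region labels as a 16-bit TIFF (0 = background)."""
    mask = np.zeros(shape, dtype=np.uint16)
    for r in regions:
        mask[r.coords[:, 0], r.coords[:, 1]] = r.label_id
    tifffile.imwrite(Path(path), mask)


def regions_to_frame(regions: Sequence[CellRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label_id": [r.label_id for r in regions],
            "area_px": [r.area_px for r in regions],
            "perimeter_px": [r.perimeter_px for r in regions],
            "centroid_row": [r.centroid[0] for r in regions],
            "centroid_col": [r.centroid[1] for r in regions],
            "solidity": [r.solidity for r in regions],
            "touches_border": [r.touches_border for r in regions],
            "rejected_stacked": [r.rejected_stacked for r in regions],
        },
        columns=list(REGION_CSV_COLUMNS),
    )


def save_regions_csv(path: str | Path, regions: Sequence[CellRegion]) -> None:
    regions_to_frame(regions).to_csv(Path(path), index=False)
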