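"""Pre/post-stress cell matching and the deformation index Dr = √(S_d/S_ud).

S_ud and S_d are the pixel areas of the same cell before and after the
hydrogel compression.  Cells are immobilized in the gel, so matching is a
one-to-one assignment on centroid distance (Hungarian algorithm) with a hard
displacement cap; areas are *not* a matching feature because they change under
stress.  Dr is unitless (the pixel scale cancels) and may fall below 1 for
cells that contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .segmentation import CellRegion

__all__ = [
    "CellPair",
    "match_cells",
    "deformation_index",
    "deformability_summary",
    "DeformabilitySummary",
    "pairs_to_frame",
]


def deformation_index(s_ud: float, s_d: float) -> float:
    """Dr = √(S_d/S_ud) from before/after pixel areas."""
    if s_ud <= 0:
        raise ValueError("pre-stress area S_ud must be positive")
    if s_d < 0:
        raise ValueError("post-stress area S_d must be non-negative")
    return float(np.sqrt(s_d / s_ud))


@dataclass
class CellPair:
    """A matched pre/post region pair; ``dr`` is derived, never stored stale."""

    cell_id: int
    s_ud: float  # pixel area before deformation
    s_d: float  # pixel area after deformation
    displacement: float  # µm between matched centroids

    @property
    def dr(self) -> float:
        return deformation_index(self.s_ud, self.s_d)


def match_cells(
    pre: Sequence[CellRegion],
    post: Sequence[CellRegion],
    pixel_scale: float,
    max_disp: float = 3.0,
) -> tuple[list[CellPair], list[CellRegion], list[CellRegion]]:
    """Optimal one-to-one centroid matching between the two frames.

    Minimizes total centroid distance (in µm) over all assignments; pairs
    farther apart than ``max_disp`` (default 3 µm — gel-immobilized cells
    barely move) are dropped to the unmatched lists.  Returns
    (pairs, unmatched_pre, unmatched_post).
    """
    if not pre or not post:
        return [], list(pre), list(post)
    pre_xy = np.array([r.centroid for r in pre], dtype=float) * pixel_scale
    post_xy = np.array([r.centroid for r in post], dtype=float) * pixel_scale
    dist = np.linalg.norm(pre_xy[:, None, :] - post_xy[None, :, :], axis=-1)
    rows, cols = linear_sum_assignment(dist)
    pairs: list[CellPair] = []
    used_pre: set[int] = set()
    used_post: set[int] = set()
    for i, j in zip(rows, cols):
        d = float(dist[i, j])
        if d > max_disp:
            continue
        pairs.append(
            CellPair(
                cell_id=pre[i].label_id,
                s_ud=float(pre[i].area_px),
                s_d=float(post[j].area_px),
                displacement=d,
            )
        )
        used_pre.add(i)
        used_post.add(j)
    unmatched_pre = [r for i, r in enumerate(pre) if i not in used_pre]
    unmatched_post = [r for j, r in enumerate(post) if j not in used_post]
    return pairs, unmatched_pre, unmatched_post


@dataclass
class DeformabilitySummary:
    n: int
    dr_mean: float
    dr_sd: float  # sample SD (n−1)
    dr_dw: float  # CV%, 100·SD/mean
    dr_median: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "dr_mean": self.dr_mean,
            "dr_sd": self.dr_sd,
            "dr_dw": self.dr_dw,
            "dr_median": self.dr_median,
        }


def deformability_summary(
    pairs: Sequence[CellPair],
) -> tuple[DeformabilitySummary, pd.DataFrame]:
    """Population Dr statistics plus the per-cell scatter table."""
    if not pairs:
        raise ValueError("deformability_summary requires at least one pair")
    table = pairs_to_frame(pairs)
    drs = table["dr"].to_numpy()
    mean = float(np.mean(drs))
    sd = float(np.std(drs, ddof=1)) if len(drs) > 1 else 0.0
    summary = DeformabilitySummary(
        n=len(drs),
        dr_mean=mean,
        dr_sd=sd,
        dr_dw=100.0 * sd / mean if mean else float("nan"),
        dr_median=float(np.median(drs)),
    )
    return summary, table


def pairs_to_frame(pairs: Sequence[CellPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [p.cell_id for p in pairs],
            "s_ud_px": [p.s_ud for p in pairs],
            "s_d_px": [p.s_d for p in pairs],
            "dr": [p.dr for p in pairs],
            "displacement_um": [p.displacement for p in pairs],
        }
    )
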