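"""Seeded generator of ground-truthed pre/post-compression RBC image pairs.

Emulates the optical field of a hydrogel-compression blood-testing chip: a
monolayer of biconcave red cells settles flat (disc face up) inside a gel,
a vertical compression expands each cell laterally, and the same immobilized
cells are imaged before and after the stress.  Every scene carries a ground
truth table, so the whole downstream pipeline (segmentation → morphometry →
deformability → classification) is testable without any external data.

Cell geometry model
-------------------
Each cell boundary is a star-convex radial curve

    r(θ) = s · R_ell(θ − φ) · (1 + ε·cos(m(θ − φ)))

where ``R_ell`` is the radius of an ellipse with the sampled axis ratio, ``φ``
a random orientation, and the m-lobed undulation amplitude ``ε`` is solved by
bisection so the boundary's circularity (4π·area/perimeter²) matches the value
sampled from the class profile.  The scale ``s`` normalizes the enclosed area
to π·d²/4, so the sampled diameter is exactly the mean diameter √(area/π).

Compression multiplies every boundary radius by the per-cell deformation index
dr, i.e. the area scales by dr² and the shape is preserved (isotropic in-plane
expansion); dr is sampled per stress level from the class profile.  The
healthy-class defaults at the two active stress settings are mean 1.194
(SD 0.045) and mean 1.241 (SD 0.033).

Photometry: dark rim, brighter biconcave centre (intensity rises quadratically
from rim to centre), on a bright background, with optional linear illumination
gradient and additive Gaussian sensor noise, clamped to 8 bits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .segmentation import FrameRole, ImageFrame

__all__ = [
    "StressLevel",
    "ClassProfile",
    "SceneConfig",
    "GroundTruthRecord",
    "DEFAULT_PROFILES",
    "sample_population",
    "apply_stress",
    "render_pair",
    "simulate_scene",
    "truth_to_frame",
    "save_scene",
]

# photometric constants (8-bit gray levels)
BACKGROUND_LEVEL = 210.0
CELL_DEPTH = 120.0  # rim attenuation below background
CENTER_RELIEF = 0.3  # centre attenuation as a fraction of rim attenuation
UNDULATION_LOBES = 5  # lobe count of the circularity-controlling undulation

_N_BOUNDARY = 512  # polygon resolution for ground-truth geometry


class StressLevel(str, Enum):
    NONE = "none"
    LOW = "low"  # the 3 kPa analogue
    HIGH = "high"  # the 6 kPa analogue


@dataclass(frozen=True)
class ClassProfile:
    """Morphology/mechanics distribution of one sample class.

    ``dr_mean``/``dr_sd`` parameterize the deformation index at the *high*
    stress setting; ``dr_low_mean``/``dr_low_sd`` at the low setting.  Healthy
    defaults use the device's printed calibration (1.194 ± 0.045 at low,
    1.241 ± 0.033 at high stress).  Numeric profiles for the disease and
    storage classes are configurable synthetic defaults drawn from standard
    hematology morphology, not measured values.
    """

    class_label: str
    diameter_mean: float = 7.5  # µm
    diameter_sd: float = 0.4
    circularity_mean: float = 0.95
    circularity_sd: float = 0.02
    axis_ratio_mean: float = 1.05  # ≥ 1
    axis_ratio_sd: float = 0.03
    dr_mean: float = 1.241  # at high stress
    dr_sd: float = 0.033
    dr_low_mean: float = 1.194  # at low stress
    dr_low_sd: float = 0.045

    def __post_init__(self) -> None:
        if not self.diameter_mean > 0:
            raise ValueError("diameter_mean must be positive")
        for name in ("diameter_sd", "circularity_sd", "axis_ratio_sd", "dr_sd", "dr_low_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.axis_ratio_mean < 1:
            raise ValueError("axis_ratio_mean must be ≥ 1")
        if self.dr_mean <= 0 or self.dr_low_mean <= 0:
            raise ValueError("dr means must be positive")

    def dr_params(self, stress_level: StressLevel | str) -> tuple[float, float]:
        level = StressLevel(stress_level)
        if level is StressLevel.NONE:
            return 1.0, 0.0
        if level is StressLevel.LOW:
            return self.dr_low_mean, self.dr_low_sd
        return self.dr_mean, self.dr_sd

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassProfile":
        return cls(**d)


def _profiles() -> dict[str, ClassProfile]:
    p = ClassProfile
    return {
        # healthy discocytes; dr from the device's printed stress calibration
        "healthy": p("healthy"),
        # megaloblastic anemia: macrocytes, mildly stiffer
        "MA": p("MA", 9.0, 0.8, 0.93, 0.03, 1.08, 0.05, 1.15, 0.045, 1.12, 0.05),
        # myelofibrosis: teardrop poikilocytes — elongated, irregular
        "MF": p("MF", 7.2, 0.9, 0.80, 0.06, 1.35, 0.12, 1.13, 0.05, 1.10, 0.06),
        # iron deficiency anemia: microcytes
        "IDA": p("IDA", 6.0, 0.6, 0.94, 0.03, 1.07, 0.04, 1.18, 0.04, 1.15, 0.05),
        # thrombotic thrombocytopenic purpura: schistocyte fragments
        "TTP": p("TTP", 6.8, 1.0, 0.72, 0.08, 1.45, 0.15, 1.10, 0.05, 1.08, 0.06),
        # thalassemia: microcytic target cells
        "Thal": p("Thal", 6.3, 0.5, 0.90, 0.04, 1.12, 0.06, 1.16, 0.04, 1.13, 0.05),
        # cold-storage classes (≤14 days vs 14–21 days): progressive sphering + stiffening
        "storage_fresh": p("storage_fresh", 7.5, 0.4, 0.94, 0.02, 1.06, 0.03, 1.21, 0.04, 1.17, 0.045),
        "storage_aged": p("storage_aged", 7.0, 0.5, 0.97, 0.02, 1.04, 0.02, 1.10, 0.045, 1.08, 0.05),
    }


#: Default per-class profiles (synthetic, user-configurable; see module docstring).
DEFAULT_PROFILES: dict[str, ClassProfile] = _profiles()


@dataclass
class SceneConfig:
    """Geometry/photometry of one simulated field of view."""

    field_width: float = 250.0  # µm
    field_height: float = 250.0
    pixel_scale: float = 0.25  # µm per pixel (4 px per µm)
    n_cells: int = 150
    stacking_fraction: float = 0.05
    stress_level: StressLevel = StressLevel.HIGH
    noise_sd: float = 3.0  # gray levels
    illumination_gradient: float = 0.1  # peak-to-peak fractional ramp
    seed: int = 0
    stack_cluster_size: int = 3  # cells per rouleaux chain
    border_margin_um: float = 0.0  # keep-out band; > max cell radius ⇒ no clipped cells

    def __post_init__(self) -> None:
        self.stress_level = StressLevel(self.stress_level)
        if self.n_cells < 0:
            raise ValueError("n_cells must be ≥ 0")
        if not 0 <= self.stacking_fraction <= 1:
            raise ValueError("stacking_fraction must be in [0, 1]")
        if self.stack_cluster_size < 2:
            raise ValueError("stack_cluster_size must be ≥ 2")
        for name in ("field_width", "field_height"):
            n_px = getattr(self, name) / self.pixel_scale
            if abs(n_px - round(n_px)) > 1e-6:
                raise ValueError(f"{name} must be an integer multiple of pixel_scale")

    @property
    def raster_shape(self) -> tuple[int, int]:
        return (
            int(round(self.field_height / self.pixel_scale)),
            int(round(self.field_width / self.pixel_scale)),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stress_level"] = self.stress_level.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        return cls(**d)


@dataclass
class CellShape:
    """Star-convex boundary parameters (see module docstring)."""

    a: float  # ellipse semi-major, µm (before area normalization)
    b: float  # ellipse semi-minor
    phi: float  # orientation, radians
    eps: float  # undulation amplitude
    m: int = UNDULATION_LOBES
    scale: float = 1.0  # area-normalizing radial scale

    def radius(self, theta: np.ndarray) -> np.ndarray:
        """Boundary radius at absolute polar angle(s) ``theta``."""
        t = np.asarray(theta) - self.phi
        r_ell = (self.a * self.b) / np.sqrt(
            (self.b * np.cos(t)) ** 2 + (self.a * np.sin(t)) ** 2
        )
        return self.scale * r_ell * (1.0 + self.eps * np.cos(self.m * t))

    @property
    def max_radius(self) -> float:
        return float(self.radius(_THETA).max())


_THETA = np.linspace(0.0, 2.0 * np.pi, _N_BOUNDARY, endpoint=False)
_CALIPER_ANGLES = np.linspace(0.0, np.pi, 180, endpoint=False)


def _polygon(shape: CellShape) -> tuple[np.ndarray, np.ndarray]:
    r = shape.radius(_THETA)
    return r * np.cos(_THETA), r * np.sin(_THETA)


def _polygon_area_perimeter(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * y2 - x2 * y))
    perim = float(np.sum(np.hypot(x2 - x, y2 - y)))
    return float(area), perim


def _shape_circularity(shape: CellShape) -> float:
    x, y = _polygon(shape)
    area, perim = _polygon_area_perimeter(x, y)
    return 4.0 * np.pi * area / perim**2


def _caliper_axis_ratio(x: np.ndarray, y: np.ndarray) -> float:
    proj = np.outer(np.cos(_CALIPER_ANGLES), x) + np.outer(np.sin(_CALIPER_ANGLES), y)
    widths = proj.max(axis=1) - proj.min(axis=1)
    return float(widths.max() / widths.min())


_THETA_SOLVE = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
_COS_SOLVE = np.cos(_THETA_SOLVE)
_SIN_SOLVE = np.sin(_THETA_SOLVE)
_COSM_SOLVE = np.cos(UNDULATION_LOBES * _THETA_SOLVE)


def _circ_at_eps(r_ell: np.ndarray, eps: float) -> float:
    """Circularity of r(θ) = r_ell(θ)·(1 + ε·cos mθ) on the solver grid."""
    r = r_ell * (1.0 + eps * _COSM_SOLVE)
    x = r * _COS_SOLVE
    y = r * _SIN_SOLVE
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * y2 - x2 * y))
    perim = np.sum(np.hypot(x2 - x, y2 - y))
    return 4.0 * np.pi * area / perim**2


def _solve_shape(diameter: float, axis_ratio: float, circ_target: float, phi: float) -> CellShape:
    """Build the boundary: solve ε for the target circularity, normalize area.

    The undulation amplitude is bisected on a coarse (256-point) grid; the
    stored ground truth is then re-evaluated on the fine grid.  Circularity is
    rotation-invariant, so the solve runs at φ = 0.
    """
    q = max(axis_ratio, 1.0)
    a, b = np.sqrt(q), 1.0 / np.sqrt(q)
    r_ell = (a * b) / np.sqrt((b * _COS_SOLVE) ** 2 + (a * _SIN_SOLVE) ** 2)
    eps = 0.0
    if circ_target < _circ_at_eps(r_ell, 0.0):  # undulate until circularity drops
        lo, hi = 0.0, 0.6
        for _ in range(22):
            mid = 0.5 * (lo + hi)
            if _circ_at_eps(r_ell, mid) > circ_target:
                lo = mid
            else:
                hi = mid
        eps = 0.5 * (lo + hi)
    shape = CellShape(a=a, b=b, phi=phi, eps=eps)
    # normalize enclosed area to π d²/4
    x, y = _polygon(shape)
    area, _ = _polygon_area_perimeter(x, y)
    target_area = np.pi * diameter**2 / 4.0
    shape.scale = float(np.sqrt(target_area / area))
    return shape


@dataclass
class GroundTruthRecord:
    """Per-cell ground truth; ``true_dr = √(true_area_post/true_area_pre)``."""

    cell_id: int
    true_diameter: float  # µm
    true_axis_ratio: float
    true_circularity: float
    true_area_pre: float  # µm²
    shape: CellShape
    centroid: tuple[float, float] | None = None  # (row, col) in µm
    true_area_post: float | None = None
    true_dr: float = 1.0
    is_stacked: bool = False
    clipped: bool = False


def sample_population(
    profile: ClassProfile, n: int, seed: int | np.random.Generator
) -> list[GroundTruthRecord]:
    """Draw ``n`` cells (pre-stress geometry only) from a class profile.

    Diameters come from a truncated-at-zero normal; axis ratios are reflected
    about 1; circularity targets are clipped to (0.2, 1].  Deterministic for a
    given seed.
    """
    if n < 0:
        raise ValueError("n must be ≥ 0")
    if not profile.diameter_mean > 0:
        raise ValueError("profile diameter_mean must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    records: list[GroundTruthRecord] = []
    for i in range(n):
        d = _sample_truncated_positive(rng, profile.diameter_mean, profile.diameter_sd)
        q = 1.0 + abs(rng.normal(0.0, profile.axis_ratio_sd) + profile.axis_ratio_mean - 1.0)
        c = float(np.clip(rng.normal(profile.circularity_mean, profile.circularity_sd), 0.2, 1.0))
        phi = float(rng.uniform(0.0, np.pi))
        shape = _solve_shape(d, q, c, phi)
        x, y = _polygon(shape)
        records.append(
            GroundTruthRecord(
                cell_id=i,
                true_diameter=d,
                true_axis_ratio=_caliper_axis_ratio(x, y),
                true_circularity=_shape_circularity(shape),
                true_area_pre=np.pi * d**2 / 4.0,
                shape=shape,
            )
        )
    return records


def _sample_truncated_positive(
    rng: np.random.Generator, mean: float, sd: float, max_retries: int = 100
) -> float:
    if sd == 0:
        return float(mean)
    for _ in range(max_retries):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise RuntimeError(
        f"could not draw a positive value from N({mean}, {sd}) in {max_retries} tries"
    )


def apply_stress(
    records: Sequence[GroundTruthRecord],
    profile: ClassProfile,
    stress_level: StressLevel | str,
    seed: int | np.random.Generator,
    max_retries: int = 100,
) -> list[GroundTruthRecord]:
    """Sample a per-cell deformation index and set the post-stress area.

    dr ~ N(mean, sd) for the stress level, resampled while non-positive (cap
    ``max_retries``); area scales by dr² (isotropic in-plane expansion).
    ``stress_level="none"`` fixes dr = 1.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mean, sd = profile.dr_params(stress_level)
    out: list[GroundTruthRecord] = []
    for rec in records:
        dr = 1.0 if StressLevel(stress_level) is StressLevel.NONE else _sample_truncated_positive(
            rng, mean, sd, max_retries
        )
        out.append(
            dataclasses.replace(
                rec, true_dr=dr, true_area_post=rec.true_area_pre * dr**2
            )
        )
    return out


# --------------------------------------------------------------------------
# placement and rendering


def _place_cells(
    records: list[GroundTruthRecord], config: SceneConfig, rng: np.random.Generator
) -> None:
    """Assign centroids in place: rouleaux chains for the stacked subset,
    dart-throwing with a disjointness margin for singles.

    Stacked cells form linear chains of ``stack_cluster_size`` with consecutive
    centre separation 0.75·(Rᵢ+Rⱼ) (guaranteed overlap); the stacked count is
    rounded down to whole clusters.  Non-stacked cells keep a centre-to-centre
    margin of 1.05·(Rᵢ+Rⱼ) + 0.5 µm against everything already placed, using
    post-stress radii so the post frame is disjoint too.
    """
    h_um, w_um = config.field_height, config.field_width
    margin = config.border_margin_um
    n = len(records)
    radii_post = np.array([r.shape.max_radius * r.true_dr for r in records])
    k_stacked = int(round(config.stacking_fraction * n))
    n_clusters = k_stacked // config.stack_cluster_size
    order = rng.permutation(n)
    stacked_ids = list(order[: n_clusters * config.stack_cluster_size])
    single_ids = [i for i in order if i not in set(stacked_ids)]

    placed_xy: list[tuple[float, float]] = []
    placed_r: list[float] = []

    def _far_enough(row: float, col: float, radius: float, margin_scale: float) -> bool:
        for (pr, pc), rr in zip(placed_xy, placed_r):
            if np.hypot(row - pr, col - pc) < margin_scale * (radius + rr) + 0.5:
                return False
        return True

    def _register(idx: int, row: float, col: float) -> None:
        rec = records[idx]
        rec.centroid = (row, col)
        r_post = radii_post[idx]
        rec.clipped = (
            row - r_post < 0 or col - r_post < 0 or row + r_post > h_um or col + r_post > w_um
        )
        placed_xy.append((row, col))
        placed_r.append(r_post)

    for c_start in range(0, len(stacked_ids), config.stack_cluster_size):
        chain = stacked_ids[c_start : c_start + config.stack_cluster_size]
        direction = rng.uniform(0.0, 2.0 * np.pi)
        chain_len = 1.5 * sum(radii_post[i] for i in chain)  # generous envelope
        for attempt in range(5000):
            row0 = rng.uniform(chain_len + margin, h_um - chain_len - margin)
            col0 = rng.uniform(chain_len + margin, w_um - chain_len - margin)
            if _far_enough(row0, col0, chain_len, 1.0):
                break
        else:
            raise RuntimeError("field too dense: could not place a stacked cluster")
        row, col = row0, col0
        prev_idx = None
        for idx in chain:
            rec = records[idx]
            rec.is_stacked = True
            if prev_idx is not None:
                # 0.75 × the two *local* pre-stress boundary radii along the
                # chain axis: overlap is guaranteed in the pre frame and only
                # deepens in the post frame (same centres, radii × dr)
                r_prev = float(records[prev_idx].shape.radius(np.array([direction]))[0])
                r_cur = float(rec.shape.radius(np.array([direction + np.pi]))[0])
                step = 0.75 * (r_prev + r_cur)
                row += step * np.sin(direction)
                col += step * np.cos(direction)
            _register(idx, row, col)
            prev_idx = idx

    for idx in single_ids:
        records[idx].is_stacked = False
        r_post = radii_post[idx]
        for attempt in range(5000):
            row = rng.uniform(margin, h_um - margin)
            col = rng.uniform(margin, w_um - margin)
            if _far_enough(row, col, r_post, 1.05):
                _register(idx, row, col)
                break
        else:
            raise RuntimeError(
                "field too dense: could not place all cells; reduce n_cells or "
                "enlarge the field"
            )


def _render_frame(
    records: Sequence[GroundTruthRecord],
    config: SceneConfig,
    post: bool,
    noise_rng: np.random.Generator,
) -> np.ndarray:
    h, w = config.raster_shape
    img = np.full((h, w), BACKGROUND_LEVEL, dtype=float)
    s = config.pixel_scale
    for rec in records:
        if rec.centroid is None:
            raise ValueError("records must be placed before rendering")
        dr = rec.true_dr if post else 1.0
        r_max = rec.shape.max_radius * dr
        cr, cc = rec.centroid
        r0 = max(int(np.floor((cr - r_max) / s - 0.5)), 0)
        r1 = min(int(np.ceil((cr + r_max) / s + 0.5)) + 1, h)
        c0 = max(int(np.floor((cc - r_max) / s - 0.5)), 0)
        c1 = min(int(np.ceil((cc + r_max) / s + 0.5)) + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        rows = (np.arange(r0, r1) + 0.5) * s - cr
        cols = (np.arange(c0, c1) + 0.5) * s - cc
        dy = rows[:, None]
        dx = cols[None, :]
        theta = np.arctan2(dy, dx)
        rho = np.hypot(dy, dx) / (rec.shape.radius(theta) * dr)
        inside = rho <= 1.0
        depth = CELL_DEPTH * (CENTER_RELIEF + (1.0 - CENTER_RELIEF) * rho**2)
        cell_val = BACKGROUND_LEVEL - np.where(inside, depth, 0.0)
        win = img[r0:r1, c0:c1]
        img[r0:r1, c0:c1] = np.where(inside, np.minimum(win, cell_val), win)
    if config.illumination_gradient:
        ramp = 1.0 + config.illumination_gradient * (np.arange(w) / max(w - 1, 1) - 0.5)
        img *= ramp[None, :]
    if config.noise_sd > 0:
        img += noise_rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_pair(
    config: SceneConfig, records: Sequence[GroundTruthRecord]
) -> tuple[ImageFrame, ImageFrame, pd.DataFrame]:
    """Render the pre/post frame pair and the ground-truth table.

    Cells are immobilized in the gel: placement is identical in both frames,
    only the boundary radius scales by the per-cell dr in the post frame.
    Deterministic for a given (config, records): placement and the two noise
    fields are drawn from streams derived from ``config.seed``.
    """
    records = [dataclasses.replace(r) for r in records]
    for r in records:
        if r.true_area_post is None:
            r.true_area_post = r.true_area_pre
    h_um = config.field_height
    w_um = config.field_width
    largest = max((r.shape.max_radius * max(r.true_dr, 1.0) for r in records), default=0.0)
    if 2.0 * largest > min(h_um, w_um):
        raise ValueError("raster smaller than the largest cell; enlarge the field")
    ss = np.random.SeedSequence(entropy=(int(config.seed), 0xC311))
    place_seed, noise_pre_seed, noise_post_seed = ss.spawn(3)
    _place_cells(records, config, np.random.default_rng(place_seed))
    pre = ImageFrame(
        _render_frame(records, config, post=False, noise_rng=np.random.default_rng(noise_pre_seed)),
        config.pixel_scale,
        FrameRole.PRE_STRESS,
    )
    post = ImageFrame(
        _render_frame(records, config, post=True, noise_rng=np.random.default_rng(noise_post_seed)),
        config.pixel_scale,
        FrameRole.POST_STRESS,
    )
    return pre, post, truth_to_frame(records)


def truth_to_frame(records: Sequence[GroundTruthRecord]) -> pd.DataFrame:
    """Ground truth as a tidy table (documented column names, µm units)."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "centroid_row_um": [r.centroid[0] if r.centroid else np.nan for r in records],
            "centroid_col_um": [r.centroid[1] if r.centroid else np.nan for r in records],
            "true_diameter_um": [r.true_diameter for r in records],
            "true_axis_ratio": [r.true_axis_ratio for r in records],
            "true_circularity": [r.true_circularity for r in records],
            "true_area_pre_um2": [r.true_area_pre for r in records],
            "true_area_post_um2": [
                r.true_area_post if r.true_area_post is not None else np.nan for r in records
            ],
            "true_dr": [r.true_dr for r in records],
            "is_stacked": [r.is_stacked for r in records],
            "clipped": [r.clipped for r in records],
        }
    )


def simulate_scene(
    profile: ClassProfile, config: SceneConfig
) -> tuple[ImageFrame, ImageFrame, pd.DataFrame]:
    """Sample a population, apply the configured stress, render the pair.

    All randomness streams derive from ``config.seed``.
    """
    ss = np.random.SeedSequence(entropy=(int(config.seed), 0x5CE11E))
    sample_seed, stress_seed = ss.spawn(2)
    records = sample_population(profile, config.n_cells, np.random.default_rng(sample_seed))
    records = apply_stress(
        records, profile, config.stress_level, np.random.default_rng(stress_seed)
    )
    return render_pair(config, records)


def save_scene(
    out_dir: str | Path,
    pre: ImageFrame,
    post: ImageFrame,
    truth: pd.DataFrame,
    config: SceneConfig | None = None,
    profile: ClassProfile | None = None,
    fmt: str = "png",
) -> dict[str, Path]:
    """Write the image pair (8-bit PNG/TIFF), truth CSV, and configs (YAML)."""
    from . import io as _io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pre": out_dir / f"pre_stress.{fmt}",
        "post": out_dir / f"post_stress.{fmt}",
        "truth": out_dir / "ground_truth.csv",
    }
    _io.save_frame(paths["pre"], pre)
    _io.save_frame(paths["post"], post)
    truth.to_csv(paths["truth"], index=False)
    meta: dict = {}
    if config is not None:
        meta["scene"] = config.to_dict()
    if profile is not None:
        meta["profile"] = profile.to_dict()
    if meta:
        paths["config"] = out_dir / "scene.yaml"
        paths["config"].write_text(yaml.safe_dump(meta, sort_keys=True))
    return paths
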