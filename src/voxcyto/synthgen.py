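"""Synthetic 3D tissue phantoms with analytic ground truth.

Generates multi-channel stacks emulating cleared-organ confocal imaging:
a structure channel (``cd31``) containing bright spherical shells
("glomeruli") and tubular vessels, a cell channel (``mhc2``) of spherical
blobs planted at controlled signed distances to the glomeruli, and a
deposit channel (``igg``) of small blobs inside a subset of glomeruli,
over autofluorescent background with Gaussian and optional Poisson noise.

Every planted object is recorded in a :class:`GroundTruth` table, and cell
population labels (within / surrounding / peripheral relative to the
nearest glomerulus surface) hold analytically by construction:

    signed distance = |c_cell - c_glom| - r_glom - r_cell

Cells are planted inside guard-banded sub-intervals of the population
gates (see ``PLANT_BANDS``) so that voxel discretisation downstream cannot
flip a label across the 0.5 µm / 20 µm thresholds: the gate thresholds sit
within half a voxel diagonal at realistic anisotropic voxel sizes, so
planting flush against them would make end-to-end recovery ill-posed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from voxcyto.io_formats import VoxelGrid

__all__ = [
    "PhantomSpec",
    "GlomeruliSpec",
    "VesselSpec",
    "CellSpec",
    "DepositSpec",
    "NoiseSpec",
    "GroundTruth",
    "PlacementError",
    "generate_phantom",
    "scenario",
    "rasterize_objects",
    "rasterize_sphere",
    "rasterize_tube",
    "population_counts",
    "analytic_cell_distance",
    "PLANT_BANDS",
    "POPULATIONS",
    "CHANNELS",
]

CHANNELS = ("cd31", "mhc2", "igg")
POPULATIONS = ("within", "surrounding", "peripheral")

#: sampling bands (lo, hi) for planted signed cell-surface distances, µm.
#: ``None`` lower bound means -r_cell. These are strict sub-intervals of
#: the population gates (<0.5 | 0.5..20 | >20) with guard margins of about
#: one voxel diagonal, so planted labels survive discretisation.
PLANT_BANDS: dict[str, tuple[float | None, float]] = {
    "within": (None, -0.8),
    "surrounding": (1.8, 18.0),
    "peripheral": (22.0, 90.0),
}

#: per-object placement retry budget
RETRY_BUDGET = 100


class PlacementError(RuntimeError):
    """Raised when an object cannot be placed within the retry budget."""

    def __init__(self, message: str, achieved: int):
        super().__init__(message)
        self.achieved = achieved


@dataclass
class GlomeruliSpec:
    count: int = 12
    radius_um: tuple[float, float] = (9.0, 0.7)  # (mean, sd)
    shell_thickness_um: float = 2.0
    min_gap_um: float = 4.0
    #: optional (lo, hi) µm band restricting centre x positions, so part of
    #: the volume stays glomeruli-free for peripheral cells
    region_x_um: tuple[float, float] | None = None


@dataclass
class VesselSpec:
    count: int = 2
    radius_um: float = 3.0
    waypoints: int = 3
    clearance_um: float = 4.0  # minimum surface gap to glomeruli


@dataclass
class CellSpec:
    count: int = 0
    radius_um: tuple[float, float] = (2.4, 0.25)
    radius_clip_um: tuple[float, float] = (1.6, 3.4)
    population_fractions: dict[str, float] = field(
        default_factory=lambda: {"within": 0.0, "surrounding": 0.0, "peripheral": 1.0}
    )
    min_gap_um: float = 1.2  # minimum surface gap between cells


@dataclass
class DepositSpec:
    fraction_of_glomeruli_with_deposits: float = 0.0
    per_glomerulus_count: int = 0
    radius_um: float = 1.2


@dataclass
class NoiseSpec:
    background_level: float = 20.0
    gaussian_sd: float = 4.0
    poisson: bool = False


@dataclass
class PhantomSpec:
    """Full parameterisation of a phantom; deterministic given ``seed``.

    ``shape_voxels`` is (z, y, x); a desk-scale default in the same
    anisotropy regime as cleared-kidney confocal stacks is
    ``(80, 288, 288)`` at ``(1.0, 0.5, 0.5)`` µm.
    """

    shape_voxels: tuple[int, int, int]
    voxel_size_um: tuple[float, float, float]
    glomeruli: GlomeruliSpec = field(default_factory=GlomeruliSpec)
    vessels: VesselSpec = field(default_factory=VesselSpec)
    cells: CellSpec = field(default_factory=CellSpec)
    deposits: DepositSpec = field(default_factory=DepositSpec)
    intensities: dict[str, float] = field(
        default_factory=lambda: {
            "glomeruli_shell": 180.0,
            "glomeruli_core": 60.0,
            "vessels": 180.0,
            "cells": 160.0,
            "deposits": 200.0,
        }
    )
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape_voxels = tuple(int(s) for s in self.shape_voxels)
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if any(s < 1 for s in self.shape_voxels):
            raise ValueError("shape_voxels must be >= 1 in every axis")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be positive")
        if self.cells.count:
            total = sum(self.cells.population_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"population_fractions must sum to 1, got {total}")
            if any(f < 0 for f in self.cells.population_fractions.values()):
                raise ValueError("population_fractions must be non-negative")
        for name, spec_ in (("glomeruli", self.glomeruli), ("vessels", self.vessels),
                            ("cells", self.cells), ("deposits", self.deposits)):
            if getattr(spec_, "count", 0) < 0 or getattr(spec_, "per_glomerulus_count", 0) < 0:
                raise ValueError(f"{name} count must be >= 0")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """(z, y, x) physical extent."""
        return tuple(s * v for s, v in zip(self.shape_voxels, self.voxel_size_um))

    @property
    def gated_within_fraction(self) -> float:
        """Planted within-fraction among cells inside the <=20 µm gate."""
        f = self.cells.population_fractions
        gated = f.get("within", 0.0) + f.get("surrounding", 0.0)
        return f.get("within", 0.0) / gated if gated else float("nan")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key, sub in (("glomeruli", GlomeruliSpec), ("vessels", VesselSpec),
                         ("cells", CellSpec), ("deposits", DepositSpec),
                         ("noise", NoiseSpec)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted-object table plus vessel centrelines.

    ``objects`` columns: ``object_id, class_name, x_um, y_um, z_um,
    radius_um, true_population, host_glomerulus_id, truncated, skipped``.
    Positions are physical (x, y, z) in µm.
    """

    objects: pd.DataFrame
    vessel_paths: list[np.ndarray] = field(default_factory=list)

    def of_class(self, class_name: str) -> pd.DataFrame:
        return self.objects[self.objects["class_name"] == class_name].reset_index(drop=True)

    @property
    def cells(self) -> pd.DataFrame:
        return self.of_class("mhc2_cells")

    @property
    def glomeruli(self) -> pd.DataFrame:
        return self.of_class("glomeruli")

    def to_csv(self, path) -> None:
        self.objects.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GroundTruth":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def population_counts(count: int, fractions: dict[str, float]) -> dict[str, int]:
    """Integer cell counts per population via largest-remainder rounding.

    Exact when each ``count * fraction`` is (numerically) an integer, e.g.
    100 cells at fractions 0.2/0.3/0.5 give exactly 20/30/50.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    keys = [k for k in POPULATIONS if k in fractions] + [
        k for k in fractions if k not in POPULATIONS
    ]
    raw = {k: count * fractions[k] for k in keys}
    counts = {k: int(math.floor(v + 1e-9)) for k, v in raw.items()}
    short = count - sum(counts.values())
    by_remainder = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), keys.index(k)))
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


def analytic_cell_distance(
    center_xyz_um: np.ndarray,
    r_cell: float,
    glom_centers_xyz: np.ndarray,
    glom_radii: np.ndarray,
) -> tuple[float, int | None]:
    """Signed surface-to-surface distance to the nearest glomerulus sphere.

    Returns ``(distance, index-of-nearest)``; ``(inf, None)`` with no
    glomeruli.  Negative means the cell sphere penetrates the glomerulus.
    """
    if len(glom_centers_xyz) == 0:
        return float("inf"), None
    d = np.linalg.norm(glom_centers_xyz - np.asarray(center_xyz_um), axis=1)
    signed = d - glom_radii - r_cell
    i = int(np.argmin(signed))
    return float(signed[i]), i


def _classify(d: float, t_in: float = 0.5, t_out: float = 20.0) -> str:
    if d < t_in:
        return "within"
    if d <= t_out:
        return "surrounding"
    return "peripheral"


def _axis_window(c: float, r: float, h: float, n: int) -> tuple[int, int, bool]:
    """Index window [lo, hi) covering [c-r, c+r] on an axis with voxel size
    h and n voxels; third element flags analytic support clipped at the
    volume border."""
    lo = int(math.floor((c - r) / h - 0.5))
    hi = int(math.ceil((c + r) / h + 0.5)) + 1
    clipped = (c - r) < 0 or (c + r) > n * h
    return max(lo, 0), min(hi, n), clipped


def rasterize_sphere(
    out: np.ndarray,
    center_xyz_um: Sequence[float],
    radius_um: float,
    value: float,
    voxel_size_um: Sequence[float],
    inner_radius_um: float = 0.0,
    core_value: float = 0.0,
) -> tuple[bool, bool]:
    """Composite a solid sphere (or shell with a dimmer core) into ``out``
    via per-voxel max.  A voxel belongs to the sphere when its centre lies
    within the analytic radius.  Returns ``(drawn_any, truncated)``.
    """
    nz, ny, nx = out.shape
    hz, hy, hx = voxel_size_um
    cx, cy, cz = center_xyz_um
    zlo, zhi, cz_clip = _axis_window(cz, radius_um, hz, nz)
    ylo, yhi, cy_clip = _axis_window(cy, radius_um, hy, ny)
    xlo, xhi, cx_clip = _axis_window(cx, radius_um, hx, nx)
    truncated = cz_clip or cy_clip or cx_clip
    if zlo >= zhi or ylo >= yhi or xlo >= xhi:
        return False, truncated
    z = (np.arange(zlo, zhi) + 0.5) * hz - cz
    y = (np.arange(ylo, yhi) + 0.5) * hy - cy
    x = (np.arange(xlo, xhi) + 0.5) * hx - cx
    d2 = z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
    inside = d2 <= radius_um**2
    if not inside.any():
        return False, truncated
    sub = out[zlo:zhi, ylo:yhi, xlo:xhi]
    if inner_radius_um > 0:
        core = d2 < inner_radius_um**2
        shell = inside & ~core
        np.maximum(sub, np.where(shell, value, 0.0), out=sub, where=inside)
        if core_value > 0:
            np.maximum(sub, np.where(core, core_value, 0.0), out=sub, where=inside)
    else:
        np.maximum(sub, np.where(inside, value, 0.0), out=sub, where=inside)
    return True, truncated


def rasterize_tube(
    out: np.ndarray,
    waypoints_xyz_um: np.ndarray,
    radius_um: float,
    value: float,
    voxel_size_um: Sequence[float],
) -> None:
    """Composite a piecewise-linear tube (capsule chain) into ``out``."""
    nz, ny, nx = out.shape
    hz, hy, hx = voxel_size_um
    for p0, p1 in zip(waypoints_xyz_um[:-1], waypoints_xyz_um[1:]):
        lo_um = np.minimum(p0, p1) - radius_um
        hi_um = np.maximum(p0, p1) + radius_um
        # xyz -> zyx windows
        zlo, zhi, _ = _axis_window((lo_um[2] + hi_um[2]) / 2, (hi_um[2] - lo_um[2]) / 2, hz, nz)
        ylo, yhi, _ = _axis_window((lo_um[1] + hi_um[1]) / 2, (hi_um[1] - lo_um[1]) / 2, hy, ny)
        xlo, xhi, _ = _axis_window((lo_um[0] + hi_um[0]) / 2, (hi_um[0] - lo_um[0]) / 2, hx, nx)
        if zlo >= zhi or ylo >= yhi or xlo >= xhi:
            continue
        z = (np.arange(zlo, zhi) + 0.5) * hz
        y = (np.arange(ylo, yhi) + 0.5) * hy
        x = (np.arange(xlo, xhi) + 0.5) * hx
        pz, py, px = np.meshgrid(z, y, x, indexing="ij")
        rel = np.stack([px - p0[0], py - p0[1], pz - p0[2]], axis=-1)
        seg = p1 - p0
        seg2 = float(seg @ seg)
        t = np.clip((rel @ seg) / seg2, 0.0, 1.0) if seg2 > 0 else np.zeros(rel.shape[:-1])
        d2 = np.sum((rel - t[..., None] * seg) ** 2, axis=-1)
        inside = d2 <= radius_um**2
        sub = out[zlo:zhi, ylo:yhi, xlo:xhi]
        np.maximum(sub, np.where(inside, value, 0.0), out=sub, where=inside)


def rasterize_objects(
    objects: pd.DataFrame,
    shape_voxels: Sequence[int],
    voxel_size_um: Sequence[float],
    intensity: float | dict[str, float],
    shell_thickness_um: float = 0.0,
    core_value: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize a table of spherical objects into one intensity channel.

    ``objects`` needs columns ``object_id, x_um, y_um, z_um, radius_um``
    (and ``class_name`` when ``intensity`` is a per-class dict).  Objects
    entirely outside the volume are skipped with a warning; partially
    clipped ones are drawn and flagged.  Returns the channel and a flag
    table ``(object_id, truncated, skipped)``.
    """
    out = np.zeros(tuple(int(s) for s in shape_voxels), dtype=np.float32)
    flags = []
    for row in objects.itertuples(index=False):
        value = intensity[row.class_name] if isinstance(intensity, dict) else intensity
        inner = max(row.radius_um - shell_thickness_um, 0.0) if shell_thickness_um else 0.0
        drawn, truncated = rasterize_sphere(
            out, (row.x_um, row.y_um, row.z_um), row.radius_um, value,
            voxel_size_um, inner_radius_um=inner, core_value=core_value,
        )
        if not drawn:
            warnings.warn(
                f"object {row.object_id} lies outside the volume; skipped",
                stacklevel=2,
            )
        flags.append((row.object_id, truncated, not drawn))
    return out, pd.DataFrame(flags, columns=["object_id", "truncated", "skipped"])


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - astronomically unlikely
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _inside_volume(center_xyz: np.ndarray, radius: float, extent_xyz: np.ndarray,
                   margin: float = 1.0) -> bool:
    return bool(
        np.all(center_xyz - radius - margin >= 0.0)
        and np.all(center_xyz + radius + margin <= extent_xyz)
    )


def _place_glomeruli(spec: PhantomSpec, rng: np.random.Generator,
                     extent_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = spec.glomeruli
    centers: list[np.ndarray] = []
    radii: list[float] = []
    mean, sd = g.radius_um
    for i in range(g.count):
        for _ in range(RETRY_BUDGET):
            r = float(np.clip(rng.normal(mean, sd), mean - 3 * sd, mean + 3 * sd))
            lo = np.array([0.0, 0.0, 0.0]) + r + 2.0
            hi = extent_xyz - r - 2.0
            if g.region_x_um is not None:
                lo[0] = max(lo[0], g.region_x_um[0])
                hi[0] = min(hi[0], g.region_x_um[1])
            if np.any(hi <= lo):
                continue
            c = rng.uniform(lo, hi)
            if centers:
                gap = np.linalg.norm(np.array(centers) - c, axis=1) - np.array(radii) - r
                if gap.min() < g.min_gap_um:
                    continue
            centers.append(c)
            radii.append(r)
            break
        else:
            raise PlacementError(
                f"could not place glomerulus {i + 1}/{g.count} within "
                f"{RETRY_BUDGET} attempts", achieved=len(centers),
            )
    return (np.array(centers).reshape(-1, 3), np.array(radii))


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    seg = b - a
    seg2 = float(seg @ seg)
    t = float(np.clip((p - a) @ seg / seg2, 0.0, 1.0)) if seg2 > 0 else 0.0
    return float(np.linalg.norm(p - (a + t * seg)))


def _place_vessels(spec: PhantomSpec, rng: np.random.Generator, extent_xyz: np.ndarray,
                   glom_centers: np.ndarray, glom_radii: np.ndarray) -> list[np.ndarray]:
    v = spec.vessels
    paths = []
    for i in range(v.count):
        for _ in range(RETRY_BUDGET):
            pts = rng.uniform(
                v.radius_um, extent_xyz - v.radius_um, size=(max(v.waypoints, 2), 3)
            )
            ok = True
            for a, b in zip(pts[:-1], pts[1:]):
                for c, r in zip(glom_centers, glom_radii):
                    if _point_segment_distance(c, a, b) < r + v.radius_um + v.clearance_um:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                paths.append(pts)
                break
        else:
            raise PlacementError(
                f"could not route vessel {i + 1}/{v.count} within "
                f"{RETRY_BUDGET} attempts", achieved=len(paths),
            )
    return paths


def _sample_band(band: tuple[float | None, float], r_cell: float,
                 rng: np.random.Generator) -> float:
    lo, hi = band
    lo = -r_cell if lo is None else lo
    return float(rng.uniform(lo, hi))


def _place_cells(
    spec: PhantomSpec,
    rng: np.random.Generator,
    extent_xyz: np.ndarray,
    glom_centers: np.ndarray,
    glom_radii: np.ndarray,
) -> pd.DataFrame:
    c = spec.cells
    counts = population_counts(c.count, c.population_fractions)
    needs_gloms = counts.get("within", 0) + counts.get("surrounding", 0) > 0
    if needs_gloms and len(glom_centers) == 0:
        raise PlacementError("cells near glomeruli requested but no glomeruli", achieved=0)
    mean, sd = c.radius_um
    placed_centers: list[np.ndarray] = []
    placed_radii: list[float] = []
    rows = []
    for pop in POPULATIONS:
        band = PLANT_BANDS[pop]
        for i in range(counts.get(pop, 0)):
            for _ in range(RETRY_BUDGET):
                r = float(np.clip(rng.normal(mean, sd), *c.radius_clip_um))
                if pop == "peripheral":
                    # uniform rejection sampling: the far-field band is a
                    # large volume fraction, unlike the thin near bands
                    center = rng.uniform(r + 1.0, extent_xyz - r - 1.0)
                else:
                    gi = int(rng.integers(len(glom_centers)))
                    d = _sample_band(band, r, rng)
                    center = glom_centers[gi] + _random_direction(rng) * (
                        glom_radii[gi] + r + d
                    )
                if not _inside_volume(center, r, extent_xyz):
                    continue
                dist, nearest = analytic_cell_distance(center, r, glom_centers, glom_radii)
                if math.isfinite(dist):
                    lo = -r if band[0] is None else band[0]
                    if not (lo - 1e-9 <= dist <= band[1] + 1e-9):
                        continue
                    if _classify(dist) != pop:  # pragma: no cover - bands imply this
                        continue
                if placed_centers:
                    gap = (
                        np.linalg.norm(np.array(placed_centers) - center, axis=1)
                        - np.array(placed_radii) - r
                    )
                    if gap.min() < c.min_gap_um:
                        continue
                placed_centers.append(center)
                placed_radii.append(r)
                rows.append(
                    {
                        "class_name": "mhc2_cells",
                        "x_um": center[0], "y_um": center[1], "z_um": center[2],
                        "radius_um": r,
                        "true_population": pop,
                        "host_glomerulus_id": np.nan,
                        "planted_distance_um": dist if math.isfinite(dist) else np.inf,
                        "nearest_glomerulus_index": -1 if nearest is None else nearest,
                    }
                )
                break
            else:
                raise PlacementError(
                    f"could not place {pop} cell {i + 1}/{counts[pop]} within "
                    f"{RETRY_BUDGET} attempts", achieved=len(rows),
                )
    return pd.DataFrame(rows)


def _place_deposits(spec: PhantomSpec, rng: np.random.Generator,
                    glom_centers: np.ndarray, glom_radii: np.ndarray,
                    glom_ids: np.ndarray) -> pd.DataFrame:
    d = spec.deposits
    rows = []
    if d.per_glomerulus_count <= 0 or d.fraction_of_glomeruli_with_deposits <= 0:
        return pd.DataFrame(rows)
    n_hosts = int(round(d.fraction_of_glomeruli_with_deposits * len(glom_centers)))
    hosts = rng.choice(len(glom_centers), size=min(n_hosts, len(glom_centers)), replace=False)
    for gi in sorted(hosts):
        for j in range(d.per_glomerulus_count):
            for _ in range(RETRY_BUDGET):
                offset = _random_direction(rng) * rng.uniform(
                    0, max(glom_radii[gi] - d.radius_um - 0.5, 0.0)
                )
                center = glom_centers[gi] + offset
                rows.append(
                    {
                        "class_name": "igg_deposits",
                        "x_um": center[0], "y_um": center[1], "z_um": center[2],
                        "radius_um": d.radius_um,
                        "true_population": None,
                        "host_glomerulus_id": int(glom_ids[gi]),
                        "planted_distance_um": np.nan,
                        "nearest_glomerulus_index": gi,
                    }
                )
                break
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, GroundTruth]:
    """Generate a seeded multi-channel phantom and its ground truth.

    Channels are ``cd31`` (glomeruli shells + vessels), ``mhc2`` (cells)
    and ``igg`` (deposits).  Deterministic given ``spec`` (bit-identical
    across calls with the same seed).
    """
    rng_place, rng_noise = (
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(2)
    )
    extent_zyx = np.array(spec.extent_um)
    extent_xyz = extent_zyx[::-1]

    glom_centers, glom_radii = (
        _place_glomeruli(spec, rng_place, extent_xyz)
        if spec.glomeruli.count > 0
        else (np.empty((0, 3)), np.empty(0))
    )
    glom_ids = np.arange(1, len(glom_centers) + 1)
    vessel_paths = (
        _place_vessels(spec, rng_place, extent_xyz, glom_centers, glom_radii)
        if spec.vessels.count > 0
        else []
    )
    cells = _place_cells(spec, rng_place, extent_xyz, glom_centers, glom_radii)
    deposits = _place_deposits(spec, rng_place, glom_centers, glom_radii, glom_ids)

    glom_df = pd.DataFrame(
        {
            "class_name": "glomeruli",
            "x_um": glom_centers[:, 0] if len(glom_centers) else [],
            "y_um": glom_centers[:, 1] if len(glom_centers) else [],
            "z_um": glom_centers[:, 2] if len(glom_centers) else [],
            "radius_um": glom_radii,
            "true_population": None,
            "host_glomerulus_id": np.nan,
            "planted_distance_um": np.nan,
            "nearest_glomerulus_index": -1,
        }
    )
    if len(cells):
        cells = cells.copy()
        cells["host_glomerulus_id"] = np.nan
    frames = [d for d in (glom_df, cells, deposits) if len(d)]
    if frames:
        objects = pd.concat(frames, ignore_index=True)
    else:
        objects = pd.DataFrame(
            columns=["class_name", "x_um", "y_um", "z_um", "radius_um",
                     "true_population", "host_glomerulus_id",
                     "planted_distance_um", "nearest_glomerulus_index"]
        )
    objects.insert(0, "object_id", np.arange(1, len(objects) + 1))

    inten = spec.intensities
    cd31, glom_flags = rasterize_objects(
        objects[objects["class_name"] == "glomeruli"],
        spec.shape_voxels, spec.voxel_size_um,
        inten["glomeruli_shell"],
        shell_thickness_um=spec.glomeruli.shell_thickness_um,
        core_value=inten["glomeruli_core"],
    )
    for path in vessel_paths:
        rasterize_tube(cd31, path, spec.vessels.radius_um, inten["vessels"],
                       spec.voxel_size_um)
    mhc2, cell_flags = rasterize_objects(
        objects[objects["class_name"] == "mhc2_cells"],
        spec.shape_voxels, spec.voxel_size_um, inten["cells"],
    )
    igg, dep_flags = rasterize_objects(
        objects[objects["class_name"] == "igg_deposits"],
        spec.shape_voxels, spec.voxel_size_um, inten["deposits"],
    )
    flags = pd.concat([glom_flags, cell_flags, dep_flags], ignore_index=True)
    objects = objects.merge(flags, on="object_id", how="left")
    for col in ("truncated", "skipped"):
        objects[col] = objects[col].where(objects[col].notna(), False).astype(bool)

    stack = np.stack([cd31, mhc2, igg]).astype(np.float32)
    stack += spec.noise.background_level
    if spec.noise.poisson:
        stack = rng_noise.poisson(np.clip(stack, 0, None)).astype(np.float32)
    if spec.noise.gaussian_sd > 0:
        stack += rng_noise.normal(0.0, spec.noise.gaussian_sd, size=stack.shape).astype(
            np.float32
        )
    grid = VoxelGrid(stack, spec.voxel_size_um, list(CHANNELS))
    return grid, GroundTruth(objects, vessel_paths)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

#: planted population counts per scenario: within / surrounding / peripheral.
#: Gated (within + surrounding) totals of 250 and 280 give exact planted
#: gated within-fractions 42/250 = 0.168 and 98/280 = 0.35, and peripheral
#: counts reproduce peripheral shares of ~73.7% and ~26.1% of all cells.
_SCENARIO_COUNTS = {
    "WT": {"within": 42, "surrounding": 208, "peripheral": 700},
    "KO": {"within": 98, "surrounding": 182, "peripheral": 99},
}
#: mean cell radius per scenario; KO infiltrating cells are planted larger
#: so that group volume comparisons separate the scenarios.
_SCENARIO_CELL_RADIUS = {"WT": (2.4, 0.25), "KO": (2.7, 0.25)}


def scenario(name: str, seed: int = 0) -> PhantomSpec:
    """Preset phantom specs for the two comparison scenarios.

    ``"WT"`` plants a gated within-fraction of 0.168, ``"KO"`` one of 0.35,
    each with 250–280 cells inside the <=20 µm gate.  All geometry is
    desk-scale: 80x288x288 voxels at (1.0, 0.5, 0.5) µm.
    """
    if name not in _SCENARIO_COUNTS:
        raise ValueError(f"unknown scenario {name!r}; expected one of "
                         f"{sorted(_SCENARIO_COUNTS)}")
    counts = _SCENARIO_COUNTS[name]
    total = sum(counts.values())
    fractions = {k: v / total for k, v in counts.items()}
    return PhantomSpec(
        shape_voxels=(80, 288, 288),
        voxel_size_um=(1.0, 0.5, 0.5),
        glomeruli=GlomeruliSpec(count=12, radius_um=(9.0, 0.7), shell_thickness_um=2.0,
                                min_gap_um=4.0, region_x_um=(12.0, 60.0)),
        vessels=VesselSpec(count=2, radius_um=3.0, waypoints=3, clearance_um=4.0),
        cells=CellSpec(count=total, radius_um=_SCENARIO_CELL_RADIUS[name],
                       population_fractions=fractions),
        deposits=DepositSpec(fraction_of_glomeruli_with_deposits=0.5,
                             per_glomerulus_count=2, radius_um=1.2),
        noise=NoiseSpec(background_level=20.0, gaussian_sd=4.0, poisson=False),
        seed=seed,
    )
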