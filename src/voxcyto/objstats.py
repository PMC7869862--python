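"""Per-object surface statistics.

One record per label: physical centroid (x, y, z in µm, centre-of-voxel
convention), exact voxel-count volume, marching-cubes surface area
honouring voxel spacing, sphericity, per-channel median intensities and
bounding-box extents.  Surface area deliberately comes from a mesh rather
than voxel-face counting — face counting overestimates the area of smooth
shapes by tens of percent, which would wreck sphericity.
"""

from __future__ import annotations

import hashlib
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import marching_cubes, mesh_surface_area, regionprops

from voxcyto.io_formats import LabelMap, VoxelGrid, make_long_table

__all__ = [
    "compute_object_stats",
    "sphericity",
    "roundness_2d",
    "mesh_area",
    "object_table_to_long",
]

#: sphericity values above this are clipped (with a warning): mesh
#: smoothing can push tiny digitised objects slightly past 1.
SPHERICITY_CLIP = 1.05


def sphericity(volume_um3: float, surface_area_um2: float) -> float:
    """pi^(1/3) * (6 V)^(2/3) / A — 1 for a perfect sphere."""
    if volume_um3 <= 0 or surface_area_um2 <= 0:
        raise ValueError("volume and surface area must be positive")
    return float(np.pi ** (1 / 3) * (6.0 * volume_um3) ** (2 / 3) / surface_area_um2)


def _mesh_sigma_vox(mask: np.ndarray) -> float:
    """Pre-mesh smoothing strength, scaled to the object's thinnest
    dimension: 0.2 x the smallest tight-bbox halfwidth (voxels), clipped
    to [0.35, 0.7].  Tuned on digitised spheres: counters the ~8%
    staircase area inflation of meshing a raw binary mask without eroding
    thin objects."""
    nz = np.nonzero(mask)
    halfwidth = min((ax.max() - ax.min() + 1) for ax in nz) / 2.0
    return float(np.clip(0.2 * halfwidth, 0.35, 0.7))


def mesh_area(mask: np.ndarray, voxel_size_um: tuple[float, float, float]) -> float:
    """Surface area of a binary mask from a marching-cubes mesh with
    physical spacing.  The mask is zero-padded so border objects close,
    and lightly smoothed before meshing so the level-0.5 surface tracks
    the underlying smooth shape instead of the voxel staircase."""
    padded = np.pad(mask, 2).astype(np.float32)
    smoothed = ndi.gaussian_filter(padded, _mesh_sigma_vox(mask))
    # smoothing can push a tiny object's maximum below the level; fall
    # back to the raw mask in that case
    if smoothed.max() <= 0.5:
        smoothed = padded
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=voxel_size_um)
    return float(mesh_surface_area(verts, faces))


def compute_object_stats(
    labelmap: LabelMap, grid: VoxelGrid | None = None
) -> pd.DataFrame:
    """Compute the per-object statistics table for a label map.

    Returns a DataFrame with one row per label: ``object_id, class_name,
    x_um, y_um, z_um, volume_um3, surface_area_um2, sphericity,
    bbox_x_um, bbox_y_um, bbox_z_um`` plus one ``median_<channel>``
    column per channel when an intensity grid is supplied.  Provenance
    (source class name, geometry hash) is stored in ``DataFrame.attrs``.
    """
    if grid is not None and not labelmap.same_geometry(grid):
        raise ValueError(
            f"geometry mismatch: labels {labelmap.shape_zyx}@{labelmap.voxel_size_um} "
            f"vs grid {grid.shape_zyx}@{grid.voxel_size_um}"
        )
    labels = labelmap.labels
    hz, hy, hx = labelmap.voxel_size_um
    voxel_volume = hz * hy * hx
    ids = labelmap.label_ids
    slices = ndi.find_objects(labels)

    rows = []
    clipped = 0
    for oid in ids:
        sl = slices[int(oid) - 1]
        sub = labels[sl] == oid
        count = int(sub.sum())
        zz, yy, xx = np.nonzero(sub)
        z0, y0, x0 = sl[0].start, sl[1].start, sl[2].start
        cz = (zz.mean() + z0 + 0.5) * hz
        cy = (yy.mean() + y0 + 0.5) * hy
        cx = (xx.mean() + x0 + 0.5) * hx
        volume = count * voxel_volume
        area = mesh_area(sub, labelmap.voxel_size_um)
        sph = sphericity(volume, area)
        if sph > SPHERICITY_CLIP:
            clipped += 1
            sph = SPHERICITY_CLIP
        row = {
            "object_id": int(oid),
            "class_name": labelmap.class_name,
            "x_um": cx, "y_um": cy, "z_um": cz,
            "volume_um3": volume,
            "surface_area_um2": area,
            "sphericity": sph,
            "bbox_x_um": (xx.max() - xx.min() + 1) * hx,
            "bbox_y_um": (yy.max() - yy.min() + 1) * hy,
            "bbox_z_um": (zz.max() - zz.min() + 1) * hz,
        }
        if grid is not None:
            for name in grid.channel_names:
                vals = grid.channel(name)[sl][sub]
                row[f"median_{name}"] = float(np.median(vals))
        rows.append(row)

    if clipped:
        warnings.warn(
            f"{clipped} object(s) had mesh sphericity > {SPHERICITY_CLIP}; "
            f"clipped to {SPHERICITY_CLIP}",
            stacklevel=2,
        )
    columns = ["object_id", "class_name", "x_um", "y_um", "z_um", "volume_um3",
               "surface_area_um2", "sphericity", "bbox_x_um", "bbox_y_um", "bbox_z_um"]
    if grid is not None:
        columns += [f"median_{name}" for name in grid.channel_names]
    df = pd.DataFrame(rows, columns=columns)
    df.attrs["class_name"] = labelmap.class_name
    df.attrs["geometry"] = _geometry_hash(labelmap)
    return df


def _geometry_hash(labelmap: LabelMap) -> str:
    h = hashlib.sha256()
    h.update(repr((labelmap.shape_zyx, labelmap.voxel_size_um)).encode())
    return h.hexdigest()[:16]


def roundness_2d(mask: np.ndarray) -> float:
    """Inverse aspect ratio (minor/major axis of the best-fit ellipse) of
    a 2D region, in (0, 1].  Degenerate regions whose fitted major axis is
    zero (e.g. a single pixel) return 1.0 by convention."""
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("roundness_2d expects a 2-D mask")
    if not mask.any():
        raise ValueError("empty region")
    props = regionprops(mask.astype(np.uint8))[0]
    major = props.axis_major_length
    if major == 0:
        return 1.0
    return float(props.axis_minor_length / major)


def object_table_to_long(stats: pd.DataFrame) -> list[pd.DataFrame]:
    """Explode a statistics table into one long-format table per parameter,
    ready for :func:`voxcyto.io_formats.concat_statistics`."""
    tables = []
    for col in stats.columns:
        if col in ("object_id", "class_name"):
            continue
        if col.startswith("median_"):
            param, channel = "median_intensity", col[len("median_"):]
        else:
            param, channel = col, None
        tables.append(
            make_long_table(
                [(int(i), param, channel, float(v))
                 for i, v in zip(stats["object_id"], stats[col])]
            )
        )
    return tables
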