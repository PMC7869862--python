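"""Image-stack and statistics-table IO.

Arrays are stored ``(channel, z, y, x)``; physical coordinates are reported
``(x, y, z)`` in micrometres at the table boundary only.  Voxel indices are
0-based and the physical position of a voxel centre is
``(index + 0.5) * voxel_size``.

Stacks are read/written as OME-TIFF via :mod:`tifffile`.  Object statistics
travel in a long format (``object_id, parameter_name, channel, value``) and
are pivoted into a wide, flow-software-compatible CSV with one row per
object.
"""

from __future__ import annotations

import io
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelGrid",
    "LabelMap",
    "read_stack",
    "write_stack",
    "make_long_table",
    "read_long_csv",
    "concat_statistics",
    "export_flowjo_csv",
    "read_flowjo_csv",
]

#: columns of a long-format statistics table
LONG_COLUMNS = ("object_id", "parameter_name", "channel", "value")

#: marker used for absent (object, parameter) cells in wide tables
MISSING = np.nan


@dataclass
class VoxelGrid:
    """Multi-channel 3D intensity volume with physical voxel spacing.

    Parameters
    ----------
    intensities
        Array of shape ``(n_channels, nz, ny, nx)``.
    voxel_size_um
        Physical voxel spacing ``(z, y, x)`` in micrometres, all > 0.
    channel_names
        One unique, non-empty name per channel.
    """

    intensities: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 4:
            raise ValueError(
                f"intensities must be 4-D (channel, z, y, x), got {self.intensities.ndim}-D"
            )
        if self.intensities.shape[0] < 1:
            raise ValueError("grid must have at least one channel")
        if min(self.intensities.shape[1:]) < 1:
            raise ValueError("spatial extents must be >= 1 in every axis")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"voxel_size_um must be 3 positive values, got {self.voxel_size_um}")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.intensities.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.intensities.shape[0]} channels"
            )
        if any(not c for c in self.channel_names):
            raise ValueError("channel names must be non-empty")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"channel names must be unique: {self.channel_names}")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.intensities.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D ``(z, y, x)`` array for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}") from None
        return self.intensities[idx]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelGrid):
            return NotImplemented
        return (
            self.intensities.dtype == other.intensities.dtype
            and np.array_equal(self.intensities, other.intensities)
            and self.voxel_size_um == other.voxel_size_um
            and self.channel_names == other.channel_names
        )


@dataclass
class LabelMap:
    """Integer-labelled 3D object map sharing a grid's geometry.

    ``labels`` holds non-negative integers with 0 reserved for background.
    Label ids are either contiguous ``1..N`` (segmentation output) or a
    sparse subset of a parent map's ids (e.g. after a glomeruli/vessel
    split); :attr:`label_ids` enumerates whichever is present.
    """

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    class_name: str = "objects"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3-D (z, y, x), got {self.labels.ndim}-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {self.labels.dtype}")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"voxel_size_um must be 3 positive values, got {self.voxel_size_um}")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def same_geometry(self, other: "LabelMap | VoxelGrid") -> bool:
        return (
            self.shape_zyx == other.shape_zyx
            and np.allclose(self.voxel_size_um, other.voxel_size_um)
        )


# ---------------------------------------------------------------------------
# OME-TIFF stacks
# ---------------------------------------------------------------------------

_OME_NS = {"ome": "http://www.openmicroscopy.org/Schemas/OME/2016-06"}


_UUID_RE = re.compile(rb"urn:uuid:[0-9a-fA-F-]{36}")


def _normalize_ome_uuid(path: Path) -> None:
    """Overwrite the time-based OME UUID with a constant so that identical
    grids produce byte-identical files (manifest reproducibility)."""
    fixed = b"urn:uuid:00000000-0000-0000-0000-000000000000"
    with open(path, "r+b") as fh:
        # tifffile places the OME description near the start for small
        # files and appends it after the pixel data for larger ones
        fh.seek(0, 2)
        size = fh.tell()
        for offset, length in ((0, 65536), (max(0, size - 2**20), 2**20)):
            fh.seek(offset)
            chunk = fh.read(length)
            m = _UUID_RE.search(chunk)
            if m is not None:
                fh.seek(offset + m.start())
                fh.write(fixed)
                return


def write_stack(grid: VoxelGrid, path: str | Path) -> None:
    """Write a :class:`VoxelGrid` as OME-TIFF, preserving channel names and
    voxel sizes. ``read_stack(write_stack(g))`` is the identity; writes are
    deterministic (byte-identical for identical grids)."""
    path = Path(path)
    vz, vy, vx = grid.voxel_size_um
    tifffile.imwrite(
        path,
        grid.intensities,
        ome=True,
        photometric="minisblack",  # never guess RGB from small axis sizes
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": vx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": vy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": vz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(grid.channel_names)},
        },
    )
    _normalize_ome_uuid(path)


def write_labelmap(labelmap: LabelMap, path: str | Path) -> None:
    """Write a label map as a single-channel OME-TIFF."""
    grid = VoxelGrid(
        labelmap.labels[None].astype(np.int32),
        labelmap.voxel_size_um,
        [labelmap.class_name],
    )
    write_stack(grid, path)


def read_labelmap(path: str | Path) -> LabelMap:
    grid = read_stack(path)
    if grid.n_channels != 1:
        raise ValueError(f"label map file must have one channel, found {grid.n_channels}")
    return LabelMap(
        grid.intensities[0].astype(np.int32), grid.voxel_size_um, grid.channel_names[0]
    )


def _parse_ome_metadata(xml_text: str) -> tuple[tuple[float, ...] | None, list[str]]:
    """Extract (z, y, x) voxel size in µm and channel names from OME-XML."""
    root = ET.fromstring(xml_text)
    pixels = root.find(".//ome:Image/ome:Pixels", _OME_NS)
    if pixels is None:
        return None, []
    sizes = []
    for ax in ("Z", "Y", "X"):
        raw = pixels.get(f"PhysicalSize{ax}")
        sizes.append(float(raw) if raw is not None else None)
    voxel = tuple(sizes) if all(s is not None for s in sizes) else None
    names = []
    for ch in pixels.findall("ome:Channel", _OME_NS):
        names.append(ch.get("Name") or "")
    return voxel, names


def read_stack(
    path: str | Path,
    voxel_size_um: Sequence[float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> VoxelGrid:
    """Read a TIFF/OME-TIFF stack into a :class:`VoxelGrid`.

    Axes are normalised to ``(channel, z, y, x)``; a plain 2D TIFF becomes a
    single-channel, depth-1 grid.  The voxel size must be present in the
    OME metadata or supplied via ``voxel_size_um`` — a missing size is an
    error, never a silent default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper().replace("S", "C").replace("I", "Z").replace("Q", "Z")
        meta_voxel: tuple[float, ...] | None = None
        meta_channels: list[str] = []
        if tf.ome_metadata:
            meta_voxel, meta_channels = _parse_ome_metadata(tf.ome_metadata)

    if len(axes) != data.ndim:
        raise ValueError(f"cannot interpret axes {axes!r} for {data.ndim}-D data")
    unknown = set(axes) - set("CZYX")
    if unknown:
        raise ValueError(f"ambiguous axis order {axes!r}: unsupported axes {sorted(unknown)}")
    if "Y" not in axes or "X" not in axes:
        raise ValueError(f"ambiguous axis order {axes!r}: need Y and X")

    # insert missing singleton axes, then order as CZYX
    for ax in "CZYX":
        if ax not in axes:
            data = data[None]
            axes = ax + axes
    order = [axes.index(ax) for ax in "CZYX"]
    data = np.transpose(data, order)

    if voxel_size_um is not None:
        voxel = tuple(float(v) for v in voxel_size_um)
    elif meta_voxel is not None:
        voxel = meta_voxel
    else:
        raise ValueError(
            f"{path}: no voxel size in metadata and no override supplied; "
            "pass voxel_size_um explicitly"
        )

    if channel_names is not None:
        names = list(channel_names)
    elif len(meta_channels) == data.shape[0] and all(meta_channels):
        names = meta_channels
    else:
        names = [f"channel_{i}" for i in range(data.shape[0])]
    return VoxelGrid(data, voxel, names)


# ---------------------------------------------------------------------------
# Statistics tables
# ---------------------------------------------------------------------------


def make_long_table(records: Sequence[tuple]) -> pd.DataFrame:
    """Build a long-format statistics table from
    ``(object_id, parameter_name, channel-or-None, value)`` tuples."""
    df = pd.DataFrame(list(records), columns=list(LONG_COLUMNS))
    return _validate_long(df)


def _validate_long(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"long table missing columns {sorted(missing)}")
    df = df.loc[:, list(LONG_COLUMNS)].copy()
    df["object_id"] = df["object_id"].astype(np.int64)
    if (df["object_id"] <= 0).any():
        raise ValueError("object ids must be positive")
    df["value"] = pd.to_numeric(df["value"])
    return df


def read_long_csv(path: str | Path, lenient: bool = False) -> pd.DataFrame:
    """Read a long-format statistics CSV.

    With ``lenient=True`` leading non-tabular header lines (as emitted by
    commercial surface-statistics exporters) are skipped until a line
    containing the expected column names is found.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if lenient:
        lines = text.splitlines()
        start = None
        for i, line in enumerate(lines):
            cols = [c.strip().lower() for c in line.split(",")]
            if {"object_id", "parameter_name", "value"} <= set(cols):
                start = i
                break
        if start is None:
            raise ValueError(f"{path}: no header row with expected column names found")
        text = "\n".join(lines[start:])
    df = pd.read_csv(io.StringIO(text))
    df.columns = [c.strip().lower() for c in df.columns]
    if "channel" not in df.columns:
        df["channel"] = None
    return _validate_long(df)


def _column_name(parameter: str, channel) -> str:
    if channel is None or (isinstance(channel, float) and np.isnan(channel)) or channel == "":
        return str(parameter)
    return f"{parameter}_{channel}"


def concat_statistics(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate long-format statistics tables into one wide table.

    Returns a DataFrame indexed by ``object_id`` with one column per
    ``parameter_name x channel`` combination, columns sorted by
    (parameter, channel).  Objects lacking a parameter get the missing
    marker (NaN; serialised as an empty CSV cell).  Conflicting duplicate
    values raise ``ValueError`` naming the collision.
    """
    if not tables:
        raise ValueError("need at least one statistics table")
    frames = [_validate_long(t) for t in tables]
    long = pd.concat(frames, ignore_index=True)
    long["channel"] = long["channel"].where(pd.notna(long["channel"]), None)

    key = ["object_id", "parameter_name", "channel"]
    keyed = long.fillna({"channel": ""}).groupby(
        ["object_id", "parameter_name", "channel"], dropna=False
    )["value"]
    conflicting = keyed.nunique() > 1
    if conflicting.any():
        oid, param, chan = conflicting[conflicting].index[0]
        raise ValueError(
            f"conflicting duplicate values for object_id={oid}, "
            f"parameter={param!r}, channel={chan or None!r}"
        )
    long = long.drop_duplicates(subset=key)

    long["column"] = [
        _column_name(p, c) for p, c in zip(long["parameter_name"], long["channel"])
    ]
    col_order = sorted(
        long[["parameter_name", "channel", "column"]]
        .drop_duplicates()
        .itertuples(index=False),
        key=lambda t: (t.parameter_name, t.channel if t.channel is not None else ""),
    )
    wide = long.pivot(index="object_id", columns="column", values="value")
    wide = wide.loc[:, [t.column for t in col_order]]
    wide = wide.sort_index()
    wide.columns.name = None
    return wide


def export_flowjo_csv(wide: pd.DataFrame, path: str | Path) -> None:
    """Write a wide table as flow-software-compatible CSV.

    Plain RFC-4180 CSV, UTF-8, '.' decimal separator, no thousands
    separators; missing markers become empty cells.  Re-parsing with
    :func:`read_flowjo_csv` yields the same table.
    """
    bad = [c for c in wide.columns if not pd.api.types.is_numeric_dtype(wide[c])]
    if bad:
        raise ValueError(f"non-numeric columns cannot be exported: {bad}")
    out = wide.copy()
    out.index.name = "object_id"
    out.to_csv(path, na_rep="", float_format=None, encoding="utf-8")


def read_flowjo_csv(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`export_flowjo_csv`."""
    df = pd.read_csv(path, index_col="object_id", encoding="utf-8")
    return df
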