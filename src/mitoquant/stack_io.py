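"""Stack and table IO plus acquisition geometry and pipeline configuration.

All stacks are indexed ``(z, y, x)`` with 0-based indices; physical lengths
are in micrometres (µm) and volumes in µm³ throughout the package. Voxel
dimensions always come from configuration, never from TIFF metadata: the
acquisition geometry of confocal systems (e.g. 103 × 103 × 150 nm at 63×,
325 × 325 × 350 nm at 20×) is part of the experimental record, and silently
trusting embedded metadata invites anisotropy bugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("mitoquant")

CHANNELS = ("mito", "nucleus", "cell")

OBJECT_TABLE_COLUMNS = [
    "cell_id",
    "object_id",
    "voxel_count",
    "volume_um3",
    "mean_intensity",
    "total_intensity",
    "size_class",
]


@dataclass
class VoxelGrid:
    """One channel's 3D intensity stack with physical voxel dimensions.

    Parameters
    ----------
    data
        3D non-negative intensity array indexed ``(z, y, x)``.
    dz, dy, dx
        Voxel edge lengths in µm, all strictly positive.
    channel
        One of ``{"mito", "nucleus", "cell"}``.
    bit_depth
        Nominal camera bit depth (16 by default; sCMOS cameras such as the
        ORCA-Flash4.0 deliver 16-bit frames).
    """

    data: np.ndarray
    dz: float
    dy: float
    dx: float
    channel: str = "mito"
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x); got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"stack needs >= 1 slice per dimension; got {self.data.shape}")
        if not (self.dz > 0 and self.dy > 0 and self.dx > 0):
            raise ValueError(f"voxel dimensions must be positive; got {(self.dz, self.dy, self.dx)}")
        if self.data.size and float(np.min(self.data)) < 0:
            raise ValueError("intensities must be non-negative")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}; got {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        """Voxel edge lengths ``(dz, dy, dx)`` in µm."""
        return (self.dz, self.dy, self.dx)

    @property
    def voxel_volume_um3(self) -> float:
        return self.dz * self.dy * self.dx

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """Copy of this grid carrying new intensity data, same geometry."""
        return replace(self, data=data)


@dataclass
class ChannelSet:
    """Aligned multi-channel acquisition of one field of view.

    The mitochondrial channel (a membrane-potential dye such as TMRM) is
    mandatory; nucleus (Hoechst) and whole-cell (Calcein-AM) channels are
    optional. All present channels must share shape and voxel dimensions.
    """

    mito: VoxelGrid
    nucleus: Optional[VoxelGrid] = None
    cell: Optional[VoxelGrid] = None

    def __post_init__(self) -> None:
        for other in (self.nucleus, self.cell):
            if other is None:
                continue
            if other.shape != self.mito.shape:
                raise ValueError(
                    f"channel shapes differ: {other.channel} {other.shape} vs mito {self.mito.shape}"
                )
            if other.voxel_dims != self.mito.voxel_dims:
                raise ValueError("channel voxel dimensions differ")


@dataclass(frozen=True)
class RoiRect:
    """Axis-aligned rectangular ROI in image (y, x) pixel coordinates."""

    roi_id: str
    y0: int
    x0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI height and width must be positive")
        if self.y0 < 0 or self.x0 < 0:
            raise ValueError("ROI origin must be non-negative")

    def area_um2(self, dy: float, dx: float) -> float:
        return self.height * self.width * dy * dx

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y0 + self.height), slice(self.x0, self.x0 + self.width)

    def check_inside(self, shape_yx: tuple[int, int]) -> None:
        if self.y0 + self.height > shape_yx[0] or self.x0 + self.width > shape_yx[1]:
            raise ValueError(f"ROI {self.roi_id} extends outside image of shape {shape_yx}")


@dataclass
class AnalysisConfig:
    """Parameters of the segmentation/quantification pipeline.

    threshold_value is deliberately a *required* number: masks are produced
    by thresholding at a constant value, shared across every stack of an
    experiment, so that volumes are comparable. A suggested value can be
    derived from a background region (see
    :func:`mitoquant.segmentation.suggest_threshold`) but the pipeline never
    picks one silently.
    """

    threshold_value: float
    threshold_nucleus: Optional[float] = None
    threshold_cell: Optional[float] = None
    median_radius: int = 1
    tophat_radius_um: float = 1.0
    connectivity: int = 26
    size_class_bounds: tuple[float, float] = (2.0, 10.0)
    fill_holes_cell: bool = True
    fill_holes_nucleus: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_value < 0:
            raise ValueError("threshold_value must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        lo, hi = self.size_class_bounds
        if not lo < hi:
            raise ValueError("size_class_bounds must be strictly increasing")
        if self.median_radius < 0:
            raise ValueError("median_radius must be >= 0")
        if self.tophat_radius_um <= 0:
            raise ValueError("tophat_radius_um must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a flat key/value text file (YAML-compatible)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "size_class_bounds" in raw:
            raw["size_class_bounds"] = tuple(float(v) for v in raw["size_class_bounds"])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        d = self.as_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["size_class_bounds"] = list(self.size_class_bounds)
        return d


# ---------------------------------------------------------------------------
# TIFF IO


def read_stack(
    path: str | Path,
    geometry: Sequence[float],
    channel: str = "mito",
    bit_depth: int = 16,
) -> VoxelGrid:
    """Read a multi-page grayscale TIFF as a z-stack.

    Pages are taken as z-slices in file order; intensities are returned
    unmodified. ``geometry`` is ``(dz, dy, dx)`` in µm and always comes from
    the caller; if the file carries conflicting OME/resolution metadata the
    configured geometry wins with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dz, dy, dx = (float(g) for g in geometry)
    with tifffile.TiffFile(path) as tf:
        shapes = {page.shape for page in tf.pages}
        if len(shapes) > 1:
            raise ValueError(f"{path.name}: pages have inconsistent shapes {sorted(shapes)}")
        data = tf.asarray()
        meta_dims = _metadata_voxel_dims(tf)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected grayscale pages, got array of ndim {data.ndim}")
    if meta_dims is not None and not np.allclose(meta_dims, (dz, dy, dx), rtol=1e-3):
        logger.warning(
            "%s: TIFF metadata voxel size %s conflicts with configured %s; using configured",
            path.name,
            meta_dims,
            (dz, dy, dx),
        )
    return VoxelGrid(data=data, dz=dz, dy=dy, dx=dx, channel=channel, bit_depth=bit_depth)


def _metadata_voxel_dims(tf: "tifffile.TiffFile") -> Optional[tuple[float, float, float]]:
    # best-effort: ImageJ-style metadata with spacing + XResolution in px/µm
    try:
        meta = tf.imagej_metadata or {}
        spacing = meta.get("spacing")
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if spacing is None or xres is None or yres is None:
            return None
        xr = xres.value[0] / xres.value[1]
        yr = yres.value[0] / yres.value[1]
        if xr <= 0 or yr <= 0:
            return None
        return (float(spacing), 1.0 / yr, 1.0 / xr)
    except Exception:  # metadata is advisory only
        return None


def write_stack(grid: VoxelGrid, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF (z as pages); lossless for integers."""
    tifffile.imwrite(Path(path), np.asarray(grid.data), photometric="minisblack")


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    """Write a label map as a 16-bit multi-page TIFF."""
    arr = np.asarray(labels)
    if arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit TIFF")
    tifffile.imwrite(Path(path), arr.astype(np.uint16), photometric="minisblack")


# ---------------------------------------------------------------------------
# tabular IO


def objects_to_frame(records, cell_id: str = "cell") -> pd.DataFrame:
    """Arrange per-object records into the canonical objects table."""
    rows = [
        {
            "cell_id": cell_id,
            "object_id": r.object_id,
            "voxel_count": r.voxel_count,
            "volume_um3": r.volume_um3,
            "mean_intensity": r.mean_intensity,
            "total_intensity": r.total_intensity,
            "size_class": r.size_class,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=OBJECT_TABLE_COLUMNS)


def write_objects_table(
    records,
    path: str | Path,
    cell_id: str = "cell",
    excel_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write one row per mitochondrial object (CSV; optionally also .xlsx).

    CSV is the canonical, diffable format; the spreadsheet writer mirrors the
    classic per-cell object workbook. Full numeric precision is stored.
    """
    df = objects_to_frame(records, cell_id=cell_id)
    df.to_csv(path, index=False)
    if excel_path is not None:
        df.to_excel(excel_path, index=False)
    return df


def read_objects_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"cell_id": str, "size_class": str})


def read_rois(path: str | Path) -> list[RoiRect]:
    """Read ROI rectangles from a CSV with columns roi_id,y0,x0,height,width."""
    df = pd.read_csv(path)
    needed = {"roi_id", "y0", "x0", "height", "width"}
    if not needed.issubset(df.columns):
        raise ValueError(f"ROI file must have columns {sorted(needed)}; got {list(df.columns)}")
    return [
        RoiRect(str(r.roi_id), int(r.y0), int(r.x0), int(r.height), int(r.width))
        for r in df.itertuples()
    ]
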