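"""Per-cell morphometry: nucleus, cell and cytoplasm volumes plus summaries.

The whole-cell (Calcein-AM) channel is thresholded and hole-filled — vacuoles
inside a cell are part of its volume — and the nucleus (Hoechst) channel is
thresholded and intersected with the cell mask. Cytoplasm volume is cell
minus nucleus, so it can never go negative. Mitochondrial content is then
expressed per cytoplasm volume, the standard normalization when comparing
cells of very different size (e.g. progenitors vs multi-nucleated myotubes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import BinaryMask, MitoObjectRecord, segment_mito, threshold_constant
from .stack_io import AnalysisConfig, ChannelSet


@dataclass
class CellQuant:
    """Per-cell aggregate quantification.

    Fields that require absent channels (nucleus/cell) or are undefined
    (percentages of an empty object list, division by zero cytoplasm) are
    ``None``.
    """

    cell_id: str
    n_objects: int
    total_mt_volume_um3: float
    total_mt_intensity: float
    nucleus_volume_um3: Optional[float] = None
    cell_volume_um3: Optional[float] = None
    cytoplasm_volume_um3: Optional[float] = None
    pct_mt_per_cytoplasm: Optional[float] = None
    size_class_pct: Optional[tuple[float, float, float]] = None


def fill_holes_3d(mask: BinaryMask) -> BinaryMask:
    """Fill cavities: background not connected (6-conn) to the border.

    Foreground is never removed; filling twice equals filling once.
    """
    filled = ndimage.binary_fill_holes(mask.data)
    return BinaryMask(filled, mask.dz, mask.dy, mask.dx)


def channel_volume(mask: BinaryMask) -> float:
    """Volume in µm³: true-voxel count times the voxel volume."""
    return float(np.count_nonzero(mask.data)) * mask.voxel_volume_um3


def size_class_percentages(
    records: list[MitoObjectRecord],
) -> Optional[tuple[float, float, float]]:
    """Percentage of objects (by count) in the small/medium/network classes.

    Returns None for an empty object list (percentages undefined).
    """
    if not records:
        return None
    n = len(records)
    counts = {"small": 0, "medium": 0, "network": 0}
    for r in records:
        counts[r.size_class] += 1
    return tuple(100.0 * counts[c] / n for c in ("small", "medium", "network"))  # type: ignore[return-value]


def quantify_cell(
    channels: ChannelSet, config: AnalysisConfig, cell_id: str = "cell"
) -> CellQuant:
    """Segment the mito channel and assemble the per-cell summary.

    Nucleus/cell channels, when present, are thresholded with their own
    constants (``threshold_nucleus`` / ``threshold_cell``; the mito constant
    is the fallback), the cell mask is hole-filled by default, and the
    nucleus mask is intersected with the cell mask before subtraction.
    """
    _, records = segment_mito(channels.mito, config)
    voxvol = channels.mito.voxel_volume_um3
    total_vol = sum(r.voxel_count for r in records) * voxvol
    total_int = float(sum(r.total_intensity for r in records))

    quant = CellQuant(
        cell_id=cell_id,
        n_objects=len(records),
        total_mt_volume_um3=total_vol,
        total_mt_intensity=total_int,
        size_class_pct=size_class_percentages(records),
    )

    cell_mask = None
    if channels.cell is not None:
        thr = config.threshold_cell if config.threshold_cell is not None else config.threshold_value
        cell_mask = threshold_constant(channels.cell, thr)
        if config.fill_holes_cell:
            cell_mask = fill_holes_3d(cell_mask)
        quant.cell_volume_um3 = channel_volume(cell_mask)

    if channels.nucleus is not None:
        thr = (
            config.threshold_nucleus
            if config.threshold_nucleus is not None
            else config.threshold_value
        )
        nuc_mask = threshold_constant(channels.nucleus, thr)
        if config.fill_holes_nucleus:
            nuc_mask = fill_holes_3d(nuc_mask)
        if cell_mask is not None:
            # intersect so cytoplasm = cell - nucleus cannot go negative
            nuc_mask = BinaryMask(
                nuc_mask.data & cell_mask.data, nuc_mask.dz, nuc_mask.dy, nuc_mask.dx
            )
        quant.nucleus_volume_um3 = channel_volume(nuc_mask)

    if quant.cell_volume_um3 is not None and quant.nucleus_volume_um3 is not None:
        quant.cytoplasm_volume_um3 = quant.cell_volume_um3 - quant.nucleus_volume_um3
        if quant.cytoplasm_volume_um3 > 0:
            quant.pct_mt_per_cytoplasm = 100.0 * total_vol / quant.cytoplasm_volume_um3
        # zero cytoplasm (nucleus mask == cell mask): percentage undefined
    return quant


_SUMMARY_FIELDS = [
    "n_objects",
    "total_mt_volume_um3",
    "nucleus_volume_um3",
    "cell_volume_um3",
    "cytoplasm_volume_um3",
    "pct_mt_per_cytoplasm",
    "total_mt_intensity",
    "pct_small",
    "pct_medium",
    "pct_network",
]


def quants_to_frame(quants: list[CellQuant]) -> pd.DataFrame:
    rows = []
    for q in quants:
        pct = q.size_class_pct or (np.nan, np.nan, np.nan)
        rows.append(
            {
                "cell_id": q.cell_id,
                "n_objects": q.n_objects,
                "total_mt_volume_um3": q.total_mt_volume_um3,
                "nucleus_volume_um3": q.nucleus_volume_um3,
                "cell_volume_um3": q.cell_volume_um3,
                "cytoplasm_volume_um3": q.cytoplasm_volume_um3,
                "pct_mt_per_cytoplasm": q.pct_mt_per_cytoplasm,
                "total_mt_intensity": q.total_mt_intensity,
                "pct_small": pct[0],
                "pct_medium": pct[1],
                "pct_network": pct[2],
            }
        )
    return pd.DataFrame(rows)


def summarize_group(quants: list[CellQuant]) -> pd.DataFrame:
    """Mean ± sample SD (n−1 denominator) per numeric field.

    Returns a frame indexed by field with columns ``mean``, ``sd``, ``n`` and
    ``sd_defined``; with a single cell the SD is reported as 0 and flagged
    undefined.
    """
    if not quants:
        raise ValueError("need at least one cell")
    df = quants_to_frame(quants)
    rows = []
    for field in _SUMMARY_FIELDS:
        vals = df[field].dropna().astype(float)
        n = len(vals)
        mean = float(vals.mean()) if n else np.nan
        sd_defined = n > 1
        sd = float(vals.std(ddof=1)) if sd_defined else 0.0
        rows.append({"field": field, "mean": mean, "sd": sd, "n": n, "sd_defined": sd_defined})
    return pd.DataFrame(rows).set_index("field")
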