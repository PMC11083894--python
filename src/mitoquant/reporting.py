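"""Group reports, end-to-end pipeline driver and run provenance.

Summary tables follow the conventional per-group layout: one row per cell
population with mean ± SD of object count, total mitochondrial volume,
cytoplasm volume, % mitochondrial volume per cytoplasm and total
mitochondrial intensity, plus the three size-class percentages. Intensity
columns are flagged as comparable only within one staining/imaging session:
dye loading varies day to day, so cross-session intensity ratios are not
meaningful and the report says so.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .morphometry import CellQuant, quantify_cell, quants_to_frame, summarize_group
from .stack_io import AnalysisConfig, ChannelSet, read_stack

logger = logging.getLogger("mitoquant")

SESSION_BOUND_FIELDS = ("total_mt_intensity",)

TABLE_COLUMNS = [
    "n_objects",
    "total_mt_volume_um3",
    "cytoplasm_volume_um3",
    "pct_mt_per_cytoplasm",
    "total_mt_intensity",
]


def reference_group_summary() -> pd.DataFrame:
    """Published example quantification (mean ± SD, n = 10 cells per group).

    TMRM-stained mesoangioblasts and mesoangioblast-derived myotubes imaged
    in 3D with a spinning-disk confocal; volumes in 10² µm³ and intensities
    in 10⁸ camera units as printed. Used for worked-example consistency
    checks; the intensity column is session-bound (the two groups were
    stained on different days, so the 17-fold intensity difference is
    illustrative only).
    """
    return pd.DataFrame(
        {
            "group": ["mesoangioblast", "myotube"],
            "n_objects_mean": [30.0, 167.0],
            "n_objects_sd": [12.0, 71.0],
            "total_mt_volume_1e2um3_mean": [7.14, 85.84],
            "total_mt_volume_1e2um3_sd": [3.22, 41.51],
            "cytoplasm_volume_1e2um3_mean": [40.43, 294.02],
            "cytoplasm_volume_1e2um3_sd": [14.98, 154.53],
            "pct_mt_per_cytoplasm_mean": [17.0, 29.2],
            "pct_mt_per_cytoplasm_sd": [3.3, 14.1],
            "total_mt_intensity_1e8_mean": [1.4, 24.3],
            "total_mt_intensity_1e8_sd": [0.7, 1.3],
            "n": [10, 10],
        }
    ).set_index("group")


def pct_volume_from_means(total_mt_volume_mean: float, cytoplasm_volume_mean: float) -> float:
    """% mitochondrial volume per cytoplasm volume from the two group means."""
    if cytoplasm_volume_mean <= 0:
        raise ValueError("cytoplasm volume mean must be > 0")
    return 100.0 * total_mt_volume_mean / cytoplasm_volume_mean


def intensity_fold_change(numerator_mean: float, denominator_mean: float) -> float:
    """Fold change between two total-intensity group means."""
    if denominator_mean <= 0:
        raise ValueError("denominator mean must be > 0")
    return numerator_mean / denominator_mean


def report_group(
    quants: Sequence[CellQuant], label: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group summary row and size-class percentage row.

    Returns ``(summary, class_pct)``: the summary holds mean ± SD of the
    five standard columns with n; session-bound intensity columns carry a
    ``*_session_bound`` flag column set True.
    """
    if not quants:
        raise ValueError("need >= 1 cell")
    stats = summarize_group(list(quants))
    row: dict = {"group": label, "n": len(quants)}
    for col in TABLE_COLUMNS:
        row[f"{col}_mean"] = stats.loc[col, "mean"]
        row[f"{col}_sd"] = stats.loc[col, "sd"]
        row[f"{col}_sd_defined"] = bool(stats.loc[col, "sd_defined"])
        if col in SESSION_BOUND_FIELDS:
            row[f"{col}_session_bound"] = True
    summary = pd.DataFrame([row]).set_index("group")
    class_row = {
        "group": label,
        "pct_small_mean": stats.loc["pct_small", "mean"],
        "pct_small_sd": stats.loc["pct_small", "sd"],
        "pct_medium_mean": stats.loc["pct_medium", "mean"],
        "pct_medium_sd": stats.loc["pct_medium", "sd"],
        "pct_network_mean": stats.loc["pct_network", "mean"],
        "pct_network_sd": stats.loc["pct_network", "sd"],
        "n": len(quants),
    }
    return summary, pd.DataFrame([class_row]).set_index("group")


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    command: str
    config: dict
    input_hashes: dict = field(default_factory=dict)
    seed: int = 0
    version: str = __version__
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    session: Optional[str] = None

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    manifest: pd.DataFrame,
    config: AnalysisConfig,
    out_dir: str | Path,
    label: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Segment → quantify → report every cell listed in ``manifest``.

    ``manifest`` needs columns ``cell_id, mito`` and optionally
    ``nucleus, cell`` (TIFF paths) plus ``dz, dy, dx`` (µm). Writes
    ``cells.csv``, ``summary.csv``, ``size_classes.csv`` and
    ``manifest.json`` into ``out_dir``; numeric outputs are a deterministic
    function of inputs + config. Any failing stage aborts naming the cell.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    required = {"cell_id", "mito", "dz", "dy", "dx"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")

    quants = []
    hashes = {}
    for row in manifest.itertuples():
        cid = str(row.cell_id)
        try:
            geometry = (float(row.dz), float(row.dy), float(row.dx))
            mito = read_stack(row.mito, geometry, channel="mito")
            hashes[str(row.mito)] = _sha256(Path(row.mito))
            nucleus = cell = None
            if "nucleus" in manifest.columns and isinstance(row.nucleus, str) and row.nucleus:
                nucleus = read_stack(row.nucleus, geometry, channel="nucleus")
                hashes[str(row.nucleus)] = _sha256(Path(row.nucleus))
            if "cell" in manifest.columns and isinstance(row.cell, str) and row.cell:
                cell = read_stack(row.cell, geometry, channel="cell")
                hashes[str(row.cell)] = _sha256(Path(row.cell))
            channels = ChannelSet(mito=mito, nucleus=nucleus, cell=cell)
            logger.info("quantifying cell %s (threshold=%s)", cid, config.threshold_value)
            quants.append(quantify_cell(channels, config, cell_id=cid))
        except Exception as exc:
            raise RuntimeError(f"pipeline failed on cell {cid!r}: {exc}") from exc

    cells = quants_to_frame(quants)
    summary, class_pct = report_group(quants, label)
    cells.to_csv(out_dir / "cells.csv", index=False)
    summary.to_csv(out_dir / "summary.csv")
    class_pct.to_csv(out_dir / "size_classes.csv")
    RunManifest(
        command=f"run_pipeline(label={label!r})",
        config=config.as_dict(),
        input_hashes=hashes,
        seed=config.seed,
    ).write(out_dir / "manifest.json")
    return cells, summary, class_pct
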