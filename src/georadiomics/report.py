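"""Result tables and heatmap figures for a finished (or partial) grid."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model_grid import GridResult
from .roi import ROISpec, default_roi_set

__all__ = ["pivot_grid", "roi_volume_order", "write_report"]

logger = logging.getLogger(__name__)


def pivot_grid(
    grid: GridResult, value: str = "test_auc", rows: str = "fs", cols: str = "classifier",
    where: dict | None = None,
) -> pd.DataFrame:
    """Pivot grid cells to a rows x cols table; failed cells become NaN."""
    df = grid.to_dataframe()
    if where:
        for k, v in where.items():
            df = df[df[k] == v]
    df = df.copy()
    df.loc[df["failed"], value] = np.nan
    return df.pivot_table(index=rows, columns=cols, values=value, aggfunc="mean", dropna=False)


def roi_volume_order(specs: list[ROISpec] | None = None) -> list[str]:
    """ROI names sorted by analytic volume (the x-axis of volume plots)."""
    specs = default_roi_set() if specs is None else specs
    return [s.name for s in sorted(specs, key=lambda s: s.analytic_volume)]


def _heatmap(df: pd.DataFrame, title: str, path: Path) -> None:
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * df.shape[1], 1.0 + 0.45 * df.shape[0])
    )
    data = np.ma.masked_invalid(df.to_numpy(dtype=float))
    im = ax.imshow(data, cmap="viridis", aspect="auto", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(df.shape[1]), df.columns, rotation=45, ha="right")
    ax.set_yticks(range(df.shape[0]), df.index)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            if not data.mask[i, j]:
                ax.text(j, i, f"{data[i, j]:.2f}", ha="center", va="center", fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(grid: GridResult, out_dir: str | Path, roi_specs=None) -> None:
    """Write CSV/JSON tables and the standard heatmaps/plots to ``out_dir``.

    Outputs: cell table CSV + provenance JSON; per-ROI AUC heatmap
    (FS x classifier); per-FS AUC heatmap (ROI x classifier); F1 heatmap;
    best-cell AUC vs ROI volume plot.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = grid.to_dataframe()
    df.to_csv(out / "grid_cells.csv", index=False)
    with open(out / "grid_provenance.json", "w") as fh:
        json.dump(grid.provenance, fh, indent=2)

    rois = sorted(df["roi"].unique())
    for roi in rois:
        _heatmap(
            pivot_grid(grid, "test_auc", "fs", "classifier", where={"roi": roi}),
            f"AUC — {roi}",
            out / f"auc_fs_by_classifier_{roi}.png",
        )
    for fs in sorted(df["fs"].unique()):
        piv = pivot_grid(grid, "test_auc", "roi", "classifier", where={"fs": fs})
        _heatmap(piv, f"AUC — FS {fs}", out / f"auc_roi_by_classifier_{fs}.png")
        _heatmap(
            pivot_grid(grid, "f1", "roi", "classifier", where={"fs": fs}),
            f"F1 — FS {fs}",
            out / f"f1_roi_by_classifier_{fs}.png",
        )

    # best AUC per ROI vs analytic ROI volume (single ROIs only)
    order = roi_volume_order(roi_specs)
    present = [r for r in order if r in rois]
    if present:
        ok = df[~df["failed"]]
        best = ok.groupby("roi")["test_auc"].max()
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(range(len(present)), [best.get(r, np.nan) for r in present], "o-")
        ax.set_xticks(range(len(present)), present, rotation=45, ha="right")
        ax.set_ylabel("best test AUC")
        ax.set_xlabel("ROI (sorted by analytic volume)")
        fig.tight_layout()
        fig.savefig(out / "auc_vs_roi_volume.png", dpi=120)
        plt.close(fig)
    logger.info("report written to %s", out)
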