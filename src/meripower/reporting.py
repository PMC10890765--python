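"""Export and visualisation of power-grid results.

A grid is persisted as a TSV plus a JSON metadata sidecar; reports add an
xlsx workbook (one sheet per metric) and optional line plots: metric versus
sample size (one line per nominal FDR), targeted power and FDC along input
strata, and metric versus depth factor.
"""

from __future__ import annotations

import json
import os

import pandas as pd

from meripower.containers import METRIC_NAMES, PowerGridResult


def write_grid(result: PowerGridResult, path: str | os.PathLike) -> None:
    """Write the long-format grid TSV; metadata goes to <path>.meta.json."""
    result.table.to_csv(path, sep="\t", index=False)
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(result.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_grid(path: str | os.PathLike) -> PowerGridResult:
    table = pd.read_csv(path, sep="\t")
    meta_path = f"{path}.meta.json"
    metadata = {}
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            metadata = json.load(fh)
    return PowerGridResult(table=table, metadata=metadata)


def write_excel(result: PowerGridResult, path: str | os.PathLike) -> None:
    """One sheet per metric, rows = design cells, columns = mean/sd summaries."""
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for metric in METRIC_NAMES:
            sub = result.table[result.table["metric"] == metric].drop(columns="metric")
            sub.to_excel(writer, sheet_name=metric, index=False)


def _lineplot(ax, sub: pd.DataFrame, x: str, group: str, metric: str) -> None:
    for gval, block in sub.groupby(group):
        block = block.sort_values(x)
        ax.plot(block[x], block["mean"], marker="o", label=f"{group}={gval}")
    ax.set_xlabel(x)
    ax.set_ylabel(metric)
    ax.legend(fontsize=7)


def render_plots(result: PowerGridResult, out_dir: str | os.PathLike,
                 delta: float | None = None) -> list[str]:
    """Line plots of the overall ('all' stratum) summaries; returns file paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    tab = result.table
    if delta is None:
        delta = sorted(tab["delta"].unique())[0]
    overall = tab[(tab["stratum"] == "all") & (tab["delta"] == delta)]
    depth0 = sorted(overall["depth_factor"].unique())[0]
    paths = []

    fig, axes = plt.subplots(1, 4, figsize=(16, 3.5))
    for ax, metric in zip(axes, ("power", "targeted_power", "fdc", "fdr")):
        sub = overall[(overall["metric"] == metric) & (overall["depth_factor"] == depth0)]
        _lineplot(ax, sub, "sample_size", "nominal_fdr", metric)
    fig.tight_layout()
    p = os.path.join(out_dir, "metrics_vs_sample_size.png")
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    strata = tab[(tab["stratum"] != "all") & (tab["delta"] == delta)
                 & (tab["depth_factor"] == depth0)]
    if len(strata):
        fdr0 = sorted(strata["nominal_fdr"].unique())[0]
        strata = strata[strata["nominal_fdr"] == fdr0].copy()
        strata["stratum_k"] = strata["stratum"].str.replace("stratum", "").astype(int)
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for ax, metric in zip(axes, ("targeted_power", "fdc")):
            _lineplot(ax, strata[strata["metric"] == metric], "stratum_k",
                      "sample_size", metric)
        fig.tight_layout()
        p = os.path.join(out_dir, "metrics_vs_stratum.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

    if overall["depth_factor"].nunique() > 1:
        fdr0 = sorted(overall["nominal_fdr"].unique())[0]
        sub = overall[overall["nominal_fdr"] == fdr0]
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for ax, metric in zip(axes, ("targeted_power", "fdc")):
            _lineplot(ax, sub[sub["metric"] == metric], "depth_factor",
                      "sample_size", metric)
        fig.tight_layout()
        p = os.path.join(out_dir, "metrics_vs_depth.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


def render_reports(
    result: PowerGridResult,
    out_dir: str | os.PathLike,
    plots: bool = False,
) -> dict[str, object]:
    """Write TSV + xlsx (+ optional plots) with deterministic names."""
    os.makedirs(out_dir, exist_ok=True)
    tsv = os.path.join(out_dir, "power_grid.tsv")
    xlsx = os.path.join(out_dir, "power_grid.xlsx")
    write_grid(result, tsv)
    write_excel(result, xlsx)
    out = {"tsv": tsv, "xlsx": xlsx, "plots": []}
    if plots:
        out["plots"] = render_plots(result, os.path.join(out_dir, "plots"))
    return out


def write_manifest(out_dir: str | os.PathLike, config: dict) -> str:
    """Machine-readable run manifest (config, seeds, versions)."""
    import numpy
    import scipy

    import meripower

    manifest = {
        "config": config,
        "versions": {
            "meripower": meripower.__version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    path = os.path.join(out_dir, "run_manifest.json")
    os.makedirs(out_dir, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
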