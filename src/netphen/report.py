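"""Figure and table bundle for a phenotyping study: per-metric bar
summaries with per-well points, and optional raster / Sholl panels.
Deterministic given identical inputs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "netphen"  # deterministic element ids
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["build_report", "plot_metric_bars", "plot_raster", "plot_sholl"]


def plot_metric_bars(metrics: pd.DataFrame, metric: str, ax=None,
                     group_col: str = "group"):
    """Bar of group means ± SEM with individual experimental units
    overlaid, the study's standard summary panel."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    groups = list(pd.unique(metrics[group_col]))
    for i, g in enumerate(groups):
        vals = metrics.loc[metrics[group_col] == g, metric].dropna().to_numpy(float)
        if vals.size == 0:
            continue
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
        ax.bar(i, vals.mean(), yerr=sem, width=0.6, alpha=0.6, capsize=4)
        jitter = (np.arange(vals.size) - vals.size / 2) * (0.3 / max(vals.size, 1))
        ax.plot(i + jitter, vals, "o", ms=3, color="k", alpha=0.6)
    ax.set_xticks(range(len(groups)), groups, rotation=20)
    ax.set_ylabel(metric)
    return ax


def plot_raster(trains, network_bursts=None, ax=None, t_max: float | None = None):
    """Spike raster for one well with network-burst epochs shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for i, (ch, times) in enumerate(sorted(trains.trains.items())):
        t = times if t_max is None else times[times <= t_max]
        ax.vlines(t, i + 0.6, i + 1.4, lw=0.5, color="k")
    if network_bursts:
        for nb in network_bursts:
            if t_max is not None and nb.start > t_max:
                continue
            ax.axvspan(nb.start, nb.end, color="tab:pink", alpha=0.3, lw=0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("channel")
    return ax


def plot_sholl(profiles: dict, value: str = "length", ax=None):
    """Sholl curves (mean per group) from {label: [ShollProfile]}."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    for label, profs in profiles.items():
        n = max(p.radii.size for p in profs)
        mat = np.zeros((len(profs), n))
        radii = None
        for i, p in enumerate(profs):
            vals = getattr(p, value)
            mat[i, :vals.size] = vals
            if p.radii.size == n:
                radii = p.radii
        ax.plot(radii, mat.mean(axis=0), label=label)
    ax.set_xlabel("distance from soma (µm)")
    ax.set_ylabel(f"dendritic {value} per shell")
    ax.legend()
    return ax


def build_report(metrics: pd.DataFrame, tests: pd.DataFrame, out_dir,
                 metric_cols: list | None = None) -> dict:
    """Write the report bundle (CSV tables + per-metric SVG figures);
    returns the artifact paths. Empty input yields an empty but valid
    bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    metrics.to_csv(out / "metrics_table.csv", index=False)
    tests.to_csv(out / "tests_table.csv", index=False)
    paths["metrics"] = str(out / "metrics_table.csv")
    paths["tests"] = str(out / "tests_table.csv")
    if len(metrics):
        if metric_cols is None:
            metric_cols = [c for c in metrics.columns
                           if metrics[c].dtype.kind in "fi"
                           and c not in ("seed",)]
        for m in metric_cols:
            fig, ax = plt.subplots(figsize=(3, 3))
            plot_metric_bars(metrics, m, ax=ax)
            fig.tight_layout()
            p = out / f"metric_{m}.svg"
            fig.savefig(p, metadata={"Date": None})
            plt.close(fig)
            paths[m] = str(p)
    return paths
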