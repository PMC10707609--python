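"""Standard agreement figures: box plot, scatter + fit, Bland-Altman."""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import AgreementReport
from .synthetic import METHOD_COLUMNS


def plot_boxes(table: pd.DataFrame, methods, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    data = [table[METHOD_COLUMNS[m]].dropna() for m in methods]
    ax.boxplot(data, tick_labels=[m.upper() for m in methods])
    ax.set_ylabel("MRD1 (mm)")
    ax.set_title("MRD1 by measurement method")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_regressions(table: pd.DataFrame, report: AgreementReport, path) -> None:
    pairs = list(combinations(report.methods, 2))
    fig, axes = plt.subplots(2, (len(pairs) + 1) // 2, figsize=(4 * ((len(pairs) + 1) // 2), 7))
    for ax, (a, b) in zip(np.ravel(axes), pairs):
        x = table[METHOD_COLUMNS[a]]
        y = table[METHOD_COLUMNS[b]]
        fit = report.regressions[(a, b)]
        ax.scatter(x, y, s=8, alpha=0.6)
        xs = np.linspace(float(x.min()), float(x.max()), 10)
        ax.plot(xs, fit.slope * xs + fit.intercept, "r-", lw=1)
        ax.set_xlabel(f"{a.upper()} (mm)")
        ax.set_ylabel(f"{b.upper()} (mm)")
        ax.set_title(f"slope {fit.slope:.2f}, R$^2$ {fit.r_squared:.3f}", fontsize=9)
    for ax in np.ravel(axes)[len(pairs):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bland_altman(table: pd.DataFrame, report: AgreementReport, path) -> None:
    pairs = list(report.bland_altman)
    fig, axes = plt.subplots(2, (len(pairs) + 1) // 2, figsize=(4 * ((len(pairs) + 1) // 2), 7))
    for ax, (a, b) in zip(np.ravel(axes), pairs):
        ba = report.bland_altman[(a, b)]
        x = table[METHOD_COLUMNS[a]].to_numpy()
        y = table[METHOD_COLUMNS[b]].to_numpy()
        ax.scatter((x + y) / 2.0, x - y, s=8, alpha=0.6)
        for val, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
            ax.axhline(val, color="r", ls=style, lw=1)
        ax.set_xlabel("mean of pair (mm)")
        ax.set_ylabel(f"{a.upper()} - {b.upper()} (mm)")
        ax.set_title(f"mean diff {ba.mean_diff:.3f}, dLOA {ba.delta_loa:.3f}", fontsize=9)
    for ax in np.ravel(axes)[len(pairs):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_all(table: pd.DataFrame, report: AgreementReport, out_dir) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [out / "boxplot.png", out / "regressions.png", out / "bland_altman.png"]
    plot_boxes(table, report.methods, paths[0])
    plot_regressions(table, report, paths[1])
    plot_bland_altman(table, report, paths[2])
    return paths
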