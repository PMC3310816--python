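"""Plotting helpers for evaluation reports (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluation import ComparisonReport, WindowScan

__all__ = ["plot_rmse_vs_window", "plot_percent_decrease"]


def plot_rmse_vs_window(
    scans: list[WindowScan], path, title: str | None = None
) -> None:
    """Normalized RMSE vs window size, one curve per scan (MS circles, SS
    triangles), best S filled."""
    fig, ax = plt.subplots(figsize=(5, 4))
    markers = {"MS": "o", "SS": "^"}
    for scan in scans:
        S_vals = [rep.S for rep in scan.reports]
        means = [rep.mean_rmse for rep in scan.reports]
        sds = [rep.sd_rmse for rep in scan.reports]
        ax.errorbar(
            S_vals, means, yerr=sds, marker=markers.get(scan.kind, "s"),
            mfc="none", capsize=3, label=scan.kind,
        )
        best = scan.best
        ax.plot([best.S], [best.mean_rmse], markers.get(scan.kind, "s"),
                color="black", zorder=5)
    ax.axhline(1.0, ls=":", color="grey", lw=1)
    ax.set_xlabel("window size S")
    ax.set_ylabel("normalized RMSE")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_percent_decrease(
    reports: dict[str, ComparisonReport], path
) -> None:
    """Mean ± sd per-fold percent decrease of MS vs SS, one bar per label."""
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = list(reports)
    means = [reports[lab].mean_percent_decrease for lab in labels]
    sds = [reports[lab].sd_percent_decrease for lab in labels]
    ax.bar(labels, means, yerr=sds, capsize=4, color="steelblue")
    ax.axhline(0.0, color="black", lw=1)
    ax.set_ylabel("percent decrease of RMSE (MS vs SS)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
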