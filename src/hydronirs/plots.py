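"""Summary figures for a cohort analysis (PNG, matplotlib).

Four panels mirror the analysis outputs: time-normalized group traces
(mean +/- standard error), per-subject delta boxplots by group, the ROC
curve of the best classifier, and AUC versus percent dialysis completion.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .pipeline import CohortAnalysisResult

__all__ = ["plot_cohort_report"]

_TRACE_METRICS = ("hbo2", "hb", "sto2", "water_ratio")
_DELTA_METRICS = ("delta_hbo2", "delta_hb", "delta_hbt", "delta_sto2",
                  "delta_water_ratio")


def plot_cohort_report(result: CohortAnalysisResult, directory) -> list[Path]:
    """Write the report figures; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    # group traces over % completion
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    for ax, metric in zip(axes.ravel(), _TRACE_METRICS):
        ts = result.trace_stats[metric]
        for grp, color in (("adverse", "tab:red"), ("nonadverse", "tab:blue")):
            if f"mean_{grp}" not in ts:
                continue
            mean = ts[f"mean_{grp}"]
            se = ts[f"se_{grp}"]
            ax.plot(ts["percent"], mean, color=color, label=grp)
            ax.fill_between(ts["percent"], mean - se, mean + se,
                            color=color, alpha=0.25, linewidth=0)
        ax.set_title(metric)
        ax.set_xlabel("% dialysis completion")
    axes[0, 0].legend(frameon=False)
    fig.tight_layout()
    path = directory / "group_traces.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    # delta boxplots by group
    fig, axes = plt.subplots(1, len(_DELTA_METRICS), figsize=(14, 4))
    for ax, metric in zip(axes, _DELTA_METRICS):
        groups = [
            result.deltas.loc[result.deltas["adverse_event"], metric].dropna(),
            result.deltas.loc[~result.deltas["adverse_event"], metric].dropna(),
        ]
        ax.boxplot(groups, tick_labels=["adverse", "nonadv."])
        ax.axhline(0.0, color="grey", linewidth=0.5)
        ax.set_title(metric, fontsize=9)
    fig.tight_layout()
    path = directory / "delta_boxplots.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    # ROC of the best classifier + AUC over completion
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    if result.best_classification is not None:
        bc = result.best_classification
        ax1.plot(bc.roc_points[:, 0], bc.roc_points[:, 1],
                 label=f"{'+'.join(bc.features)} (AUC {bc.auc:.2f})")
    ax1.plot([0, 1], [0, 1], "--", color="grey", linewidth=0.8)
    ax1.set_xlabel("false positive rate")
    ax1.set_ylabel("true positive rate")
    ax1.legend(frameon=False, fontsize=8)
    ax1.set_title("best feature subset ROC")
    ax2.plot(result.auc_vs_completion["percent"],
             result.auc_vs_completion["auc"])
    ax2.axhline(0.5, color="grey", linewidth=0.5)
    ax2.set_ylim(0.0, 1.0)
    ax2.set_xlabel("% dialysis completion")
    ax2.set_ylabel("AUC")
    ax2.set_title("classification AUC over completion")
    fig.tight_layout()
    path = directory / "classification.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
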