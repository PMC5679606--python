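"""Optional matplotlib renderings of evaluation output (ROC, PR, top-k% bars)."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from diffslc.evaluation import EvalCurve

__all__ = ["plot_roc", "plot_pr", "plot_top_percent"]


def plot_roc(curves: Mapping[str, EvalCurve], path: str) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for method, curve in sorted(curves.items()):
        frame = curve.to_frame()
        ax.plot(frame["fpr"], frame["tpr"], label=f"{method} (AUC={curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pr(curves: Mapping[str, EvalCurve], path: str) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for method, curve in sorted(curves.items()):
        frame = curve.to_frame()
        ax.plot(frame["recall"], frame["precision"], label=method)
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_top_percent(table: pd.DataFrame, path: str, column: str = "hits") -> None:
    pivot = table.pivot(index="percent", columns="method", values=column)
    ax = pivot.plot.bar(figsize=(6, 4))
    ax.set_ylabel(f"essential genes ({column}) in top slice")
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    plt.close(ax.figure)
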