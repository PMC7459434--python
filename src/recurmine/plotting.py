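"""Figure helpers: month-level ROC and observed-vs-predicted KM curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluate import KmPair, MonthRoc


def plot_roc(roc: MonthRoc, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(roc.fpr, roc.tpr, lw=1.5)
    ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"Month-level ROC (AUC = {roc.auc:.3f})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_km_pair(km: KmPair, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4.5))
    km.observed.plot_survival_function(ax=ax, color="firebrick", ci_show=False)
    km.predicted.plot_survival_function(ax=ax, color="steelblue", ci_show=False)
    ax.set_xlabel("months since diagnosis")
    ax.set_ylabel("event-free probability")
    ax.set_title(f"Observed vs predicted event timing (PT = {km.threshold})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
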