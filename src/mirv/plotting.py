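"""Optional ROC and Kaplan-Meier plots from pipeline result tables.

Matplotlib is imported lazily; the analysis pipeline never calls these.
"""

from __future__ import annotations

import pandas as pd


def plot_roc(roc_table: pd.DataFrame, out_path: str) -> None:
    """Mean ROC curves (one line per model) from a ``roc_*`` result table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, sub in roc_table.groupby("model"):
        ax.plot(sub["fpr"], sub["tpr"], label=str(label))
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(fontsize=8)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_km(km_table: pd.DataFrame, out_path: str) -> None:
    """Stepwise survival curves with confidence bands from a ``km_curves_*`` table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for (subgroup, stratum), sub in km_table.groupby(["subgroup", "stratum"]):
        ax.step(sub["time"], sub["survival"], where="post",
                label=f"{subgroup}:{stratum}")
        ax.fill_between(sub["time"], sub["ci_low"], sub["ci_high"],
                        step="post", alpha=0.15)
    ax.set_xlabel("Years")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
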