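"""Minimal figure helpers (fate-averaged traces, flag summaries)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

FATE_COLORS = {"MFP": "#7b3294", "LFP": "#a6611a", "pMN": "#018571", "dorsal": "#2c7bb6"}


def save_average_traces(averages: dict, path) -> None:
    """Mean +/- SD intensity per fate over time."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for fate, df in averages.items():
        c = FATE_COLORS.get(fate, "gray")
        ax.plot(df["t"], df["mean"], color=c, label=f"{fate}")
        ax.fill_between(
            df["t"], df["mean"] - df["sd"], df["mean"] + df["sd"], color=c, alpha=0.2
        )
    ax.set_xlabel("time (hpf)")
    ax.set_ylabel("intensity (AU)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_flag(result, path) -> None:
    """Ranked color-band ('French flag') plot for one metric."""
    fig, ax = plt.subplots(figsize=(2.2, 5))
    n = len(result.ranked_cells)
    for i, cell in enumerate(result.ranked_cells):
        fate = result.predicted[cell]
        ax.barh(n - i, 1, height=1, color=FATE_COLORS.get(fate, "gray"), edgecolor="none")
    for b in result.band_boundaries:
        ax.axhline(n - b + 0.5, color="black", lw=1.5)
    ax.set_xlim(0, 1)
    ax.set_xticks([])
    ax.set_ylabel("cells ranked by metric (high to low)")
    ax.set_title(f"{result.metric}\n{result.accuracy:.1f}% correct", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_flag_summary(table, path) -> None:
    """Bar chart of accuracy per metric per group with chance level."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    groups = list(table.iloc[:, 0].unique())
    metrics = list(table["metric"].unique())
    width = 0.8 / len(groups)
    for gi, g in enumerate(groups):
        sub = table[table.iloc[:, 0] == g].set_index("metric")
        xs = [i + gi * width for i in range(len(metrics))]
        ax.bar(xs, [sub.loc[m, "accuracy_pct"] for m in metrics], width, label=str(g))
        ax.errorbar(
            xs,
            [sub.loc[m, "chance_mean_pct"] for m in metrics],
            yerr=[sub.loc[m, "chance_sd_pct"] for m in metrics],
            fmt="_",
            color="black",
            capsize=3,
        )
    ax.set_xticks([i + width / 2 for i in range(len(metrics))])
    ax.set_xticklabels(metrics, rotation=20, fontsize=8)
    ax.set_ylabel("fate-prediction accuracy (%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
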