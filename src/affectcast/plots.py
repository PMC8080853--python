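"""Report figures: order sweeps, seasonal error bars, per-user trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_order_sweep", "plot_seasonal_error", "plot_user_trajectory"]


def plot_order_sweep(sweep: pd.DataFrame, path) -> None:
    """r vs order p, one line per order mode."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for mode, grp in sweep.groupby("mode"):
        grp = grp.sort_values("p")
        ax.plot(grp["p"], grp["r"], marker="o", label=mode)
    ax.set_xlabel("order p")
    ax.set_ylabel("Pearson r (OOS-Time)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_seasonal_error(monthly: pd.DataFrame, path) -> None:
    """Mean squared error per calendar month with standard-error bars."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(monthly["month"], monthly["mse"], yerr=monthly["se"], capsize=3)
    for _, row in monthly.iterrows():
        ax.annotate(
            str(int(row["n_users"])),
            (row["month"], row["mse"]),
            ha="center",
            va="bottom",
            fontsize=8,
        )
    ax.set_xlabel("month")
    ax.set_ylabel("mean squared error")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_user_trajectory(
    frame: pd.DataFrame, baseline_frame: pd.DataFrame, user_id: str, path
) -> None:
    """One user's forecasted changes vs truth, with a baseline overlay."""
    mine = frame[frame["user_id"] == user_id].sort_values("target_index")
    base = baseline_frame[baseline_frame["user_id"] == user_id].sort_values(
        "target_index"
    )
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(mine["target_index"], mine["y_true"], "k-o", label="observed change")
    ax.plot(mine["target_index"], mine["y_hat"], "-s", label=str(mine["model_id"].iloc[0]))
    if len(base):
        ax.plot(base["target_index"], base["y_hat"], "--^", label=str(base["model_id"].iloc[0]))
    ax.set_xlabel("change index (week)")
    ax.set_ylabel("affect change")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
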