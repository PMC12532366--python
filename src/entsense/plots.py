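"""Diagnostic plots: the Werner tangle-entropy plane and SVM boundaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import werner_curve

__all__ = ["plot_werner_ts", "plot_decision_boundary"]

_COLORS = {"transgenic": "tab:red", "control": "tab:green"}


def plot_werner_ts(measurements, path, title: str = "Tangle vs linear entropy"):
    """Scatter measured (T, S) points over the theoretical Werner path."""
    fig, ax = plt.subplots(figsize=(5, 4))
    curve = werner_curve(np.linspace(0, 1, 300))
    ax.plot(curve[:, 0], curve[:, 1], "k-", lw=1.2, label="Werner path")
    for label, grp in measurements.groupby("label"):
        ax.scatter(
            grp["tangle"], grp["linear_entropy"], s=12, alpha=0.7,
            color=_COLORS.get(label, "tab:blue"), label=label,
        )
    ax.set_xlabel("tangle")
    ax.set_ylabel("linear entropy")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_decision_boundary(records, split_result, path, features=("tangle", "linear_entropy")):
    """Training/test points of one leave-one-replicate-out split with the
    fitted linear decision boundary (2D feature sets only)."""
    if len(features) != 2 or split_result.weights is None:
        raise ValueError("decision-boundary plot requires a fitted 2D rule")
    held = split_result.held_out_replicate
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, grp in records.groupby("label"):
        train = grp[grp["replicate_id"] != held]
        test = grp[grp["replicate_id"] == held]
        color = _COLORS.get(label, "tab:blue")
        ax.scatter(train[features[0]], train[features[1]], s=12, alpha=0.4,
                   color=color, label=f"{label} (train)")
        ax.scatter(test[features[0]], test[features[1]], s=24, marker="x",
                   color=color, label=f"{label} (test)")
    (w1, w2), b = split_result.weights, split_result.bias
    xs = np.linspace(records[features[0]].min(), records[features[0]].max(), 50)
    if abs(w2) > 1e-12:
        ax.plot(xs, -(w1 * xs + b) / w2, "k--", lw=1, label="boundary")
    ax.set_xlabel(features[0])
    ax.set_ylabel(features[1])
    ax.set_title(f"held-out replicate {held}")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
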