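"""Minimal PNG plot helpers: scatter, ROC, Bland–Altman."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluate import _placements, bland_altman

__all__ = ["plot_scatter", "plot_roc", "plot_bland_altman"]


def plot_scatter(x, y, path, xlabel="reference sqrt PD", ylabel="mimic sqrt PD"):
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=6, alpha=0.5)
    lim = [min(np.min(x), np.min(y)), max(np.max(x), np.max(y))]
    ax.plot(lim, lim, "k--", lw=0.8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_roc(scores, labels, path):
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    order = np.argsort(-s, kind="mergesort")
    tp = np.cumsum(y[order] == 1) / max((y == 1).sum(), 1)
    fp = np.cumsum(y[order] == 0) / max((y == 0).sum(), 1)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(np.r_[0, fp], np.r_[0, tp])
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_bland_altman(x, y, path):
    stats = bland_altman(x, y)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter((x + y) / 2, x - y, s=6, alpha=0.5)
    for key, style in [("mean_diff", "b-"), ("lower_limit", "r--"),
                       ("upper_limit", "r--")]:
        ax.axhline(stats[key], ls=style[1:], color=style[0], lw=0.9)
    ax.set_xlabel("mean of measurements")
    ax.set_ylabel("difference")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
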