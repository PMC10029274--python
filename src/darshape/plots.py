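"""Small plotting helpers (wss/f(k) curves, PC1-PC2 scatter, temporal
sequences). All return the matplotlib Axes so callers can style further."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .clustering_pca import ClusterCurves


def plot_wss_curves(curves: ClusterCurves, chosen_k: int | None = None, ax=None):
    if ax is None:
        _, ax = plt.subplots(1, 3, figsize=(12, 3.2))
    ks = sorted(curves.wss)
    ax[0].plot(ks, [curves.wss[k] for k in ks], "o-")
    ax[0].set(xlabel="k", ylabel="wss(k)")
    sk = sorted(curves.s)
    ax[1].plot(sk, [curves.s[k] for k in sk], "o-")
    ax[1].set(xlabel="k", ylabel="s(k)")
    fk = sorted(curves.f)
    ax[2].plot(fk, [curves.f[k] for k in fk], "o-")
    ax[2].set(xlabel="k", ylabel="f(k)")
    if chosen_k is not None and chosen_k in curves.f:
        ax[2].plot([chosen_k], [curves.f[chosen_k]], "ro")
    return ax


def plot_pc_scatter(scores: np.ndarray, labels: np.ndarray, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for lab in np.unique(labels):
        sel = labels == lab
        ax.scatter(scores[sel, 0], scores[sel, 1], s=6, label=str(lab))
    ax.set(xlabel="PC1 (extent)", ylabel="PC2 (openness)")
    ax.legend(title="cluster", fontsize="small")
    return ax


def plot_temporal_sequence(seq: pd.DataFrame, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 1.6))
    dates = pd.to_datetime(seq["night_date"])
    gaps = seq["is_gap"].to_numpy(dtype=bool)
    ax.scatter(dates[gaps], np.zeros(gaps.sum()), c="lightgray", s=6)
    have = ~gaps
    ax.scatter(dates[have], np.zeros(have.sum()),
               c=seq.loc[have, "cluster"].astype(int), cmap="tab10", s=18)
    bounds = seq.loc[seq["quadrimester"].diff().fillna(0) != 0, "night_date"]
    for b in pd.to_datetime(bounds):
        ax.axvline(b, ls="--", c="k", lw=0.5)
    ax.set_yticks([])
    return ax
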