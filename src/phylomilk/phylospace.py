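"""Ancestral-state reconstruction and phylomorphospace / mixture-triangle plots.

Ancestral states are generalized-least-squares (maximum-likelihood) estimates
under Brownian motion: with tip covariance A and node-tip shared-path matrix
P, the reconstruction at internal nodes is mu + P A^{-1} (y - mu), where mu
is the GLS root estimate.  Reconstruction is done per trait (traits are
handled independently, as BM GLS factorizes).
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.collections import LineCollection  # noqa: E402

from phylomilk.core import Phylogeny

plt.rcParams["svg.hashsalt"] = "phylomilk"


@dataclass
class AncestralStates:
    """Per-node reconstructed trait values; tip rows equal the observations."""

    states: pd.DataFrame  # index = node id (0..n_nodes-1), columns = traits
    method: str = "BM-GLS"

    def at_tips(self, tree: Phylogeny) -> pd.DataFrame:
        out = self.states.loc[list(tree.tip_indices)]
        out.index = tree.tip_labels
        return out


def _node_tip_shared_depth(tree: Phylogeny) -> np.ndarray:
    """(n_nodes, n_tips) matrix of root-to-MRCA(node, tip) path lengths."""
    below = tree.tips_below()
    P = np.zeros((tree.n_nodes, tree.n_tips))
    for i in range(1, tree.n_nodes):
        P[i] = P[tree.parent[i]] + tree.blen[i] * below[i]
    return P


def ancestral_bm(tree: Phylogeny, traits) -> AncestralStates:
    """GLS ancestral reconstruction under Brownian motion (no missing values)."""
    df = traits.data if hasattr(traits, "data") else pd.DataFrame(traits)
    df = df.reindex(tree.tip_labels)
    if df.isna().any().any():
        raise ValueError("missing trait values: impute (shift model) or drop first")
    A = tree.mrca_depths()
    A = A + 1e-12 * np.mean(np.diag(A)) * np.eye(len(A))
    Ainv_y = np.linalg.solve(A, df.to_numpy(dtype=float))
    ones = np.ones(len(A))
    Ainv_1 = np.linalg.solve(A, ones)
    mu = (ones @ Ainv_y) / (ones @ Ainv_1)  # GLS root per trait
    P = _node_tip_shared_depth(tree)
    resid = df.to_numpy(dtype=float) - mu
    states = mu + P @ np.linalg.solve(A, resid)
    out = pd.DataFrame(states, index=range(tree.n_nodes), columns=df.columns)
    tips = tree.tip_indices
    out.iloc[tips] = df.to_numpy(dtype=float)  # exact at the tips
    return AncestralStates(states=out)


def plot_phylomorphospace(
    tree: Phylogeny,
    traits,
    states: AncestralStates | None = None,
    pair=("protein", "fat"),
    aquatic: pd.Series | None = None,
    path=None,
    ax=None,
):
    """Tip scatter in trait-trait space with tree edges through ancestors.

    ``aquatic`` (a 0/1-or-ordinal species series) switches those species to
    triangle markers.  Returns ``(fig, ax)``; the drawn edge collection has
    one segment per non-root node.
    """
    df = traits.data if hasattr(traits, "data") else pd.DataFrame(traits)
    df = df.reindex(tree.tip_labels)
    if states is None:
        states = ancestral_bm(tree, df[list(pair)])
    xs = states.states[pair[0]].to_numpy()
    ys = states.states[pair[1]].to_numpy()
    segments = [
        [(xs[tree.parent[i]], ys[tree.parent[i]]), (xs[i], ys[i])]
        for i in range(1, tree.n_nodes)
    ]
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    ax.add_collection(LineCollection(segments, colors="0.6", linewidths=0.7,
                                     zorder=1, label="edges"))
    tip_x = df[pair[0]].to_numpy(dtype=float)
    tip_y = df[pair[1]].to_numpy(dtype=float)
    if aquatic is not None:
        aq = aquatic.reindex(tree.tip_labels).fillna(0).to_numpy() > 0
    else:
        aq = np.zeros(len(tip_x), dtype=bool)
    ax.scatter(tip_x[~aq], tip_y[~aq], s=18, c="tab:blue", marker="o",
               zorder=2, label="terrestrial")
    if aq.any():
        ax.scatter(tip_x[aq], tip_y[aq], s=26, c="tab:red", marker="^",
                   zorder=3, label="aquatic")
    ax.set_xlabel(pair[0])
    ax.set_ylabel(pair[1])
    if path is not None:
        fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
        plt.close(fig)
    return fig, ax


def plot_mixture_triangle(traits_renormalized, path=None, ax=None, isocline_step=25):
    """Right-angle mixture plot: fat vs protein with sugar isoclines.

    Expects composition renormalized so fat + protein + sugar = 100; sugar
    appears as diagonal lines fat + protein = 100 - s.
    """
    g = traits_renormalized.g100g if hasattr(traits_renormalized, "g100g") \
        else pd.DataFrame(traits_renormalized)
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    for s in range(0, 100, isocline_step):
        ax.plot([0, 100 - s], [100 - s, 0], linestyle=":", color="0.6",
                linewidth=0.8, zorder=1)
        ax.annotate(f"sugar {s}", xy=(100 - s, 0), fontsize=7,
                    xytext=(2, 2), textcoords="offset points")
    ax.plot([0, 100, 0, 0], [0, 0, 100, 0], color="0.3", linewidth=0.8)
    ok = g[["fat", "protein"]].notna().all(axis=1)
    ax.scatter(g.loc[ok, "fat"], g.loc[ok, "protein"], s=18, c="tab:blue", zorder=2)
    ax.set_xlabel("fat (% of macronutrients)")
    ax.set_ylabel("protein (% of macronutrients)")
    ax.set_xlim(-2, 102)
    ax.set_ylim(-2, 102)
    if path is not None:
        fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
        plt.close(fig)
    return fig, ax
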