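"""Kolmogorov-Smirnov Importance (KSI) tests for clade distinctiveness.

The KSI statistic for a clade is the sample-size-scaled two-sample KS
distance sqrt(n1 n2 / (n1 + n2)) * sup |F1 - F2| between the trait
distribution inside the clade and outside it.  For pairs and triples of
traits the supremum is the exact Peacock multidimensional statistic: the
maximum empirical-CDF discrepancy over every axis-orientation quadrant
(2^d of them) and every grid point defined by the pooled sample coordinates.

The iterative search scores every internal node, reports the best clade,
removes its tips, and repeats, producing a series of clades of declining
distinctiveness; near-equivalent neighboring nodes along the winner's
ancestor/descendant chain are reported as a nodeset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from phylomilk.core import Phylogeny, TraitMatrix


def _scale(n1: int, n2: int) -> float:
    return float(np.sqrt(n1 * n2 / (n1 + n2)))


def ks_scaled(x, y) -> float:
    """Sample-size-scaled univariate two-sample KS statistic.

    Evaluates the ECDF difference at all pooled data points, so ties are
    handled exactly.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    xs, ys = np.sort(x), np.sort(y)
    f1 = np.searchsorted(xs, pooled, side="right") / len(x)
    f2 = np.searchsorted(ys, pooled, side="right") / len(y)
    return _scale(len(x), len(y)) * float(np.max(np.abs(f1 - f2)))


def _quadrant_cdf_max(x: np.ndarray, y: np.ndarray) -> float:
    """max over 2^d orientations and pooled grid points of |F1 - F2|.

    Histogram both samples on the grid of pooled unique coordinates per axis,
    then inclusive cumulative sums in each axis direction give every
    orientation's ECDF at every grid point at once.
    """
    d = x.shape[1]
    axes = [np.unique(np.concatenate([x[:, k], y[:, k]])) for k in range(d)]
    shape = tuple(len(a) for a in axes)
    D = np.zeros(shape)
    ix = tuple(np.searchsorted(axes[k], x[:, k]) for k in range(d))
    iy = tuple(np.searchsorted(axes[k], y[:, k]) for k in range(d))
    np.add.at(D, ix, 1.0 / len(x))
    np.add.at(D, iy, -1.0 / len(y))
    # one inclusive cumulative sum T gives every orientation by
    # inclusion-exclusion: the >=-inclusive count along axis k at index i
    # equals (axis total) - (<=-count at i-1), and the signed difference
    # histogram has total mass 0, so all 2^d quadrant ECDF differences are
    # +/- combinations of T evaluated at shifted indices.
    T = D
    for k in range(d):
        T = np.cumsum(T, axis=k)
    best = 0.0
    for orient in product((0, 1), repeat=d):
        C = T
        for k, o in enumerate(orient):
            if o == 1:
                # replace <=-inclusive with (total along k) - value at i-1
                tot = np.take(C, [-1], axis=k)
                shifted = np.concatenate(
                    [np.zeros_like(tot), np.take(C, range(shape[k] - 1), axis=k)],
                    axis=k,
                )
                C = tot - shifted
        best = max(best, float(np.max(np.abs(C))))
    return best


def peacock_nd(x, y, scaled: bool = True) -> float:
    """Exact Peacock multidimensional two-sample KS statistic (d = 2 or 3)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("samples must share dimensionality")
    d = x.shape[1]
    if d not in (2, 3):
        raise ValueError(f"peacock_nd supports d in (2, 3), got {d}")
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing coordinates are not allowed")
    stat = _quadrant_cdf_max(x, y)
    return (_scale(len(x), len(y)) if scaled else 1.0) * stat


def _clade_stat(inside: np.ndarray, outside: np.ndarray) -> float:
    if inside.shape[1] == 1:
        return ks_scaled(inside[:, 0], outside[:, 0])
    return peacock_nd(inside, outside)


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------


@dataclass
class KSIRank:
    rank: int
    node: int
    name: str
    statistic: float
    ratio: float  # statistic / rank-1 statistic
    nodeset: list  # node names, ancestor/descendant chain within threshold
    n_inside: int
    n_outside: int


@dataclass
class KSIResult:
    trait_set: tuple
    ranks: list  # of KSIRank
    n_species: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait_set": ["-".join(self.trait_set)] * len(self.ranks),
                "node": [r.name for r in self.ranks],
                "rank": [r.rank for r in self.ranks],
                "KSI": [r.statistic for r in self.ranks],
                "KSI_over_max": [r.ratio for r in self.ranks],
                "nodesets": ["; ".join(r.nodeset) for r in self.ranks],
            }
        )


def _node_name(tree: Phylogeny, node: int) -> str:
    lab = tree.labels[node]
    return str(lab) if lab else f"nd{node}"


def ksi_search(
    tree: Phylogeny,
    traits: TraitMatrix | pd.DataFrame,
    trait_set=("fat",),
    n_ranks: int = 5,
    min_clade: int = 4,
    nodeset_frac: float = 0.95,
) -> KSIResult:
    """Iterative clade-distinctiveness ranking for one trait set.

    Species missing any trait in the set are excluded up front (listwise
    within the set).  Per iteration every internal non-root node whose clade
    has at least ``min_clade`` remaining tips both inside and outside is
    scored; the winning clade's tips are removed before the next rank.
    """
    values = traits.data if isinstance(traits, TraitMatrix) else traits
    trait_set = tuple(trait_set)
    sub = values.reindex(tree.tip_labels)[list(trait_set)]
    alive = ~sub.isna().any(axis=1).to_numpy()
    V = sub.to_numpy(dtype=float)
    below = tree.tips_below()
    internal = [i for i in range(1, tree.n_nodes) if not tree.is_tip[i]]
    if min_clade > alive.sum() // 2:
        raise ValueError("min_clade larger than half the usable species")

    ranks: list[KSIRank] = []
    top_stat = None
    for r in range(1, n_ranks + 1):
        if alive.sum() < 2 * min_clade:
            warnings.warn(f"stopping at rank {r - 1}: fewer than {2 * min_clade} "
                          "species remain", stacklevel=2)
            break
        stats: dict[int, tuple[float, int, int]] = {}
        for node in internal:
            ins = below[node] & alive
            n_in = int(ins.sum())
            n_out = int(alive.sum()) - n_in
            if n_in < min_clade or n_out < min_clade:
                continue
            stat = _clade_stat(V[ins], V[alive & ~below[node]])
            stats[node] = (stat, n_in, n_out)
        if not stats:
            warnings.warn(f"stopping at rank {r - 1}: no testable clade", stacklevel=2)
            break
        winner = min(stats, key=lambda nd: (-stats[nd][0], nd))
        stat, n_in, n_out = stats[winner]
        if top_stat is None:
            top_stat = stat
        chain = _ancestor_descendant_chain(tree, winner, below)
        nodeset = [
            _node_name(tree, nd) for nd in chain
            if nd in stats and stats[nd][0] >= nodeset_frac * stat
        ]
        ranks.append(
            KSIRank(
                rank=r,
                node=winner,
                name=_node_name(tree, winner),
                statistic=stat,
                ratio=stat / top_stat if top_stat > 0 else 1.0,
                nodeset=nodeset,
                n_inside=n_in,
                n_outside=n_out,
            )
        )
        alive = alive & ~below[winner]
    return KSIResult(trait_set=trait_set, ranks=ranks, n_species=int(sub.notna().all(axis=1).sum()))


def _ancestor_descendant_chain(tree: Phylogeny, node: int, below: np.ndarray) -> list:
    """Winner plus its ancestors and descendant internal nodes, winner first,
    then by decreasing overlap with the winner's clade."""
    anc = []
    p = tree.parent[node]
    while p > 0:
        anc.append(p)
        p = tree.parent[p]
    desc = [i for i in range(1, tree.n_nodes)
            if not tree.is_tip[i] and i != node and below[node][below[i]].all()
            and below[i].sum() < below[node].sum()]
    ordered = [node] + sorted(anc + desc, key=lambda nd: (abs(int(below[nd].sum()) -
                                                              int(below[node].sum())), nd))
    return ordered


DEFAULT_TRAIT_SETS = (
    ("fat",), ("protein",), ("sugar",),
    ("fat", "protein"), ("fat", "sugar"), ("protein", "sugar"),
    ("fat", "protein", "sugar"),
)


def ksi_table(results) -> pd.DataFrame:
    """Stack per-trait-set results into one long table (five rows per block)."""
    frames = [r.to_frame() for r in results]
    if not frames:
        return pd.DataFrame(columns=["trait_set", "node", "rank", "KSI",
                                     "KSI_over_max", "nodesets"])
    return pd.concat(frames, ignore_index=True)
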