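"""Shared data model: trees, trait tables, covariate tables, and alignment.

Trees are parsed with :mod:`dendropy` and converted to a flat array
representation (preorder node arrays) that the numerical code consumes.
Trait and covariate tables are thin wrappers around :class:`pandas.DataFrame`
with the invariants the downstream models rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

TRAITS = ("fat", "protein", "sugar")

DIET_LEVELS = ("herbivore", "omnivore", "carnivore")


def _normalize_name(name: str) -> str:
    """Exact-match normalization: strip, collapse whitespace, underscores->spaces."""
    return " ".join(str(name).replace("_", " ").split())


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class Phylogeny:
    """Rooted phylogeny with branch lengths, in preorder array form.

    Node 0 is the root.  ``parent[i]`` is the preorder index of node ``i``'s
    parent (-1 for the root) and ``blen[i]`` the length of the branch above
    node ``i`` (0 for the root).  ``labels[i]`` is the tip name for leaves and
    an optional label for internal nodes.  Tip order (``tip_indices``) is the
    canonical species order used by every aligned table and matrix.
    """

    parent: np.ndarray
    blen: np.ndarray
    labels: list
    is_tip: np.ndarray

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.blen = np.asarray(self.blen, dtype=float)
        self.is_tip = np.asarray(self.is_tip, dtype=bool)
        if self.parent[0] != -1:
            raise ValueError("node 0 must be the root (parent -1)")
        if np.any(self.blen < 0):
            raise ValueError("negative branch length")
        tips = [self.labels[i] for i in np.flatnonzero(self.is_tip)]
        if len(set(tips)) != len(tips):
            raise ValueError("duplicate tip labels")
        if any(t is None for t in tips):
            raise ValueError("unlabeled tip")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.empty(len(nodes), dtype=int)
        blen = np.zeros(len(nodes))
        labels: list = []
        is_tip = np.zeros(len(nodes), dtype=bool)
        for i, nd in enumerate(nodes):
            parent[i] = -1 if nd.parent_node is None else index[id(nd.parent_node)]
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise ValueError("tree has a branch without a length")
                blen[i] = float(nd.edge.length)
            if nd.is_leaf():
                is_tip[i] = True
                if nd.taxon is None or nd.taxon.label is None:
                    raise ValueError("unlabeled tip")
                labels.append(_normalize_name(nd.taxon.label))
            else:
                lab = nd.label
                if lab is None and nd.taxon is not None:
                    lab = nd.taxon.label
                labels.append(lab)
        return cls(parent=parent, blen=blen, labels=labels, is_tip=is_tip)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        tree.seed_node = nodes[0]
        for i in range(1, self.n_nodes):
            nodes[self.parent[i]].add_child(nodes[i])
            nodes[i].edge.length = float(self.blen[i])
        for i in range(self.n_nodes):
            if self.is_tip[i]:
                nodes[i].taxon = taxa.new_taxon(self.labels[i])
            elif self.labels[i] is not None:
                nodes[i].label = str(self.labels[i])
        return tree

    # -- basic structure ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_indices]

    def children(self) -> list:
        kids: list = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            kids[self.parent[i]].append(i)
        return kids

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node (preorder accumulation)."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.blen[i]
        return d

    @property
    def height(self) -> float:
        return float(self.node_depths()[self.is_tip].max())

    def is_ultrametric(self, rtol: float = 1e-8) -> bool:
        d = self.node_depths()[self.is_tip]
        return bool(np.ptp(d) <= rtol * max(d.max(), 1.0))

    def tips_below(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips) matrix: tip j descends from (or is) node i."""
        out = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
        col = {int(t): j for j, t in enumerate(self.tip_indices)}
        for i in range(self.n_nodes - 1, -1, -1):
            if self.is_tip[i]:
                out[i, col[i]] = True
            if self.parent[i] >= 0:
                out[self.parent[i]] |= out[i]
        return out

    def mrca_depths(self) -> np.ndarray:
        """(n, n) matrix of root-to-MRCA distances in canonical tip order.

        Under Brownian motion this is the phylogenetic covariance matrix A:
        shared path length from the root, with root-to-tip distances on the
        diagonal.
        """
        below = self.tips_below()
        weighted = below * self.blen[:, None]
        return weighted.T.astype(float) @ below

    def newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick", suppress_rooting=True).strip()

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            parent=self.parent.copy(),
            blen=self.blen.copy(),
            labels=list(self.labels),
            is_tip=self.is_tip.copy(),
        )


def read_newick(path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths.

    Polytomies are preserved; a missing branch length or duplicate tip label
    is an error.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except dendropy.utility.error.DataParseError as err:
        raise ValueError(f"could not parse Newick: {err}") from err
    return Phylogeny.from_dendropy(tree)


def read_newick_string(s: str) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    except dendropy.utility.error.DataParseError as err:
        raise ValueError(f"could not parse Newick: {err}") from err
    return Phylogeny.from_dendropy(tree)


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def scale_tree_height(tree: Phylogeny) -> Phylogeny:
    """Rescale all branch lengths so the maximum root-to-tip distance is 1.

    Keeps the selection strength alpha and the phylogenetic covariance in
    per-tree-height units, which makes heritability scale-free.
    """
    h = tree.height
    if h <= 0:
        raise ValueError("cannot scale a zero-height tree")
    out = tree.copy()
    out.blen = out.blen / h
    return out


def phylo_covariance(tree: Phylogeny) -> np.ndarray:
    """Brownian-motion phylogenetic covariance matrix (shared branch lengths)."""
    return tree.mrca_depths()


# ---------------------------------------------------------------------------
# Trait matrix
# ---------------------------------------------------------------------------


class TraitMatrix:
    """Species-by-macronutrient table (fat, protein, sugar) with a dry-matter column.

    ``data`` holds the three macronutrient columns on the current scale
    (``proportion`` of mass, or ``logit``); the raw g/100 g values are kept in
    ``g100g``.  Missing values are NaN; exact zeros (e.g. sugar below the
    detection limit) are converted to missing at load time because the logit
    transform is undefined there.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        scale: str = "proportion",
        dry_matter: pd.Series | None = None,
        g100g: pd.DataFrame | None = None,
    ):
        if scale not in ("proportion", "logit"):
            raise ValueError(f"unknown scale {scale!r}")
        data = data.loc[:, list(TRAITS)].astype(float)
        if data.index.duplicated().any():
            raise ValueError("duplicate species names in trait table")
        if scale == "proportion":
            vals = data.to_numpy()
            bad = ~np.isnan(vals) & ((vals <= 0) | (vals >= 1))
            if bad.any():
                raise ValueError("proportions must lie strictly in (0, 1)")
        self.data = data
        self.scale = scale
        self.dry_matter = dry_matter.astype(float) if dry_matter is not None else None
        self.g100g = g100g if g100g is not None else (data * 100.0 if scale == "proportion" else None)

    @classmethod
    def from_g100g(cls, df: pd.DataFrame, dry_matter: pd.Series | None = None) -> "TraitMatrix":
        """Build from concentrations in g per 100 g; zeros become missing."""
        df = df.loc[:, list(TRAITS)].astype(float)
        zero = df.to_numpy() == 0.0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero concentration(s) treated as missing "
                "(below detection; logit undefined at 0)",
                stacklevel=2,
            )
            df = df.mask(df == 0.0)
        return cls(df / 100.0, scale="proportion", dry_matter=dry_matter, g100g=df)

    @property
    def species(self) -> list:
        return list(self.data.index)

    @property
    def mask(self) -> pd.DataFrame:
        """True where the value is missing."""
        return self.data.isna()

    def to_logit(self) -> "TraitMatrix":
        from phylomilk.transforms import logit

        if self.scale == "logit":
            return self
        out = TraitMatrix.__new__(TraitMatrix)
        out.data = logit(self.data)
        out.scale = "logit"
        out.dry_matter = self.dry_matter
        out.g100g = self.g100g
        return out

    def to_proportion(self) -> "TraitMatrix":
        from phylomilk.transforms import inverse_logit

        if self.scale == "proportion":
            return self
        return TraitMatrix(inverse_logit(self.data), scale="proportion",
                           dry_matter=self.dry_matter, g100g=self.g100g)

    def restrict(self, species: Sequence[str]) -> "TraitMatrix":
        out = TraitMatrix.__new__(TraitMatrix)
        out.data = self.data.loc[list(species)]
        out.scale = self.scale
        out.dry_matter = self.dry_matter.loc[[s for s in species if s in self.dry_matter.index]] \
            if self.dry_matter is not None else None
        out.g100g = self.g100g.loc[list(species)] if self.g100g is not None else None
        return out


def read_traits(path, species_col: str = "species") -> TraitMatrix:
    """Read a delimited trait table of g/100 g concentrations.

    Expects columns ``fat``, ``protein``, ``sugar`` and optionally
    ``dry_matter``; the species-name column is normalized for matching.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df[species_col] = df[species_col].map(_normalize_name)
    df = df.set_index(species_col)
    dm = df["dry_matter"] if "dry_matter" in df.columns else None
    return TraitMatrix.from_g100g(df, dry_matter=dm)


def write_traits(traits: TraitMatrix, path) -> None:
    df = traits.g100g.copy() if traits.g100g is not None else traits.data.copy()
    if traits.dry_matter is not None:
        df = df.join(traits.dry_matter.rename("dry_matter"))
    df.index.name = "species"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# Covariate table
# ---------------------------------------------------------------------------

CONTINUOUS_COVARIATES = ("female_mass", "rep_output", "lactation_length")
ORDINAL_COVARIATES = {"arid": (0, 1), "aquatic": (0, 3), "precociality": (0, 10)}
COVARIATE_COLUMNS = ("arid", "aquatic", "diet") + CONTINUOUS_COVARIATES + ("precociality",)


class CovariateTable:
    """Ecological and life-history predictors with the codings the model expects.

    Columns: ``arid`` (0/1), ``aquatic`` (ordinal 0-3), ``diet``
    (herbivore/omnivore/carnivore), ``female_mass``, ``rep_output``,
    ``lactation_length`` (continuous; log10-centered once ``centered`` is
    True), ``precociality`` (ordinal).
    """

    def __init__(self, data: pd.DataFrame, centered: bool = False):
        missing_cols = [c for c in COVARIATE_COLUMNS if c not in data.columns]
        if missing_cols:
            raise ValueError(f"covariate table lacks columns: {missing_cols}")
        if data.index.duplicated().any():
            raise ValueError("duplicate species names in covariate table")
        data = data.loc[:, list(COVARIATE_COLUMNS)].copy()
        for col, (lo, hi) in ORDINAL_COVARIATES.items():
            vals = data[col].dropna()
            if not vals.isin(range(lo, hi + 1)).all():
                raise ValueError(f"{col} values must be integers in [{lo}, {hi}]")
        bad_diet = set(data["diet"].dropna()) - set(DIET_LEVELS)
        if bad_diet:
            raise ValueError(f"unknown diet level(s): {sorted(bad_diet)}")
        if centered:
            means = data[list(CONTINUOUS_COVARIATES)].mean()
            if (means.abs() > 1e-8).any():
                raise ValueError("centered continuous covariates must have mean 0")
        self.data = data
        self.centered = centered

    @property
    def species(self) -> list:
        return list(self.data.index)

    def complete_cases(self) -> list:
        """Species with no missing covariate (eligible for the mixed model)."""
        return list(self.data.index[~self.data.isna().any(axis=1)])

    def restrict(self, species: Sequence[str]) -> "CovariateTable":
        out = CovariateTable.__new__(CovariateTable)
        out.data = self.data.loc[list(species)]
        out.centered = self.centered
        return out


def read_covariates(path, species_col: str = "species") -> CovariateTable:
    df = pd.read_csv(path, sep=None, engine="python")
    df[species_col] = df[species_col].map(_normalize_name)
    df = df.set_index(species_col)
    return CovariateTable(df, centered=bool(np.allclose(
        df[list(CONTINUOUS_COVARIATES)].mean(), 0.0, atol=1e-8)))


def write_covariates(covs: CovariateTable, path) -> None:
    df = covs.data.copy()
    df.index.name = "species"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignedDataset:
    """Tree, traits and covariates restricted to a common species set.

    Species order is the tree's canonical tip order in all three components.
    """

    tree: Phylogeny
    traits: TraitMatrix
    covariates: CovariateTable | None = None
    dropped_from_tree: list = field(default_factory=list)
    dropped_from_tables: list = field(default_factory=list)

    def __post_init__(self) -> None:
        tips = self.tree.tip_labels
        if self.traits.species != tips:
            raise ValueError("trait rows are not in tree tip order")
        if self.covariates is not None and self.covariates.species != tips:
            raise ValueError("covariate rows are not in tree tip order")
        if self.traits.mask.all(axis=1).any():
            raise ValueError("species with all three milk traits missing")

    @property
    def species(self) -> list:
        return self.tree.tip_labels

    @property
    def n(self) -> int:
        return self.tree.n_tips


def _prune_to(tree: Phylogeny, keep: Sequence[str]) -> Phylogeny:
    dtree = tree.to_dendropy()
    dtree.retain_taxa_with_labels(list(keep))
    return Phylogeny.from_dendropy(dtree)


def trim_and_align(
    tree: Phylogeny,
    traits: TraitMatrix,
    covariates: CovariateTable | None = None,
) -> AlignedDataset:
    """Restrict tree and tables to their common species and canonicalize order.

    Tips absent from the trait table are pruned; table rows absent from the
    tree are dropped with a warning.  Species missing covariates are kept
    (the mixed-model stage excludes them itself); species missing all three
    milk traits are dropped.
    """
    tips = set(tree.tip_labels)
    usable = {
        s for s in traits.species
        if not traits.mask.loc[s].all()
    }
    common = tips & usable
    if len(common) < 3:
        raise ValueError(f"only {len(common)} species shared between tree and traits")
    dropped_tips = sorted(tips - common)
    dropped_rows = sorted(set(traits.species) - common)
    if dropped_rows:
        warnings.warn(
            f"{len(dropped_rows)} trait-table species not in the tree (or fully "
            f"missing) were dropped: {', '.join(dropped_rows[:5])}"
            + ("..." if len(dropped_rows) > 5 else ""),
            stacklevel=2,
        )
    pruned = tree if not dropped_tips else _prune_to(tree, sorted(common))
    order = pruned.tip_labels
    traits_r = traits.restrict(order)
    covs_r = None
    if covariates is not None:
        cov_df = covariates.data.reindex(order)
        covs_r = CovariateTable.__new__(CovariateTable)
        covs_r.data = cov_df
        covs_r.centered = covariates.centered
    return AlignedDataset(
        tree=pruned,
        traits=traits_r,
        covariates=covs_r,
        dropped_from_tree=dropped_tips,
        dropped_from_tables=dropped_rows,
    )
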