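"""Synthetic trees, covariates, and trivariate trait data with known truth.

The generator mirrors the statistical structure the analysis assumes: an
ultrametric birth-death tree scaled to unit height; logit-scale macronutrient
traits evolving by correlated Brownian motion or scalar Ornstein-Uhlenbeck
(one selection strength shared by all traits) with optional optimum shifts on
internal edges; ecological covariates with phylogenetic signal (thresholded
Brownian liabilities, so the design is clade-confounded like real mammalian
ecology); independent residual noise; and missingness confined to sugar.

The default preset emulates the mammalian milk study conditions: 124 tips,
phylogenetic heritabilities near (0.98, 1.00, 0.87) for (fat, protein,
sugar), phylogenetic correlations (0.68, -0.75, -0.47), and 15 of 124 sugar
values missing completely at random.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from phylomilk.core import (
    AlignedDataset,
    CovariateTable,
    Phylogeny,
    TraitMatrix,
    scale_tree_height,
    write_covariates,
    write_newick,
)
from phylomilk.transforms import inverse_logit

TRAITS = ("fat", "protein", "sugar")


def _corr_to_cov(variances, correlations) -> np.ndarray:
    """3x3 covariance from variances and (fp, fs, ps) correlations."""
    v = np.asarray(variances, dtype=float)
    fp, fs, ps = correlations
    R = np.array([[1.0, fp, fs], [fp, 1.0, ps], [fs, ps, 1.0]])
    s = np.sqrt(v)
    return R * np.outer(s, s)


# Study-scale defaults: logit-scale phylogenetic variances sized to the
# observed interspecific spread (fat spans ~1-60 g/100 g, sugar ~0.1-8),
# heritabilities and correlations from the trivariate mixed-model estimates.
DEFAULT_H2 = (0.976, 0.997, 0.872)
DEFAULT_RP = (0.675, -0.750, -0.473)
DEFAULT_RR = (0.156, 0.380, 0.251)
DEFAULT_VP = (1.7, 0.45, 2.5)

DEFAULT_B = pd.DataFrame(
    {
        "fat": [-2.161, -0.190, 0.220, 0.194, 0.799, -0.049, 0.150, -0.901, 0.066],
        "protein": [-2.347, -0.166, 0.044, -0.029, 0.162, -0.034, 0.167, 0.105, -0.031],
        "sugar": [-3.204, -0.019, -0.376, 0.089, -0.376, -0.103, -0.246, 0.398, -0.039],
    },
    index=[
        "intercept", "arid", "aquatic", "diet_omnivore", "diet_carnivore",
        "female_mass", "rep_output", "lactation_length", "precociality",
    ],
)


def default_sigma_p() -> np.ndarray:
    return _corr_to_cov(DEFAULT_VP, DEFAULT_RP)


def default_sigma_r() -> np.ndarray:
    h2 = np.asarray(DEFAULT_H2)
    vr = np.asarray(DEFAULT_VP) * (1.0 - h2) / h2
    return _corr_to_cov(vr, DEFAULT_RR)


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic dataset."""

    n_tips: int = 124
    birth_rate: float = 1.0
    death_rate: float = 0.0
    sigma_p: np.ndarray = field(default_factory=default_sigma_p)
    sigma_r: np.ndarray = field(default_factory=default_sigma_r)
    B: pd.DataFrame = field(default_factory=lambda: DEFAULT_B.copy())
    alpha: float = 0.0
    n_shifts: int = 0
    shift_size: float = 8.0  # in per-trait marginal SD units (see plant_shifts)
    min_shift_clade: int = 8
    sugar_missing_frac: float = 15.0 / 124.0
    with_covariates: bool = True

    def __post_init__(self) -> None:
        for name in ("sigma_p", "sigma_r"):
            m = np.asarray(getattr(self, name), dtype=float)
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-9:
                raise ValueError(f"{name} must be positive semi-definite")
            setattr(self, name, m)
        if not 0 <= self.sugar_missing_frac < 1:
            raise ValueError("missingness fraction must be in [0, 1)")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class SyntheticDataset:
    """Aligned synthetic data plus the generating truth, for recovery scoring."""

    dataset: AlignedDataset
    truth: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_newick(self.dataset.tree, outdir / "tree.nwk")
        g = inverse_logit(self.dataset.traits.data) * 100.0
        if self.dataset.traits.dry_matter is not None:
            g = g.join(self.dataset.traits.dry_matter.rename("dry_matter"))
        g.index.name = "species"
        g.to_csv(outdir / "traits.csv")
        if self.dataset.covariates is not None:
            write_covariates(self.dataset.covariates, outdir / "covariates.csv")
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray)
                else v.to_dict() if isinstance(v, (pd.DataFrame, pd.Series))
                else [sorted(c) for c in v] if k == "shift_clades"
                else v)
            for k, v in self.truth.items()
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, birth_rate: float = 1.0, death_rate: float = 0.0,
                  seed: int | None = None) -> Phylogeny:
    """Ultrametric birth-death tree with ``n_tips`` extant tips, unit height.

    Tips are renamed ``sp001 ...`` in preorder so names are stable across
    library versions.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    dtree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_tips,
        rng=random.Random(None if seed is None else int(seed)),
    )
    tree = Phylogeny.from_dendropy(dtree)
    # the generator stops at the n-th birth, leaving a zero-length cherry;
    # run the clock to the next event so all tips are distinct (keeps the
    # tree ultrametric, then rescaled to unit height anyway)
    tail = random.Random(None if seed is None else int(seed) + 1).expovariate(
        n_tips * (birth_rate + death_rate)
    )
    tree.blen[tree.is_tip] += tail
    counter = 0
    width = max(3, len(str(n_tips)))
    for i in range(tree.n_nodes):
        if tree.is_tip[i]:
            counter += 1
            tree.labels[i] = f"sp{counter:0{width}d}"
    return scale_tree_height(tree)


def simulate_planted_clade_tree(n_tips: int, seed: int | None = None):
    """Tree with a focal clade of exactly ``n_tips // 2`` tips, for power checks.

    Three birth-death subtrees are grafted onto a fixed backbone so that the
    focal clade (half the tips) hangs below an inner node rather than the
    root.  With that construction the sample-size scale sqrt(n1 n2 / n) of
    the focal clade strictly exceeds that of every other testable clade, so
    a strongly displaced focal clade is the unique argmax of the scaled KS /
    Peacock statistics: ancestors, descendants and disjoint clades all have
    strictly smaller scale and an ECDF discrepancy of at most 1.

    Returns ``(tree, planted_edge)`` where ``planted_edge`` is the preorder
    node index of the focal clade's root (the edge carrying the shift).
    """
    half = n_tips // 2
    quarter_a = (n_tips - half) // 2
    quarter_b = n_tips - half - quarter_a
    rng = np.random.default_rng(seed)
    sub = [
        simulate_tree(m, seed=int(rng.integers(2**31)))
        for m in (quarter_a, half, quarter_b)
    ]
    # backbone depths: sibling clade at 0.2 (height 0.8); inner node at 0.3
    # carrying the focal clade and the second sibling at 0.4 (height 0.6)
    parent = [-1, 0]
    blen = [0.0, 0.3]
    labels: list = [None, None]
    is_tip = [False, False]

    def graft(tree: Phylogeny, attach_to: int, stem: float, scale: float):
        offset = len(parent)
        for i in range(tree.n_nodes):
            parent.append(attach_to if i == 0 else tree.parent[i] + offset)
            blen.append(stem if i == 0 else tree.blen[i] * scale)
            labels.append(tree.labels[i])
            is_tip.append(bool(tree.is_tip[i]))
        return offset

    focal = graft(sub[1], attach_to=1, stem=0.1, scale=0.6)
    graft(sub[2], attach_to=1, stem=0.1, scale=0.6)
    graft(sub[0], attach_to=0, stem=0.2, scale=0.8)
    counter = 0
    width = max(3, len(str(n_tips)))
    for i in range(len(labels)):
        if is_tip[i]:
            counter += 1
            labels[i] = f"sp{counter:0{width}d}"
    tree = Phylogeny(parent=np.array(parent), blen=np.array(blen),
                     labels=labels, is_tip=np.array(is_tip))
    return tree, focal


# ---------------------------------------------------------------------------
# Trait processes
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_bm_traits(tree: Phylogeny, sigma: np.ndarray, root_state=0.0,
                       seed=None) -> pd.DataFrame:
    """Correlated Brownian motion on the tree; returns tip values (logit scale).

    Child value = parent value + N(0, branch_length * sigma), recursively
    from the root.
    """
    return simulate_scou_traits(tree, alpha=0.0, rates=sigma, root_state=root_state,
                                shifts=(), seed=seed)


def simulate_scou_traits(
    tree: Phylogeny,
    alpha: float,
    rates: np.ndarray,
    root_state=0.0,
    shifts=(),
    seed=None,
) -> pd.DataFrame:
    """Scalar Ornstein-Uhlenbeck simulation with optimum shifts on edges.

    Every trait shares the selection strength ``alpha``; the Brownian rate
    matrix ``rates`` sets (co)variances of the stochastic increments.  A shift
    ``(edge, delta)`` moves the optimum vector by ``delta`` from the start of
    the edge indexed by its child node, for that whole clade.  At ``alpha = 0``
    the process is exact Brownian motion and ``delta`` becomes a step change
    in the mean.  Branch transitions use the exact OU Gaussian (mean decay
    ``exp(-alpha t)``), not Euler steps.
    """
    rng = _as_rng(seed)
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    k = rates.shape[0]
    root = np.broadcast_to(np.asarray(root_state, dtype=float), (k,)).copy()
    shift_map: dict[int, np.ndarray] = {}
    for edge, delta in shifts:
        edge = int(edge)
        if edge <= 0 or edge >= tree.n_nodes:
            raise ValueError(f"shift edge {edge} does not exist")
        if edge in shift_map:
            raise ValueError(f"two shifts on edge {edge}")
        shift_map[edge] = np.broadcast_to(np.asarray(delta, dtype=float), (k,))
    # PSD square root (eigh handles the semi-definite case Cholesky cannot)
    w, U = np.linalg.eigh(rates)
    w = np.clip(w, 0.0, None)
    sqrt_rates = U * np.sqrt(w)

    values = np.zeros((tree.n_nodes, k))
    optima = np.zeros((tree.n_nodes, k))
    values[0] = root
    optima[0] = root
    for i in range(1, tree.n_nodes):
        p = tree.parent[i]
        theta = optima[p] + shift_map.get(i, 0.0)
        optima[i] = theta
        b = tree.blen[i]
        x = values[p]
        if alpha == 0.0:
            mean = x + (shift_map[i] if i in shift_map else 0.0)
            scale = np.sqrt(b)
        else:
            decay = np.exp(-alpha * b)
            mean = theta + (x - theta) * decay
            scale = np.sqrt((1.0 - decay**2) / (2.0 * alpha))
        values[i] = mean + scale * (sqrt_rates @ rng.standard_normal(k))
    tips = tree.tip_indices
    cols = list(TRAITS[:k]) if k <= 3 else [f"trait{j}" for j in range(k)]
    return pd.DataFrame(values[tips], index=tree.tip_labels, columns=cols)


def scou_tip_moment_matrices(tree: Phylogeny, alpha: float):
    """(mean-decay weights are model-side; see phylomilk.shifts) tip covariance
    structure C(alpha): cov = exp(-a(di+dj-2tij)) (1-exp(-2a tij))/(2a); the
    alpha->0 limit is the Brownian matrix of MRCA depths."""
    A = tree.mrca_depths()
    if alpha == 0.0:
        return A
    d = np.diag(A).copy()
    dsum = d[:, None] + d[None, :]
    with np.errstate(over="ignore"):
        C = np.exp(-alpha * (dsum - 2.0 * A)) * (1.0 - np.exp(-2.0 * alpha * A)) / (2.0 * alpha)
    return C


# ---------------------------------------------------------------------------
# Covariates and effects
# ---------------------------------------------------------------------------


def _liability(tree: Phylogeny, rng) -> np.ndarray:
    return simulate_bm_traits(tree, np.array([[1.0]]), 0.0, rng).to_numpy()[:, 0]


def _bin_by_quantile(x: np.ndarray, qs) -> np.ndarray:
    cuts = np.quantile(x, qs)
    return np.searchsorted(cuts, x, side="right")


def simulate_covariates(tree: Phylogeny, seed=None) -> CovariateTable:
    """Ecological predictors with phylogenetic signal.

    Discrete predictors are thresholded Brownian liabilities (so categories
    cluster in clades, as mammalian ecology does); continuous predictors are
    Brownian values treated as already log10-transformed, then centered.
    """
    rng = _as_rng(seed)
    sp = tree.tip_labels
    arid = (_bin_by_quantile(_liability(tree, rng), [0.8])).astype(int)
    aquatic = _bin_by_quantile(_liability(tree, rng), [0.85, 0.92, 0.96]).astype(int)
    diet = np.array(["herbivore", "omnivore", "carnivore"])[
        _bin_by_quantile(_liability(tree, rng), [0.45, 0.75])
    ]
    precociality = _bin_by_quantile(_liability(tree, rng), [0.25, 0.5, 0.75]).astype(int)
    mass = 1.0 * _liability(tree, rng) + 0.2 * rng.standard_normal(len(sp))
    output = 0.5 * _liability(tree, rng) + 0.1 * rng.standard_normal(len(sp))
    lact = 0.3 * _liability(tree, rng) + 0.05 * rng.standard_normal(len(sp))
    df = pd.DataFrame(
        {
            "arid": arid,
            "aquatic": aquatic,
            "diet": diet,
            "female_mass": mass - mass.mean(),
            "rep_output": output - output.mean(),
            "lactation_length": lact - lact.mean(),
            "precociality": precociality,
        },
        index=sp,
    )
    return CovariateTable(df, centered=True)


def attach_covariates_and_effects(
    tree: Phylogeny,
    trait_values: pd.DataFrame,
    covariates: CovariateTable,
    B: pd.DataFrame,
    seed=None,
) -> pd.DataFrame:
    """Shift logit-scale trait values by the fixed-effect predictor X @ B."""
    from phylomilk.pmm import build_design

    X, names = build_design(covariates)
    B = B.loc[list(names), list(trait_values.columns)]
    shift = X @ B.to_numpy()
    return trait_values + pd.DataFrame(shift, index=trait_values.index,
                                       columns=trait_values.columns)


def impose_missingness(values: pd.DataFrame, fraction: float, trait: str = "sugar",
                       seed=None) -> pd.DataFrame:
    """Mask exactly round(fraction * n) entries of one trait, MCAR."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = _as_rng(seed)
    out = values.copy()
    n_mask = int(round(fraction * len(out)))
    if n_mask:
        rows = rng.choice(len(out), size=n_mask, replace=False)
        out.iloc[rows, out.columns.get_loc(trait)] = np.nan
    return out


def plant_shifts(tree: Phylogeny, n_shifts: int, size: float, rates: np.ndarray,
                 alpha: float = 0.0, seed=None, min_clade: int = 8,
                 max_clade: int | None = None, signs=None):
    """Choose disjoint internal edges and build optimum-shift vectors.

    Shift magnitude is calibrated to the realized displacement at the tips:
    ``size`` marginal Brownian standard deviations (per unit tree height) on
    every trait.  Under weak selection an optimum jump only moves tips by a
    factor 1 - exp(-alpha (h - t_shift)), so the optimum jump is inflated by
    its inverse; alternating signs across traits keep the shifted clades
    inside a plausible trait range.
    """
    rng = _as_rng(seed)
    depths = tree.node_depths()
    h = tree.height
    below = tree.tips_below()
    counts = below.sum(axis=1)
    n = tree.n_tips
    upper = max(min_clade, n // 3) if max_clade is None else max_clade
    candidates = [
        i for i in range(1, tree.n_nodes)
        if not tree.is_tip[i] and min_clade <= counts[i] <= upper
    ]
    rng.shuffle(candidates)
    chosen: list[int] = []
    for c in candidates:
        if all(not (below[c] & below[o]).any() for o in chosen):
            chosen.append(c)
        if len(chosen) == n_shifts:
            break
    if len(chosen) < n_shifts:
        raise ValueError(f"could not place {n_shifts} disjoint shifts (min_clade={min_clade})")
    sd = np.sqrt(np.diag(np.atleast_2d(rates)))
    if signs is None:
        signs = [(-1.0) ** (j + t) for j in range(n_shifts) for t in range(len(sd))]
        signs = np.array(signs).reshape(n_shifts, len(sd))
    shifts = []
    for j, edge in enumerate(chosen):
        gain = 1.0
        if alpha > 0:
            gain = 1.0 - np.exp(-alpha * (h - depths[tree.parent[edge]]))
        shifts.append((edge, size * sd * signs[j] / gain))
    clades = [frozenset(np.array(tree.tip_labels)[below[e]]) for e, _ in shifts]
    return shifts, clades


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


def make_dataset(config: SimulationConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate a complete aligned dataset plus its truth record."""
    config = config or SimulationConfig()
    rng = _as_rng(seed)
    tree = simulate_tree(config.n_tips, config.birth_rate, config.death_rate,
                         seed=int(rng.integers(2**31)))
    shifts, shift_clades = ((), [])
    if config.n_shifts > 0:
        shifts, shift_clades = plant_shifts(
            tree, config.n_shifts, config.shift_size, config.sigma_p,
            alpha=config.alpha, seed=rng, min_clade=config.min_shift_clade,
        )
    phylo_part = simulate_scou_traits(
        tree, config.alpha, config.sigma_p, root_state=0.0, shifts=shifts, seed=rng
    )
    covs = None
    values = phylo_part
    if config.with_covariates:
        covs = simulate_covariates(tree, seed=rng)
        values = attach_covariates_and_effects(tree, values, covs, config.B)
    else:
        values = values + config.B.loc["intercept"]
    if np.any(config.sigma_r):
        resid = rng.multivariate_normal(np.zeros(3), config.sigma_r,
                                        size=len(values), method="eigh")
        values = values + resid
    premask = values.copy()
    values = impose_missingness(values, config.sugar_missing_frac, "sugar", seed=rng)

    traits = TraitMatrix.__new__(TraitMatrix)
    traits.data = values
    traits.scale = "logit"
    traits.g100g = inverse_logit(values) * 100.0
    # dry matter = macronutrients + minor solids (ash etc.), for the QC stage
    traits.dry_matter = (traits.g100g.sum(axis=1, skipna=False) + 1.5
                         + 0.3 * rng.standard_normal(len(values)))
    traits.dry_matter.name = "dry_matter"

    dataset = AlignedDataset(tree=tree, traits=traits, covariates=covs)
    vp, vr = np.diag(config.sigma_p), np.diag(config.sigma_r)
    truth = {
        "sigma_p": config.sigma_p,
        "sigma_r": config.sigma_r,
        "B": config.B,
        "h2": vp / (vp + vr),
        "r_p": config.sigma_p / np.sqrt(np.outer(vp, vp)),
        "alpha": config.alpha,
        "shift_edges": [int(e) for e, _ in shifts],
        "shift_deltas": [np.asarray(d) for _, d in shifts],
        "shift_clades": shift_clades,
        "missing_sugar": [s for s in values.index if np.isnan(values.at[s, "sugar"])],
        "masked_sugar_values": {
            s: float(premask.at[s, "sugar"])
            for s in values.index if np.isnan(values.at[s, "sugar"])
        },
    }
    return SyntheticDataset(dataset=dataset, truth=truth)


PRESETS = {
    "paper124": lambda: SimulationConfig(),
    "paper124_shifts": lambda: SimulationConfig(
        alpha=0.07, n_shifts=2, shift_size=8.0, with_covariates=False,
        sigma_r=np.zeros((3, 3)),
    ),
    "bm_null": lambda: SimulationConfig(
        alpha=0.0, n_shifts=0, with_covariates=False,
        sigma_r=np.zeros((3, 3)), sugar_missing_frac=0.0,
    ),
    "tiny": lambda: SimulationConfig(
        n_tips=16, sugar_missing_frac=0.125, with_covariates=True,
    ),
}


def make_preset(name: str, seed: int | None = None) -> SyntheticDataset:
    try:
        config = PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return make_dataset(config, seed=seed)
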