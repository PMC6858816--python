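"""Scalar Ornstein-Uhlenbeck shift-regime detection, optima, and imputation.

Model: all traits follow an OU process with one shared selection strength
alpha and a trait rate matrix R; "shifts" are instantaneous jumps of the
optimum vector theta placed at the start of internal edges, so every shift
defines a selective regime for the clade below it.  For an edge e starting at
depth t_e, a jump delta contributes delta * (1 - exp(-alpha (d_i - t_e))) to
the expected value of each tip i below e, and tip covariance is

    cov(i, j) = R * exp(-alpha (d_i + d_j - 2 t_ij)) (1 - exp(-2 alpha t_ij)) / (2 alpha)

with t_ij the root-to-MRCA depth.  At alpha = 0 this is exactly Brownian
motion with step changes in the mean.  Because the mean is linear in (root,
jumps) and the covariance separates as kron(R, C(alpha)), the maximum
likelihood fit for a fixed shift configuration is closed-form GLS; shift
locations are searched greedily per alpha on a profile-likelihood grid, and
the number of shifts K is chosen by a BIC-style penalized likelihood.
Missing trait cells are imputed as conditional expectations under the fitted
Gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from phylomilk.core import Phylogeny
from phylomilk.simulate import scou_tip_moment_matrices
from phylomilk.transforms import inverse_logit


def half_life(alpha: float, tree_height: float = 1.0) -> float:
    """Phylogenetic half-life ln(2) / (alpha * height), in tree-height units."""
    if alpha <= 0:
        warnings.warn("alpha <= 0: half-life is infinite (Brownian motion)", stacklevel=2)
        return float("inf")
    return float(np.log(2.0) / (alpha * tree_height))


def back_transform_optima(theta_logit):
    """Logit-scale optima back to raw percentages (g/100 g)."""
    return inverse_logit(theta_logit) * 100.0


def shift_design(tree: Phylogeny, shift_edges, alpha: float) -> np.ndarray:
    """n x (K+1) mean design: intercept column plus one jump column per shift.

    Column j+1 is 1 - exp(-alpha (d_tip - t_e)) for tips below shift edge e
    (1 when alpha = 0), zero elsewhere.
    """
    below = tree.tips_below()
    depths = tree.node_depths()
    tipd = depths[tree.tip_indices]
    n = tree.n_tips
    U = np.ones((n, len(shift_edges) + 1))
    for j, e in enumerate(shift_edges):
        e = int(e)
        if e <= 0 or e >= tree.n_nodes:
            raise ValueError(f"shift edge {e} does not exist")
        mask = below[e]
        col = np.zeros(n)
        if alpha == 0.0:
            col[mask] = 1.0
        else:
            col[mask] = 1.0 - np.exp(-alpha * (tipd[mask] - depths[tree.parent[e]]))
        U[:, j + 1] = col
    return U


def tip_coloring(tree: Phylogeny, shift_edges) -> np.ndarray:
    """Regime index per tip: 0 for the root regime, j for shift j; the most
    recent (smallest-clade) shift on a tip's root path wins."""
    below = tree.tips_below()
    color = np.zeros(tree.n_tips, dtype=int)
    order = sorted(range(len(shift_edges)),
                   key=lambda j: -int(below[int(shift_edges[j])].sum()))
    for j in order:
        color[below[int(shift_edges[j])]] = j + 1
    return color


def _coloring_valid(tree, shift_edges, below=None) -> bool:
    color = tip_coloring(tree, shift_edges)
    return len(np.unique(color)) == len(shift_edges) + 1


def scou_loglik(Y, tree: Phylogeny, shifts, root, alpha: float, rates,
                jitter: float = 1e-10) -> float:
    """Exact Gaussian log-likelihood of observed tip cells under scalar OU.

    ``shifts`` is a sequence of ``(edge, delta_vector)``; missing cells are
    marginalized by row selection.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = Y.shape
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    edges = [int(e) for e, _ in shifts]
    U = shift_design(tree, edges, alpha)
    coef = np.vstack([np.broadcast_to(np.asarray(root, float), (k,))]
                     + [np.broadcast_to(np.asarray(d, float), (k,)) for _, d in shifts])
    mu = (U @ coef).T.ravel()
    C = scou_tip_moment_matrices(tree, alpha)
    V = np.kron(rates, C)
    obs = ~np.isnan(Y.T.ravel())
    Vs = V[np.ix_(obs, obs)]
    Vs = Vs + jitter * max(np.mean(np.diag(Vs)), 1e-300) * np.eye(Vs.shape[0])
    r = Y.T.ravel()[obs] - mu[obs]
    cf = cho_factor(Vs, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    quad = float(r @ cho_solve(cf, r))
    m = int(obs.sum())
    return -0.5 * (m * np.log(2.0 * np.pi) + logdet + quad)


# ---------------------------------------------------------------------------
# Per-alpha GLS workspace
# ---------------------------------------------------------------------------


class _AlphaWorkspace:
    """Precomputed quantities making every candidate-edge GLS O(K^3)."""

    def __init__(self, tree: Phylogeny, Y: np.ndarray, alpha: float,
                 candidates, jitter: float = 1e-9):
        self.alpha = alpha
        self.candidates = list(candidates)
        self.pos = {e: i + 1 for i, e in enumerate(self.candidates)}
        C = scou_tip_moment_matrices(tree, alpha)
        C = C + jitter * max(np.mean(np.diag(C)), 1e-300) * np.eye(len(C))
        self.cf = cho_factor(C, lower=True)
        self.logdetC = 2.0 * float(np.sum(np.log(np.diag(self.cf[0]))))
        Ufull = np.ones((tree.n_tips, len(self.candidates) + 1))
        Uc = shift_design(tree, self.candidates, alpha)
        Ufull[:, 1:] = Uc[:, 1:]
        W = cho_solve(self.cf, Ufull)
        self.G = Ufull.T @ W
        self.U = Ufull
        self.set_response(Y)
        self.n = tree.n_tips

    def set_response(self, Y: np.ndarray) -> None:
        self.Y = Y
        MY = cho_solve(self.cf, Y)
        self.GY = self.U.T @ MY
        self.YMY = Y.T @ MY

    def gls(self, edges):
        """(coef, rates, loglik) for the shift set ``edges`` (complete data)."""
        idx = [0] + [self.pos[e] for e in edges]
        G = self.G[np.ix_(idx, idx)]
        rhs = self.GY[idx]
        try:
            coef = np.linalg.solve(G, rhs)
        except np.linalg.LinAlgError:
            return None
        n, k = self.Y.shape
        R = (self.YMY - rhs.T @ coef) / n
        R = (R + R.T) / 2.0
        sign, logdetR = np.linalg.slogdet(R + 1e-12 * np.trace(R) / k * np.eye(k))
        if sign <= 0:
            return None
        ll = -0.5 * (n * k * np.log(2.0 * np.pi) + k * self.logdetC
                     + n * logdetR + n * k)
        return coef, R, float(ll)


def _candidate_edges(tree: Phylogeny, min_clade: int = 1):
    """Internal non-root edges whose clade keeps at least min_clade tips on
    both sides."""
    below = tree.tips_below()
    n = tree.n_tips
    return [
        i for i in range(1, tree.n_nodes)
        if not tree.is_tip[i]
        and min_clade <= below[i].sum() <= n - min_clade
    ]


def _best_addition(ws: _AlphaWorkspace, tree, chosen):
    """Best single edge to add to ``chosen``, or None."""
    best = None
    for e in ws.candidates:
        if e in chosen:
            continue
        trial = list(chosen) + [e]
        if not _coloring_valid(tree, trial):
            continue
        res = ws.gls(trial)
        if res is None:
            continue
        if best is None or res[2] > best[1]:
            best = (e, res[2])
    return best


def _greedy_path(ws: _AlphaWorkspace, tree, K_max: int, first_edge=None):
    """Forward selection of shift edges; returns nested (edges, loglik) per K."""
    chosen: list[int] = []
    out = []
    base = ws.gls(chosen)
    if base is None:
        return []
    out.append((tuple(chosen), base[2]))
    if first_edge is not None and K_max > 0:
        res = ws.gls([first_edge])
        if res is None or not _coloring_valid(tree, [first_edge]):
            return out
        chosen = [first_edge]
        out.append((tuple(chosen), res[2]))
    while len(chosen) < K_max:
        best = _best_addition(ws, tree, chosen)
        if best is None:
            break
        chosen.append(best[0])
        out.append((tuple(chosen), best[1]))
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class ShiftFit:
    """A fitted shift configuration with optima, rates and imputations."""

    K: int
    shift_edges: tuple
    shift_clades: list  # frozenset of tip names per shift
    alpha: float
    root_state: np.ndarray
    deltas: np.ndarray  # K x k optimum jumps (mean steps when alpha == 0)
    optima: pd.DataFrame  # (K+1) regimes x traits, logit scale
    optima_percent: pd.DataFrame
    rates: np.ndarray
    loglik: float
    tip_regimes: pd.Series
    imputed: pd.DataFrame  # conditional means at missing cells, NaN elsewhere
    criterion_curve: pd.DataFrame | None = None
    equivalence: list = field(default_factory=list)
    trait_names: list = field(default_factory=list)

    @property
    def phylo_half_life(self) -> float:
        return half_life(self.alpha)


def default_alpha_grid():
    """Profile grid for the selection strength on a unit-height tree."""
    return np.concatenate([[0.0], np.logspace(-3, np.log10(50.0), 7)])


def _initial_completion(Y: np.ndarray, tree: Phylogeny, n_iter: int = 6) -> np.ndarray:
    """Fill missing cells by EM under intercept-only Brownian motion."""
    if not np.isnan(Y).any():
        return Y
    ws = None
    filled = Y.copy()
    col_means = np.nanmean(Y, axis=0)
    miss = np.isnan(Y)
    filled[miss] = np.take(col_means, np.where(miss)[1])
    C = scou_tip_moment_matrices(tree, 0.0)
    for _ in range(n_iter):
        if ws is None:
            ws = _AlphaWorkspace(tree, filled, 0.0, [])
        else:
            ws.set_response(filled)
        res = ws.gls([])
        if res is None:
            break
        coef, R, _ = res
        filled = _conditional_mean_fill(Y, np.ones((len(Y), 1)) @ coef[:1], R, C)
    return filled


def _conditional_mean_fill(Y, mu, R, C, jitter=1e-10):
    """Replace NaN cells of Y by E[missing | observed] under N(mu, kron(R, C))."""
    n, k = Y.shape
    vec = Y.T.ravel()
    muv = np.asarray(mu).T.ravel()
    obs = ~np.isnan(vec)
    if obs.all():
        return Y.copy()
    V = np.kron(R, C)
    Voo = V[np.ix_(obs, obs)]
    Voo = Voo + jitter * max(np.mean(np.diag(Voo)), 1e-300) * np.eye(Voo.shape[0])
    Vmo = V[np.ix_(~obs, obs)]
    cf = cho_factor(Voo, lower=True)
    fill = muv[~obs] + Vmo @ cho_solve(cf, vec[obs] - muv[obs])
    out = vec.copy()
    out[~obs] = fill
    return out.reshape(k, n).T


def _refit_em(Y, tree, edges, alpha, n_iter=25, tol=1e-9):
    """GLS/imputation iterations for one configuration; exact final loglik."""
    C = scou_tip_moment_matrices(tree, alpha)
    filled = _initial_completion(Y, tree)
    ws = _AlphaWorkspace(tree, filled, alpha, list(edges))
    U = shift_design(tree, list(edges), alpha)
    prev = -np.inf
    coef = R = None
    has_missing = np.isnan(Y).any()
    for _ in range(n_iter if has_missing else 1):
        res = ws.gls(list(edges))
        if res is None:
            raise RuntimeError("singular GLS system in shift refit")
        coef, R, ll = res
        if not has_missing or abs(ll - prev) < tol:
            prev = ll
            break
        prev = ll
        filled = _conditional_mean_fill(Y, U @ coef, R, C)
        ws.set_response(filled)
    shifts = [(e, coef[j + 1]) for j, e in enumerate(edges)]
    exact_ll = scou_loglik(Y, tree, shifts, coef[0], alpha, R)
    imputed = _conditional_mean_fill(Y, U @ coef, R, C)
    return coef, R, exact_ll, imputed


def _n_params(K: int, k: int) -> int:
    # regime optima (K+1 rows) + rate matrix + alpha
    return (K + 1) * k + k * (k + 1) // 2 + 1


def fit_shifts_em(
    traits,
    tree: Phylogeny,
    K: int,
    alpha_grid=None,
    seed: int | None = None,
    n_restarts: int = 2,
    min_clade: int = 1,
) -> ShiftFit:
    """Fit a K-shift scalar-OU model (profile grid over alpha, greedy shifts).

    ``traits`` is a species x traits frame on the logit scale (NaN allowed).
    """
    fit = _search(traits, tree, K_max=K, alpha_grid=alpha_grid, seed=seed,
                  n_restarts=n_restarts, min_clade=min_clade)
    return _finalize(traits, tree, fit["per_k"][K], fit, K)


def select_K(
    traits,
    tree: Phylogeny,
    K_max: int = 8,
    alpha_grid=None,
    seed: int | None = None,
    n_restarts: int = 2,
    min_clade: int = 1,
    criterion: str = "bic",
) -> ShiftFit:
    """Fit K = 0..K_max and select K by penalized likelihood (BIC-style).

    The full criterion curve is kept on the returned fit so near-ties between
    neighboring K are visible.
    """
    if criterion != "bic":
        raise ValueError("only the BIC-style criterion is implemented")
    search = _search(traits, tree, K_max=K_max, alpha_grid=alpha_grid, seed=seed,
                     n_restarts=n_restarts, min_clade=min_clade)
    Y = _as_matrix(traits)
    n_obs = int((~np.isnan(Y)).sum())
    k = Y.shape[1]
    n_edges = len(_candidate_edges(tree, min_clade))
    rows = []
    for K in range(K_max + 1):
        edges, alpha, _ = search["per_k"][K]
        coef, R, ll, _ = _refit_em(Y, tree, edges, alpha)
        # BIC plus a Birge-Massart-style complexity term for the number of
        # K-edge shift configurations, without which tree-structured Brownian
        # means are routinely over-segmented
        pen = (_n_params(K, k) * np.log(n_obs)
               + 2.0 * np.log(comb(n_edges, K)))
        rows.append({"K": K, "alpha": alpha, "loglik": ll,
                     "criterion": -2.0 * ll + pen})
    curve = pd.DataFrame(rows)
    K_best = int(curve.loc[curve["criterion"].idxmin(), "K"])
    fit = _finalize(traits, tree, search["per_k"][K_best], search, K_best)
    fit.criterion_curve = curve
    return fit


def _as_matrix(traits) -> np.ndarray:
    df = traits.data if hasattr(traits, "data") else traits
    return np.asarray(df, dtype=float)


def _trait_frame(traits) -> pd.DataFrame:
    return traits.data if hasattr(traits, "data") else traits


def _search(traits, tree, K_max, alpha_grid, seed, n_restarts, min_clade):
    Y = _as_matrix(traits)
    grid = default_alpha_grid() if alpha_grid is None else np.asarray(alpha_grid, float)
    candidates = _candidate_edges(tree, min_clade)
    if K_max > len(candidates):
        raise ValueError(f"K={K_max} exceeds the {len(candidates)} internal edges")
    filled = _initial_completion(Y, tree)
    rng = np.random.default_rng(seed)
    per_k: dict[int, tuple] = {}
    improved = False
    workspaces: dict[float, _AlphaWorkspace] = {}
    for alpha in grid:
        ws = _AlphaWorkspace(tree, filled, float(alpha), candidates)
        workspaces[float(alpha)] = ws
        starts = [None]
        if n_restarts > 0 and K_max > 0:
            singles = sorted(
                (e for e in candidates if ws.gls([e]) is not None),
                key=lambda e: -ws.gls([e])[2],
            )[:10]
            for _ in range(n_restarts):
                if singles:
                    starts.append(int(rng.choice(singles)))
        for first in starts:
            path = _greedy_path(ws, tree, K_max, first_edge=first)
            for Kp, (edges, ll) in enumerate(path):
                if Kp not in per_k or ll > per_k[Kp][2]:
                    per_k[Kp] = (edges, float(alpha), ll)
                    improved = True
    if not improved and K_max > 0:
        raise RuntimeError("shift search failed to improve over any start")
    # nested-improvement guard: extend the best (K-1)-set if a restart path
    # terminated early and left a gap
    for K in range(1, K_max + 1):
        prev = per_k.get(K - 1)
        cur = per_k.get(K)
        if prev is not None and (cur is None or cur[2] < prev[2] - 1e-9):
            ws = workspaces[prev[1]]
            best = _best_addition(ws, tree, list(prev[0]))
            if best is not None:
                per_k[K] = (tuple(list(prev[0]) + [best[0]]), prev[1], best[1])
    for K in range(K_max + 1):
        if K not in per_k:
            raise RuntimeError(f"no valid {K}-shift configuration found")
    return {"per_k": per_k, "grid": grid, "Y": Y}


def _finalize(traits, tree, chosen, search, K) -> ShiftFit:
    frame = _trait_frame(traits)
    trait_names = list(frame.columns)
    Y = search["Y"]
    edges, alpha, _ = chosen
    coef, R, ll, imputed_full = _refit_em(Y, tree, edges, alpha)
    k = Y.shape[1]
    below = tree.tips_below()
    tips = np.array(tree.tip_labels)
    clades = [frozenset(tips[below[int(e)]]) for e in edges]
    # regime optima: accumulate ancestral jumps (shift chains may be nested)
    names = ["root"] + [f"shift_{j + 1}" for j in range(K)]
    optima = np.empty((K + 1, k))
    optima[0] = coef[0]
    for j, e in enumerate(edges):
        anc = [m for m, e2 in enumerate(edges)
               if m != j and below[int(e2)][below[int(e)]].all()]
        optima[j + 1] = coef[0] + coef[j + 1] + sum(coef[m + 1] for m in anc)
    optima_df = pd.DataFrame(optima, index=names, columns=trait_names)
    color = tip_coloring(tree, edges)
    imputed = pd.DataFrame(np.where(np.isnan(Y), imputed_full, np.nan),
                           index=frame.index, columns=trait_names)
    equivalence = equivalent_solutions(tree, edges)
    edges = tuple(int(e) for e in (equivalence[0] if equivalence else edges))
    return ShiftFit(
        K=K,
        shift_edges=edges,
        shift_clades=clades,
        alpha=float(alpha),
        root_state=coef[0].copy(),
        deltas=coef[1:].copy(),
        optima=optima_df,
        optima_percent=back_transform_optima(optima_df),
        rates=R,
        loglik=float(ll),
        tip_regimes=pd.Series(color, index=frame.index, name="regime"),
        imputed=imputed,
        equivalence=equivalence,
        trait_names=trait_names,
    )


# ---------------------------------------------------------------------------
# Degeneracy
# ---------------------------------------------------------------------------


def _partition_key(tree: Phylogeny, edges) -> frozenset:
    color = tip_coloring(tree, edges)
    return frozenset(frozenset(np.flatnonzero(color == c)) for c in np.unique(color))


def equivalent_solutions(tree: Phylogeny, shift_edges, max_exhaustive: int = 20000):
    """All shift-edge sets yielding the identical tip-to-regime partition.

    Small problems are enumerated exhaustively; larger ones are explored by
    closure over single-edge substitutions.  The list is sorted so the
    lexicographically smallest solution comes first.
    """
    edges = tuple(sorted(int(e) for e in shift_edges))
    K = len(edges)
    if K == 0:
        return [()]
    target = _partition_key(tree, edges)
    candidates = _candidate_edges(tree, 1)
    found = {edges}
    if comb(len(candidates), K) <= max_exhaustive:
        for combo in combinations(candidates, K):
            if _partition_key(tree, combo) == target:
                found.add(tuple(sorted(combo)))
    else:
        frontier = [edges]
        while frontier:
            current = frontier.pop()
            for i in range(K):
                for e in candidates:
                    if e in current:
                        continue
                    trial = tuple(sorted(current[:i] + (e,) + current[i + 1:]))
                    if trial in found:
                        continue
                    if _partition_key(tree, trial) == target:
                        found.add(trial)
                        frontier.append(trial)
    return sorted(found)
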