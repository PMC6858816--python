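"""Trivariate phylogenetic mixed model with ecological fixed effects.

The model for the n x k matrix Y of logit-scale milk concentrations is

    vec(Y) ~ N( vec(X B),  Sigma_P (x) A  +  Sigma_R (x) I_n )

where X is the n x 9 ecological design, B the 9 x k fixed-effect matrix, A
the Brownian phylogenetic covariance of the (unit-height) tree, Sigma_P the
phylogenetic and Sigma_R the residual trait covariance, and (x) the Kronecker
product (trait-major stacking).  Missing trait cells are marginalized exactly
by row selection of the stacked Gaussian rather than imputed.

Derived quantities: phylogenetic heritability h2_t = Sigma_P[tt] /
(Sigma_P[tt] + Sigma_R[tt]) and phylogenetic / residual correlations.

Two inference backends share one contract: a deterministic maximum-likelihood
path (quasi-Newton on a log-Cholesky parameterization, fixed effects profiled
out by GLS) with Wald intervals for B and an optional parametric bootstrap
for covariance-derived quantities; and an ensemble MCMC backend (emcee) with
weakly informative priors, whose two-sided tail fractions give MCMC-style
p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from phylomilk.core import AlignedDataset, CovariateTable, DIET_LEVELS, phylo_covariance

COEF_NAMES = (
    "intercept", "arid", "aquatic", "diet_omnivore", "diet_carnivore",
    "female_mass", "rep_output", "lactation_length", "precociality",
)


def build_design(covs: CovariateTable):
    """Fixed-effect design matrix in the canonical column order.

    Diet enters as two dummies with herbivore as the reference level; ordinal
    predictors enter as numeric scores.  Returns ``(X, names)``.
    """
    df = covs.data
    if df.isna().any().any():
        bad = list(df.index[df.isna().any(axis=1)])
        raise ValueError(f"missing covariates for: {', '.join(map(str, bad[:5]))}")
    unseen = set(df["diet"]) - set(DIET_LEVELS)
    if unseen:
        raise ValueError(f"unseen diet level(s): {sorted(unseen)}")
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["arid"].to_numpy(float),
            df["aquatic"].to_numpy(float),
            (df["diet"] == "omnivore").to_numpy(float),
            (df["diet"] == "carnivore").to_numpy(float),
            df["female_mass"].to_numpy(float),
            df["rep_output"].to_numpy(float),
            df["lactation_length"].to_numpy(float),
            df["precociality"].to_numpy(float),
        ]
    )
    return X, list(COEF_NAMES)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _stacked_system(Y: np.ndarray, X: np.ndarray, A: np.ndarray,
                    sigma_p: np.ndarray, sigma_r: np.ndarray, jitter: float = 1e-8):
    """Selected (observed-cell) covariance, design and response of vec(Y)."""
    n, k = Y.shape
    obs = ~np.isnan(Y.T.ravel())  # trait-major stacking
    V = np.kron(sigma_p, A) + np.kron(sigma_r, np.eye(n))
    Vs = V[np.ix_(obs, obs)]
    Vs = Vs + jitter * max(np.mean(np.diag(Vs)), 1e-12) * np.eye(Vs.shape[0])
    Xs = np.kron(np.eye(k), X)[obs]
    ys = Y.T.ravel()[obs]
    return ys, Xs, Vs, obs


def pmm_loglik(Y, X, A, sigma_p, sigma_r, B, jitter: float = 1e-8) -> float:
    """Exact Gaussian log-likelihood of the observed trait cells.

    ``Y`` is n x k with NaN for missing cells; ``B`` is p x k.
    """
    Y = np.asarray(Y, dtype=float)
    B = np.asarray(B, dtype=float)
    ys, _, Vs, obs = _stacked_system(Y, X, A, np.asarray(sigma_p, float),
                                     np.asarray(sigma_r, float), jitter)
    mu = (X @ B).T.ravel()[obs]
    try:
        cf = cho_factor(Vs, lower=True)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("covariance not positive definite after jitter") from err
    r = ys - mu
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    quad = float(r @ cho_solve(cf, r))
    m = len(ys)
    return -0.5 * (m * np.log(2.0 * np.pi) + logdet + quad)


def _gls(ys, Xs, Vs):
    """GLS coefficients, their covariance, and the profile log-likelihood."""
    cf = cho_factor(Vs, lower=True)
    Vx = cho_solve(cf, Xs)
    XtVX = Xs.T @ Vx
    XtVy = Vx.T @ ys
    cov_b = np.linalg.inv(XtVX)
    beta = cov_b @ XtVy
    r = ys - Xs @ beta
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    quad = float(r @ cho_solve(cf, r))
    m = len(ys)
    ll = -0.5 * (m * np.log(2.0 * np.pi) + logdet + quad)
    return beta, cov_b, ll


# log-Cholesky parameterization of a k x k covariance ------------------------


def _n_chol(k: int) -> int:
    return k * (k + 1) // 2


def _chol_unpack(params, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    idx = 0
    for i in range(k):
        for j in range(i + 1):
            L[i, j] = np.exp(params[idx]) if i == j else params[idx]
            idx += 1
    return L


def _chol_pack(S: np.ndarray) -> np.ndarray:
    k = S.shape[0]
    L = np.linalg.cholesky(S + 1e-10 * np.eye(k))
    out = []
    for i in range(k):
        for j in range(i + 1):
            out.append(np.log(L[i, i]) if i == j else L[i, j])
    return np.array(out)


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------


@dataclass
class PMMFit:
    """Point estimates, intervals and diagnostics of a fitted mixed model."""

    B: pd.DataFrame
    B_low: pd.DataFrame
    B_high: pd.DataFrame
    B_p: pd.DataFrame
    sigma_p: pd.DataFrame
    sigma_r: pd.DataFrame
    h2: pd.Series
    r_p: pd.DataFrame
    r_r: pd.DataFrame
    intervals: dict  # name -> (low, high) for h2/r entries
    loglik: float
    backend: str
    n_species: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def trait_names(self) -> list:
        return list(self.B.columns)


def _derived(sigma_p: np.ndarray, sigma_r: np.ndarray):
    vp, vr = np.diag(sigma_p), np.diag(sigma_r)
    h2 = vp / np.maximum(vp + vr, 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_p = sigma_p / np.sqrt(np.maximum(np.outer(vp, vp), 1e-300))
        r_r = sigma_r / np.sqrt(np.maximum(np.outer(vr, vr), 1e-300))
    return h2, np.clip(r_p, -1, 1), np.clip(r_r, -1, 1)


def _pair_names(traits):
    return [(traits[i], traits[j]) for i in range(len(traits)) for j in range(i + 1, len(traits))]


# ---------------------------------------------------------------------------
# ML backend
# ---------------------------------------------------------------------------


def _ml_objective(Y, X, A, include_residual, jitter):
    k = Y.shape[1]
    nc = _n_chol(k)

    def unpack(theta):
        Lp = _chol_unpack(theta[:nc], k)
        sp = Lp @ Lp.T
        if include_residual:
            Lr = _chol_unpack(theta[nc:], k)
            sr = Lr @ Lr.T
        else:
            sr = np.zeros((k, k))
        return sp, sr

    def nll(theta):
        sp, sr = unpack(theta)
        try:
            ys, Xs, Vs, _ = _stacked_system(Y, X, A, sp, sr, jitter)
            _, _, ll = _gls(ys, Xs, Vs)
        except np.linalg.LinAlgError:
            return 1e10
        return -ll if np.isfinite(ll) else 1e10

    return nll, unpack


def _ml_point_fit(Y, X, A, include_residual=True, jitter=1e-8, theta0=None):
    n, k = Y.shape
    nc = _n_chol(k)
    nll, unpack = _ml_objective(Y, X, A, include_residual, jitter)
    if theta0 is None:
        # moment start: split the OLS residual covariance between the two parts
        Bols = np.linalg.lstsq(X, np.nan_to_num(Y, nan=np.nanmean(Y)), rcond=None)[0]
        R = np.nan_to_num(Y - X @ Bols, nan=0.0)
        S = np.atleast_2d(np.cov(R.T)) + 1e-6 * np.eye(k)
        mean_diag_a = float(np.mean(np.diag(A)))
        theta0 = _chol_pack(0.5 * S / max(mean_diag_a, 1e-12))
        if include_residual:
            theta0 = np.concatenate([theta0, _chol_pack(0.5 * S)])
    best = None
    for attempt, start in enumerate([theta0, theta0 + 0.3]):
        res = optimize.minimize(nll, start, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    sp, sr = unpack(best.x)
    ys, Xs, Vs, obs = _stacked_system(Y, X, A, sp, sr, jitter)
    beta, cov_b, ll = _gls(ys, Xs, Vs)
    return {
        "sigma_p": sp, "sigma_r": sr, "beta": beta, "cov_b": cov_b,
        "loglik": ll, "theta": best.x, "success": bool(best.success),
        "message": str(best.message), "n_eval": int(best.nfev),
    }


def _fit_ml(Y, X, A, trait_names, coef_names, n_boot, seed, include_residual, jitter):
    n, k = Y.shape
    p = X.shape[1]
    fit = _ml_point_fit(Y, X, A, include_residual, jitter)
    if not fit["success"]:
        raise RuntimeError(f"PMM optimizer did not converge: {fit['message']}")
    B = fit["beta"].reshape(k, p).T
    se = np.sqrt(np.diag(fit["cov_b"])).reshape(k, p).T
    z = np.where(se > 0, B / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    B_low, B_high = B - 1.96 * se, B + 1.96 * se
    h2, r_p, r_r = _derived(fit["sigma_p"], fit["sigma_r"])

    intervals = {}
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = {"h2": [], "r_p": [], "r_r": []}
        mask = np.isnan(Y)
        V = np.kron(fit["sigma_p"], A) + np.kron(fit["sigma_r"], np.eye(n))
        mu = (X @ B).T.ravel()
        L = np.linalg.cholesky(V + 1e-10 * np.mean(np.diag(V)) * np.eye(n * k))
        for _ in range(n_boot):
            yb = (mu + L @ rng.standard_normal(n * k)).reshape(k, n).T
            yb[mask] = np.nan
            try:
                bf = _ml_point_fit(yb, X, A, include_residual, jitter, theta0=fit["theta"])
            except (np.linalg.LinAlgError, RuntimeError):
                continue
            bh2, brp, brr = _derived(bf["sigma_p"], bf["sigma_r"])
            draws["h2"].append(bh2)
            draws["r_p"].append(brp)
            draws["r_r"].append(brr)
        if draws["h2"]:
            h2d = np.array(draws["h2"])
            for t, name in enumerate(trait_names):
                intervals[f"h2_{name}"] = tuple(np.quantile(h2d[:, t], [0.025, 0.975]))
            for mat, tag in ((np.array(draws["r_p"]), "r_p"), (np.array(draws["r_r"]), "r_r")):
                for i, j in [(i, j) for i in range(k) for j in range(i + 1, k)]:
                    key = f"{tag}_{trait_names[i]}_{trait_names[j]}"
                    intervals[key] = tuple(np.quantile(mat[:, i, j], [0.025, 0.975]))
    if not intervals:  # degenerate intervals at the point estimate
        for t, name in enumerate(trait_names):
            intervals[f"h2_{name}"] = (float(h2[t]), float(h2[t]))
        for mat, tag in ((r_p, "r_p"), (r_r, "r_r")):
            for i, j in [(i, j) for i in range(k) for j in range(i + 1, k)]:
                intervals[f"{tag}_{trait_names[i]}_{trait_names[j]}"] = (
                    float(mat[i, j]), float(mat[i, j]))

    idx = pd.Index(coef_names, name="term")
    return PMMFit(
        B=pd.DataFrame(B, index=idx, columns=trait_names),
        B_low=pd.DataFrame(B_low, index=idx, columns=trait_names),
        B_high=pd.DataFrame(B_high, index=idx, columns=trait_names),
        B_p=pd.DataFrame(pvals, index=idx, columns=trait_names),
        sigma_p=pd.DataFrame(fit["sigma_p"], index=trait_names, columns=trait_names),
        sigma_r=pd.DataFrame(fit["sigma_r"], index=trait_names, columns=trait_names),
        h2=pd.Series(h2, index=trait_names, name="h2"),
        r_p=pd.DataFrame(r_p, index=trait_names, columns=trait_names),
        r_r=pd.DataFrame(r_r, index=trait_names, columns=trait_names),
        intervals=intervals,
        loglik=float(fit["loglik"]),
        backend="ml",
        n_species=n,
        converged=True,
        diagnostics={"n_eval": fit["n_eval"], "message": fit["message"],
                     "n_boot": int(n_boot or 0)},
    )


# ---------------------------------------------------------------------------
# MCMC backend (emcee)
# ---------------------------------------------------------------------------


def _fit_mcmc(Y, X, A, trait_names, coef_names, seed, include_residual, jitter,
              n_steps, n_burn):
    import emcee

    n, k = Y.shape
    p = X.shape[1]
    nc = _n_chol(k)
    ml = _ml_point_fit(Y, X, A, include_residual, jitter)
    ndim = p * k + nc * (2 if include_residual else 1)

    def log_prob(theta):
        b = theta[: p * k]
        cov_theta = theta[p * k:]
        # weakly informative priors: B ~ N(0, 5^2), Cholesky params ~ N(0, 2^2)
        lp = -0.5 * np.sum((b / 5.0) ** 2) - 0.5 * np.sum((cov_theta / 2.0) ** 2)
        Lp = _chol_unpack(cov_theta[:nc], k)
        sp = Lp @ Lp.T
        sr = np.zeros((k, k))
        if include_residual:
            Lr = _chol_unpack(cov_theta[nc:], k)
            sr = Lr @ Lr.T
        B = b.reshape(k, p).T
        try:
            ll = pmm_loglik(Y, X, A, sp, sr, B, jitter)
        except np.linalg.LinAlgError:
            return -np.inf
        return lp + ll if np.isfinite(ll) else -np.inf

    rng = np.random.default_rng(seed)
    center = np.concatenate([ml["beta"], ml["theta"]])
    nwalkers = max(2 * ndim + 2, 64)
    p0 = center + 0.01 * rng.standard_normal((nwalkers, ndim))
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob,
                                    moves=emcee.moves.StretchMove())
    sampler.random_state = np.random.RandomState(int(rng.integers(2**31))).get_state()
    state = sampler.run_mcmc(p0, n_burn, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, n_steps, progress=False)
    chain = sampler.get_chain(flat=True, thin=4)

    Bd = chain[:, : p * k].reshape(-1, k, p).transpose(0, 2, 1)  # draws x p x k
    sp_d = np.empty((len(chain), k, k))
    sr_d = np.zeros((len(chain), k, k))
    for m in range(len(chain)):
        Lp = _chol_unpack(chain[m, p * k: p * k + nc], k)
        sp_d[m] = Lp @ Lp.T
        if include_residual:
            Lr = _chol_unpack(chain[m, p * k + nc:], k)
            sr_d[m] = Lr @ Lr.T

    B_med = np.median(Bd, axis=0)
    B_low = np.quantile(Bd, 0.025, axis=0)
    B_high = np.quantile(Bd, 0.975, axis=0)
    frac_pos = (Bd > 0).mean(axis=0)
    pvals = np.clip(2.0 * np.minimum(frac_pos, 1.0 - frac_pos), 1.0 / len(chain), 1.0)

    h2_d = np.array([_derived(sp_d[m], sr_d[m])[0] for m in range(len(chain))])
    rp_d = np.array([_derived(sp_d[m], sr_d[m])[1] for m in range(len(chain))])
    rr_d = np.array([_derived(sp_d[m], sr_d[m])[2] for m in range(len(chain))])
    sp_mean, sr_mean = sp_d.mean(axis=0), sr_d.mean(axis=0)
    h2 = np.median(h2_d, axis=0)
    r_p = np.clip(np.median(rp_d, axis=0), -1, 1)
    r_r = np.clip(np.median(rr_d, axis=0), -1, 1)
    np.fill_diagonal(r_p, 1.0)
    np.fill_diagonal(r_r, 1.0)

    intervals = {}
    for t, name in enumerate(trait_names):
        intervals[f"h2_{name}"] = tuple(np.quantile(h2_d[:, t], [0.025, 0.975]))
    for mat, tag in ((rp_d, "r_p"), (rr_d, "r_r")):
        for i, j in [(i, j) for i in range(k) for j in range(i + 1, k)]:
            intervals[f"{tag}_{trait_names[i]}_{trait_names[j]}"] = tuple(
                np.quantile(mat[:, i, j], [0.025, 0.975]))

    idx = pd.Index(coef_names, name="term")
    mean_lp = float(np.mean(sampler.get_log_prob(flat=True)))
    try:
        act = float(np.mean(sampler.get_autocorr_time(quiet=True)))
    except Exception:
        act = float("nan")
    return PMMFit(
        B=pd.DataFrame(B_med, index=idx, columns=trait_names),
        B_low=pd.DataFrame(B_low, index=idx, columns=trait_names),
        B_high=pd.DataFrame(B_high, index=idx, columns=trait_names),
        B_p=pd.DataFrame(pvals, index=idx, columns=trait_names),
        sigma_p=pd.DataFrame(sp_mean, index=trait_names, columns=trait_names),
        sigma_r=pd.DataFrame(sr_mean, index=trait_names, columns=trait_names),
        h2=pd.Series(h2, index=trait_names, name="h2"),
        r_p=pd.DataFrame(r_p, index=trait_names, columns=trait_names),
        r_r=pd.DataFrame(r_r, index=trait_names, columns=trait_names),
        intervals=intervals,
        loglik=float(ml["loglik"]),
        backend="mcmc",
        n_species=n,
        converged=True,
        diagnostics={"n_draws": int(len(chain)), "mean_log_posterior": mean_lp,
                     "autocorr_time": act},
    )


# ---------------------------------------------------------------------------
# Public fit
# ---------------------------------------------------------------------------


def fit_pmm(
    data: AlignedDataset,
    backend: str = "ml",
    seed: int | None = None,
    n_boot: int = 0,
    include_residual: bool = True,
    jitter: float = 1e-8,
    min_species: int = 30,
    mcmc_steps: int = 1000,
    mcmc_burn: int = 400,
) -> PMMFit:
    """Fit the trivariate phylogenetic mixed model on logit-scale traits.

    Species with any missing covariate are excluded (traits with missing
    cells are marginalized, not dropped).  The tree is used at unit height so
    Sigma_P is per-tree-height and heritability scale-free.
    """
    if data.covariates is None:
        raise ValueError("PMM needs a covariate table")
    if data.traits.scale != "logit":
        raise ValueError("traits must be on the logit scale (TraitMatrix.to_logit)")
    keep = data.covariates.complete_cases()
    dropped = [s for s in data.species if s not in keep]
    if dropped:
        warnings.warn(f"{len(dropped)} species without complete covariates excluded "
                      "from the mixed model", stacklevel=2)
    from phylomilk.core import trim_and_align

    sub = data
    if dropped:
        sub = trim_and_align(data.tree, data.traits.restrict(keep),
                             data.covariates.restrict(keep))
    n = sub.n
    if n < min_species:
        raise ValueError(f"only {n} species with complete covariates (< {min_species})")
    from phylomilk.core import scale_tree_height

    tree = scale_tree_height(sub.tree)
    A = phylo_covariance(tree)
    X, names = build_design(sub.covariates)
    Y = sub.traits.data.to_numpy(dtype=float)
    traits = list(sub.traits.data.columns)
    if backend == "ml":
        return _fit_ml(Y, X, A, traits, names, n_boot, seed, include_residual, jitter)
    if backend == "mcmc":
        return _fit_mcmc(Y, X, A, traits, names, seed, include_residual, jitter,
                         mcmc_steps, mcmc_burn)
    raise ValueError(f"unknown backend {backend!r}")


def summarize_pmm(fit: PMMFit):
    """Regression-coefficient and covariance-summary tables.

    The first table has one row per fixed-effect term with estimate, interval
    and p-value per trait; the second is the trait x trait matrix with
    heritabilities on the diagonal, phylogenetic correlations above it and
    residual correlations below.
    """
    blocks = {}
    for t in fit.trait_names:
        blocks[f"{t}_beta"] = fit.B[t]
        blocks[f"{t}_low"] = fit.B_low[t]
        blocks[f"{t}_high"] = fit.B_high[t]
        blocks[f"{t}_p"] = fit.B_p[t]
    coef_table = pd.DataFrame(blocks)

    k = len(fit.trait_names)
    M = np.empty((k, k))
    for i in range(k):
        M[i, i] = fit.h2.iloc[i]
        for j in range(i + 1, k):
            M[i, j] = fit.r_p.iloc[i, j]
            M[j, i] = fit.r_r.iloc[j, i]
    cov_table = pd.DataFrame(M, index=fit.trait_names, columns=fit.trait_names)
    return coef_table, cov_table
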