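"""Quality control, the logit transform, and covariate codings.

Milk macronutrient concentrations are proportions of mass, so they are
modeled on the logit scale where Gaussian trait-evolution models respect the
(0, 1) boundaries.  The quality check regresses dry matter on the sum of the
macronutrients: a milk sample's dry matter should be nearly an affine
function of fat + protein (+ sugar), so large studentized residuals point at
transcription or assay problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from phylomilk.core import CONTINUOUS_COVARIATES, CovariateTable, TraitMatrix

AQUATIC_LEVELS = {"terrestrial": 0, "partly": 1, "mostly": 2, "completely": 3}


def logit(p):
    """ln(p / (1 - p)) for proportions strictly inside (0, 1).

    Accepts scalars, arrays, Series or DataFrames; NaN passes through.
    Values at or outside the boundary raise (no clamping): a true 0 means
    "below detection" and should be treated as missing upstream.
    """
    arr = np.asarray(p, dtype=float) if not isinstance(p, (pd.Series, pd.DataFrame)) else p
    vals = arr.to_numpy() if isinstance(arr, (pd.Series, pd.DataFrame)) else arr
    bad = ~np.isnan(vals) & ((vals <= 0) | (vals >= 1))
    if np.any(bad):
        raise ValueError("logit requires 0 < p < 1")
    if isinstance(arr, (pd.Series, pd.DataFrame)):
        return np.log(arr / (1.0 - arr))
    out = np.log(arr / (1.0 - arr))
    return float(out) if np.isscalar(p) else out


def inverse_logit(x):
    """exp(x) / (1 + exp(x)), mapping the real line onto (0, 1)."""
    from scipy.special import expit

    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(expit(x.to_numpy(dtype=float)), index=x.index,
                            columns=x.columns)
    if isinstance(x, pd.Series):
        return pd.Series(expit(x.to_numpy(dtype=float)), index=x.index, name=x.name)
    out = expit(np.asarray(x, dtype=float))
    return float(out) if np.isscalar(x) else out


def encode_aquatic(category: str) -> int:
    """Ordinal aquatic-adaptation code: terrestrial 0, partly 1, mostly 2, completely 3."""
    try:
        return AQUATIC_LEVELS[str(category).strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown aquatic category {category!r}; expected one of {sorted(AQUATIC_LEVELS)}"
        ) from None


@dataclass
class QCReport:
    """Dry-matter regression diagnostics, sorted by |residual| descending."""

    table: pd.DataFrame  # fitted, residual, studentized, flagged per species
    slope: float
    intercept: float
    r_squared: float
    threshold: float
    use_sugar: bool

    @property
    def flagged(self) -> list:
        return list(self.table.index[self.table["flagged"]])

    def to_csv(self, path) -> None:
        df = self.table.copy()
        df.index.name = "species"
        df.to_csv(path)


def dry_matter_check(
    traits: TraitMatrix, use_sugar: bool = True, threshold: float = 3.0
) -> QCReport:
    """Regress dry matter on the macronutrient sum and flag outliers.

    Species whose |externally studentized residual| exceeds ``threshold`` are
    flagged for inspection; nothing is deleted automatically.
    """
    if traits.dry_matter is None or traits.dry_matter.dropna().empty:
        warnings.warn("no dry-matter values; QC report is empty", stacklevel=2)
        empty = pd.DataFrame(columns=["component_sum", "dry_matter", "fitted",
                                      "residual", "studentized", "flagged"])
        return QCReport(empty, np.nan, np.nan, np.nan, threshold, use_sugar)

    g = traits.g100g if traits.g100g is not None else traits.to_proportion().data * 100.0
    cols = ["fat", "protein"] + (["sugar"] if use_sugar else [])
    comp = g[cols].sum(axis=1, skipna=False)
    dm = traits.dry_matter.reindex(comp.index)
    ok = comp.notna() & dm.notna()
    if ok.sum() < 10:
        raise ValueError(f"need >= 10 species with dry matter and components, have {int(ok.sum())}")
    x, y = comp[ok], dm[ok]
    fit = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
    if fit.ssr <= 1e-10 * max(1.0, float((y**2).sum())):
        # numerically exact fit: studentized residuals are 0/0 noise
        stud = np.zeros(len(x))
    else:
        stud = OLSInfluence(fit).resid_studentized_external
    table = pd.DataFrame(
        {
            "component_sum": x,
            "dry_matter": y,
            "fitted": fit.fittedvalues,
            "residual": fit.resid,
            "studentized": stud,
        },
        index=x.index,
    )
    table["flagged"] = table["studentized"].abs() > threshold
    table = table.reindex(table["residual"].abs().sort_values(ascending=False).index)
    return QCReport(
        table=table,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        threshold=threshold,
        use_sugar=use_sugar,
    )


def center_log_predictors(covs: CovariateTable) -> CovariateTable:
    """log10-transform then mean-center the continuous covariates.

    Ordinal and categorical columns are untouched.  Guarded by the table's
    ``centered`` flag so it cannot be applied twice.
    """
    if covs.centered:
        raise ValueError("covariates are already log10-centered")
    df = covs.data.copy()
    for col in CONTINUOUS_COVARIATES:
        vals = df[col]
        bad = vals[vals.notna() & (vals <= 0)]
        if len(bad):
            raise ValueError(
                f"non-positive {col} for species: {', '.join(map(str, bad.index[:5]))}"
            )
        logged = np.log10(vals)
        df[col] = logged - logged.mean()
    return CovariateTable(df, centered=True)


def renormalize_composition(traits: TraitMatrix) -> TraitMatrix:
    """Rescale fat/protein/sugar to percentages summing to 100.

    Used for the right-angle mixture (nutritional-geometry) display; species
    with any missing component keep NaN everywhere.
    """
    g = traits.g100g if traits.g100g is not None else traits.to_proportion().data * 100.0
    g = g[["fat", "protein", "sugar"]].astype(float)
    total = g.sum(axis=1, skipna=False)
    if (total.dropna() == 0).any():
        raise ValueError("zero macronutrient sum cannot be renormalized")
    out = g.div(total, axis=0) * 100.0
    res = TraitMatrix.__new__(TraitMatrix)
    res.data = out / 100.0
    res.scale = "proportion"
    res.dry_matter = traits.dry_matter
    res.g100g = out
    return res
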