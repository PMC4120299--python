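"""Negative binomial regression of premature CHD death counts.

NB2 parameterization (variance mu + alpha * mu^2), log link, full maximum
likelihood including the dispersion. Coefficients are reported as
incidence rate ratios with Wald 95% CIs computed on the log scale and
exponentiated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, ConfigError, ModelConvergenceError
from .types import PracticeCovariates

__all__ = ["fit_negative_binomial", "compare_models", "ModelComparison",
           "covariates_to_frame", "MortalityModelFit"]

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MortalityModelFit:
    """Result of one count-regression fit.

    ``table`` is indexed by term (intercept + covariates) with columns
    irr, ci_lower, ci_upper, p_value.
    """

    table: pd.DataFrame
    dispersion: float
    log_likelihood: float
    n: int
    covariates: tuple
    offset: str
    converged: bool

    def irr(self, term: str) -> float:
        return float(self.table.loc[term, "irr"])


def covariates_to_frame(data: Union[pd.DataFrame, Sequence[PracticeCovariates]]) -> pd.DataFrame:
    """Normalize input to a DataFrame with death_count, exposure + covariate columns."""
    if isinstance(data, pd.DataFrame):
        return data.copy()
    rows = []
    for pc in data:
        pc.validate()
        row = {"practice_id": pc.practice_id, "death_count": pc.death_count,
               "exposure": pc.exposure}
        row.update(pc.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def _design(df: pd.DataFrame, covariates: Sequence[str], offset: str):
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ConfigError(f"covariates not in data: {missing}")
    if df[list(covariates)].isna().any().any() or df["death_count"].isna().any():
        raise ValueError("missing values in model data")
    X = df[list(covariates)].astype(float)
    degenerate = [c for c in covariates if np.ptp(X[c].to_numpy()) == 0.0]
    if degenerate:
        raise CollinearityError(degenerate)
    exog = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        # identify columns that are linear combinations of the preceding ones
        culprits = []
        cols = exog.to_numpy()
        for j in range(1, cols.shape[1]):
            if np.linalg.matrix_rank(cols[:, : j + 1]) < j + 1:
                culprits.append(exog.columns[j])
        raise CollinearityError(culprits or list(covariates))
    if offset == "log-exposure":
        if "exposure" not in df.columns or (df["exposure"] <= 0).any():
            raise ConfigError("log-exposure offset requires a positive exposure column")
        off = np.log(df["exposure"].astype(float).to_numpy())
    elif offset == "none":
        off = None
    else:
        raise ConfigError(f"unknown offset mode {offset!r}")
    y = df["death_count"].astype(float).to_numpy()
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("death_count must be non-negative integers")
    return y, exog, off


def _irr_table(params, bse, pvalues, names) -> pd.DataFrame:
    coef = np.asarray(params, dtype=float)
    se = np.asarray(bse, dtype=float)
    table = pd.DataFrame({
        "irr": np.exp(coef),
        "ci_lower": np.exp(coef - Z95 * se),
        "ci_upper": np.exp(coef + Z95 * se),
        "p_value": np.asarray(pvalues, dtype=float),
    }, index=list(names))
    return table.rename(index={"const": "intercept"})


def fit_negative_binomial(
    data: Union[pd.DataFrame, Sequence[PracticeCovariates]],
    covariates: Sequence[str],
    offset: str = "none",
    dispersion: Optional[float] = None,
) -> MortalityModelFit:
    """Fit an NB2 count regression and report IRRs with Wald 95% CIs.

    Parameters
    ----------
    data
        DataFrame (or sequence of :class:`PracticeCovariates`) with
        ``death_count``, ``exposure`` and the covariate columns.
    covariates
        Names of the explanatory variables; an intercept is always added.
    offset
        ``"none"`` (covariate-only layout) or ``"log-exposure"``.
    dispersion
        ``None`` estimates the NB2 dispersion by maximum likelihood;
        ``0`` fits the Poisson limit (same log-link mean model).
    """
    df = covariates_to_frame(data)
    covariates = list(covariates)
    if len(df) <= len(covariates) + 2:
        raise ValueError(f"n={len(df)} too small for {len(covariates)} covariates")
    y, exog, off = _design(df, covariates, offset)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if dispersion == 0:
            model = sm.Poisson(y, exog, offset=off)
            res = model.fit(disp=0, maxiter=200)
            alpha = 0.0
            params, bse, pvalues = res.params, res.bse, res.pvalues
            names = exog.columns
        elif dispersion is None:
            model = sm.NegativeBinomial(y, exog, loglike_method="nb2", offset=off)
            res = model.fit(disp=0, maxiter=500)
            if not res.mle_retvals.get("converged", False):
                res = model.fit(disp=0, method="bfgs", maxiter=2000)
            alpha = float(res.params[-1])
            params, bse, pvalues = res.params[:-1], res.bse[:-1], res.pvalues[:-1]
            names = exog.columns
        else:
            if dispersion < 0:
                raise ConfigError("dispersion must be >= 0")
            model = sm.GLM(y, exog, offset=off,
                           family=sm.families.NegativeBinomial(alpha=dispersion))
            res = model.fit()
            alpha = float(dispersion)
            params, bse, pvalues = res.params, res.bse, res.pvalues
            names = exog.columns
    converged = bool(getattr(res, "mle_retvals", {"converged": True}).get("converged", True))
    if not converged:
        raise ModelConvergenceError("negative binomial fit did not converge",
                                    trace=getattr(res, "mle_retvals", None))
    return MortalityModelFit(
        table=_irr_table(params, bse, pvalues, names),
        dispersion=alpha,
        log_likelihood=float(res.llf),
        n=len(df),
        covariates=tuple(covariates),
        offset=offset,
        converged=converged,
    )


@dataclass(frozen=True)
class ModelComparison:
    """Side-by-side fits without and with an added covariate."""

    base: MortalityModelFit
    augmented: MortalityModelFit
    added_covariate: str
    table: pd.DataFrame      # per-term IRR/CI/p for both fits + IRR change
    lr_statistic: float
    lr_p_value: float


def compare_models(
    data: Union[pd.DataFrame, Sequence[PracticeCovariates]],
    base_covariates: Sequence[str],
    added_covariate: str,
    offset: str = "none",
) -> ModelComparison:
    """Refit with one extra covariate and tabulate the IRR shifts.

    Both models are fitted to exactly the same observations. The layout
    mirrors the published with/without comparison: one row per term, the
    base columns blank for the added covariate, plus a likelihood-ratio
    test for its inclusion.
    """
    base_covariates = list(base_covariates)
    if added_covariate in base_covariates:
        raise ConfigError(f"{added_covariate!r} is already in the base covariate set")
    df = covariates_to_frame(data)
    base = fit_negative_binomial(df, base_covariates, offset=offset)
    augmented = fit_negative_binomial(df, base_covariates + [added_covariate], offset=offset)
    if base.n != augmented.n:
        raise ValueError("fits used differing observation sets")

    rows = []
    for term in ["intercept"] + base_covariates + [added_covariate]:
        in_base = term in base.table.index
        row = {"term": term}
        for label, fit, present in (("base", base, in_base), ("with_added", augmented, True)):
            sub = fit.table.loc[term] if present else None
            row[f"irr_{label}"] = float(sub["irr"]) if present else np.nan
            row[f"ci_lower_{label}"] = float(sub["ci_lower"]) if present else np.nan
            row[f"ci_upper_{label}"] = float(sub["ci_upper"]) if present else np.nan
            row[f"p_{label}"] = float(sub["p_value"]) if present else np.nan
        row["irr_change"] = (row["irr_with_added"] - row["irr_base"]) if in_base else np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("term")
    lr = 2.0 * (augmented.log_likelihood - base.log_likelihood)
    return ModelComparison(
        base=base,
        augmented=augmented,
        added_covariate=added_covariate,
        table=table,
        lr_statistic=float(lr),
        lr_p_value=float(stats.chi2.sf(max(lr, 0.0), df=1)),
    )
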