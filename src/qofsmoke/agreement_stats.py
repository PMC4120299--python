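"""Agreement statistics for paired prevalence estimates.

Conventions
-----------
* Differences are always first argument minus second. Callers compare
  (register-based, survey) and (chronic, general) in that order so the
  signs of the reported mean differences carry the intended direction.
* Lin's concordance correlation coefficient uses 1/n moment estimators
  (the original form); Bland-Altman limits use the sample (n-1) standard
  deviation and a fixed 1.96 multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError
from .types import AgreementSummary, CalibrationFit

LOA_MULTIPLIER = 1.96


def _paired_arrays(x, y, min_n=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < min_n:
        raise InsufficientDataError(f"need at least {min_n} pairs, got {x.size}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN values in paired series")
    return x, y


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def pearson_correlation(x, y) -> CorrelationResult:
    """Sample Pearson correlation with its two-sided t-transform p value."""
    x, y = _paired_arrays(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for a constant series")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=x.size)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean x - mean y)^2), with biased (1/n)
    moment estimators. Equal constant series concord perfectly (1.0);
    unequal constant series have zero concordance.
    """
    x, y = _paired_arrays(x, y)
    mx, my = x.mean(), y.mean()
    sx2 = ((x - mx) ** 2).mean()
    sy2 = ((y - my) ** 2).mean()
    sxy = ((x - mx) * (y - my)).mean()
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        return 1.0
    return float(2.0 * sxy / denom)


def bland_altman(x, y) -> AgreementSummary:
    """Bland-Altman agreement summary for paired series (x minus y).

    Limits of agreement are mean difference +/- 1.96 x sample SD of the
    differences. Pearson r and Lin's CCC for the pair are reported in the
    same summary (r is NaN when either series is constant).
    """
    x, y = _paired_arrays(x, y)
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    try:
        r = pearson_correlation(x, y).r
    except DegenerateDataError:
        r = float("nan")
    return AgreementSummary(
        n_pairs=int(x.size),
        pearson_r=r,
        lin_ccc=lin_ccc(x, y),
        mean_difference=mean_diff,
        sd_difference=sd_diff,
        loa_lower=mean_diff - LOA_MULTIPLIER * sd_diff,
        loa_upper=mean_diff + LOA_MULTIPLIER * sd_diff,
    )


def bland_altman_pairs(x, y, ids: Optional[Sequence] = None) -> pd.DataFrame:
    """Per-pair (mean, difference) table backing the Bland-Altman plot."""
    x, y = _paired_arrays(x, y)
    frame = pd.DataFrame({"mean": (x + y) / 2.0, "difference": x - y})
    if ids is not None:
        frame.insert(0, "id", list(ids))
    return frame


def fit_calibration(
    chronic,
    general,
    outlier_threshold: float = 3.0,
    ids: Optional[Sequence] = None,
) -> CalibrationFit:
    """OLS of general prevalence on chronic prevalence with outlier pruning.

    Iteratively drops every point whose externally studentized residual
    exceeds ``outlier_threshold`` in magnitude and refits, until none
    remain. ``outlier_threshold=inf`` reduces to plain OLS. Removed points
    are reported by id so the pruning is auditable.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    x, y = _paired_arrays(chronic, general, min_n=10)
    if np.ptp(x) == 0:
        raise DegenerateDataError("chronic series is constant; slope undefined")
    idx = np.arange(x.size)
    labels = list(ids) if ids is not None else list(range(x.size))
    if len(labels) != x.size:
        raise ValueError("ids length mismatch")

    removed = []
    while True:
        exog = sm.add_constant(x[idx])
        res = sm.OLS(y[idx], exog).fit()
        if not np.isfinite(outlier_threshold):
            break
        # an (almost) exact fit has no meaningful studentized residuals
        resid_scale = 1e-8 * max(1.0, float(np.abs(y[idx]).max()))
        if np.sqrt(max(res.mse_resid, 0.0)) <= resid_scale or idx.size <= 3:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            student = OLSInfluence(res).resid_studentized_external
        mask = np.abs(np.nan_to_num(student, nan=0.0)) > outlier_threshold
        if not mask.any():
            break
        removed.extend(labels[i] for i in idx[mask])
        idx = idx[~mask]
        if idx.size < 3:
            raise InsufficientDataError("outlier removal left fewer than 3 points")
    return CalibrationFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        n_used=int(idx.size),
        removed_ids=frozenset(removed),
        residual_sd=float(np.sqrt(res.mse_resid)),
    )


def yearly_concordance(estimates_by_year: pd.DataFrame) -> pd.DataFrame:
    """Pairwise concordance across years of a practices x years matrix.

    For every ordered year pair (earlier column first) reports Lin's CCC
    and the mean difference (first year minus second). Requires a fully
    aligned matrix: any missing cell means the complete-series filter was
    not applied, which is an error here rather than a silent drop.
    """
    if estimates_by_year.shape[1] < 2:
        raise InsufficientDataError("need at least two year columns")
    if estimates_by_year.isna().any().any():
        bad = estimates_by_year.columns[estimates_by_year.isna().any()].tolist()
        raise ValueError(f"misaligned practice sets (missing values in years {bad})")
    rows = []
    for a, b in combinations(estimates_by_year.columns, 2):
        xa = estimates_by_year[a].to_numpy(dtype=float)
        xb = estimates_by_year[b].to_numpy(dtype=float)
        rows.append({
            "year_a": a,
            "year_b": b,
            "lin_ccc": lin_ccc(xa, xb),
            "mean_difference": float((xa - xb).mean()),
            "n_pairs": xa.size,
        })
    return pd.DataFrame(rows)


def plot_agreement(x, y, path, xlabel="Survey estimate", ylabel="Register-based estimate"):
    """Scatter of paired estimates with the identity line; saves to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = _paired_arrays(x, y)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=18, color="black")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    ax.plot([lo, hi], [lo, hi], linestyle="--", color="grey")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bland_altman(x, y, path):
    """Bland-Altman plot: mean-difference line and 1.96 SD limits; saves to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = bland_altman(x, y)
    pairs = bland_altman_pairs(x, y)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(pairs["mean"], pairs["difference"], s=18, color="black")
    ax.axhline(summary.mean_difference, color="black")
    ax.axhline(summary.loa_lower, linestyle="--", color="grey")
    ax.axhline(summary.loa_upper, linestyle="--", color="grey")
    ax.set_xlabel("Mean of paired estimates")
    ax.set_ylabel("Difference (first - second)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
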