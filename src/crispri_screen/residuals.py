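"""Cross-condition regression residual calling of condition-specific genes.

Gene scores from the competence-induced contrast (Ci+C vs mock) are
regressed on scores from the library-only contrast (Ci vs mock) by
ordinary least squares. Genes whose fitness effect is shared between the
two conditions fall on the regression line; condition-specific genes
stand out as outliers of the standardized residuals, classified beyond
a +/-2.5 cutoff (depleted below, enriched above).

Residuals are internally studentized by default (leverage-corrected,
r_i = e_i / (sigma_hat * sqrt(1 - h_i))); the plain e_i / sigma_hat
form is available via ``kind='simple'``. At typical screen sizes
(thousands of genes) the two are numerically indistinguishable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    residual_df: int
    sigma_hat: float


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        common = x.index.intersection(y.index)
        return (
            x.loc[common].to_numpy(dtype=float),
            y.loc[common].to_numpy(dtype=float),
            common,
        )
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    return x, y, pd.RangeIndex(len(x))


def fit_score_regression(x, y) -> RegressionFit:
    """OLS fit y = intercept + slope*x on genes present in both contrasts.

    Series inputs are inner-joined on their (gene) index. Requires >= 3
    points; all-identical y (SST = 0) is an error.
    """
    xv, yv, _ = _as_xy(x, y)
    n = len(xv)
    if n < 3:
        raise ValueError("regression needs >= 3 genes present in both contrasts")
    sst = float(np.sum((yv - yv.mean()) ** 2))
    if sst == 0:
        raise ValueError("all y values identical (SST = 0); regression undefined")
    sxx = float(np.sum((xv - xv.mean()) ** 2))
    if sxx == 0:
        raise ValueError("all x values identical; slope undefined")
    slope = float(np.sum((xv - xv.mean()) * (yv - yv.mean())) / sxx)
    intercept = float(yv.mean() - slope * xv.mean())
    resid = yv - (intercept + slope * xv)
    sse = float(np.sum(resid**2))
    return RegressionFit(
        slope=slope,
        intercept=intercept,
        r_squared=1.0 - sse / sst,
        residual_df=n - 2,
        sigma_hat=float(np.sqrt(sse / (n - 2))),
    )


def standardized_residuals(fit: RegressionFit, x, y, kind: str = "internal") -> pd.Series:
    """Standardized residuals of the fitted score regression.

    ``kind='internal'`` divides each residual by
    sigma_hat * sqrt(1 - h_i) with leverage
    h_i = 1/n + (x_i - xbar)^2 / Sxx; ``kind='simple'`` divides by
    sigma_hat alone.
    """
    if kind not in ("internal", "simple"):
        raise ValueError("kind must be 'internal' or 'simple'")
    xv, yv, index = _as_xy(x, y)
    n = len(xv)
    if n <= 2:
        raise ValueError("residuals need n > 2")
    e = yv - (fit.intercept + fit.slope * xv)
    if fit.sigma_hat == 0 or fit.r_squared >= 1 - 1e-12:
        # (numerically) perfect fit: every residual is exactly zero
        return pd.Series(np.zeros(n), index=index, name="std_residual")
    if kind == "simple":
        r = e / fit.sigma_hat
    else:
        sxx = np.sum((xv - xv.mean()) ** 2)
        h = 1.0 / n + (xv - xv.mean()) ** 2 / sxx
        r = e / (fit.sigma_hat * np.sqrt(1.0 - h))
    return pd.Series(r, index=index, name="std_residual")


def classify_outliers(
    x: pd.Series,
    y: pd.Series,
    cutoff: float = 2.5,
    kind: str = "internal",
) -> tuple[pd.DataFrame, RegressionFit]:
    """Fit the score regression and classify genes by standardized residual.

    Returns (calls, fit) where calls has one row per gene with columns
    x, y, fitted, residual, std_residual and class in
    {depleted, enriched, neutral}. Ties at exactly +/-cutoff are neutral
    (strict inequality).
    """
    xv, yv, index = _as_xy(x, y)
    fit = fit_score_regression(pd.Series(xv, index=index), pd.Series(yv, index=index))
    r = standardized_residuals(fit, pd.Series(xv, index=index), pd.Series(yv, index=index), kind=kind)
    fitted = fit.intercept + fit.slope * xv
    klass = np.where(r < -cutoff, "depleted", np.where(r > cutoff, "enriched", "neutral"))
    calls = pd.DataFrame(
        {
            "x": xv,
            "y": yv,
            "fitted": fitted,
            "residual": yv - fitted,
            "std_residual": r.to_numpy(),
            "class": klass,
        },
        index=index,
    )
    calls.index.name = "gene"
    return calls, fit


def confirm_direct(
    calls: pd.DataFrame, direct: pd.DataFrame, fdr_cutoff: float = 0.05
) -> pd.DataFrame:
    """Flag residual calls confirmed by the direct treatment-vs-treatment
    contrast: a depleted (enriched) gene is confirmed iff its
    depletion-tail (enrichment-tail) FDR in ``direct`` is <= the cutoff.
    Genes absent from the direct contrast are unconfirmed with a warning.
    """
    out = calls.copy()
    confirmed = []
    missing = []
    for gene, row in out.iterrows():
        if row["class"] == "neutral":
            confirmed.append(False)
            continue
        if gene not in direct.index:
            missing.append(gene)
            confirmed.append(False)
            continue
        col = "fdr_neg" if row["class"] == "depleted" else "fdr_pos"
        confirmed.append(bool(direct.loc[gene, col] <= fdr_cutoff))
    if missing:
        logger.warning("%d called genes absent from the direct contrast", len(missing))
    out["confirmed_by_direct"] = confirmed
    return out
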