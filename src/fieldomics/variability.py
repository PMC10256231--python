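"""Expression and phenotype variability statistics.

Coefficients of variation (percent), a fitted mean-CV^2 trend of the form
CV^2(x) = a/xbar + b (gamma-family GLM with identity link, as used for
highly-variable-gene detection on count data), the normalized CV
normCV = log2(CV^2 / trend(xbar)), the 3-scaled-MAD outlier rule, and
Shapiro-Wilk / Anderson-Darling normality screening.

CV^2 here is dimensionless (fractional, not percent^2); output headers of
the analysis drivers state this explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
import statsmodels.api as sm

__all__ = [
    "CvTrend",
    "coefficient_of_variation",
    "detect_outliers",
    "fit_cv_trend",
    "norm_cv",
    "normality_screen",
    "gene_variability_table",
]

MAD_SCALE = 1.4826  # normal-consistency constant


@dataclass(frozen=True)
class CvTrend:
    """Fitted CV^2(x) = a/xbar + b trend."""

    a: float
    b: float
    min_samples_expressed: int

    def __call__(self, mean: np.ndarray | float) -> np.ndarray | float:
        return self.a / np.asarray(mean, dtype=float) + self.b


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * sd / mean, with the sample (n-1) sd."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    m = x.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / m)


def detect_outliers(values) -> np.ndarray:
    """Flag values more than 3 scaled MADs from the median.

    Scaled MAD = 1.4826 * median(|x - median|).  When the scaled MAD is
    zero (over half the values identical) any value different from the
    median is flagged, the limit-consistent extension of the rule.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    med = np.median(x)
    dev = np.abs(x - med)
    smad = MAD_SCALE * np.median(dev)
    if smad == 0:
        return dev > 0
    return dev > 3 * smad


def fit_cv_trend(
    normalized_counts: pd.DataFrame,
    min_samples_expressed: int = 10,
) -> CvTrend:
    """Fit the mean-CV^2 trend over genes expressed in enough samples.

    Genes with a positive normalized count in at least
    ``min_samples_expressed`` samples enter the fit of
    CV^2 = a/mean + b via a gamma-family GLM with identity link.  On
    GLM failure, falls back to robust (soft-L1) least squares on
    (1/mean, CV^2) and warns in the returned trend via a console message.
    """
    expressed = (normalized_counts > 0).sum(axis=1) >= min_samples_expressed
    if expressed.sum() < 10:
        raise ValueError("fewer than 10 genes expressed in enough samples")
    sub = normalized_counts.loc[expressed]
    means = sub.mean(axis=1).to_numpy()
    keep = means > 0
    means = means[keep]
    cv2 = (sub.std(axis=1, ddof=1).to_numpy()[keep] / means) ** 2
    exog = np.column_stack([1.0 / means, np.ones_like(means)])
    try:
        with warnings.catch_warnings():
            # the identity link for the gamma family is the deliberate
            # trend parametrization, not an accident
            warnings.simplefilter("ignore")
            model = sm.GLM(
                cv2, exog, family=sm.families.Gamma(link=sm.families.links.Identity())
            )
            start = np.maximum(np.linalg.lstsq(exog, cv2, rcond=None)[0], 1e-6)
            res = model.fit(start_params=start)
        a, b = res.params
        if not np.all(np.isfinite(res.params)):
            raise ValueError("non-finite GLM parameters")
    except Exception:
        sol = least_squares(
            lambda th: th[0] / means + th[1] - cv2,
            x0=np.array([1.0, 0.01]),
            loss="soft_l1",
        )
        a, b = sol.x
    return CvTrend(a=float(a), b=float(b), min_samples_expressed=min_samples_expressed)


def norm_cv(cv2, mean, trend: CvTrend) -> np.ndarray:
    """normCV = log2(CV^2 / trend(mean)); requires a positive trend value."""
    cv2 = np.asarray(cv2, dtype=float)
    expected = np.asarray(trend(mean), dtype=float)
    if np.any(expected <= 0):
        raise ValueError("trend is non-positive at some requested means")
    return np.log2(cv2 / expected)


def normality_screen(values, alpha: float = 0.01) -> tuple[float, float, bool]:
    """Shapiro-Wilk p, Anderson-Darling statistic, and a pass flag.

    The screen passes when both tests have p > alpha (1% by default); the
    Anderson-Darling p-value is interpolated from its reference tables.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 values")
    if np.allclose(x, x[0]):
        raise ValueError("normality tests undefined for constant data")
    shapiro_p = float(stats.shapiro(x).pvalue)
    ad = stats.anderson(x, dist="norm", method="interpolate")
    return shapiro_p, float(ad.statistic), bool(shapiro_p > alpha and ad.pvalue > alpha)


def gene_variability_table(
    normalized_counts: pd.DataFrame,
    min_samples_expressed: int = 10,
) -> tuple[pd.DataFrame, CvTrend]:
    """Per-gene (mean, CV, CV2, normCV) table plus the fitted trend.

    normCV is reported only for genes meeting the expression threshold used
    to fit the trend; others get NaN.
    """
    trend = fit_cv_trend(normalized_counts, min_samples_expressed)
    means = normalized_counts.mean(axis=1)
    sds = normalized_counts.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sds / means
        cv2 = (sds / means) ** 2
    eligible = ((normalized_counts > 0).sum(axis=1) >= min_samples_expressed) & (means > 0)
    ncv = pd.Series(np.nan, index=normalized_counts.index)
    ncv[eligible] = norm_cv(cv2[eligible].to_numpy(), means[eligible].to_numpy(), trend)
    return (
        pd.DataFrame(
            {"mean": means, "cv_percent": cv, "cv2_fraction": cv2, "norm_cv": ncv}
        ),
        trend,
    )
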