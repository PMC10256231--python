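"""Single-feature association under spatially correlated residuals.

The association model for a phenotype vector y and a z-scored feature x is

    y = beta0 + beta1 * x + eps,   eps ~ N(0, Sigma),
    Sigma_ij = sigma2 * (nu * I_ij + (1 - nu) * exp(-(d_ij / r)^2)),

with d_ij the field distance between plants i and j, nugget nu in [0, 1]
the iid fraction of residual variance and range r the correlation decay
scale.  (nu, r) are estimated by ReML with (beta0, beta1, sigma2) profiled
out by generalized least squares; Wald tests on beta1 use a t reference
with n - 2 degrees of freedom.  When the ReML optimization fails the model
falls back to ordinary regression, flagged in the fit.

For count-ratio phenotypes (a numerator conditioned on a denominator) the
module provides the conditional log-link model

    n ~ N(d * exp(beta0 + beta1 * x) - c, Sigma)

with offset c >= 0 (zero unless requested) and four error structures:
constant variance, spatial (Gaussian covariogram), heteroscedastic with
variance linear in the fitted mean, or spatial + heteroscedastic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .spatial import bh_adjust

__all__ = [
    "GaussianCovariance",
    "SpatialLmeFit",
    "RatioModelFit",
    "gaussian_covariance",
    "fit_spatial_lme",
    "screen_features",
    "cv_score_single_feature",
    "fit_loglink_ratio",
    "oos_r2",
]

_EPS = 1e-6


def _is_constant(v: np.ndarray) -> bool:
    v = np.asarray(v, dtype=float)
    return v.std() <= 1e-10 * max(1.0, float(np.abs(v).max(initial=0.0)))


@dataclass(frozen=True)
class GaussianCovariance:
    sigma2: float
    nugget: float
    range_: float


@dataclass
class SpatialLmeFit:
    beta0: float
    beta1: float
    cov: GaussianCovariance | None
    se_beta1: float
    wald_stat: float
    p: float
    q: float | None = None
    converged: bool = True
    fallback_used: bool = False
    reml: float = np.nan  # maximized restricted log-likelihood

    def predict(self, x) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(x, dtype=float)


def gaussian_covariance(
    distances: np.ndarray, sigma2: float, nugget: float, range_: float
) -> np.ndarray:
    """Sigma_ij = sigma2 * (nu * I_ij + (1 - nu) * exp(-(d_ij/r)^2))."""
    distances = np.asarray(distances, dtype=float)
    if not np.allclose(distances, distances.T) or np.any(np.diag(distances) != 0):
        raise ValueError("distances must be symmetric with zero diagonal")
    if sigma2 <= 0 or not 0 <= nugget <= 1 or range_ <= 0:
        raise ValueError("require sigma2 > 0, nugget in [0, 1], range > 0")
    eye = np.eye(distances.shape[0])
    return sigma2 * (nugget * eye + (1 - nugget) * np.exp(-((distances / range_) ** 2)))


def _correlation(distances: np.ndarray, nugget: float, range_: float) -> np.ndarray:
    eye = np.eye(distances.shape[0])
    return nugget * eye + (1 - nugget) * np.exp(-((distances / range_) ** 2))


def _gls_profile(y: np.ndarray, X: np.ndarray, R: np.ndarray):
    """Profile (beta, sigma2) out of the restricted likelihood for fixed R.

    Returns (neg_reml, beta, sigma2_reml, xrx_inv) or None when R is not
    positive definite.
    """
    n, p = X.shape
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        return None
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    xtx = Xw.T @ Xw
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return None
    beta = xtx_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    if rss <= 0:
        return None
    sigma2 = rss / (n - p)
    logdet_r = 2 * np.log(np.diag(L)).sum()
    sign, logdet_x = np.linalg.slogdet(xtx)
    if sign <= 0:
        return None
    neg_reml = 0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1) + logdet_r + logdet_x)
    return neg_reml, beta, sigma2, xtx_inv


def _distances(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)


_NU_GRID = (0.05, 0.25, 0.5, 0.75, 0.95)
_R_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)


def _ols_fit(y: np.ndarray, X: np.ndarray) -> SpatialLmeFit:
    n = len(y)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design (constant feature?)")
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - X.shape[1])
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = float(beta[1] / se)
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return SpatialLmeFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        cov=None,
        se_beta1=se,
        wald_stat=t,
        p=p,
        converged=True,
        fallback_used=True,
    )


def fit_spatial_lme(
    y,
    x,
    coords,
    nu_grid: Sequence[float] = _NU_GRID,
    r_grid: Sequence[float] = _R_GRID,
    n_restarts: int = 5,
    fixed: tuple[float, float] | None = None,
) -> SpatialLmeFit:
    """Fit the spatial LME by ReML over (nu, r) with GLS-profiled fixed effects.

    A coarse grid over (nu, r) seeds ``n_restarts`` quasi-Newton runs on
    the unconstrained (logit nu, log r) scale.  ``fixed`` pins (nu, r)
    instead of optimizing, for degenerate-limit checks.  On failure the
    ordinary regression fallback is returned with ``fallback_used`` set.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 plants")
    if _is_constant(x):
        raise ValueError("constant feature: rank-deficient design")
    X = np.column_stack([np.ones_like(y), x])
    D = _distances(coords)

    if fixed is not None:
        nu, r = fixed
        out = _gls_profile(y, X, _correlation(D, nu, r))
        if out is None:
            return _ols_fit(y, X)
        neg, beta, sigma2, xtx_inv = out
        n = len(y)
        se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
        t = float(beta[1] / se)
        return SpatialLmeFit(
            beta0=float(beta[0]),
            beta1=float(beta[1]),
            cov=GaussianCovariance(sigma2=float(sigma2), nugget=float(nu), range_=float(r)),
            se_beta1=se,
            wald_stat=t,
            p=float(2 * stats.t.sf(abs(t), df=n - 2)),
            converged=True,
            fallback_used=False,
            reml=-float(neg),
        )

    def neg_reml(theta: np.ndarray) -> float:
        nu = 1.0 / (1.0 + np.exp(-np.clip(theta[0], -30, 30)))
        r = float(np.exp(np.clip(theta[1], -10, 10)))
        R = _correlation(D, nu, r)
        out = _gls_profile(y, X, R)
        return np.inf if out is None else out[0]

    # coarse grid, then local optimization from the best few points
    grid = [
        (np.log(nu / (1 - nu)), np.log(r))
        for nu in nu_grid
        for r in r_grid
    ]
    scored = sorted(grid, key=lambda th: neg_reml(np.array(th)))
    best = None
    for th0 in scored[:n_restarts]:
        try:
            res = optimize.minimize(
                neg_reml, np.array(th0), method="L-BFGS-B",
                options={"maxiter": 200, "ftol": 1e-10},
            )
        except Exception:
            continue
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        return _ols_fit(y, X)

    nu = float(1.0 / (1.0 + np.exp(-np.clip(best.x[0], -30, 30))))
    r = float(np.exp(np.clip(best.x[1], -10, 10)))
    out = _gls_profile(y, X, _correlation(D, nu, r))
    if out is None:
        return _ols_fit(y, X)
    _, beta, sigma2, xtx_inv = out
    n = len(y)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = float(beta[1] / se)
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return SpatialLmeFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        cov=GaussianCovariance(sigma2=float(sigma2), nugget=nu, range_=r),
        se_beta1=se,
        wald_stat=t,
        p=p,
        converged=bool(best.success),
        fallback_used=False,
        reml=-float(best.fun),
    )


def _zscore(v: np.ndarray, mean: float | None = None, sd: float | None = None):
    mean = v.mean() if mean is None else mean
    sd = v.std(ddof=0) if sd is None else sd
    return (v - mean) / sd if sd > 0 else v - mean


def screen_features(
    y: pd.Series,
    X: pd.DataFrame,
    coords: np.ndarray,
    **lme_kwargs,
) -> pd.DataFrame:
    """Per-feature spatial LME association with BH adjustment.

    ``X`` is plants x features; each column is z-scored across all included
    plants before fitting (plants with missing y are dropped first).
    Returns a table (feature, beta1, p, q, fallback, converged) sorted by q.
    Features that cannot be fitted even by the ordinary-regression fallback
    are excluded from the BH family and reported with NaN statistics.
    """
    y = pd.Series(y)
    keep = y.notna()
    yv = y[keep].to_numpy(dtype=float)
    coords = np.asarray(coords, dtype=float)[keep.to_numpy()]
    rows = []
    for feat in X.columns:
        xv = X.loc[keep, feat].to_numpy(dtype=float)
        if _is_constant(xv):
            rows.append((feat, np.nan, np.nan, np.nan, True, False))
            continue
        fit = fit_spatial_lme(yv, _zscore(xv), coords, **lme_kwargs)
        rows.append((feat, fit.beta1, fit.se_beta1, fit.p, fit.fallback_used, fit.converged))
    table = pd.DataFrame(
        rows, columns=["feature", "beta1", "se_beta1", "p", "fallback", "converged"]
    ).set_index("feature")
    valid = table["p"].notna()
    table["q"] = np.nan
    table.loc[valid, "q"] = bh_adjust(table.loc[valid, "p"].to_numpy())
    return table.sort_values("q")


def oos_r2(y_true, y_pred) -> float:
    """Out-of-sample R^2 = 1 - SSE / SST with the test-set mean in SST."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) < 2:
        raise ValueError("need at least 2 test points")
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        return np.nan
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / sst


def cv_score_single_feature(
    y,
    x,
    coords,
    n_repeats: int = 9,
    n_folds: int = 10,
    seed: int = 0,
    **lme_kwargs,
) -> dict:
    """Repeated k-fold cross-validated prediction from one feature.

    Per split the spatial LME is fitted on the training plants (the
    feature re-z-scored on the training fold to avoid leakage) and the
    test plants are predicted from the fixed effects beta0 + beta1 * x.
    Reports the median out-of-sample R^2 over all splits and the medians
    over repeats of the pooled R^2 / Pearson correlation computed on each
    repeat's concatenated test predictions.
    """
    from sklearn.model_selection import KFold

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    coords = np.asarray(coords, dtype=float)
    split_r2: list[float] = []
    pooled_r2: list[float] = []
    pooled_pcc: list[float] = []
    for rep in range(n_repeats):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        preds = np.empty_like(y)
        for train, test in kf.split(y):
            mu, sd = x[train].mean(), x[train].std(ddof=0)
            xtr = _zscore(x[train], mu, sd)
            xte = _zscore(x[test], mu, sd)
            try:
                fit = fit_spatial_lme(y[train], xtr, coords[train], **lme_kwargs)
            except ValueError:
                preds[test] = y[train].mean()
                split_r2.append(oos_r2(y[test], preds[test]))
                continue
            preds[test] = fit.predict(xte)
            split_r2.append(oos_r2(y[test], preds[test]))
        pooled_r2.append(oos_r2(y, preds))
        pooled_pcc.append(float(stats.pearsonr(y, preds).statistic))
    clean = [v for v in split_r2 if np.isfinite(v)]
    return {
        "split_r2": split_r2,
        "pooled_r2": pooled_r2,
        "pooled_pcc": pooled_pcc,
        "median_test_r2": float(np.median(clean)),
        "median_pooled_r2": float(np.median(pooled_r2)),
        "median_pooled_pcc": float(np.median(pooled_pcc)),
    }


@dataclass
class RatioModelFit:
    beta0: float
    beta1: float
    offset_c: float
    error_structure: str
    sigma2: float
    nugget: float | None
    range_: float | None
    se_beta1: float
    p: float
    loglik: float
    converged: bool

    def predict_mean(self, d, x) -> np.ndarray:
        m = np.asarray(d, float) * np.exp(self.beta0 + self.beta1 * np.asarray(x, float))
        return m - self.offset_c


_STRUCTURES = ("constant", "spatial", "heteroscedastic", "spatial+heteroscedastic")


def fit_loglink_ratio(
    numerator,
    denominator,
    x,
    coords=None,
    error_structure: str = "constant",
    with_offset: bool = False,
    sd_linear: bool = False,
) -> RatioModelFit:
    """Fit the conditional log-link ratio model by maximum likelihood.

    The numerator is normal with mean d * exp(beta0 + beta1 x) - c given
    the denominator d; c >= 0 only when ``with_offset``.  The error
    covariance is sigma2 * W with W depending on the structure: identity,
    the Gaussian correlogram, diag of the fitted mean (variance linear in
    the estimate; set ``sd_linear`` for the sd-linear alternative), or the
    combination.  sigma2 is profiled out; the Wald p for beta1 uses a
    finite-difference Hessian and a t reference with n - 2 df.
    """
    if error_structure not in _STRUCTURES:
        raise ValueError(f"unknown error structure {error_structure!r}")
    n_vec = np.asarray(numerator, dtype=float)
    d_vec = np.asarray(denominator, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(d_vec <= 0):
        raise ValueError("denominator must be positive")
    if np.any(n_vec < 0):
        raise ValueError("numerator must be non-negative")
    n = len(n_vec)
    spatial = "spatial" in error_structure
    hetero = "heteroscedastic" in error_structure
    if spatial:
        if coords is None:
            raise ValueError("spatial error structures need coordinates")
        D = _distances(coords)

    k_mean = 2 + (1 if with_offset else 0)

    def unpack(theta):
        b0, b1 = theta[0], theta[1]
        # strictly positive log-scale offset; the c -> 0 boundary is reached
        # smoothly as theta -> -inf
        c = float(np.exp(np.clip(theta[2], -30, 30))) if with_offset else 0.0
        nu = rr = None
        if spatial:
            nu = 1.0 / (1.0 + np.exp(-np.clip(theta[k_mean], -30, 30)))
            rr = float(np.exp(np.clip(theta[k_mean + 1], -10, 10)))
        return b0, b1, c, nu, rr

    def negloglik(theta):
        b0, b1, c, nu, rr = unpack(theta)
        mu = d_vec * np.exp(np.clip(b0 + b1 * x, -40, 40)) - c
        if np.any(mu <= 0):
            return np.inf
        resid = n_vec - mu
        if hetero:
            v = mu if not sd_linear else mu**2
            sqrt_v = np.sqrt(v)
        else:
            sqrt_v = np.ones(n)
        if spatial:
            W = sqrt_v[:, None] * _correlation(D, nu, rr) * sqrt_v[None, :]
            try:
                L = np.linalg.cholesky(W)
            except np.linalg.LinAlgError:
                return np.inf
            rw = linalg.solve_triangular(L, resid, lower=True)
            quad = float(rw @ rw)
            logdet = 2 * np.log(np.diag(L)).sum()
        else:
            quad = float(np.sum(resid**2 / sqrt_v**2))
            logdet = 2 * np.log(sqrt_v).sum()
        if quad <= 0:
            return np.inf
        sigma2 = quad / n
        return 0.5 * (n * (np.log(2 * np.pi * sigma2) + 1) + logdet)

    ratio0 = np.log(max(np.mean(n_vec / d_vec), 1e-6))
    theta0 = [ratio0, 0.0]
    if with_offset:
        theta0.append(np.log(0.1))  # c initialized near zero
    if spatial:
        theta0 += [0.0, 0.0]  # nu = 0.5, r = 1
    theta0 = np.array(theta0)
    res = optimize.minimize(negloglik, theta0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-12})
    if with_offset:
        # the offset direction is weakly identified; restart from a larger c
        alt = theta0.copy()
        alt[2] = np.log(max(np.mean(n_vec) * 0.3, 0.3))
        res2 = optimize.minimize(negloglik, alt, method="Nelder-Mead",
                                 options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-12})
        if np.isfinite(res2.fun) and res2.fun < res.fun:
            res = res2
    converged = bool(res.success and np.isfinite(res.fun))
    b0, b1, c, nu, rr = unpack(res.x)
    mu = d_vec * np.exp(b0 + b1 * x) - c
    # profiled sigma2 at the optimum
    if hetero:
        v = mu if not sd_linear else mu**2
    else:
        v = np.ones(n)
    resid = n_vec - mu
    if spatial:
        W = np.sqrt(v)[:, None] * _correlation(D, nu, rr) * np.sqrt(v)[None, :]
        sigma2 = float(resid @ np.linalg.solve(W, resid)) / n
    else:
        sigma2 = float(np.sum(resid**2 / v)) / n

    # Wald se for beta1 from a central-difference Hessian of the profiled
    # negative log-likelihood over the mean parameters
    h = 1e-4
    idx = list(range(k_mean))
    H = np.zeros((k_mean, k_mean))
    f0 = negloglik(res.x)
    for a in idx:
        for b in idx:
            ta = res.x.copy()
            if a == b:
                ta[a] += h
                fpp = negloglik(ta)
                ta[a] -= 2 * h
                fmm = negloglik(ta)
                H[a, a] = (fpp - 2 * f0 + fmm) / h**2
            else:
                tpp = res.x.copy(); tpp[a] += h; tpp[b] += h
                tpm = res.x.copy(); tpm[a] += h; tpm[b] -= h
                tmp = res.x.copy(); tmp[a] -= h; tmp[b] += h
                tmm = res.x.copy(); tmm[a] -= h; tmm[b] -= h
                H[a, b] = (negloglik(tpp) - negloglik(tpm) - negloglik(tmp) + negloglik(tmm)) / (
                    4 * h**2
                )
    try:
        cov_beta = np.linalg.inv(H)
        se = float(np.sqrt(max(cov_beta[1, 1], 0)))
    except np.linalg.LinAlgError:
        se = np.nan
    if se and np.isfinite(se) and se > 0:
        t = b1 / se
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    else:
        p = np.nan
        converged = False
    return RatioModelFit(
        beta0=float(b0),
        beta1=float(b1),
        offset_c=float(c),
        error_structure=error_structure,
        sigma2=sigma2,
        nugget=nu,
        range_=rr,
        se_beta1=se,
        p=p,
        loglik=-float(res.fun),
        converged=converged,
    )
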