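"""Regularized-log normalization with batch fixed effects and shrunken plant effects.

Counts k_ij for gene i and sample j are modelled as

    k_ij ~ NB(mu_ij, alpha_i),   mu_ij = s_j * q_ij,
    log2(q_ij) = beta_i0 + batch_coef_i[b_j] + beta_i,p(j)

with s_j a library-size factor, b_j the sequencing batch of sample j (one
designated reference batch absorbed in the intercept) and p(j) the plant.
The intercept and batch coefficients carry a flat prior; the per-plant
coefficients carry a zero-centered normal prior whose variance is
estimated once, globally, by quantile matching on unshrunken per-plant
log2 fold changes computed relative to batch means.  The rlog value of
gene i in plant p is beta_i0 + beta_ip: library-size effects and batch
effects are removed and technical repeats collapse to one value per plant.

A second output, the batch/size-factor normalized counts
x_ij = k_ij / (2^batch_coef * s_j) with repeats averaged, feeds the
variability statistics (no log transform, no shrinkage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "RlogModel",
    "drop_unexpressed",
    "estimate_size_factors",
    "estimate_dispersions",
    "estimate_prior_variance",
    "fit_rlog",
    "rlog_matrix",
    "batch_normalized_counts",
]

DISPERSION_FLOOR = 1e-8


def drop_unexpressed(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero counts in every sample (the only prefilter)."""
    return counts.loc[counts.sum(axis=1) > 0]


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    For each sample, the median over genes of k_ij divided by the gene's
    geometric mean across samples, using genes with nonzero counts in all
    samples; if no such gene exists, geometric means are taken over
    positive counts only.
    """
    values = counts.to_numpy(dtype=float)
    if values.sum() == 0:
        raise ValueError("all-zero count matrix")
    if values.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    all_positive = (values > 0).all(axis=1)
    with np.errstate(divide="ignore"):
        logs = np.log(values)
    if all_positive.any():
        geo = np.exp(logs[all_positive].mean(axis=1))
        ratios = values[all_positive] / geo[:, None]
    else:
        # geometric means over positive counts only
        pos = values > 0
        geo = np.exp(np.where(pos, logs, 0.0).sum(axis=1) / np.maximum(pos.sum(axis=1), 1))
        with np.errstate(invalid="ignore"):
            ratios = np.where(pos, values / geo[:, None], np.nan)
    s = np.nanmedian(ratios, axis=0)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("could not estimate positive size factors for all samples")
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    meta: pd.DataFrame | None = None,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments, floored at ``floor``.

    Without metadata, alpha_i = (var - mean) / mean^2 on size-factor
    normalized counts across all samples — appropriate when samples are
    replicates of one condition.  With metadata, samples of the same plant
    (technical repeats) are the only replication under a design with
    per-plant coefficients, so the residual dispersion is estimated from
    within-plant variation: with x_j = k_j / s_j and group means mu_p,

        alpha = [sum_p S_p - sum_p (1 - 1/n_p) mu_p sum_j 1/s_j]
                / [sum_p (1 - 1/n_p) n_p mu_p^2],

    S_p the within-group sum of squares, pooling all repeated plants.
    Genes with sub-Poisson residual variance get the floor.
    """
    norm = counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    if meta is None:
        m = norm.mean(axis=1)
        v = norm.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (v - m) / m**2
        alpha = np.where(np.isfinite(alpha), alpha, floor)
        return pd.Series(np.maximum(alpha, floor), index=counts.index, name="dispersion")

    plants = meta["plant_id"].to_numpy()
    s = size_factors.to_numpy(dtype=float)
    ss = np.zeros(len(counts))
    poisson_part = np.zeros(len(counts))
    denom = np.zeros(len(counts))
    for plant in pd.unique(plants):
        idx = np.flatnonzero(plants == plant)
        n_p = idx.size
        if n_p < 2:
            continue
        x = norm[:, idx]
        mu = x.mean(axis=1)
        ss += ((x - mu[:, None]) ** 2).sum(axis=1)
        w = 1.0 - 1.0 / n_p
        poisson_part += w * mu * np.sum(1.0 / s[idx])
        denom += w * n_p * mu**2
    if not np.any(denom > 0):
        # no technical repeats: fall back to the across-sample estimator
        return estimate_dispersions(counts, size_factors, meta=None, floor=floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (ss - poisson_part) / denom
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    return pd.Series(np.maximum(alpha, floor), index=counts.index, name="dispersion")


@dataclass
class RlogModel:
    """Fitted per-gene coefficients of the penalized NB model (log2 scale)."""

    gene_ids: tuple[str, ...]
    plants: tuple[str, ...]
    batches: tuple[str, ...]  # non-reference batches, order of batch_coefs columns
    reference_batch: str
    intercepts: np.ndarray  # (n_genes,)
    batch_coefs: np.ndarray  # (n_genes, n_nonref)
    plant_effects: np.ndarray  # (n_genes, n_plants)
    dispersions: np.ndarray
    prior_variance: float
    converged: np.ndarray  # bool per gene
    fallback: np.ndarray  # bool per gene: plant effects shrunk fully to 0

    def batch_factor(self, gene_idx: int, batch: str) -> float:
        """Batch effect on the count scale (1 for the reference batch)."""
        if batch == self.reference_batch:
            return 1.0
        return float(2.0 ** self.batch_coefs[gene_idx, self.batches.index(batch)])


def _design_indices(meta: pd.DataFrame, reference_batch: str | None):
    plants = tuple(pd.unique(meta["plant_id"]))
    batch_levels = list(pd.unique(meta["batch"]))
    if reference_batch is None:
        # largest batch absorbs into the intercept
        reference_batch = meta["batch"].value_counts().idxmax()
    if reference_batch not in batch_levels:
        raise ValueError(f"reference batch {reference_batch!r} not present")
    nonref = tuple(b for b in batch_levels if b != reference_batch)
    plant_idx = np.array([plants.index(p) for p in meta["plant_id"]])
    batch_idx = np.array(
        [nonref.index(b) if b != reference_batch else -1 for b in meta["batch"]]
    )
    return plants, nonref, reference_batch, plant_idx, batch_idx


def estimate_prior_variance(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    size_factors: pd.Series,
    quantile: float = 0.95,
    reference_batch: str | None = None,
) -> float:
    """Global prior variance for plant effects by quantile matching.

    Unshrunken per-plant log2 fold changes are computed from
    log2(k/s + 0.5), per sample relative to the mean of its batch, then
    averaged over a plant's technical repeats.  The given upper quantile
    of their absolute values across all genes and plants is matched to the
    same quantile of a zero-mean normal.
    """
    if not 0.5 < quantile < 1:
        raise ValueError("quantile must be in (0.5, 1)")
    values = counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    y = np.log2(values + 0.5)
    batches = meta["batch"].to_numpy()
    dev = np.empty_like(y)
    for b in pd.unique(batches):
        mask = batches == b
        dev[:, mask] = y[:, mask] - y[:, mask].mean(axis=1, keepdims=True)
    lfc = pd.DataFrame(dev, columns=meta["plant_id"].to_numpy()).T.groupby(level=0).mean()
    q_obs = np.quantile(np.abs(lfc.to_numpy()), quantile)
    z = stats.norm.ppf(0.5 + quantile / 2)
    return float(max(q_obs / z, 1e-6) ** 2)


LN2 = np.log(2.0)


def _negloglik_and_grad(beta, k, s, X_plant, X_batch, alpha, inv_prior_var, n_nonref):
    """Penalized NB negative log-likelihood and gradient (coefs in log2)."""
    b0 = beta[0]
    bb = beta[1 : 1 + n_nonref]
    u = beta[1 + n_nonref :]
    eta = b0 + X_batch @ bb + X_plant @ u
    mu = s * np.exp2(np.clip(eta, -60, 60))
    if alpha < 1e-6:
        # Poisson limit: exact and numerically stable where r = 1/alpha
        # would overwhelm the gammaln differences
        ll = (k * np.log(mu) - mu - special.gammaln(k + 1)).sum()
        dl_deta = LN2 * (k - mu)
    else:
        r = 1.0 / alpha
        ll = (
            special.gammaln(k + r)
            - special.gammaln(r)
            - special.gammaln(k + 1)
            + r * np.log(r / (r + mu))
            + k * np.log(mu / (r + mu))
        ).sum()
        dl_deta = LN2 * (k - mu * (k + r) / (mu + r))
    penalty = 0.5 * inv_prior_var * (u @ u)
    grad = np.concatenate(
        [[dl_deta.sum()], X_batch.T @ dl_deta, X_plant.T @ dl_deta - 0.0]
    )
    grad[1 + n_nonref :] -= inv_prior_var * u
    return -(ll - penalty), -grad


def fit_rlog(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    dispersions: pd.Series | None = None,
    size_factors: pd.Series | None = None,
    prior_variance: float | None = None,
    prior_quantile: float = 0.95,
    reference_batch: str | None = None,
) -> RlogModel:
    """Fit the penalized NB model per gene.

    Maximizes the NB likelihood with a flat prior on intercept and batch
    coefficients and a zero-centered normal prior on plant coefficients
    (shared technical repeats), via L-BFGS with the analytic gradient.  On
    optimizer failure the gene falls back to an intercept+batch fit with
    plant effects fully shrunk to zero, flagged in the result.
    """
    counts = drop_unexpressed(counts)
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    size_factors = size_factors.loc[counts.columns]
    if dispersions is None:
        dispersions = estimate_dispersions(counts, size_factors, meta=meta)
    dispersions = dispersions.loc[counts.index]
    if prior_variance is None:
        prior_variance = estimate_prior_variance(
            counts, meta, size_factors, quantile=prior_quantile, reference_batch=reference_batch
        )

    plants, nonref, ref, plant_idx, batch_idx = _design_indices(meta, reference_batch)
    n_samples = len(meta)
    if counts.shape[1] != n_samples:
        raise ValueError("metadata rows must match count columns")
    n_plants, n_nonref = len(plants), len(nonref)
    X_plant = np.zeros((n_samples, n_plants))
    X_plant[np.arange(n_samples), plant_idx] = 1.0
    X_batch = np.zeros((n_samples, n_nonref))
    in_batch = batch_idx >= 0
    X_batch[np.flatnonzero(in_batch), batch_idx[in_batch]] = 1.0

    s = size_factors.to_numpy(dtype=float)
    K = counts.to_numpy(dtype=float)
    alphas = np.maximum(dispersions.to_numpy(dtype=float), DISPERSION_FLOOR)
    # below this the penalty Hessian (1/prior_variance) dwarfs the likelihood
    # curvature and the limit is exact: plant effects are pinned at zero
    hard_zero = prior_variance < 1e-8
    inv_pv = 0.0 if hard_zero else 1.0 / prior_variance

    n_genes = K.shape[0]
    intercepts = np.zeros(n_genes)
    batch_coefs = np.zeros((n_genes, n_nonref))
    plant_effects = np.zeros((n_genes, n_plants))
    converged = np.zeros(n_genes, dtype=bool)
    fallback = np.zeros(n_genes, dtype=bool)

    for g in range(n_genes):
        k = K[g]
        alpha = alphas[g]
        b0_init = np.log2((k / s).mean() + 0.5)
        if hard_zero:
            def _reduced0(beta):
                full = np.concatenate([beta, np.zeros(n_plants)])
                return _negloglik_and_grad(
                    full, k, s, X_plant, X_batch, alpha, 0.0, n_nonref
                )[0]

            red = optimize.minimize(
                _reduced0,
                np.concatenate([[b0_init], np.zeros(n_nonref)]),
                method="Nelder-Mead",
                options={"maxiter": 500, "xatol": 1e-10, "fatol": 1e-12},
            )
            intercepts[g] = red.x[0]
            batch_coefs[g] = red.x[1 : 1 + n_nonref]
            converged[g] = bool(red.success)
            continue
        x0 = np.concatenate([[b0_init], np.zeros(n_nonref + n_plants)])
        res = optimize.minimize(
            _negloglik_and_grad,
            x0,
            args=(k, s, X_plant, X_batch, alpha, inv_pv, n_nonref),
            method="L-BFGS-B",
            jac=True,
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
        )
        ok = res.success and np.all(np.isfinite(res.x))
        if not ok:
            # fall back: intercept + batch only, plant effects pinned at 0
            def _reduced(beta):
                full = np.concatenate([beta, np.zeros(n_plants)])
                return _negloglik_and_grad(
                    full, k, s, X_plant, X_batch, alpha, inv_pv, n_nonref
                )[0]

            red = optimize.minimize(
                _reduced, x0[: 1 + n_nonref], method="Nelder-Mead",
                options={"maxiter": 500},
            )
            res_x = np.concatenate([red.x, np.zeros(n_plants)])
            fallback[g] = True
            converged[g] = bool(red.success)
        else:
            res_x = res.x
            converged[g] = True
        intercepts[g] = res_x[0]
        batch_coefs[g] = res_x[1 : 1 + n_nonref]
        plant_effects[g] = res_x[1 + n_nonref :]

    return RlogModel(
        gene_ids=tuple(counts.index),
        plants=plants,
        batches=nonref,
        reference_batch=ref,
        intercepts=intercepts,
        batch_coefs=batch_coefs,
        plant_effects=plant_effects,
        dispersions=alphas,
        prior_variance=float(prior_variance),
        converged=converged,
        fallback=fallback,
    )


def rlog_matrix(model: RlogModel) -> pd.DataFrame:
    """Genes x plants rlog values, beta_i0 + beta_ip (batch effects excluded)."""
    values = model.intercepts[:, None] + model.plant_effects
    return pd.DataFrame(values, index=list(model.gene_ids), columns=list(model.plants))


def batch_normalized_counts(
    counts: pd.DataFrame,
    model: RlogModel,
    meta: pd.DataFrame,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Batch/size-factor normalized counts x_ij = k_ij / (2^batch_coef * s_j).

    No log transform and no shrinkage; technical repeats of a plant are
    collapsed by arithmetic averaging.  Returns genes x plants.
    """
    counts = counts.loc[list(model.gene_ids)]
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    batch_factors = np.ones((len(model.gene_ids), len(meta)))
    for j, b in enumerate(meta["batch"]):
        if b != model.reference_batch:
            col = model.batches.index(b)
            batch_factors[:, j] = 2.0 ** model.batch_coefs[:, col]
    x = counts.to_numpy(dtype=float) / (batch_factors * s[None, :])
    frame = pd.DataFrame(x, index=counts.index, columns=meta["plant_id"].to_numpy())
    collapsed = frame.T.groupby(level=0).mean().T
    return collapsed[list(model.plants)]
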