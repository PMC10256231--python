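"""Spatial autocorrelation and category-level rank/enrichment statistics.

Moran's I over a field grid,

    I = (n/w) * (x - xbar)' C (x - xbar) / ||x - xbar||^2,

with C either a binary queen-contiguity matrix (horizontal, vertical and
diagonal grid neighbors connected) or an inverse-distance matrix, w the sum
of C.  Significance comes from either a random-permutation null (pseudo
p-values with the +1 correction) or the closed-form normality
approximation.  The module also provides Benjamini-Hochberg adjustment,
two-sided Mann-Whitney U tests of category rank positions, and upper-tail
hypergeometric enrichment for generic gene-category annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import FieldDesign

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "build_spatial_weights",
    "morans_i",
    "moran_permutation_test",
    "moran_parametric_test",
    "moran_test",
    "bh_adjust",
    "ranked_category_mwu",
    "hypergeometric_enrichment",
]


@dataclass(frozen=True)
class SpatialWeights:
    """Connectivity matrix C over an ordered set of plants."""

    C: np.ndarray
    plants: tuple[str, ...]
    mode: str  # "queen" | "inverse_distance"

    @property
    def w(self) -> float:
        return float(self.C.sum())

    @property
    def n(self) -> int:
        return len(self.plants)


@dataclass(frozen=True)
class MoranResult:
    I: float
    p_perm: float | None = None
    p_param: float | None = None
    n_perm: int | None = None
    seed: int | None = None


def build_spatial_weights(
    design: FieldDesign,
    mode: str = "queen",
    available_plants: Sequence[str] | None = None,
) -> SpatialWeights:
    """Build queen-contiguity or inverse-distance weights.

    Queen mode connects plants whose grid positions differ by at most one
    in both row and column; inverse-distance mode sets C_ij = 1/d_ij with
    d_ij the metric field distance.  The matrix is restricted to
    ``available_plants`` (weights can differ between phenotypes when plants
    have missing values).  Plants left without neighbors keep a zero row
    with a warning.
    """
    plants = tuple(available_plants) if available_plants is not None else design.analysis_plants
    if len(plants) < 2:
        raise ValueError("need at least 2 available plants")
    if mode == "queen":
        pos = design.grid_positions(plants)
        dr = np.abs(pos[:, 0][:, None] - pos[:, 0][None, :])
        dc = np.abs(pos[:, 1][:, None] - pos[:, 1][None, :])
        C = ((dr <= 1) & (dc <= 1)).astype(float)
        np.fill_diagonal(C, 0.0)
    elif mode == "inverse_distance":
        xy = design.coords(plants)
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        with np.errstate(divide="ignore"):
            C = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
    else:
        raise ValueError(f"unknown weights mode: {mode!r}")
    isolated = np.flatnonzero(C.sum(axis=1) == 0)
    if isolated.size:
        warnings.warn(
            f"{isolated.size} plant(s) have no neighbors and keep zero weight rows",
            stacklevel=2,
        )
    return SpatialWeights(C=C, plants=plants, mode=mode)


def _centered(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    z = x - x.mean()
    if np.allclose(z, 0):
        raise ValueError("zero variance: Moran's I undefined for constant x")
    return z


def morans_i(x, W: SpatialWeights) -> float:
    """Global Moran's I of x under the weights W."""
    z = _centered(x)
    if len(z) != W.n:
        raise ValueError("x length must match the weights")
    return float(len(z) / W.w * (z @ W.C @ z) / (z @ z))


def moran_permutation_test(
    x,
    W: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> float:
    """Permutation pseudo p-value for Moran's I.

    Recomputes I on ``n_perm`` random permutations of x and reports
    (1 + #{I_perm at least as extreme}) / (1 + n_perm).  The default tail is
    upper (positive autocorrelation); ``alternative='two-sided'`` doubles
    the smaller tail.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    z = _centered(x)
    n = len(z)
    denom = z @ z
    i_obs = n / W.w * (z @ W.C @ z) / denom
    rng = np.random.default_rng(seed)
    # permuting centered values == centering permuted values
    perms = rng.permuted(np.broadcast_to(z, (n_perm, n)), axis=1)
    i_perm = n / W.w * np.einsum("ki,ij,kj->k", perms, W.C, perms) / denom
    tol = 1e-12
    upper = (1 + np.sum(i_perm >= i_obs - tol)) / (1 + n_perm)
    if alternative == "greater":
        return float(upper)
    if alternative == "two-sided":
        lower = (1 + np.sum(i_perm <= i_obs + tol)) / (1 + n_perm)
        return float(min(1.0, 2 * min(upper, lower)))
    raise ValueError(f"unknown alternative: {alternative!r}")


def moran_parametric_test(x, W: SpatialWeights) -> tuple[float, float, float]:
    """Normality-approximation test of Moran's I.

    Returns (two-sided p, E[I], Var[I]) with E[I] = -1/(n-1) and the
    closed-form variance under normality,

        Var[I] = (n^2 S1 - n S2 + 3 w^2) / ((n^2 - 1) w^2) - E[I]^2,

    S1 = 1/2 sum_ij (c_ij + c_ji)^2 and S2 = sum_i (row_i + col_i)^2.
    """
    z = _centered(x)
    n = len(z)
    if n < 4:
        raise ValueError("parametric test needs n >= 4")
    C = W.C
    w = W.w
    i_obs = n / w * (z @ C @ z) / (z @ z)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * np.sum((C + C.T) ** 2)
    s2 = np.sum((C.sum(axis=1) + C.sum(axis=0)) ** 2)
    var_i = (n**2 * s1 - n * s2 + 3 * w**2) / ((n**2 - 1) * w**2) - e_i**2
    if var_i <= 1e-14:
        # a saturated graph (every pair connected) pins I at -1/(n-1) for
        # any x, so the null variance is exactly zero
        if abs(i_obs - e_i) < 1e-9:
            return 1.0, float(e_i), float(max(var_i, 0.0))
        raise ValueError("non-positive Moran variance: pathological weights")
    zscore = (i_obs - e_i) / np.sqrt(var_i)
    p = float(2 * stats.norm.sf(abs(zscore)))
    return p, float(e_i), float(var_i)


def moran_test(
    x,
    W: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MoranResult:
    """Moran's I with both the permutation and the parametric p-value."""
    return MoranResult(
        I=morans_i(x, W),
        p_perm=moran_permutation_test(x, W, n_perm=n_perm, seed=seed, alternative=alternative),
        p_param=moran_parametric_test(x, W)[0],
        n_perm=n_perm,
        seed=seed,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ranked_category_mwu(
    ranked_ids: Sequence[str],
    categories: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U tests of category rank positions.

    For each category, members of the ranked feature list form group 1 and
    the remaining features group 2; the test asks whether members gravitate
    toward the top or bottom of the list.  Normal approximation with tie
    correction; BH adjustment across categories.
    """
    ranked_ids = list(ranked_ids)
    if len(set(ranked_ids)) != len(ranked_ids):
        raise ValueError("ranked list contains duplicates")
    position = {fid: i + 1 for i, fid in enumerate(ranked_ids)}
    rows = []
    for name, members in categories.items():
        members = set(members)
        if not members:
            raise ValueError(f"category {name!r} is empty")
        missing = members - position.keys()
        if missing:
            raise ValueError(f"category {name!r} has members absent from the ranked list")
        if len(members) < 2 or len(members) >= len(ranked_ids):
            raise ValueError(f"category {name!r} must have 2 <= size < list size")
        in_ranks = np.array([position[m] for m in members], dtype=float)
        out_ranks = np.array(
            [position[f] for f in ranked_ids if f not in members], dtype=float
        )
        res = stats.mannwhitneyu(
            in_ranks, out_ranks, alternative="two-sided", method="asymptotic"
        )
        rows.append((name, len(members), float(res.statistic), float(res.pvalue)))
    table = pd.DataFrame(rows, columns=["category", "size", "U", "p"]).set_index("category")
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table


def hypergeometric_enrichment(
    hit_set: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a hit set in each category.

    p = P(overlap >= observed) drawing |hits| items from the universe with
    |category| marked; BH adjustment across categories.
    """
    universe = set(universe)
    hits = set(hit_set)
    if not hits <= universe:
        raise ValueError("hit set must be a subset of the universe")
    rows = []
    for name, members in categories.items():
        members = set(members)
        if not members <= universe:
            raise ValueError(f"category {name!r} contains ids outside the universe")
        overlap = len(hits & members)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(hits)))
        rows.append((name, len(members), overlap, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["category", "size", "overlap", "p"]
    ).set_index("category")
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table
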