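"""Synthetic single-plant field-trial generator.

Emulates a field trial in which ~100 plants are grown on a regular grid,
the interior (non-border) plants are profiled by RNA-seq (with technical
repeats across sequencing batches), phenotyped, and measured for height
over the season.  Every generative quantity — the latent micro-environment
field, per-gene plant effects, causal-gene coefficients, growth-curve
parameters — is recorded as ground truth so downstream statistics can be
tested for recovery and calibration.

The default configuration mirrors the study conditions this package was
designed around: a 10x10 grid with 0.5 m spacing, 62 analysis plants after
border exclusion and emergence failures, 3 sequencing batches, and
negative-binomial counts with multiplicative batch effects and library-size
factors.

Randomness flows from one master seed through named ``numpy`` SeedSequence
substreams (field layout, latent field, gene parameters, counts,
phenotypes, growth), so any stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import GrowthParams, TemperatureSeries, beta_sigmoid_height, gdd_transform

__all__ = [
    "FieldDesign",
    "SimulationConfig",
    "SyntheticTruth",
    "make_field_design",
    "simulate_latent_field",
    "simulate_expression",
    "simulate_phenotypes",
    "simulate_growth_params",
    "simulate_growth_series",
    "make_temperature_series",
    "simulate_trial",
]

_STREAMS = {"design": 0, "latent": 1, "genes": 2, "counts": 3, "phenotypes": 4, "growth": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class FieldDesign:
    """Grid layout of a field trial.

    Rows/cols index grid positions; ``spacing`` is the distance in meters
    between adjacent rows and columns.  Border positions (first/last row or
    column) and missing positions (emergence failures) are flagged; the
    remaining plants form the analysis set.
    """

    n_rows: int
    n_cols: int
    spacing: float
    rows: np.ndarray  # per position
    cols: np.ndarray
    plant_ids: tuple[str, ...]
    border_mask: np.ndarray
    missing_mask: np.ndarray

    @property
    def analysis_mask(self) -> np.ndarray:
        return ~self.border_mask & ~self.missing_mask

    @property
    def analysis_plants(self) -> tuple[str, ...]:
        return tuple(np.asarray(self.plant_ids)[self.analysis_mask])

    def grid_positions(self, plants: Sequence[str] | None = None) -> np.ndarray:
        """(row, col) integer grid positions for the given plants."""
        plants = self.analysis_plants if plants is None else plants
        lookup = {p: i for i, p in enumerate(self.plant_ids)}
        idx = np.array([lookup[p] for p in plants])
        return np.column_stack([self.rows[idx], self.cols[idx]])

    def coords(self, plants: Sequence[str] | None = None) -> np.ndarray:
        """Metric (x, y) field coordinates in meters."""
        return self.grid_positions(plants) * self.spacing


def _plant_id(row: int, col: int) -> str:
    # row-number + column-letter convention, e.g. "02C"
    return f"{row + 1:02d}{chr(ord('A') + col)}"


def make_field_design(
    n_rows: int,
    n_cols: int,
    spacing: float = 0.5,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> FieldDesign:
    """Build a grid design with border flags and random emergence failures.

    Missing positions are drawn among interior positions only (border
    plants are excluded from analysis anyway).  Raises if fewer than 4
    analysis plants remain.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid must be at least 2x2")
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must be in [0, 1)")
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    border = (rows == 0) | (rows == n_rows - 1) | (cols == 0) | (cols == n_cols - 1)
    missing = np.zeros_like(border)
    interior = np.flatnonzero(~border)
    # fraction of all grid positions, realized among interior plants (border
    # positions never enter the analysis set anyway)
    n_missing = min(int(round(missing_fraction * rows.size)), interior.size)
    if n_missing:
        rng = _rng(seed, "design")
        missing[rng.choice(interior, size=n_missing, replace=False)] = True
    design = FieldDesign(
        n_rows=n_rows,
        n_cols=n_cols,
        spacing=spacing,
        rows=rows,
        cols=cols,
        plant_ids=tuple(_plant_id(r, c) for r, c in zip(rows, cols)),
        border_mask=border,
        missing_mask=missing,
    )
    if design.analysis_mask.sum() < 4:
        raise ValueError("degenerate grid: fewer than 4 analysis plants")
    return design


def gaussian_covariogram(
    distances: np.ndarray, sigma2: float, nugget: float, range_: float
) -> np.ndarray:
    """Sigma_ij = sigma2 * (nu*I_ij + (1-nu)*exp(-(d_ij/r)^2))."""
    if not 0 <= nugget <= 1:
        raise ValueError("nugget must lie in [0, 1]")
    if range_ <= 0 or sigma2 <= 0:
        raise ValueError("range and sigma2 must be positive")
    eye = np.eye(distances.shape[0])
    return sigma2 * (nugget * eye + (1 - nugget) * np.exp(-((distances / range_) ** 2)))


def simulate_latent_field(
    design: FieldDesign,
    sigma2: float = 1.0,
    nugget: float = 0.3,
    range_: float = 1.0,
    seed: int = 0,
    size: int | None = None,
) -> np.ndarray:
    """Draw spatially autocorrelated latent micro-environment values.

    One multivariate-normal realization per draw over the analysis plants,
    with the Gaussian covariogram (nugget nu, range r in meters).  Returns
    shape (n_plants,) or (size, n_plants).  Near-singular covariances are
    jittered on the diagonal.
    """
    coords = design.coords()
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cov = gaussian_covariogram(d, sigma2, nugget, range_)
    rng = _rng(seed, "latent")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(cov + 1e-8 * sigma2 * np.eye(len(cov)))
    n = len(coords)
    z = rng.standard_normal((size or 1, n))
    draws = z @ chol.T
    return draws[0] if size is None else draws


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic trial.

    Expression: per-gene log2 baselines are uniform on
    ``baseline_log2_range``; per-gene NB dispersions uniform on
    ``nb_dispersion_range``; non-reference batches get multiplicative
    effects with log2 sd ``batch_effect_sd``; library size factors uniform
    on ``size_factor_range``.  Plant effects on the log2 scale are
    ``loading_i * latent_p + Normal(0, plant_noise_sd)`` with loadings
    Normal(0, ``gene_loading_sd``).  A random ``technical_repeat_fraction``
    of plants receives a second sequencing sample sharing the plant effect.

    The causal genes form a co-expressed module: they share a per-plant
    program score (iid standard normal, weighted by ``causal_module_sd``)
    on top of their individual loadings and noise, the way genes acting in
    one pathway covary across plants.

    Phenotypes: a continuous trait is a linear combination of the causal
    genes' true plant effects plus ``phenotype_spatial_coef`` times the
    latent field plus iid noise; a count trait is drawn NB around the
    exponentiated linear predictor; a ratio trait is emitted as
    (numerator, denominator) with numerator Normal(d * exp(b0 + b1*x), sd).
    """

    n_genes: int = 1000
    n_causal_genes: int = 20
    n_batches: int = 3
    technical_repeat_fraction: float = 0.2
    nb_dispersion_range: tuple[float, float] = (0.005, 0.05)
    batch_effect_sd: float = 0.3
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    baseline_log2_range: tuple[float, float] = (3.0, 12.0)
    latent_nugget: float = 0.3
    latent_range: float = 1.0
    latent_sigma2: float = 1.0
    gene_loading_sd: float = 0.7
    plant_noise_sd: float = 0.45
    causal_module_sd: float = 1.0
    phenotype_effect_sizes: tuple[float, ...] | None = None
    phenotype_spatial_coef: float = 0.5
    phenotype_noise_sd: float = 0.5
    trait_baseline: float = 10.0
    ratio_beta0: float = 0.7
    ratio_beta1: float = 0.3
    ratio_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_batches) < 1 or self.n_causal_genes < 0:
            raise ValueError("counts must be >= 1")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("n_causal_genes cannot exceed n_genes")
        if not 0 <= self.technical_repeat_fraction <= 1:
            raise ValueError("technical_repeat_fraction must be in [0, 1]")
        if not 0 <= self.latent_nugget <= 1:
            raise ValueError("latent_nugget must be in [0, 1]")
        if self.latent_range <= 0:
            raise ValueError("latent_range must be positive")

    def effect_sizes(self) -> np.ndarray:
        if self.phenotype_effect_sizes is not None:
            if len(self.phenotype_effect_sizes) != self.n_causal_genes:
                raise ValueError("need one effect size per causal gene")
            return np.asarray(self.phenotype_effect_sizes, dtype=float)
        # total module effect of 2 shared equally: the trait's genetic signal
        # does not balloon with the module size
        if self.n_causal_genes == 0:
            return np.zeros(0)
        return np.full(self.n_causal_genes, 2.0 / self.n_causal_genes)


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator."""

    plants: tuple[str, ...]
    gene_ids: tuple[str, ...]
    latent_field: np.ndarray
    gene_plant_effects: np.ndarray  # genes x plants, log2 scale
    gene_loadings: np.ndarray
    baselines_log2: np.ndarray
    dispersions: np.ndarray
    batch_effects_log2: pd.DataFrame  # genes x batches (reference column = 0)
    causal_gene_ids: tuple[str, ...]
    true_phenotype_coefs: np.ndarray
    module_scores: np.ndarray | None = None
    true_growth_params: dict[str, GrowthParams] = field(default_factory=dict)


def _batch_labels(n_batches: int) -> list[str]:
    return [f"batch{i + 1}" for i in range(n_batches)]


def reference_batch(n_batches: int) -> str:
    """The designated reference batch (the second batch when there are >= 2)."""
    return _batch_labels(n_batches)[1 if n_batches >= 2 else 0]


def simulate_expression(
    design: FieldDesign,
    config: SimulationConfig,
    latent: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a raw count matrix with batch effects and technical repeats.

    Returns (counts genes x samples, sample metadata, truth).  Counts for
    gene i in sample j are NB with mean s_j * 2^(b_batch) * 2^(b_i0 + b_ip)
    and dispersion alpha_i; technical repeats share b_ip but draw their own
    counts with their own size factor and batch.
    """
    plants = list(design.analysis_plants)
    n_plants = len(plants)
    latent = np.asarray(latent, dtype=float)
    if latent.shape != (n_plants,):
        raise ValueError("latent values must match the analysis plants")

    rng_genes = _rng(config.seed, "genes")
    rng_counts = _rng(config.seed, "counts")

    gene_ids = tuple(f"gene{i:05d}" for i in range(config.n_genes))
    baselines = rng_genes.uniform(*config.baseline_log2_range, size=config.n_genes)
    dispersions = rng_genes.uniform(*config.nb_dispersion_range, size=config.n_genes)
    loadings = rng_genes.normal(0.0, config.gene_loading_sd, size=config.n_genes)
    causal_idx = rng_genes.choice(config.n_genes, size=config.n_causal_genes, replace=False)
    causal_idx.sort()

    plant_effects = (
        loadings[:, None] * latent[None, :]
        + rng_genes.normal(0.0, config.plant_noise_sd, size=(config.n_genes, n_plants))
    )
    # causal genes covary as a module through a shared program score
    module_scores = rng_genes.standard_normal(n_plants)
    if causal_idx.size and config.causal_module_sd > 0:
        plant_effects[causal_idx] += config.causal_module_sd * module_scores[None, :]

    batches = _batch_labels(config.n_batches)
    ref = reference_batch(config.n_batches)
    batch_lfc = pd.DataFrame(
        rng_genes.normal(0.0, config.batch_effect_sd, size=(config.n_genes, config.n_batches)),
        index=list(gene_ids),
        columns=batches,
    )
    batch_lfc[ref] = 0.0

    # one sample per plant, plus a technical repeat for a random plant subset
    n_repeats = int(round(config.technical_repeat_fraction * n_plants))
    repeat_plants = rng_counts.choice(n_plants, size=n_repeats, replace=False)
    sample_plant = list(range(n_plants)) + sorted(repeat_plants.tolist())
    n_samples = len(sample_plant)
    sample_ids = []
    seen: dict[int, int] = {}
    for p in sample_plant:
        seen[p] = seen.get(p, 0) + 1
        sample_ids.append(f"{plants[p]}_r{seen[p]}")
    # near-equal batch split over shuffled samples
    order = rng_counts.permutation(n_samples)
    sample_batch = np.empty(n_samples, dtype=object)
    for k, j in enumerate(order):
        sample_batch[j] = batches[k % config.n_batches]
    size_factors = rng_counts.uniform(*config.size_factor_range, size=n_samples)

    log2_mu = (
        baselines[:, None]
        + plant_effects[:, sample_plant]
        + batch_lfc.to_numpy()[:, [batches.index(b) for b in sample_batch]]
    )
    mu = size_factors[None, :] * np.exp2(log2_mu)
    alpha = dispersions[:, None]
    r = 1.0 / np.maximum(alpha, 1e-12)
    counts_arr = np.where(
        alpha > 1e-6,
        rng_counts.negative_binomial(r, r / (r + mu)),
        rng_counts.poisson(mu),
    )

    counts = pd.DataFrame(counts_arr, index=list(gene_ids), columns=sample_ids)
    grid = design.grid_positions(plants)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "plant_id": [plants[p] for p in sample_plant],
            "batch": sample_batch,
            "row": grid[sample_plant, 0],
            "col": grid[sample_plant, 1],
            "size_factor_true": size_factors,
        }
    )
    truth = SyntheticTruth(
        plants=tuple(plants),
        gene_ids=gene_ids,
        latent_field=latent,
        gene_plant_effects=plant_effects,
        gene_loadings=loadings,
        baselines_log2=baselines,
        dispersions=dispersions,
        batch_effects_log2=batch_lfc,
        causal_gene_ids=tuple(gene_ids[i] for i in causal_idx),
        true_phenotype_coefs=config.effect_sizes(),
        module_scores=module_scores,
    )
    return counts, meta, truth


def simulate_phenotypes(
    truth: SyntheticTruth,
    config: SimulationConfig,
    latent: np.ndarray,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a plant x phenotype table tied to the recorded truth.

    ``trait`` is linear in the causal genes' true plant effects plus a
    spatial term and iid noise; ``count_trait`` is NB around the
    exponentiated standardized predictor; the ratio trait is emitted as
    ``ratio_numerator``/``ratio_denominator`` with the numerator normal
    around d * exp(b0 + b1 * signal) given the denominator.
    """
    rng = _rng(config.seed if seed is None else seed, "phenotypes")
    plants = list(truth.plants)
    n = len(plants)
    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    causal = np.array([gene_index[g] for g in truth.causal_gene_ids], dtype=int)
    coefs = truth.true_phenotype_coefs

    signal = np.zeros(n)
    if causal.size:
        signal = coefs @ truth.gene_plant_effects[causal, :]
    trait = (
        config.trait_baseline
        + signal
        + config.phenotype_spatial_coef * latent
        + rng.normal(0.0, config.phenotype_noise_sd, size=n)
    )

    z = (signal - signal.mean()) / (signal.std() + 1e-12)
    count_mu = np.exp(3.0 + 0.4 * z)
    r = 1.0 / 0.1
    count_trait = rng.negative_binomial(r, r / (r + count_mu))

    denominator = rng.integers(1, 6, size=n).astype(float)
    ratio_mean = denominator * np.exp(config.ratio_beta0 + config.ratio_beta1 * z)
    numerator = np.maximum(rng.normal(ratio_mean, config.ratio_noise_sd), 0.0)

    return pd.DataFrame(
        {
            "trait": trait,
            "count_trait": count_trait,
            "ratio_numerator": numerator,
            "ratio_denominator": denominator,
        },
        index=pd.Index(plants, name="plant_id"),
    )


def causal_signal(truth: SyntheticTruth) -> np.ndarray:
    """Z-scored per-plant causal signal (the phenotypes' generative driver)."""
    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    causal = np.array([gene_index[g] for g in truth.causal_gene_ids], dtype=int)
    signal = np.zeros(len(truth.plants))
    if causal.size:
        signal = truth.true_phenotype_coefs @ truth.gene_plant_effects[causal, :]
    return (signal - signal.mean()) / (signal.std() + 1e-12)


def simulate_growth_params(design: FieldDesign, seed: int = 0) -> dict[str, GrowthParams]:
    """Draw per-plant beta-sigmoid parameters typical of winter rapeseed.

    Heights in cm, ages in GDD counted from a September sowing: initial
    height 10-30 cm, final height 120-160 cm, maximal growth at 480-560
    GDD (inside the dense spring measurement window) and growth ending
    150-250 GDD later, i.e. between the last spring measurement and the
    summer harvest.
    """
    rng = _rng(seed, "growth")
    params = {}
    for plant in design.analysis_plants:
        h0 = rng.uniform(10.0, 30.0)
        hmax = rng.uniform(120.0, 160.0)
        tm = rng.uniform(480.0, 560.0)
        te = tm + rng.uniform(150.0, 250.0)
        params[plant] = GrowthParams(h0=h0, hmax=hmax, tm=tm, te=te)
    return params


def simulate_growth_series(
    growth_params: dict[str, GrowthParams],
    temps: TemperatureSeries,
    measurement_days: Sequence[int],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-plant (day, height) series on the beta-sigmoid curve plus noise.

    Heights are evaluated at the GDD ages of the measurement days and
    perturbed with iid Normal(0, noise_sd) errors (cm).
    """
    for plant, p in growth_params.items():
        if not p.tm < p.te:
            raise ValueError(f"plant {plant}: tm must be < te")
        if not p.h0 < p.hmax:
            raise ValueError(f"plant {plant}: h0 must be < hmax")
    rng = _rng(seed, "growth")
    ages = gdd_transform(measurement_days, temps)
    records = []
    for plant, p in growth_params.items():
        heights = beta_sigmoid_height(ages, p)
        noisy = heights + rng.normal(0.0, noise_sd, size=len(ages)) if noise_sd > 0 else heights
        for day, h in zip(measurement_days, noisy):
            records.append((plant, int(day), float(h)))
    return pd.DataFrame(records, columns=["plant_id", "day", "height_cm"])


def make_temperature_series(
    start_doy: int = 252,
    n_days: int = 320,
    t_base: float = 5.0,
    seed: int = 0,
) -> TemperatureSeries:
    """Synthetic daily mean temperatures for a temperate-field season.

    A sinusoidal annual cycle (mean 10 degC, amplitude 8, coldest in
    mid-January) plus Normal(0, 2) day-to-day noise, starting at sowing in
    early September and running past harvest the next summer.
    """
    rng = _rng(seed, "growth")
    days = np.arange(start_doy, start_doy + n_days)
    t = 10.0 + 8.0 * np.sin(2 * np.pi * (days - 105) / 365.25) + rng.normal(0, 2.0, n_days)
    return TemperatureSeries(days=days, temps=t, t_base=t_base)


def simulate_trial(
    config: SimulationConfig | None = None,
    n_rows: int = 10,
    n_cols: int = 10,
    spacing: float = 0.5,
    missing_fraction: float = 0.02,
) -> dict:
    """Run the full generator: layout, latent field, counts, phenotypes, growth.

    Returns a dict with keys design, latent, counts, meta, truth,
    phenotypes, growth_series, temperature.
    """
    config = config or SimulationConfig()
    design = make_field_design(
        n_rows, n_cols, spacing, missing_fraction=missing_fraction, seed=config.seed
    )
    latent = simulate_latent_field(
        design,
        sigma2=config.latent_sigma2,
        nugget=config.latent_nugget,
        range_=config.latent_range,
        seed=config.seed,
    )
    counts, meta, truth = simulate_expression(design, config, latent)
    phenotypes = simulate_phenotypes(truth, config, latent)
    truth.true_growth_params = simulate_growth_params(design, seed=config.seed)
    temps = make_temperature_series(seed=config.seed)
    sowing = int(temps.days[0])
    # 13 height measurements between 189 and 231 DAS plus the final harvest
    das = np.round(np.linspace(189, 231, 13)).astype(int).tolist() + [278]
    measurement_days = [sowing + d for d in das]
    growth_series = simulate_growth_series(
        truth.true_growth_params, temps, measurement_days, noise_sd=1.0, seed=config.seed
    )
    return {
        "design": design,
        "latent": latent,
        "counts": counts,
        "meta": meta,
        "truth": truth,
        "phenotypes": phenotypes,
        "growth_series": growth_series,
        "temperature": temps,
    }
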