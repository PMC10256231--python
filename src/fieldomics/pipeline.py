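"""Table IO, configuration and end-to-end orchestration.

Readers validate the on-disk exchange formats (counts TSV, sample-metadata
CSV, phenotype CSV/XLSX, layout CSV, temperature CSV), cross-reference
plant identifiers between tables, and hand typed in-memory objects to the
analysis stages.  ``run_pipeline`` chains normalization, variability,
spatial autocorrelation, association and prediction as toggled by the
configuration, writing per-stage tables plus a provenance manifest (seeds,
package version, config hash).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lme, predict, rlog, spatial, variability
from . import simulate as simulate_mod
from .growth import TemperatureSeries
from .simulate import FieldDesign, make_field_design

__all__ = [
    "PipelineConfig",
    "Dataset",
    "load_tables",
    "run_pipeline",
    "write_simulation",
    "read_layout",
    "read_counts",
]


@dataclass
class PipelineConfig:
    """Validated stage parameters; unknown keys in a config file are rejected."""

    counts: str = "counts.tsv"
    metadata: str = "sample_meta.csv"
    phenotypes: str = "phenotypes.csv"
    layout: str = "layout.csv"
    temperature: str | None = None
    annotation: str | None = None
    out_dir: str = "results"
    seed: int = 0
    n_perm: int = 100_000
    n_repeats: int = 9
    n_folds: int = 10
    t_base: float = 5.0
    moran_q_threshold: float = 0.05
    assoc_q_threshold: float = 0.05
    spearman_q_threshold: float = 0.01
    run_normalize: bool = True
    run_variability: bool = True
    run_moran: bool = True
    run_assoc: bool = True
    run_predict: bool = False
    predict_phenotypes: tuple[str, ...] = ()
    predict_selectors: tuple[str, ...] = ("median", "spearman")
    predict_models: tuple[str, ...] = ("enet",)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("predict_phenotypes", "predict_selectors", "predict_models"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        # where the results land does not change what was computed
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        canon = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class Dataset:
    design: FieldDesign
    counts: pd.DataFrame
    meta: pd.DataFrame
    phenotypes: pd.DataFrame
    temperature: TemperatureSeries | None = None
    annotation: dict[str, set[str]] | None = None
    dropped_plants: tuple[str, ...] = ()


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    values = counts.to_numpy()
    if not np.all(np.isfinite(values)) or np.any(values < 0) or np.any(values != np.round(values)):
        raise ValueError(f"{path}: counts must be non-negative integers")
    return counts.astype(np.int64)


def read_layout(path: str | Path) -> FieldDesign:
    """Rebuild a FieldDesign from a layout CSV (plant_id, row, col, border, missing)."""
    layout = pd.read_csv(path)
    required = {"plant_id", "row", "col", "border", "missing"}
    if not required <= set(layout.columns):
        raise ValueError(f"{path}: layout needs columns {sorted(required)}")
    spacing = float(layout.attrs.get("spacing", 0.5))
    if "spacing" in layout.columns:
        spacing = float(layout["spacing"].iloc[0])
    return FieldDesign(
        n_rows=int(layout["row"].max()) + 1,
        n_cols=int(layout["col"].max()) + 1,
        spacing=spacing,
        rows=layout["row"].to_numpy(),
        cols=layout["col"].to_numpy(),
        plant_ids=tuple(layout["plant_id"].astype(str)),
        border_mask=layout["border"].to_numpy(bool),
        missing_mask=layout["missing"].to_numpy(bool),
    )


def _read_phenotypes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        table = pd.read_excel(path, index_col=0)
    else:
        table = pd.read_csv(path, index_col=0)
    table.index = table.index.astype(str)
    return table


def load_tables(config: PipelineConfig) -> Dataset:
    """Load and cross-validate all input tables.

    Counts are integer-checked; every sample must map to a plant in the
    layout; phenotype rows for plants absent from the layout's analysis
    set are dropped with a warning (e.g. a plant that did not survive the
    season appears in early tables only).
    """
    counts = read_counts(config.counts)
    meta = pd.read_csv(config.metadata)
    for col in ("sample_id", "plant_id", "batch"):
        if col not in meta.columns:
            raise ValueError(f"metadata must contain column {col!r}")
    meta["plant_id"] = meta["plant_id"].astype(str)
    if list(counts.columns) != list(meta["sample_id"].astype(str)):
        raise ValueError("count columns and metadata sample_id must match in order")
    design = read_layout(config.layout)
    analysis = set(design.analysis_plants)
    unknown = set(meta["plant_id"]) - analysis
    if unknown:
        raise ValueError(f"samples map to plants outside the analysis set: {sorted(unknown)}")
    phenotypes = _read_phenotypes(config.phenotypes)
    for col in phenotypes.columns:
        if not pd.api.types.is_numeric_dtype(phenotypes[col]):
            # qualitative scores (e.g. lesion severity classes) keep their order
            levels = sorted(phenotypes[col].dropna().unique())
            phenotypes[col] = pd.Categorical(
                phenotypes[col], categories=levels, ordered=True
            )
    dropped = tuple(sorted(set(phenotypes.index) - analysis))
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} phenotype plant(s) absent from the layout: {dropped}",
            stacklevel=2,
        )
        phenotypes = phenotypes.loc[[p for p in phenotypes.index if p in analysis]]
    temperature = None
    if config.temperature:
        temp = pd.read_csv(config.temperature)
        temperature = TemperatureSeries(
            days=temp["day"].to_numpy(int),
            temps=temp["temp_c"].to_numpy(float),
            t_base=config.t_base,
        )
    annotation = None
    if config.annotation:
        ann = pd.read_csv(config.annotation, sep="\t", header=None, names=["gene", "category"])
        annotation = {c: set(g) for c, g in ann.groupby("category")["gene"]}
    return Dataset(
        design=design,
        counts=counts,
        meta=meta,
        phenotypes=phenotypes,
        temperature=temperature,
        annotation=annotation,
        dropped_plants=dropped,
    )


def write_simulation(trial: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated trial to the on-disk exchange formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design: FieldDesign = trial["design"]
    paths = {}
    paths["counts"] = out / "counts.tsv"
    trial["counts"].to_csv(paths["counts"], sep="\t")
    paths["metadata"] = out / "sample_meta.csv"
    trial["meta"].to_csv(paths["metadata"], index=False)
    paths["phenotypes"] = out / "phenotypes.csv"
    trial["phenotypes"].to_csv(paths["phenotypes"])
    layout = pd.DataFrame(
        {
            "plant_id": design.plant_ids,
            "row": design.rows,
            "col": design.cols,
            "border": design.border_mask,
            "missing": design.missing_mask,
            "spacing": design.spacing,
        }
    )
    paths["layout"] = out / "layout.csv"
    layout.to_csv(paths["layout"], index=False)
    paths["growth"] = out / "growth_series.csv"
    trial["growth_series"].to_csv(paths["growth"], index=False)
    temps: TemperatureSeries = trial["temperature"]
    paths["temperature"] = out / "temperature.csv"
    pd.DataFrame({"day": temps.days, "temp_c": temps.temps}).to_csv(
        paths["temperature"], index=False
    )
    truth = trial["truth"]
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(
        json.dumps(
            {
                "causal_gene_ids": list(truth.causal_gene_ids),
                "true_phenotype_coefs": truth.true_phenotype_coefs.tolist(),
                "latent_field": truth.latent_field.tolist(),
                "causal_signal": simulate_mod.causal_signal(truth).tolist(),
                "plants": list(truth.plants),
                "growth_params": {
                    p: {"h0": g.h0, "hmax": g.hmax, "tm": g.tm, "te": g.te}
                    for p, g in truth.true_growth_params.items()
                },
            },
            indent=1,
        )
    )
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages and write their tables under ``out_dir``.

    Stage order: normalize -> variability -> moran -> assoc -> predict.
    Partial outputs are preserved if a later stage raises.  Returns a dict
    of in-memory stage results plus the provenance manifest.
    """
    data = load_tables(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"dataset": data}
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }

    counts = rlog.drop_unexpressed(data.counts)
    size_factors = rlog.estimate_size_factors(counts)

    if config.run_normalize:
        model = rlog.fit_rlog(counts, data.meta, size_factors=size_factors)
        rmat = rlog.rlog_matrix(model)
        normed = rlog.batch_normalized_counts(counts, model, data.meta, size_factors)
        rmat.to_csv(out / "rlog.tsv", sep="\t")
        normed.to_csv(out / "normalized_counts.tsv", sep="\t")
        results.update(rlog_model=model, rlog=rmat, normalized=normed)
        manifest["stages"].append("normalize")

    if config.run_variability and "normalized" in results:
        gene_table, trend = variability.gene_variability_table(results["normalized"])
        gene_table.to_csv(out / "gene_variability.tsv", sep="\t")
        pheno_rows = []
        for col in data.phenotypes.columns:
            vals = data.phenotypes[col].dropna().to_numpy(dtype=float)
            # CVs are meaningful for positive-valued measurements only
            if len(vals) < 8 or np.allclose(vals, vals[0]) or vals.mean() <= 0:
                continue
            cv = variability.coefficient_of_variation(vals)
            mask = variability.detect_outliers(vals)
            kept = vals[~mask]
            cv_no = (
                variability.coefficient_of_variation(kept)
                if len(kept) >= 2 and kept.mean() != 0
                else np.nan
            )
            try:
                sh_p, ad_stat, ok = variability.normality_screen(vals)
            except ValueError:
                sh_p, ad_stat, ok = np.nan, np.nan, False
            pheno_rows.append((col, cv, cv_no, int(mask.sum()), sh_p, ad_stat, ok))
        pheno_table = pd.DataFrame(
            pheno_rows,
            columns=[
                "phenotype",
                "cv_percent",
                "cv_percent_no_outliers",
                "n_outliers",
                "shapiro_p",
                "anderson_stat",
                "normal_at_0.01",
            ],
        ).set_index("phenotype")
        pheno_table.to_csv(out / "phenotype_variability.tsv", sep="\t")
        results.update(gene_variability=gene_table, cv_trend=trend, phenotype_variability=pheno_table)
        manifest["stages"].append("variability")

    if config.run_moran and "rlog" in results:
        W = spatial.build_spatial_weights(data.design, mode="queen")
        rmat = results["rlog"][list(W.plants)]
        rows = []
        for gene, values in rmat.iterrows():
            x = values.to_numpy(dtype=float)
            if np.allclose(x, x[0]):
                continue
            res = spatial.moran_test(x, W, n_perm=config.n_perm, seed=config.seed)
            rows.append((gene, res.I, res.p_perm, res.p_param))
        moran_table = pd.DataFrame(rows, columns=["id", "I", "p_perm", "p_param"]).set_index("id")
        moran_table["q_perm"] = spatial.bh_adjust(moran_table["p_perm"].to_numpy())
        moran_table["q_param"] = spatial.bh_adjust(moran_table["p_param"].to_numpy())
        moran_table.to_csv(out / "moran_genes.tsv", sep="\t")
        results["moran_genes"] = moran_table
        manifest["stages"].append("moran")

    if config.run_assoc and "rlog" in results:
        plants = list(results["rlog"].columns)
        coords = data.design.coords(plants)
        X = results["rlog"].T
        summary_rows = []
        assoc_tables = {}
        for col in data.phenotypes.select_dtypes(include=[np.number]).columns:
            yp = data.phenotypes[col].reindex(plants)
            if yp.notna().sum() < 10 or yp.dropna().std() == 0:
                continue
            table = lme.screen_features(yp, X, coords)
            table.to_csv(out / f"assoc_{col}.tsv", sep="\t")
            assoc_tables[col] = table
            sig = table["q"] <= config.assoc_q_threshold
            top = table.index[0] if len(table) else None
            summary_rows.append(
                (col, int(sig.sum()), top, float(table["q"].iloc[0]) if len(table) else np.nan)
            )
        assoc_summary = pd.DataFrame(
            summary_rows, columns=["phenotype", "n_significant", "top_feature", "top_q"]
        ).set_index("phenotype")
        assoc_summary.to_csv(out / "assoc_summary.tsv", sep="\t")
        results.update(assoc=assoc_tables, assoc_summary=assoc_summary)
        manifest["stages"].append("assoc")

    if config.run_predict and "rlog" in results:
        plants = list(results["rlog"].columns)
        X = results["rlog"].T
        scheme = predict.CvScheme(config.n_repeats, config.n_folds, config.seed)
        pred_rows = []
        pred_results: dict = {}
        targets = config.predict_phenotypes or tuple(
            data.phenotypes.select_dtypes(include=[np.number]).columns
        )
        for col in targets:
            yp = data.phenotypes[col].reindex(plants)
            if yp.isna().any():
                continue
            for sel in config.predict_selectors:
                for mod in config.predict_models:
                    res = predict.run_repeated_cv(X, yp.to_numpy(), sel, mod, scheme)
                    pred_results[(col, sel, mod)] = res
                    pred_rows.append(
                        (col, sel, mod, res.median_test_r2, res.median_pooled_r2, res.median_pooled_pcc)
                    )
        pred_summary = pd.DataFrame(
            pred_rows,
            columns=[
                "phenotype",
                "selector",
                "model",
                "median_test_r2",
                "median_pooled_r2",
                "median_pooled_pcc",
            ],
        )
        pred_summary.to_csv(out / "prediction_summary.tsv", sep="\t", index=False)
        results.update(predictions=pred_results, prediction_summary=pred_summary)
        manifest["stages"].append("predict")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
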