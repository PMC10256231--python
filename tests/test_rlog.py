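"""Size factors, dispersions and the penalized NB normalization model."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from fieldomics import rlog, simulate


def _meta(plants, batches=None, prefix="s"):
    plants = list(plants)
    batches = batches or ["b1"] * len(plants)
    return pd.DataFrame(
        {
            "sample_id": [f"{prefix}{i}" for i in range(len(plants))],
            "plant_id": plants,
            "batch": batches,
        }
    )


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(rlog.estimate_size_factors(counts), 1.0)

    def test_doubled_library_median_of_ratios(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        s = rlog.estimate_size_factors(counts)
        np.testing.assert_allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_single_sample_unit_factor(self):
        counts = pd.DataFrame({"a": [5, 9]})
        np.testing.assert_allclose(rlog.estimate_size_factors(counts), [1.0])

    def test_geometric_mean_one(self, rng):
        counts = pd.DataFrame(rng.poisson(100, size=(50, 8)))
        s = rlog.estimate_size_factors(counts)
        assert np.exp(np.mean(np.log(s))) == pytest.approx(1.0)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            rlog.estimate_size_factors(pd.DataFrame(np.zeros((3, 2))))

    def test_no_universally_expressed_gene_falls_back(self, rng):
        counts = pd.DataFrame(rng.poisson(30, size=(40, 4)))
        counts.iloc[:, 0] = np.where(np.arange(40) % 2 == 0, 0, counts.iloc[:, 0])
        counts.iloc[:, 1] = np.where(np.arange(40) % 2 == 1, 0, counts.iloc[:, 1])
        s = rlog.estimate_size_factors(counts)
        assert np.all(s > 0)


class TestDispersions:
    def test_nb_gene_recovered_across_samples(self, rng):
        alpha = 0.5
        r = 1 / alpha
        mu = 100.0
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu), size=(1, 500)), index=["g"]
        )
        s = pd.Series(np.ones(500), index=counts.columns)
        est = rlog.estimate_dispersions(counts, s)["g"]
        assert est == pytest.approx(alpha, abs=0.1)

    def test_poisson_gene_hits_floor_region(self, rng):
        counts = pd.DataFrame(rng.poisson(200, size=(1, 800)), index=["g"])
        s = pd.Series(np.ones(800), index=counts.columns)
        assert rlog.estimate_dispersions(counts, s)["g"] < 0.01

    def test_constant_gene_floor(self):
        counts = pd.DataFrame(np.full((1, 20), 50), index=["g"])
        s = pd.Series(np.ones(20), index=counts.columns)
        assert rlog.estimate_dispersions(counts, s)["g"] == rlog.DISPERSION_FLOOR

    def test_repeat_based_estimator_ignores_plant_variation(self, rng):
        """With metadata, between-plant differences do not inflate alpha."""
        alpha = 0.03
        r = 1 / alpha
        n_plants = 40
        plant_mu = np.exp(rng.normal(np.log(200), 1.0, n_plants))  # huge biology
        cols, plants = [], []
        for p in range(n_plants):
            for rep in range(2):
                cols.append(rng.negative_binomial(r, r / (r + plant_mu[p])))
                plants.append(f"p{p}")
        counts = pd.DataFrame(np.array(cols, dtype=float).T.reshape(1, -1), index=["g"])
        counts.columns = [f"s{i}" for i in range(2 * n_plants)]
        meta = _meta(plants)
        s = pd.Series(np.ones(2 * n_plants), index=counts.columns)
        est_with = rlog.estimate_dispersions(counts, s, meta=meta)["g"]
        est_without = rlog.estimate_dispersions(counts, s)["g"]
        assert est_with == pytest.approx(alpha, abs=0.03)
        assert est_without > 0.5  # inflated by plant-to-plant variation


def _saturated_nb_mle(k, s, alpha):
    """Brute-force per-gene NB MLE with one free mean per sample (log2)."""
    out = []
    for kj, sj in zip(k, s):
        def nll(b):
            mu = sj * 2.0**b[0]
            r = 1 / alpha
            return -(
                special.gammaln(kj + r)
                - special.gammaln(r)
                + r * np.log(r / (r + mu))
                + kj * np.log(mu / (r + mu))
            )
        res = optimize.minimize_scalar(lambda b: nll([b]), bounds=(-5, 25), method="bounded")
        out.append(res.x)
    return np.array(out)


class TestFitRlog:
    def test_constant_gene_reduces_to_intercept(self):
        counts = pd.DataFrame([[16] * 6], index=["g"], columns=[f"s{i}" for i in range(6)])
        meta = _meta([f"p{i}" for i in range(6)])
        s = pd.Series(np.ones(6), index=counts.columns)
        model = rlog.fit_rlog(counts, meta, size_factors=s, prior_variance=1.0)
        assert model.intercepts[0] == pytest.approx(4.0, abs=1e-4)
        np.testing.assert_allclose(model.plant_effects[0], 0.0, atol=1e-4)

    def test_infinite_shrinkage_collapses_plant_effects(self, small_trial):
        counts = small_trial["counts"].iloc[:10]
        model = rlog.fit_rlog(counts, small_trial["meta"], prior_variance=1e-10)
        np.testing.assert_allclose(model.plant_effects, 0.0, atol=1e-3)
        rmat = rlog.rlog_matrix(model)
        # every plant gets the intercept
        np.testing.assert_allclose(
            rmat.to_numpy(), np.broadcast_to(model.intercepts[:, None], rmat.shape), atol=1e-3
        )

    def test_no_shrinkage_limit_matches_saturated_mle(self, rng):
        """prior variance -> inf, one sample per plant, one batch: rlog
        matches the brute-force per-sample NB MLE."""
        n = 12
        mu = 150.0
        alpha = 0.05
        r = 1 / alpha
        k = rng.negative_binomial(r, r / (r + mu), size=n).astype(float)
        k = np.maximum(k, 1)
        counts = pd.DataFrame([k], index=["g"], columns=[f"s{i}" for i in range(n)])
        meta = _meta([f"p{i}" for i in range(n)])
        s = pd.Series(np.ones(n), index=counts.columns)
        disp = pd.Series([alpha], index=["g"])
        model = rlog.fit_rlog(
            counts, meta, dispersions=disp, size_factors=s, prior_variance=1e8
        )
        fitted = rlog.rlog_matrix(model).to_numpy()[0]
        expected = _saturated_nb_mle(k, np.ones(n), alpha)
        np.testing.assert_allclose(fitted, expected, atol=1e-3)

    def test_batch_scaling_invariance(self, small_trial):
        """Multiplying one non-reference batch by a constant moves its
        coefficients by log2 of the constant but leaves the rlog output of
        well-measured genes unchanged (counts near zero carry genuinely
        different Poisson information after scaling)."""
        counts = small_trial["counts"].iloc[:15]
        meta = small_trial["meta"]
        model0 = rlog.fit_rlog(counts, meta, prior_variance=0.5, reference_batch="batch2")
        scaled = counts.copy().astype(float)
        b1 = meta["batch"] == "batch1"
        scaled.loc[:, b1.to_numpy()] *= 4.0
        scaled = scaled.round().astype(int)
        s0 = rlog.estimate_size_factors(counts)
        model1 = rlog.fit_rlog(
            scaled,
            meta,
            size_factors=s0,  # same library scaling: the shift must go to the batch term
            dispersions=pd.Series(model0.dispersions, index=counts.index),
            prior_variance=0.5,
            reference_batch="batch2",
        )
        i1 = model1.batches.index("batch1")
        i0 = model0.batches.index("batch1")
        assert np.median(model1.batch_coefs[:, i1] - model0.batch_coefs[:, i0]) == pytest.approx(
            2.0, abs=0.05
        )
        well_measured = (counts.min(axis=1) >= 50).to_numpy()
        assert well_measured.sum() >= 3
        r0 = rlog.rlog_matrix(model0).to_numpy()[well_measured]
        r1 = rlog.rlog_matrix(model1).to_numpy()[well_measured]
        np.testing.assert_allclose(r1, r0, atol=0.1)

    def test_shrinkage_monotonicity(self):
        """The prior contracts plant effects: per-gene norms shrink
        strictly, coordinates up to the coupling through the shared
        intercept (small tolerance)."""
        rng = np.random.default_rng(5)
        n = 30
        mu = 2.0 ** rng.uniform(5, 9, size=(20, 1)) * 2.0 ** rng.normal(
            0, 0.6, size=(20, n)
        )
        alpha = 0.03
        r = 1 / alpha
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(n)],
        )
        meta = _meta([f"p{i}" for i in range(n)])
        s = pd.Series(np.ones(n), index=counts.columns)
        disp = pd.Series(np.full(20, alpha), index=counts.index)
        flat = rlog.fit_rlog(counts, meta, dispersions=disp, size_factors=s,
                             prior_variance=1e8)
        for pv in (0.5, 0.05):
            shrunk = rlog.fit_rlog(counts, meta, dispersions=disp, size_factors=s,
                                   prior_variance=pv)
            norms_s = np.linalg.norm(shrunk.plant_effects, axis=1)
            norms_f = np.linalg.norm(flat.plant_effects, axis=1)
            assert np.all(norms_s <= norms_f + 1e-6)
            assert np.all(
                np.abs(shrunk.plant_effects) <= np.abs(flat.plant_effects) + 0.05
            )

    def test_sample_order_permutation_invariance(self, small_trial):
        counts = small_trial["counts"].iloc[:8]
        meta = small_trial["meta"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(meta))
        counts_p = counts.iloc[:, perm]
        meta_p = meta.iloc[perm].reset_index(drop=True)
        m0 = rlog.fit_rlog(counts, meta, prior_variance=0.5, reference_batch="batch2")
        m1 = rlog.fit_rlog(counts_p, meta_p, prior_variance=0.5, reference_batch="batch2")
        r0 = rlog.rlog_matrix(m0)
        r1 = rlog.rlog_matrix(m1)[r0.columns]
        np.testing.assert_allclose(r0.to_numpy(), r1.to_numpy(), atol=1e-4)

    def test_recovery_of_true_plant_effects(self):
        """Fitted and true plant effects correlate >= 0.9 for genes with
        mean normalized count >= 20 at the default generator settings."""
        cfg = simulate.SimulationConfig(n_genes=150, n_causal_genes=15, seed=21)
        trial = simulate.simulate_trial(cfg)
        counts, meta, truth = trial["counts"], trial["meta"], trial["truth"]
        s = rlog.estimate_size_factors(counts)
        model = rlog.fit_rlog(counts, meta, size_factors=s)
        means = (counts.to_numpy() / s.to_numpy()[None, :]).mean(axis=1)
        keep = means >= 20
        fit = model.plant_effects[keep]
        tr = truth.gene_plant_effects[keep]
        fit = fit - fit.mean(axis=1, keepdims=True)
        tr = tr - tr.mean(axis=1, keepdims=True)
        assert np.corrcoef(fit.ravel(), tr.ravel())[0, 1] >= 0.9


class TestOutputs:
    def test_rlog_collapses_technical_repeats(self, small_trial, small_rlog):
        rmat = rlog.rlog_matrix(small_rlog)
        meta = small_trial["meta"]
        assert list(rmat.columns) == list(pd.unique(meta["plant_id"]))
        assert rmat.shape[1] == len(small_trial["design"].analysis_plants)

    def test_batch_normalized_single_batch_is_k_over_s(self):
        counts = pd.DataFrame(
            [[10, 20, 40], [5, 10, 20]], index=["g1", "g2"], columns=["s0", "s1", "s2"]
        )
        meta = _meta(["p0", "p1", "p2"])
        s = pd.Series([0.5, 1.0, 2.0], index=counts.columns)
        model = rlog.fit_rlog(counts, meta, size_factors=s, prior_variance=1.0)
        normed = rlog.batch_normalized_counts(counts, model, meta, size_factors=s)
        np.testing.assert_allclose(normed.to_numpy(), [[20, 20, 20], [10, 10, 10]])

    def test_repeats_collapsed_by_averaging(self):
        counts = pd.DataFrame([[10, 14, 8]], index=["g"], columns=["s0", "s1", "s2"])
        meta = _meta(["pA", "pA", "pB"])
        s = pd.Series(np.ones(3), index=counts.columns)
        model = rlog.fit_rlog(counts, meta, size_factors=s, prior_variance=1.0)
        normed = rlog.batch_normalized_counts(counts, model, meta, size_factors=s)
        assert normed.loc["g", "pA"] == pytest.approx(12.0)
        assert normed.loc["g", "pB"] == pytest.approx(8.0)

    def test_known_batch_factor_divides_counts(self):
        counts = pd.DataFrame([[100, 100, 100, 100]], index=["g"])
        counts.columns = ["s0", "s1", "s2", "s3"]
        meta = _meta(["p0", "p1", "p2", "p3"], batches=["b1", "b1", "b2", "b2"])
        s = pd.Series(np.ones(4), index=counts.columns)
        model = rlog.fit_rlog(counts, meta, size_factors=s, prior_variance=1.0,
                              reference_batch="b2")
        # overwrite with a known batch effect of 2.0 on the count scale
        model.batch_coefs[0, model.batches.index("b1")] = 1.0
        normed = rlog.batch_normalized_counts(counts, model, meta, size_factors=s)
        assert normed.loc["g", "p0"] == pytest.approx(50.0)
        assert normed.loc["g", "p2"] == pytest.approx(100.0)
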