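import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from strivar import synthetic as syn
from strivar.de import (
    aggregate_pseudobulk,
    build_effect_profile_matrix,
    cluster_age_profiles,
    cross_celltype_effect_correlation,
    estimate_transcriptome_impact,
    fit_age_sex_de,
    normalize_log2cpm,
)


class TestAggregatePseudobulk:
    def _tiny(self):
        matrix = np.array([[1, 3], [2, 4]])  # 2 genes x 2 nuclei
        barcodes = ["bc1", "bc2"]
        assignments = pd.DataFrame(
            {"nucleus_id": barcodes, "donor_id": "d1", "region": "CaH",
             "cell_type": "OPC"}
        )
        return matrix, ["g1", "g2"], barcodes, assignments

    def test_sums_counts_per_donor(self):
        matrix, features, barcodes, assignments = self._tiny()
        pb, _ = aggregate_pseudobulk(matrix, features, barcodes, assignments,
                                     min_cells=1)
        assert pb[("OPC", "CaH")].counts.loc["d1"].tolist() == [4, 6]

    def test_min_cells_excludes_and_logs(self):
        matrix, features, barcodes, assignments = self._tiny()
        pb, log = aggregate_pseudobulk(matrix, features, barcodes, assignments,
                                       min_cells=10)
        assert pb == {}
        assert log["excluded"].all() and log["n_cells"].iloc[0] == 2

    def test_nucleus_order_invariance(self):
        matrix, features, barcodes, assignments = self._tiny()
        pb1, _ = aggregate_pseudobulk(matrix, features, barcodes, assignments,
                                      min_cells=1)
        pb2, _ = aggregate_pseudobulk(matrix[:, ::-1], features, barcodes[::-1],
                                      assignments, min_cells=1)
        pd.testing.assert_frame_equal(pb1[("OPC", "CaH")].counts,
                                      pb2[("OPC", "CaH")].counts)

    def test_unassigned_barcode_rejected(self):
        matrix, features, barcodes, assignments = self._tiny()
        with pytest.raises(ValueError):
            aggregate_pseudobulk(matrix, features, barcodes + ["bc3"],
                                 assignments, min_cells=1)


class TestNormalizeLog2cpm:
    def test_known_values(self):
        counts = pd.DataFrame({"g1": [0], "g2": [1000]}, index=["d1"])
        out = normalize_log2cpm(counts, pd.Series([1e6], index=["d1"]))
        assert out.loc["d1", "g1"] == 0.0
        assert out.loc["d1", "g2"] == pytest.approx(np.log2(1001), abs=1e-9)

    def test_scale_invariance(self, rng):
        counts = pd.DataFrame(rng.poisson(50, (3, 20)).astype(float))
        doubled = normalize_log2cpm(counts * 2)
        assert np.allclose(doubled.to_numpy(), normalize_log2cpm(counts).to_numpy())

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            normalize_log2cpm(pd.DataFrame({"g": [0]}), pd.Series([0.0]))


class TestFitAgeSexDE:
    def test_noiseless_gene_recovers_exact_slope(self):
        config = syn.CohortConfig(
            n_donors=60, regions=("CaH",), library_log_sd=0.0,
            cell_types={"OPC": syn.CellTypeSpec(baseline_logit=-3.0)},
            genes=[syn.GeneSpec(gene_id="G0", baseline_log2cpm=13.0,
                                age_log2fc_per_decade=0.1)],
            seed=4,
        )
        donors, truth = syn.generate_cohort(config)
        pb = syn.generate_pseudobulk(donors, truth, config, noiseless=True)
        res = fit_age_sex_de(pb[("OPC", "CaH")], donors)
        # the log2(cpm + 1) offset is negligible for a highly expressed gene
        assert res["beta_age"].iloc[0] == pytest.approx(0.100, abs=1e-3)
        assert res["p_age"].iloc[0] < 1e-30

    def test_matches_ols_oracle_with_equal_weights(self, small_cohort):
        pb = small_cohort["pb"][("OPC", "CaH")]
        donors = small_cohort["donors"]
        pb_eq = syn.PseudobulkMatrix(
            cell_type=pb.cell_type, region=pb.region, counts=pb.counts,
            library_size=pb.library_size,
            cells_per_donor=pd.Series(100.0, index=pb.counts.index),
        )
        res = fit_age_sex_de(pb_eq, donors).set_index("gene")
        meta = donors.set_index("donor_id").loc[pb.counts.index]
        X = np.column_stack([
            np.ones(len(meta)), (meta["age"] - 60) / 10,
            (meta["sex"] == "M").astype(float),
        ])
        Y = pb_eq.log2cpm()
        for g in res.index[:5]:
            ols = sm.OLS(Y[g].to_numpy(), X).fit()
            assert res.loc[g, "beta_age"] == pytest.approx(ols.params[1],
                                                           abs=1e-10)
            assert res.loc[g, "se_age"] == pytest.approx(ols.bse[1], abs=1e-10)

    def test_sex_hits_confined_to_sex_chromosomes(self):
        config = syn.default_cohort_config(n_donors=150, n_genes=400, n_eqtl=0,
                                           seed=21)
        donors, truth = syn.generate_cohort(config)
        pb = syn.generate_pseudobulk(donors, truth, config,
                                     cell_types=["Astrocyte"], regions=["CaH"])
        gene_meta = pd.DataFrame(
            {"gene_id": [g.gene_id for g in config.genes],
             "chrom_class": [g.chrom_class for g in config.genes]}
        )
        res = fit_age_sex_de(pb[("Astrocyte", "CaH")], donors, gene_meta=gene_meta)
        hits = res[res["q_sex"] < 0.05]
        assert len(hits) >= 5  # chrY/chrX effects are detectable
        autosomal_frac = (hits["chrom_class"] == "autosome").mean()
        assert autosomal_frac <= 0.05

    def test_rank_deficient_design_rejected(self, small_cohort):
        pb = small_cohort["pb"][("OPC", "CaH")]
        donors = small_cohort["donors"].copy()
        donors["dup"] = (donors["age"] - 60) / 10.0
        with pytest.raises(ValueError):
            fit_age_sex_de(pb, donors, covariates=["dup"])


class TestEffectProfileClustering:
    def test_k1_centroid_is_column_mean(self, rng):
        mat = pd.DataFrame(rng.normal(size=(30, 4)),
                           columns=list("abcd"))
        labels, centroids, _ = cluster_age_profiles(mat, k=1, seed=0)
        assert centroids.iloc[0].to_numpy() == pytest.approx(
            mat.mean(axis=0).to_numpy()
        )

    def test_separable_blobs_recovered_exactly(self, rng):
        up = np.tile([0.3, 0.3, 0.3, 0.3], (40, 1)) + rng.normal(0, 0.02, (40, 4))
        down = np.tile([0.0, 0.0, -0.4, 0.0], (40, 1)) + rng.normal(0, 0.02, (40, 4))
        mat = pd.DataFrame(np.vstack([up, down]), columns=list("abcd"))
        truth = np.repeat([0, 1], 40)
        labels, _, _ = cluster_age_profiles(mat, k=2, seed=1)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_deterministic_given_seed(self, rng):
        mat = pd.DataFrame(rng.normal(size=(50, 3)))
        l1, _, _ = cluster_age_profiles(mat, k=3, seed=7)
        l2, _, _ = cluster_age_profiles(mat, k=3, seed=7)
        assert (l1 == l2).all()

    def test_objective_nonincreasing_over_lloyd_iterations(self, rng):
        X = rng.normal(size=(200, 5))
        inertias = [
            KMeans(n_clusters=4, init="random", n_init=1, max_iter=it,
                   random_state=0).fit(X).inertia_
            for it in (1, 2, 3, 5, 10, 30)
        ]
        assert np.all(np.diff(inertias) <= 1e-9)

    def test_k_larger_than_genes_rejected(self, rng):
        mat = pd.DataFrame(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            cluster_age_profiles(mat, k=6, seed=0)

    def test_profile_matrix_includes_only_union_significant(self, small_de_results):
        mat, mask = build_effect_profile_matrix(small_de_results, fdr=0.05)
        q = small_de_results.pivot_table(index="gene", columns="cell_type",
                                         values="q_age", aggfunc="first")
        assert ((q.loc[mat.index] < 0.05).any(axis=1)).all()
        assert mask.shape == mat.shape


class TestCrossCellTypeCorrelation:
    def test_self_correlation_is_one(self, small_de_results):
        out = cross_celltype_effect_correlation(small_de_results, min_genes=10)
        assert np.allclose(np.diag(out.to_numpy()), 1.0)

    def test_symmetric(self, small_de_results):
        out = cross_celltype_effect_correlation(small_de_results, min_genes=10)
        assert np.allclose(out.to_numpy(), out.to_numpy().T, equal_nan=True)

    def test_shared_profiles_correlate_specific_do_not(self):
        # two MSN subtypes share one age profile; glia get independent ones
        rng = np.random.default_rng(5)
        cts = ["MSN_D1", "MSN_D2", "Astrocyte"]
        shared = {f"G{i:03d}": rng.normal(0, 0.15) for i in range(120)}
        genes = []
        for gid, eff in shared.items():
            astro = rng.normal(0, 0.15)
            genes.append(syn.GeneSpec(
                gene_id=gid, baseline_log2cpm=6.0,
                age_log2fc_per_decade={"MSN_D1": eff, "MSN_D2": eff,
                                       "Astrocyte": astro}))
        config = syn.CohortConfig(
            n_donors=150, regions=("CaH",),
            cell_types={ct: syn.CellTypeSpec(baseline_logit=-2.0) for ct in cts},
            genes=genes, seed=6,
        )
        donors, truth = syn.generate_cohort(config)
        pb = syn.generate_pseudobulk(donors, truth, config)
        res = pd.concat(
            [fit_age_sex_de(pb[(ct, "CaH")], donors) for ct in cts],
            ignore_index=True,
        )
        rho2 = cross_celltype_effect_correlation(res, min_genes=20)
        assert rho2.loc["MSN_D1", "MSN_D2"] > 0.8
        assert rho2.loc["MSN_D1", "Astrocyte"] < 0.2

    def test_insufficient_genes_reported_na(self, small_de_results):
        out = cross_celltype_effect_correlation(small_de_results, min_genes=10**6)
        off_diag = out.to_numpy()[~np.eye(len(out), dtype=bool)]
        assert np.isnan(off_diag).all()


class TestTranscriptomeImpact:
    def _results(self, betas, ses):
        return pd.DataFrame(
            {"gene": [f"G{i}" for i in range(len(betas))], "cell_type": "x",
             "beta_age": betas, "se_age": ses}
        )

    def test_null_within_three_bootstrap_se(self, rng):
        se = np.full(500, 0.02)
        betas = rng.normal(0, se)
        est = estimate_transcriptome_impact(self._results(betas, se), seed=1)
        assert abs(est.impact) < 3 * est.se

    def test_recovers_known_mean_squared_effect(self, rng):
        # true beta ~ N(0, 0.05^2): the moment estimator averages to 0.0025
        vals = []
        for _ in range(200):
            true = rng.normal(0, 0.05, 800)
            se = np.full(800, 0.02)
            betas = true + rng.normal(0, se)
            vals.append(
                estimate_transcriptome_impact(self._results(betas, se),
                                              n_boot=10, seed=0).impact
            )
        assert np.mean(vals) == pytest.approx(0.0025, abs=2e-4)

    def test_orders_strong_vs_weak_cell_types(self, rng):
        wins = 0
        for _ in range(60):
            se = np.full(400, 0.02)
            strong = rng.normal(0, 0.08, 400) + rng.normal(0, se)
            weak = rng.normal(0, 0.02, 400) + rng.normal(0, se)
            a = estimate_transcriptome_impact(self._results(strong, se),
                                              n_boot=10, seed=0).impact
            b = estimate_transcriptome_impact(self._results(weak, se),
                                              n_boot=10, seed=0).impact
            wins += a > b
        assert wins >= 57  # >= 95% of seeds

    def test_noise_genes_do_not_shift_estimate(self, rng):
        true = rng.normal(0, 0.05, 1000)
        se = np.full(1000, 0.02)
        betas = true + rng.normal(0, se)
        base = estimate_transcriptome_impact(self._results(betas, se),
                                             n_boot=10, seed=0)
        noise = rng.normal(0, 0.02, 4000)
        mixed = self._results(np.r_[betas, noise], np.r_[se, np.full(4000, 0.02)])
        diluted = estimate_transcriptome_impact(mixed, n_boot=10, seed=0)
        # the added terms have mean ~0, so the estimate shrinks by the known
        # dilution factor rather than drifting arbitrarily
        assert diluted.impact == pytest.approx(base.impact * 1000 / 5000,
                                               abs=3 * base.se)

    def test_missing_ses_rejected(self):
        df = self._results(np.zeros(200), np.full(200, np.nan))
        with pytest.raises(ValueError):
            estimate_transcriptome_impact(df)
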