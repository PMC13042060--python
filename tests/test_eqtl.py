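import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.metrics import adjusted_rand_score

from conftest import gene_tables
from strivar import synthetic as syn
from strivar.eqtl import (
    build_effect_matrix,
    cluster_eqtls,
    constraint_effect_association,
    map_cis_eqtls,
    orient_rows,
    pairwise_sharing,
)


@pytest.fixture(scope="module")
def eqtl_run(small_cohort):
    genes, snps = gene_tables(small_cohort["config"])
    pb = {ct: small_cohort["pb"][(ct, "CaH")]
          for ct in small_cohort["cell_types"]}
    results, contexts = map_cis_eqtls(
        pb, small_cohort["dosages"], snps, genes, small_cohort["donors"],
        return_context=True,
    )
    return results, contexts


class TestMapCisEqtls:
    def test_gene_level_p_is_bonferroni_min_p(self, eqtl_run):
        results, _ = eqtl_run
        tested = results.dropna(subset=["p_gene"])
        expected = np.minimum(tested["p_nominal"] * tested["n_cis_snps"], 1.0)
        assert tested["p_gene"].to_numpy() == pytest.approx(expected.to_numpy())

    def test_beta_matches_full_ols_oracle(self, eqtl_run, small_cohort):
        # Frisch-Waugh: the residualized marginal slope equals the dosage
        # coefficient of the full OLS with covariates
        results, contexts = eqtl_run
        from strivar.stats import inverse_normal_transform

        row = results.dropna(subset=["p_gene"]).iloc[7]
        ct = row["cell_type"]
        pb = small_cohort["pb"][(ct, "CaH")]
        donors = small_cohort["donors"].set_index("donor_id")
        shared = contexts[ct].donors
        y = inverse_normal_transform(pb.log2cpm().loc[shared, row["gene"]])
        meta = donors.loc[shared]
        X = np.column_stack([
            np.ones(len(shared)),
            small_cohort["dosages"].loc[shared, row["lead_snp"]],
            (meta["age"] - 60) / 10.0,
            (meta["sex"] == "M").astype(float),
        ])
        ols = sm.OLS(y, X).fit()
        assert row["beta"] == pytest.approx(ols.params[1], abs=1e-10)
        assert row["p_nominal"] == pytest.approx(ols.pvalues[1], rel=1e-6)

    def test_planted_eqtls_detected(self, eqtl_run, small_cohort):
        results, _ = eqtl_run
        planted = {g.gene_id: g for g in small_cohort["config"].genes
                   if g.eqtl_snp is not None}
        eg = results[results["egene"]]
        # strong planted effects (R^2 ~ 0.4+) should dominate the calls
        assert len(eg) >= 10
        frac_planted = eg["gene"].isin(planted).mean()
        assert frac_planted > 0.9

    def test_gene_without_cis_snps_reported_na(self, small_cohort):
        genes, snps = gene_tables(small_cohort["config"])
        genes = pd.concat(
            [genes, pd.DataFrame([{"gene_id": "G_orphan", "chrom": "chr21",
                                   "tss": 5_000_000}])], ignore_index=True)
        pb = {"OPC": small_cohort["pb"][("OPC", "CaH")]}
        counts = pb["OPC"].counts.copy()
        counts["G_orphan"] = 100
        pb = {"OPC": syn.PseudobulkMatrix(
            cell_type="OPC", region="CaH", counts=counts,
            library_size=pb["OPC"].library_size,
            cells_per_donor=pb["OPC"].cells_per_donor)}
        res = map_cis_eqtls(pb, small_cohort["dosages"], snps, genes,
                            small_cohort["donors"])
        orphan = res[res["gene"] == "G_orphan"]
        assert len(orphan) == 1
        assert orphan["n_cis_snps"].iloc[0] == 0
        assert np.isnan(orphan["p_gene"].iloc[0])

    def test_power_oracle_strong_single_snp(self, rng):
        # a SNP explaining 20% of variance at n=150: the F/t-statistic
        # comfortably clears a Bonferroni+BH 0.01 bar in >= 95% of seeds
        detected = 0
        n_seeds = 200
        for _ in range(n_seeds):
            g = rng.binomial(2, 0.3, 150).astype(float)
            gs = (g - g.mean()) / g.std()
            y = np.sqrt(0.2) * gs + rng.normal(0, np.sqrt(0.8), 150)
            r = np.corrcoef(g, y)[0, 1]
            t = r * np.sqrt(146 / (1 - r**2))
            from scipy import stats as sps

            p = 2 * sps.t.sf(abs(t), 146)
            detected += (p * 20) < 1e-3  # 20 cis SNPs, conservative eGene bar
        assert detected / n_seeds >= 0.95


class TestOrientation:
    def test_all_negative_row_flipped(self):
        mat = pd.DataFrame([[-1.0, -2.0, -0.5]], columns=list("abc"))
        out, flips = orient_rows(mat)
        assert flips[0] == -1 and (out.to_numpy() > 0).all()

    def test_majority_positive_row_unchanged(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0, -1.0, -2.0]])
        out, flips = orient_rows(mat)
        assert flips[0] == 1
        pd.testing.assert_frame_equal(out, mat)

    def test_orientation_is_idempotent(self, rng):
        mat = pd.DataFrame(rng.normal(size=(50, 6)))
        once, _ = orient_rows(mat)
        twice, flips = orient_rows(once)
        assert (flips == 1).all()
        pd.testing.assert_frame_equal(twice, once)


class TestEffectMatrix:
    def test_cell_type_specific_effect_localized(self):
        # an astrocyte-only eQTL shows large |beta| only in astrocyte columns
        cts = ["Astrocyte_striatal", "Astrocyte_cortical", "MSN_D1"]
        snp = syn.SnpSpec("rs_astro", "chr1", 1_001_000, 0.4)
        genes = [syn.GeneSpec(
            gene_id="G_astro", chrom="chr1", tss=1_000_000,
            baseline_log2cpm=6.0, eqtl_snp="rs_astro",
            eqtl_effect={"Astrocyte_striatal": 0.8, "Astrocyte_cortical": 0.8},
        )]
        genes += [syn.GeneSpec(gene_id=f"N{i}", chrom="chr2",
                               tss=1_000_000 + i * 200_000,
                               baseline_log2cpm=6.0) for i in range(30)]
        config = syn.CohortConfig(
            n_donors=150, regions=("CaH",),
            cell_types={ct: syn.CellTypeSpec(baseline_logit=-2.0) for ct in cts},
            genes=genes, snps=[snp], seed=8,
        )
        donors, truth = syn.generate_cohort(config)
        dosages = syn.generate_genotypes(donors, config, truth)
        pb = syn.generate_pseudobulk(donors, truth, config)
        gene_df, snp_df = gene_tables(config)
        res, ctx = map_cis_eqtls(
            {ct: pb[(ct, "CaH")] for ct in cts}, dosages, snp_df, gene_df,
            donors, return_context=True)
        mat, mask, lead = build_effect_matrix(res, ctx)
        row = mat.loc["G_astro"]
        assert abs(row["Astrocyte_striatal"]) > 3 * abs(row["MSN_D1"])
        assert abs(row["Astrocyte_cortical"]) > 3 * abs(row["MSN_D1"])

    def test_lead_snp_from_best_cell_type(self, eqtl_run):
        results, contexts = eqtl_run
        mat, mask, lead = build_effect_matrix(results, contexts)
        eg = results[results["egene"]]
        for _, row in lead.iterrows():
            best = eg[eg["gene"] == row["gene"]].sort_values("p_gene").iloc[0]
            assert row["lead_snp"] == best["lead_snp"]


class TestClusterEqtls:
    def test_k1_centroid_is_column_mean(self, rng):
        mat = pd.DataFrame(rng.normal(size=(40, 5)))
        labels, centroids, summary = cluster_eqtls(mat, k=1, seed=0)
        assert centroids.iloc[0].to_numpy() == pytest.approx(
            mat.mean(axis=0).to_numpy())

    def test_planted_patterns_recovered(self, rng):
        cols = ["MSN", "interneuron", "microglia", "astro"]
        pan = np.tile([1.0, 1.0, 1.0, 1.0], (30, 1))
        msn = np.tile([1.2, 0.0, 0.0, 0.0], (30, 1))
        mic = np.tile([0.0, 0.0, 1.2, 0.0], (30, 1))
        mat = pd.DataFrame(np.vstack([pan, msn, mic]) + rng.normal(0, 0.05, (90, 4)),
                           columns=cols)
        truth = np.repeat([0, 1, 2], 30)
        labels, _, summary = cluster_eqtls(mat, k=3, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert summary["n_eqtls"].sum() == 90

    def test_reproducible_given_seed(self, rng):
        mat = pd.DataFrame(rng.normal(size=(60, 4)))
        l1, _, _ = cluster_eqtls(mat, k=4, seed=3)
        l2, _, _ = cluster_eqtls(mat, k=4, seed=3)
        assert (l1 == l2).all()

    def test_k_exceeding_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_eqtls(pd.DataFrame(rng.normal(size=(5, 2))), k=13)


class TestPairwiseSharing:
    def _mat_sig(self, rng, rho_shared=True):
        n = 80
        base = rng.normal(0, 1, n)
        if rho_shared:
            a, b = base + rng.normal(0, 0.1, n), base + rng.normal(0, 0.1, n)
        else:
            a, b = base, rng.normal(0, 1, n)
        mat = pd.DataFrame({"a": a, "b": b},
                           index=[f"g{i}" for i in range(n)])
        sig = pd.DataFrame(True, index=mat.index, columns=mat.columns)
        return mat, sig

    def test_self_sharing_is_one(self, rng):
        mat, sig = self._mat_sig(rng)
        out = pairwise_sharing(mat, sig)
        assert out.loc["a", "a"] == 1.0

    def test_shared_effects_give_high_rho2(self, rng):
        mat, sig = self._mat_sig(rng, rho_shared=True)
        assert pairwise_sharing(mat, sig).loc["a", "b"] > 0.9

    def test_disjoint_effects_give_low_rho2(self, rng):
        mat, sig = self._mat_sig(rng, rho_shared=False)
        assert pairwise_sharing(mat, sig).loc["a", "b"] < 0.1

    def test_insufficient_eqtls_na(self, rng):
        mat, sig = self._mat_sig(rng)
        out = pairwise_sharing(mat.iloc[:5], sig.iloc[:5])
        assert np.isnan(out.loc["a", "b"])


class TestConstraintAssociation:
    def test_perfect_inverse_monotone(self):
        effects = pd.Series(np.linspace(1.0, 0.1, 100),
                            index=[f"g{i}" for i in range(100)])
        constraint = pd.Series(np.linspace(0.0, 1.0, 100),
                               index=effects.index)
        res = constraint_effect_association(effects, constraint)
        assert res.spearman_rho == pytest.approx(-1.0)
        assert res.direction == "negative"

    def test_constrained_genes_with_smaller_effects_detected(self, rng):
        hits = 0
        for _ in range(40):
            constrained = rng.random(300) < 0.5
            scale = np.where(constrained, 0.5, 1.0)
            effects = pd.Series(np.abs(rng.normal(0, scale)),
                                index=[f"g{i}" for i in range(300)])
            scores = pd.Series(constrained.astype(float)
                               + rng.normal(0, 0.1, 300), index=effects.index)
            res = constraint_effect_association(effects, scores)
            hits += (res.spearman_rho < 0) and (res.spearman_p < 0.01)
        assert hits >= 38  # >= 95% of seeds

    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(200):
            effects = pd.Series(np.abs(rng.normal(0, 1, 100)),
                                index=[f"g{i}" for i in range(100)])
            scores = pd.Series(rng.normal(size=100), index=effects.index)
            ps.append(constraint_effect_association(effects, scores).spearman_p)
        # mean of a uniform is 0.5; sd 1/sqrt(12)
        assert abs(np.mean(ps) - 0.5) < 3 * (1 / np.sqrt(12)) / np.sqrt(200)

    def test_constant_scores_rejected(self):
        effects = pd.Series(np.linspace(1, 2, 60),
                            index=[f"g{i}" for i in range(60)])
        with pytest.raises(ValueError):
            constraint_effect_association(
                effects, pd.Series(1.0, index=effects.index))
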