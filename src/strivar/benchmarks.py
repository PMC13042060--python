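"""Parameter-recovery and calibration experiments on synthetic cohorts.

Each function simulates cohorts under stated generating values, runs the
corresponding analysis from this package, and summarises recovery across
seeds. These are the package's reproducibility workloads: the acceptance
script and the acceptance test suite both call them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthetic as syn
from .abundance import bh_adjust, fit_beta_binomial
from .de import fit_age_sex_de
from .eqtl import map_cis_eqtls

__all__ = [
    "SlopeRecovery",
    "recover_abundance_slope",
    "recover_msn_ratio",
    "recover_msn_fraction",
    "recover_cross_region_r2",
    "abundance_null_calibration",
    "de_null_calibration",
    "egene_null_calibration",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


@dataclass
class SlopeRecovery:
    mean_estimate: float
    truth: float
    coverage: float  # fraction of seeds whose 95% CI contains the truth
    estimates: np.ndarray
    n_donors: int


def _abundance_obs(samples: pd.DataFrame, donors: pd.DataFrame, cell_type: str,
                   denominator_cols=None) -> pd.DataFrame:
    obs = samples.merge(donors, on="donor_id")
    if denominator_cols is None:
        N = obs["total_nuclei"]
    else:
        N = obs[list(denominator_cols)].sum(axis=1)
    return pd.DataFrame(
        {
            "donor_id": obs["donor_id"],
            "region": obs["region"],
            "k": obs[cell_type],
            "N": N,
            "age": obs["age"],
            "sex": obs["sex"],
        }
    )


def recover_abundance_slope(
    config_factory,
    cell_type: str,
    truth: float,
    n_seeds: int = 200,
    seed: int = 1,
) -> SlopeRecovery:
    """Generate cohorts with a known log-odds age slope and refit it.

    ``config_factory(seed)`` must return a CohortConfig whose ``cell_type``
    carries the generating slope ``truth``. Returns the mean recovered slope
    and the 95% CI coverage across seeds.
    """
    est = np.empty(n_seeds)
    covered = np.zeros(n_seeds, dtype=bool)
    n_donors = 0
    for i, s in enumerate(_child_seeds(seed, n_seeds)):
        config = config_factory(s)
        n_donors = config.n_donors
        donors, tr = syn.generate_cohort(config)
        samples = syn.generate_cell_counts(donors, tr, config)
        obs = _abundance_obs(samples, donors, cell_type)
        fit = fit_beta_binomial(obs, cell_type=cell_type, compute_lrt=False)
        est[i] = fit.beta_age
        covered[i] = (
            fit.ci_low["age_decades"] <= truth <= fit.ci_high["age_decades"]
        )
    return SlopeRecovery(
        mean_estimate=float(est.mean()),
        truth=truth,
        coverage=float(covered.mean()),
        estimates=est,
        n_donors=n_donors,
    )


def recover_msn_ratio(
    n_donors: int = 131,
    region: str = "CaH",
    n_seeds: int = 200,
    seed: int = 1,
) -> dict:
    """Cohort-mean D1/D2 MSN count ratio in one region.

    Per donor the ratio is D1 count / D2 count (D2 is the multinomial
    remainder); the per-seed statistic is the donor mean, averaged across
    seeds. The Monte-Carlo SE reported is the per-seed SD of the cohort mean.
    """
    means = np.empty(n_seeds)
    for i, s in enumerate(_child_seeds(seed, n_seeds)):
        config = syn.msn_subtype_config("d1d2", n_donors=n_donors,
                                        regions=(region,), seed=s)
        donors, tr = syn.generate_cohort(config)
        samples = syn.generate_cell_counts(donors, tr, config)
        ratio = samples["MSN_D1"] / samples["Other"].clip(lower=1)
        means[i] = float(ratio.mean())
    return {
        "mean_ratio": float(means.mean()),
        "per_seed_sd": float(means.std(ddof=1)),
        "n_donors": n_donors,
        "n_seeds": n_seeds,
    }


def recover_msn_fraction(
    kind: str,
    n_donors: int,
    n_seeds: int = 200,
    seed: int = 1,
) -> dict:
    """Cohort-mean percentage of MSNs in a subtype pool.

    kind='striosome' (CaH+Pu) or 'eccentric' (NAC); the statistic is the
    donor-mean subtype share of MSNs in percent, averaged across seeds and
    regions.
    """
    col = {"striosome": "MSN_striosome", "eccentric": "MSN_eccentric"}[kind]
    means = np.empty(n_seeds)
    for i, s in enumerate(_child_seeds(seed, n_seeds)):
        config = syn.msn_subtype_config(kind, n_donors=n_donors, seed=s)
        donors, tr = syn.generate_cohort(config)
        samples = syn.generate_cell_counts(donors, tr, config)
        frac = samples[col] / samples["total_nuclei"]
        means[i] = float(frac.mean()) * 100.0
    return {
        "mean_percent": float(means.mean()),
        "per_seed_sd": float(means.std(ddof=1)),
        "n_donors": n_donors,
        "n_seeds": n_seeds,
    }


def recover_cross_region_r2(
    cell_type: str,
    n_donors: int = 114,
    n_seeds: int = 200,
    seed: int = 1,
    r2: float | None = None,
) -> dict:
    """Sample Pearson r^2 of paired-donor fractions across two regions.

    The generator's shared and sample-level variances are set so the latent
    cross-region r^2 equals the target; the recovered value is the mean
    sample r^2 of the observed caudate and DFC fractions.
    """
    vals = np.empty(n_seeds)
    target = syn.CROSS_REGION_R2[cell_type] if r2 is None else r2
    for i, s in enumerate(_child_seeds(seed, n_seeds)):
        config = syn.glial_sharing_config(cell_type, n_donors=n_donors, r2=target,
                                          seed=s)
        donors, tr = syn.generate_cohort(config)
        samples = syn.generate_cell_counts(donors, tr, config)
        frac = samples.assign(f=samples[cell_type] / samples["total_nuclei"])
        wide = frac.pivot(index="donor_id", columns="region", values="f")
        r = np.corrcoef(wide.iloc[:, 0], wide.iloc[:, 1])[0, 1]
        vals[i] = r**2
    return {
        "mean_r2": float(vals.mean()),
        "target": float(target),
        "per_seed_sd": float(vals.std(ddof=1)),
        "n_donors": n_donors,
        "n_seeds": n_seeds,
    }


def abundance_null_calibration(
    n_seeds: int = 200,
    n_donors: int = 100,
    seed: int = 1,
    alpha: float = 0.05,
) -> np.ndarray:
    """Per-seed indicator: focal age slope reaches BH q < alpha under the null.

    All generating slopes are zero; per seed, four cell types are fit in two
    regions and BH is applied across the family of age and sex tests; the
    focal cell type's age test is scored.
    """
    hits = np.zeros(n_seeds, dtype=bool)
    for i, s in enumerate(_child_seeds(seed, n_seeds)):
        config = syn.opc_attrition_config(
            n_donors=n_donors, regions=("CaH", "DFC"), slope_per_decade=0.0,
            seed=s,
        )
        donors, tr = syn.generate_cohort(config)
        samples = syn.generate_cell_counts(donors, tr, config)
        ps = []
        for ct in ("OPC", "Astrocyte", "Microglia", "Oligodendrocyte"):
            obs = _abundance_obs(samples, donors, ct)
            fit = fit_beta_binomial(obs, cell_type=ct, compute_lrt=False)
            ps.extend([fit.p_age, fit.p_sex] if fit.p_sex is not None
                      else [fit.p_age])
        q = bh_adjust(ps)
        hits[i] = q[0] < alpha  # the focal (OPC) age test
    return hits


def de_null_calibration(
    n_seeds: int = 200,
    n_donors: int = 100,
    n_genes: int = 300,
    seed: int = 1,
    alpha: float = 0.05,
) -> np.ndarray:
    """Per-seed fraction of genes with BH q_age < alpha under a null generator."""
    fracs = np.empty(n_seeds)
    for i, s in enumerate(_child_seeds(seed, n_seeds)):
        config = syn.interneuron_composition_config(n_donors=n_donors, seed=s)
        genes, _ = syn.default_gene_specs(
            list(config.cell_types), n_genes=n_genes, n_age_shared=0,
            n_age_specific=0, n_chry=0, n_chrx_sex=0, n_eqtl=0, seed=s,
        )
        config.genes = genes
        donors, tr = syn.generate_cohort(config)
        pb = syn.generate_pseudobulk(donors, tr, config,
                                     cell_types=["TAC3-PLPP4"],
                                     regions=[config.regions[0]])
        res = fit_age_sex_de(pb[("TAC3-PLPP4", config.regions[0])], donors)
        fracs[i] = float((res["q_age"] < alpha).mean())
    return fracs


def egene_null_calibration(
    n_seeds: int = 200,
    n_donors: int = 150,
    n_genes: int = 200,
    seed: int = 1,
    fdr: float = 0.01,
) -> np.ndarray:
    """Per-seed fraction of genes called eGenes under a no-eQTL generator."""
    fracs = np.empty(n_seeds)
    for i, s in enumerate(_child_seeds(seed, n_seeds)):
        config = syn.interneuron_composition_config(n_donors=n_donors, seed=s)
        genes, snps = syn.default_gene_specs(
            list(config.cell_types), n_genes=n_genes, n_age_shared=0,
            n_age_specific=0, n_chry=0, n_chrx_sex=0, n_eqtl=0, seed=s,
        )
        # decoy SNPs only: no expression effect anywhere
        config.genes = genes
        config.snps = snps
        donors, tr = syn.generate_cohort(config)
        dosages = syn.generate_genotypes(donors, config, tr)
        pb = syn.generate_pseudobulk(donors, tr, config,
                                     cell_types=["TAC3-PLPP4"],
                                     regions=[config.regions[0]])
        gene_table = pd.DataFrame(
            {"gene_id": [g.gene_id for g in genes],
             "chrom": [g.chrom for g in genes],
             "tss": [g.tss for g in genes]}
        )
        snp_table = pd.DataFrame(
            {"snp_id": [v.snp_id for v in snps],
             "chrom": [v.chrom for v in snps],
             "pos": [v.pos for v in snps]}
        )
        res = map_cis_eqtls(
            {"TAC3-PLPP4": pb[("TAC3-PLPP4", config.regions[0])]},
            dosages, snp_table, gene_table, donors, fdr=fdr,
        )
        tested = res["p_gene"].notna()
        fracs[i] = float(res.loc[tested, "egene"].mean()) if tested.any() else 0.0
    return fracs


def clock_residual_experiment(
    n_seeds: int = 20,
    n_donors: int = 120,
    biological_age_sd: float = 4.0,
    n_repeats: int = 1,
    seed: int = 1,
) -> pd.DataFrame:
    """Clocks for three cell types with a donor-shared biological-age offset.

    Per seed: generate pseudobulk for three cell types whose expression
    responds to (age + shared offset), run DE, train a clock per cell type,
    fit the bias curve, and summarise (a) the max |Spearman| between
    corrected residuals and chronological age and (b) the mean off-diagonal
    Spearman correlation of corrected residuals across cell types.
    """
    from .clock import fit_bias_curve, residual_correlation, train_clock

    cts = ["MSN_D1", "Astrocyte", "OPC"]
    rows = []
    for i, s in enumerate(_child_seeds(seed, n_seeds)):
        config = syn.CohortConfig(
            n_donors=n_donors, regions=("CaH",),
            cell_types={ct: syn.CellTypeSpec(baseline_logit=-2.0) for ct in cts},
            biological_age_sd=biological_age_sd,
            seed=s,
        )
        genes, _ = syn.default_gene_specs(
            cts, n_genes=150, n_age_shared=30, n_age_specific=25, n_chry=0,
            n_chrx_sex=0, n_eqtl=0, seed=s,
        )
        config.genes = genes
        donors, tr = syn.generate_cohort(config)
        pb = syn.generate_pseudobulk(donors, tr, config)
        preds_all = []
        max_age_corr = 0.0
        for ct in cts:
            de = fit_age_sex_de(pb[(ct, "CaH")], donors)
            _, preds = train_clock(pb[(ct, "CaH")], de, donors,
                                   n_repeats=n_repeats, seed=s)
            _, corrected = fit_bias_curve(preds["predicted_age"], preds["age"])
            from scipy import stats as sps

            rho = sps.spearmanr(corrected, preds["age"]).statistic
            max_age_corr = max(max_age_corr, abs(float(rho)))
            preds_all.append(preds.assign(corrected_residual=corrected))
        from .clock import residual_correlation as _rc

        corr = _rc(pd.concat(preds_all, ignore_index=True))
        off = corr.to_numpy()[~np.eye(len(cts), dtype=bool)]
        rows.append(
            {"seed": s, "max_age_residual_corr": max_age_corr,
             "mean_offdiag_residual_corr": float(np.mean(off))}
        )
    return pd.DataFrame(rows)
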