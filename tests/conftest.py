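import numpy as np
import pandas as pd
import pytest

from strivar import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-donor single-region cohort with genes, genotypes and pseudobulk."""
    config = syn.default_cohort_config(n_donors=120, n_genes=300, n_eqtl=40, seed=3)
    donors, truth = syn.generate_cohort(config)
    dosages = syn.generate_genotypes(donors, config, truth)
    cts = ["OPC", "Astrocyte", "TAC3-PLPP4"]
    pb = syn.generate_pseudobulk(donors, truth, config, cell_types=cts,
                                 regions=["CaH"])
    return {
        "config": config,
        "donors": donors,
        "truth": truth,
        "dosages": dosages,
        "pb": pb,
        "cell_types": cts,
    }


@pytest.fixture(scope="session")
def small_de_results(small_cohort):
    from strivar.de import fit_age_sex_de

    res = [
        fit_age_sex_de(small_cohort["pb"][(ct, "CaH")], small_cohort["donors"])
        for ct in small_cohort["cell_types"]
    ]
    return pd.concat(res, ignore_index=True)


def gene_tables(config):
    genes = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in config.genes],
            "chrom": [g.chrom for g in config.genes],
            "tss": [g.tss for g in config.genes],
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in config.snps],
            "chrom": [s.chrom for s in config.snps],
            "pos": [s.pos for s in config.snps],
        }
    )
    return genes, snps
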