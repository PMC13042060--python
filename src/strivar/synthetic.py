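"""Synthetic multi-region, multi-donor snRNA-seq cohort generator.

Emulates the statistical structure of a pooled ("village") single-nucleus
study of the human striatum and cortex: ~150 adult donors (ages 27-90, with
ages above 89 collapsed to 90 for privacy, as brain banks do), five sampled
regions (caudate head, putamen, nucleus accumbens, internal capsule,
dorsolateral prefrontal cortex), donor-level cell-type propensities shared
across regions, age-dependent attrition of specific cell types on the
log-odds scale, cell-type-specific age effects on gene expression (log2
fold-change per decade), sex effects confined to sex-chromosome genes, and
cis-eQTL effects with cell-type sharing patterns.

Every random draw descends deterministically from ``CohortConfig.seed`` via
``numpy.random.SeedSequence``, and every generating parameter is retained in
a :class:`TruthRecord` so downstream modules can be tested for parameter
recovery.

Count model
-----------
For donor *i*, region *r* and cell type *g*, the latent logit fraction is

    l_igr = baseline_logit_g(r) + slope_g * (age_i - 60)/10 + u_ig + e_igr

with ``u_ig ~ N(0, tau2_g)`` shared across regions and
``e_igr ~ N(0, sigma2_g)`` independent per sample. Per-sample counts are a
single multinomial over (cell types..., Other) with probabilities
``p_g = expit(l_igr)`` and the remainder assigned to Other. This guarantees
compositional closure while keeping each focal type's marginal logit exactly
equal to the linear predictor -- the model the abundance analyses assume.
The cross-region correlation of a donor's latent logits is
``tau2 / (tau2 + sigma2)`` by construction.
"""

from __future__ import annotations

import dataclasses
import json
from functools import lru_cache
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "CellTypeSpec",
    "GeneSpec",
    "SnpSpec",
    "CohortConfig",
    "TruthRecord",
    "PseudobulkMatrix",
    "generate_cohort",
    "generate_cell_counts",
    "generate_pseudobulk",
    "generate_genotypes",
    "generate_nucleus_counts",
    "simulate_village_barcodes",
    "default_cohort_config",
    "default_gene_specs",
    "opc_attrition_config",
    "interneuron_composition_config",
    "msn_subtype_config",
    "glial_sharing_config",
    "SHARED_LOGIT_VARIANCE",
    "CROSS_REGION_R2",
]

AGE_CENTER = 60.0  # years; effects are per decade centred here
DECADE = 10.0

# Shared (cross-region) donor-level logit variance implied by the observed
# median pairwise fold differences: exp(0.9539 * sigma_shared) = fold.
# 1.2-fold (astrocytes, OPCs) and 1.4-fold (microglia).
SHARED_LOGIT_VARIANCE = {
    "Astrocyte": (np.log(1.2) / 0.95387) ** 2,  # ~0.0365
    "OPC": (np.log(1.2) / 0.95387) ** 2,
    "Microglia": (np.log(1.4) / 0.95387) ** 2,  # ~0.1244
}

# Caudate-vs-DFC Pearson r^2 of donor-level glial fractions.
CROSS_REGION_R2 = {"OPC": 0.22, "Astrocyte": 0.18, "Microglia": 0.29}

DEFAULT_REGIONS = ("CaH", "Pu", "NAC", "ic", "DFC")
STRIATAL_REGIONS = ("CaH", "Pu", "NAC")


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass
class CellTypeSpec:
    """Generating parameters for one cell type.

    ``baseline_logit`` is the logit of the type's expected fraction (of the
    composition denominator) at age 60, either a scalar or a per-region map.
    ``age_slope_per_decade`` acts on the log-odds scale. ``tau2`` is the
    donor-level variance shared across regions; ``sigma2`` the per-sample
    noise variance. ``lineage`` ('neuron' | 'glia' | 'other') supports
    denominator modes downstream.
    """

    baseline_logit: float | Mapping[str, float]
    age_slope_per_decade: float = 0.0
    tau2: float = 0.0
    sigma2: float = 0.0
    lineage: str = "glia"

    def region_logit(self, region: str) -> float:
        if isinstance(self.baseline_logit, Mapping):
            return float(self.baseline_logit[region])
        return float(self.baseline_logit)

    def validate(self, name: str, regions: Sequence[str]) -> None:
        if self.tau2 < 0 or self.sigma2 < 0:
            raise ValueError(f"{name}: variance components must be >= 0")
        if self.lineage not in {"neuron", "glia", "other"}:
            raise ValueError(f"{name}: unknown lineage {self.lineage!r}")
        if isinstance(self.baseline_logit, Mapping):
            missing = set(regions) - set(self.baseline_logit)
            if missing:
                raise ValueError(f"{name}: baseline_logit missing regions {missing}")


@dataclass
class SnpSpec:
    snp_id: str
    chrom: str
    pos: int
    maf: float

    def validate(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: MAF must be in (0, 0.5], got {self.maf}")


@dataclass
class GeneSpec:
    """Generating parameters for one gene's pseudobulk expression.

    ``baseline_log2cpm`` and ``age_log2fc_per_decade`` are scalars or
    per-cell-type maps. ``sex_effect_log2fc`` is male-vs-female; genes with
    ``chrom_class == 'chrY'`` are additionally zeroed in XX donors.
    ``eqtl_effect`` is log2 change per alternate allele (scalar or per cell
    type) for ``eqtl_snp``.
    """

    gene_id: str
    chrom: str = "chr1"
    tss: int = 1_000_000
    chrom_class: str = "autosome"
    baseline_log2cpm: float | Mapping[str, float] = 5.0
    age_log2fc_per_decade: float | Mapping[str, float] = 0.0
    sex_effect_log2fc: float = 0.0
    eqtl_snp: str | None = None
    eqtl_effect: float | Mapping[str, float] = 0.0
    constraint: float | None = None

    def per_celltype(self, value, cell_type: str) -> float:
        if isinstance(value, Mapping):
            return float(value.get(cell_type, 0.0))
        return float(value)

    def baseline(self, cell_type: str) -> float:
        if isinstance(self.baseline_log2cpm, Mapping):
            return float(self.baseline_log2cpm.get(cell_type, 0.0))
        return float(self.baseline_log2cpm)


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort (the study conditions)."""

    n_donors: int = 150
    age_range: tuple[float, float] = (27.0, 90.0)
    age_cap: float = 90.0
    male_fraction: float = 111.0 / 178.0
    regions: tuple[str, ...] = DEFAULT_REGIONS
    village_size: int = 20
    nuclei_per_sample: float = 5000.0
    nuclei_dispersion: float = 0.0  # 0 -> Poisson totals; >0 -> gamma-Poisson
    cell_types: dict[str, CellTypeSpec] = field(default_factory=dict)
    genes: list[GeneSpec] = field(default_factory=list)
    snps: list[SnpSpec] = field(default_factory=list)
    doublet_rate: float = 0.0
    nb_dispersion: float = 0.05
    library_log_mean: float = 15.0
    library_log_sd: float = 0.3
    cells_per_pseudobulk: float = 500.0
    biological_age_sd: float = 0.0  # donor offset (years) shared by all cell types
    celltype_age_sd: float = 0.0  # independent per (donor, cell type) offset (years)
    extra_covariates: dict[str, Callable] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors <= 0:
            raise ValueError("n_donors must be positive")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError("male_fraction must be in [0, 1]")
        if not (0.0 <= self.doublet_rate <= 1.0):
            raise ValueError("doublet_rate must be in [0, 1]")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range min must be < max")
        if self.village_size < 1:
            raise ValueError("village_size must be >= 1")
        if not self.cell_types:
            raise ValueError("at least one cell type is required")
        for name, spec in self.cell_types.items():
            spec.validate(name, self.regions)
        for region in self.regions:
            total = sum(
                expit(spec.region_logit(region)) for spec in self.cell_types.values()
            )
            if total >= 1.0:
                raise ValueError(
                    f"region {region}: baseline fractions sum to {total:.3f} >= 1; "
                    "leave room for the remainder pool"
                )
        snp_ids = {s.snp_id for s in self.snps}
        for s in self.snps:
            s.validate()
        for g in self.genes:
            if g.eqtl_snp is not None and g.eqtl_snp not in snp_ids:
                raise ValueError(f"{g.gene_id}: unknown eQTL SNP {g.eqtl_snp!r}")


# ---------------------------------------------------------------------------
# Truth record
# ---------------------------------------------------------------------------


@dataclass
class TruthRecord:
    """Everything needed to recompute the generated observables.

    Holds realized donor-level latents alongside the config; given the seed,
    all generated outputs are byte-reproducible.
    """

    seed: int
    ages: np.ndarray
    sexes: np.ndarray  # 'M' / 'F'
    villages: np.ndarray
    propensities: dict[str, np.ndarray]  # cell type -> u_i
    age_offsets_shared: np.ndarray
    age_offsets_celltype: dict[str, np.ndarray]
    dosages: pd.DataFrame | None = None
    config_dict: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, pd.DataFrame):
                return {"index": o.index.tolist(), "columns": o.columns.tolist(),
                        "values": o.values.tolist()}
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        payload = dataclasses.asdict(self)
        return json.dumps(payload, default=_enc, indent=1, sort_keys=True)


def _spawn(seed: int, key: int) -> np.random.Generator:
    """Deterministic child generator for one generation stage."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("extra_covariates", None)
    return json.loads(json.dumps(d, default=lambda o: getattr(o, "tolist", lambda: str(o))()))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw donors (ages, sexes, villages) and their latent propensities.

    Ages are uniform on ``age_range`` then capped at ``age_cap`` (brain banks
    report ages above 89 only as "90+"). Sexes are Bernoulli(male_fraction).
    Donors are assigned to villages of ``village_size`` in order.
    """
    config.validate()
    rng = _spawn(config.seed, 0)
    n = config.n_donors
    ages = np.minimum(rng.uniform(*config.age_range, size=n), config.age_cap)
    sexes = np.where(rng.random(n) < config.male_fraction, "M", "F")
    villages = np.arange(n) // config.village_size
    donors = pd.DataFrame(
        {
            "donor_id": [f"D{i:04d}" for i in range(n)],
            "age": ages,
            "sex": sexes,
            "village_id": [f"V{v:02d}" for v in villages],
        }
    )
    for name, sampler in config.extra_covariates.items():
        donors[name] = np.asarray(sampler(rng, n))

    prop_rng = _spawn(config.seed, 1)
    propensities = {
        ct: prop_rng.normal(0.0, np.sqrt(spec.tau2), size=n)
        for ct, spec in config.cell_types.items()
    }
    off_rng = _spawn(config.seed, 2)
    shared = off_rng.normal(0.0, config.biological_age_sd, size=n) \
        if config.biological_age_sd > 0 else np.zeros(n)
    per_ct = {
        ct: (off_rng.normal(0.0, config.celltype_age_sd, size=n)
             if config.celltype_age_sd > 0 else np.zeros(n))
        for ct in config.cell_types
    }
    truth = TruthRecord(
        seed=config.seed,
        ages=ages,
        sexes=sexes,
        villages=villages,
        propensities=propensities,
        age_offsets_shared=shared,
        age_offsets_celltype=per_ct,
        config_dict=_config_to_dict(config),
    )
    return donors, truth


def generate_cell_counts(
    donors: pd.DataFrame, truth: TruthRecord, config: CohortConfig
) -> pd.DataFrame:
    """Per (donor, region) multinomial cell-type counts.

    Returns a wide table: donor_id, region, one column per cell type, an
    ``Other`` remainder column, and ``total_nuclei``. Counts per sample sum
    exactly to ``total_nuclei`` (compositional closure).
    """
    if len(donors) != len(truth.ages):
        raise ValueError("donor table does not match truth record")
    rng = _spawn(config.seed, 3)
    types = list(config.cell_types)
    age_dec = (truth.ages - AGE_CENTER) / DECADE
    rows = []
    for region in config.regions:
        n = len(donors)
        if config.nuclei_dispersion > 0:
            lam = rng.gamma(
                1.0 / config.nuclei_dispersion,
                config.nuclei_dispersion * config.nuclei_per_sample,
                size=n,
            )
        else:
            lam = np.full(n, config.nuclei_per_sample)
        totals = np.maximum(rng.poisson(lam), 1)
        probs = np.empty((n, len(types)))
        for j, ct in enumerate(types):
            spec = config.cell_types[ct]
            lo = (
                spec.region_logit(region)
                + spec.age_slope_per_decade * age_dec
                + truth.propensities[ct]
                + rng.normal(0.0, np.sqrt(spec.sigma2), size=n)
            )
            probs[:, j] = expit(lo)
        row_sum = probs.sum(axis=1)
        over = row_sum > 0.995  # defensive: keep a sliver for the remainder pool
        if np.any(over):
            probs[over] *= (0.995 / row_sum[over])[:, None]
        full = np.column_stack([probs, 1.0 - probs.sum(axis=1)])
        counts = rng.multinomial(totals, full)
        for i in range(n):
            rec = {"donor_id": donors["donor_id"].iloc[i], "region": region}
            rec.update({ct: int(counts[i, j]) for j, ct in enumerate(types)})
            rec["Other"] = int(counts[i, -1])
            rec["total_nuclei"] = int(totals[i])
            rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class PseudobulkMatrix:
    """Donor-aggregated expression for one (cell type, region).

    ``counts`` is donors x genes; ``library_size`` and ``cells_per_donor``
    are per-donor. ``log2cpm()`` applies log2(counts * 1e6 / library + 1).
    """

    cell_type: str
    region: str
    counts: pd.DataFrame
    library_size: pd.Series
    cells_per_donor: pd.Series

    def log2cpm(self) -> pd.DataFrame:
        from .de import normalize_log2cpm

        return normalize_log2cpm(self.counts, self.library_size)


def _expected_log2cpm(
    gene: GeneSpec,
    cell_type: str,
    ages_eff: np.ndarray,
    male: np.ndarray,
    dosage: np.ndarray | None,
) -> np.ndarray:
    mu = np.full(ages_eff.shape, gene.baseline(cell_type))
    mu = mu + gene.per_celltype(gene.age_log2fc_per_decade, cell_type) * (
        (ages_eff - AGE_CENTER) / DECADE
    )
    if gene.sex_effect_log2fc != 0.0:
        mu = mu + gene.sex_effect_log2fc * male
    if gene.eqtl_snp is not None and dosage is not None:
        mu = mu + gene.per_celltype(gene.eqtl_effect, cell_type) * dosage
    return mu


def generate_pseudobulk(
    donors: pd.DataFrame,
    truth: TruthRecord,
    config: CohortConfig,
    cell_types: Sequence[str] | None = None,
    regions: Sequence[str] | None = None,
    noiseless: bool = False,
) -> dict[tuple[str, str], PseudobulkMatrix]:
    """Negative-binomial pseudobulk counts per (cell type, region).

    Expression model per gene/donor (log2-CPM scale): baseline +
    age_log2fc * (effective age - 60)/10 + sex effect + eQTL effect * dosage.
    Effective age = chronological age + donor-shared offset + per-cell-type
    offset. Counts are gamma-Poisson with dispersion ``nb_dispersion`` around
    library_size * 2^log2cpm / 1e6; chrY genes are zeroed in XX donors.
    With ``noiseless=True`` the expected counts are returned directly
    (Gaussian-limit oracle for regression tests).
    """
    if not config.genes:
        raise ValueError("config has no gene specs")
    cell_types = list(cell_types or config.cell_types)
    regions = list(regions or config.regions)
    rng = _spawn(config.seed, 4)
    male = (truth.sexes == "M").astype(float)
    dosages = truth.dosages
    out: dict[tuple[str, str], PseudobulkMatrix] = {}
    gene_ids = [g.gene_id for g in config.genes]
    for ct in cell_types:
        ages_eff = truth.ages + truth.age_offsets_shared + truth.age_offsets_celltype.get(
            ct, 0.0
        )
        for region in regions:
            lib = np.exp(
                rng.normal(config.library_log_mean, config.library_log_sd, len(donors))
            )
            cells = np.maximum(
                rng.poisson(config.cells_per_pseudobulk, len(donors)), 2
            ).astype(float)
            mat = np.empty((len(donors), len(config.genes)))
            for j, gene in enumerate(config.genes):
                dos = None
                if gene.eqtl_snp is not None and dosages is not None:
                    dos = dosages[gene.eqtl_snp].to_numpy()
                log2cpm = _expected_log2cpm(gene, ct, ages_eff, male, dos)
                mu = lib * np.exp2(log2cpm) / 1e6
                if gene.chrom_class == "chrY":
                    mu = np.where(male == 1.0, mu, 0.0)
                if noiseless:
                    mat[:, j] = mu
                else:
                    if config.nb_dispersion > 0:
                        shape = 1.0 / config.nb_dispersion
                        lam = rng.gamma(shape, mu * config.nb_dispersion)
                    else:
                        lam = mu
                    mat[:, j] = rng.poisson(lam)
            counts = pd.DataFrame(mat, index=donors["donor_id"], columns=gene_ids)
            out[(ct, region)] = PseudobulkMatrix(
                cell_type=ct,
                region=region,
                counts=counts,
                library_size=pd.Series(lib, index=donors["donor_id"]),
                cells_per_donor=pd.Series(cells, index=donors["donor_id"]),
            )
    return out


def generate_genotypes(
    donors: pd.DataFrame, config: CohortConfig, truth: TruthRecord | None = None
) -> pd.DataFrame:
    """Hardy-Weinberg dosages (0/1/2), donors x SNPs.

    Stored on the truth record when one is supplied, so pseudobulk
    generation can apply cis-eQTL effects.
    """
    if not config.snps:
        raise ValueError("config has no SNPs")
    for s in config.snps:
        s.validate()
    rng = _spawn(config.seed, 5)
    n = len(donors)
    cols = {}
    for s in config.snps:
        p = s.maf
        probs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
        cols[s.snp_id] = rng.choice([0, 1, 2], size=n, p=probs)
    dosages = pd.DataFrame(cols, index=donors["donor_id"])
    if truth is not None:
        truth.dosages = dosages
    return dosages


def generate_nucleus_counts(
    donors: pd.DataFrame,
    truth: TruthRecord,
    config: CohortConfig,
    nuclei_per_donor: int = 20,
    umis_per_nucleus: float = 2000.0,
    cell_types: Sequence[str] | None = None,
    region: str | None = None,
):
    """Small-scale per-nucleus counts for testing the aggregation path.

    Returns ``(matrix, barcodes, assignments)`` where ``matrix`` is genes x
    nuclei (dense ndarray; write with scipy.io.mmwrite as needed) and
    ``assignments`` has nucleus_id, donor_id, region, cell_type.
    """
    if not config.genes:
        raise ValueError("config has no gene specs")
    cell_types = list(cell_types or config.cell_types)
    region = region or config.regions[0]
    rng = _spawn(config.seed, 6)
    male = (truth.sexes == "M").astype(float)
    barcodes, records, cols = [], [], []
    for i, donor in enumerate(donors["donor_id"]):
        for ct in cell_types:
            ages_eff = np.array(
                [truth.ages[i] + truth.age_offsets_shared[i]
                 + truth.age_offsets_celltype.get(ct, np.zeros(len(donors)))[i]]
            )
            rates = np.array(
                [
                    np.exp2(_expected_log2cpm(g, ct, ages_eff, male[i : i + 1], None))[0]
                    if not (g.chrom_class == "chrY" and male[i] == 0.0)
                    else 0.0
                    for g in config.genes
                ]
            )
            rates = rates / rates.sum()
            for k in range(nuclei_per_donor):
                bc = f"{donor}:{ct}:{k:03d}"
                barcodes.append(bc)
                records.append(
                    {"nucleus_id": bc, "donor_id": donor, "region": region,
                     "cell_type": ct}
                )
                cols.append(rng.poisson(rates * umis_per_nucleus))
    matrix = np.column_stack(cols)
    assignments = pd.DataFrame(records)
    return matrix, barcodes, assignments


def simulate_village_barcodes(
    n_barcodes: int,
    composition: Sequence[float],
    doublet_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate barcode-level doublet structure for one village.

    Each barcode is a doublet with probability ``doublet_rate``; a doublet
    draws two donors independently from ``composition`` and is *genotypic*
    when they differ. Returns nucleus_id, donor_id, is_doublet,
    genotypic_doublet.
    """
    p = np.asarray(composition, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("composition must sum to 1")
    is_dbl = rng.random(n_barcodes) < doublet_rate
    d1 = rng.choice(p.size, size=n_barcodes, p=p)
    d2 = rng.choice(p.size, size=n_barcodes, p=p)
    genotypic = is_dbl & (d1 != d2)
    return pd.DataFrame(
        {
            "nucleus_id": [f"BC{i:06d}" for i in range(n_barcodes)],
            "donor_id": d1,
            "is_doublet": is_dbl,
            "genotypic_doublet": genotypic,
        }
    )


# ---------------------------------------------------------------------------
# Preset configurations (the study conditions for recovery experiments)
# ---------------------------------------------------------------------------


def _fraction_logits(fractions: Mapping[str, float]) -> dict[str, float]:
    return {k: float(logit(v)) for k, v in fractions.items()}


def opc_attrition_config(
    n_donors: int = 150,
    regions: Sequence[str] = DEFAULT_REGIONS,
    baseline_fraction: float = 0.03,
    slope_per_decade: float = -0.096,
    tau2: float = 0.04,
    sigma2: float = 0.02,
    nuclei_per_sample: float = 5000.0,
    seed: int = 0,
) -> CohortConfig:
    """Cohort for OPC age-attrition recovery (fraction of all nuclei).

    Defaults: 3% OPCs at age 60 declining at -0.096 log-odds per decade,
    donor-shared variance 0.04, sample noise 0.02.
    """
    cell_types = {
        "OPC": CellTypeSpec(
            baseline_logit=float(logit(baseline_fraction)),
            age_slope_per_decade=slope_per_decade,
            tau2=tau2,
            sigma2=sigma2,
            lineage="glia",
        ),
        "Astrocyte": CellTypeSpec(
            baseline_logit=float(logit(0.15)),
            tau2=SHARED_LOGIT_VARIANCE["Astrocyte"],
            sigma2=SHARED_LOGIT_VARIANCE["Astrocyte"]
            / np.sqrt(CROSS_REGION_R2["Astrocyte"])
            - SHARED_LOGIT_VARIANCE["Astrocyte"],
            lineage="glia",
        ),
        "Microglia": CellTypeSpec(
            baseline_logit=float(logit(0.08)),
            tau2=SHARED_LOGIT_VARIANCE["Microglia"],
            sigma2=SHARED_LOGIT_VARIANCE["Microglia"]
            / np.sqrt(CROSS_REGION_R2["Microglia"])
            - SHARED_LOGIT_VARIANCE["Microglia"],
            lineage="glia",
        ),
        "Oligodendrocyte": CellTypeSpec(
            baseline_logit={"CaH": float(logit(0.30)), "Pu": float(logit(0.35)),
                            "NAC": float(logit(0.28)), "ic": float(logit(0.65)),
                            "DFC": float(logit(0.22))},
            tau2=0.002,
            sigma2=0.05,
            lineage="glia",
        ),
        "Neuron": CellTypeSpec(
            baseline_logit={"CaH": float(logit(0.30)), "Pu": float(logit(0.28)),
                            "NAC": float(logit(0.30)), "ic": float(logit(0.03)),
                            "DFC": float(logit(0.35))},
            tau2=0.01,
            sigma2=0.02,
            lineage="neuron",
        ),
    }
    keep_regions = tuple(regions)
    for spec in cell_types.values():
        if isinstance(spec.baseline_logit, Mapping):
            spec.baseline_logit = {
                r: spec.baseline_logit.get(r, float(logit(0.2))) for r in keep_regions
            }
    return CohortConfig(
        n_donors=n_donors,
        regions=keep_regions,
        nuclei_per_sample=nuclei_per_sample,
        cell_types=cell_types,
        seed=seed,
    )


def interneuron_composition_config(
    n_donors: int = 150,
    regions: Sequence[str] = STRIATAL_REGIONS,
    tac3_fraction: float = 0.015,
    tac3_slope: float = -0.047,
    tau2: float = 0.04,
    sigma2: float = 0.02,
    neurons_per_sample: float = 2000.0,
    seed: int = 0,
) -> CohortConfig:
    """Neuron-only cohort: interneuron fractions relative to all neurons.

    TAC3-PLPP4 at 1.5% of neurons declining at -0.047 log-odds per decade;
    PTHLH-PVALB and MSN pools make up the rest (MSNs are the multinomial
    remainder).
    """
    cell_types = {
        "TAC3-PLPP4": CellTypeSpec(
            baseline_logit=float(logit(tac3_fraction)),
            age_slope_per_decade=tac3_slope,
            tau2=tau2,
            sigma2=sigma2,
            lineage="neuron",
        ),
        "PTHLH-PVALB": CellTypeSpec(
            baseline_logit=float(logit(0.035)),
            tau2=tau2,
            sigma2=sigma2,
            lineage="neuron",
        ),
    }
    return CohortConfig(
        n_donors=n_donors,
        regions=tuple(regions),
        nuclei_per_sample=neurons_per_sample,
        cell_types=cell_types,
        seed=seed,
    )


def msn_subtype_config(
    kind: str,
    n_donors: int,
    regions: Sequence[str] | None = None,
    msns_per_sample: float = 1500.0,
    seed: int = 0,
) -> CohortConfig:
    """MSN-subtype composition cohorts (denominator = all MSNs).

    kind='d1d2'     : D1 vs D2 with per-region mean D1/D2 odds 1.23 (CaH),
                      1.00 (Pu), 1.02 (NAC).
    kind='striosome': striosome vs matrix MSNs, striosomes 17% of MSNs in
                      CaH and Pu.
    kind='eccentric': eccentric vs canonical MSNs, 19% in NAC, 7% in CaH/Pu.

    Propensities are noise-free (pure multinomial sampling) so the cohort
    mean is exactly the generating proportion.
    """
    if kind == "d1d2":
        regions = tuple(regions or ("CaH",))
        ratio = {"CaH": 1.23, "Pu": 1.00, "NAC": 1.02}
        # log-odds vs the remainder pool: P(D1) = ratio/(1+ratio), D2 is the
        # multinomial remainder
        cell_types = {
            "MSN_D1": CellTypeSpec(
                baseline_logit={r: float(np.log(ratio[r])) for r in regions},
                lineage="neuron",
            ),
        }
    elif kind == "striosome":
        regions = tuple(regions or ("CaH", "Pu"))
        cell_types = {
            "MSN_striosome": CellTypeSpec(
                baseline_logit=float(logit(0.17)), lineage="neuron"
            ),
        }
    elif kind == "eccentric":
        regions = tuple(regions or ("NAC",))
        frac = {"NAC": 0.19, "CaH": 0.07, "Pu": 0.07}
        cell_types = {
            "MSN_eccentric": CellTypeSpec(
                baseline_logit={r: float(logit(frac[r])) for r in regions},
                lineage="neuron",
            ),
        }
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return CohortConfig(
        n_donors=n_donors,
        regions=regions,
        nuclei_per_sample=msns_per_sample,
        cell_types=cell_types,
        seed=seed,
    )


@lru_cache(maxsize=64)
def _calibrate_latent_correlation(
    baseline_logit: float,
    total_var: float,
    target_r2: float,
    nuclei: float,
    n_mc: int = 400_000,
    cal_seed: int = 97,
) -> float:
    """Latent logit correlation giving a population fraction-scale r^2.

    The Pearson r^2 of measured fractions is attenuated below the latent
    logit correlation squared by the expit nonlinearity and by binomial
    sampling at ``nuclei`` per sample. Inverts that map by Monte-Carlo with
    common random numbers (deterministic internal seed) and Brent's method.
    """
    from scipy.optimize import brentq

    rng = np.random.default_rng(cal_seed)
    z_shared = rng.standard_normal(n_mc)
    z1, z2 = rng.standard_normal(n_mc), rng.standard_normal(n_mc)
    b1, b2 = rng.standard_normal(n_mc), rng.standard_normal(n_mc)

    def observed_r2(rho: float) -> float:
        tau = np.sqrt(total_var * rho)
        sig = np.sqrt(total_var * (1.0 - rho))
        p1 = expit(baseline_logit + tau * z_shared + sig * z1)
        p2 = expit(baseline_logit + tau * z_shared + sig * z2)
        f1 = p1 + b1 * np.sqrt(p1 * (1 - p1) / nuclei)
        f2 = p2 + b2 * np.sqrt(p2 * (1 - p2) / nuclei)
        return float(np.corrcoef(f1, f2)[0, 1] ** 2)

    return float(brentq(lambda r: observed_r2(r) - target_r2, 1e-4, 1 - 1e-4,
                        xtol=1e-4))


def glial_sharing_config(
    cell_type: str,
    n_donors: int = 114,
    regions: Sequence[str] = ("CaH", "DFC"),
    baseline_fraction: float | None = None,
    r2: float | None = None,
    total_var: float | None = None,
    nuclei_per_sample: float = 5000.0,
    calibrate: bool = True,
    seed: int = 0,
) -> CohortConfig:
    """Two-region cohort for cross-region sharing (r^2) recovery.

    The total latent logit variance defaults to the fold-difference-implied
    shared variance divided by sqrt(r^2). With ``calibrate=True`` the
    shared/noise split is chosen so the *population* Pearson r^2 of measured
    fractions equals the target (the latent logit correlation is slightly
    above sqrt(r^2) to offset expit nonlinearity and binomial sampling).
    ``calibrate=False`` instead sets tau2/(tau2+sigma2) = r2 directly.
    """
    r2 = CROSS_REGION_R2[cell_type] if r2 is None else r2
    if total_var is None:
        total_var = SHARED_LOGIT_VARIANCE[cell_type] / np.sqrt(r2)
    baselines = {"OPC": 0.03, "Astrocyte": 0.15, "Microglia": 0.08}
    frac = baselines[cell_type] if baseline_fraction is None else baseline_fraction
    base_logit = float(logit(frac))
    if calibrate:
        rho = _calibrate_latent_correlation(
            round(base_logit, 6), round(float(total_var), 6), round(float(r2), 6),
            float(nuclei_per_sample),
        )
    else:
        rho = r2
    tau2 = float(total_var * rho)
    sigma2 = float(total_var * (1.0 - rho))
    cell_types = {
        cell_type: CellTypeSpec(
            baseline_logit=base_logit, tau2=tau2, sigma2=sigma2, lineage="glia"
        )
    }
    return CohortConfig(
        n_donors=n_donors,
        regions=tuple(regions),
        nuclei_per_sample=nuclei_per_sample,
        cell_types=cell_types,
        seed=seed,
    )


def default_gene_specs(
    cell_types: Sequence[str],
    n_genes: int = 500,
    n_age_shared: int = 40,
    n_age_specific: int = 30,
    age_effect_sd: float = 0.1,
    n_chry: int = 8,
    n_chrx_sex: int = 4,
    sex_effect_log2fc: float = 2.0,
    n_eqtl: int = 100,
    eqtl_effect: float = 0.6,
    eqtl_shared_frac: float = 0.16,
    eqtl_neuron_frac: float = 0.16,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 1,
) -> tuple[list[GeneSpec], list[SnpSpec]]:
    """Structured gene/SNP specs mirroring the observed effect architecture.

    Age effects: a shared block that moves modestly in the same direction in
    every cell type, plus per-cell-type-specific blocks (strongest for MSN
    types when present). Sex effects confined to chrY (male-only expression)
    and a few chrX genes elevated in XX donors. eQTLs split into
    shared / neuron-shared / cell-type-specific patterns (roughly 16/16/68%).
    """
    rng = np.random.default_rng(seed)
    cell_types = list(cell_types)
    genes: list[GeneSpec] = []
    snps: list[SnpSpec] = []
    chroms = [f"chr{c}" for c in range(1, 6)]

    def _pos(i: int) -> tuple[str, int]:
        return chroms[i % len(chroms)], 1_000_000 + (i // len(chroms)) * 400_000

    gi = 0

    def _new(gene_kwargs) -> GeneSpec:
        nonlocal gi
        chrom, tss = _pos(gi)
        base = rng.uniform(3.0, 8.0)
        g = GeneSpec(
            gene_id=f"G{gi:04d}", chrom=chrom, tss=tss, baseline_log2cpm=base,
            **gene_kwargs,
        )
        gi += 1
        return g

    # shared age block: same modest positive effect in all cell types
    for _ in range(n_age_shared):
        eff = abs(rng.normal(age_effect_sd, age_effect_sd / 2))
        genes.append(
            _new(dict(age_log2fc_per_decade={ct: eff for ct in cell_types}))
        )
    # cell-type-specific age blocks; MSN-like types get larger effects
    for ct in cell_types:
        scale = age_effect_sd * (2.0 if ct.upper().startswith("MSN") else 1.0)
        for _ in range(n_age_specific):
            genes.append(
                _new(dict(age_log2fc_per_decade={ct: rng.normal(0.0, scale)}))
            )
    # sex-chromosome genes
    for _ in range(n_chry):
        genes.append(
            _new(dict(chrom_class="chrY", sex_effect_log2fc=sex_effect_log2fc))
        )
        genes[-1].chrom = "chrY"
    for _ in range(n_chrx_sex):
        genes.append(
            _new(dict(chrom_class="chrX", sex_effect_log2fc=-sex_effect_log2fc / 2))
        )
        genes[-1].chrom = "chrX"
    # eQTL genes
    n_shared = int(round(n_eqtl * eqtl_shared_frac))
    n_neuron = int(round(n_eqtl * eqtl_neuron_frac))
    neuron_like = [ct for ct in cell_types if "MSN" in ct.upper()
                   or "NEURON" in ct.upper() or "INTERNEURON" in ct.upper()]
    for j in range(n_eqtl):
        chrom, tss = _pos(gi)
        maf = rng.uniform(*maf_range)
        snp = SnpSpec(snp_id=f"rs{j:05d}", chrom=chrom, pos=tss + 1000, maf=maf)
        snps.append(snp)
        if j < n_shared:
            eff = {ct: eqtl_effect for ct in cell_types}
        elif j < n_shared + n_neuron and neuron_like:
            eff = {ct: eqtl_effect for ct in neuron_like}
        else:
            target = cell_types[j % len(cell_types)]
            eff = {target: eqtl_effect}
        genes.append(
            _new(dict(eqtl_snp=snp.snp_id, eqtl_effect=eff))
        )
    # remaining genes are null
    while gi < n_genes:
        genes.append(_new({}))
    # decoy SNPs with no expression effect
    for j in range(n_eqtl, n_eqtl + 50):
        chrom, tss = _pos(rng.integers(0, max(gi - 1, 1)))
        snps.append(
            SnpSpec(snp_id=f"rs{j:05d}", chrom=chrom, pos=tss + 2000,
                    maf=float(rng.uniform(*maf_range)))
        )
    return genes, snps


def default_cohort_config(
    n_donors: int = 150, n_genes: int = 500, n_eqtl: int = 100, seed: int = 0
) -> CohortConfig:
    """The full desk-scale cohort: all cell types, genes, and SNPs."""
    config = opc_attrition_config(n_donors=n_donors, seed=seed)
    config.cell_types["TAC3-PLPP4"] = CellTypeSpec(
        baseline_logit=float(logit(0.005)),
        age_slope_per_decade=-0.047,
        tau2=0.04,
        sigma2=0.02,
        lineage="neuron",
    )
    genes, snps = default_gene_specs(
        list(config.cell_types), n_genes=n_genes, n_eqtl=n_eqtl, seed=seed + 1
    )
    config.genes = genes
    config.snps = snps
    return config
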