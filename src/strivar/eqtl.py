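"""Cell-type-resolved cis-eQTL mapping and effect-pattern analysis.

Per cell type, donor log2 expression is rank inverse-normal transformed
(Blom offset) and regressed on SNP dosage with age and sex as covariates,
for every SNP within a cis window (default +/-1 Mb) of the gene's TSS.
The lead SNP is the minimum-p cis SNP; the gene-level p is the Bonferroni
min-p (min p x number of cis SNPs, capped at 1); eGenes are called by BH
across genes within cell type at FDR 0.01.

For the cross-cell-type effect matrix, each eGene's lead SNP is taken from
the cell type with the smallest gene-level p and its effect recomputed in
every cell type; rows are sign-oriented so the majority effect direction is
positive. K-means (K=13 by default) groups eQTLs into sharing patterns;
pairwise sharing is Spearman rho^2 over eQTLs significant in at least one
member of the pair. Fold-change-scale effects (log2 CPM per allele, no rank
transform) feed the constraint-vs-effect-size test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .stats import bh_adjust, inverse_normal_transform, wilcoxon_rank_sum

__all__ = [
    "map_cis_eqtls",
    "build_effect_matrix",
    "orient_rows",
    "cluster_eqtls",
    "pairwise_sharing",
    "constraint_effect_association",
    "ConstraintAssociation",
    "inverse_normal_transform",
]


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Project out covariate space C (with intercept) from columns of M."""
    beta, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ beta


def _covariate_matrix(meta: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(meta))]
    if "age" in covariates:
        cols.append((meta["age"].to_numpy(dtype=float) - 60.0) / 10.0)
    if "sex" in covariates and meta["sex"].nunique() > 1:
        cols.append((meta["sex"] == "M").astype(float).to_numpy())
    for c in covariates:
        if c in ("age", "sex"):
            continue
        cols.append(meta[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def _marginal_stats(y_res: np.ndarray, G_res: np.ndarray, df: int):
    """Per-SNP slope/SE/p of residualized expression on residualized dosage."""
    gss = (G_res**2).sum(axis=0)
    gss = np.where(gss <= 0, np.nan, gss)
    beta = (G_res.T @ y_res) / gss
    yss = float((y_res**2).sum())
    rss = yss - beta**2 * gss
    rss = np.maximum(rss, 1e-300)
    se = np.sqrt(rss / df / gss)
    t = beta / se
    p = 2 * sps.t.sf(np.abs(t), df)
    return beta, se, p


@dataclass
class _CellTypeContext:
    cell_type: str
    donors: pd.Index
    y_int_res: pd.DataFrame  # residualized INT expression, donors x genes
    y_log_res: pd.DataFrame  # residualized log2cpm (fold-change scale)
    g_res: pd.DataFrame  # residualized dosages
    df: int


def _prepare_context(
    pb, dosages: pd.DataFrame, donors: pd.DataFrame, covariates: Sequence[str],
    min_expr_frac: float,
) -> _CellTypeContext:
    shared = pb.counts.index.intersection(dosages.index)
    meta = donors.set_index("donor_id").loc[shared]
    log2 = pb.log2cpm().loc[shared]
    expressed = (pb.counts.loc[shared].to_numpy() > 0).mean(axis=0) >= min_expr_frac
    log2 = log2.loc[:, log2.columns[expressed]]
    C = _covariate_matrix(meta.reset_index(), covariates)
    yint = np.column_stack(
        [inverse_normal_transform(log2[g].to_numpy()) for g in log2.columns]
    )
    yint_res = _residualize(yint, C)
    ylog_res = _residualize(log2.to_numpy(), C)
    G = dosages.loc[shared].to_numpy(dtype=float)
    g_res = _residualize(G, C)
    df = len(shared) - C.shape[1] - 1
    return _CellTypeContext(
        cell_type=pb.cell_type,
        donors=shared,
        y_int_res=pd.DataFrame(yint_res, index=shared, columns=log2.columns),
        y_log_res=pd.DataFrame(ylog_res, index=shared, columns=log2.columns),
        g_res=pd.DataFrame(g_res, index=shared, columns=dosages.columns),
        df=df,
    )


def _cis_index(genes: pd.DataFrame, snps: pd.DataFrame, window: float):
    """gene_id -> array of SNP ids within the window of the TSS."""
    out = {}
    by_chrom = {c: sub.sort_values("pos") for c, sub in snps.groupby("chrom")}
    for _, g in genes.iterrows():
        sub = by_chrom.get(g["chrom"])
        if sub is None:
            out[g["gene_id"]] = np.array([], dtype=object)
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, g["tss"] - window, side="left")
        hi = np.searchsorted(pos, g["tss"] + window, side="right")
        out[g["gene_id"]] = sub["snp_id"].to_numpy()[lo:hi]
    return out


def map_cis_eqtls(
    pb_by_celltype: Mapping[str, object],
    dosages: pd.DataFrame,
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    donors: pd.DataFrame,
    window: float = 1_000_000.0,
    covariates: Sequence[str] = ("age", "sex"),
    maf_min: float = 0.05,
    fdr: float = 0.01,
    min_donors: int = 40,
    min_expr_frac: float = 0.25,
    return_context: bool = False,
):
    """Map cis-eQTLs per cell type; call eGenes at the requested FDR.

    ``pb_by_celltype`` maps cell type -> PseudobulkMatrix (regions already
    chosen or pooled by the caller). ``snps`` has snp_id, chrom, pos;
    ``genes`` has gene_id, chrom, tss. Genes with no cis SNP are recorded
    with NA statistics. Returns a tidy results table (one row per
    gene x cell type).
    """
    maf = dosages.mean(axis=0) / 2.0
    maf = np.minimum(maf, 1 - maf)
    usable_snps = maf.index[maf >= maf_min]
    snps_use = snps[snps["snp_id"].isin(usable_snps)]
    cis = _cis_index(genes, snps_use, window)
    rows = []
    contexts = {}
    for ct, pb in pb_by_celltype.items():
        ctx = _prepare_context(pb, dosages[usable_snps], donors, covariates,
                               min_expr_frac)
        if len(ctx.donors) < min_donors:
            raise ValueError(
                f"{ct}: only {len(ctx.donors)} donors with genotype+expression"
            )
        contexts[ct] = ctx
        for gene_id in ctx.y_int_res.columns:
            snp_ids = cis.get(gene_id, np.array([], dtype=object))
            if snp_ids.size == 0:
                rows.append(
                    {"gene": gene_id, "cell_type": ct, "lead_snp": None,
                     "beta": np.nan, "se": np.nan, "p_nominal": np.nan,
                     "n_cis_snps": 0, "p_gene": np.nan}
                )
                continue
            G = ctx.g_res[snp_ids].to_numpy()
            beta, se, p = _marginal_stats(
                ctx.y_int_res[gene_id].to_numpy(), G, ctx.df
            )
            j = int(np.nanargmin(p))
            rows.append(
                {"gene": gene_id, "cell_type": ct, "lead_snp": snp_ids[j],
                 "beta": float(beta[j]), "se": float(se[j]),
                 "p_nominal": float(p[j]), "n_cis_snps": int(snp_ids.size),
                 "p_gene": float(min(p[j] * snp_ids.size, 1.0))}
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    out["egene"] = False
    for ct in pb_by_celltype:
        m = (out["cell_type"] == ct) & out["p_gene"].notna()
        if m.any():
            out.loc[m, "q"] = bh_adjust(out.loc[m, "p_gene"])
    out["egene"] = out["q"] < fdr
    if return_context:
        return out, contexts
    return out


def _beta_for_snp(ctx: _CellTypeContext, gene: str, snp: str,
                  scale: str = "int") -> tuple[float, float, float]:
    ymat = ctx.y_int_res if scale == "int" else ctx.y_log_res
    if gene not in ymat.columns or snp not in ctx.g_res.columns:
        return np.nan, np.nan, np.nan
    g = ctx.g_res[snp].to_numpy()
    if float((g**2).sum()) <= 1e-12:
        return np.nan, np.nan, np.nan  # monomorphic in this subset
    beta, se, p = _marginal_stats(ymat[gene].to_numpy(), g[:, None], ctx.df)
    return float(beta[0]), float(se[0]), float(p[0])


def orient_rows(mat: pd.DataFrame, mask: pd.DataFrame | None = None
                ) -> tuple[pd.DataFrame, np.ndarray]:
    """Flip each row so the majority effect direction is positive.

    Ties on sign counts are broken by the sign of the row sum. Returns the
    oriented matrix and the applied flip signs (+1/-1 per row). Orientation
    is idempotent: re-orienting an oriented matrix changes nothing.
    """
    vals = mat.to_numpy().copy()
    use = mask.to_numpy() if mask is not None else ~np.isnan(vals)
    flips = np.ones(len(vals))
    for i in range(len(vals)):
        row = np.where(use[i], vals[i], 0.0)
        n_pos = int(np.sum(row > 0))
        n_neg = int(np.sum(row < 0))
        if n_neg > n_pos or (n_neg == n_pos and row.sum() < 0):
            flips[i] = -1.0
    return pd.DataFrame(vals * flips[:, None], index=mat.index,
                        columns=mat.columns), flips


def build_effect_matrix(
    results: pd.DataFrame,
    contexts: Mapping[str, _CellTypeContext],
    scale: str = "int",
    orient: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """eGene x cell-type matrix of lead-SNP effects.

    The lead SNP for each eGene comes from the cell type with the smallest
    gene-level p; its effect is recomputed in every cell type. Missing
    entries (gene untested or SNP monomorphic in a cell type) are imputed 0
    and recorded in the mask. Returns (matrix, mask, lead table).
    """
    eg = results[results["egene"]]
    if eg.empty:
        raise ValueError("no eGenes to build a matrix from")
    lead = (
        eg.sort_values("p_gene").groupby("gene", sort=True).first()[
            ["lead_snp", "cell_type", "p_gene"]
        ]
    )
    cts = list(contexts)
    mat = pd.DataFrame(np.nan, index=lead.index, columns=cts)
    for gene, row in lead.iterrows():
        for ct in cts:
            b, _, _ = _beta_for_snp(contexts[ct], gene, row["lead_snp"], scale)
            mat.loc[gene, ct] = b
    mask = mat.notna()
    mat = mat.fillna(0.0)
    if orient:
        mat, _ = orient_rows(mat, mask)
    return mat, mask, lead.reset_index()


def cluster_eqtls(
    mat: pd.DataFrame, k: int = 13, seed: int = 0, n_init: int = 50
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """K-means over eQTL effect patterns; summarise each cluster.

    Returns (labels, centroids, summary with dominant cell types and the
    shared-vs-specific breakdown). A cluster is "shared" when at least half
    the cell types have centroid effects >= 50% of the centroid maximum.
    """
    if k > len(mat):
        raise ValueError(f"k={k} exceeds the number of eQTLs ({len(mat)})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = pd.Series(km.fit_predict(mat.to_numpy()), index=mat.index,
                       name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, columns=mat.columns)
    rows = []
    for c in range(k):
        cen = centroids.iloc[c]
        peak = cen.abs().max()
        dominant = [str(c) for c in cen.index[cen.abs() >= 0.5 * peak]] \
            if peak > 0 else []
        rows.append(
            {
                "cluster": c,
                "n_eqtls": int((labels == c).sum()),
                "dominant_cell_types": ",".join(dominant),
                "shared": len(dominant) >= max(2, len(mat.columns) // 2),
            }
        )
    summary = pd.DataFrame(rows)
    total = summary["n_eqtls"].sum()
    summary["fraction"] = summary["n_eqtls"] / total
    return labels, centroids, summary


def pairwise_sharing(
    mat: pd.DataFrame,
    significant: pd.DataFrame,
    min_eqtls: int = 30,
) -> pd.DataFrame:
    """Spearman rho^2 of effects between cell types over union-significant eQTLs.

    ``significant`` is a boolean gene x cell-type frame (eGene calls). Pairs
    with fewer than ``min_eqtls`` qualifying eQTLs get NA.
    """
    cts = list(mat.columns)
    out = pd.DataFrame(np.eye(len(cts)), index=cts, columns=cts)
    for a, b in combinations(cts, 2):
        qual = significant.reindex(mat.index)[[a, b]].fillna(False).any(axis=1)
        sub = mat.loc[qual, [a, b]]
        if len(sub) < min_eqtls:
            out.loc[a, b] = out.loc[b, a] = np.nan
            continue
        rho = sps.spearmanr(sub[a], sub[b]).statistic
        out.loc[a, b] = out.loc[b, a] = float(rho**2)
    return out


@dataclass
class ConstraintAssociation:
    spearman_rho: float
    spearman_p: float
    wilcoxon_stat: float
    wilcoxon_p: float
    n_genes: int
    direction: str  # 'negative' when constrained genes have smaller effects


def constraint_effect_association(
    effects: pd.Series,
    constraint: pd.Series,
    constrained_flag: pd.Series | None = None,
) -> ConstraintAssociation:
    """Association of |effect size| (fold-change scale) with gene constraint.

    Spearman correlation of |beta| with the constraint score across eGenes,
    plus a two-group Wilcoxon rank-sum on a binary constrained /
    unconstrained split (provided flag, else a median split on the score).
    Higher constraint scores mean less tolerance to loss of function.
    """
    shared = effects.index.intersection(constraint.index)
    if len(shared) < 50:
        raise ValueError("constraint scores cover fewer than 50 eGenes")
    x = effects.loc[shared].abs().to_numpy(dtype=float)
    c = constraint.loc[shared].to_numpy(dtype=float)
    if np.allclose(c, c[0]):
        raise ValueError("constraint scores are constant")
    rho, p = sps.spearmanr(x, c)
    if constrained_flag is not None:
        flag = constrained_flag.loc[shared].to_numpy(dtype=bool)
    else:
        flag = c >= np.median(c)
    stat, wp = wilcoxon_rank_sum(x[flag], x[~flag])
    return ConstraintAssociation(
        spearman_rho=float(rho),
        spearman_p=float(p),
        wilcoxon_stat=stat,
        wilcoxon_p=wp,
        n_genes=int(len(shared)),
        direction="negative" if rho < 0 else "non-negative",
    )
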