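"""Pseudobulk differential expression by age and sex.

Nucleus-level counts are summed per (donor, cell type, region) into
pseudobulk libraries, normalized to log2 CPM, and modelled per gene by a
linear regression on age (decades, centred at 60) and sex, weighted by the
log of the per-donor cell count. Effects are log2 fold-change per decade of
age. Downstream summaries: cross-cell-type Spearman rho^2 of age effects on
union-significant genes, k-means clustering of gene age-profiles, and a
method-of-moments transcriptome-wide impact ("TWI (simplified)"): the mean
over genes of (beta_hat^2 - SE^2), an unbiased estimate of the mean squared
true effect that corrects each squared estimate for its estimation error.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps
from sklearn.cluster import KMeans

from .stats import bh_adjust
from .synthetic import PseudobulkMatrix

__all__ = [
    "aggregate_pseudobulk",
    "normalize_log2cpm",
    "fit_age_sex_de",
    "build_effect_profile_matrix",
    "cross_celltype_effect_correlation",
    "cluster_age_profiles",
    "gap_statistic",
    "estimate_transcriptome_impact",
    "TwiEstimate",
    "export_rnk",
]


def aggregate_pseudobulk(
    matrix,
    features: Sequence[str],
    barcodes: Sequence[str],
    assignments: pd.DataFrame,
    min_cells: int = 10,
) -> tuple[dict[tuple[str, str], PseudobulkMatrix], pd.DataFrame]:
    """Sum nucleus counts into donor pseudobulk per (cell type, region).

    ``matrix`` is genes x nuclei (sparse or dense); ``assignments`` maps
    nucleus_id -> donor_id, region, cell_type. Donors contributing fewer
    than ``min_cells`` nuclei to a (cell type, region) are excluded and
    reported in the returned log. Barcodes missing from ``assignments``
    raise.
    """
    m = sparse.csc_matrix(matrix)
    if m.shape[1] != len(barcodes):
        raise ValueError("matrix columns do not match barcodes")
    amap = assignments.set_index("nucleus_id")
    missing = [b for b in barcodes if b not in amap.index]
    if missing:
        raise ValueError(f"{len(missing)} barcodes missing from assignments, "
                         f"e.g. {missing[0]!r}")
    meta = amap.loc[list(barcodes)]
    out: dict[tuple[str, str], PseudobulkMatrix] = {}
    log_rows = []
    for (ct, region), sub in meta.groupby(["cell_type", "region"], sort=True):
        donors, counts, cells = [], [], []
        for donor, dsub in sub.groupby("donor_id", sort=True):
            idx = np.flatnonzero(
                (meta["cell_type"].to_numpy() == ct)
                & (meta["region"].to_numpy() == region)
                & (meta["donor_id"].to_numpy() == donor)
            )
            n_cells = idx.size
            if n_cells < min_cells:
                log_rows.append(
                    {"cell_type": ct, "region": region, "donor_id": donor,
                     "n_cells": n_cells, "excluded": True}
                )
                continue
            donors.append(donor)
            cells.append(n_cells)
            counts.append(np.asarray(m[:, idx].sum(axis=1)).ravel())
            log_rows.append(
                {"cell_type": ct, "region": region, "donor_id": donor,
                 "n_cells": n_cells, "excluded": False}
            )
        if not donors:
            continue
        counts_df = pd.DataFrame(
            np.vstack(counts), index=donors, columns=list(features)
        )
        out[(ct, region)] = PseudobulkMatrix(
            cell_type=ct,
            region=region,
            counts=counts_df,
            library_size=counts_df.sum(axis=1),
            cells_per_donor=pd.Series(cells, index=donors, dtype=float),
        )
    return out, pd.DataFrame(log_rows)


def normalize_log2cpm(counts: pd.DataFrame, library_size=None) -> pd.DataFrame:
    """log2(count * 1e6 / library_size + 1), row-wise libraries."""
    if library_size is None:
        library_size = counts.sum(axis=1)
    lib = np.asarray(library_size, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    vals = np.log2(counts.to_numpy(dtype=float) * 1e6 / lib[:, None] + 1.0)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def _wls(X: np.ndarray, Y: np.ndarray, w: np.ndarray):
    """Weighted least squares for many genes sharing one design.

    Returns (beta p x G, se p x G, df).
    """
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    Yw = Y * sw[:, None]
    XtX = Xw.T @ Xw
    XtXinv = np.linalg.inv(XtX)
    beta = XtXinv @ (Xw.T @ Yw)
    resid = Yw - Xw @ beta
    df = X.shape[0] - X.shape[1]
    if df <= 0:
        raise ValueError("design is saturated: no residual degrees of freedom")
    s2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(XtXinv), s2))
    return beta, se, df


def fit_age_sex_de(
    pb: PseudobulkMatrix,
    donors: pd.DataFrame,
    gene_meta: pd.DataFrame | None = None,
    covariates: Sequence[str] = (),
    min_expr_frac: float = 0.25,
    min_donors: int = 20,
) -> pd.DataFrame:
    """Per-gene weighted linear DE on log2 CPM.

    Model: log2cpm ~ age_decades + sex_male (+ covariates), weights
    log(cell count). Genes expressed (nonzero) in fewer than
    ``min_expr_frac`` of donors are skipped. Returns a tidy table with
    beta/se/t/p/q per test (BH within this cell type x region, separately
    for age and sex), plus chromosome class when ``gene_meta`` (gene_id,
    chrom_class) is given.
    """
    meta = donors.set_index("donor_id").loc[pb.counts.index]
    if len(meta) < min_donors:
        raise ValueError(f"need >= {min_donors} donors, have {len(meta)}")
    Ylog = normalize_log2cpm(pb.counts, pb.library_size)
    expressed = (pb.counts.to_numpy() > 0).mean(axis=0) >= min_expr_frac
    genes = pb.counts.columns[expressed]
    Y = Ylog.loc[:, genes].to_numpy()
    cols = [np.ones(len(meta)), (meta["age"].to_numpy() - 60.0) / 10.0]
    names = ["intercept", "age_decades"]
    has_sex = meta["sex"].nunique() > 1
    if has_sex:
        cols.append((meta["sex"] == "M").astype(float).to_numpy())
        names.append("sex_male")
    for c in covariates:
        cols.append(meta[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    w = np.log(np.maximum(pb.cells_per_donor.to_numpy(), 2.0))
    beta, se, df = _wls(X, Y, w)
    out = pd.DataFrame(
        {
            "gene": genes,
            "cell_type": pb.cell_type,
            "region": pb.region,
            "mean_log2cpm": Y.mean(axis=0),
            "n_donors": len(meta),
        }
    )
    ia = names.index("age_decades")
    out["beta_age"] = beta[ia]
    out["se_age"] = se[ia]
    out["t_age"] = beta[ia] / se[ia]
    out["p_age"] = 2 * sps.t.sf(np.abs(out["t_age"]), df)
    out["q_age"] = bh_adjust(out["p_age"])
    if has_sex:
        isx = names.index("sex_male")
        out["beta_sex"] = beta[isx]
        out["se_sex"] = se[isx]
        out["t_sex"] = beta[isx] / se[isx]
        out["p_sex"] = 2 * sps.t.sf(np.abs(out["t_sex"]), df)
        out["q_sex"] = bh_adjust(out["p_sex"])
    if gene_meta is not None:
        out = out.merge(
            gene_meta[["gene_id", "chrom_class"]].rename(columns={"gene_id": "gene"}),
            on="gene", how="left",
        )
    return out


def build_effect_profile_matrix(
    results: pd.DataFrame,
    fdr: float = 0.05,
    value: str = "beta_age",
    qcol: str = "q_age",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes x cell types matrix of age effects for profile clustering.

    Includes genes significant (q < fdr) in at least one cell type; genes
    untested in a cell type are imputed 0 and flagged in the returned mask
    (True where a measured value is present).
    """
    mat = results.pivot_table(index="gene", columns="cell_type", values=value,
                              aggfunc="first")
    q = results.pivot_table(index="gene", columns="cell_type", values=qcol,
                            aggfunc="first")
    include = (q < fdr).any(axis=1)
    mat = mat.loc[include]
    mask = mat.notna()
    return mat.fillna(0.0), mask


def cross_celltype_effect_correlation(
    results: pd.DataFrame,
    fdr: float = 0.05,
    min_genes: int = 50,
    value: str = "beta_age",
    qcol: str = "q_age",
    union_significant: bool = True,
) -> pd.DataFrame:
    """Pairwise Spearman rho^2 of gene-level age effects between cell types.

    For each pair, genes significant (q < fdr) in at least one member are
    used (set ``union_significant=False`` for the all-genes variant). Pairs
    with fewer than ``min_genes`` shared genes get NA.
    """
    cts = sorted(results["cell_type"].unique())
    beta = results.pivot_table(index="gene", columns="cell_type", values=value,
                               aggfunc="first")
    q = results.pivot_table(index="gene", columns="cell_type", values=qcol,
                            aggfunc="first")
    out = pd.DataFrame(np.eye(len(cts)), index=cts, columns=cts)
    for a, b in combinations(cts, 2):
        sub = beta[[a, b]].dropna()
        if union_significant:
            sig = (q.loc[sub.index, [a, b]] < fdr).any(axis=1)
            sub = sub[sig]
        if len(sub) < min_genes:
            out.loc[a, b] = out.loc[b, a] = np.nan
            continue
        rho = sps.spearmanr(sub[a], sub[b]).statistic
        out.loc[a, b] = out.loc[b, a] = rho**2
    return out


def cluster_age_profiles(
    mat: pd.DataFrame, k: int = 8, seed: int = 0, n_init: int = 50
) -> tuple[pd.Series, pd.DataFrame, float]:
    """K-means over gene age-effect profiles (rows genes, columns cell types).

    Returns (labels, centroids, within-cluster sum of squares). Deterministic
    given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(mat):
        raise ValueError(f"k={k} exceeds the number of genes ({len(mat)})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(mat.to_numpy())
    centroids = pd.DataFrame(km.cluster_centers_, columns=mat.columns)
    return pd.Series(labels, index=mat.index, name="cluster"), centroids, float(
        km.inertia_
    )


def gap_statistic(
    mat: pd.DataFrame, k_values: Sequence[int] = tuple(range(1, 13)),
    n_ref: int = 10, seed: int = 0,
) -> pd.DataFrame:
    """Gap statistic over candidate k (uniform-box reference sets)."""
    X = mat.to_numpy()
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    rows = []
    for k in k_values:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        log_w = np.log(max(km.inertia_, 1e-300))
        ref = []
        for _ in range(n_ref):
            Xr = rng.uniform(lo, hi, size=X.shape)
            ref.append(
                np.log(max(KMeans(n_clusters=k, n_init=3,
                                  random_state=seed).fit(Xr).inertia_, 1e-300))
            )
        rows.append(
            {"k": k, "gap": float(np.mean(ref) - log_w),
             "sk": float(np.std(ref) * np.sqrt(1 + 1 / n_ref))}
        )
    return pd.DataFrame(rows)


@dataclass
class TwiEstimate:
    """Simplified transcriptome-wide impact: mean true squared effect."""

    cell_type: str
    impact: float
    se: float
    n_genes: int
    label: str = "TWI (simplified)"


def estimate_transcriptome_impact(
    results: pd.DataFrame,
    beta_col: str = "beta_age",
    se_col: str = "se_age",
    n_boot: int = 1000,
    seed: int = 0,
    min_genes: int = 100,
) -> TwiEstimate:
    """Method-of-moments impact: mean over genes of (beta_hat^2 - SE^2).

    E[beta_hat^2] = beta^2 + SE^2, so subtracting each gene's squared
    standard error gives an unbiased estimate of the mean squared true
    effect; pure-noise genes contribute zero in expectation. SE by gene-level
    bootstrap.
    """
    sub = results.dropna(subset=[beta_col, se_col])
    if len(sub) < min_genes:
        raise ValueError(f"need >= {min_genes} tested genes with SEs")
    terms = sub[beta_col].to_numpy() ** 2 - sub[se_col].to_numpy() ** 2
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, terms.size, size=(n_boot, terms.size))
    boots = terms[idx].mean(axis=1)
    ct = sub["cell_type"].iloc[0] if "cell_type" in sub else ""
    return TwiEstimate(
        cell_type=str(ct), impact=float(terms.mean()), se=float(boots.std(ddof=1)),
        n_genes=int(terms.size),
    )


def export_rnk(results: pd.DataFrame, path: str, stat: str = "t_age") -> None:
    """GSEA-compatible .rnk: gene <tab> ranking statistic, descending."""
    out = results[["gene", stat]].sort_values(stat, ascending=False)
    out.to_csv(path, sep="\t", header=False, index=False)
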