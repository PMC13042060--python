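"""Village-level quality control.

Pooled ("village") designs process ~20 donors' tissue as one sample and
reassign nuclei to donors from transcribed variants. Droplets containing two
donors' nuclei ("genotypic doublets") are directly detectable, and because
only a fraction 1 - sum(p_i^2) of random donor pairs is heterotypic, the
genotypic count also calibrates the *total* doublet rate and flags clusters
enriched for doublet profiles.

Sample exclusion follows the data-driven rule: drop samples with too few
nuclei, then samples whose centred-log-ratio composition is a robust-z
outlier within their region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "expected_genotypic_doublet_fraction",
    "infer_total_doublet_rate",
    "flag_doublet_clusters",
    "exclude_outlier_samples",
]


def expected_genotypic_doublet_fraction(proportions) -> float:
    """Probability that a random pair of nuclei comes from two donors.

    For a village with donor nucleus proportions p_i this is 1 - sum(p_i^2);
    0.95 for twenty equally represented donors.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions sum to {p.sum():.8f}, not 1")
    return float(1.0 - np.sum(p**2))


def infer_total_doublet_rate(n_genotypic: int, n_barcodes: int, proportions) -> float:
    """Total doublet rate implied by the observed genotypic-doublet count."""
    if n_genotypic > n_barcodes:
        raise ValueError("n_genotypic cannot exceed n_barcodes")
    if n_genotypic == 0:
        return 0.0
    frac = expected_genotypic_doublet_fraction(proportions)
    if frac == 0.0:
        raise ValueError("single-donor village: genotypic doublets unobservable")
    return float((n_genotypic / n_barcodes) / frac)


def flag_doublet_clusters(
    assignments: pd.DataFrame,
    alpha: float = 0.05,
    enrichment: float = 2.0,
) -> pd.DataFrame:
    """Flag clusters enriched for genotypic doublets.

    ``assignments`` needs columns ``cluster`` and ``genotypic_doublet`` (0/1).
    Each cluster gets a one-sided binomial test of its genotypic-doublet
    count against the dataset-wide rate; BH across clusters; flagged when
    q < alpha AND the observed fraction is at least ``enrichment`` times the
    dataset-wide rate (so huge clusters with trivial excess are not flagged).
    """
    if assignments.empty:
        raise ValueError("no nuclei supplied")
    base = float(assignments["genotypic_doublet"].mean())
    rows = []
    for cluster, sub in assignments.groupby("cluster", sort=True):
        n = len(sub)
        if n == 0:
            raise ValueError(f"empty cluster {cluster!r}")
        x = int(sub["genotypic_doublet"].sum())
        p = float(sps.binom.sf(x - 1, n, base)) if base > 0 else (1.0 if x == 0 else 0.0)
        rows.append(
            {
                "cluster_id": cluster,
                "n_nuclei": n,
                "n_genotypic_doublets": x,
                "observed_fraction": x / n,
                "expected_fraction": base,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    out["flagged"] = (out["q"] < alpha) & (
        out["observed_fraction"] >= enrichment * base
    )
    return out


def _clr(counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    x = counts + pseudocount
    logx = np.log(x / x.sum(axis=1, keepdims=True))
    return logx - logx.mean(axis=1, keepdims=True)


def exclude_outlier_samples(
    samples: pd.DataFrame,
    celltype_cols: list[str],
    min_nuclei: int = 500,
    z_thresh: float = 4.0,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition samples into kept / excluded with machine-readable reasons.

    Exclusions: total_nuclei < min_nuclei ("low_ascertainment"), then per
    region a robust z (median/MAD, with the 1.4826 Gaussian consistency
    factor) on each centred-log-ratio coordinate of the cell-type
    composition; samples with max |z| > z_thresh get
    "abnormal_composition". Zero counts take a 0.5 pseudocount before the
    log-ratio. Raises if everything would be excluded.
    """
    required = {"donor_id", "region", "total_nuclei"}
    if not required <= set(samples.columns):
        raise ValueError(f"samples table needs columns {sorted(required)}")
    for region, sub in samples.groupby("region"):
        if len(sub) < 3:
            raise ValueError(f"region {region!r} has fewer than 3 samples")
    excluded = []
    low = samples["total_nuclei"] < min_nuclei
    for _, row in samples[low].iterrows():
        excluded.append(
            {"donor_id": row["donor_id"], "region": row["region"],
             "reason": "low_ascertainment",
             "detail": f"total_nuclei={row['total_nuclei']}<{min_nuclei}"}
        )
    remaining = samples[~low]
    bad_idx = []
    for region, sub in remaining.groupby("region"):
        counts = sub[celltype_cols].to_numpy(dtype=float)
        clr = _clr(counts, pseudocount)
        med = np.median(clr, axis=0)
        mad = sps.median_abs_deviation(clr, axis=0, scale="normal")
        dev = clr - med
        with np.errstate(divide="ignore", invalid="ignore"):
            z = dev / mad
        # degenerate coordinate (MAD 0): any deviation is infinitely outlying
        z = np.where(mad <= 0, np.where(np.abs(dev) > 1e-9, np.inf, 0.0), z)
        worst = np.max(np.abs(z), axis=1)
        for i, (idx, row) in enumerate(sub.iterrows()):
            if worst[i] > z_thresh:
                bad_idx.append(idx)
                coord = celltype_cols[int(np.argmax(np.abs(z[i])))]
                excluded.append(
                    {"donor_id": row["donor_id"], "region": row["region"],
                     "reason": "abnormal_composition",
                     "detail": f"max|z|={worst[i]:.2f}>{z_thresh} at {coord}"}
                )
    kept = remaining.drop(index=bad_idx)
    if kept.empty:
        raise ValueError("all samples excluded; thresholds are likely misconfigured")
    return kept.reset_index(drop=True), pd.DataFrame(
        excluded, columns=["donor_id", "region", "reason", "detail"]
    )
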