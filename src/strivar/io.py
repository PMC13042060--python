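"""Readers and writers for the on-disk interchange formats.

All tables are tab-delimited with a header row. Sparse counts go to Matrix
Market (1-based indices) with companion features/barcodes TSVs. Genotypes are
written as minimal VCF 4.2 (GT:DS per donor column, 1-based positions) and
read back with cyvcf2.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts_mtx(matrix, features: Sequence[str], barcodes: Sequence[str],
                     prefix: str) -> None:
    """Write genes x nuclei counts as counts.mtx + features.tsv + barcodes.tsv."""
    m = sparse.csc_matrix(matrix)
    spio.mmwrite(os.path.join(prefix, "counts.mtx"), m)
    pd.DataFrame({"gene_id": list(features)}).to_csv(
        os.path.join(prefix, "features.tsv"), sep="\t", index=False
    )
    pd.DataFrame({"barcode": list(barcodes)}).to_csv(
        os.path.join(prefix, "barcodes.tsv"), sep="\t", index=False
    )


def read_counts_mtx(prefix: str):
    matrix = spio.mmread(os.path.join(prefix, "counts.mtx")).tocsc()
    features = pd.read_csv(os.path.join(prefix, "features.tsv"), sep="\t")[
        "gene_id"
    ].tolist()
    barcodes = pd.read_csv(os.path.join(prefix, "barcodes.tsv"), sep="\t")[
        "barcode"
    ].tolist()
    return matrix, features, barcodes


def write_pseudobulk(pb_by_key: dict, path: str) -> None:
    """Combined pseudobulk TSV: rows genes, columns 'donor:region:celltype'."""
    cols = {}
    for (ct, region), pb in pb_by_key.items():
        for donor in pb.counts.index:
            cols[f"{donor}:{region}:{ct}"] = pb.counts.loc[donor].to_numpy()
    any_pb = next(iter(pb_by_key.values()))
    out = pd.DataFrame(cols, index=any_pb.counts.columns)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_genes_table(genes, path: str) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "tss": g.tss,
            "chrom_class": g.chrom_class,
            "constraint": "" if g.constraint is None else g.constraint,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_vcf(dosages: pd.DataFrame, snps, path: str) -> None:
    """Minimal VCF 4.2 with GT and DS fields; donors as sample columns.

    ``dosages`` is donors x SNPs (values 0/1/2); ``snps`` is a sequence of
    objects with snp_id, chrom, pos attributes.
    """
    donors = list(dosages.index)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">',
    ]
    chroms = sorted({s.chrom for s in snps})
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(donors)
    )
    order = sorted(snps, key=lambda s: (s.chrom, s.pos))
    for s in order:
        d = dosages[s.snp_id].to_numpy().astype(int)
        fields = [s.chrom, str(s.pos), s.snp_id, "A", "G", ".", "PASS", ".", "GT:DS"]
        fields += [f"{gt_map[int(v)]}:{int(v)}" for v in d]
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf_dosages(path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into (dosages donors x SNPs, snp table).

    Dosage is taken from the DS FORMAT field when present, else from the
    genotype allele count.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    donors = list(vcf.samples)
    cols, rows = {}, []
    for v in vcf:
        try:
            ds = np.asarray(v.format("DS"), dtype=float).ravel()
        except Exception:
            gts = np.asarray(v.genotypes)[:, :2]
            ds = gts.sum(axis=1).astype(float)
        cols[v.ID] = ds
        rows.append({"snp_id": v.ID, "chrom": v.CHROM, "pos": v.POS})
    dosages = pd.DataFrame(cols, index=donors)
    return dosages, pd.DataFrame(rows)


def write_truth(truth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())
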