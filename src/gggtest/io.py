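"""Readers, gene/SNP mapping, and the PPI-pair scan driver.

Conventions: genomic coordinates are 1-based inclusive (VCF/UCSC style);
SNPs map to a gene when they fall within ``flank`` bp (default 5 kb) of its
interval; dosages count copies of the VCF REF allele by default (flip with
``ref_counting=False`` for PLINK-style ALT counting).
"""
from __future__ import annotations

import logging
import os
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .combine import chunk_pairs, gg_gates, gg_minp, gg_tprod, gg_tts
from .correlation import corr_tests_from_genotypes
from .datatypes import (
    CovariateTable,
    GeneModel,
    GenePairResult,
    GenotypeMatrix,
    PhenotypeVector,
    TruncationConfig,
)
from .marker import pairwise_pvalues
from .pca_test import gg_pc_test

logger = logging.getLogger("gggtest")

__all__ = [
    "read_genotypes",
    "write_dosage_tsv",
    "read_phenotype",
    "read_covariates",
    "read_gene_models",
    "read_pair_list",
    "read_ld_reference",
    "map_snps_to_genes",
    "scan_pairs",
    "bonferroni_threshold",
]


class ParseError(ValueError):
    pass


def read_genotypes(
    path: str,
    fmt: str = "vcf",
    ref_counting: bool = True,
    samples: Optional[List[str]] = None,
) -> Tuple[GenotypeMatrix, List[str]]:
    """Load a genotype matrix; returns (matrix, sample ids).

    ``fmt`` is one of ``vcf`` (GT fields; multiallelic records rejected),
    ``plink-raw`` (PLINK --recode A output, counted-allele dosages taken
    as-is), or ``tsv-dosage`` (sample-id column + one dosage column per
    SNP). Missing dosages are mean-imputed per SNP.
    """
    if fmt == "vcf":
        return _read_vcf(path, ref_counting)
    if fmt == "plink-raw":
        return _read_plink_raw(path)
    if fmt == "tsv-dosage":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {fmt}")


def _read_vcf(path: str, ref_counting: bool) -> Tuple[GenotypeMatrix, List[str]]:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    dosage_cols, ids, positions = [], [], []
    for k, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise ParseError(
                f"multiallelic record at {var.CHROM}:{var.POS} "
                f"(record {k + 1}); split it first"
            )
        # gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        gt = np.asarray(var.gt_types, dtype=float)
        alt = np.where(gt == 3, 2.0, np.where(gt == 1, 1.0, np.where(gt == 0, 0.0, np.nan)))
        dos = 2.0 - alt if ref_counting else alt
        if np.isnan(dos).any():
            mean = np.nanmean(dos)
            dos = np.where(np.isnan(dos), mean, dos)
        dosage_cols.append(dos)
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        positions.append((var.CHROM, var.POS))
    if not dosage_cols:
        raise ParseError(f"no variant records in {path}")
    return (
        GenotypeMatrix(
            dosages=np.column_stack(dosage_cols), snp_ids=ids, positions=positions
        ),
        sample_ids,
    )


def _read_plink_raw(path: str) -> Tuple[GenotypeMatrix, List[str]]:
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ParseError(f"not a PLINK .raw file (missing columns {missing})")
    snp_cols = [c for c in df.columns if c not in meta]
    ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    dosages = df[snp_cols].to_numpy(dtype=float)
    col_means = np.nanmean(dosages, axis=0)
    nan_mask = np.isnan(dosages)
    dosages[nan_mask] = np.take(col_means, np.where(nan_mask)[1])
    return GenotypeMatrix(dosages=dosages, snp_ids=ids), df["IID"].astype(str).tolist()


def _read_dosage_tsv(path: str) -> Tuple[GenotypeMatrix, List[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosages = df.to_numpy(dtype=float)
    if np.isnan(dosages).any():
        col_means = np.nanmean(dosages, axis=0)
        nan_mask = np.isnan(dosages)
        dosages[nan_mask] = np.take(col_means, np.where(nan_mask)[1])
    return (
        GenotypeMatrix(dosages=dosages, snp_ids=list(df.columns)),
        df.index.astype(str).tolist(),
    )


def write_dosage_tsv(path: str, geno: GenotypeMatrix, sample_ids: Sequence[str]) -> None:
    pd.DataFrame(geno.dosages, index=list(sample_ids), columns=list(geno.snp_ids)).to_csv(
        path, sep="\t", index_label="sample"
    )


def read_phenotype(
    path: str, trait: Optional[str] = None, log_transform: bool = False
) -> Tuple[PhenotypeVector, List[str]]:
    """Two-plus-column TSV: sample id then trait column(s).

    ``log_transform`` applies natural log before any model fit (for skewed
    traits such as triglycerides); it is recorded in the trait name.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    col = trait if trait is not None else df.columns[0]
    vals = df[col].to_numpy(dtype=float)
    keep = np.isfinite(vals)
    if log_transform:
        vals = np.log(vals)
    name = f"log({col})" if log_transform else col
    return (
        PhenotypeVector(values=vals[keep], trait_name=name),
        df.index[keep].astype(str).tolist(),
    )


def read_covariates(path: str) -> Tuple[CovariateTable, List[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return (
        CovariateTable(values=df.to_numpy(dtype=float), names=list(df.columns)),
        df.index.astype(str).tolist(),
    )


def read_gene_models(path: str, flank: int = 5_000) -> List[GeneModel]:
    """BED-like TSV: name, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["name", "chrom", "start", "end"],
        comment="#",
    )
    return [
        GeneModel(name=str(r.name_), chrom=str(r.chrom), start=int(r.start),
                  end=int(r.end), flank=flank)
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def read_pair_list(path: str, genes: Sequence[GeneModel]) -> List[Tuple[str, str]]:
    """Two-column TSV of gene names; deduplicated, order-normalized, no self-pairs."""
    known = {g.name for g in genes}
    seen = set()
    pairs: List[Tuple[str, str]] = []
    df = pd.read_csv(path, sep="\t", header=None, names=["g1", "g2"], comment="#")
    for g1, g2 in zip(df.g1.astype(str), df.g2.astype(str)):
        if g1 == g2:
            logger.warning("skipping self-pair %s", g1)
            continue
        for g in (g1, g2):
            if g not in known:
                raise ValueError(f"pair gene {g} has no gene model")
        key = tuple(sorted((g1, g2)))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(key)
    return pairs


def map_snps_to_genes(
    geno: GenotypeMatrix, genes: Sequence[GeneModel]
) -> Dict[str, List[int]]:
    """Per-gene SNP column indices (a SNP may land in several genes).

    Genes with no SNPs are flagged and omitted.
    """
    if geno.positions is None:
        raise ValueError("genotype matrix has no SNP positions")
    mapping: Dict[str, List[int]] = {}
    for gene in genes:
        idx = [
            k
            for k, (chrom, pos) in enumerate(geno.positions)
            if gene.contains(chrom, int(pos))
        ]
        if not idx:
            logger.warning("gene %s has no SNPs within +/-%d bp", gene.name, gene.flank)
            continue
        mapping[gene.name] = idx
    return mapping


def read_ld_reference(
    ld_path: str, freq_path: str
) -> Tuple[pd.DataFrame, pd.Series]:
    """Reference-panel LD for the external-LD Sigma route.

    ``ld_path``: TSV holding a square signed dosage-correlation matrix with
    SNP ids as both header and first column (within-gene blocks are
    extracted per gene at scan time; cross-gene entries are ignored).
    ``freq_path``: two-column TSV of SNP id and reference allele frequency.
    """
    ld = pd.read_csv(ld_path, sep="\t", index_col=0)
    ld.index = ld.index.astype(str)
    ld.columns = ld.columns.astype(str)
    if list(ld.index) != list(ld.columns):
        raise ParseError("LD matrix rows and columns disagree")
    freq = pd.read_csv(freq_path, sep="\t", header=None, names=["snp", "freq"],
                       comment="#").set_index("snp")["freq"].astype(float)
    freq.index = freq.index.astype(str)
    if ((freq <= 0) | (freq >= 1)).any():
        raise ParseError("reference allele frequencies must lie in (0, 1)")
    return ld, freq


def bonferroni_threshold(alpha: float, n_tests: int, n_traits: int = 1) -> float:
    """Significance threshold over chunk-level tests x traits."""
    if n_tests < 1 or n_traits < 1:
        raise ValueError("test and trait counts must be positive")
    return alpha / (n_tests * n_traits)


_SCAN_COLS = [
    "gene1", "gene2", "chunk", "method", "n_pairs", "statistic",
    "p_gene", "n_null_samples", "seed",
]


def scan_pairs(
    pairs: Sequence[Tuple[str, str]],
    geno: GenotypeMatrix,
    phenotype: PhenotypeVector,
    covars: Optional[CovariateTable],
    genes: Sequence[GeneModel],
    methods: Sequence[str] = ("minP", "GATES", "tTS", "tProd"),
    config: Optional[TruncationConfig] = None,
    max_pairs: int = 500,
    seed: int = 0,
    out_path: Optional[str] = None,
    alpha: float = 0.05,
    n_traits: int = 1,
    ld_reference: Optional[Tuple[pd.DataFrame, pd.Series]] = None,
) -> pd.DataFrame:
    """Run the requested gene-level tests over a list of gene pairs.

    Gene pairs whose SNP-pair count exceeds ``max_pairs`` are split into
    contiguous chunks, each reported (and counted for multiple testing) as
    its own test. Rows are appended to ``out_path`` incrementally; a rerun
    with the same output file resumes after the last written chunk.

    With ``ld_reference`` (from :func:`read_ld_reference`) Sigma comes from
    reference-panel LD through the product-correlation polynomial instead
    of the individual-level genotypes.
    """
    if config is None:
        config = TruncationConfig()
    gene_snps = map_snps_to_genes(geno, genes)
    done = set()
    writer = None
    if out_path is not None and os.path.exists(out_path) and os.path.getsize(out_path):
        prev = pd.read_csv(out_path, sep="\t")
        done = set(zip(prev.gene1, prev.gene2, prev.chunk.astype(str), prev.method))
    rows: List[dict] = []
    if out_path is not None:
        writer = open(out_path, "a")
        if not done:
            writer.write("\t".join(_SCAN_COLS) + "\n")
    n_chunk_tests = 0
    try:
        for g1name, g2name in pairs:
            if g1name not in gene_snps or g2name not in gene_snps:
                logger.warning(
                    "skipping pair (%s, %s): a gene has no mapped SNPs",
                    g1name, g2name,
                )
                continue
            sub1 = geno.select(gene_snps[g1name])
            sub2 = geno.select(gene_snps[g2name])
            chunks = chunk_pairs(sub1.n_snps, sub2.n_snps, max_pairs)
            for c_idx, (r1, r2) in enumerate(chunks):
                n_chunk_tests += 1
                chunk_id = f"{c_idx + 1}/{len(chunks)}"
                c1 = sub1.select(list(r1))
                c2 = sub2.select(list(r2))
                p = pairwise_pvalues(phenotype, c1, c2, covars)
                # extreme t statistics can underflow t.sf to exactly 0
                p = np.where(np.isfinite(p), np.clip(p, 1e-300, 1.0), p)
                if ld_reference is None:
                    sigma = corr_tests_from_genotypes(c1, c2, covars)
                else:
                    sigma = _external_sigma_for_chunk(c1, c2, ld_reference)
                okmask = np.isfinite(p)
                if not okmask.all():
                    keep = np.flatnonzero(okmask)
                    logger.warning(
                        "pair (%s, %s) chunk %s: %d singular SNP pairs skipped",
                        g1name, g2name, chunk_id, int((~okmask).sum()),
                    )
                    p = p[keep]
                    sigma = sigma.submatrix(keep)
                for method in methods:
                    key = (g1name, g2name, chunk_id, method)
                    if key in done:
                        continue
                    res = _run_method(
                        method, p, sigma, phenotype, c1, c2, covars,
                        config, seed, g1name, g2name, chunk_id,
                    )
                    row = res.as_row()
                    rows.append(row)
                    if writer is not None:
                        writer.write("\t".join(str(row[c]) for c in _SCAN_COLS) + "\n")
                        writer.flush()
    finally:
        if writer is not None:
            writer.close()
    threshold = bonferroni_threshold(alpha, max(n_chunk_tests, 1), n_traits)
    logger.info(
        "scan complete: %d chunk-level tests, trait %s, Bonferroni threshold %.3g",
        n_chunk_tests, phenotype.trait_name, threshold,
    )
    df = pd.DataFrame(rows, columns=_SCAN_COLS)
    df.attrs["bonferroni_threshold"] = threshold
    df.attrs["n_chunk_tests"] = n_chunk_tests
    df.attrs["trait"] = phenotype.trait_name
    return df


def _external_sigma_for_chunk(c1, c2, ld_reference):
    from .correlation import sigma_from_external_ld

    ld, freq = ld_reference
    for geno in (c1, c2):
        missing = [s for s in geno.snp_ids if s not in ld.index or s not in freq.index]
        if missing:
            raise ValueError(f"SNPs absent from the LD reference: {missing[:5]}")
    ld1 = ld.loc[c1.snp_ids, c1.snp_ids].to_numpy()
    ld2 = ld.loc[c2.snp_ids, c2.snp_ids].to_numpy()
    return sigma_from_external_ld(
        ld1, ld2, freq.loc[c1.snp_ids].to_numpy(), freq.loc[c2.snp_ids].to_numpy()
    )


def _run_method(
    method, p, sigma, phenotype, c1, c2, covars, config, seed, g1, g2, chunk_id
) -> GenePairResult:
    if method == "minP":
        return gg_minp(p, sigma, gene1=g1, gene2=g2, chunk_id=chunk_id, seed=seed)
    if method == "GATES":
        return gg_gates(p, sigma, gene1=g1, gene2=g2, chunk_id=chunk_id)
    if method == "tTS":
        return gg_tts(p, sigma, config, gene1=g1, gene2=g2, chunk_id=chunk_id, seed=seed)
    if method == "tProd":
        return gg_tprod(p, sigma, config, gene1=g1, gene2=g2, chunk_id=chunk_id, seed=seed)
    if method == "PC":
        res = gg_pc_test(phenotype, c1, c2, covars, gene1=g1, gene2=g2)
        res.chunk_id = chunk_id
        return res
    raise ValueError(f"unknown method: {method}")
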