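"""Readers and writers for genotype, phenotype, residual and result files.

Genotype TSV dialect: tab-separated, first column ``id``, remaining
columns site IDs, integer minor-allele counts.  Phenotype TSV: columns
``id, y1, y2`` plus optional ``cov_*`` covariates.  Genotype and
phenotype files are joined explicitly on ``id``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .rvtests import TestResult
from .simgen import GenotypeMatrix, VariantSite

__all__ = [
    "read_genotypes_vcf",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "write_residuals",
    "write_results",
    "align_ids",
    "load_config",
]


def read_genotypes_vcf(path: str, region: str | None = None) -> tuple[GenotypeMatrix, list[str]]:
    """Read biallelic GT records into a minor-allele-count matrix.

    Sites are oriented so the counted allele has frequency <= 0.5.
    Multiallelic records and missing genotypes are errors (no imputation).
    Returns the matrix and the sample IDs.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(path)
    samples = list(vcf.samples)
    columns, sites = [], []
    iterator = vcf(region) if region else vcf
    for variant in iterator:
        if len(variant.ALT) != 1:
            raise ValueError(f"multiallelic record at {variant.CHROM}:{variant.POS}")
        alleles = np.array([gt[:2] for gt in variant.genotypes], dtype=int)
        if (alleles < 0).any():
            raise ValueError(f"missing genotype at {variant.CHROM}:{variant.POS}")
        counts = alleles.sum(axis=1)
        af = counts.mean() / 2.0
        if af > 0.5:
            counts = 2 - counts
            af = 1.0 - af
        sid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        columns.append(counts)
        sites.append(VariantSite(site_id=sid, maf=max(af, 1e-12) if af <= 0.5 else 0.5))
    if not columns:
        raise ValueError(f"no variant records read from {path}")
    return GenotypeMatrix(np.column_stack(columns).astype(np.int8), sites), samples


def write_genotypes_tsv(G: GenotypeMatrix, path: str, ids=None, seed: int | None = None) -> None:
    ids = ids if ids is not None else [f"ind{i}" for i in range(G.n_individuals)]
    df = pd.DataFrame(G.counts, columns=[s.site_id for s in G.sites])
    df.insert(0, "id", ids)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_genotypes_tsv(path: str) -> tuple[GenotypeMatrix, list[str]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "id" not in df.columns:
        raise ValueError("genotype TSV must have an 'id' first column")
    ids = df["id"].astype(str).tolist()
    counts = df.drop(columns="id").to_numpy(dtype=np.int8)
    mafs = np.clip(counts.mean(axis=0) / 2.0, 1e-12, 0.5)
    sites = [VariantSite(site_id=c, maf=m) for c, m in zip(df.columns[1:], mafs)]
    return GenotypeMatrix(counts, sites), ids


def write_genotypes_vcf(G: GenotypeMatrix, path: str, ids=None) -> None:
    """Minimal biallelic GT-only VCF with synthetic coordinates."""
    ids = ids if ids is not None else [f"ind{i}" for i in range(G.n_individuals)]
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        for j, site in enumerate(G.sites):
            gts = "\t".join(gt_strings[int(c)] for c in G.counts[:, j])
            fh.write(f"1\t{j + 1}\t{site.site_id}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


def write_phenotypes(ph, path: str, ids=None, seed: int | None = None) -> None:
    n = ph.y1.size
    ids = ids if ids is not None else [f"ind{i}" for i in range(n)]
    df = pd.DataFrame({"id": ids, "y1": ph.y1, "y2": ph.y2})
    if ph.covariates is not None:
        C = np.atleast_2d(np.asarray(ph.covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        for k in range(C.shape[1]):
            df[f"cov_{k}"] = C[:, k]
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_phenotypes(path: str):
    """Read a phenotype table; returns (CohortPhenotypes, ids)."""
    from .simtrait import CohortPhenotypes

    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("id", "y1", "y2"):
        if col not in df.columns:
            raise ValueError(f"phenotype file is missing required column '{col}'")
    if df[["y1", "y2"]].isna().any().any():
        raise ValueError("phenotype file contains missing trait values")
    cov_cols = [c for c in df.columns if c.startswith("cov_")]
    cov = df[cov_cols].to_numpy(dtype=float) if cov_cols else None
    return CohortPhenotypes(df["y1"].to_numpy(), df["y2"].to_numpy(), cov), df["id"].astype(str).tolist()


def align_ids(genotype_ids: list[str], phenotype_ids: list[str]) -> np.ndarray:
    """Positions of genotype IDs in the phenotype table (explicit join on id)."""
    pos = {pid: i for i, pid in enumerate(phenotype_ids)}
    missing = [g for g in genotype_ids if g not in pos]
    if missing:
        raise ValueError(
            f"ID mismatch: {len(missing)} of {len(genotype_ids)} genotype IDs "
            f"absent from the phenotype file (e.g. {missing[:3]})"
        )
    return np.array([pos[g] for g in genotype_ids])


def write_residuals(residuals, path: str, ids=None, seed: int | None = None) -> None:
    n = residuals.e.size
    ids = ids if ids is not None else [f"ind{i}" for i in range(n)]
    df = pd.DataFrame({"id": ids, "residual": residuals.e})
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def write_results(results: dict[str, TestResult] | list[TestResult], path: str,
                  region: str = "region1", seed: int | None = None) -> None:
    rows = []
    values = results.values() if isinstance(results, dict) else results
    for r in values:
        rows.append({
            "region": region, "test": r.test, "statistic": r.statistic,
            "p_empirical": r.p_empirical,
            "p_analytic": "" if r.p_analytic is None else r.p_analytic,
            "n_perm": r.n_perm,
            "vt_threshold": "" if r.vt_threshold is None else r.vt_threshold,
        })
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, float_format="%.12g")


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration file must define a mapping")
    return cfg
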