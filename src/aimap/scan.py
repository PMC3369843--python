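"""Empirical genome scan: genotype I/O and per-SNP application of the tests.

Genotypes come from VCF (phase read from the standard phased separator), a
HapMap-style genotype TSV (unphased), or a simple phased haplotype-matrix
TSV.  The scan joins them with an AI-status table and runs the requested
tests at every SNP passing the minor-allele-frequency filter; SNPs that
cannot be tested are reported with reason codes rather than dropped silently.
Positions are 1-based in files, 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ai_status import AIStatusVector
from .stats import (binomial_haplotype_test, contingency_genotype_test,
                    linear_regression_test)

__all__ = [
    "SNPRecord",
    "GenotypeDataset",
    "read_genotypes",
    "write_haplotype_matrix",
    "genome_scan",
]

MISSING = -1

# HapMap genotype files carry 11 metadata columns before the individuals
_HAPMAP_META = 11


@dataclass
class SNPRecord:
    """One SNP: ordered allele pair per individual; -1 marks a missing allele.

    ``alleles[:, 0]`` is chromosome 1, ``alleles[:, 1]`` chromosome 2; the
    order is meaningful only when ``phased`` is True.  Allele coding is 0 =
    reference/`A`, 1 = alternate/`a`.
    """

    chrom: str
    pos: int
    snp_id: str
    ref: str
    alt: str
    alleles: np.ndarray
    phased: bool

    def genotypes(self) -> np.ndarray:
        """Unordered 0/1/2 alternate-allele counts; -1 where missing."""
        a = self.alleles
        g = a.sum(axis=1)
        g[(a < 0).any(axis=1)] = MISSING
        return g

    def maf(self) -> float:
        a = self.alleles[self.alleles >= 0]
        if a.size == 0:
            return float("nan")
        f = a.mean()
        return float(min(f, 1.0 - f))


@dataclass
class GenotypeDataset:
    individuals: list[str]
    records: list[SNPRecord]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


def _read_vcf(path) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    records = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue  # bi-allelic SNPs only
        alleles = np.empty((len(individuals), 2), dtype=np.int8)
        phased = True
        for i, gt in enumerate(v.genotypes):
            a0, a1 = gt[0], gt[1]
            alleles[i, 0] = a0 if a0 >= 0 else MISSING
            alleles[i, 1] = a1 if a1 >= 0 else MISSING
            if not gt[2]:
                phased = False
        records.append(SNPRecord(
            chrom=str(v.CHROM), pos=int(v.POS), snp_id=v.ID or ".",
            ref=v.REF, alt=v.ALT[0], alleles=alleles, phased=phased,
        ))
    return GenotypeDataset(individuals, records)


def _read_haplotype_matrix(path) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta = ["chrom", "pos", "id", "ref", "alt"]
    hap_cols = [c for c in df.columns if c not in meta]
    individuals = []
    for c in hap_cols[::2]:
        if not c.endswith("_1"):
            raise ValueError(f"unexpected haplotype column {c!r}")
        individuals.append(c[:-2])
    records = []
    hap_idx = [df.columns.get_loc(c) for c in hap_cols]
    for row in df.itertuples(index=False):
        # positional access keeps arbitrary individual names safe
        vals = [row[i] for i in hap_idx]
        alleles = np.array(
            [MISSING if v in (".", "NA", None) else int(v) for v in vals],
            dtype=np.int8,
        ).reshape(-1, 2)
        records.append(SNPRecord(
            chrom=str(row.chrom), pos=int(row.pos), snp_id=str(row.id),
            ref=str(row.ref), alt=str(row.alt), alleles=alleles, phased=True,
        ))
    return GenotypeDataset(individuals, records)


def write_haplotype_matrix(dataset: GenotypeDataset, path) -> None:
    """Write a phased dataset as a haplotype-matrix TSV (round-trips)."""
    cols: dict[str, list] = {k: [] for k in ("chrom", "pos", "id", "ref", "alt")}
    hap: dict[str, list] = {}
    for ind in dataset.individuals:
        hap[f"{ind}_1"] = []
        hap[f"{ind}_2"] = []
    for rec in dataset.records:
        cols["chrom"].append(rec.chrom)
        cols["pos"].append(rec.pos)
        cols["id"].append(rec.snp_id)
        cols["ref"].append(rec.ref)
        cols["alt"].append(rec.alt)
        for i, ind in enumerate(dataset.individuals):
            for j in (0, 1):
                v = rec.alleles[i, j]
                hap[f"{ind}_{j + 1}"].append("." if v < 0 else int(v))
    pd.DataFrame({**cols, **hap}).to_csv(path, sep="\t", index=False)


def _read_hapmap(path) -> GenotypeDataset:
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    individuals = list(df.columns[_HAPMAP_META:])
    records = []
    for row in df.itertuples(index=False):
        ref, alt = str(row[1]).split("/")
        alleles = np.empty((len(individuals), 2), dtype=np.int8)
        for i, gt in enumerate(row[_HAPMAP_META:]):
            gt = str(gt)
            if len(gt) != 2 or "N" in gt:
                alleles[i] = MISSING
                continue
            for j, base in enumerate(gt):
                if base == ref:
                    alleles[i, j] = 0
                elif base == alt:
                    alleles[i, j] = 1
                else:
                    alleles[i] = MISSING
                    break
        records.append(SNPRecord(
            chrom=str(row[2]), pos=int(row[3]), snp_id=str(row[0]),
            ref=ref, alt=alt, alleles=alleles, phased=False,
        ))
    return GenotypeDataset(individuals, records)


def read_genotypes(path, format: str = "vcf") -> GenotypeDataset:
    """Read genotypes from ``vcf``, ``hapmap_tsv`` or ``haplotype_matrix``."""
    readers = {
        "vcf": _read_vcf,
        "hapmap_tsv": _read_hapmap,
        "haplotype_matrix": _read_haplotype_matrix,
    }
    if format not in readers:
        raise ValueError(f"unrecognised format {format!r}")
    return readers[format](path)


def _check_ids(dataset: GenotypeDataset, ai: AIStatusVector) -> None:
    if ai.n_individuals != dataset.n_individuals:
        raise ValueError(
            f"AI table has {ai.n_individuals} individuals, dataset has "
            f"{dataset.n_individuals}")
    if ai.ids is not None:
        mismatched = [
            (a, b) for a, b in zip(ai.ids, dataset.individuals) if a != b
        ]
        if mismatched:
            raise ValueError(f"individual-ID mismatch: {mismatched}")


def genome_scan(dataset: GenotypeDataset, ai: AIStatusVector,
                maf_min: float = 0.05,
                tests=("contingency", "binomial", "regression"),
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the requested tests at every SNP; returns (results, excluded).

    Results are sorted by (chrom, pos) and carry raw p-values plus
    log10(1/p) columns; no genome-wide multiple-testing correction is
    applied.  SNPs that cannot be tested are returned in the second frame
    with a reason code (``monomorphic``, ``maf_below_threshold``,
    ``degenerate``); haplotype tests on unphased records are reported as
    not computable (p = NA, status code) rather than silently skipped.
    """
    _check_ids(dataset, ai)
    if ai.n_ai == 0 or ai.n_ai == ai.n_individuals:
        raise ValueError("need at least one AI and one non-AI individual")
    results = []
    excluded = []
    for rec in dataset.records:
        maf = rec.maf()
        base = {"chrom": rec.chrom, "pos": rec.pos, "id": rec.snp_id,
                "maf": maf}
        if not np.isfinite(maf) or maf == 0.0:
            excluded.append({**base, "reason": "monomorphic"})
            continue
        if maf < maf_min:
            excluded.append({**base, "reason": "maf_below_threshold"})
            continue
        g = rec.genotypes()
        called = g >= 0
        if len(np.unique(g[called])) < 2 or not (ai.ai[called].any()
                                                 and (~ai.ai[called]).any()):
            excluded.append({**base, "reason": "degenerate"})
            continue
        row = dict(base, n_used=int(called.sum()))
        if "contingency" in tests:
            res = contingency_genotype_test(g, ai.ai)
            row["p_contingency"] = res.p_value
        haplotype_ok = rec.phased and (ai.direction[ai.ai] != 0).all()
        if "binomial" in tests:
            if haplotype_ok:
                mask = ai.ai & (rec.alleles >= 0).all(axis=1)
                res = binomial_haplotype_test(
                    rec.alleles[mask, 0], rec.alleles[mask, 1],
                    ai.direction[mask])
                row["p_binomial"] = res.p_value
                row["n_ai_used"] = res.n_used
            else:
                row["p_binomial"] = np.nan
                row["status_binomial"] = "not_computable_unphased"
        if "regression" in tests:
            if haplotype_ok:
                mask = (rec.alleles >= 0).all(axis=1)
                sub = AIStatusVector(ai.ai[mask], ai.direction[mask])
                res = linear_regression_test(
                    rec.alleles[mask, 0], rec.alleles[mask, 1], sub)
                row["p_regression"] = res.p_value
            else:
                row["p_regression"] = np.nan
                row["status_regression"] = "not_computable_unphased"
        for test in ("contingency", "binomial", "regression"):
            p = row.get(f"p_{test}")
            if p is not None and np.isfinite(p):
                row[f"log10_inv_p_{test}"] = -np.log10(p)
        results.append(row)
    res_df = pd.DataFrame(results)
    if not res_df.empty:
        res_df = res_df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return res_df, pd.DataFrame(excluded)
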