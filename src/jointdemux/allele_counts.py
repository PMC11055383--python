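"""Sparse per-cell allele counts in the cellSNP-lite layout.

Single-cell pileup tools emit, per candidate SNP and cell barcode, the
total read depth (DP) and the alternative-allele depth (AD) as two sparse
variants-by-cells matrices, alongside the variant list (VCF) and the cell
barcode list (TSV).  This module holds that triple and reads/writes the
on-disk layout (MatrixMarket + VCF/TSV).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


@dataclass(frozen=True, order=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class AlleleCountSet:
    """AD/DP sparse count matrices (variants x cells) plus row/column metadata."""

    variants: list[VariantRecord]
    barcodes: list[str]
    AD: sp.csr_matrix
    DP: sp.csr_matrix

    def __post_init__(self) -> None:
        self.AD = sp.csr_matrix(self.AD)
        self.DP = sp.csr_matrix(self.DP)
        shape = (len(self.variants), len(self.barcodes))
        if self.AD.shape != shape or self.DP.shape != shape:
            raise ValueError("AD/DP shapes do not match variant/barcode lists")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variant records")
        diff = (self.AD - self.DP).tocoo()
        if diff.nnz and diff.data.max() > 0:
            raise ValueError("AD exceeds DP at some entries")
        if self.AD.nnz and self.AD.data.min() < 0:
            raise ValueError("negative AD counts")
        if self.DP.nnz and self.DP.data.min() < 0:
            raise ValueError("negative DP counts")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.variants), len(self.barcodes))

    def barcode_index(self) -> dict[str, int]:
        return {bc: j for j, bc in enumerate(self.barcodes)}

    def subset_variants(self, keep: list[int]) -> "AlleleCountSet":
        return AlleleCountSet(
            [self.variants[i] for i in keep],
            list(self.barcodes),
            self.AD[keep, :],
            self.DP[keep, :],
        )


# ---------------------------------------------------------------------------
# Variant list I/O

def contig_header_lines(variants: list[VariantRecord]) -> str:
    """One ##contig line per chromosome, in order of first appearance."""
    seen: dict[str, None] = {}
    for v in variants:
        seen.setdefault(v.chrom)
    return "".join(f"##contig=<ID={c}>\n" for c in seen)


def write_variants_vcf(variants: list[VariantRecord], path: str | Path) -> None:
    """Minimal site-only VCF v4.2 (the cellSNP base VCF dialect)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(contig_header_lines(variants))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\n")


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alts = rec.alts or (".",)
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref or ".",
                    alt=alts[0],
                    id=rec.id,
                )
            )
    return out


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Fallback variant list: TSV with CHROM, POS, REF, ALT columns."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str, "POS": int, "REF": str, "ALT": str})
    for col in ("CHROM", "POS", "REF", "ALT"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return [
        VariantRecord(r.CHROM, int(r.POS), r.REF, r.ALT) for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Directory-level read/write (cellSNP-lite file names)

AD_MTX = "cellSNP.tag.AD.mtx"
DP_MTX = "cellSNP.tag.DP.mtx"
BASE_VCF = "cellSNP.base.vcf"
SAMPLES_TSV = "cellSNP.samples.tsv"


def write_allele_counts(acs: AlleleCountSet, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / AD_MTX), acs.AD.tocoo(), field="integer")
    scipy.io.mmwrite(str(outdir / DP_MTX), acs.DP.tocoo(), field="integer")
    write_variants_vcf(acs.variants, outdir / BASE_VCF)
    with open(outdir / SAMPLES_TSV, "w") as fh:
        for bc in acs.barcodes:
            fh.write(bc + "\n")


def read_allele_counts(indir: str | Path) -> AlleleCountSet:
    indir = Path(indir)
    AD = sp.csr_matrix(scipy.io.mmread(str(indir / AD_MTX)))
    DP = sp.csr_matrix(scipy.io.mmread(str(indir / DP_MTX)))
    vcf = indir / BASE_VCF
    if vcf.exists():
        variants = read_variants_vcf(vcf)
    else:
        variants = read_variants_tsv(indir / (BASE_VCF + ".tsv"))
    barcodes = [
        line.strip() for line in open(indir / SAMPLES_TSV) if line.strip()
    ]
    return AlleleCountSet(variants, barcodes, AD.astype(np.int64), DP.astype(np.int64))
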