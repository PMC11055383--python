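"""Minimal donor-genotype reconstruction from pooled single-cell variants.

After the joint assignment, every donor has a group of cells it can trust
(*consistent*: hashing and genetics agreed) and a group it propagated its
identity to (*inconsistent*: rescued negatives and overridden conflicts).
Pooling reads per donor across the consistent cells, a variant is called
for a donor when one allele is strongly overrepresented: aggregated read
depth strictly above ``depth_threshold`` (default 10) and the REF or ALT
read frequency strictly above ``freq_threshold`` (default 0.90).  A call is
kept only if the inconsistent group — where it has enough coverage to
speak — shows the same overrepresented allele.  Calls that no other donor
shares are the *donor-specific variants*: a minimal genotype that
distinguishes each donor in the pool, serialized as homozygous diploid VCF
genotypes with samples renamed to the matched hashtags.

A pooled-read frequency above 90% is only compatible with homozygosity,
hence the 0/0 / 1/1 calls; heterozygous sites never pass the filter and
are deliberately absent from the reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .allele_counts import AlleleCountSet, VariantRecord
from .matching import DonorMatchResult
from .rescue import CONFIRMED, CONFLICT, RESCUED, SINGLET, JointAssignment

logger = logging.getLogger(__name__)

REF = "REF"
ALT = "ALT"


@dataclass
class RefinementConfig:
    """Thresholds for the overrepresented-allele filters (all strict >)."""

    depth_threshold: int = 10
    freq_threshold: float = 0.90
    require_inconsistent_support: bool = True
    inconsistent_depth_threshold: int = 10
    keep_uncovered_inconsistent: bool = True  # keep on consistent-group evidence alone
    specific_mode: str = "unique_call"  # or "exclusive"

    def __post_init__(self) -> None:
        if not (0.5 < self.freq_threshold < 1):
            raise ValueError("freq_threshold must be in (0.5, 1)")
        if self.depth_threshold < 1:
            raise ValueError("depth_threshold must be >= 1")
        if self.specific_mode not in ("unique_call", "exclusive"):
            raise ValueError("specific_mode must be 'unique_call' or 'exclusive'")


@dataclass
class DonorGenotypeSet:
    """Per-donor overrepresented-allele calls at retained variants."""

    donors: list[str]
    calls: dict[str, dict[VariantRecord, str]]  # donor -> variant -> REF|ALT
    provenance: dict[str, dict[str, int]] = field(default_factory=dict)

    def variant_union(self) -> list[VariantRecord]:
        seen: set[VariantRecord] = set()
        for c in self.calls.values():
            seen.update(c)
        return sorted(seen, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"Donor": d, "NumVariants": len(self.calls.get(d, {}))} for d in self.donors],
            columns=["Donor", "NumVariants"],
        )


def partition_cells(joint: JointAssignment, donor: str) -> tuple[set[str], set[str]]:
    """Split one donor's cells into consistent vs inconsistent groups.

    Consistent = confirmed provenance; inconsistent = rescued or conflict.
    Doublets and negatives belong to neither.  Raises if the label has no
    singlets in the joint assignment.
    """
    consistent, inconsistent = set(), set()
    for bc, (lab, prov) in joint.entries.items():
        if lab.kind != SINGLET or lab.name != donor:
            continue
        if prov == CONFIRMED:
            consistent.add(bc)
        elif prov in (RESCUED, CONFLICT):
            inconsistent.add(bc)
    if not consistent and not inconsistent:
        raise ValueError(f"donor {donor!r} has no singlet cells in the joint assignment")
    return consistent, inconsistent


def aggregate_counts(
    counts: AlleleCountSet, cells: set[str] | list[str]
) -> pd.DataFrame:
    """Sum AD and DP over a cell group, per variant.

    Returns a frame indexed by variant row position with columns
    ``sumAD, sumDP``, restricted to variants with non-zero pooled depth.
    """
    idx = counts.barcode_index()
    unknown = [bc for bc in cells if bc not in idx]
    if unknown:
        raise ValueError(f"unknown barcode(s): {unknown[:3]}")
    cols = sorted(idx[bc] for bc in set(cells))
    if not cols:
        return pd.DataFrame(columns=["sumAD", "sumDP"], dtype=np.int64)
    sum_ad = np.asarray(counts.AD[:, cols].sum(axis=1)).ravel()
    sum_dp = np.asarray(counts.DP[:, cols].sum(axis=1)).ravel()
    keep = sum_dp > 0
    return pd.DataFrame(
        {"sumAD": sum_ad[keep].astype(np.int64), "sumDP": sum_dp[keep].astype(np.int64)},
        index=np.flatnonzero(keep),
    )


def overrepresented_allele(
    sum_ad: int, sum_dp: int, cfg: RefinementConfig | None = None
) -> str | None:
    """Call the overrepresented allele for one pooled (AD, DP) pair.

    None when pooled depth <= depth_threshold or neither allele frequency
    exceeds freq_threshold.
    """
    cfg = cfg or RefinementConfig()
    if sum_ad > sum_dp:
        raise ValueError(f"AD ({sum_ad}) exceeds DP ({sum_dp})")
    if sum_dp <= cfg.depth_threshold:
        return None
    if sum_ad / sum_dp > cfg.freq_threshold:
        return ALT
    if (sum_dp - sum_ad) / sum_dp > cfg.freq_threshold:
        return REF
    return None


def _calls_for_group(
    agg: pd.DataFrame, cfg: RefinementConfig
) -> dict[int, str]:
    """Overrepresented-allele calls per variant row index, vectorized."""
    if agg.empty:
        return {}
    dp = agg["sumDP"].to_numpy()
    ad = agg["sumAD"].to_numpy()
    deep = dp > cfg.depth_threshold
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_f = np.where(dp > 0, ad / dp, 0.0)
    is_alt = deep & (alt_f > cfg.freq_threshold)
    is_ref = deep & ((1.0 - alt_f) > cfg.freq_threshold)
    out: dict[int, str] = {}
    for row, a, r in zip(agg.index, is_alt, is_ref):
        if a:
            out[int(row)] = ALT
        elif r:
            out[int(row)] = REF
    return out


def informative_variants(
    counts: AlleleCountSet,
    joint: JointAssignment,
    donor: str,
    cfg: RefinementConfig | None = None,
) -> dict[VariantRecord, str]:
    """Variants with a concordant overrepresented allele for one donor.

    The call is made on the consistent group; when the inconsistent group
    has pooled depth above ``inconsistent_depth_threshold`` at the variant,
    its own overrepresented allele must agree or the variant is dropped.
    Variants the inconsistent group cannot speak on (insufficient depth)
    are kept on consistent-group evidence alone (configurable).
    """
    cfg = cfg or RefinementConfig()
    consistent, inconsistent = partition_cells(joint, donor)
    if not consistent:
        raise ValueError(f"donor {donor!r} has no consistently assigned cells")
    cons_agg = aggregate_counts(counts, consistent)
    cons_calls = _calls_for_group(cons_agg, cfg)
    if not cons_calls:
        return {}
    result: dict[VariantRecord, str] = {}
    if cfg.require_inconsistent_support and inconsistent:
        inc_agg = aggregate_counts(counts, inconsistent)
        inc_dp = inc_agg["sumDP"].to_dict()
        inc_cfg = RefinementConfig(
            depth_threshold=cfg.inconsistent_depth_threshold,
            freq_threshold=cfg.freq_threshold,
            require_inconsistent_support=False,
        )
        inc_calls = _calls_for_group(inc_agg, inc_cfg)
        for row, allele in cons_calls.items():
            covered = inc_dp.get(row, 0) > cfg.inconsistent_depth_threshold
            if covered:
                if inc_calls.get(row) == allele:
                    result[counts.variants[row]] = allele
            elif cfg.keep_uncovered_inconsistent:
                result[counts.variants[row]] = allele
    else:
        result = {counts.variants[row]: allele for row, allele in cons_calls.items()}
    return result


def donor_specific_variants(
    per_donor_calls: dict[str, dict[VariantRecord, str]],
    mode: str = "unique_call",
) -> dict[str, dict[VariantRecord, str]]:
    """Keep, per donor, the calls that set it apart from every other donor.

    ``unique_call`` (default): a (variant, allele) call survives for donor
    d iff no other donor carries the identical call — two donors calling
    different alleles at the same variant both keep theirs.  ``exclusive``:
    the variant must have passed the filters in exactly one donor.
    """
    if len(per_donor_calls) < 2:
        raise ValueError("need at least 2 profiled donors")
    if mode == "unique_call":
        tally: dict[tuple[VariantRecord, str], int] = {}
        for calls in per_donor_calls.values():
            for v, a in calls.items():
                tally[(v, a)] = tally.get((v, a), 0) + 1
        out = {
            d: {v: a for v, a in calls.items() if tally[(v, a)] == 1}
            for d, calls in per_donor_calls.items()
        }
    elif mode == "exclusive":
        seen: dict[VariantRecord, int] = {}
        for calls in per_donor_calls.values():
            for v in calls:
                seen[v] = seen.get(v, 0) + 1
        out = {
            d: {v: a for v, a in calls.items() if seen[v] == 1}
            for d, calls in per_donor_calls.items()
        }
    else:
        raise ValueError("mode must be 'unique_call' or 'exclusive'")
    for d, calls in out.items():
        logger.info("donor_specific_variants: %s -> %d variants", d, len(calls))
    return out


def reconstruct_genotypes(
    counts: AlleleCountSet,
    joint: JointAssignment,
    cfg: RefinementConfig | None = None,
    donors: list[str] | None = None,
) -> DonorGenotypeSet:
    """End-to-end reconstruction: informative then donor-specific variants."""
    cfg = cfg or RefinementConfig()
    if donors is None:
        donors = sorted(
            {
                lab.name
                for lab, prov in joint.entries.values()
                if lab.kind == SINGLET and prov in (CONFIRMED, RESCUED, CONFLICT)
            }
        )
    per_donor = {d: informative_variants(counts, joint, d, cfg) for d in donors}
    specific = donor_specific_variants(per_donor, mode=cfg.specific_mode)
    provenance = {
        d: {
            "variants_total": len(counts.variants),
            "informative": len(per_donor[d]),
            "donor_specific": len(specific[d]),
        }
        for d in donors
    }
    return DonorGenotypeSet(donors=list(donors), calls=specific, provenance=provenance)


# ---------------------------------------------------------------------------
# VCF serialization of the reconstructed genotypes

def write_donor_vcf(
    genotypes: DonorGenotypeSet,
    path: str | Path,
    match: DonorMatchResult | dict[str, str] | None = None,
) -> None:
    """Write reconstructed genotypes as a GT-only VCF v4.2.

    One sample column per donor.  REF calls become 0/0, ALT calls 1/1, and
    ``./.`` marks variants in the union where a donor has no call.  When a
    match (or a plain donor -> hashtag dict) is given, sample columns are
    renamed accordingly; donors without a match keep their name (logged).
    Records are sorted by (chrom, pos).
    """
    if match is None:
        rename: dict[str, str] = {}
    elif isinstance(match, dict):
        rename = dict(match)
    else:
        rename = match.donor_to_hashtag()
    samples = []
    for d in genotypes.donors:
        if rename and d not in rename:
            logger.warning("write_donor_vcf: donor %s has no matched hashtag; name kept", d)
        samples.append(rename.get(d, d))
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicate sample names after renaming: {samples}")
    from .allele_counts import contig_header_lines

    union = genotypes.variant_union()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(contig_header_lines(union))
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype '
            "(homozygous calls only: a pooled-read frequency above the "
            'overrepresentation cutoff is inconsistent with heterozygosity)">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for v in union:
            gts = []
            for d in genotypes.donors:
                call = genotypes.calls.get(d, {}).get(v)
                gts.append({REF: "0/0", ALT: "1/1"}.get(call, "./."))
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_donor_vcf(path: str | Path) -> DonorGenotypeSet:
    """Read back a GT-only donor VCF into a :class:`DonorGenotypeSet`."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        donors = list(vf.header.samples)
        calls: dict[str, dict[VariantRecord, str]] = {d: {} for d in donors}
        for rec in vf:
            v = VariantRecord(rec.chrom, rec.pos, rec.ref or ".", (rec.alts or (".",))[0], rec.id)
            for d in donors:
                gt = rec.samples[d].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                if all(a == 0 for a in gt):
                    calls[d][v] = REF
                elif all(a == 1 for a in gt):
                    calls[d][v] = ALT
    return DonorGenotypeSet(donors=donors, calls=calls)
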