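# jointdemux

Joint deconvolution of multiplexed single-cell experiments that combine
**cell hashing** (HTO barcodes per sample) with **genotype-based
demultiplexing** (natural genetic variation per donor).

## The problem

In a pooled experiment each droplet gets a three-way verdict from every
demultiplexer: *singlet* (one sample's signal), *doublet*, or *negative*.
Hashing names its singlets by hashtag but fails badly when staining is
noisy — many true cells end up negative.  Genotype-based tools run without
reference genotypes recover singlets reliably, but only as *anonymous*
donor clusters.  `jointdemux` connects the two:

1. **Donor matching (Phi score).**  Each method's verdicts become a
   barcodes × labels 0/1 matrix.  Columns are correlated pairwise with
   Pearson's *r*, which for indicator vectors is exactly the phi
   coefficient of the 2×2 contingency table,

   φ(d, h) = (n₁₁n₀₀ − n₁₀n₀₁) / √(n₁₊ n₀₊ n₊₁ n₊₀).

   Donors and hashtags pair when they are mutual best matches, and a
   method pair is scored by

   Phi score = Σ_matched max(φ, 0) / K,

   with K the expected donor count — 1 only for a complete, perfectly
   concordant match.  Across several candidate method pairs the complete
   match with the highest score wins.
2. **Rescue.**  Hashing negatives that genetics confidently calls as a
   matched donor's singlet receive that donor's hashtag (provenance
   `rescued`); genetic negatives are never rescued, disagreements are
   flagged as `conflict`.
3. **Genotype refinement.**  Per donor, reads are pooled over cells both
   methods agree on; a variant is called when pooled depth > 10 and one
   allele exceeds 90% frequency, the rescued/conflict cells must show the
   same overrepresented allele, and calls shared with another donor are
   discarded.  The surviving *donor-specific variants* form a minimal
   homozygous genotype per donor, written as a GT-only VCF with samples
   named by hashtag.
4. **Verification re-demultiplexing.**  A transparent binomial-likelihood
   assigner demultiplexes every cell against the reconstructed genotypes
   (AD ~ Binomial(DP, ε) at REF calls, Binomial(DP, 1 − ε) at ALT calls,
   doublet models average the pair); concordance between refined and
   rescued assignments measures how much identity signal the minimal
   genotypes carry.

A fully parameterized simulator generates complete synthetic experiments
(diploid genotypes with planted donor-private variants, sparse AD/DP
counts, negative-binomial HTO counts with staining failure, noisy method
tables under a hidden donor permutation) so every stage can be validated
against ground truth.

## Worked example

```python
import jointdemux as jd

exp = jd.simulate_experiment(jd.SimConfig(seed=0))   # 6 donors, 5000 cells
m = jd.match_methods(exp.genetic_table, exp.hashing_table, n_expected_donors=6)
for d, h, c in m.pairs:
    print(f"{d} -> {h}  (phi = {c:.3f})")
print(f"Phi score = {m.phi_score:.3f}")

joint = jd.joint_assign(exp.hashing_table, exp.genetic_table, m)
print(jd.rescue_rate(exp.hashing_table, joint))
```

prints

```
donor0 -> Hashtag3  (phi = 0.744)
donor1 -> Hashtag4  (phi = 0.757)
donor2 -> Hashtag2  (phi = 0.763)
donor3 -> Hashtag6  (phi = 0.771)
donor4 -> Hashtag5  (phi = 0.786)
donor5 -> Hashtag1  (phi = 0.765)
Phi score = 0.764
(0.9600532623169108, 0.9486)
```

Every anonymous donor pairs with exactly one hashtag (here recovering the
simulator's hidden permutation); the Phi score of 0.76 reflects 30%
staining failure and 5% hashing label noise.  After rescue, 96% of the
hashing negatives get a donor identity and 94.9% of all cells are
singlets.  Continuing with `jd.reconstruct_genotypes`, `jd.assign_cells`
and `jd.concordance` (see `examples/04–05`) reconstructs 70–85
donor-specific variants per donor and re-demultiplexes the cells against
them with 99.3% agreement on shared singlets.

The `examples/` directory has one short script per capability; the
`jointdemux` console command exposes the same stages as subcommands
(`simulate`, `match`, `rescue`, `refine`, `demux-ref`, `summary`,
`pipeline`), e.g.

```bash
jointdemux pipeline --out-dir run1 --seed 0
```

## File formats

* Assignment tables: CSV `Barcode,Assignment` (strings `doublet`,
  `negative` case-insensitive; everything else a singlet label).
* Allele counts: cellSNP-lite layout — MatrixMarket `AD`/`DP`
  (variants × cells), site-only VCF, barcode TSV.
* Joint assignment: CSV `Barcode,Assignment,Provenance`.
* Reconstructed genotypes: VCF v4.2, GT-only, homozygous calls.

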