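# Methods

## Donor matching by phi correlation

Each demultiplexer's verdicts are binarized into a barcodes × labels
indicator matrix: entry (c, l) = 1 iff barcode c is a singlet of label l.
Doublets and negatives give all-zero rows by default; doublet pairs can
optionally set both component columns (`binarize_doublets`), but this is
off because upstream tools report doublet pairs in incompatible formats,
and the matching signal lives in the singlets.  Two methods are compared
over the **intersection** of their barcode sets (dropped counts are
logged); the union would dilute correlations with rows one method never
saw.

Column-wise Pearson correlation of two indicator matrices is computed via
integer-valued sufficient statistics

r = (n·Σxy − Σx·Σy) / √((n·Σx − (Σx)²)(n·Σy − (Σy)²)),

which for 0/1 data is algebraically the 2×2 contingency-table phi
coefficient and is numerically exact up to the final division: identical
columns correlate to exactly 1.0, which the perfect-concordance tests
rely on.  Columns with zero variance (empty or full indicator) have
undefined correlation; their entries are **defined as 0 and flagged**, so
an empty donor can never win a match.

Donor d and hashtag h pair iff each is the other's argmax (mutual best
match).  Argmax ties resolve to the lexicographically smallest partner
label, then mutuality is re-checked — determinism matters more than the
(measure-zero) tie itself.  The **Phi score** of a method pair is
Σ max(r, 0) over matched pairs divided by the expected donor count K.
Summing over matched pairs only (not all non-negative entries) keeps the
score in [0, 1] with 1 attained exactly at a complete, perfect match.  K
is a required user input, as in any genotype-free genetic workflow.
When several method pairs are available, complete matches
(`all_donors_matched`) beat partial ones regardless of score, then higher
score wins, then the lexicographically smaller method-name pair.

## Rescue

For each barcode shared by the chosen hashing and genetic tables, the
genetic verdict gates everything: genetic negatives stay negative (cells
that cannot be genetically deconvoluted are ineligible for rescue) and
genetic doublets stay doublets.  A genetic singlet of a matched donor
d ↦ h becomes singlet h with provenance `confirmed` (hashing agreed),
`rescued` (hashing negative), or `conflict` (hashing said another hashtag
or doublet).  Conflicts keep the genetic identity because the rescue
premise is that genetics is the trustworthy side when hashing is noisy;
`conflict_policy="drop"` excludes them instead.  How a
hashing-doublet/genetic-singlet cell should be finally labeled is a
genuine open choice; treating it as a flagged conflict keeps the
information without silently promoting it.  Singlets of unmatched donors
are kept under their anonymous name and flagged `unmatched_donor`.

`summarize_flows` tabulates (hashing label → final label, provenance)
counts with percentages normalized per hashing label; `rescue_rate`
reports the fraction of hashing negatives rescued and the overall singlet
fraction (the first is not-applicable when there are no negatives).

## Genotype refinement

Per donor, cells split into a **consistent** group (provenance
`confirmed`) and an **inconsistent** group (`rescued` + `conflict`).
Reads are pooled per variant over the consistent group and an
*overrepresented allele* is called when

* pooled depth sumDP > `depth_threshold` (default 10, strict), and
* sumAD/sumDP > `freq_threshold` (default 0.90, strict) for ALT, or the
  mirrored condition for REF.

Both thresholds are strict inequalities; a pooled frequency above 90% is
incompatible with heterozygosity, which is why reconstructed genotypes
are emitted as homozygous diploid calls (0/0 or 1/1) and why the VCF
header says so.  When the inconsistent group has pooled depth above
`inconsistent_depth_threshold` at the variant, its own overrepresented
allele must agree or the variant is dropped — this is the concordance
check that protects against contamination introduced by rescue.  Variants
the inconsistent group cannot speak on are kept on consistent-group
evidence alone (configurable; the alternative floor is a documented
choice, not an established convention).

**Donor-specific** defaults to the (variant, allele)-call reading: a call
survives for donor d iff no other donor carries the identical call, so
two donors calling different alleles at one variant both keep theirs.
The stricter reading — the variant passes the filters in exactly one
donor — is available as `specific_mode="exclusive"`.  Both readings are
defensible from the per-donor-count figure the workflow is meant to
produce; the default maximizes genotype information per donor.

Filter monotonicity (raising either threshold never adds variants) and
the re-verification of every emitted call from raw counts are asserted by
the test suite.

## Verification re-demultiplexing

The sanity check deliberately avoids re-implementing a full variational
donor-inference tool; with known homozygous genotypes the likelihood is
elementary.  Per cell and donor model, AD ~ Binomial(DP, p) with p = ε at
REF calls and 1 − ε at ALT calls (ε = 0.01 default); doublet models use
the average p of the pair.  The binomial coefficient is omitted: it is
genotype-independent per covered site, so it shifts all models equally
wherever they share sites.

Because donor-specific genotypes give each donor a largely **disjoint**
called-variant set, summing each model only over its own called sites is
not a valid comparison — a doublet model whose pair shares almost no
called sites would win with a near-empty sum.  `assign_cells` therefore
assigns an uninformative ALT-read probability of 0.5 at every site a
donor does not call, putting all K + K(K−1)/2 models on a common site
set; sites uncalled by every donor contribute an identical constant and
cancel from rankings and margins.  The single-genotype primitive
`genotype_loglik` keeps the simpler contract (uncalled/uncovered sites
contribute 0), which is exact for one model in isolation.

A cell is **negative** when it covers fewer than `min_informative_sites`
(default 10) called sites, or when the best model beats the runner-up by
less than `loglik_margin` (default 2 nats ≈ likelihood ratio 7.4).
Ambiguous and low-coverage cells are collapsed into the same `negative`
category to stay within the three-way verdict vocabulary.  The assigner
is fully deterministic.

`concordance` compares two tables over barcodes that are singlets in
both; this intentionally excludes cells the refined pass demotes to
negative (fewer variants ⇒ shallower effective coverage ⇒ more
negatives), mirroring how refinement is evaluated in practice.

## Synthetic experiments

The simulator emulates the statistical structure the pipeline assumes,
not any particular instrument:

* **Genotypes** — M shared variants with per-variant MAF ~ U(0.05, 0.5)
  and per-donor dosage ~ Binomial(2, MAF), plus `n_private_per_donor`
  planted variants per donor that are hom-ALT in the owner and hom-REF
  elsewhere.  Planted privates give refinement a known recoverable
  target.
* **Droplets** — each cell draws a donor uniformly (optional abundance
  weights); with probability δ a second distinct donor (doublet).
* **Allele counts** — each (variant, cell) is covered with probability q;
  covered depth DP ~ 1 + Poisson(λ − 1) (guaranteeing ≥ 1 read);
  AD ~ Binomial(DP, p) with p = (g/2)(1 − ε) + (1 − g/2)ε, averaged over
  the two donors for doublets.
* **HTO counts** — negative binomial (dispersion size 5) with signal mean
  on the cell's own hashtag(s) and background mean elsewhere; with
  probability f the cell is unstained and signal is replaced by
  background.  The NB noise model is a modeling convenience — the
  pipeline stages only need separable stained/failed regimes, and no
  published noise model is being reproduced.
* **Method tables** — the genetic table renames donors through a hidden
  random permutation and corrupts singlets at `genetic_misassign_rate`;
  the hashing table labels unstained cells negative and corrupts stained
  singlets at `hashing_misassign_rate`.  The hidden permutation is
  returned so tests can verify recovery.

Defaults (the study conditions): K = 6 donors, N = 5000 cells, M = 500
shared + 50 private variants per donor, δ = 0.05, f = 0.30, q = 0.05,
λ = 2 reads, ε = 0.01, HTO means 200/10, genetic misassignment 0.01,
hashing misassignment 0.05.  Six donors with a high staining-failure rate
emulate the regime the rescue workflow exists for (a hashed nuclei pool
with a noisy HTO library); genetic misassignment is set an order of
magnitude below hashing misassignment because genotype-based tools are
the reliable side in that regime, which is the premise of rescue.  Unit
tests use a reduced configuration (4 donors, 1200 cells, 220 variants)
for speed; the simulation-heavy properties (matching recovery, refinement
recovery, concordance) run at the full default sizes above.

What the simulator does **not** model: ambient RNA and barcode swapping,
empty droplets, donor-abundance skew by default, linkage between
variants, transcriptome counts, batch structure, or non-uniform coverage
(expression-dependent pileup).  Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms under the stated
noise model, not performance on any real dataset.

### Recovery property and label noise

The planted-private recovery property (≥ 90% per donor, zero cross-donor
false privates) is evaluated with error-free method tables.  With noisy
tables, misassigned cells contaminate the rescued/conflict groups and the
inconsistent-group concordance check then (correctly) discards the
contaminated planted variants — that behaviour is the filter doing its
job, and conflating it with reconstruction accuracy would make the
property test about the noise level rather than the machinery.  The
acceptance script reports the noisy-default donor-specific variant count
alongside, unasserted.

## Numerical and degenerate-input choices

* Phi correlations are computed from integer sufficient statistics; no
  epsilon regularization anywhere in matching.
* Zero-variance indicator columns → correlation defined 0, flagged.
* All row/column orders are lexicographic and all writers sort, so
  fixed-seed runs serialize byte-identically.
* Empty barcode intersections, unusable (singlet-free) tables, unknown
  donors/barcodes, AD > DP, and duplicate barcodes or sample names raise
  `ValueError` naming the offender.
* A hashing table with zero negatives yields a not-applicable rescue
  fraction (`None`), not 0.
* Likelihood probabilities are clipped at 1e-300 before log only to keep
  the arithmetic finite at p ∈ {0, 1}; with 0 < ε < 0.5 the clip is never
  active.

## Problem sizes

Default test and acceptance runs use 6 donors × 5000 cells × 800 variants
(and 20 × 3000 cells for matching-recovery replicates), sizes at which
every stage completes in seconds while pooled per-donor depths (~50 reads
per variant) sit comfortably above the filter thresholds, matching the
regime the thresholds were designed for.

## Known limitations

* The re-demultiplexer assumes homozygous reference genotypes; it is a
  verification instrument, not a replacement for full genetic
  demultiplexers (no heterozygous likelihoods, no ambient-RNA term, no
  doublet-rate prior — the doublet prior is uniform over pairs).
* Donor matching assumes the two methods share enough barcodes and that
  donors map 1:1 to hashtags; pools with repeated donors across hashtags
  violate the mutual-best-match premise.
* Multi-trial wide summary tables are supported as one table per trial
  column, not as a single wide file.
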