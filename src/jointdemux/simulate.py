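"""Synthetic multiplexed single-cell experiments with known ground truth.

The generator emulates the inputs of a pooled, hashed experiment end to
end: K genetically distinct donors with diploid genotypes at shared common
SNPs (per-variant minor-allele frequency drawn on [0.05, 0.5]) plus a set
of planted donor-private homozygous-ALT variants; droplets that are
singlets or (at rate delta) doublets; sparse AD/DP allele counts with
per-variant coverage probability q, read depth 1 + Poisson(lambda - 1) and
per-read error eps; negative-binomial HTO counts where a fraction f of
cells fail staining (signal replaced by background); and the two noisy
method-output tables a hashing and a genetic demultiplexer would emit,
with the genetic donors anonymized through a hidden permutation that is
returned for test oracles.

Everything is deterministic under the config seed, including the on-disk
serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .allele_counts import AlleleCountSet, VariantRecord, write_allele_counts
from .assignment import (
    AssignmentTable,
    doublet,
    negative,
    singlet,
    write_assignment_table,
)

_BASES = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults emulate a six-donor hashed nuclei pool with a badly stained
    hashing library (30% failure) and shallow variant coverage, the regime
    the rescue workflow exists for.
    """

    n_donors: int = 6
    n_variants: int = 500              # shared common SNPs
    n_private_per_donor: int = 50      # planted donor-private hom-ALT variants
    n_cells: int = 5000
    doublet_rate: float = 0.05
    stain_fail_rate: float = 0.30
    coverage_rate: float = 0.05        # per-(variant, cell) coverage probability
    mean_depth: float = 2.0            # mean reads at covered entries (>= 1)
    base_error: float = 0.01           # per-read allele error
    hto_signal_mean: float = 200.0
    hto_background_mean: float = 10.0
    hto_dispersion: float = 5.0        # negative-binomial size parameter
    genetic_misassign_rate: float = 0.01
    hashing_misassign_rate: float = 0.05
    donor_weights: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ValueError("need at least 2 donors")
        if not (0 <= self.doublet_rate < 1 and 0 <= self.stain_fail_rate < 1):
            raise ValueError("rates must be in [0, 1)")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")

    def donor_names(self) -> list[str]:
        return [f"sample{i + 1}" for i in range(self.n_donors)]

    def hashtag_names(self) -> list[str]:
        return [f"Hashtag{i + 1}" for i in range(self.n_donors)]


@dataclass
class SimTruth:
    """Ground truth per barcode: donor(s), doublet flag, staining flag."""

    frame: pd.DataFrame  # columns: Barcode, Donor, Donor2, IsDoublet, Stained

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class DonorGenotypes:
    """Simulated diploid dosages (variants x donors) with planted privates."""

    variants: list[VariantRecord]
    donors: list[str]
    dosage: np.ndarray                   # (M, K) in {0, 1, 2}
    private_owner: np.ndarray            # (M,) donor index or -1 for shared
    maf: np.ndarray                      # (M,) drawn MAF (0 for planted rows)

    def private_variants(self, donor_index: int) -> list[VariantRecord]:
        return [v for v, o in zip(self.variants, self.private_owner) if o == donor_index]


@dataclass
class Experiment:
    config: SimConfig
    genotypes: DonorGenotypes
    counts: AlleleCountSet
    hto: pd.DataFrame                    # barcodes x hashtags
    truth: SimTruth
    hashing_table: AssignmentTable
    genetic_table: AssignmentTable
    donor_map: dict[str, str]            # anonymous genetic label -> hashtag


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stage]))


def simulate_genotypes(cfg: SimConfig) -> DonorGenotypes:
    """Draw donor genotypes: shared common SNPs plus planted privates."""
    rng = _rng(cfg, 0)
    K, M = cfg.n_donors, cfg.n_variants
    P = cfg.n_private_per_donor * K
    maf = rng.uniform(0.05, 0.5, size=M)
    shared = rng.binomial(2, maf[:, None], size=(M, K))
    dosage = np.zeros((M + P, K), dtype=np.int8)
    dosage[:M] = shared
    owner = np.full(M + P, -1, dtype=np.int64)
    for k in range(K):
        rows = M + k * cfg.n_private_per_donor + np.arange(cfg.n_private_per_donor)
        dosage[rows, k] = 2
        owner[rows] = k
    variants = []
    for i in range(M + P):
        ref = _BASES[i % 4]
        alt = _BASES[(i + 1) % 4]
        variants.append(VariantRecord("chr1", 1000 + 100 * i, ref, alt))
    full_maf = np.concatenate([maf, np.zeros(P)])
    return DonorGenotypes(variants, cfg.donor_names(), dosage, owner, full_maf)


def _draw_truth(cfg: SimConfig, rng: np.random.Generator) -> SimTruth:
    K, N = cfg.n_donors, cfg.n_cells
    weights = None
    if cfg.donor_weights is not None:
        weights = np.asarray(cfg.donor_weights, dtype=float)
        weights = weights / weights.sum()
    d1 = rng.choice(K, size=N, p=weights)
    is_dbl = rng.random(N) < cfg.doublet_rate
    # second donor uniform over the others (no abundance skew by default)
    d2 = (d1 + rng.integers(1, K, size=N)) % K
    stained = rng.random(N) >= cfg.stain_fail_rate
    names = cfg.donor_names()
    frame = pd.DataFrame(
        {
            "Barcode": [f"cell{i:05d}" for i in range(N)],
            "Donor": [names[i] for i in d1],
            "Donor2": [names[j] if dbl else "" for j, dbl in zip(d2, is_dbl)],
            "IsDoublet": is_dbl,
            "Stained": stained,
        }
    )
    return SimTruth(frame)


def simulate_cells(
    cfg: SimConfig, genotypes: DonorGenotypes
) -> tuple[AlleleCountSet, pd.DataFrame, SimTruth]:
    """Draw droplets, allele counts and HTO counts given donor genotypes."""
    rng = _rng(cfg, 1)
    truth = _draw_truth(cfg, rng)
    tf = truth.frame
    K = cfg.n_donors
    name_to_idx = {n: i for i, n in enumerate(genotypes.donors)}
    d1 = tf["Donor"].map(name_to_idx).to_numpy()
    d2 = np.where(
        tf["IsDoublet"].to_numpy(),
        tf["Donor2"].map(lambda s: name_to_idx.get(s, -1)).to_numpy(),
        d1,
    )

    M = len(genotypes.variants)
    N = cfg.n_cells
    eps = cfg.base_error
    # per-(variant, donor) ALT-read probability from dosage g:
    # p = (g/2)(1 - eps) + (1 - g/2) eps
    half_g = genotypes.dosage.astype(np.float32) / 2.0
    p_donor = half_g * (1.0 - eps) + (1.0 - half_g) * eps
    p_cell = 0.5 * (p_donor[:, d1] + p_donor[:, d2])  # (M, N); equals p_donor col for singlets

    covered = rng.random((M, N)) < cfg.coverage_rate
    vi, ci = np.nonzero(covered)
    dp = 1 + rng.poisson(cfg.mean_depth - 1.0, size=vi.size)
    ad = rng.binomial(dp, p_cell[vi, ci].astype(np.float64))
    AD = sp.csr_matrix((ad, (vi, ci)), shape=(M, N), dtype=np.int64)
    DP = sp.csr_matrix((dp, (vi, ci)), shape=(M, N), dtype=np.int64)
    counts = AlleleCountSet(
        list(genotypes.variants), tf["Barcode"].tolist(), AD, DP
    )

    # HTO counts: NB(signal) on own hashtag(s) when stained, NB(background)
    # everywhere else; stain failure replaces signal by background.
    means = np.full((N, K), cfg.hto_background_mean)
    stained = tf["Stained"].to_numpy()
    rows = np.arange(N)
    means[rows[stained], d1[stained]] = cfg.hto_signal_mean
    dbl_and_stained = stained & tf["IsDoublet"].to_numpy()
    means[rows[dbl_and_stained], d2[dbl_and_stained]] = cfg.hto_signal_mean
    size = cfg.hto_dispersion
    hto_counts = rng.negative_binomial(size, size / (size + means))
    hto = pd.DataFrame(hto_counts, index=tf["Barcode"], columns=cfg.hashtag_names())
    return counts, hto, truth


def simulate_method_outputs(
    truth: SimTruth, cfg: SimConfig
) -> tuple[AssignmentTable, AssignmentTable, dict[str, str]]:
    """Emulate the verdict tables a hashing and a genetic tool would emit.

    The genetic table anonymizes donors through a hidden random
    permutation and corrupts singlets at ``genetic_misassign_rate``; the
    hashing table labels unstained cells negative and corrupts stained
    singlets at ``hashing_misassign_rate``.  Returns the two tables plus
    the oracle map anonymous-donor-label -> true hashtag.
    """
    rng = _rng(cfg, 2)
    K = cfg.n_donors
    names = cfg.donor_names()
    tags = cfg.hashtag_names()
    tag_of = dict(zip(names, tags))
    perm = rng.permutation(K)
    anon_of = {names[i]: f"donor{perm[i]}" for i in range(K)}
    donor_map = {anon_of[n]: tag_of[n] for n in names}

    genetic: dict[str, object] = {}
    hashing: dict[str, object] = {}
    for row in truth.frame.itertuples(index=False):
        bc = row.Barcode
        if row.IsDoublet:
            genetic[bc] = doublet()
            hashing[bc] = doublet() if row.Stained else negative()
            continue
        g_name = row.Donor
        if rng.random() < cfg.genetic_misassign_rate:
            g_name = names[(names.index(g_name) + int(rng.integers(1, K))) % K]
        genetic[bc] = singlet(anon_of[g_name])
        if not row.Stained:
            hashing[bc] = negative()
        else:
            h_name = row.Donor
            if rng.random() < cfg.hashing_misassign_rate:
                h_name = names[(names.index(h_name) + int(rng.integers(1, K))) % K]
            hashing[bc] = singlet(tag_of[h_name])
    return (
        AssignmentTable("hashing_sim", "hashing", hashing),
        AssignmentTable("genetic_sim", "genetic", genetic),
        donor_map,
    )


def simulate_experiment(cfg: SimConfig) -> Experiment:
    """Full synthetic experiment: genotypes, counts, HTO, truth, tables."""
    genotypes = simulate_genotypes(cfg)
    counts, hto, truth = simulate_cells(cfg, genotypes)
    hashing, genetic, donor_map = simulate_method_outputs(truth, cfg)
    return Experiment(cfg, genotypes, counts, hto, truth, hashing, genetic, donor_map)


def write_experiment(exp: Experiment, outdir: str | Path) -> None:
    """Serialize every artifact in the dialects the other modules read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_allele_counts(exp.counts, outdir / "cellsnp")
    exp.hto.to_csv(outdir / "hto_counts.csv")
    exp.truth.write_csv(outdir / "truth.csv")
    write_assignment_table(exp.hashing_table, outdir / "hashing_assignment.csv")
    write_assignment_table(exp.genetic_table, outdir / "genetic_assignment.csv")
    pd.DataFrame(
        sorted(exp.donor_map.items()), columns=["AnonymousDonor", "Hashtag"]
    ).to_csv(outdir / "true_donor_map.csv", index=False)
    # planted donor-private variants, for external validation
    rows = []
    for k, donor in enumerate(exp.genotypes.donors):
        for v in exp.genotypes.private_variants(k):
            rows.append({"Donor": donor, "CHROM": v.chrom, "POS": v.pos, "REF": v.ref, "ALT": v.alt})
    pd.DataFrame(rows, columns=["Donor", "CHROM", "POS", "REF", "ALT"]).to_csv(
        outdir / "planted_private_variants.csv", index=False
    )


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=int(seed))
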