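"""Re-demultiplexing against reconstructed donor genotypes.

The sanity check for genotype reconstruction: run a genetic demultiplexer
that takes the minimal (homozygous, donor-specific) genotypes as reference
and assigns each cell to a donor, then measure how often it agrees with the
rescued assignment.  The assigner is a transparent binomial-likelihood
model: at a variant called REF for a donor, alternative reads arise only
from sequencing error (rate eps), so AD ~ Binomial(DP, eps); at an ALT
call, AD ~ Binomial(DP, 1 - eps).  A cell's log-likelihood under a donor is
the sum over its covered, called variants; doublet models average the two
donors' allele probabilities.  A cell is *negative* when it covers too few
called sites or when the best model's advantage over the runner-up is below
a log-likelihood margin.

The binomial coefficient is omitted from the likelihood: per covered site
it does not depend on the genotype, so it shifts every model equally.

When scoring whole cells, models must be compared over a common site set:
reconstructed genotypes are donor-specific, so each donor calls a largely
disjoint set of variants, and summing each model only over its own called
sites would favor models with fewer sites.  ``assign_cells`` therefore
fills an uninformative allele probability of 0.5 at sites a donor does not
call; sites uncalled by every donor then contribute an identical constant
to all models and cancel from rankings and margins.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .allele_counts import AlleleCountSet
from .assignment import AssignmentTable, CellLabel, SINGLET, doublet, negative, singlet
from .refinement import ALT, REF, DonorGenotypeSet

logger = logging.getLogger(__name__)


@dataclass
class DemuxModelConfig:
    error_rate: float = 0.01       # eps: per-read probability of the off-genotype allele
    min_informative_sites: int = 10
    loglik_margin: float = 2.0     # nats required between best and runner-up
    doublet_models: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.error_rate < 0.5):
            raise ValueError("error_rate must be in (0, 0.5)")
        if self.loglik_margin < 0:
            raise ValueError("loglik_margin must be >= 0")


def genotype_loglik(
    cell_counts: dict | list,
    genotype: dict,
    cfg: DemuxModelConfig | None = None,
) -> float:
    """Log-likelihood of one cell's reads under one donor genotype.

    ``cell_counts`` maps variant -> (AD, DP); ``genotype`` maps variant ->
    "REF" | "ALT".  Variants without a call or without coverage contribute
    0 (empty product).
    """
    cfg = cfg or DemuxModelConfig()
    eps = cfg.error_rate
    items = cell_counts.items() if isinstance(cell_counts, dict) else cell_counts
    total = 0.0
    for v, (ad, dp) in items:
        if dp <= 0:
            continue
        if ad < 0 or ad > dp:
            raise ValueError(f"invalid counts AD={ad}, DP={dp}")
        call = genotype.get(v)
        if call is None:
            continue
        p = 1.0 - eps if call == ALT else eps
        total += ad * np.log(p) + (dp - ad) * np.log(1.0 - p)
    return float(total)


def _probability_matrix(
    counts: AlleleCountSet, genotypes: DonorGenotypeSet
) -> tuple[np.ndarray, np.ndarray]:
    """(M x K) ALT-read probability p in {eps, 1-eps} placeholder and call mask.

    Returns the per-variant genotype dosage proxy g in {0, 1} (0 = REF
    call, 1 = ALT call) and a boolean called-mask; probabilities are
    derived by the caller from its error rate.
    """
    key_to_row = {v.key: i for i, v in enumerate(counts.variants)}
    M, K = len(counts.variants), len(genotypes.donors)
    g = np.zeros((M, K), dtype=np.float64)
    called = np.zeros((M, K), dtype=bool)
    for k, d in enumerate(genotypes.donors):
        for v, allele in genotypes.calls.get(d, {}).items():
            i = key_to_row.get(v.key)
            if i is None:
                continue
            called[i, k] = True
            g[i, k] = 1.0 if allele == ALT else 0.0
    return g, called


def assign_cells(
    counts: AlleleCountSet,
    genotypes: DonorGenotypeSet,
    cfg: DemuxModelConfig | None = None,
    method_name: str = "refined",
) -> AssignmentTable:
    """Demultiplex every cell against the reconstructed genotypes.

    Evaluates all K singlet models and (optionally) all K(K-1)/2 doublet
    models; deterministic — no randomness anywhere.  See the module
    docstring for the model and the negative rules.
    """
    cfg = cfg or DemuxModelConfig()
    if len(genotypes.donors) < 2:
        raise ValueError("need at least 2 donors to demultiplex")
    g, called = _probability_matrix(counts, genotypes)
    eps = cfg.error_rate
    AD = counts.AD.tocsr().astype(np.float64)
    DP = counts.DP.tocsr().astype(np.float64)
    RD = DP - AD  # reference-allele depth

    models: list[CellLabel] = []
    logliks: list[np.ndarray] = []

    def model_loglik(p_col: np.ndarray) -> np.ndarray:
        # per cell: sum over covered variants of AD*log(p) + (DP-AD)*log(1-p)
        lp = np.log(np.clip(p_col, 1e-300, 1.0))
        l1p = np.log(np.clip(1.0 - p_col, 1e-300, 1.0))
        return np.asarray(AD.T @ lp).ravel() + np.asarray(RD.T @ l1p).ravel()

    donors = genotypes.donors
    # ALT-read probability per (variant, donor); uninformative 0.5 where the
    # donor has no call, so every model spans the same site set (see module
    # docstring) and fully-uncalled sites cancel between models.
    p_single = np.where(called, g * (1.0 - eps) + (1.0 - g) * eps, 0.5)
    for k, d in enumerate(donors):
        models.append(singlet(d))
        logliks.append(model_loglik(p_single[:, k]))
    if cfg.doublet_models:
        for i, j in itertools.combinations(range(len(donors)), 2):
            p_pair = 0.5 * (p_single[:, i] + p_single[:, j])
            models.append(doublet(donors[i], donors[j]))
            logliks.append(model_loglik(p_pair))

    L = np.vstack(logliks)  # models x cells

    # informative sites per cell: covered (DP > 0) and called in >= 1 donor
    any_called = called.any(axis=1).astype(np.float64)
    covered = DP.copy()
    covered.data = (covered.data > 0).astype(np.float64)
    n_sites = np.asarray(covered.T @ any_called).ravel()

    order = np.argsort(-L, axis=0)
    best = order[0]
    second = order[1]
    margin = L[best, np.arange(L.shape[1])] - L[second, np.arange(L.shape[1])]

    entries: dict[str, CellLabel] = {}
    for c, bc in enumerate(counts.barcodes):
        if n_sites[c] < cfg.min_informative_sites or margin[c] < cfg.loglik_margin:
            entries[bc] = negative()
        else:
            entries[bc] = models[best[c]]
    return AssignmentTable(method_name, "genetic", entries)


def concordance(a: AssignmentTable, b: AssignmentTable) -> tuple[float | None, int]:
    """Agreement between two assignments over cells singlet in both.

    Returns (fraction of shared both-singlet barcodes with identical
    labels, count of both-singlet barcodes); the fraction is None when no
    barcode is a singlet in both tables.
    """
    shared = set(a.entries) & set(b.entries)
    if not shared:
        raise ValueError("tables share no barcodes")
    both = [
        bc
        for bc in shared
        if a.entries[bc].kind == SINGLET and b.entries[bc].kind == SINGLET
    ]
    if not both:
        return None, 0
    agree = sum(1 for bc in both if a.entries[bc].name == b.entries[bc].name)
    return agree / len(both), len(both)
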