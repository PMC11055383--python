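r"""Donor-to-hashtag matching by the phi (Pearson) correlation score.

Genotype-based demultiplexing without reference genotypes yields *anonymous*
donor clusters; cell hashing yields named hashtags.  When both methods ran
on the same pooled experiment, a donor cluster and the hashtag of the same
biological sample mark (mostly) the same set of barcodes.  This module
exploits that: each method's verdicts are binarized into barcodes-by-labels
indicator matrices, columns are correlated pairwise with Pearson's r — which
on 0/1 vectors is exactly the phi coefficient of the 2x2 contingency table

    phi = (n11*n00 - n10*n01) / sqrt(n1+ * n0+ * n+1 * n+0)

— donors and hashtags are paired when they are each other's highest
correlation (mutual best match), and the overall *Phi score* of the method
pair is

    score = sum over matched pairs of max(r, 0) / n_expected_donors,

a number in [0, 1] that is 1 only when every expected donor is matched with
perfect concordance.  Across several candidate method pairs, the pair with
complete matching and the highest score is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assignment import (
    SINGLET,
    AssignmentTable,
    BinaryAssignmentMatrix,
    CellLabel,
    align_on_common_barcodes,
    binarize,
    singlet,
)

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Donor-by-hashtag phi correlations.

    Columns of either side with zero variance (an all-zero or all-one
    indicator — e.g. a donor with no singlets among the common barcodes)
    have undefined Pearson correlation; their entries are defined as 0 and
    the label is flagged, so an empty donor can never win a match.
    """

    donor_labels: list[str]
    hashtag_labels: list[str]
    values: np.ndarray  # shape (donors, hashtags), float64 in [-1, 1]
    zero_variance_donors: list[str] = field(default_factory=list)
    zero_variance_hashtags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.donor_labels, columns=self.hashtag_labels)

    def write_csv(self, path: str | Path) -> None:
        """Serialize donors-as-rows, hashtags-as-columns (heat-map input)."""
        df = self.to_frame()
        df.index.name = "Donor"
        df.to_csv(path)


@dataclass
class DonorMatchResult:
    """Outcome of matching one genetic method against one hashing method."""

    correlations: CorrelationMatrix
    pairs: list[tuple[str, str, float]]  # (donor, hashtag, correlation)
    all_donors_matched: bool
    phi_score: float
    n_expected_donors: int
    genetic_method: str = ""
    hashing_method: str = ""

    def donor_to_hashtag(self) -> dict[str, str]:
        return {d: h for d, h, _ in self.pairs}

    def write_pairs_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.pairs, columns=["Donor", "Hashtag", "Correlation"]).to_csv(
            path, index=False
        )


def pairwise_phi(
    genetic: BinaryAssignmentMatrix, hashing: BinaryAssignmentMatrix
) -> CorrelationMatrix:
    """Column-wise Pearson correlation of two aligned indicator matrices.

    Requires identical barcode order on both sides (use
    :func:`~jointdemux.assignment.align_on_common_barcodes` first) and at
    least two rows.  All sums below are integer-valued, so the result is
    numerically exact up to the final division and square root; identical
    columns correlate to exactly 1.0.
    """
    if genetic.barcodes != hashing.barcodes:
        raise ValueError(
            "row (barcode) order differs between matrices; align_on_common_barcodes first"
        )
    n = len(genetic.barcodes)
    if n < 2:
        raise ValueError("need at least 2 common barcodes to correlate")
    G = genetic.values.astype(np.float64)
    H = hashing.values.astype(np.float64)
    s11 = G.T @ H                      # co-assignment counts, donors x hashtags
    rg = G.sum(axis=0)                 # per-donor singlet counts
    ch = H.sum(axis=0)                 # per-hashtag singlet counts
    num = n * s11 - np.outer(rg, ch)
    var_g = n * rg - rg**2             # n * variance * n, since x^2 = x for 0/1
    var_h = n * ch - ch**2
    den = np.sqrt(np.outer(var_g, var_h))
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    zd = [l for l, v in zip(genetic.labels, var_g) if v == 0]
    zh = [l for l, v in zip(hashing.labels, var_h) if v == 0]
    return CorrelationMatrix(list(genetic.labels), list(hashing.labels), values, zd, zh)


def _best_partner(scores: np.ndarray, partner_labels: list[str]) -> int:
    """Index of the maximum, ties broken by lexicographically smaller label."""
    best = np.flatnonzero(scores == scores.max())
    if len(best) == 1:
        return int(best[0])
    return int(min(best, key=lambda j: partner_labels[j]))


def mutual_best_match(corr: CorrelationMatrix) -> list[tuple[str, str, float]]:
    """Pair donors and hashtags that are each other's highest correlation.

    Deterministic: argmax ties resolve to the lexicographically smallest
    partner label, then mutuality is re-checked.  Labels without a mutual
    best partner are omitted.  Returned pairs are sorted by donor label.
    """
    V = corr.values
    if V.size == 0:
        return []
    pairs = []
    best_h = [_best_partner(V[i, :], corr.hashtag_labels) for i in range(V.shape[0])]
    best_d = [_best_partner(V[:, j], corr.donor_labels) for j in range(V.shape[1])]
    for i, d in enumerate(corr.donor_labels):
        j = best_h[i]
        if best_d[j] == i:
            pairs.append((d, corr.hashtag_labels[j], float(V[i, j])))
    pairs.sort(key=lambda p: p[0])
    if pairs and max(p[2] for p in pairs) <= 0:
        logger.warning("mutual_best_match: all matched correlations <= 0; low-confidence match")
    return pairs


def phi_score(pairs: list[tuple[str, str, float]], n_expected_donors: int) -> float:
    """Sum of non-negative matched correlations over the expected donor count."""
    if n_expected_donors < 1:
        raise ValueError("n_expected_donors must be >= 1")
    n_donor_labels = len({d for d, _, _ in pairs})
    if n_expected_donors < n_donor_labels:
        logger.warning(
            "n_expected_donors (%d) < distinct matched donor labels (%d)",
            n_expected_donors,
            n_donor_labels,
        )
    return float(sum(max(c, 0.0) for _, _, c in pairs) / n_expected_donors)


def match_methods(
    genetic_table: AssignmentTable,
    hashing_table: AssignmentTable,
    n_expected_donors: int,
) -> DonorMatchResult:
    """Match one genetic demultiplexer's donors to one hasher's hashtags.

    Composes binarization, barcode alignment, column-wise phi correlation,
    mutual-best matching and the Phi score.  ``all_donors_matched`` is true
    iff every genetic singlet label landed in a pair.
    """
    for t in (genetic_table, hashing_table):
        if not t.is_usable():
            raise ValueError(f"table {t.method_name!r} has no singlet labels; cannot match")
    gmat, hmat = align_on_common_barcodes(binarize(genetic_table), binarize(hashing_table))
    corr = pairwise_phi(gmat, hmat)
    pairs = mutual_best_match(corr)
    matched_donors = {d for d, _, _ in pairs}
    all_matched = set(genetic_table.singlet_names()) <= matched_donors
    score = phi_score(pairs, n_expected_donors)
    return DonorMatchResult(
        correlations=corr,
        pairs=pairs,
        all_donors_matched=all_matched,
        phi_score=score,
        n_expected_donors=n_expected_donors,
        genetic_method=genetic_table.method_name,
        hashing_method=hashing_table.method_name,
    )


def select_best_pair(
    genetic_tables: list[AssignmentTable],
    hashing_tables: list[AssignmentTable],
    n_expected_donors: int,
) -> tuple[DonorMatchResult, tuple[str, str], list[DonorMatchResult]]:
    """Evaluate every (genetic, hashing) method combination and rank them.

    Fully matched pairs beat partially matched ones regardless of score;
    within each group a higher Phi score wins; exact ties resolve to the
    lexicographically smaller (genetic, hashing) method-name pair.  When no
    combination matches every donor, the best partial match is returned
    (callers can see ``all_donors_matched`` is false).
    """
    if not genetic_tables or not hashing_tables:
        raise ValueError("need at least one table per family")
    results = []
    for g in genetic_tables:
        for h in hashing_tables:
            results.append(match_methods(g, h, n_expected_donors))
    ranking = sorted(
        results,
        key=lambda r: (
            not r.all_donors_matched,
            -r.phi_score,
            (r.genetic_method, r.hashing_method),
        ),
    )
    best = ranking[0]
    if not best.all_donors_matched:
        logger.warning(
            "select_best_pair: no method pair matched all donors; returning partial match %s/%s",
            best.genetic_method,
            best.hashing_method,
        )
    return best, (best.genetic_method, best.hashing_method), ranking


def relabel_genetic(genetic_table: AssignmentTable, match: DonorMatchResult) -> AssignmentTable:
    """Rename anonymous donor singlets to their matched hashtags.

    Singlets of unmatched donors keep their anonymous name (counted in the
    log); doublets and negatives pass through unchanged.
    """
    if not match.pairs:
        raise ValueError("match has no pairs; nothing to relabel")
    mapping = match.donor_to_hashtag()
    entries: dict[str, CellLabel] = {}
    unmatched = 0
    for bc, lab in genetic_table.entries.items():
        if lab.kind == SINGLET:
            if lab.name in mapping:
                entries[bc] = singlet(mapping[lab.name])
            else:
                entries[bc] = lab
                unmatched += 1
        else:
            entries[bc] = lab
    if unmatched:
        logger.info("relabel_genetic: %d singlets kept anonymous (unmatched donor)", unmatched)
    return AssignmentTable(f"{genetic_table.method_name}_matched", "genetic", entries)
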