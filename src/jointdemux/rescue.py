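"""Joint (rescued) per-cell assignment.

Once anonymous genetic donors are matched to hashtags, cells that the
hashing library failed to stain (hashing *negatives*) but that carry a
confident genetic singlet call can be given the hashtag of their matched
donor — they are *rescued*.  Only genetically deconvoluted singlets are
eligible; genetic negatives and doublets are never rescued.  Each final
call carries a provenance tag so downstream QC can distinguish cells the
two methods agreed on from cells recovered or overridden by genetics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .assignment import (
    DOUBLET,
    NEGATIVE,
    SINGLET,
    AssignmentTable,
    CellLabel,
    doublet,
    negative,
    singlet,
)
from .matching import DonorMatchResult

logger = logging.getLogger(__name__)

CONFIRMED = "confirmed"
RESCUED = "rescued"
CONFLICT = "conflict"
UNMATCHED_DONOR = "unmatched_donor"

PROVENANCES = (CONFIRMED, RESCUED, CONFLICT, DOUBLET, NEGATIVE, UNMATCHED_DONOR)


@dataclass
class JointAssignment:
    """Final donor identity plus provenance per barcode."""

    entries: dict[str, tuple[CellLabel, str]] = field(default_factory=dict)

    def counts_by_provenance(self) -> dict[str, int]:
        out = {p: 0 for p in PROVENANCES}
        for _, prov in self.entries.values():
            out[prov] += 1
        return out

    def singlet_barcodes(self, label: str | None = None) -> list[str]:
        return [
            bc
            for bc, (lab, _) in self.entries.items()
            if lab.kind == SINGLET and (label is None or lab.name == label)
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"Barcode": bc, "Assignment": lab.as_string(), "Provenance": prov}
            for bc, (lab, prov) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["Barcode", "Assignment", "Provenance"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def as_assignment_table(self, method_name: str = "rescued") -> AssignmentTable:
        """View the final labels as a standard genetic-family table."""
        return AssignmentTable(
            method_name, "genetic", {bc: lab for bc, (lab, _) in self.entries.items()}
        )


def read_joint_assignment(path: str | Path) -> JointAssignment:
    df = pd.read_csv(path, dtype=str)
    for col in ("Barcode", "Assignment", "Provenance"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    entries: dict[str, tuple[CellLabel, str]] = {}
    for bc, a, prov in zip(df["Barcode"], df["Assignment"], df["Provenance"]):
        if prov not in PROVENANCES:
            raise ValueError(f"{path}: unknown provenance {prov!r}")
        if a == DOUBLET:
            lab = doublet()
        elif a == NEGATIVE:
            lab = negative()
        else:
            lab = singlet(a)
        if bc in entries:
            raise ValueError(f"{path}: duplicate barcode {bc!r}")
        entries[str(bc)] = (lab, prov)
    return JointAssignment(entries)


def joint_assign(
    hashing_table: AssignmentTable,
    genetic_table: AssignmentTable,
    match: DonorMatchResult,
    conflict_policy: str = "flag",
) -> JointAssignment:
    """Combine hashing and genetic verdicts under a donor-hashtag match.

    For every barcode shared by the two tables:

    * genetic singlet of a matched donor ``d -> h``:
        - hashing singlet ``h``        -> (singlet h, confirmed)
        - hashing negative             -> (singlet h, rescued)
        - hashing singlet ``h' != h``  -> (singlet h, conflict)
        - hashing doublet              -> (singlet h, conflict)
    * genetic singlet of an unmatched donor -> (anonymous singlet, unmatched_donor)
    * genetic doublet  -> (doublet, doublet)
    * genetic negative -> (negative, negative) — never rescued.

    Conflicts take the genetic identity (hashing is assumed the noisy side)
    and are flagged; ``conflict_policy="drop"`` excludes them from the
    joint assignment instead.  Barcodes outside the intersection are
    excluded and counted in the log.
    """
    if conflict_policy not in ("flag", "drop"):
        raise ValueError("conflict_policy must be 'flag' or 'drop'")
    common = sorted(set(hashing_table.entries) & set(genetic_table.entries))
    if not common:
        raise ValueError("hashing and genetic tables share no barcodes")
    n_outside = (
        len(hashing_table.entries) + len(genetic_table.entries) - 2 * len(common)
    )
    if n_outside:
        logger.info("joint_assign: %d barcodes outside the intersection excluded", n_outside)
    mapping = match.donor_to_hashtag()
    entries: dict[str, tuple[CellLabel, str]] = {}
    dropped_conflicts = 0
    for bc in common:
        g = genetic_table.entries[bc]
        h = hashing_table.entries[bc]
        if g.kind == NEGATIVE:
            entries[bc] = (negative(), NEGATIVE)
        elif g.kind == DOUBLET:
            entries[bc] = (doublet(g.name, g.second_name), DOUBLET)
        elif g.name in mapping:
            tag = mapping[g.name]
            if h.kind == SINGLET and h.name == tag:
                entries[bc] = (singlet(tag), CONFIRMED)
            elif h.kind == NEGATIVE:
                entries[bc] = (singlet(tag), RESCUED)
            else:  # hashing doublet, or singlet of a different hashtag
                if conflict_policy == "drop":
                    dropped_conflicts += 1
                else:
                    entries[bc] = (singlet(tag), CONFLICT)
        else:
            entries[bc] = (singlet(g.name), UNMATCHED_DONOR)
    if dropped_conflicts:
        logger.info("joint_assign: dropped %d conflicting barcodes (policy=drop)", dropped_conflicts)
    return JointAssignment(entries)


def summarize_flows(hashing_table: AssignmentTable, joint: JointAssignment) -> pd.DataFrame:
    """Count classification flows from hashing verdicts to final calls.

    One row per (hashing label, final label, provenance) triple, with
    counts and percentages normalized within each hashing label — the
    tabular form of the rescue Sankey diagram.  Counts sum to the number
    of barcodes in the joint assignment.
    """
    rows: dict[tuple[str, str, str], int] = {}
    for bc, (lab, prov) in joint.entries.items():
        h = hashing_table.entries.get(bc)
        hname = h.as_string() if h is not None else "absent"
        if h is not None and h.kind == DOUBLET:
            hname = DOUBLET
        key = (hname, lab.as_string() if lab.kind == SINGLET else lab.kind, prov)
        rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [
            {"HashingLabel": k[0], "FinalLabel": k[1], "Provenance": k[2], "Count": v}
            for k, v in sorted(rows.items())
        ],
        columns=["HashingLabel", "FinalLabel", "Provenance", "Count"],
    )
    if df.empty:
        df["Percent"] = pd.Series(dtype=float)
        return df
    totals = df.groupby("HashingLabel")["Count"].transform("sum")
    df["Percent"] = 100.0 * df["Count"] / totals
    return df


def rescue_rate(
    hashing_table: AssignmentTable, joint: JointAssignment
) -> tuple[float | None, float]:
    """(fraction of hashing negatives rescued, fraction of all cells singlet).

    The first fraction is ``None`` (not applicable) when the hashing table
    has no negatives among the jointly assigned barcodes.
    """
    common = set(joint.entries)
    n_hash_neg = sum(
        1 for bc in common if hashing_table.entries[bc].kind == NEGATIVE
    )
    n_rescued = sum(1 for _, prov in joint.entries.values() if prov == RESCUED)
    n_singlet = sum(1 for lab, _ in joint.entries.values() if lab.kind == SINGLET)
    singlet_fraction = n_singlet / len(common) if common else 0.0
    if n_hash_neg == 0:
        return None, singlet_fraction
    return n_rescued / n_hash_neg, singlet_fraction
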