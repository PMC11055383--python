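"""Per-method cell classifications and their binary-matrix form.

Every demultiplexer — hashing-based or genotype-based — ultimately emits a
three-way verdict per cell barcode: a *singlet* carrying a sample label
(hashtag or anonymous donor), a *doublet*, or a *negative* (background-only
signal / insufficient read coverage).  This module holds that verdict table,
reads and writes its two-column CSV dialect, and converts tables into the
barcodes-by-labels 0/1 indicator matrices that donor matching correlates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SINGLET = "singlet"
DOUBLET = "doublet"
NEGATIVE = "negative"

#: Default case-insensitive mapping from assignment strings to non-singlet
#: kinds.  Anything not in this map is taken verbatim as a singlet label.
DEFAULT_SYNONYMS: Mapping[str, str] = {
    "doublet": DOUBLET,
    "negative": NEGATIVE,
    "unassigned": NEGATIVE,
}


@dataclass(frozen=True)
class CellLabel:
    """Classification of one droplet.

    ``name`` is present iff ``kind == "singlet"``.  ``second_name`` may
    carry the second component of a doublet when the upstream tool reports
    the pair; most tools do not, and nothing downstream requires it.
    """

    kind: str
    name: str | None = None
    second_name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (SINGLET, DOUBLET, NEGATIVE):
            raise ValueError(f"unknown label kind {self.kind!r}")
        if self.kind == SINGLET and not self.name:
            raise ValueError("singlet labels require a non-empty name")
        if self.kind == NEGATIVE and self.name is not None:
            raise ValueError("negative labels carry no name")

    def as_string(self) -> str:
        """Serialized form used in assignment CSVs."""
        if self.kind == SINGLET:
            return self.name  # type: ignore[return-value]
        if self.kind == DOUBLET and self.name and self.second_name:
            return f"{self.name}+{self.second_name}"
        return self.kind


def singlet(name: str) -> CellLabel:
    return CellLabel(SINGLET, name)


def doublet(name: str | None = None, second: str | None = None) -> CellLabel:
    return CellLabel(DOUBLET, name, second)


def negative() -> CellLabel:
    return CellLabel(NEGATIVE)


@dataclass
class AssignmentTable:
    """One demultiplexer's verdicts, keyed by cell barcode."""

    method_name: str
    family: str  # "hashing" | "genetic"
    entries: dict[str, CellLabel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("hashing", "genetic"):
            raise ValueError(f"family must be 'hashing' or 'genetic', got {self.family!r}")

    @property
    def barcodes(self) -> list[str]:
        return list(self.entries)

    def singlet_names(self) -> list[str]:
        """Sorted distinct singlet labels present in the table."""
        return sorted({lab.name for lab in self.entries.values() if lab.kind == SINGLET})

    def is_usable(self) -> bool:
        """A table is usable for matching iff it has at least one singlet."""
        return len(self.singlet_names()) > 0

    def counts(self) -> dict[str, int]:
        out = {SINGLET: 0, DOUBLET: 0, NEGATIVE: 0}
        for lab in self.entries.values():
            out[lab.kind] += 1
        return out


@dataclass
class BinaryAssignmentMatrix:
    """Barcodes-by-labels 0/1 indicator matrix.

    Row ``c``, column ``l`` is 1 iff the source table classified barcode
    ``c`` as a singlet of label ``l``.  Under singlet-only binarization
    (the default) every row sums to at most 1.
    """

    barcodes: list[str]
    labels: list[str]
    values: np.ndarray  # shape (len(barcodes), len(labels)), dtype int8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.barcodes), len(self.labels)):
            raise ValueError("matrix shape does not match barcode/label lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.barcodes, columns=self.labels)


def parse_label(value: str, synonyms: Mapping[str, str] | None = None) -> CellLabel:
    """Map one assignment string to a :class:`CellLabel`.

    Matching against the synonym map is case-insensitive; any unmatched
    string is a singlet label, kept verbatim.
    """
    syn = DEFAULT_SYNONYMS if synonyms is None else synonyms
    kind = syn.get(str(value).strip().lower())
    if kind == DOUBLET:
        return doublet()
    if kind == NEGATIVE:
        return negative()
    name = str(value).strip()
    if not name:
        raise ValueError("empty assignment string")
    return singlet(name)


def read_assignment_table(
    path: str | Path,
    method_name: str,
    family: str,
    synonyms: Mapping[str, str] | None = None,
) -> AssignmentTable:
    """Read a two-column assignment CSV (``Barcode,Assignment``).

    A third ``Method`` column, if present, is ignored.  Duplicate barcodes
    and missing headers raise ``ValueError`` naming the offender.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("Barcode", "Assignment"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dup = df["Barcode"][df["Barcode"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate barcode {dup.iloc[0]!r}")
    entries = {
        str(bc): parse_label(a, synonyms)
        for bc, a in zip(df["Barcode"], df["Assignment"])
    }
    table = AssignmentTable(method_name, family, entries)
    if not table.is_usable():
        logger.warning("%s: table %s has no singlets; unusable for matching", path, method_name)
    return table


def write_assignment_table(table: AssignmentTable, path: str | Path) -> None:
    """Write the CSV dialect read by :func:`read_assignment_table`.

    Rows are sorted by barcode so output is byte-stable.
    """
    rows = [
        {"Barcode": bc, "Assignment": table.entries[bc].as_string(), "Method": table.method_name}
        for bc in sorted(table.entries)
    ]
    pd.DataFrame(rows, columns=["Barcode", "Assignment", "Method"]).to_csv(path, index=False)


def binarize(
    table: AssignmentTable,
    labels: Sequence[str] | None = None,
    binarize_doublets: bool = False,
) -> BinaryAssignmentMatrix:
    """Convert a verdict table into its 0/1 indicator matrix.

    Doublet and negative rows are all-zero unless ``binarize_doublets`` is
    set and the doublet's component labels were parseable, in which case
    both component columns get a 1.  Column order defaults to the sorted
    distinct singlet names; an explicit ``labels`` sequence overrides it
    (columns follow the requested order, including requested subsets).
    """
    if labels is None:
        labels = table.singlet_names()
    labels = list(labels)
    col = {l: j for j, l in enumerate(labels)}
    barcodes = sorted(table.entries)
    values = np.zeros((len(barcodes), len(labels)), dtype=np.int8)
    for i, bc in enumerate(barcodes):
        lab = table.entries[bc]
        if lab.kind == SINGLET and lab.name in col:
            values[i, col[lab.name]] = 1
        elif lab.kind == DOUBLET and binarize_doublets and lab.name and lab.second_name:
            for nm in (lab.name, lab.second_name):
                if nm in col:
                    values[i, col[nm]] = 1
    return BinaryAssignmentMatrix(barcodes, labels, values)


def align_on_common_barcodes(
    a: BinaryAssignmentMatrix, b: BinaryAssignmentMatrix
) -> tuple[BinaryAssignmentMatrix, BinaryAssignmentMatrix]:
    """Restrict two indicator matrices to their common barcodes.

    Both outputs share an identical, sorted row order.  Dropped-barcode
    counts per side are logged; an empty intersection raises.
    """
    common = sorted(set(a.barcodes) & set(b.barcodes))
    if not common:
        raise ValueError("no barcodes in common between the two matrices")
    for name, m in (("first", a), ("second", b)):
        dropped = len(m.barcodes) - len(common)
        if dropped:
            logger.info("align_on_common_barcodes: dropped %d barcodes from %s matrix", dropped, name)
    out = []
    for m in (a, b):
        idx = {bc: i for i, bc in enumerate(m.barcodes)}
        rows = np.array([idx[bc] for bc in common], dtype=int)
        out.append(BinaryAssignmentMatrix(common, list(m.labels), m.values[rows]))
    return out[0], out[1]
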