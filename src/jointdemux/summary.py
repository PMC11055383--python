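"""Merged multi-method summary tables."""

from __future__ import annotations

import pandas as pd

from .assignment import AssignmentTable


def merge_summaries(tables: list[AssignmentTable]) -> pd.DataFrame:
    """One row per barcode in the union, one assignment column per method.

    Barcodes absent from a method's table get ``NA``.  Duplicate method
    names are an error.
    """
    if not tables:
        raise ValueError("need at least one table")
    names = [t.method_name for t in tables]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate method names: {names}")
    union = sorted(set().union(*(set(t.entries) for t in tables)))
    data = {"Barcode": union}
    for t in tables:
        data[t.method_name] = [
            t.entries[bc].as_string() if bc in t.entries else "NA" for bc in union
        ]
    return pd.DataFrame(data)


def classification_counts(tables: list[AssignmentTable]) -> pd.DataFrame:
    """Singlet/doublet/negative tallies per method."""
    rows = []
    for t in tables:
        c = t.counts()
        rows.append(
            {
                "Method": t.method_name,
                "Family": t.family,
                "Singlet": c["singlet"],
                "Doublet": c["doublet"],
                "Negative": c["negative"],
                "Total": sum(c.values()),
            }
        )
    return pd.DataFrame(rows, columns=["Method", "Family", "Singlet", "Doublet", "Negative", "Total"])
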