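"""Single-cell QC filtering and lineage-barcode calling.

Cells carry expressed lineage-tag reads alongside expression QC metrics.
After removing low-quality cells (few detected features, high
mitochondrial fraction, or outlying high feature counts), each cell's tag
entries are resolved to a single lineage call: the barcode itself when
unambiguous, "complex" when several tags tie at substantial read support,
or "others" when no confident call can be made.  Calls are then annotated
against the winner barcodes of the awakened population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

COMPLEX = "complex"
OTHERS = "others"


@dataclass
class QCReport:
    n_input: int
    n_removed_low_features: int
    n_removed_high_features: int
    n_removed_mito: int
    n_kept: int


def qc_filter_cells(
    qc: pd.DataFrame,
    min_features: int = 200,
    max_pct_mito: float = 20.0,
    high_feature_quantile: float = 0.99,
) -> tuple[pd.DataFrame, QCReport]:
    """Remove low-quality cells and high-count outliers.

    Cells with fewer than ``min_features`` detected features or more than
    ``max_pct_mito`` percent mitochondrial reads are removed; cells with
    feature counts strictly above the ``high_feature_quantile`` of all
    cells are removed as presumptive doublets (the study names no number
    for "high (outliers)"; the 99th percentile is the configurable
    default).
    """
    required = {"cell_id", "n_features", "pct_mito"}
    if not required <= set(qc.columns):
        raise ValueError(f"QC table missing columns: {sorted(required - set(qc.columns))}")
    low = qc["n_features"] < min_features
    mito = qc["pct_mito"] > max_pct_mito
    upper = qc["n_features"].quantile(high_feature_quantile)
    high = qc["n_features"] > upper
    keep = ~(low | mito | high)
    report = QCReport(
        n_input=len(qc),
        n_removed_low_features=int(low.sum()),
        n_removed_high_features=int((high & ~low & ~mito).sum()),
        n_removed_mito=int((mito & ~low).sum()),
        n_kept=int(keep.sum()),
    )
    return qc.loc[keep].reset_index(drop=True), report


def call_cell_barcode(
    entries: dict[str, int] | pd.Series,
    percentile: float = 90.0,
    complex_min_reads: int = 3,
    dominance_ratio: float = 5.0,
) -> str:
    """Resolve one cell's tag read counts to a lineage call.

    A single tag is its own call.  With several tags: entries strictly
    above the within-cell read-count percentile (computed with the
    "higher" quantile method, so with two entries the 90th percentile is
    the max) are candidates; exactly one candidate wins the call.  If all
    entries tie at the same read count above ``complex_min_reads`` the
    cell is "complex".  When no entry clears the percentile, a unique
    maximum at least ``dominance_ratio`` times the runner-up is accepted
    — an explicit extension of the percentile rule for small tag sets,
    recorded in output metadata.  Everything else is "others".
    """
    if isinstance(entries, pd.Series):
        entries = entries.to_dict()
    if not entries:
        return OTHERS
    if len(entries) == 1:
        return next(iter(entries))
    barcodes = np.array(list(entries.keys()))
    reads = np.array(list(entries.values()), dtype=float)
    if np.all(reads == reads[0]):
        return COMPLEX if reads[0] > complex_min_reads else OTHERS
    cutoff = np.percentile(reads, percentile, method="higher")
    candidates = barcodes[reads > cutoff]
    if len(candidates) == 1:
        return str(candidates[0])
    if len(candidates) == 0:
        order = np.argsort(reads)[::-1]
        top, second = reads[order[0]], reads[order[1]]
        if top >= dominance_ratio * second and (reads == top).sum() == 1:
            return str(barcodes[order[0]])
    return OTHERS


def call_all_cells(
    tags: pd.DataFrame,
    qc_passing_cells: Optional[Sequence[str]] = None,
    percentile: float = 90.0,
    complex_min_reads: int = 3,
    dominance_ratio: float = 5.0,
) -> pd.DataFrame:
    """Lineage calls for every cell in a tag table.

    ``tags`` has columns cell_id, barcode_id, reads.  Cells listed in
    ``qc_passing_cells`` but with no tags are labelled "others".
    Returns a DataFrame (cell_id, label).
    """
    required = {"cell_id", "barcode_id", "reads"}
    if not required <= set(tags.columns):
        raise ValueError(f"tag table missing columns: {sorted(required - set(tags.columns))}")
    if (tags["reads"] < 1).any():
        raise ValueError("tag reads must be >= 1")
    calls = {}
    for cell, grp in tags.groupby("cell_id"):
        entries = dict(zip(grp["barcode_id"], grp["reads"]))
        calls[cell] = call_cell_barcode(
            entries, percentile, complex_min_reads, dominance_ratio
        )
    if qc_passing_cells is not None:
        for cell in qc_passing_cells:
            calls.setdefault(cell, OTHERS)
        calls = {c: calls[c] for c in qc_passing_cells}
    return pd.DataFrame(
        {"cell_id": list(calls.keys()), "label": list(calls.values())}
    )


def annotate_winner_status(
    calls: pd.DataFrame, winner_barcodes: Sequence[str]
) -> pd.DataFrame:
    """Mark cells carrying a winning barcode.

    Cells whose label is in the winner set are "winner", cells with any
    other specific barcode are "other", and "complex"/"others" cells stay
    "unassigned".
    """
    winners = set(winner_barcodes)

    def status(label: str) -> str:
        if label in (COMPLEX, OTHERS):
            return "unassigned"
        return "winner" if label in winners else "other"

    out = calls.copy()
    out["status"] = out["label"].map(status)
    return out


def barcode_call_rate(calls: pd.DataFrame) -> float:
    """Fraction of cells resolved to a specific barcode label."""
    if len(calls) == 0:
        raise ValueError("no cells to compute a call rate over")
    specific = ~calls["label"].isin([COMPLEX, OTHERS])
    return float(specific.mean())
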