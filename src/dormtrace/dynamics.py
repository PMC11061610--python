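"""Clonal dynamics over time-ordered barcode frequency tables.

Lineage survival relative to the founder population (POT), quartile-binned
survival, winner identification at awakening, founder doubling-time
estimation, and richness/extinction trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

QUARTILE_BINS = ("low", "low-mid", "mid-high", "high")


@dataclass
class SurvivalSummary:
    """Lineage survival of POT barcodes in one later sample."""

    n_pot_barcodes: int
    n_surviving: int
    fraction_surviving: float
    bin_fractions: dict[str, float]
    bin_sizes: dict[str, int]


@dataclass
class WinnerReport:
    winners: pd.DataFrame  # barcode, frequency, rank
    sweep: bool
    threshold: float


def survival_summary(
    pot_freqs: pd.Series, sample_freqs: pd.Series
) -> SurvivalSummary:
    """Surviving-lineage fraction, overall and by POT-frequency quartile.

    A lineage survives if its frequency is nonzero in the sample among
    those nonzero in the POT.  Quartile bins (low, low-mid, mid-high,
    high) partition the POT's nonzero barcodes by frequency rank, with
    ties broken by barcode id so bin sizes are as equal as possible.
    """
    pot = pot_freqs[pot_freqs > 0]
    if len(pot) == 0:
        raise ValueError("POT has no nonzero barcodes")
    sample = sample_freqs.reindex(pot.index, fill_value=0.0)
    surviving = sample > 0
    order = (
        pd.DataFrame({"f": pot, "id": pot.index.astype(str)})
        .sort_values(["f", "id"], ascending=[True, True])
        .index
    )
    groups = np.array_split(np.asarray(order), 4)
    bin_fractions = {}
    bin_sizes = {}
    for name, grp in zip(QUARTILE_BINS, groups):
        bin_sizes[name] = len(grp)
        bin_fractions[name] = (
            float(surviving.loc[grp].mean()) if len(grp) else float("nan")
        )
    return SurvivalSummary(
        n_pot_barcodes=len(pot),
        n_surviving=int(surviving.sum()),
        fraction_surviving=float(surviving.mean()),
        bin_fractions=bin_fractions,
        bin_sizes=bin_sizes,
    )


def identify_winners(
    freqs: pd.Series, threshold: float = 0.10, sweep_threshold: float = 0.5
) -> WinnerReport:
    """Barcodes at or above the winner frequency threshold at awakening.

    Winners are ranked by descending frequency; the sweep flag fires when
    the top winner holds at least half the population (our
    operationalization of a clonal sweep).
    """
    sel = freqs[freqs >= threshold].sort_values(ascending=False)
    winners = pd.DataFrame(
        {
            "barcode": sel.index,
            "frequency": sel.to_numpy(),
            "rank": np.arange(1, len(sel) + 1),
        }
    )
    sweep = bool(len(sel) > 0 and sel.iloc[0] >= sweep_threshold)
    return WinnerReport(winners=winners, sweep=sweep, threshold=threshold)


def doubling_time(
    x: float | np.ndarray,
    t_expand: float = 13.0,
    convention: str = "n_minus_1",
) -> np.ndarray:
    """Per-founder doubling time implied by clone size after expansion.

    A founder cell that expands to ``x`` cells in ``t_expand`` days under
    the convention x = 2**(n-1) has made n - 1 = log2(x) divisions in n
    division times, so each division takes t = t_expand / (log2(x) + 1)
    days (a founder that never divides has x = 1, t = t_expand).  The
    alternative convention x = 2**n (t = t_expand / log2(x), undefined at
    x = 1) is exposed because the printed formula is ambiguous.

    Returns time per division in days; multiply by 24 for hours.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 1):
        raise ValueError("clone size x must be >= 1")
    if convention == "n_minus_1":
        return t_expand / (np.log2(x) + 1.0)
    if convention == "n":
        if np.any(x == 1):
            raise ValueError("x=1 undefined under the x=2**n convention")
        return t_expand / np.log2(x)
    raise ValueError(f"unknown convention {convention!r}")


def doubling_times_from_frequencies(
    freqs: pd.Series,
    n_pot: float = 9.0e7,
    founders_per_barcode: float = 1.0,
    t_expand: float = 13.0,
) -> pd.Series:
    """Doubling time in hours per barcode from POT frequencies.

    Clone size x = frequency * n_pot / founders_per_barcode; zero-frequency
    barcodes are dropped.
    """
    f = freqs[freqs > 0]
    x = np.maximum(f.to_numpy() * n_pot / founders_per_barcode, 1.0)
    t = doubling_time(x, t_expand=t_expand)
    return pd.Series(24.0 * t, index=f.index, name="doubling_time_h")


def richness_trajectory(
    tables: Sequence[pd.Series], timepoints: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Surviving-barcode counts and per-interval extinction rates.

    ``tables`` are frequency tables ordered in time over a shared barcode
    universe.  Extinction rate for interval (t-1, t] = lineages lost /
    lineages present at t-1.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 timepoints")
    if timepoints is None:
        timepoints = list(range(len(tables)))
    timepoints = list(timepoints)
    if any(b <= a for a, b in zip(timepoints, timepoints[1:])):
        raise ValueError("timepoints must be strictly increasing")
    idx = tables[0].index
    for t in tables[1:]:
        idx = idx.union(t.index)
    present = [t.reindex(idx, fill_value=0.0) > 0 for t in tables]
    rows = []
    for i, (tp, p) in enumerate(zip(timepoints, present)):
        n = int(p.sum())
        if i == 0:
            rate = float("nan")
        else:
            prev = present[i - 1]
            n_prev = int(prev.sum())
            lost = int((prev & ~p).sum())
            rate = lost / n_prev if n_prev else float("nan")
        rows.append({"timepoint": tp, "n_barcodes": n, "extinction_rate": rate})
    return pd.DataFrame(rows)
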