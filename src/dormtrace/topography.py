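"""Awakening topography: classifying confluency time-series.

Each culture well is imaged as a grid of scanning windows (default 3x3)
twice a week for months.  This module detects well-level awakening (the
50%-confluency rule), labels each window as awakening (AW), failed
awakening (FA), dormant (D) or clearance (CLEAR), and classifies each
well's awakening origin as global (GA), localized from one origin (1LA),
localized from several origins (>1LA), or dormant (D).

The study's origin rules were applied by human inspection of image
sequences; every quantitative surrogate here (onset threshold, regression
fraction, simultaneity window, adjacency rule) is an explicit, documented
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

WINDOW_LABELS = ("AW", "FA", "D", "CLEAR")
WELL_CLASSES = ("GA", "1LA", ">1LA", "D")


@dataclass
class TopographyParams:
    """Tunable thresholds of the topography classifier.

    awaken_threshold
        Well-mean confluency (%) defining well awakening (default 50).
    window_onset_threshold
        Rise (%) above a window's baseline that opens a growth episode.
    regression_fraction
        Fractional drop from an episode's peak that closes it as a
        failed awakening.
    clearance_epsilon
        Max confluency (%) below which a window counts as cleared
        ("no cells detected").
    simultaneity_window
        Days within which multiple awakening onsets count as simultaneous
        (global awakening).
    min_confirm_scans
        Consecutive scans required to confirm a threshold crossing
        (suppresses single-scan artifacts at twice-weekly scanning).
    """

    awaken_threshold: float = 50.0
    window_onset_threshold: float = 10.0
    regression_fraction: float = 0.5
    clearance_epsilon: float = 1.0
    simultaneity_window: float = 14.0
    min_confirm_scans: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.regression_fraction <= 1:
            raise ValueError("regression_fraction must be in (0, 1]")
        for name in (
            "awaken_threshold",
            "window_onset_threshold",
            "clearance_epsilon",
            "simultaneity_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Episode:
    onset_day: float
    peak_day: float
    peak_value: float
    end_day: Optional[float]  # collapse day for FA; None while open
    kind: str  # "AW" or "FA"


@dataclass
class WindowLabel:
    well: str
    row: int
    col: int
    label: str  # AW / FA / D / CLEAR
    episodes: list[Episode] = field(default_factory=list)

    @property
    def onset_day(self) -> Optional[float]:
        for ep in self.episodes:
            if ep.kind == self.label:
                return ep.onset_day
        return self.episodes[0].onset_day if self.episodes else None


def _validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    required = {"well", "row", "col", "day", "confluency_pct"}
    if not required <= set(panel.columns):
        missing = required - set(panel.columns)
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    return panel.sort_values(["well", "row", "col", "day"])


def detect_well_awakening(
    panel: pd.DataFrame, params: TopographyParams = TopographyParams()
) -> pd.Series:
    """First day each well's mean confluency reaches the awakening threshold.

    The crossing must hold for ``min_confirm_scans`` consecutive scans;
    wells that never cross get NaN.
    """
    panel = _validate_panel(panel)
    out = {}
    for well, grp in panel.groupby("well"):
        means = grp.groupby("day")["confluency_pct"].mean().sort_index()
        if len(means) < 2:
            raise ValueError(f"well {well} has fewer than 2 scans")
        above = (means.to_numpy() >= params.awaken_threshold).astype(int)
        day = np.nan
        k = params.min_confirm_scans
        for i in range(len(above) - k + 1):
            if above[i : i + k].all():
                day = float(means.index[i])
                break
        out[well] = day
    return pd.Series(out, name="awakening_day")


def _window_episodes(
    days: np.ndarray, conf: np.ndarray, params: TopographyParams
) -> list[Episode]:
    """Open/close growth episodes along one window's scan series."""
    baseline = float(np.median(conf[: min(3, len(conf))]))
    open_level = baseline + params.window_onset_threshold
    episodes: list[Episode] = []
    i = 0
    n = len(days)
    k = params.min_confirm_scans
    while i <= n - k:
        if all(conf[i + j] > open_level for j in range(k)):
            onset = days[i]
            peak_v = conf[i]
            peak_d = days[i]
            j = i
            closed_at = None
            while j < n:
                if conf[j] > peak_v:
                    peak_v, peak_d = conf[j], days[j]
                elif conf[j] < peak_v * (1.0 - params.regression_fraction):
                    closed_at = days[j]
                    break
                j += 1
            kind = "FA" if closed_at is not None else "AW"
            episodes.append(
                Episode(
                    onset_day=float(onset),
                    peak_day=float(peak_d),
                    peak_value=float(peak_v),
                    end_day=float(closed_at) if closed_at is not None else None,
                    kind=kind,
                )
            )
            if closed_at is None:
                break
            # resume after the collapse, waiting until back below open level
            while j < n and conf[j] > open_level:
                j += 1
            i = j
        else:
            i += 1
    return episodes


def label_windows(
    panel: pd.DataFrame, params: TopographyParams = TopographyParams()
) -> list[WindowLabel]:
    """Label each scanning window as AW, FA, D or CLEAR.

    CLEAR if the window never exceeds ``clearance_epsilon``.  Otherwise
    growth episodes are opened when confluency exceeds baseline (median of
    the first 3 scans) + onset threshold for ``min_confirm_scans``
    consecutive scans; an episode that regresses below ``peak * (1 -
    regression_fraction)`` closes as FA, while an episode still elevated
    at the end of the series is AW.  Windows with no episodes are D.  A
    window may accrue several FA episodes; a single AW episode wins the
    window label.
    """
    panel = _validate_panel(panel)
    labels: list[WindowLabel] = []
    for (well, r, c), grp in panel.groupby(["well", "row", "col"]):
        days = grp["day"].to_numpy(dtype=float)
        conf = grp["confluency_pct"].to_numpy(dtype=float)
        if conf.max() < params.clearance_epsilon:
            labels.append(WindowLabel(well, int(r), int(c), "CLEAR"))
            continue
        episodes = _window_episodes(days, conf, params)
        if not episodes:
            label = "D"
        elif any(ep.kind == "AW" for ep in episodes):
            label = "AW"
        else:
            label = "FA"
        labels.append(WindowLabel(well, int(r), int(c), label, episodes))
    return labels


def _rook_adjacent(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1


def _connected_components(
    positions: list[tuple[int, int]]
) -> list[list[tuple[int, int]]]:
    remaining = set(positions)
    comps = []
    while remaining:
        stack = [remaining.pop()]
        comp = []
        while stack:
            p = stack.pop()
            comp.append(p)
            neigh = [q for q in remaining if _rook_adjacent(p, q)]
            for q in neigh:
                remaining.remove(q)
                stack.append(q)
        comps.append(comp)
    return comps


@dataclass
class WellClass:
    well: str
    well_class: str  # GA / 1LA / >1LA / D
    n_aw_windows: int
    n_fa_episodes: int
    first_onset: Optional[float]


def classify_well(
    labels: list[WindowLabel], params: TopographyParams = TopographyParams()
) -> WellClass:
    """Classify one well's awakening origin from its window labels.

    GA: at least 3 awakening windows with onsets inside the simultaneity
    window, spanning non-adjacent grid positions.  1LA: awakening windows
    form a single rook-connected origin (one window, or adjacent windows
    consistent with expansion).  >1LA: two or more non-adjacent origins.
    D: no awakening windows.  When both GA and LA readings are possible,
    GA takes precedence (documented tie-break).
    """
    if not labels:
        raise ValueError("no window labels supplied")
    well = labels[0].well
    aw = [wl for wl in labels if wl.label == "AW"]
    n_fa = sum(
        sum(1 for ep in wl.episodes if ep.kind == "FA") for wl in labels
    )
    if not aw:
        return WellClass(well, "D", 0, n_fa, None)
    onsets = np.array([wl.onset_day for wl in aw], dtype=float)
    first = float(onsets.min())
    positions = [(wl.row, wl.col) for wl in aw]

    simultaneous = [
        p for p, o in zip(positions, onsets) if o <= first + params.simultaneity_window
    ]
    if len(simultaneous) >= 3 and any(
        not _rook_adjacent(a, b) and a != b
        for i, a in enumerate(simultaneous)
        for b in simultaneous[i + 1 :]
    ):
        return WellClass(well, "GA", len(aw), n_fa, first)

    comps = _connected_components(positions)
    cls = "1LA" if len(comps) == 1 else ">1LA"
    return WellClass(well, cls, len(aw), n_fa, first)


def classify_panel(
    panel: pd.DataFrame, params: TopographyParams = TopographyParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label all windows and classify all wells of a confluency panel.

    Returns ``(window_table, well_table)`` DataFrames ready for TSV
    export.
    """
    labels = label_windows(panel, params)
    awakening = detect_well_awakening(panel, params)
    win_rows = [
        {
            "well": wl.well,
            "row": wl.row,
            "col": wl.col,
            "label": wl.label,
            "onset_day": wl.onset_day if wl.label in ("AW", "FA") else np.nan,
        }
        for wl in labels
    ]
    by_well: dict[str, list[WindowLabel]] = {}
    for wl in labels:
        by_well.setdefault(wl.well, []).append(wl)
    well_rows = []
    for well, wls in by_well.items():
        wc = classify_well(wls, params)
        well_rows.append(
            {
                "well": well,
                "well_class": wc.well_class,
                "n_aw_windows": wc.n_aw_windows,
                "n_fa_episodes": wc.n_fa_episodes,
                "first_onset": wc.first_onset,
                "awakening_day": awakening.get(well, np.nan),
            }
        )
    return pd.DataFrame(win_rows), pd.DataFrame(well_rows)


def failed_awakening_count(labels: list[WindowLabel]) -> pd.DataFrame:
    """Per-well FA episode counts with onset/peak/collapse days."""
    rows = []
    for wl in labels:
        for ep in wl.episodes:
            if ep.kind == "FA":
                rows.append(
                    {
                        "well": wl.well,
                        "row": wl.row,
                        "col": wl.col,
                        "onset_day": ep.onset_day,
                        "peak_day": ep.peak_day,
                        "collapse_day": ep.end_day,
                    }
                )
    return pd.DataFrame(
        rows, columns=["well", "row", "col", "onset_day", "peak_day", "collapse_day"]
    )
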