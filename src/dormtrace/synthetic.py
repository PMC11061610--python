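"""Synthetic data generation for the dormancy lineage-tracing pipeline.

Emulates the experimental design of a long-term barcoded lineage-tracing
study of endocrine-therapy-induced dormancy: a founder population ("POT")
of uniquely barcoded cells expanded under heterogeneous replicative
fitness, multinomial splitting into replicate "carbon copies", per-cell
death / dormancy-entry / awakening dynamics under treatment, sequencing
count noise, confluency-scan grids with planted awakening events,
expression matrices with planted dormancy genes, and per-cell barcode-tag
tables with multi-tag and ambient noise.

Every generator takes an explicit seed and emits, alongside the dataset, a
machine-readable truth record sufficient to score the downstream module
that consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

GENERATOR_VERSION = "1.0"

__all__ = [
    "ExpansionModel",
    "TreatmentModel",
    "PotPopulation",
    "TreatmentTrajectory",
    "PlantedEvent",
    "PlantedEventSpec",
    "simulate_pot",
    "split_carbon_copies",
    "simulate_treatment",
    "persister_probability",
    "simulate_sequencing",
    "generate_confluency_panel",
    "make_well_events",
    "generate_expression_dataset",
    "generate_cell_barcode_table",
    "simulate_barcode_reads",
]


# ---------------------------------------------------------------------------
# founder population
# ---------------------------------------------------------------------------


@dataclass
class ExpansionModel:
    """Pre-treatment expansion of the barcoded founder population.

    Defaults mirror the study design: 100,000 founder lineages expanded for
    13 days to ~90 million cells.  ``n_barcodes=100`` is the conventional
    low-complexity setting used for desk-scale dormancy experiments.

    Parameters
    ----------
    n_barcodes : int
        Number of founder lineages (one barcode per founder cell).
    t_expand : float
        Expansion duration in days.
    n_pot : float
        Target population size in cells at harvest.
    doubling_time_mean : float
        Mean per-lineage doubling time in hours.  32 h gives ~9.8
        doublings in 13 days, i.e. a ~900-fold expansion.
    doubling_time_cv : float
        Coefficient of variation of lineage doubling times; heterogeneous
        replicative fitness is what skews the POT frequency distribution.
    """

    n_barcodes: int = 100_000
    t_expand: float = 13.0
    n_pot: float = 9.0e7
    doubling_time_mean: float = 32.0
    doubling_time_cv: float = 0.15
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_barcodes < 1:
            raise ValueError("n_barcodes must be >= 1")
        if self.t_expand <= 0:
            raise ValueError("t_expand must be positive")
        if self.n_pot < self.n_barcodes:
            raise ValueError("n_pot must be >= n_barcodes")
        if self.doubling_time_mean <= 0:
            raise ValueError("doubling_time_mean must be positive")
        if self.doubling_time_cv < 0:
            raise ValueError("doubling_time_cv must be >= 0")


@dataclass
class PotPopulation:
    """Barcode composition of the expanded founder population."""

    barcode_ids: np.ndarray
    frequencies: np.ndarray
    n_cells: float

    def __post_init__(self) -> None:
        self.barcode_ids = np.asarray(self.barcode_ids)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.barcode_ids) != len(self.frequencies):
            raise ValueError("barcode_ids and frequencies length mismatch")
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be non-negative")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1 within 1e-9")


def _barcode_names(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"BC{i:0{width}d}" for i in range(n)])


def simulate_pot(model: ExpansionModel) -> PotPopulation:
    """Expand founder lineages with heterogeneous doubling times.

    Each lineage draws a doubling time from a lognormal distribution with
    arithmetic mean ``doubling_time_mean`` (hours) and coefficient of
    variation ``doubling_time_cv``; lineage *i* contributes
    ``2**(24 * t_expand / dt_i)`` cells.  Frequencies are normalized, so
    only relative fitness matters.  Computation is carried out in log2
    space to avoid overflow at high fitness spread.
    """
    rng = np.random.default_rng(model.seed)
    if model.doubling_time_cv == 0:
        dt = np.full(model.n_barcodes, model.doubling_time_mean)
    else:
        sigma2 = np.log1p(model.doubling_time_cv**2)
        mu = np.log(model.doubling_time_mean) - sigma2 / 2.0
        dt = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=model.n_barcodes)
    log2_cells = 24.0 * model.t_expand / dt
    log2_cells -= log2_cells.max()
    weights = np.exp2(log2_cells)
    freqs = weights / weights.sum()
    return PotPopulation(
        barcode_ids=_barcode_names(model.n_barcodes),
        frequencies=freqs,
        n_cells=model.n_pot,
    )


def split_carbon_copies(
    pot: PotPopulation,
    n_copies: int,
    cells_per_copy: int,
    seed: Optional[int] = None,
) -> list[np.ndarray]:
    """Seed replicate flasks by multinomial sampling from the POT.

    Each copy is an independent multinomial draw of ``cells_per_copy``
    cells with the POT barcode frequencies, so replicates start with
    statistically identical composition.
    """
    if len(pot.frequencies) == 0:
        raise ValueError("cannot split an empty POT")
    if cells_per_copy < 1:
        raise ValueError("cells_per_copy must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        rng.multinomial(cells_per_copy, pot.frequencies) for _ in range(n_copies)
    ]


# ---------------------------------------------------------------------------
# treatment dynamics
# ---------------------------------------------------------------------------


@dataclass
class TreatmentModel:
    """Per-cell daily dynamics under endocrine treatment.

    During the latency window each cycling cell dies with probability
    ``death_prob`` per day or enters dormancy with probability
    ``dormancy_prob`` (the "lottery" parameter: lineage-independent by
    construction); surviving cycling cells keep proliferating with daily
    growth factor ``awakened_growth``.  After latency no new dormancy is
    entered; residual cycling cells continue to die or grow.  Dormant
    cells neither divide nor die; once the latency window has closed and
    dormancy is established they awaken with daily hazard
    ``awaken_hazard``; awakened cells grow at ``awakened_growth`` and are
    no longer drug-sensitive.  Growth of proliferating pools stops at the
    flask carrying ``capacity``.

    Defaults emulate the study's arc at desk scale: a sharp lineage
    bottleneck by day 30 with roughly a third of lineages persisting into
    dormancy when founding clones hold ~16 cells, then single-lineage
    awakenings well before a 150-day horizon.
    """

    death_prob: float = 0.50
    dormancy_prob: float = 0.012
    latency_days: int = 30
    awaken_hazard: float = 1.5e-4
    awakened_growth: float = 1.4
    capacity: float = 1.0e7
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("death_prob", "dormancy_prob", "awaken_hazard"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.death_prob + self.dormancy_prob > 1.0:
            raise ValueError("death_prob + dormancy_prob must be <= 1")
        if self.awakened_growth < 1.0:
            raise ValueError("awakened_growth must be >= 1")
        if self.latency_days < 0:
            raise ValueError("latency_days must be >= 0")


@dataclass
class TreatmentTrajectory:
    """Ground-truth clonal dynamics of one treated replicate."""

    days: np.ndarray
    barcode_ids: np.ndarray
    live_counts: np.ndarray  # (n_barcodes, n_days) cycling + awakened
    dormant_counts: np.ndarray  # (n_barcodes, n_days)
    floating_counts: np.ndarray  # (n_days,) dead cells that day
    awakening_day: Optional[float]
    winner_truth: list[str] = field(default_factory=list)

    def total_viable(self) -> np.ndarray:
        return self.live_counts.sum(axis=0) + self.dormant_counts.sum(axis=0)


def _grow(counts: np.ndarray, factor: float, rng: np.random.Generator) -> np.ndarray:
    """Multiply integer counts by a growth factor with stochastic rounding.

    Exact when ``counts * factor`` is integral; otherwise the fractional
    part becomes one extra cell with matching probability, preserving the
    expectation (a lineage of 1 cell can still grow).
    """
    if factor == 1.0:
        return counts
    scaled = counts * factor
    base = np.floor(scaled)
    frac = scaled - base
    return (base + (rng.random(len(counts)) < frac)).astype(np.int64)


def simulate_treatment(
    copy_counts: np.ndarray,
    model: TreatmentModel,
    horizon_days: int = 150,
    sample_days: Optional[Sequence[int]] = None,
    barcode_ids: Optional[Sequence[str]] = None,
    winner_fraction: float = 0.10,
) -> TreatmentTrajectory:
    """Run daily per-cell stochastic dynamics for one carbon copy.

    A discrete-time Markov chain at daily resolution: binomially-thinned
    death and dormancy entry, binomial awakening, and deterministic
    exponential growth of proliferating pools.  The trajectory is sampled
    at ``sample_days`` (default: every day).

    The awakening day is the first sampled day at which the total viable
    count exceeds twice its post-latency running minimum, sustained for
    three consecutive sampled days.  ``winner_truth`` lists barcodes whose
    awakened descendants make up at least ``winner_fraction`` of the final
    viable population.
    """
    if horizon_days < model.latency_days:
        raise ValueError("horizon_days must be >= latency_days")
    copy_counts = np.asarray(copy_counts, dtype=np.int64)
    n = len(copy_counts)
    if barcode_ids is None:
        barcode_ids = _barcode_names(n)
    barcode_ids = np.asarray(barcode_ids)
    if sample_days is None:
        sample_days = np.arange(horizon_days + 1)
    sample_days = np.asarray(sorted(set(int(d) for d in sample_days)))
    if sample_days.max() > horizon_days or sample_days.min() < 0:
        raise ValueError("sample_days must lie within [0, horizon_days]")

    rng = np.random.default_rng(model.seed)
    cycling = copy_counts.copy()
    dormant = np.zeros(n, dtype=np.int64)
    awakened = np.zeros(n, dtype=np.int64)

    live_out = np.zeros((n, len(sample_days)), dtype=np.int64)
    dorm_out = np.zeros((n, len(sample_days)), dtype=np.int64)
    float_out = np.zeros(len(sample_days), dtype=np.int64)
    sample_index = {d: i for i, d in enumerate(sample_days)}

    if 0 in sample_index:
        live_out[:, 0] = cycling
    dead_today = 0

    for day in range(1, horizon_days + 1):
        deaths = rng.binomial(cycling, model.death_prob)
        remaining = cycling - deaths
        if day <= model.latency_days and model.dormancy_prob > 0:
            p_cond = model.dormancy_prob / (1.0 - model.death_prob)
            entries = rng.binomial(remaining, p_cond)
        else:
            entries = np.zeros(n, dtype=np.int64)
        at_capacity = (
            cycling.sum() + dormant.sum() + awakened.sum()
        ) >= model.capacity
        growth = 1.0 if at_capacity else model.awakened_growth
        cycling = _grow(remaining - entries, growth, rng)
        dormant = dormant + entries
        if model.awaken_hazard > 0 and day > model.latency_days:
            wake = rng.binomial(dormant, model.awaken_hazard)
            dormant = dormant - wake
            awakened = awakened + wake
        awakened = _grow(awakened, growth, rng)
        dead_today = int(deaths.sum())
        if day in sample_index:
            i = sample_index[day]
            live_out[:, i] = cycling + awakened
            dorm_out[:, i] = dormant
            float_out[i] = dead_today

    totals = live_out.sum(axis=0) + dorm_out.sum(axis=0)
    awakening_day = _detect_awakening(sample_days, totals, model.latency_days)

    winners: list[str] = []
    if awakening_day is not None:
        final_awakened = awakened
        total_final = totals[-1]
        if final_awakened.sum() > 0 and total_final > 0:
            frac = final_awakened / total_final
            winners = [str(b) for b in barcode_ids[frac >= winner_fraction]]
        if not winners:
            winners = [str(barcode_ids[np.argmax(live_out[:, -1])])]

    return TreatmentTrajectory(
        days=sample_days,
        barcode_ids=barcode_ids,
        live_counts=live_out,
        dormant_counts=dorm_out,
        floating_counts=float_out,
        awakening_day=awakening_day,
        winner_truth=winners,
    )


def _detect_awakening(
    days: np.ndarray, totals: np.ndarray, latency_days: int
) -> Optional[float]:
    """First sampled day with totals > 2x the post-latency running minimum,
    sustained for >=3 consecutive sampled days."""
    post = days >= latency_days
    if post.sum() < 3:
        return None
    d = days[post]
    t = totals[post].astype(float)
    runmin = np.minimum.accumulate(t)
    flag = t > 2.0 * np.maximum(runmin, 1.0)
    for i in range(len(flag) - 2):
        if flag[i] and flag[i + 1] and flag[i + 2]:
            return float(d[i])
    return None


def persister_probability(model: TreatmentModel) -> float:
    """Closed-form per-cell probability of surviving into dormancy.

    Enumerates the daily per-cell Markov chain over the latency window:
    a cell still cycling on day *t* enters dormancy with probability
    ``dormancy_prob`` having neither died nor entered earlier.  Valid as a
    per-founder-cell compound probability when growth is 1 (no division);
    with division it is a per-cell, not per-lineage, quantity.
    """
    stay = 1.0 - model.death_prob - model.dormancy_prob
    p = 0.0
    surviving = 1.0
    for _ in range(model.latency_days):
        p += surviving * model.dormancy_prob
        surviving *= stay
    return p


# ---------------------------------------------------------------------------
# sequencing noise
# ---------------------------------------------------------------------------


def simulate_sequencing(
    counts: np.ndarray,
    depth: int,
    dispersion: float = 0.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Sample sequencing reads over barcode frequencies.

    Pure multinomial at ``dispersion=0``; Dirichlet-multinomial otherwise,
    with per-barcode concentration ``f_i / dispersion`` so that small
    dispersion recovers the multinomial.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("counts must have positive total")
    rng = np.random.default_rng(seed)
    freqs = counts / counts.sum()
    if depth == 0:
        return np.zeros(len(counts), dtype=np.int64)
    if dispersion == 0:
        return rng.multinomial(depth, freqs)
    alpha = np.where(freqs > 0, freqs / dispersion, 0.0)
    p = np.zeros_like(freqs)
    pos = alpha > 0
    p[pos] = rng.dirichlet(alpha[pos])
    return rng.multinomial(depth, p)


# ---------------------------------------------------------------------------
# confluency panels with planted awakening topography
# ---------------------------------------------------------------------------

EVENT_KINDS = ("AW", "FA", "D", "CLEAR")
WELL_CLASSES = ("GA", "1LA", ">1LA", "D")


@dataclass
class PlantedEvent:
    well: str
    row: int
    col: int
    kind: str  # AW, FA, D, CLEAR
    onset_day: float = 0.0
    peak_day: Optional[float] = None  # FA only

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class PlantedEventSpec:
    """Planted ground truth for a confluency panel.

    Windows not covered by an event default to dormant (flat baseline).
    ``well_classes`` records the intended awakening class per well.
    """

    events: list[PlantedEvent]
    grid_shape: tuple[int, int] = (3, 3)
    horizon_days: float = 150.0
    noise_sd: float = 0.0
    baseline: float = 5.0
    scan_interval: float = 3.5
    well_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for ev in self.events:
            key = (ev.well, ev.row, ev.col)
            if key in seen:
                raise ValueError(f"contradictory events planted in window {key}")
            seen.add(key)
            if not 0 <= ev.onset_day < self.horizon_days:
                raise ValueError("onset_day must lie in [0, horizon_days)")


def _window_series(
    ev: PlantedEvent, days: np.ndarray, baseline: float
) -> np.ndarray:
    if ev.kind == "CLEAR":
        return np.zeros(len(days))
    if ev.kind == "D":
        return np.full(len(days), baseline)
    if ev.kind == "AW":
        # logistic rise from baseline to ~95% over ~20 days after onset
        mid = ev.onset_day + 10.0
        c = baseline + (95.0 - baseline) / (1.0 + np.exp(-(days - mid) / 2.5))
        return np.where(days < ev.onset_day, baseline, c)
    # FA: linear rise to a sub-threshold peak, then regression below baseline
    peak_day = ev.peak_day if ev.peak_day is not None else ev.onset_day + 10.0
    peak_amp = 25.0
    rise_t = max(peak_day - ev.onset_day, 1.0)
    decay_t = rise_t
    c = np.full(len(days), baseline)
    rising = (days >= ev.onset_day) & (days < peak_day)
    c[rising] = baseline + (peak_amp - baseline) * (days[rising] - ev.onset_day) / rise_t
    falling = (days >= peak_day) & (days < peak_day + decay_t)
    c[falling] = peak_amp + (0.4 * baseline - peak_amp) * (
        days[falling] - peak_day
    ) / decay_t
    c[days >= peak_day + decay_t] = 0.4 * baseline
    return c


def generate_confluency_panel(
    spec: PlantedEventSpec, seed: Optional[int] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format confluency scans plus a per-window truth table.

    Returns ``(panel, truth)``: the panel has columns
    ``well,row,col,day,confluency_pct``; the truth table has one row per
    window with its planted label plus the intended well class.
    """
    rng = np.random.default_rng(seed)
    days = np.arange(0.0, spec.horizon_days + 1e-9, spec.scan_interval)
    rows_p, cols_p = spec.grid_shape
    planted = {(ev.well, ev.row, ev.col): ev for ev in spec.events}
    wells = sorted({ev.well for ev in spec.events}) or ["W1"]

    records = []
    truth_records = []
    for well in wells:
        for r in range(rows_p):
            for c in range(cols_p):
                ev = planted.get(
                    (well, r, c), PlantedEvent(well, r, c, "D", onset_day=0.0)
                )
                series = _window_series(ev, days, spec.baseline)
                if spec.noise_sd > 0:
                    # measurement noise scales with occupancy: an empty
                    # (cleared) window images as ~0 with only trace jitter
                    sd_eff = spec.noise_sd * np.clip(
                        series / spec.baseline, 0.05, 1.0
                    )
                    series = series + rng.normal(0.0, 1.0, len(days)) * sd_eff
                series = np.clip(series, 0.0, 100.0)
                for d, v in zip(days, series):
                    records.append((well, r, c, d, v))
                truth_records.append(
                    {
                        "well": well,
                        "row": r,
                        "col": c,
                        "label": ev.kind,
                        "onset_day": ev.onset_day if ev.kind in ("AW", "FA") else np.nan,
                        "well_class": spec.well_classes.get(well, ""),
                    }
                )
    panel = pd.DataFrame(
        records, columns=["well", "row", "col", "day", "confluency_pct"]
    )
    truth = pd.DataFrame(truth_records)
    return panel, truth


def make_well_events(
    well: str,
    well_class: str,
    rng: np.random.Generator,
    grid_shape: tuple[int, int] = (3, 3),
    horizon_days: float = 150.0,
    n_fa: int = 0,
    n_clear: int = 0,
) -> tuple[list[PlantedEvent], str]:
    """Plant window events realizing a desired awakening class for one well.

    ``1LA``: one awakening window; ``>1LA``: two non-adjacent awakening
    origins with onsets >= 25 days apart; ``GA``: every window awakens
    within a 7-day span; ``D``: no awakening.  ``n_fa`` failed-awakening
    and ``n_clear`` cleared windows are planted into remaining free
    positions.  Returns the events and the class (= the truth label).
    """
    if well_class not in WELL_CLASSES:
        raise ValueError(f"unknown well class {well_class!r}")
    rows_n, cols_n = grid_shape
    positions = [(r, c) for r in range(rows_n) for c in range(cols_n)]
    events: list[PlantedEvent] = []
    onset_lo, onset_hi = 40.0, horizon_days - 45.0

    def fa_positions(k: int, exclude: set) -> list[tuple[int, int]]:
        free = [p for p in positions if p not in exclude]
        idx = rng.choice(len(free), size=min(k, len(free)), replace=False)
        return [free[i] for i in np.atleast_1d(idx)]

    if well_class == "1LA":
        r, c = positions[rng.integers(len(positions))]
        onset = rng.uniform(onset_lo, onset_hi)
        events.append(PlantedEvent(well, r, c, "AW", onset_day=onset))
        used = {(r, c)}
    elif well_class == ">1LA":
        corners = [(0, 0), (0, cols_n - 1), (rows_n - 1, 0), (rows_n - 1, cols_n - 1)]
        i, j = rng.choice(4, size=2, replace=False)
        onset = rng.uniform(onset_lo, onset_hi - 30.0)
        events.append(PlantedEvent(well, *corners[i], "AW", onset_day=onset))
        events.append(PlantedEvent(well, *corners[j], "AW", onset_day=onset + 25.0))
        used = {corners[i], corners[j]}
    elif well_class == "GA":
        base = rng.uniform(onset_lo, onset_hi)
        for r, c in positions:
            events.append(
                PlantedEvent(well, r, c, "AW", onset_day=base + rng.uniform(0.0, 7.0))
            )
        used = set(positions)
    else:  # D
        used = set()

    for r, c in fa_positions(n_fa, used):
        used.add((r, c))
        onset = rng.uniform(20.0, horizon_days - 30.0)
        events.append(PlantedEvent(well, r, c, "FA", onset_day=onset))
    for r, c in fa_positions(n_clear, used):
        used.add((r, c))
        events.append(PlantedEvent(well, r, c, "CLEAR"))
    return events, well_class


# ---------------------------------------------------------------------------
# expression matrices with planted dormancy genes
# ---------------------------------------------------------------------------


def generate_expression_dataset(
    n_genes: int,
    n_pot: int,
    n_dormancy: int,
    n_other: int,
    planted_up: Sequence[str],
    planted_down: Sequence[str],
    effect_size: float,
    sigma: float = 0.5,
    seed: Optional[int] = None,
) -> dict:
    """Normalized expression with planted dormancy-up/down genes.

    Background gene *g* is Normal(mu_g, sigma) across all samples; planted
    up (down) genes are shifted by +effect_size (-effect_size) log2 units
    in dormancy samples.  The DE table carries the observed dormancy-vs-POT
    mean shift as log2fc, a two-sample t p-value, and BH-adjusted padj.

    Returns a dict with ``expr`` (genes x samples), ``de`` (gene, log2fc,
    pvalue, padj), ``annotations`` (sample, group) and ``truth``.
    """
    planted_up = list(planted_up)
    planted_down = list(planted_down)
    if set(planted_up) & set(planted_down):
        raise ValueError("planted up and down gene sets must be disjoint")
    if n_dormancy < 6:
        raise ValueError("need at least 6 dormancy samples")
    rng = np.random.default_rng(seed)

    width = max(4, len(str(n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]
    for g in planted_up + planted_down:
        if g not in set(genes):
            raise ValueError(f"planted gene {g} outside the gene universe")
    samples = (
        [f"POT_{i+1}" for i in range(n_pot)]
        + [f"DORM_{i+1}" for i in range(n_dormancy)]
        + [f"OTH_{i+1}" for i in range(n_other)]
    )
    groups = ["POT"] * n_pot + ["dormancy"] * n_dormancy + ["other"] * n_other

    mu = rng.uniform(3.0, 12.0, n_genes)
    mat = rng.normal(mu[:, None], sigma, size=(n_genes, len(samples)))
    gene_index = {g: i for i, g in enumerate(genes)}
    dorm_cols = np.array([g == "dormancy" for g in groups])
    for g in planted_up:
        mat[gene_index[g], dorm_cols] += effect_size
    for g in planted_down:
        mat[gene_index[g], dorm_cols] -= effect_size

    expr = pd.DataFrame(mat, index=genes, columns=samples)
    pot_cols = np.array([g == "POT" for g in groups])
    from scipy import stats as _stats

    log2fc = mat[:, dorm_cols].mean(axis=1) - mat[:, pot_cols].mean(axis=1)
    tstat, pvals = _stats.ttest_ind(
        mat[:, dorm_cols], mat[:, pot_cols], axis=1, equal_var=False
    )
    from statsmodels.stats.multitest import multipletests

    padj = multipletests(pvals, method="fdr_bh")[1]
    de = pd.DataFrame(
        {"gene": genes, "log2fc": log2fc, "pvalue": pvals, "padj": padj}
    )
    annotations = pd.DataFrame({"sample": samples, "group": groups})
    return {
        "expr": expr,
        "de": de,
        "annotations": annotations,
        "truth": {"up": planted_up, "down": planted_down},
    }


# ---------------------------------------------------------------------------
# per-cell barcode tags
# ---------------------------------------------------------------------------


def generate_cell_barcode_table(
    n_cells: int,
    frequencies: np.ndarray,
    multi_tag_rate: float = 0.0,
    ambient_rate: float = 0.0,
    mean_reads: float = 20.0,
    seed: Optional[int] = None,
) -> dict:
    """Per-cell lineage-tag read counts with multi-tag and ambient noise.

    Each cell integrates one true barcode drawn by frequency, with reads
    ~ 1 + Poisson(mean_reads - 1).  With probability ``multi_tag_rate`` a
    second genuinely integrated barcode of comparable reads is added; with
    probability ``ambient_rate`` a spurious low-count (1-2 read) tag is
    added.

    Returns a dict with ``tags`` (cell_id, barcode_id, reads), ``qc``
    (cell_id, n_features, pct_mito) and ``truth`` (cell_id, true_barcode).
    """
    frequencies = np.asarray(frequencies, dtype=float)
    if len(frequencies) == 0:
        raise ValueError("frequencies must be non-empty")
    if not (0 <= multi_tag_rate <= 1 and 0 <= ambient_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    freqs = frequencies / frequencies.sum()
    rng = np.random.default_rng(seed)
    n_bc = len(freqs)
    barcodes = _barcode_names(n_bc)

    width = max(4, len(str(n_cells)))
    rows = []
    truth_rows = []
    true_idx = rng.choice(n_bc, size=n_cells, p=freqs)
    for i in range(n_cells):
        cell = f"CELL_{i:0{width}d}"
        bi = true_idx[i]
        reads = 1 + rng.poisson(max(mean_reads - 1.0, 0.0))
        rows.append((cell, barcodes[bi], int(reads)))
        truth_rows.append((cell, barcodes[bi]))
        if n_bc > 1 and rng.random() < multi_tag_rate:
            other = int(rng.integers(n_bc - 1))
            other = other if other < bi else other + 1
            reads2 = 1 + rng.poisson(max(mean_reads - 1.0, 0.0))
            rows.append((cell, barcodes[other], int(reads2)))
        if n_bc > 1 and rng.random() < ambient_rate:
            amb = int(rng.integers(n_bc - 1))
            amb = amb if amb < bi else amb + 1
            rows.append((cell, barcodes[amb], int(rng.integers(1, 3))))
    tags = (
        pd.DataFrame(rows, columns=["cell_id", "barcode_id", "reads"])
        .groupby(["cell_id", "barcode_id"], as_index=False)["reads"]
        .sum()
    )
    qc = pd.DataFrame(
        {
            "cell_id": [f"CELL_{i:0{width}d}" for i in range(n_cells)],
            "n_features": np.clip(
                rng.normal(3000, 600, n_cells).round().astype(int), 300, None
            ),
            "pct_mito": np.clip(rng.normal(5.0, 3.0, n_cells), 0.0, 19.0),
        }
    )
    truth = pd.DataFrame(truth_rows, columns=["cell_id", "true_barcode"])
    return {"tags": tags, "qc": qc, "truth": truth}


# ---------------------------------------------------------------------------
# raw barcode reads (FASTQ-level)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_barcode_reads(
    library: pd.DataFrame,
    counts: np.ndarray,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: Optional[int] = None,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Generate reads embedding library barcodes with per-base errors.

    ``library`` needs columns ``barcode_id, sequence``.  Each read places
    its barcode at a random offset inside random flanking sequence and
    applies uniform substitution errors at ``error_rate``.  Returns
    ``(reads, truth)`` where reads are ``(read_id, sequence)`` pairs and
    truth holds the source barcode index per read.
    """
    rng = np.random.default_rng(seed)
    seqs = library["sequence"].to_numpy()
    bc_len = len(seqs[0])
    if read_length < bc_len:
        raise ValueError("read_length must be >= barcode length")
    counts = np.asarray(counts, dtype=int)
    reads = []
    truth = np.repeat(np.arange(len(seqs)), counts)
    rng.shuffle(truth)
    for ridx, bi in enumerate(truth):
        flank_n = read_length - bc_len
        offset = int(rng.integers(flank_n + 1))
        left = "".join(rng.choice(_BASES, offset))
        right = "".join(rng.choice(_BASES, flank_n - offset))
        seq = np.array(list(left + seqs[bi] + right))
        if error_rate > 0:
            err = rng.random(read_length) < error_rate
            if err.any():
                seq[err] = rng.choice(_BASES, err.sum())
        reads.append((f"read_{ridx}", "".join(seq)))
    return reads, truth


def random_barcode_library(
    n_barcodes: int, length: int = 48, seed: Optional[int] = None
) -> pd.DataFrame:
    """A random barcode library (unique fixed-length DNA tags)."""
    rng = np.random.default_rng(seed)
    seen = set()
    seqs = []
    while len(seqs) < n_barcodes:
        s = "".join(rng.choice(_BASES, length))
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return pd.DataFrame(
        {"barcode_id": _barcode_names(n_barcodes), "sequence": seqs}
    )
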