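"""The dormancy-lottery null model and goodness-of-fit test.

The null model says every cell, regardless of lineage, has the same
probability of surviving into the dormant persister pool ("dormancy
lottery").  Under it, the probability that a lineage with initial
frequency *f* is still detected after a population-wide bottleneck to
``round(N*s)`` cells is the closed form ``1 - (1-f)**round(N*s)``.

The module simulates lineage survival across replicate instances from an
empirical founder (POT) frequency distribution with survival ratios drawn
from a truncated normal, and tests observed per-well barcode presence
against the model with a chi-square statistic calibrated by Monte-Carlo
parametric bootstrap.  The original study made this comparison visually;
the formal test is this package's own construction and its output is
labelled accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class LotteryConfig:
    """Configuration of the lottery simulation.

    ``n_pot`` is the population size N at treatment onset, ``n_barcodes``
    the number of lineages simulated per instance, ``n_instances`` the
    number of replicate instances K (20 for a quick look, 1000 for the
    full run), and ``ratio_mean``/``ratio_sd`` the parameters of the
    survival-ratio distribution (truncated to [0, 1]).
    """

    n_pot: int = 100_000
    n_barcodes: int = 100
    n_instances: int = 1000
    ratio_mean: float = 0.001
    ratio_sd: float = 0.0005
    renormalize: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.n_pot >= self.n_barcodes >= 1:
            raise ValueError("need n_pot >= n_barcodes >= 1")
        if self.n_instances < 1:
            raise ValueError("n_instances must be >= 1")
        if not 0.0 <= self.ratio_mean <= 1.0:
            raise ValueError("ratio_mean must be in [0, 1]")
        if self.ratio_sd < 0:
            raise ValueError("ratio_sd must be >= 0")


@dataclass
class LotteryResult:
    """Per-barcode, per-instance outcome of the lottery simulation."""

    frequencies: np.ndarray  # (B, K) initial frequencies f_ik
    initial_counts: np.ndarray  # (B, K) c0_ik ~ Binomial(N, f)
    month1_counts: np.ndarray  # (B, K) c1_ik ~ Binomial(round(N*s_k), f)
    survival_ratios: np.ndarray  # (K,) sampled s_k
    surviving_instances: np.ndarray = field(init=False)  # (B,) k_i

    def __post_init__(self) -> None:
        self.surviving_instances = (self.month1_counts > 0).sum(axis=1)


def _sample_truncnorm(
    mu: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal(mu, sd) truncated to [0, 1] (deterministic when sd == 0)."""
    if sd == 0:
        return np.full(size, mu)
    a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def analytic_survival_prob(f: float, n_pot: float, s: float) -> float:
    """Closed-form lineage survival probability under the lottery.

    P(at least one of the lineage's cells survives a bottleneck to
    round(N*s) cells) = 1 - (1-f)**round(N*s), with round-half-to-even;
    N*s < 1 rounds to a degenerate bottleneck of 0 cells (certain
    extinction).
    """
    m = int(np.round(n_pot * s))
    return float(1.0 - (1.0 - f) ** m)


def observed_survival_ratios(
    pot_counts: pd.Series,
    well_counts: list[pd.Series],
    min_reads: int = 3,
) -> tuple[np.ndarray, float, float]:
    """Per-well barcode survival ratios relative to the POT.

    ratio_w = (# barcodes with >= min_reads reads in well w) /
    (# barcodes with >= min_reads reads in the POT).  Returns the ratio
    vector, its mean and its sample standard deviation.
    """
    if len(well_counts) < 2:
        raise ValueError("need at least 2 wells")
    pot_observed = pot_counts[pot_counts >= min_reads].index
    if len(pot_observed) == 0:
        raise ValueError("POT has no observed barcodes")
    ratios = np.array(
        [
            (w.reindex(pot_observed, fill_value=0) >= min_reads).sum()
            / len(pot_observed)
            for w in well_counts
        ],
        dtype=float,
    )
    return ratios, float(ratios.mean()), float(ratios.std(ddof=1))


def simulate_lottery(
    pot_frequencies: np.ndarray, config: LotteryConfig
) -> LotteryResult:
    """Simulate lineage survival through the dormancy bottleneck.

    Per instance k: a survival ratio s_k is drawn from the truncated
    normal; initial frequencies are resampled with replacement from the
    empirical POT frequency distribution (renormalized across the drawn
    barcodes by default); initial counts c0 ~ Binomial(N, f) and month-1
    counts c1 ~ Binomial(round(N*s_k), f).  A barcode survives an instance
    when c1 > 0.
    """
    pot_frequencies = np.asarray(pot_frequencies, dtype=float)
    pot_frequencies = pot_frequencies[pot_frequencies > 0]
    if len(pot_frequencies) == 0:
        raise ValueError("POT frequency distribution is degenerate")
    rng = np.random.default_rng(config.seed)
    B, K, N = config.n_barcodes, config.n_instances, config.n_pot

    s = _sample_truncnorm(config.ratio_mean, config.ratio_sd, K, rng)
    f = rng.choice(pot_frequencies, size=(B, K), replace=True)
    if config.renormalize:
        f = f / f.sum(axis=0, keepdims=True)
    c0 = rng.binomial(N, f)
    reduced = np.round(N * s).astype(np.int64)  # round-half-to-even
    c1 = rng.binomial(reduced[None, :], f)
    return LotteryResult(
        frequencies=f, initial_counts=c0, month1_counts=c1, survival_ratios=s
    )


# ---------------------------------------------------------------------------
# fitting observed well presence against the lottery model
# ---------------------------------------------------------------------------


def invert_survival_ratio(
    ratio: float, frequencies: np.ndarray, n_pot: float
) -> float:
    """Per-cell survival probability implied by a barcode survival ratio.

    The observed ratio is a barcode-level quantity, r(s) = mean_i
    [1 - (1-f_i)**(N*s)], not the per-cell survival s itself; this solves
    r(s) = ratio for s by bisection on the (monotone) continuous
    relaxation.  Ratios at or beyond the achievable range clip to the
    boundary.
    """
    f = np.asarray(frequencies, dtype=float)
    f = f[f > 0]

    def g(s: float) -> float:
        return float(np.mean(-np.expm1(np.log1p(-f) * n_pot * s))) - ratio

    if ratio <= 0:
        return 0.0
    if g(1.0) <= 0:
        return 1.0
    return float(optimize.brentq(g, 0.0, 1.0, xtol=1e-12))


def simulate_well_presence(
    initial_counts: np.ndarray,
    n_wells: int,
    mu_s: float,
    sd_s: float,
    n_pot: float,
    selection_mask: Optional[np.ndarray] = None,
    selection_factor: float = 1.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Generate a (B, W) presence matrix under lottery or selection.

    Per well a survival probability s_w is drawn from the truncated
    normal; lineage i with c_i cells is present with probability
    1 - (1-s_w)**c_i.  With a selection mask, masked lineages use
    min(selection_factor * s_w, 1) — the "some lineages are poised to
    enter dormancy" alternative.
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(initial_counts, dtype=float)
    s = _sample_truncnorm(mu_s, sd_s, n_wells, rng)
    s_mat = np.tile(s, (len(c), 1))
    if selection_mask is not None:
        s_mat[np.asarray(selection_mask, bool), :] = np.minimum(
            selection_factor * s, 1.0
        )
    p = -np.expm1(np.log1p(-np.minimum(s_mat, 1.0 - 1e-12)) * c[:, None])
    return (rng.random(p.shape) < p).astype(np.int8)


def _log_bins(c: np.ndarray, n_bins: int, min_per_bin: int = 5) -> np.ndarray:
    """Log-spaced bin index per barcode, small bins collapsed into neighbors."""
    c = np.asarray(c, dtype=float)
    pos = c[c > 0]
    lo, hi = pos.min(), pos.max()
    if hi <= lo:
        return np.zeros(len(c), dtype=int)
    edges = np.geomspace(lo, hi, n_bins + 1)
    edges[0], edges[-1] = lo * 0.999, hi * 1.001
    idx = np.clip(np.digitize(c, edges) - 1, 0, n_bins - 1)
    idx[c <= 0] = 0
    # collapse under-filled bins leftwards
    remap = {}
    cur = 0
    for b in range(n_bins):
        size = int((idx == b).sum())
        if b > 0 and size < min_per_bin:
            remap[b] = remap.get(b - 1, b - 1)
        else:
            remap[b] = b
            cur = b
    idx = np.array([remap[b] for b in idx])
    # relabel contiguously
    uniq = np.unique(idx)
    relabel = {u: i for i, u in enumerate(uniq)}
    return np.array([relabel[b] for b in idx])


@dataclass
class LotteryFitReport:
    """Goodness-of-fit of observed well presence to the lottery model."""

    statistic: float
    p_value: float
    verdict: str  # "consistent" | "inconsistent"
    alpha: float
    per_bin: pd.DataFrame
    mu_s: float
    sd_s: float


def lottery_fit(
    initial_counts: np.ndarray,
    presence: np.ndarray,
    n_pot: float,
    n_mc: int = 199,
    n_bins: int = 5,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> LotteryFitReport:
    """Test observed per-barcode well presence against the lottery null.

    ``presence`` is the observed (B, W) 0/1 matrix of barcode detection
    across wells.  The per-cell survival distribution is fitted from the
    data (each well's barcode survival ratio inverted to a per-cell
    probability, then mean/sd taken), lineages are binned by initial cell
    count (log-spaced), and a chi-square-style statistic combines the
    standardized deviations of per-bin presence totals and per-bin
    presence variances from their Monte-Carlo null expectations.  The
    p-value is a parametric bootstrap over ``n_mc`` replicate datasets.
    """
    c = np.asarray(initial_counts, dtype=float)
    presence = np.asarray(presence)
    if presence.ndim != 2 or presence.shape[0] != len(c):
        raise ValueError("presence must be a (n_barcodes, n_wells) matrix")
    n_wells = presence.shape[1]
    if n_wells < 2:
        raise ValueError("need at least 2 wells")
    w = presence.sum(axis=1).astype(float)
    rng = np.random.default_rng(seed)
    f = np.maximum(c, 0.0) / n_pot

    # fit the per-cell survival distribution: invert each well's barcode
    # survival ratio to the per-cell probability it implies
    ratios = presence.mean(axis=0)
    s_wells = np.array([invert_survival_ratio(r, f, n_pot) for r in ratios])
    s_hat = float(s_wells.mean())
    sd_hat = float(s_wells.std(ddof=1))

    bins = _log_bins(c, n_bins)
    n_b = bins.max() + 1

    def bin_stats(wvec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        totals = np.array([wvec[bins == b].sum() for b in range(n_b)])
        variances = np.array(
            [wvec[bins == b].var(ddof=0) if (bins == b).sum() > 1 else 0.0 for b in range(n_b)]
        )
        return totals, variances

    def simulate_null(k: int) -> np.ndarray:
        pres = simulate_well_presence(
            c, n_wells, s_hat, sd_hat, n_pot, seed=rng.integers(2**31)
        )
        return pres.sum(axis=1).astype(float)

    null_T = np.empty((n_mc, n_b))
    null_V = np.empty((n_mc, n_b))
    for k in range(n_mc):
        wk = simulate_null(k)
        null_T[k], null_V[k] = bin_stats(wk)

    E_T, S_T = null_T.mean(axis=0), null_T.std(axis=0, ddof=1)
    E_V, S_V = null_V.mean(axis=0), null_V.std(axis=0, ddof=1)
    S_T = np.where(S_T > 0, S_T, 1.0)
    S_V = np.where(S_V > 0, S_V, 1.0)

    def statistic(totals: np.ndarray, variances: np.ndarray) -> float:
        zt = (totals - E_T) / S_T
        zv = (variances - E_V) / S_V
        return float((zt**2).sum() + (zv**2).sum())

    obs_T, obs_V = bin_stats(w)
    S_obs = statistic(obs_T, obs_V)
    S_null = np.array([statistic(null_T[k], null_V[k]) for k in range(n_mc)])
    p = float((1 + (S_null >= S_obs).sum()) / (n_mc + 1))
    verdict = "consistent" if p >= alpha else "inconsistent"

    per_bin = pd.DataFrame(
        {
            "bin": np.arange(n_b),
            "n_barcodes": [int((bins == b).sum()) for b in range(n_b)],
            "observed_presence": obs_T,
            "expected_presence": E_T,
            "observed_variance": obs_V,
            "expected_variance": E_V,
        }
    )
    return LotteryFitReport(
        statistic=S_obs,
        p_value=p,
        verdict=verdict,
        alpha=alpha,
        per_bin=per_bin,
        mu_s=s_hat,
        sd_s=sd_hat,
    )
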