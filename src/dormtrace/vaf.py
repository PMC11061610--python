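"""Longitudinal variant-allele-frequency (VAF) analysis.

VAF computation from per-sample ref/alt depths, Fisher-exact testing of
VAF change across samples, presence/absence classification against the
founder (POT) samples for phylogeny input, germline removal against a
matched normal, and the targeted-panel filter chain for patient variants
(depth, read-orientation support, allele frequency, consequence
severity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONSEQUENCE_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
VARIANT_KEY = ["chrom", "pos", "ref", "alt"]


def compute_vaf(alt_depth: np.ndarray, ref_depth: np.ndarray) -> np.ndarray:
    """VAF = alt / (alt + ref); zero total depth yields NaN (indeterminate)."""
    alt = np.asarray(alt_depth, dtype=float)
    ref = np.asarray(ref_depth, dtype=float)
    if np.any(alt < 0) or np.any(ref < 0):
        raise ValueError("depths must be non-negative")
    total = alt + ref
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(total > 0, alt / np.where(total > 0, total, 1.0), np.nan)
    return vaf


def vaf_table(
    table: pd.DataFrame, samples: Sequence[str]
) -> pd.DataFrame:
    """Per-variant VAF for each sample from ``{s}_alt`` / ``{s}_ref`` columns."""
    out = {}
    for s in samples:
        alt_c, ref_c = f"{s}_alt", f"{s}_ref"
        if alt_c not in table.columns or ref_c not in table.columns:
            raise ValueError(f"missing depth columns for sample {s}")
        out[s] = compute_vaf(table[alt_c].to_numpy(), table[ref_c].to_numpy())
    return pd.DataFrame(out, index=table.index)


# ---------------------------------------------------------------------------
# VAF change testing
# ---------------------------------------------------------------------------


def _montecarlo_fisher(
    alt: np.ndarray, ref: np.ndarray, n_mc: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo exact conditional test on a 2 x k depth table.

    Conditions on all margins: random tables are drawn by sequential
    multivariate-hypergeometric column fills, ordered by the Pearson
    chi-square statistic.
    """
    k = len(alt)
    col_tot = alt + ref
    alt_tot = int(alt.sum())
    n_tot = int(col_tot.sum())
    if alt_tot == 0 or alt_tot == n_tot:
        return 1.0

    def chi2(a: np.ndarray) -> float:
        e_alt = col_tot * alt_tot / n_tot
        e_ref = col_tot - e_alt
        with np.errstate(invalid="ignore", divide="ignore"):
            t1 = np.where(e_alt > 0, (a - e_alt) ** 2 / e_alt, 0.0)
            t2 = np.where(e_ref > 0, ((col_tot - a) - e_ref) ** 2 / e_ref, 0.0)
        return float(t1.sum() + t2.sum())

    obs = chi2(alt.astype(float))
    count = 0
    for _ in range(n_mc):
        remaining = alt_tot
        pool = n_tot
        a_sim = np.zeros(k)
        for j in range(k - 1):
            a_sim[j] = rng.hypergeometric(remaining, pool - remaining, col_tot[j])
            remaining -= int(a_sim[j])
            pool -= int(col_tot[j])
        a_sim[k - 1] = remaining
        if chi2(a_sim) >= obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_mc)


def test_vaf_change(
    alt_depths: Sequence[int],
    ref_depths: Sequence[int],
    method: str = "pairwise-min",
    alpha: float = 0.01,
    n_mc: int = 2000,
    seed: Optional[int] = None,
) -> tuple[float, bool]:
    """Fisher-exact test for VAF change of one variant across samples.

    Two samples: the exact Fisher test on the 2x2 (alt, ref) x sample
    table.  More samples: either the minimum Bonferroni-adjusted pairwise
    Fisher p ("pairwise-min", conservative) or a Monte-Carlo exact
    conditional test on the full 2 x k table ("montecarlo").  Returns
    ``(p_value, changed)`` with ``changed = p < alpha``.
    """
    alt = np.asarray(alt_depths, dtype=np.int64)
    ref = np.asarray(ref_depths, dtype=np.int64)
    if len(alt) < 2:
        raise ValueError("need at least 2 samples")
    totals = alt + ref
    ok = totals > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 samples with nonzero depth")
    alt, ref = alt[ok], ref[ok]
    k = len(alt)
    if k == 2:
        p = float(stats.fisher_exact([[alt[0], ref[0]], [alt[1], ref[1]]])[1])
    elif method == "pairwise-min":
        n_pairs = k * (k - 1) // 2
        p = 1.0
        for i in range(k):
            for j in range(i + 1, k):
                pij = stats.fisher_exact(
                    [[alt[i], ref[i]], [alt[j], ref[j]]]
                )[1]
                p = min(p, min(1.0, pij * n_pairs))
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        p = _montecarlo_fisher(alt, ref, n_mc, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    return p, bool(p < alpha)


def changed_variants(
    table: pd.DataFrame,
    samples: Sequence[str],
    method: str = "pairwise-min",
    alpha: float = 0.01,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-variant VAF-change p-values and flags across ``samples``."""
    pvals = []
    flags = []
    for _, row in table.iterrows():
        alt = [row[f"{s}_alt"] for s in samples]
        ref = [row[f"{s}_ref"] for s in samples]
        p, changed = test_vaf_change(alt, ref, method=method, alpha=alpha, seed=seed)
        pvals.append(p)
        flags.append(changed)
    out = table.copy()
    out["p_value"] = pvals
    out["changed"] = flags
    return out


# ---------------------------------------------------------------------------
# presence / absence classification
# ---------------------------------------------------------------------------


def classify_presence(
    vafs: pd.DataFrame,
    pot_samples: Sequence[str],
    absent_threshold: float = 0.05,
    present_threshold: float = 0.10,
    min_support_reads: int = 1,
    alt_depths: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Presence matrix for phylogeny input.

    A variant is flagged POT-absent when its mean VAF over the POT
    samples is strictly below ``absent_threshold``.  Per non-POT sample:
    "present" when VAF strictly exceeds ``present_threshold``, "absent"
    when VAF is 0, otherwise "indeterminate" (including zero-depth
    entries).  When alt depths are supplied, variants lacking
    ``min_support_reads`` in every non-POT sample are dropped.
    """
    pot_samples = list(pot_samples)
    if not pot_samples:
        raise ValueError("POT sample set must be non-empty")
    missing = [s for s in pot_samples if s not in vafs.columns]
    if missing:
        raise ValueError(f"POT samples not in VAF table: {missing}")
    other = [s for s in vafs.columns if s not in pot_samples]
    pot_absent = vafs[pot_samples].mean(axis=1) < absent_threshold

    status = pd.DataFrame(index=vafs.index, columns=other, dtype=object)
    for s in other:
        v = vafs[s]
        status[s] = np.select(
            [v > present_threshold, v == 0],
            ["present", "absent"],
            default="indeterminate",
        )
        status.loc[v.isna(), s] = "indeterminate"
    status["pot_absent"] = pot_absent
    if alt_depths is not None and other:
        support = alt_depths[other].max(axis=1) >= min_support_reads
        status = status.loc[support]
    return status


def drop_germline(
    table: pd.DataFrame,
    normal_sample: str,
    vaf_threshold: float = 0.1,
) -> pd.DataFrame:
    """Remove presumptive germline variants using a matched normal.

    Variants with normal-sample VAF strictly above ``vaf_threshold`` are
    dropped; variants with zero normal depth are kept with a warning
    (indeterminate normal).
    """
    alt_c, ref_c = f"{normal_sample}_alt", f"{normal_sample}_ref"
    if alt_c not in table.columns or ref_c not in table.columns:
        raise ValueError(f"normal sample {normal_sample} not in table")
    vaf = compute_vaf(table[alt_c].to_numpy(), table[ref_c].to_numpy())
    indeterminate = np.isnan(vaf)
    if indeterminate.any():
        logger.warning(
            "%d variants have zero depth in the matched normal; kept",
            int(indeterminate.sum()),
        )
    keep = ~(vaf > vaf_threshold)
    return table.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# patient-panel filter chain
# ---------------------------------------------------------------------------


@dataclass
class FilterAttrition:
    """Per-filter attrition of the patient-panel chain (order is fixed)."""

    n_input: int
    after_depth: int
    after_orientation: int
    after_vaf: int
    after_consequence: int

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "depth_ge_20": self.after_depth,
            "orientation_ge_4": self.after_orientation,
            "vaf_ge_0.1": self.after_vaf,
            "consequence_moderate_high": self.after_consequence,
        }


def filter_patient_variants(
    table: pd.DataFrame,
    min_depth: int = 20,
    min_orientation_support: int = 4,
    min_vaf: float = 0.1,
    consequences: Sequence[str] = ("MODERATE", "HIGH"),
    fathmm_threshold: Optional[float] = None,
) -> tuple[pd.DataFrame, FilterAttrition]:
    """Sequential targeted-panel filters for patient variants.

    In order: total allele depth (ref+alt) >= 20 reads; alternate-allele
    read-pair orientation support F1R2 + F2R1 >= 4; allele frequency
    >= 0.1; consequence level MODERATE or HIGH.  An optional FATHMM
    score cut (> threshold) applies when scores are supplied.  Returns
    the surviving variants and the per-filter attrition counts.
    """
    for col in ("ref_depth", "alt_depth", "f1r2_alt", "f2r1_alt", "consequence_level"):
        if col not in table.columns:
            raise ValueError(f"missing required column: {col}")
    t = table
    n0 = len(t)
    t = t[(t["ref_depth"] + t["alt_depth"]) >= min_depth]
    n1 = len(t)
    t = t[(t["f1r2_alt"] + t["f2r1_alt"]) >= min_orientation_support]
    n2 = len(t)
    vaf = compute_vaf(t["alt_depth"].to_numpy(), t["ref_depth"].to_numpy())
    t = t[vaf >= min_vaf]
    n3 = len(t)
    t = t[t["consequence_level"].isin(list(consequences))]
    n4 = len(t)
    if fathmm_threshold is not None:
        if "fathmm_score" not in t.columns:
            raise ValueError("missing required column: fathmm_score")
        t = t[t["fathmm_score"] > fathmm_threshold]
    attrition = FilterAttrition(
        n_input=n0,
        after_depth=n1,
        after_orientation=n2,
        after_vaf=n3,
        after_consequence=n4,
    )
    return t.reset_index(drop=True), attrition


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------


def read_vcf(path: str) -> pd.DataFrame:
    """Read per-sample AD depths from a VCF into the canonical wide table.

    Produces one row per (chrom, pos, ref, alt) with ``{sample}_ref`` and
    ``{sample}_alt`` columns taken from the AD format field.  Coordinates
    stay 1-based as in VCF.
    """
    import pysam

    rows = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            for ai, alt in enumerate(rec.alts or ()):
                row = {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                }
                for s in samples:
                    ad = rec.samples[s].get("AD")
                    if ad is None or ad[0] is None:
                        row[f"{s}_ref"] = 0
                        row[f"{s}_alt"] = 0
                    else:
                        row[f"{s}_ref"] = int(ad[0])
                        row[f"{s}_alt"] = int(ad[ai + 1]) if len(ad) > ai + 1 else 0
                rows.append(row)
    return pd.DataFrame(rows)
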