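"""Dormancy gene-signature derivation and sample scoring.

Starting from a differential-expression table (dormancy vs founder
population), significantly differential genes are z-scored across the
founder (POT) and dormancy samples, and genes recurrently extreme in the
dormancy samples — positive z at or above a permissive quantile floor in
at least ``min_recurrence`` dormancy samples for the up list, the
symmetric rule on negative z for the down list — form the ordered
dormancy-up and dormancy-down signatures.  Samples are scored against a
signature by their mean z over its genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

#: |log2FC| > 1 and padj < 0.01, used for signature derivation
SIGNATURE_PRESET = (1.0, 0.01)
#: fold change of at least 1.5x and padj < 0.01, the general DEG rule
GENERAL_PRESET = (float(np.log2(1.5)), 0.01)


def adjust_pvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(
    de: pd.DataFrame,
    lfc_threshold: float = SIGNATURE_PRESET[0],
    padj_threshold: float = SIGNATURE_PRESET[1],
) -> pd.Index:
    """Genes with |log2fc| strictly above the fold-change threshold and
    padj strictly below the significance threshold."""
    if lfc_threshold <= 0 or padj_threshold <= 0:
        raise ValueError("thresholds must be positive")
    required = {"gene", "log2fc", "padj"}
    if not required <= set(de.columns):
        raise ValueError(f"DE table missing columns: {sorted(required - set(de.columns))}")
    mask = (de["log2fc"].abs() > lfc_threshold) & (de["padj"] < padj_threshold)
    return pd.Index(de.loc[mask, "gene"])


def zscore_matrix(
    expr: pd.DataFrame,
    sample_subset: Sequence[str],
    extend_to_all: bool = False,
) -> tuple[pd.DataFrame, pd.Index]:
    """Per-gene z-scores computed over a sample subset.

    z = (x - mean) / sd with the sample standard deviation (ddof=1),
    mean/sd taken over ``sample_subset`` only.  With ``extend_to_all``
    the subset's mean/sd are applied to the remaining samples as well
    (for display across the full time course).  Zero-variance genes get
    z = 0 and are returned in the flagged index.
    """
    subset = list(sample_subset)
    if len(subset) < 2:
        raise ValueError("need at least 2 samples in the z-score subset")
    missing = [s for s in subset if s not in expr.columns]
    if missing:
        raise ValueError(f"samples not in matrix: {missing}")
    sub = expr[subset]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    flagged = expr.index[sd == 0]
    safe_sd = sd.replace(0, 1.0)
    target = expr if extend_to_all else sub
    z = target.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[flagged] = 0.0
    return z, flagged


@dataclass
class SignatureResult:
    """Ordered dormancy-up/down gene lists with their ordering keys."""

    up_genes: list[str]
    down_genes: list[str]
    stats: pd.DataFrame  # gene, direction, cv, cumulative_z, recurrence
    z_matrix: pd.DataFrame


def _recurrence_counts(
    z: pd.DataFrame,
    dormancy_samples: list[str],
    quantile: float,
    sign: int,
    reference: str,
) -> pd.Series:
    """Per-gene count of dormancy samples passing the signed quantile rule.

    For the up rule (sign=+1) a dormancy sample counts when its z is
    positive and at or above the ``quantile`` of the reference positive
    z-scores; the down rule (sign=-1) mirrors it on negative z.  The
    reference set is the gene's own signed z-scores (default) or the
    pooled signed distribution (``reference="global"``).
    """
    zd = z[dormancy_samples]
    # quantiles use order-statistic ("lower"/"higher") interpolation so the
    # rule is a permissive floor: the boundary member of the signed set
    # itself passes, rather than being interpolated away
    if sign > 0:
        signed = z.where(z > 0)
        if reference == "global":
            q = np.nanquantile(signed.to_numpy(), quantile, method="lower")
            thresh = pd.Series(q, index=z.index)
        else:
            thresh = signed.quantile(quantile, axis=1, interpolation="lower")
        passing = zd.gt(0) & zd.ge(thresh, axis=0)
    else:
        signed = z.where(z < 0)
        if reference == "global":
            q = np.nanquantile(signed.to_numpy(), quantile, method="higher")
            thresh = pd.Series(q, index=z.index)
        else:
            thresh = signed.quantile(quantile, axis=1, interpolation="higher")
        passing = zd.lt(0) & zd.le(thresh, axis=0)
    # genes with no z-scores of the required sign have NaN thresholds and
    # contribute count 0
    return passing.fillna(False).sum(axis=1)


def derive_dormancy_signature(
    z_matrix: pd.DataFrame,
    dormancy_samples: Sequence[str],
    min_recurrence: int = 6,
    up_quantile: float = 0.1,
    down_quantile: float = 0.9,
    quantile_reference: str = "per-gene-signed",
) -> SignatureResult:
    """Select and order the dormancy-up and dormancy-down gene lists.

    A gene enters the up list when it is recurrently high in dormancy:
    positive z at or above the ``up_quantile`` of its positive z-scores
    in at least ``min_recurrence`` dormancy samples; the down list is the
    symmetric rule on negative z with ``down_quantile``.  Lists are
    ordered by ascending coefficient of variation of the gene's z over
    dormancy samples (consistency first), with descending \\|cumulative
    z\\| as tie-key; both keys are reported.
    """
    dormancy_samples = list(dormancy_samples)
    if len(dormancy_samples) < min_recurrence:
        raise ValueError("fewer dormancy samples than min_recurrence")
    if quantile_reference not in ("per-gene-signed", "global"):
        raise ValueError("quantile_reference must be 'per-gene-signed' or 'global'")

    up_counts = _recurrence_counts(
        z_matrix, dormancy_samples, up_quantile, +1, quantile_reference
    )
    down_counts = _recurrence_counts(
        z_matrix, dormancy_samples, down_quantile, -1, quantile_reference
    )
    up_mask = up_counts >= min_recurrence
    down_mask = down_counts >= min_recurrence
    conflict = up_mask & down_mask
    if conflict.any():
        raise ValueError(
            f"genes satisfy both up and down recurrence rules: "
            f"{list(z_matrix.index[conflict])[:5]}"
        )

    zd = z_matrix[dormancy_samples]
    cum_z = zd.sum(axis=1)
    mean_z = zd.mean(axis=1)
    sd_z = zd.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (sd_z / mean_z.abs()).replace([np.inf, -np.inf], np.nan)

    def ordered(mask: pd.Series, direction: str) -> pd.DataFrame:
        sub = pd.DataFrame(
            {
                "gene": z_matrix.index[mask],
                "direction": direction,
                "cv": cv[mask].to_numpy(),
                "cumulative_z": cum_z[mask].to_numpy(),
                "recurrence": (up_counts if direction == "up" else down_counts)[
                    mask
                ].to_numpy(),
            }
        )
        sub["_abs_cum"] = sub["cumulative_z"].abs()
        sub = sub.sort_values(
            ["cv", "_abs_cum", "gene"], ascending=[True, False, True]
        ).drop(columns="_abs_cum")
        return sub.reset_index(drop=True)

    up_tab = ordered(up_mask, "up")
    down_tab = ordered(down_mask, "down")
    return SignatureResult(
        up_genes=list(up_tab["gene"]),
        down_genes=list(down_tab["gene"]),
        stats=pd.concat([up_tab, down_tab], ignore_index=True),
        z_matrix=z_matrix,
    )


def score_samples(
    z_matrix: pd.DataFrame, signature_genes: Sequence[str]
) -> pd.Series:
    """Per-sample signature score: mean z over the signature genes.

    Signature genes absent from the matrix are dropped with a warning;
    an empty overlap is an error.
    """
    genes = [g for g in signature_genes if g in z_matrix.index]
    dropped = set(signature_genes) - set(genes)
    if not genes:
        raise ValueError("no signature genes present in the matrix")
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "%d signature genes absent from matrix", len(dropped)
        )
    return z_matrix.loc[genes].mean(axis=0).rename("signature_score")
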