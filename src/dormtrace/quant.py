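"""Barcode quantification: read matching, count filtering, normalization,
and replicate concordance.

Turns raw barcode evidence (read counts per barcode per sample, or raw
FASTQ plus a barcode library) into filtered per-sample lineage frequency
tables. Counts below the minimum-read support are treated as non-surviving
lineages and kept as explicit zero frequencies so downstream survival
analyses can count extinctions.
"""

from __future__ import annotations

import gzip
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: read-support threshold for the high-complexity (100k-barcode) design
MIN_READS_HIGH = 10
#: read-support threshold for the low-complexity dormancy design
MIN_READS_DORMANCY = 3


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class BarcodeCountMatrix:
    """Integer read counts per barcode per sample.

    ``counts`` is a DataFrame indexed by barcode_id with one column per
    sample; ``sample_meta`` optionally carries (sample, arm, timepoint).
    """

    counts: pd.DataFrame
    sample_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate barcode ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample names")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class BarcodeFrequencyTable:
    """Per-sample barcode frequencies after minimum-read filtering.

    Frequencies of retained barcodes sum to 1 per sample; barcodes failing
    the read threshold are explicit zeros.  ``flagged_samples`` lists
    samples with no retained reads at all (all-zero columns).
    """

    frequencies: pd.DataFrame
    min_reads: int
    flagged_samples: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# read matching
# ---------------------------------------------------------------------------


def read_library(path: str | Path) -> pd.DataFrame:
    """Load a barcode library CSV (barcode_id, sequence) and validate it."""
    lib = pd.read_csv(path)
    if not {"barcode_id", "sequence"} <= set(lib.columns):
        raise ValueError("library CSV needs barcode_id and sequence columns")
    seqs = lib["sequence"].str.upper()
    if seqs.duplicated().any():
        raise ValueError("library sequences must be unique")
    if seqs.str.len().nunique() != 1:
        raise ValueError("library sequences must have uniform length")
    if not seqs.str.fullmatch("[ACGT]+").all():
        raise ValueError("library sequences must use the ACGT alphabet")
    lib = lib.copy()
    lib["sequence"] = seqs
    return lib


def _iter_fastq(path: str | Path) -> Iterable[tuple[str, str]]:
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper()


def _hamming_best(read: str, barcode: str, max_mm: int) -> int:
    """Minimum Hamming distance of ``barcode`` over all offsets in ``read``
    (capped search: distances above max_mm are reported as max_mm + 1)."""
    L = len(barcode)
    best = max_mm + 1
    for off in range(len(read) - L + 1):
        d = 0
        window = read[off : off + L]
        for a, b in zip(window, barcode):
            if a != b:
                d += 1
                if d >= best:
                    break
        if d < best:
            best = d
            if best == 0:
                return 0
    return best


def match_reads_to_library(
    reads: Iterable[tuple[str, str]] | str | Path,
    library: pd.DataFrame,
    max_mismatches: int = 1,
    sample_name: str = "sample",
) -> tuple[BarcodeCountMatrix, dict]:
    """Assign reads to library barcodes by tolerant substring search.

    Each read is assigned to the unique barcode whose sequence occurs
    within it at Hamming distance <= ``max_mismatches``; ties at the
    minimum distance (two or more barcodes equally close) are discarded as
    ambiguous, as are reads matching nothing and reads shorter than the
    barcode.  Exact substring hits are resolved through a hash index
    before any distance scan.

    Returns the single-sample count matrix and a tally dict with
    ``assigned``/``discarded`` (conserving the input read count).
    """
    if len(library) == 0:
        raise ValueError("library must be non-empty")
    if isinstance(reads, (str, Path)):
        reads = _iter_fastq(reads)
    seqs = library["sequence"].tolist()
    ids = library["barcode_id"].tolist()
    bc_len = len(seqs[0])
    exact = {s: i for i, s in enumerate(seqs)}

    counts = np.zeros(len(seqs), dtype=np.int64)
    assigned = 0
    discarded = 0
    for _rid, seq in reads:
        if len(seq) < bc_len:
            discarded += 1
            continue
        hit = None
        for off in range(len(seq) - bc_len + 1):
            idx = exact.get(seq[off : off + bc_len])
            if idx is not None:
                hit = idx
                break
        if hit is None and max_mismatches > 0:
            best_d = max_mismatches + 1
            best_i: list[int] = []
            for i, bc in enumerate(seqs):
                d = _hamming_best(seq, bc, max_mismatches)
                if d < best_d:
                    best_d, best_i = d, [i]
                elif d == best_d:
                    best_i.append(i)
            if best_d <= max_mismatches and len(best_i) == 1:
                hit = best_i[0]
        if hit is None:
            discarded += 1
        else:
            counts[hit] += 1
            assigned += 1
    matrix = BarcodeCountMatrix(
        counts=pd.DataFrame({sample_name: counts}, index=pd.Index(ids, name="barcode_id"))
    )
    return matrix, {"assigned": assigned, "discarded": discarded}


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------


def filter_and_normalize(
    matrix: BarcodeCountMatrix, min_reads: int = MIN_READS_HIGH
) -> BarcodeFrequencyTable:
    """Apply the minimum-read filter and library-size normalization.

    Per sample, barcodes supported by at least ``min_reads`` reads are
    retained and their counts divided by the retained library size; all
    other barcodes get frequency 0.  A sample left with zero retained
    reads is flagged and reported all-zero.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    counts = matrix.counts
    retained = counts.where(counts >= min_reads, 0)
    libsize = retained.sum(axis=0)
    flagged = list(libsize.index[libsize == 0])
    for s in flagged:
        logger.warning("sample %s has no barcodes passing min_reads=%d", s, min_reads)
    denom = libsize.replace(0, 1)
    freqs = retained / denom
    return BarcodeFrequencyTable(
        frequencies=freqs, min_reads=min_reads, flagged_samples=flagged
    )


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho at small n.

    Enumerates all n! orderings of one rank vector (vectorized Pearson on
    centered ranks, so ties are handled)."""
    n = len(x)
    rx = stats.rankdata(x) - (n + 1) / 2.0
    ry = stats.rankdata(y) - (n + 1) / 2.0
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 1.0
    perms = np.array(list(itertools.permutations(ry)))
    rho_all = perms @ rx / denom
    return float(np.mean(np.abs(rho_all) >= abs(rho_obs) - 1e-12))


def replicate_concordance(
    freq_a: pd.Series, freq_b: pd.Series
) -> tuple[float, float]:
    """Spearman rank correlation between two frequency tables.

    Tables are aligned on the union of their barcode universes with zeros
    filled in.  The p-value uses the t approximation for n >= 10 and an
    exact rank-permutation test below.
    """
    idx = freq_a.index.union(freq_b.index)
    a = freq_a.reindex(idx, fill_value=0.0).to_numpy(dtype=float)
    b = freq_b.reindex(idx, fill_value=0.0).to_numpy(dtype=float)
    if len(idx) < 3:
        raise ValueError("need at least 3 shared barcodes")
    res = stats.spearmanr(a, b)
    rho = float(res.statistic)
    if len(idx) >= 10:
        p = float(res.pvalue)
    else:
        p = _exact_spearman_pvalue(a, b, rho)
    return rho, p


def high_frequency_matrix(
    tables: list[BarcodeFrequencyTable] | list[pd.DataFrame],
    threshold: float = 0.1,
    inclusive: bool = False,
) -> pd.DataFrame:
    """Frequencies of barcodes exceeding ``threshold`` in at least one sample.

    Rows are barcodes whose maximum frequency across all samples is
    strictly above the threshold (``inclusive=True`` switches to >=),
    ordered by that maximum descending with ties broken by barcode id.
    Values are the raw (unfiltered-on-threshold) frequencies.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    frames = [
        t.frequencies if isinstance(t, BarcodeFrequencyTable) else t for t in tables
    ]
    merged = pd.concat(frames, axis=1).fillna(0.0)
    maxima = merged.max(axis=1)
    keep = maxima >= threshold if inclusive else maxima > threshold
    sub = merged.loc[keep]
    order = (
        pd.DataFrame({"m": maxima.loc[keep], "id": sub.index})
        .sort_values(["m", "id"], ascending=[False, True])
        .index
    )
    return sub.loc[order]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_counts_tsv(path: str | Path) -> BarcodeCountMatrix:
    """Read a counts TSV with a barcode_id column and one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if "barcode_id" not in df.columns:
        raise ValueError("counts TSV needs a barcode_id column")
    df = df.set_index("barcode_id")
    return BarcodeCountMatrix(counts=df.astype(np.int64))


def write_frequencies_tsv(table: BarcodeFrequencyTable, path: str | Path) -> None:
    table.frequencies.rename_axis("barcode_id").reset_index().to_csv(
        path, sep="\t", index=False
    )
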