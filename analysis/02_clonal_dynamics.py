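#!/usr/bin/env python
"""Clonal dynamics over the simulated cohort: frequency normalization,
lineage survival through the day-30 bottleneck, winner identification at
the endpoint, and founder doubling times.

Reads results/cohort/ (run 01_simulate_cohort.py first) and writes
survival and winner tables to results/dynamics/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dormtrace import dynamics, quant

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "dynamics"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pot = pd.read_csv(
        ROOT / "cohort" / "pot_frequencies.tsv", sep="\t", index_col="barcode_id"
    )["frequency"]
    matrix = quant.read_counts_tsv(ROOT / "cohort" / "endpoint_counts.tsv")
    table = quant.filter_and_normalize(matrix, min_reads=quant.MIN_READS_HIGH)
    truth = json.loads((ROOT / "cohort" / "truth.json").read_text())

    rows = []
    for sample in table.frequencies.columns:
        freqs = table.frequencies[sample]
        summ = dynamics.survival_summary(pot, freqs)
        win = dynamics.identify_winners(freqs)
        expected = set(truth[sample]["winners"])
        found = set(win.winners["barcode"])
        rows.append(
            {
                "sample": sample,
                "fraction_surviving": summ.fraction_surviving,
                "n_winners": len(found),
                "sweep": win.sweep,
                "winners_match_truth": found == expected,
                **{f"survival_{k}": v for k, v in summ.bin_fractions.items()},
            }
        )
        print(
            f"{sample}: {summ.fraction_surviving:.2f} of POT lineages at "
            f"endpoint, winners {sorted(found)} "
            f"({'match' if found == expected else 'MISMATCH'}), "
            f"sweep={win.sweep}"
        )
    report = pd.DataFrame(rows)
    report.to_csv(OUT / "survival_winners.tsv", sep="\t", index=False)

    hours = dynamics.doubling_times_from_frequencies(pot, n_pot=9.0e7)
    hours.rename_axis("barcode_id").reset_index().to_csv(
        OUT / "doubling_times.tsv", sep="\t", index=False
    )
    print(
        f"founder doubling times: median {hours.median():.1f} h, "
        f"range {hours.min():.1f}-{hours.max():.1f} h"
    )
    print(f"wrote dynamics tables to {OUT}")


if __name__ == "__main__":
    main()
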