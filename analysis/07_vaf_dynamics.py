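#!/usr/bin/env python
"""Longitudinal VAF dynamics: change testing across timepoints, presence
classification against the founder samples, and the patient-panel filter
chain.

Simulates a variant table with a subset of truly drifting variants,
tests all of them, classifies presence for phylogeny input, runs the
targeted-panel chain on its fixture, and writes results/vaf/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dormtrace import benchmarks as bm
from dormtrace import vaf

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "vaf"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    n_var, n_drift = 500, 50
    depth = 120
    true_vaf = rng.uniform(0.05, 0.5, n_var)
    samples = ["POT1", "POT2", "DORM", "AWAKE"]
    table = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_var + 1) * 1000,
            "ref": "A",
            "alt": "T",
        }
    )
    drifting = np.zeros(n_var, bool)
    drifting[:n_drift] = True
    for s in samples:
        v = true_vaf.copy()
        if s == "AWAKE":  # hitch-hiking on the sweeping lineage
            v[drifting] = np.minimum(v[drifting] * 3.0, 0.95)
        alt = rng.binomial(depth, v)
        table[f"{s}_alt"] = alt
        table[f"{s}_ref"] = depth - alt
    tested = vaf.changed_variants(table, samples)
    n_changed = int(tested["changed"].sum())
    tp = int(tested.loc[drifting, "changed"].sum())
    print(
        f"{n_changed}/{n_var} variants changed VAF at P<0.01 "
        f"({tp}/{n_drift} of the truly drifting ones)"
    )
    tested.to_csv(OUT / "vaf_change.tsv", sep="\t", index=False)

    vafs = vaf.vaf_table(table, samples)
    presence = vaf.classify_presence(vafs, ["POT1", "POT2"])
    presence.to_csv(OUT / "presence.tsv", sep="\t")
    print(
        f"{int(presence['pot_absent'].sum())} variants absent from POTs "
        f"(mean VAF < 5%) -> phylogeny input"
    )

    panel = bm.patient_filter_fixture()
    survivors, attrition = vaf.filter_patient_variants(panel)
    (OUT / "patient_attrition.json").write_text(
        json.dumps(attrition.as_dict(), indent=2)
    )
    print(f"patient panel attrition: {attrition.as_dict()}")
    print(f"wrote VAF tables to {OUT}")


if __name__ == "__main__":
    main()
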