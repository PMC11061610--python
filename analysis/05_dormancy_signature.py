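#!/usr/bin/env python
"""Dormancy gene signature: derive ordered up/down gene lists from a
planted expression dataset and score all samples against them.

Writes the signature table, z-matrix and per-sample scores to
results/signature/.
"""

from pathlib import Path

from dormtrace import signature as sig
from dormtrace import synthetic as syn

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "signature"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genes = [f"G{i:04d}" for i in range(500)]
    up, down = genes[:50], genes[50:100]
    data = syn.generate_expression_dataset(
        500, 6, 6, 4, up, down, effect_size=4.0, sigma=0.5, seed=SEED
    )
    data["expr"].rename_axis("gene").to_csv(OUT / "expression.tsv", sep="\t")
    data["de"].to_csv(OUT / "de.tsv", sep="\t", index=False)

    degs = sig.select_degs(data["de"])
    print(f"{len(degs)} significant genes (|log2FC| > 1, padj < 0.01)")
    ann = data["annotations"]
    subset = list(ann.loc[ann["group"].isin(["POT", "dormancy"]), "sample"])
    dorm = list(ann.loc[ann["group"] == "dormancy", "sample"])
    expr = data["expr"]
    z, flagged = sig.zscore_matrix(expr.loc[expr.index.isin(degs)], subset)
    res = sig.derive_dormancy_signature(z, dorm)
    res.stats.to_csv(OUT / "signature.tsv", sep="\t", index=False)

    tp_up = len(set(res.up_genes) & set(up))
    tp_down = len(set(res.down_genes) & set(down))
    print(
        f"dormancy-up: {len(res.up_genes)} genes ({tp_up} planted); "
        f"dormancy-down: {len(res.down_genes)} genes ({tp_down} planted)"
    )

    z_all, _ = sig.zscore_matrix(
        expr.loc[expr.index.isin(degs)], subset, extend_to_all=True
    )
    scores = sig.score_samples(z_all, res.up_genes)
    scores.rename_axis("sample").reset_index().to_csv(
        OUT / "up_scores.tsv", sep="\t", index=False
    )
    by_group = scores.groupby(ann.set_index("sample")["group"]).mean()
    print("mean dormancy-up score by group:")
    print(by_group.round(3).to_string())
    print(f"wrote signature tables to {OUT}")


if __name__ == "__main__":
    main()
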