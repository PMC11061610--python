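"""End-to-end verification benchmarks over synthetic study conditions.

Each function regenerates its inputs from scratch under a seed, runs the
relevant pipeline stage, and returns the measured quantity.  They are the
shared substrate of the acceptance test suite and the reproduction
script; problem sizes are desk-scale versions of the study design (100
lineages, 18 wells, 1000 lottery instances, 150-day horizons).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dormtrace import dynamics, lottery as lot, sc_barcode as sc
from dormtrace import signature as sig
from dormtrace import synthetic as syn
from dormtrace import topography as topo
from dormtrace import vaf

N_POT_CELLS = 100_000
N_WELLS = 18
N_BARCODES = 100


def _design(seed: int) -> np.ndarray:
    """Per-barcode initial cell counts under the low-complexity design."""
    pot = syn.simulate_pot(syn.ExpansionModel(n_barcodes=N_BARCODES, seed=seed))
    rng = np.random.default_rng(seed + 1)
    return rng.binomial(N_POT_CELLS, pot.frequencies)


def lottery_oracle_grid(seed: int, n_instances: int = 1000) -> dict:
    """Sweep (f, N, s): fraction of grid cells where the simulated survival
    proportion lies within 3 binomial SE of 1 - (1-f)^round(N*s)."""
    ok = 0
    cells = 0
    for f in (0.001, 0.005, 0.01, 0.05, 0.2):
        for n_pot in (1000, 10_000, 50_000, 100_000, 200_000):
            for s in (0.0005, 0.001, 0.005, 0.02, 0.1):
                config = lot.LotteryConfig(
                    n_pot=n_pot,
                    n_barcodes=1,
                    n_instances=n_instances,
                    ratio_mean=s,
                    ratio_sd=0.0,
                    renormalize=False,
                    seed=seed + cells,
                )
                res = lot.simulate_lottery(np.array([f]), config)
                p_hat = res.surviving_instances[0] / n_instances
                p = lot.analytic_survival_prob(f, n_pot, s)
                se = np.sqrt(max(p * (1 - p), 1e-12) / n_instances)
                if se == 0:
                    ok += p_hat == p
                else:
                    ok += abs(p_hat - p) <= 3 * se
                cells += 1
    return {"pass_fraction": ok / cells, "n": cells}


def lottery_calibration(seed: int, n_trials: int = 100) -> dict:
    """Fraction of lottery-generated datasets judged consistent at alpha=.05."""
    c = _design(seed)
    consistent = 0
    for trial in range(n_trials):
        pres = lot.simulate_well_presence(
            c, N_WELLS, 0.001, 0.0003, N_POT_CELLS, seed=seed * 7919 + trial
        )
        rep = lot.lottery_fit(c, pres, N_POT_CELLS, seed=seed * 104729 + trial)
        consistent += rep.verdict == "consistent"
    return {"rate": consistent / n_trials, "n": n_trials}


def lottery_power(seed: int, n_trials: int = 100) -> dict:
    """Power against 10% of lineages with 5x dormancy-entry probability."""
    c = _design(seed)
    rng = np.random.default_rng(seed + 3)
    inconsistent = 0
    for trial in range(n_trials):
        mask = np.zeros(len(c), bool)
        mask[rng.choice(len(c), len(c) // 10, replace=False)] = True
        pres = lot.simulate_well_presence(
            c,
            N_WELLS,
            0.001,
            0.0003,
            N_POT_CELLS,
            selection_mask=mask,
            selection_factor=5.0,
            seed=seed * 6151 + trial,
        )
        rep = lot.lottery_fit(c, pres, N_POT_CELLS, seed=seed * 9973 + trial)
        inconsistent += rep.verdict == "inconsistent"
    return {"rate": inconsistent / n_trials, "n": n_trials}


def doubling_time_check() -> dict:
    """Max |error| of the closed form against an independently coded table."""
    import math

    xs = [1, 2, 4, 8, 16, 32, 64, 128, 256, 512, 1024, 2048, 4096, 8192,
          10, 100, 1000, 1e6, 3.5, 900]
    max_err = 0.0
    for x in xs:
        expected = 13.0 / (math.log(x, 2) + 1.0)
        got = float(dynamics.doubling_time(x))
        max_err = max(max_err, abs(got - expected))
    return {"max_abs_error_days": max_err, "n": len(xs)}


def topography_roundtrip(
    seed: int, n_panels: int = 200, noise_sd: float = 2.0
) -> dict:
    """Window-label and well-class recovery over seeded planted panels."""
    rng = np.random.default_rng(seed + 5)
    win_ok = win_tot = well_ok = well_tot = 0
    for i in range(n_panels):
        cls = topo.WELL_CLASSES[i % 4]
        events, true_cls = syn.make_well_events("W1", cls, rng, n_fa=1, n_clear=1)
        spec = syn.PlantedEventSpec(
            events=events, noise_sd=noise_sd, well_classes={"W1": true_cls}
        )
        panel, truth = syn.generate_confluency_panel(spec, seed=seed * 31 + i)
        windows, wells = topo.classify_panel(panel)
        merged = windows.merge(truth, on=["well", "row", "col"])
        win_ok += int((merged["label_x"] == merged["label_y"]).sum())
        win_tot += len(merged)
        well_ok += int(wells["well_class"].iloc[0] == true_cls)
        well_tot += 1
    return {
        "window_accuracy": win_ok / win_tot,
        "well_accuracy": well_ok / well_tot,
        "n": n_panels,
    }


def topography_noise_free(seed: int, n_panels: int = 20) -> dict:
    """Noise-free planted panels must be recovered exactly."""
    out = topography_roundtrip(seed, n_panels=n_panels, noise_sd=0.0)
    return out


def _signature_run(seed: int, effect_size: float) -> tuple[set, set, set, set]:
    genes = [f"G{i:04d}" for i in range(500)]
    up, down = genes[:50], genes[50:100]
    data = syn.generate_expression_dataset(
        500, 6, 6, 4, up, down, effect_size=effect_size, sigma=0.5, seed=seed
    )
    degs = sig.select_degs(data["de"])
    ann = data["annotations"]
    subset = list(ann.loc[ann["group"].isin(["POT", "dormancy"]), "sample"])
    dorm = list(ann.loc[ann["group"] == "dormancy", "sample"])
    expr = data["expr"]
    sub = expr.loc[expr.index.isin(degs)]
    if sub.empty:
        return set(), set(), set(up), set(down)
    z, _ = sig.zscore_matrix(sub, subset)
    res = sig.derive_dormancy_signature(z, dorm)
    return set(res.up_genes), set(res.down_genes), set(up), set(down)


def signature_recovery(seed: int) -> dict:
    """Precision/recall of planted dormancy genes at a 4-log2-unit shift
    against sigma = 0.5 within-group noise."""
    found_up, found_down, up, down = _signature_run(seed, effect_size=4.0)
    out = {}
    for name, found, planted in (
        ("up", found_up, up),
        ("down", found_down, down),
    ):
        out[f"precision_{name}"] = len(found & planted) / max(len(found), 1)
        out[f"recall_{name}"] = len(found & planted) / len(planted)
    out["n"] = len(up) + len(down)
    return out


def signature_null(seed: int, n_seeds: int = 100) -> dict:
    """Median signature size on effect-free data across seeds."""
    sizes = []
    for i in range(n_seeds):
        found_up, found_down, _, _ = _signature_run(seed * 53 + i, effect_size=0.0)
        sizes.append(len(found_up) + len(found_down))
    return {"median_size": float(np.median(sizes)), "n": n_seeds}


def sc_barcode_recovery(seed: int, n_cells: int = 1000) -> dict:
    """Dominant-barcode recovery at zero noise and at ambient rate 0.3."""
    freqs = np.full(30, 1 / 30)
    out = {}
    for name, ambient, multi in (
        ("clean", 0.0, 0.0),
        ("ambient", 0.3, 0.02),
    ):
        data = syn.generate_cell_barcode_table(
            n_cells, freqs, multi_tag_rate=multi, ambient_rate=ambient,
            seed=seed + int(ambient * 100),
        )
        calls = sc.call_all_cells(data["tags"])
        merged = calls.merge(data["truth"], on="cell_id")
        out[f"accuracy_{name}"] = float(
            (merged["label"] == merged["true_barcode"]).mean()
        )
    out["n"] = n_cells
    return out


def vaf_null_uniformity(seed: int, n_variants: int = 1000) -> dict:
    """Fraction of null (no-change) variants with Fisher p < 0.01."""
    rng = np.random.default_rng(seed + 11)
    depth = 500
    hits = 0
    for _ in range(n_variants):
        alt = rng.binomial(depth, 0.3, size=2)
        p, _ = vaf.test_vaf_change(alt, depth - alt)
        hits += p < 0.01
    return {"fraction": hits / n_variants, "n": n_variants}


def patient_filter_fixture() -> pd.DataFrame:
    """The ten-variant targeted-panel fixture (built in code, not shipped).

    Engineered so exactly one variant falls at each filter boundary and
    three variants survive the full chain.
    """
    rows = [
        ("chr1", 10011, "A", "T", 15, 4, 2, 2, "MODERATE"),
        ("chr2", 20022, "C", "G", 40, 3, 1, 2, "HIGH"),
        ("chr3", 30033, "G", "A", 50, 5, 2, 1, "MODERATE"),
        ("chr4", 40044, "T", "C", 90, 8, 4, 4, "HIGH"),
        ("chr5", 50055, "A", "G", 60, 6, 3, 3, "MODERATE"),
        ("chr6", 60066, "C", "T", 30, 10, 5, 4, "LOW"),
        ("chr7", 70077, "G", "C", 25, 12, 6, 5, "MODIFIER"),
        ("chr8", 80088, "T", "A", 16, 4, 2, 2, "MODERATE"),
        ("chr9", 90099, "A", "C", 36, 4, 2, 2, "HIGH"),
        ("chr10", 100100, "C", "A", 100, 50, 20, 20, "HIGH"),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "ref_depth", "alt_depth",
            "f1r2_alt", "f2r1_alt", "consequence_level",
        ],
    )


def patient_filter_survivors() -> dict:
    table, _ = vaf.filter_patient_variants(patient_filter_fixture())
    return {"survivors": len(table), "n": 10}


def winner_recovery(seed: int, n_runs: int = 200) -> dict:
    """Winner-truth recovery across seeded treatment simulations."""
    pot = syn.simulate_pot(syn.ExpansionModel(n_barcodes=N_BARCODES, seed=seed))
    copy = syn.split_carbon_copies(pot, 1, 20_000, seed=seed + 1)[0]
    hits = 0
    awakened = 0
    for i in range(n_runs):
        traj = syn.simulate_treatment(
            copy,
            syn.TreatmentModel(seed=seed * 131 + i),
            horizon_days=150,
            sample_days=range(0, 151, 5),
        )
        if traj.awakening_day is None:
            # no awakening: recovered iff no winners are claimed either way
            final = traj.live_counts[:, -1] + traj.dormant_counts[:, -1]
            if final.sum() == 0:
                hits += 1
                continue
            f = pd.Series(final / final.sum(), index=traj.barcode_ids)
            hits += dynamics.identify_winners(f).winners.empty
            continue
        awakened += 1
        final = traj.live_counts[:, -1] + traj.dormant_counts[:, -1]
        f = pd.Series(final / final.sum(), index=traj.barcode_ids)
        rep = dynamics.identify_winners(f)
        hits += set(rep.winners["barcode"]) == set(traj.winner_truth)
    return {"rate": hits / n_runs, "n": n_runs, "awakened": awakened}


def dormancy_survival_fraction(seed: int, n_copies: int = 20) -> dict:
    """Mean fraction of lineages persisting at the day-30 bottleneck under
    the default treatment model with ~16-cell founding clones."""
    pot = syn.simulate_pot(syn.ExpansionModel(n_barcodes=N_BARCODES, seed=seed))
    copies = syn.split_carbon_copies(pot, n_copies, 1600, seed=seed + 2)
    fracs = []
    for i, copy in enumerate(copies):
        traj = syn.simulate_treatment(
            copy,
            syn.TreatmentModel(seed=seed * 389 + i),
            horizon_days=31,
            sample_days=[0, 30],
        )
        alive = traj.live_counts[:, 1] + traj.dormant_counts[:, 1]
        seeded = copy > 0
        fracs.append(((alive > 0) & seeded).sum() / seeded.sum())
    return {"fraction": float(np.mean(fracs)), "n": n_copies}
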