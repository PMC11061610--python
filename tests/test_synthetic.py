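"""Generator correctness: closed-form limits, conservation laws,
determinism under seeds, and analytic survival oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dormtrace import synthetic as syn


def gini(x):
    """Gini coefficient by the direct pairwise-difference formula."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    return float(np.sum((2 * np.arange(1, n + 1) - n - 1) * x) / (n * np.sum(x)))


class TestSimulatePot:
    def test_zero_fitness_spread_gives_uniform_frequencies(self):
        pot = syn.simulate_pot(
            syn.ExpansionModel(n_barcodes=100, doubling_time_cv=0.0, seed=1)
        )
        np.testing.assert_allclose(pot.frequencies, np.full(100, 0.01))

    def test_same_seed_reproduces_frequencies(self):
        m = syn.ExpansionModel(n_barcodes=500, seed=42)
        a = syn.simulate_pot(m).frequencies
        b = syn.simulate_pot(m).frequencies
        np.testing.assert_array_equal(a, b)

    def test_higher_fitness_spread_skews_frequencies(self):
        kw = dict(n_barcodes=1000, seed=7)
        lo = syn.simulate_pot(syn.ExpansionModel(doubling_time_cv=0.05, **kw))
        hi = syn.simulate_pot(syn.ExpansionModel(doubling_time_cv=0.2, **kw))
        assert gini(hi.frequencies) > gini(lo.frequencies)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            syn.ExpansionModel(doubling_time_mean=-1.0)
        with pytest.raises(ValueError):
            syn.ExpansionModel(n_barcodes=1000, n_pot=10)


class TestCarbonCopies:
    def test_copy_conserves_cell_count(self, pot100):
        copies = syn.split_carbon_copies(pot100, 3, 12345, seed=0)
        assert all(c.sum() == 12345 for c in copies)

    def test_single_barcode_pot_gets_everything(self):
        pot = syn.PotPopulation(["BC1"], [1.0], 1000)
        (copy,) = syn.split_carbon_copies(pot, 1, 500, seed=1)
        assert copy[0] == 500

    def test_replicates_are_concordant(self):
        pot = syn.simulate_pot(syn.ExpansionModel(n_barcodes=100, seed=3))
        a, b = syn.split_carbon_copies(pot, 2, 100_000, seed=4)
        rho = stats.spearmanr(a, b).statistic
        assert rho > 0.95

    def test_empty_pot_rejected(self):
        with pytest.raises(ValueError):
            syn.PotPopulation(np.array([]), np.array([]), 0)


class TestSimulateTreatment:
    def test_pure_growth_matches_closed_form(self):
        model = syn.TreatmentModel(
            death_prob=0.0,
            dormancy_prob=0.0,
            awaken_hazard=0.0,
            awakened_growth=2.0,
            seed=0,
        )
        copy = np.array([4, 8])
        traj = syn.simulate_treatment(copy, model, horizon_days=31, sample_days=[0, 5, 10])
        np.testing.assert_array_equal(
            traj.total_viable(), [12, 12 * 2**5, 12 * 2**10]
        )

    def test_certain_death_extinguishes_everything(self):
        model = syn.TreatmentModel(
            death_prob=1.0, dormancy_prob=0.0, seed=0
        )
        copy = np.array([100, 200])
        traj = syn.simulate_treatment(copy, model, horizon_days=40, sample_days=[0, 30, 40])
        assert traj.total_viable()[1] == 0
        assert traj.awakening_day is None
        assert traj.winner_truth == []

    def test_lineage_survival_matches_markov_chain_oracle(self):
        # no division, no awakening: survival into dormancy of a c-cell
        # lineage is 1 - (1 - p_s)^c with p_s from the daily chain
        model = syn.TreatmentModel(
            death_prob=0.25,
            dormancy_prob=0.05,
            latency_days=10,
            awaken_hazard=0.0,
            awakened_growth=1.0,
        )
        p_s = sum(
            0.05 * (1 - 0.25 - 0.05) ** t for t in range(10)
        )
        assert syn.persister_probability(model) == pytest.approx(p_s)
        c = 8
        n_rep = 500
        survived = 0
        for s in range(n_rep):
            m = syn.TreatmentModel(
                death_prob=0.25,
                dormancy_prob=0.05,
                latency_days=10,
                awaken_hazard=0.0,
                awakened_growth=1.0,
                seed=s,
            )
            t = syn.simulate_treatment(
                np.array([c]), m, horizon_days=10, sample_days=[10]
            )
            survived += int(t.total_viable()[0] > 0)
        p_lineage = 1 - (1 - p_s) ** c
        se = np.sqrt(p_lineage * (1 - p_lineage) / n_rep)
        assert abs(survived / n_rep - p_lineage) <= 3 * se

    def test_awakening_produces_winner_truth(self, carbon_copy):
        traj = syn.simulate_treatment(
            carbon_copy,
            syn.TreatmentModel(seed=5),
            horizon_days=150,
            sample_days=range(0, 151, 5),
        )
        assert traj.awakening_day is not None
        assert traj.awakening_day >= 30
        assert len(traj.winner_truth) >= 1

    def test_horizon_shorter_than_latency_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_treatment(
                np.array([10]), syn.TreatmentModel(), horizon_days=10
            )


class TestSimulateSequencing:
    def test_zero_depth_gives_zero_reads(self):
        reads = syn.simulate_sequencing(np.array([5, 5]), depth=0, seed=0)
        assert reads.sum() == 0

    def test_depth_is_conserved(self, rng):
        counts = rng.integers(1, 100, 50)
        for disp in (0.0, 0.01):
            reads = syn.simulate_sequencing(counts, depth=10_000, dispersion=disp, seed=1)
            assert reads.sum() == 10_000

    def test_multinomial_read_fraction_within_binomial_margin(self):
        counts = np.zeros(100)
        counts[0] = 1
        counts[1:] = 99 / 99
        f = 0.01
        depth = 10**6
        reads = syn.simulate_sequencing(counts, depth=depth, seed=2)
        margin = 3 * np.sqrt(f * (1 - f) / depth)
        assert abs(reads[0] / depth - f) <= margin

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_sequencing(np.array([1.0]), 10, dispersion=-0.1)


class TestConfluencyPanel:
    def test_noise_free_dormant_windows_are_flat(self):
        spec = syn.PlantedEventSpec(events=[syn.PlantedEvent("W1", 0, 0, "D")])
        panel, truth = syn.generate_confluency_panel(spec, seed=0)
        assert (panel["confluency_pct"] == spec.baseline).all()
        assert set(truth["label"]) == {"D"}

    def test_cleared_window_stays_below_detection(self):
        spec = syn.PlantedEventSpec(
            events=[syn.PlantedEvent("W1", 1, 1, "CLEAR")], noise_sd=2.0
        )
        panel, _ = syn.generate_confluency_panel(spec, seed=1)
        win = panel[(panel["row"] == 1) & (panel["col"] == 1)]
        assert win["confluency_pct"].max() < 1.0

    def test_contradictory_events_rejected(self):
        with pytest.raises(ValueError, match="contradictory"):
            syn.PlantedEventSpec(
                events=[
                    syn.PlantedEvent("W1", 0, 0, "AW", onset_day=50),
                    syn.PlantedEvent("W1", 0, 0, "FA", onset_day=60),
                ]
            )


class TestExpressionDataset:
    def test_null_data_yields_no_degs(self):
        data = syn.generate_expression_dataset(
            2000, 4, 6, 0, [], [], effect_size=0.0, seed=3
        )
        de = data["de"]
        n_hits = ((de["log2fc"].abs() > 1) & (de["padj"] < 0.01)).sum()
        assert n_hits == 0

    def test_strong_effect_passes_deg_thresholds(self):
        up = [f"G{i:04d}" for i in range(10)]
        down = [f"G{i:04d}" for i in range(10, 20)]
        data = syn.generate_expression_dataset(
            1000, 6, 6, 0, up, down, effect_size=4.0, sigma=0.5, seed=4
        )
        de = data["de"].set_index("gene")
        planted = de.loc[up + down]
        assert ((planted["log2fc"].abs() > 1) & (planted["padj"] < 0.01)).all()

    def test_overlapping_planted_sets_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_expression_dataset(
                100, 4, 6, 0, ["G0001"], ["G0001"], 2.0
            )


class TestCellBarcodeTable:
    def test_cell_count_conserved_and_noise_free_single_tagged(self):
        freqs = np.full(20, 1 / 20)
        data = syn.generate_cell_barcode_table(500, freqs, seed=5)
        tags = data["tags"]
        assert tags["cell_id"].nunique() == 500
        assert (tags.groupby("cell_id").size() == 1).all()
        merged = tags.merge(data["truth"], on="cell_id")
        assert (merged["barcode_id"] == merged["true_barcode"]).all()

    def test_empty_frequencies_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_cell_barcode_table(10, np.array([]), seed=0)
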