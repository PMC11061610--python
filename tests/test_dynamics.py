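"""Lineage survival, quartile binning, winners, doubling times,
and richness trajectories."""

import math

import numpy as np
import pandas as pd
import pytest

from dormtrace import dynamics, synthetic as syn

# independent tabulation of t = T / (log2(x) + 1), T = 13 days, computed
# with math.log at freeze time
DOUBLING_TABLE = [
    (1, 13.0),
    (2, 6.5),
    (4, 13.0 / 3),
    (8, 3.25),
    (16, 2.6),
    (32, 13.0 / 6),
    (64, 13.0 / 7),
    (128, 1.625),
    (256, 13.0 / 9),
    (512, 1.3),
    (1024, 13.0 / 11),
    (2048, 13.0 / 12),
    (4096, 1.0),
    (8192, 13.0 / 14),
    (10, 13.0 / (math.log(10, 2) + 1)),
    (100, 13.0 / (math.log(100, 2) + 1)),
    (1000, 13.0 / (math.log(1000, 2) + 1)),
    (1e6, 13.0 / (math.log(1e6, 2) + 1)),
    (3.5, 13.0 / (math.log(3.5, 2) + 1)),
    (900, 13.0 / (math.log(900, 2) + 1)),
]


class TestSurvivalSummary:
    def test_identical_sample_survives_fully(self, pot100):
        f = pd.Series(pot100.frequencies, index=pot100.barcode_ids)
        s = dynamics.survival_summary(f, f)
        assert s.fraction_surviving == 1.0
        assert all(v == 1.0 for v in s.bin_fractions.values())

    def test_all_zero_sample_survives_nothing(self, pot100):
        f = pd.Series(pot100.frequencies, index=pot100.barcode_ids)
        s = dynamics.survival_summary(f, f * 0)
        assert s.fraction_surviving == 0.0

    def test_quartile_enumeration_on_eight_barcodes(self):
        pot = pd.Series(
            [0.30, 0.25, 0.15, 0.10, 0.08, 0.06, 0.04, 0.02],
            index=list("ABCDEFGH"),
        )
        sample = pot.copy()
        sample[["E", "F", "G", "H"]] = 0.0
        s = dynamics.survival_summary(pot, sample)
        assert s.fraction_surviving == 0.5
        assert s.bin_fractions["high"] == 1.0
        assert s.bin_fractions["mid-high"] == 1.0
        assert s.bin_fractions["low-mid"] == 0.0
        assert s.bin_fractions["low"] == 0.0

    def test_bins_partition_the_pot(self, pot100):
        f = pd.Series(pot100.frequencies, index=pot100.barcode_ids)
        s = dynamics.survival_summary(f, f)
        assert sum(s.bin_sizes.values()) == s.n_pot_barcodes

    def test_empty_pot_rejected(self):
        with pytest.raises(ValueError):
            dynamics.survival_summary(pd.Series([0.0, 0.0]), pd.Series([0.0, 0.0]))


class TestIdentifyWinners:
    def test_single_dominant_winner_is_a_sweep(self):
        f = pd.Series([0.92] + [0.01] * 8)
        rep = dynamics.identify_winners(f)
        assert len(rep.winners) == 1
        assert rep.sweep

    def test_uniform_population_has_no_winners(self):
        f = pd.Series(np.full(100, 0.01))
        rep = dynamics.identify_winners(f)
        assert rep.winners.empty
        assert not rep.sweep

    def test_joint_integration_two_winners_no_sweep(self):
        # two lineages carried by the same awakened clone
        f = pd.Series(
            [0.45, 0.40] + [0.015] * 10,
            index=["B1", "B2"] + [f"M{i}" for i in range(10)],
        )
        rep = dynamics.identify_winners(f)
        assert list(rep.winners["barcode"]) == ["B1", "B2"]
        assert not rep.sweep

    def test_winner_truth_recovered_from_simulation(self, pot100, carbon_copy):
        hits = 0
        n = 25
        for s in range(n):
            traj = syn.simulate_treatment(
                carbon_copy,
                syn.TreatmentModel(seed=s),
                horizon_days=150,
                sample_days=range(0, 151, 5),
            )
            if traj.awakening_day is None:
                continue
            final = traj.live_counts[:, -1] + traj.dormant_counts[:, -1]
            f = pd.Series(final / final.sum(), index=traj.barcode_ids)
            rep = dynamics.identify_winners(f)
            hits += set(rep.winners["barcode"]) == set(traj.winner_truth)
        assert hits >= n - 1


class TestDoublingTime:
    @pytest.mark.parametrize("x,expected", DOUBLING_TABLE)
    def test_closed_form_matches_independent_table(self, x, expected):
        assert dynamics.doubling_time(x) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_in_x(self):
        x = np.linspace(1, 1e5, 200)
        t = dynamics.doubling_time(x)
        assert (np.diff(t) < 0).all()

    def test_alternative_convention_flag(self):
        assert dynamics.doubling_time(8, convention="n") == pytest.approx(13 / 3)
        with pytest.raises(ValueError):
            dynamics.doubling_time(1, convention="n")

    def test_clone_size_below_one_rejected(self):
        with pytest.raises(ValueError):
            dynamics.doubling_time(0.5)

    def test_per_barcode_hours_from_frequencies(self):
        f = pd.Series({"A": 4096 / 9e7, "B": 0.0})
        hours = dynamics.doubling_times_from_frequencies(f)
        assert list(hours.index) == ["A"]
        assert hours["A"] == pytest.approx(24.0)


class TestRichnessTrajectory:
    def test_constant_tables_have_zero_extinction(self):
        f = pd.Series([0.5, 0.5], index=list("AB"))
        out = dynamics.richness_trajectory([f, f, f])
        assert (out["extinction_rate"].iloc[1:] == 0).all()

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            dynamics.richness_trajectory([pd.Series([1.0])])

    def test_unordered_timepoints_rejected(self):
        f = pd.Series([1.0])
        with pytest.raises(ValueError):
            dynamics.richness_trajectory([f, f], timepoints=[5, 3])

    def test_extinction_concentrates_in_latency(self, carbon_copy):
        traj = syn.simulate_treatment(
            carbon_copy,
            syn.TreatmentModel(seed=9),
            horizon_days=90,
            sample_days=[0, 15, 30, 60, 90],
        )
        tables = [
            pd.Series(
                traj.live_counts[:, i] + traj.dormant_counts[:, i],
                index=traj.barcode_ids,
                dtype=float,
            )
            for i in range(len(traj.days))
        ]
        out = dynamics.richness_trajectory(tables, timepoints=list(traj.days))
        entry_rates = out["extinction_rate"].iloc[1:3]  # day 15, 30
        post_rates = out["extinction_rate"].iloc[3:]  # day 60, 90
        assert entry_rates.mean() > post_rates.mean()

    def test_survival_monotone_without_resurrection(self, pot100, carbon_copy):
        traj = syn.simulate_treatment(
            carbon_copy,
            syn.TreatmentModel(seed=13),
            horizon_days=60,
            sample_days=[0, 20, 40, 60],
        )
        alive = traj.live_counts + traj.dormant_counts
        pot = pd.Series(alive[:, 0], index=traj.barcode_ids, dtype=float)
        fracs = [
            dynamics.survival_summary(
                pot, pd.Series(alive[:, i], index=traj.barcode_ids, dtype=float)
            ).fraction_surviving
            for i in range(alive.shape[1])
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
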