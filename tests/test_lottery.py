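"""The dormancy-lottery null model: closed-form oracle, simulation
agreement, ratio inversion, and the goodness-of-fit test."""

import numpy as np
import pandas as pd
import pytest

from dormtrace import lottery as lot
from dormtrace import synthetic as syn


class TestObservedSurvivalRatios:
    def test_well_identical_to_pot_has_ratio_one(self):
        pot = pd.Series([10, 20, 30], index=list("ABC"))
        ratios, mean, sd = lot.observed_survival_ratios(pot, [pot, pot])
        np.testing.assert_array_equal(ratios, [1.0, 1.0])
        assert mean == 1.0

    def test_empty_well_has_ratio_zero(self):
        pot = pd.Series([10, 20], index=list("AB"))
        empty = pd.Series([0, 0], index=list("AB"))
        ratios, _, _ = lot.observed_survival_ratios(pot, [empty, pot])
        assert ratios[0] == 0.0

    def test_mean_and_sample_sd(self):
        pot = pd.Series(np.full(100, 10), index=[f"B{i}" for i in range(100)])
        wells = []
        for k in (30, 40, 50):
            w = pd.Series(0, index=pot.index)
            w.iloc[:k] = 10
            wells.append(w)
        ratios, mean, sd = lot.observed_survival_ratios(pot, wells)
        np.testing.assert_allclose(ratios, [0.3, 0.4, 0.5])
        assert mean == pytest.approx(0.4)
        assert sd == pytest.approx(np.std([0.3, 0.4, 0.5], ddof=1))

    def test_unobserved_pot_rejected(self):
        pot = pd.Series([1, 2], index=list("AB"))
        with pytest.raises(ValueError):
            lot.observed_survival_ratios(pot, [pot, pot], min_reads=5)


class TestAnalyticSurvival:
    def test_zero_frequency_never_survives(self):
        assert lot.analytic_survival_prob(0.0, 1e5, 0.5) == 0.0

    def test_certain_frequency_always_survives(self):
        assert lot.analytic_survival_prob(1.0, 1e5, 0.001) == 1.0

    def test_printed_example_value(self):
        p = lot.analytic_survival_prob(0.01, 100_000, 0.001)
        assert p == pytest.approx(1 - 0.99**100)
        assert p == pytest.approx(0.63397, abs=1e-5)

    def test_sub_cell_bottleneck_means_extinction(self):
        assert lot.analytic_survival_prob(0.5, 100, 0.004) == 0.0


class TestSimulateLottery:
    def test_certain_survival_with_degenerate_inputs(self):
        config = lot.LotteryConfig(
            n_pot=100, n_barcodes=1, n_instances=20, ratio_mean=1.0,
            ratio_sd=0.0, renormalize=False, seed=0,
        )
        res = lot.simulate_lottery(np.array([1.0]), config)
        assert res.surviving_instances[0] == 20

    def test_survival_proportion_matches_oracle(self):
        config = lot.LotteryConfig(
            n_pot=100_000, n_barcodes=1, n_instances=1000, ratio_mean=0.001,
            ratio_sd=0.0, renormalize=False, seed=1,
        )
        res = lot.simulate_lottery(np.array([0.01]), config)
        p = lot.analytic_survival_prob(0.01, 100_000, 0.001)
        se = np.sqrt(p * (1 - p) / 1000)
        assert abs(res.surviving_instances[0] / 1000 - p) <= 3 * se

    def test_sampled_ratios_respect_truncation(self):
        config = lot.LotteryConfig(
            n_instances=500, ratio_mean=0.05, ratio_sd=0.5, seed=2
        )
        res = lot.simulate_lottery(np.full(100, 0.01), config)
        assert ((res.survival_ratios >= 0) & (res.survival_ratios <= 1)).all()

    def test_zero_sd_is_deterministic_in_s(self):
        config = lot.LotteryConfig(n_instances=50, ratio_sd=0.0, seed=3)
        res = lot.simulate_lottery(np.full(100, 0.01), config)
        assert (res.survival_ratios == config.ratio_mean).all()

    def test_survival_nondecreasing_in_frequency(self):
        # common random numbers: same config/seed, frequency scaled up
        base = lot.LotteryConfig(
            n_pot=100_000, n_barcodes=1, n_instances=1000, ratio_mean=0.001,
            ratio_sd=0.0, renormalize=False, seed=4,
        )
        k_low = lot.simulate_lottery(np.array([0.002]), base).surviving_instances[0]
        k_high = lot.simulate_lottery(np.array([0.02]), base).surviving_instances[0]
        assert k_high >= k_low

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError):
            lot.simulate_lottery(np.zeros(5), lot.LotteryConfig())


class TestInvertSurvivalRatio:
    def test_round_trip_through_forward_map(self, pot100):
        f = pot100.frequencies
        N = 100_000
        for s_true in (0.0005, 0.002, 0.01):
            r = float(np.mean(1 - (1 - f) ** (N * s_true)))
            s_hat = lot.invert_survival_ratio(r, f, N)
            assert s_hat == pytest.approx(s_true, rel=1e-6)

    def test_boundary_ratios_clip(self, pot100):
        assert lot.invert_survival_ratio(0.0, pot100.frequencies, 1e5) == 0.0
        assert lot.invert_survival_ratio(1.0, pot100.frequencies, 1e5) == 1.0


@pytest.fixture(scope="module")
def design(pot100):
    rng = np.random.default_rng(55)
    return rng.binomial(100_000, pot100.frequencies)


class TestLotteryFit:
    def test_lottery_data_is_called_consistent(self, design):
        hits = 0
        for trial in range(10):
            pres = lot.simulate_well_presence(
                design, 18, 0.001, 0.0003, 100_000, seed=300 + trial
            )
            rep = lot.lottery_fit(design, pres, 100_000, seed=trial)
            hits += rep.verdict == "consistent"
        assert hits >= 8

    def test_selection_data_is_called_inconsistent(self, design):
        rng = np.random.default_rng(66)
        hits = 0
        for trial in range(10):
            mask = np.zeros(len(design), bool)
            mask[rng.choice(len(design), 10, replace=False)] = True
            pres = lot.simulate_well_presence(
                design, 18, 0.001, 0.0003, 100_000,
                selection_mask=mask, selection_factor=5.0, seed=400 + trial,
            )
            rep = lot.lottery_fit(design, pres, 100_000, seed=trial)
            hits += rep.verdict == "inconsistent"
        assert hits >= 8

    def test_expected_presence_tracks_analytic_curve(self, design):
        pres = lot.simulate_well_presence(
            design, 18, 0.001, 0.0, 100_000, seed=77
        )
        rep = lot.lottery_fit(design, pres, 100_000, seed=5)
        f = design / 100_000
        for _, row in rep.per_bin.iterrows():
            assert row["expected_presence"] >= 0
        # per-bin expected totals agree with the closed form at the fitted s
        p = np.array(
            [lot.analytic_survival_prob(fi, 100_000, rep.mu_s) for fi in f]
        )
        total_expected = rep.per_bin["expected_presence"].sum()
        assert total_expected == pytest.approx(18 * p.sum(), rel=0.1)

    def test_runs_fast_at_full_size(self, design):
        import time

        t0 = time.time()
        res = lot.simulate_lottery(
            design / design.sum(),
            lot.LotteryConfig(n_instances=1000, seed=8),
        )
        assert time.time() - t0 < 10.0
        assert res.month1_counts.shape == (100, 1000)
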