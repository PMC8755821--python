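"""ANOVA selectivity, Tukey preference, SI, chance simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pigeonvis.responsiveness import classify_session
from pigeonvis.selectivity import (
    ChanceSimConfig,
    analyze_session_selectivity,
    anova_selectivity,
    chance_simulation,
    preferred_grouping,
    scrambled_vs_original,
    selectivity_index,
)
from pigeonvis.session_synth import (
    NeuronProfile,
    TaskConfig,
    ValidationError,
    generate_session,
)


def tuned_neuron_session(target_si=0.5, preferred=2, seed=0, sign="excitatory",
                         baseline=10.0):
    gain = 2.0 if sign == "excitatory" else 0.5
    profile = NeuronProfile(
        neuron_id="a", response_class=sign, baseline_rate_hz=baseline,
        stim_gain=gain, preferred_grouping=preferred, target_si=target_si,
    )
    return generate_session(TaskConfig(rng_seed=seed), [profile])


class TestSelectivityIndex:
    def test_two_to_one_ratio_gives_one_third(self):
        assert selectivity_index(20.0, [10.0] * 4) == pytest.approx(1 / 3)
        assert round(selectivity_index(20.0, [10.0] * 4), 2) == 0.33

    def test_equal_rates_give_zero(self):
        assert selectivity_index(10.0, [10.0, 10.0]) == 0.0

    def test_three_to_one_gives_half(self):
        assert selectivity_index(3.0, [1.0]) == pytest.approx(0.5)

    def test_inhibitory_uses_mirrored_contrast(self):
        assert selectivity_index(10.0, [30.0], sign="inhibitory") == pytest.approx(0.5)

    def test_clipped_at_zero_when_direction_violated(self):
        assert selectivity_index(5.0, [10.0]) == 0.0

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValidationError):
            selectivity_index(0.0, [0.0, 0.0])

    @given(st.floats(0.1, 100.0), st.floats(0.1, 100.0), st.floats(0.01, 100.0))
    def test_invariant_to_common_rescaling(self, p, o, scale):
        a = selectivity_index(p, [o])
        b = selectivity_index(p * scale, [o * scale])
        assert a == pytest.approx(b, abs=1e-12)

    @given(st.floats(0.0, 100.0), st.lists(st.floats(0.0, 100.0), min_size=1,
                                           max_size=6))
    def test_bounded_in_unit_interval(self, p, others):
        if p + np.mean(others) == 0:
            return
        assert 0.0 <= selectivity_index(p, others) <= 1.0


class TestAnovaSelectivity:
    def test_planted_tuning_detected(self):
        trials = tuned_neuron_session(target_si=0.5, seed=3)
        res = anova_selectivity(trials)
        assert res.selective and res.anova_p < 0.05

    def test_identical_rates_not_selective(self):
        trials = pd.DataFrame(
            {"neuron_id": "a", "grouping": np.repeat([0, 1], 5),
             "rate_stim_hz": 5.0, "rate_baseline_hz": 5.0}
        )
        res = anova_selectivity(trials)
        assert not res.selective
        assert res.anova_F == 0.0

    def test_two_grouping_equal_means_runs(self):
        rng = np.random.default_rng(1)
        trials = pd.DataFrame(
            {"neuron_id": "a", "grouping": np.repeat([0, 1], 50),
             "rate_stim_hz": rng.poisson(10, 100).astype(float),
             "rate_baseline_hz": 10.0}
        )
        res = anova_selectivity(trials)
        assert res.anova_F < 4.0

    def test_null_calibration_across_replicates(self):
        """Untuned units are called selective at about the alpha rate."""
        hits = 0
        n = 200
        profiles = [NeuronProfile(neuron_id=f"n{i:03d}", baseline_rate_hz=10.0)
                    for i in range(n)]
        trials = generate_session(TaskConfig(rng_seed=17), profiles)
        for _, sub in trials.groupby("neuron_id"):
            hits += anova_selectivity(sub).selective
        frac = hits / n
        assert abs(frac - 0.05) < 2 * np.sqrt(0.05 * 0.95 / n) + 0.01


class TestTukeyDecisions:
    def test_matches_scipy_studentized_range_pvalues(self):
        """The cached-critical-value screen reaches exactly the same
        accept/reject decisions as thresholding scipy's Tukey p-values."""
        from scipy import stats as sps

        from pigeonvis.selectivity import tukey_significant_pairs

        rng = np.random.default_rng(7)
        for trial in range(10):
            shift = rng.uniform(0, 3)
            groups = [rng.normal(10 + shift * (g == 2), 3, 20) for g in range(5)]
            ours = set(tukey_significant_pairs(groups, alpha=0.05))
            ref = sps.tukey_hsd(*groups)
            theirs = {
                (i, j)
                for i in range(5)
                for j in range(i + 1, 5)
                if ref.pvalue[i, j] < 0.05
            }
            assert ours == theirs


class TestPreferredGrouping:
    def test_recovers_planted_preference(self):
        trials = tuned_neuron_session(target_si=0.5, preferred=3, seed=5)
        res = anova_selectivity(trials)
        pref, pairs = preferred_grouping(trials, res)
        assert pref == 3
        assert len(pairs) >= 1

    def test_inhibitory_preference_is_most_suppressed(self):
        trials = tuned_neuron_session(target_si=0.5, preferred=1, seed=5,
                                      sign="inhibitory", baseline=30.0)
        res = anova_selectivity(trials)
        pref, _ = preferred_grouping(trials, res, sign="inhibitory")
        assert pref == 1

    def test_requires_selective_neuron(self):
        trials = tuned_neuron_session(target_si=0.0, seed=5)
        res = anova_selectivity(trials)
        if not res.selective:
            with pytest.raises(ValidationError):
                preferred_grouping(trials, res)

    def test_recovery_rate_at_si_half(self):
        """Planted SI 0.5 with 32 trials/grouping recovers >= 95%."""
        hits = 0
        n = 60
        for seed in range(n):
            trials = tuned_neuron_session(target_si=0.5, preferred=seed % 5,
                                          seed=100 + seed)
            df = analyze_session_selectivity(trials)
            if df["selective"].iloc[0] and df["preferred_grouping"].iloc[0] == seed % 5:
                hits += 1
        assert hits / n >= 0.95


class TestSIRecovery:
    @pytest.mark.parametrize("target", [0.2, 0.33, 0.5])
    def test_empirical_si_unbiased_within_three_se(self, target):
        """Full-path SI estimates are unbiased at planted SI values."""
        estimates = []
        for seed in range(400):
            trials = tuned_neuron_session(target_si=target, preferred=1,
                                          seed=1000 + seed)
            df = analyze_session_selectivity(trials)
            si = df["si"].iloc[0]
            if si is not None and not pd.isna(si):
                estimates.append(si)
        estimates = np.asarray(estimates)
        assert len(estimates) >= 380  # near-total power at these effect sizes
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - target) < 3 * se


class TestChanceSimulation:
    def test_fraction_near_alpha_for_77_neurons(self):
        sim = chance_simulation(ChanceSimConfig(n_neurons=77, rng_seed=0))
        # binomial 95% band around 0.05 with n = 77
        assert sim["fraction"] <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 77)

    def test_fraction_scales_with_alpha(self):
        sim = chance_simulation(
            ChanceSimConfig(n_neurons=5000, alpha=0.01, rng_seed=1)
        )
        assert abs(sim["fraction"] - 0.01) < 2 * np.sqrt(0.01 * 0.99 / 5000) + 0.002

    def test_large_n_tight_binomial_bound(self):
        sim = chance_simulation(ChanceSimConfig(n_neurons=10000, rng_seed=2))
        assert 0.045 <= sim["fraction"] <= 0.055

    def test_per_neuron_rate_ranges_accepted(self):
        lo = np.linspace(0, 5, 20)
        hi = lo + 10.0
        sim = chance_simulation(
            ChanceSimConfig(n_neurons=20, rate_min=tuple(lo), rate_max=tuple(hi),
                            rng_seed=3)
        )
        assert sim["n_neurons"] == 20

    def test_degenerate_range_gives_zero_fraction(self):
        sim = chance_simulation(
            ChanceSimConfig(n_neurons=10, rate_min=5.0, rate_max=5.0, rng_seed=0)
        )
        assert sim["fraction"] == 0.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            ChanceSimConfig(n_neurons=10, rate_min=10.0, rate_max=5.0)
        with pytest.raises(ValidationError):
            ChanceSimConfig(trials_per_grouping=1)


class TestScrambledVsOriginal:
    def test_planted_scrambling_preference_detected(self):
        rng = np.random.default_rng(0)
        original = rng.normal(10, 2, 77)
        scrambled = original + 2.0 + rng.normal(0, 0.5, 77)
        res = scrambled_vs_original(scrambled, original)
        assert res["p"] < 0.01 and res["t"] > 0
        assert res["mean_scrambled"] > res["mean_original"]

    def test_identical_means_give_t_zero_p_one(self):
        x = np.arange(10.0)
        res = scrambled_vs_original(x, x)
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(42)
        hits = sum(
            scrambled_vs_original(rng.normal(10, 2, 77), rng.normal(10, 2, 77))["p"]
            < 0.05
            for _ in range(100)
        )
        assert hits <= 12  # ~ binomial(100, 0.05) upper band

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValidationError):
            scrambled_vs_original([1.0], [2.0])
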