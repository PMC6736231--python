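import numpy as np
import pytest

from effectbench import (
    Corpus,
    EffectRecord,
    corpus_power_summary,
    power_correlation,
    power_two_sample_t,
    solve_n_correlation,
    solve_n_two_sample,
)
from effectbench.power import PowerQuery, _continuous_power_r, _continuous_power_t


class TestTwoSamplePower:
    @pytest.mark.parametrize(
        "d, n1, n2, expected",
        [
            (0.38, 64, 64, 0.57),  # equal groups at the medium benchmark
            (0.76, 30, 19, 0.72),  # typical unequal case/control design
            (0.38, 30, 19, 0.25),
            (0.16, 30, 19, 0.08),
        ],
    )
    def test_benchmark_designs_two_decimals(self, d, n1, n2, expected):
        assert round(power_two_sample_t(d, n1, n2).power, 2) == expected

    def test_null_effect_power_equals_alpha(self):
        for alpha in (0.01, 0.05, 0.10):
            res = power_two_sample_t(0.0, 50, 50, alpha=alpha)
            assert res.power == pytest.approx(alpha, abs=1e-9)

    def test_equal_groups_match_the_unequal_formula(self):
        res = power_two_sample_t(0.5, 40, 40)
        assert res.ncp == pytest.approx(0.5 * np.sqrt(40 / 2))
        assert res.df == 78

    def test_monotone_in_effect_groups_and_alpha(self):
        base = power_two_sample_t(0.4, 30, 30).power
        assert power_two_sample_t(0.5, 30, 30).power > base
        assert power_two_sample_t(0.4, 40, 30).power > base
        assert power_two_sample_t(0.4, 30, 40).power > base
        assert power_two_sample_t(0.4, 30, 30, alpha=0.10).power > base

    def test_monotone_nondecreasing_in_n_on_grid(self):
        grid = [4, 8, 16, 64, 256, 1024, 10_000]
        powers = [power_two_sample_t(0.2, n, n).power for n in grid]
        assert all(b >= a for a, b in zip(powers, powers[1:]))

    def test_one_tailed_power_at_null_equals_alpha(self):
        assert power_two_sample_t(0.0, 30, 30, tails="one").power == pytest.approx(
            0.05, abs=1e-9
        )

    def test_one_and_two_tailed_powers_are_probabilities(self):
        for tails in ("two", "one"):
            p = power_two_sample_t(0.4, 25, 25, tails=tails).power
            assert 0 < p < 1

    def test_too_small_groups_raise(self):
        with pytest.raises(ValueError):
            power_two_sample_t(0.5, 1, 30)

    def test_monte_carlo_rejection_rate_matches(self):
        """Exact noncentral-t power agrees with simulated rejection rates."""
        from scipy import stats

        rng = np.random.default_rng(2024)
        reps = 100_000
        for d, n1, n2 in [(0.5, 30, 19), (0.38, 64, 64)]:
            x = rng.normal(d, 1.0, size=(reps, n1))
            y = rng.normal(0.0, 1.0, size=(reps, n2))
            t, _ = stats.ttest_ind(x, y, axis=1)
            crit = stats.t.ppf(0.975, n1 + n2 - 2)
            rate = np.mean(np.abs(t) > crit)
            power = power_two_sample_t(d, n1, n2).power
            se = np.sqrt(power * (1 - power) / reps)
            assert abs(rate - power) < 3 * se


class TestCorrelationPower:
    @pytest.mark.parametrize(
        "r, n, expected", [(0.32, 129, 0.96), (0.20, 129, 0.63), (0.12, 129, 0.27)]
    )
    def test_benchmark_designs_two_decimals(self, r, n, expected):
        assert round(power_correlation(r, n).power, 2) == expected

    def test_null_is_close_to_alpha_and_to_monte_carlo(self):
        """At rho=0 the approximation sits within .01 of the test's size."""
        from scipy import stats

        approx = power_correlation(0.0, 100).power
        assert approx == pytest.approx(0.05, abs=0.01)
        rng = np.random.default_rng(7)
        reps, n = 100_000, 100
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = np.einsum("ij,ij->i", xc, yc) / np.sqrt(
            np.einsum("ij,ij->i", xc, xc) * np.einsum("ij,ij->i", yc, yc)
        )
        t = r * np.sqrt((n - 2) / (1 - r**2))
        rate = np.mean(np.abs(t) > stats.t.ppf(0.975, n - 2))
        assert abs(approx - rate) < 0.01

    def test_monotone_in_r_and_n(self):
        base = power_correlation(0.2, 100).power
        assert power_correlation(0.3, 100).power > base
        assert power_correlation(0.2, 200).power > base
        # the Fisher-z approximation overshoots the test's size at minimal
        # df (its n=4 value exceeds the n=8 one for small r), so the
        # monotone range starts just above the boundary
        grid = [8, 32, 128, 1024, 10_000]
        powers = [power_correlation(0.1, n).power for n in grid]
        assert all(b >= a for a, b in zip(powers, powers[1:]))

    def test_n_below_four_is_out_of_domain(self):
        with pytest.raises(ValueError):
            power_correlation(0.3, 3)


class TestSampleSizeSolvers:
    @pytest.mark.parametrize(
        "d, target, expected", [(0.50, 0.80, 64), (0.38, 0.80, 110)]
    )
    def test_per_group_sizes_for_standard_targets(self, d, target, expected):
        assert solve_n_two_sample(d, target) == expected

    @pytest.mark.parametrize(
        "r, target, expected", [(0.32, 0.60, 47), (0.32, 0.80, 74), (0.32, 0.90, 98)]
    )
    def test_correlation_sizes_for_standard_targets(self, r, target, expected):
        assert solve_n_correlation(r, target) == expected

    @pytest.mark.parametrize("d", [0.16, 0.38, 0.76, 1.2])
    @pytest.mark.parametrize("target", [0.60, 0.80, 0.90])
    def test_two_sample_solver_minimality(self, d, target):
        n = solve_n_two_sample(d, target)
        assert power_two_sample_t(d, n, n).power >= target
        if n > 2:
            assert power_two_sample_t(d, n - 1, n - 1).power < target

    @pytest.mark.parametrize("r", [0.12, 0.20, 0.32, 0.5])
    @pytest.mark.parametrize("target", [0.60, 0.80, 0.90])
    def test_correlation_solver_minimality(self, r, target):
        n = solve_n_correlation(r, target)
        assert _continuous_power_r(r, n, 0.05, "two") >= target
        if n > 4:
            assert _continuous_power_r(r, n - 1, 0.05, "two") < target

    def test_solver_matches_continuous_power_at_the_returned_n(self):
        n = solve_n_two_sample(0.38, 0.80)
        assert _continuous_power_t(0.38, n, 0.05, "two") >= 0.80

    def test_zero_effect_is_rejected(self):
        with pytest.raises(ValueError):
            solve_n_two_sample(0.0, 0.8)
        with pytest.raises(ValueError):
            solve_n_correlation(0.0, 0.8)

    def test_unreachable_target_raises(self):
        with pytest.raises(ValueError, match="not reachable"):
            solve_n_correlation(1e-5, 0.9)


class TestPowerQuery:
    def test_validates_alpha_effect_and_target(self):
        with pytest.raises(ValueError):
            PowerQuery(metric="r", effect=0.2, alpha=1.5)
        with pytest.raises(ValueError):
            PowerQuery(metric="r", effect=-0.2)
        with pytest.raises(ValueError):
            PowerQuery(metric="r", effect=0.2, target_power=0.04)
        q = PowerQuery(metric="g", effect=0.38, n1=30, n2=19)
        assert q.alpha == 0.05


class TestCorpusPowerSummary:
    def test_single_median_design_is_underpowered_at_medium_effect(self):
        corpus = Corpus(records=[EffectRecord("m", "s", "r", 0.25, 129)])
        summary = corpus_power_summary(corpus, {"r": 0.20}, metric="r")
        assert summary.fraction_powered == 0.0
        assert summary.median_n1 == 129
        assert round(summary.powers[0], 2) == 0.63

    def test_huge_samples_are_all_powered(self):
        corpus = Corpus(
            records=[EffectRecord("m", f"s{i}", "r", 0.1, 100_000) for i in range(5)]
        )
        summary = corpus_power_summary(corpus, {"r": 0.20})
        assert summary.fraction_powered == 1.0

    def test_matches_brute_force_per_row_loop(self, synth_corpus):
        ref = {"r": 0.20, "g": 0.38}
        summary = corpus_power_summary(synth_corpus, ref)
        expected = []
        for rec in synth_corpus:
            if rec.metric == "r":
                expected.append(power_correlation(ref["r"], rec.n1).power)
            else:
                expected.append(power_two_sample_t(ref["g"], rec.n1, rec.n2).power)
        assert summary.powers == pytest.approx(tuple(expected))
        assert summary.fraction_powered == pytest.approx(
            sum(1 for p in expected if p >= 0.80) / len(expected)
        )

    def test_empty_selection_raises(self, toy_corpus):
        with pytest.raises(ValueError):
            corpus_power_summary(toy_corpus, 0.2, metric="r", subgroup="biomedical")
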