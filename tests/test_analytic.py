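from fractions import Fraction

import numpy as np
import pytest

from transgame import (
    GameParams,
    best_response_table,
    evolve_deviant,
    evolve_homogeneous,
    expected_payoff,
    homogeneous_transition,
    mixed_pair_pmf,
)

from oracle import enumerate_game, joint_count_color_pmf, purple_count_pmf

P_EXACT = (Fraction(1, 20), Fraction(3, 20), Fraction(5, 20))  # 0.05/0.15/0.25


class TestMixedPairPmf:
    def test_four_players_two_purple(self):
        # of the 3 perfect matchings of 4 players, 1 pairs like with like
        pmf = mixed_pair_pmf(4, 2)
        assert pmf == pytest.approx([1 / 3, 0.0, 2 / 3], abs=1e-12)

    def test_degenerate_cases(self):
        assert mixed_pair_pmf(2, 1) == pytest.approx([0.0, 1.0])
        assert mixed_pair_pmf(6, 0) == pytest.approx([1.0])

    @pytest.mark.parametrize("N", [2, 4, 6, 8, 10, 12, 14, 16, 18, 20])
    def test_normalization_all_counts(self, N):
        for n in range(N + 1):
            pmf = mixed_pair_pmf(N, n)
            assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
            exact = mixed_pair_pmf(N, n, exact=True)
            assert sum(exact.values()) == 1  # exact rational arithmetic
            for m, frac in exact.items():
                assert pmf[m] == pytest.approx(float(frac), abs=1e-12)

    def test_parity_support(self):
        # residual purple group must itself admit a perfect matching
        pmf = mixed_pair_pmf(8, 3)
        assert all(pmf[m] == 0 for m in range(len(pmf)) if (3 - m) % 2)

    @pytest.mark.parametrize("N,n", [(5, 2), (4, 5)])
    def test_invalid_inputs(self, N, n):
        with pytest.raises(ValueError):
            mixed_pair_pmf(N, n)


class TestHomogeneousTransition:
    def test_zero_probability_is_identity(self):
        out = homogeneous_transition(6, 3, 0.0)
        assert out[3] == pytest.approx(1.0, abs=1e-12)

    def test_two_players_closed_form(self):
        out = homogeneous_transition(2, 1, 0.05)
        assert out[1] == pytest.approx(0.95)
        assert out[2] == pytest.approx(0.05)

    def test_four_players_composed_with_binomial(self):
        # m ~ {0: 1/3, 2: 2/3}; X | m ~ Binomial(m, 0.1)
        out = homogeneous_transition(4, 2, 0.1)
        assert out[2] == pytest.approx(1 / 3 + (2 / 3) * 0.81, abs=1e-12)
        assert out[3] == pytest.approx((2 / 3) * 2 * 0.1 * 0.9, abs=1e-12)
        assert out[4] == pytest.approx((2 / 3) * 0.01, abs=1e-12)


class TestEvolveHomogeneous:
    def test_zero_rounds_is_outbreak_point_mass(self):
        p = GameParams(n_players=10, n_rounds=0, n_initial_purple=3)
        dist = evolve_homogeneous([], p)
        assert dist.probs.shape == (1, 11)
        assert dist.probs[0, 3] == 1.0

    @pytest.mark.parametrize("shared", ["HHH", "GGG", "HGH"])
    def test_matches_enumeration_oracle(self, shared):
        p = GameParams(n_players=6, n_rounds=3, n_initial_purple=2)
        hist = enumerate_game([list(shared)] * 6, 2, *P_EXACT)
        mine = evolve_homogeneous(shared, p)
        for t in range(4):
            oracle = np.array([float(x) for x in purple_count_pmf(hist[t], 6)])
            assert np.abs(oracle - mine.probs[t]).max() < 1e-12

    def test_rows_normalized_and_support_bounded(self, params):
        dist = evolve_homogeneous("H" * 25, params)
        assert np.allclose(dist.probs.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(dist.probs[:, : params.n_initial_purple] == 0)

    def test_stochastic_monotonicity_over_rounds(self, params):
        # purple count only grows: CDF at round t+1 pointwise <= CDF at t
        dist = evolve_homogeneous("H" * 25, params)
        cdf = np.cumsum(dist.probs, axis=1)
        assert np.all(cdf[1:] <= cdf[:-1] + 1e-12)

    def test_expected_final_monotone_in_probability_and_seeds(self):
        # more transmissible or more seeds => larger expected final outbreak
        means = []
        for p_gg in (0.01, 0.05, 0.10, 0.25):
            pp = GameParams(p_gg=p_gg, p_gh=max(p_gg, 0.15))
            means.append(evolve_homogeneous("G" * 25, pp).mean_by_round()[-1])
        assert all(a < b for a, b in zip(means, means[1:]))
        seed_means = [
            evolve_homogeneous("G" * 25, GameParams(n_initial_purple=n0)).mean_by_round()[-1]
            for n0 in (0, 4, 8, 16, 32)
        ]
        assert all(a < b or (a == b == 0) for a, b in zip(seed_means, seed_means[1:]))


class TestEvolveDeviant:
    @pytest.mark.parametrize(
        "shared,dev,n0",
        [("GG", "HH", 1), ("HH", "GG", 2), ("HG", "GH", 1)],
    )
    def test_matches_enumeration_oracle_n4(self, shared, dev, n0):
        p = GameParams(n_players=4, n_rounds=2, n_initial_purple=n0)
        choices = [list(dev)] + [list(shared)] * 3
        hist = enumerate_game(choices, n0, *P_EXACT)
        mine = evolve_deviant(shared, dev, p)
        for t in range(3):
            oracle = np.array(
                [[float(c) for c in row] for row in joint_count_color_pmf(hist[t], 4, 0)]
            )
            assert np.abs(oracle - mine.joint[t]).max() < 1e-12

    def test_matches_enumeration_oracle_n6(self):
        p = GameParams(n_players=6, n_rounds=3, n_initial_purple=2)
        choices = [["G"] * 3] + [["H"] * 3] * 5
        hist = enumerate_game(choices, 2, *P_EXACT)
        mine = evolve_deviant("HHH", "GGG", p)
        oracle = np.array(
            [[float(c) for c in row] for row in joint_count_color_pmf(hist[-1], 6, 0)]
        )
        assert np.abs(oracle - mine.joint[-1]).max() < 1e-12

    def test_identical_deviant_recovers_homogeneous_survival(self, params):
        # with deviant == shared, exchangeability gives survival = 1 - E[n_T]/N
        for shared in ("G" * 25, "H" * 25):
            dev = evolve_deviant(shared, shared, params)
            homog = evolve_homogeneous(shared, params)
            expect = 1.0 - homog.mean_by_round()[-1] / params.n_players
            assert dev.final_survival() == pytest.approx(expect, abs=1e-10)

    def test_zero_probability_params(self):
        p = GameParams(p_gg=0, p_gh=0, p_hh=0)
        dev = evolve_deviant("G" * 25, "H" * 25, p)
        assert dev.final_survival() == pytest.approx(1 - 8 / 100, abs=1e-12)

    def test_survival_non_increasing(self, params):
        dev = evolve_deviant("G" * 25, "H" * 25, params)
        assert np.all(np.diff(dev.survival) <= 1e-12)
        assert np.allclose(dev.joint.sum(axis=(1, 2)), 1.0, atol=1e-10)


class TestExpectedPayoff:
    def test_examples(self, params):
        assert expected_payoff("H" * 25, 1.0, params) == 5.0
        assert expected_payoff("G" * 25, 0.0, params) == 0.0
        assert expected_payoff("G" * 25, 0.92, params) == pytest.approx(0.92)

    def test_invalid_survival(self, params):
        with pytest.raises(ValueError):
            expected_payoff("G" * 25, 1.2, params)


class TestBestResponse:
    def test_risky_deviant_dominates_in_mixed_and_safe_populations(self, params):
        """The social-dilemma signature: against all-safe and front-loaded
        shared strategies, a lone all-H deviant strictly out-earns a lone
        all-G deviant."""
        T = params.n_rounds
        scenarios = {
            "all_g": "G" * T,
            "rs5": "H" * 5 + "G" * (T - 5),
            "rs15": "H" * 15 + "G" * (T - 15),
        }
        table = best_response_table(scenarios, params)
        assert table["h_dominates"].all()

    def test_all_risky_population_is_the_boundary_case(self, params):
        """Against a fully risky population the two deviant payoffs are
        nearly equal; the exact chain puts the safe deviant marginally
        ahead (within half a percent), so dominance is not strict there."""
        table = best_response_table({"all_h": "H" * params.n_rounds}, params)
        row = table.iloc[0]
        assert row.deviant_g_payoff == pytest.approx(row.deviant_h_payoff, rel=5e-3)

    def test_zero_probability_ratio(self):
        p = GameParams(p_gg=0, p_gh=0, p_hh=0)
        table = best_response_table({"all_g": "G" * 25}, p)
        row = table.iloc[0]
        # identical survival, points ratio 1000/200
        assert row.deviant_h_payoff == pytest.approx(5 * row.deviant_g_payoff)

    def test_empty_scenarios_rejected(self, params):
        with pytest.raises(ValueError):
            best_response_table({}, params)


class TestFrontLoading:
    @pytest.mark.parametrize("h", [1, 5, 12])
    def test_early_risk_beats_late_risk(self, params, h):
        """Against an all-safe population, taking the h risky rounds first
        yields survival at least as high as taking them last: the purple
        pool only grows, so risk taken late is riskier."""
        T = params.n_rounds
        front = "H" * h + "G" * (T - h)
        back = "G" * (T - h) + "H" * h
        shared = "G" * T
        s_front = evolve_deviant(shared, front, params).final_survival()
        s_back = evolve_deviant(shared, back, params).final_survival()
        assert s_front >= s_back
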