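"""Likelihood kernel, simulated likelihood and quadrant invariance."""

import numpy as np
import pytest

import antimix as am
from antimix.mmnl_core import conventional_loglik

from conftest import make_config


def toy_panel(chosen_rows, n_alts, base=0):
    return am.ChoicePanel(
        chosen=tuple(np.asarray(c) for c in chosen_rows), n_alts=n_alts,
        base_alt=base,
    )


class TestLogitChoiceProb:
    def test_equal_utilities_give_uniform(self):
        np.testing.assert_allclose(
            am.logit_choice_prob(np.zeros(4)), np.full(4, 0.25)
        )

    def test_log_two_closed_form(self):
        np.testing.assert_allclose(
            am.logit_choice_prob(np.array([np.log(2), 0.0])), [2 / 3, 1 / 3]
        )

    def test_shift_invariance_and_normalization(self):
        u = np.array([1.3, -0.4, 2.2, 0.0])
        p = am.logit_choice_prob(u)
        np.testing.assert_allclose(p, am.logit_choice_prob(u + 57.0), atol=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            am.logit_choice_prob(np.array([0.0, np.inf]))


class TestPanelLogprob:
    def test_single_binary_situation(self):
        panel = toy_panel([[0]], n_alts=2)
        assert am.panel_logprob_given_beta(panel, 0, [0.0]) == pytest.approx(
            np.log(0.5)
        )

    def test_twenty_quarter_probability_situations(self):
        panel = toy_panel([np.zeros(20, dtype=int)], n_alts=4)
        got = am.panel_logprob_given_beta(panel, 0, [0.0, 0.0, 0.0])
        assert got == pytest.approx(20 * np.log(0.25), abs=1e-12)

    def test_matches_direct_product_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            t, j = rng.integers(1, 6), int(rng.integers(2, 5))
            chosen = rng.integers(0, j, size=t)
            panel = toy_panel([chosen], n_alts=j)
            beta = rng.normal(size=j - 1)
            # oracle: multiply raw probabilities situation by situation
            asc = np.concatenate([[0.0], beta])
            prod = 1.0
            for c in chosen:
                prod *= am.logit_choice_prob(asc)[c]
            got = am.panel_logprob_given_beta(panel, 0, beta)
            assert got == pytest.approx(np.log(prod), abs=1e-10)
            assert got <= 0.0


class TestTransformDraws:
    def test_zero_draw_returns_mean(self):
        p = am.MixingParams(means=[1.0, -2.0], chol=np.eye(2), mixed_alts=(1, 2))
        np.testing.assert_allclose(
            am.transform_draws(np.zeros(2), p), [1.0, -2.0]
        )

    def test_one_dim_scaling(self):
        p = am.MixingParams(means=[0.0], chol=[[2.5]], mixed_alts=(1,))
        assert am.transform_draws(np.array([1.3]), p) == pytest.approx(3.25)

    def test_triangular_multiply(self):
        p = am.MixingParams(
            means=[0.5, 0.5], chol=[[1.0, 0.0], [0.5, 2.0]], mixed_alts=(1, 2)
        )
        np.testing.assert_allclose(
            am.transform_draws(np.ones(2), p), [1.5, 3.0]
        )


class TestFlipFactor:
    def test_diagonal_flip(self):
        out = am.flip_factor(np.diag([1.0, 2.0, 3.0]), (-1, 1, -1))
        np.testing.assert_array_equal(out, np.diag([-1.0, 2.0, -3.0]))

    def test_identity_signs(self):
        q = np.array([[1.0, 0.0], [0.5, 2.0]])
        np.testing.assert_array_equal(am.flip_factor(q, (1, 1)), q)

    def test_column_flip_two_by_two(self):
        q = np.array([[1.0, 0.0], [0.5, 2.0]])
        out = am.flip_factor(q, (-1, 1))
        np.testing.assert_array_equal(out, [[-1.0, 0.0], [-0.5, 2.0]])
        np.testing.assert_array_equal(out @ out.T, q @ q.T)

    def test_covariance_conserved_for_random_factors(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(1, 5))
            q = np.tril(rng.normal(size=(n, n)))
            cov = q @ q.T
            for signs in am.all_quadrants(n):
                out = am.flip_factor(q, signs)
                np.testing.assert_allclose(
                    out @ out.T, cov, rtol=1e-15, atol=1e-15
                )

    def test_rejects_bad_signs(self):
        with pytest.raises(ValueError):
            am.flip_factor(np.eye(2), (2, 1))


class TestSimulatedLoglik:
    def test_degenerate_mixing_equals_conventional_logit(self, small_sim):
        panel = small_sim.panel
        params = am.MixingParams(
            means=[0.6, -0.2, 1.1], chol=np.zeros((3, 3)), mixed_alts=(1, 2, 3)
        )
        draws = am.build_draws(make_config(r=16, i=panel.n_individuals))
        sl = am.simulated_loglik(panel, params, draws)
        direct = sum(
            am.panel_logprob_given_beta(panel, i, params.means, params)
            for i in range(panel.n_individuals)
        )
        assert sl == pytest.approx(direct, abs=1e-8)
        assert sl == pytest.approx(conventional_loglik(panel, params), abs=1e-10)

    def test_matches_per_individual_loop_oracle(self, small_sim, small_params):
        panel, params = small_sim.panel, small_params
        draws = am.build_draws(make_config(r=8, i=panel.n_individuals))
        # oracle: raw average of exponentiated panel products, per individual
        ll = 0.0
        for i in range(panel.n_individuals):
            probs = [
                np.exp(
                    am.panel_logprob_given_beta(
                        panel, i,
                        am.transform_draws(draws.points[i, r], params),
                        params,
                    )
                )
                for r in range(8)
            ]
            ll += np.log(np.mean(probs))
        assert am.simulated_loglik(panel, params, draws) == pytest.approx(
            ll, abs=1e-8
        )

    def test_dimension_mismatch_rejected(self, small_sim, small_params):
        draws = am.build_draws(
            make_config(n_dims=2, r=8, i=small_sim.panel.n_individuals)
        )
        with pytest.raises(ValueError, match="dimension"):
            am.simulated_loglik(small_sim.panel, small_params, draws)

    def test_quadrature_oracle_one_dim(self):
        # I=1, T=1, J=2, mean 0.5, sd 1: Gauss-Hermite is near-exact
        panel = toy_panel([[0]], n_alts=2, base=1)
        params = am.MixingParams(means=[0.5], chol=[[1.0]], mixed_alts=(0,))
        x, w = np.polynomial.hermite.hermgauss(64)
        probs = 1.0 / (1.0 + np.exp(-(0.5 + np.sqrt(2) * x)))
        gh = np.log((w / np.sqrt(np.pi)) @ probs)

        def sl(r):
            cfg = am.DrawConfig(
                n_dims=1, primes=(2,), draws_per_individual=r, n_individuals=1,
            )
            return am.simulated_loglik(panel, params, am.build_draws(cfg))

        assert abs(sl(10**5) - gh) < 1e-4
        assert abs(sl(10**4) - gh) < abs(sl(10**2) - gh)


class TestQuadrantScan:
    def test_three_dim_scan_has_eight_entries(self, small_sim, small_params):
        draws = am.build_draws(
            make_config(r=16, i=small_sim.panel.n_individuals)
        )
        scan = am.quadrant_scan(small_sim.panel, small_params, draws)
        assert len(scan.per_quadrant_ll) == 8
        assert scan.max_abs_difference >= 0.0

    def test_full_antithetic_draws_are_quadrant_invariant(
        self, small_sim, small_params
    ):
        draws = am.build_draws(
            make_config(r=96, i=small_sim.panel.n_individuals, mode="full")
        )
        scan = am.quadrant_scan(small_sim.panel, small_params, draws)
        assert scan.max_abs_difference <= 1e-8

    def test_conventional_draws_leave_a_gap(self, small_sim, small_params):
        draws = am.build_draws(
            make_config(r=96, i=small_sim.panel.n_individuals, mode="none")
        )
        scan = am.quadrant_scan(small_sim.panel, small_params, draws)
        assert scan.max_abs_difference > 0.01

    def test_gap_shrinks_from_100_to_1000_draws(self, small_sim, small_params):
        def gap(r):
            draws = am.build_draws(
                make_config(r=r, i=small_sim.panel.n_individuals, mode="none")
            )
            return am.quadrant_scan(
                small_sim.panel, small_params, draws
            ).max_abs_difference

        assert gap(1000) < gap(100)

    def test_one_dim_mode_partial_invariance(self, small_sim, small_params):
        panel, params = small_sim.panel, small_params
        draws = am.build_draws(
            make_config(r=16, i=panel.n_individuals, mode="one_dim")
        )
        base = am.simulated_loglik(panel, params, draws)
        from dataclasses import replace

        def ll(signs):
            return am.simulated_loglik(
                panel,
                replace(params, chol=am.flip_factor(params.chol, signs)),
                draws,
            )

        # global flip: exact symmetry
        assert ll((-1, -1, -1)) == pytest.approx(base, abs=1e-8)
        # proper-subset flips: at least one strictly different at small R
        partial = [ll(s) for s in am.all_quadrants(3) if 0 < sum(x < 0 for x in s) < 3]
        assert max(abs(v - base) for v in partial) > 1e-6

    def test_symmetric_kernel_removes_all_quadrant_spread(self, small_sim):
        # with a kernel symmetric in each coordinate of beta (and zero-mean
        # diagonal mixing, where a column sign flip is exactly a coordinate
        # sign flip of beta), even conventional draws give a quadrant-
        # invariant simulated likelihood: the asymmetry of the logit kernel,
        # not the draws alone, creates the spread
        params = am.MixingParams(
            means=np.zeros(3), chol=np.diag([1.0, 0.8, 1.2]),
            mixed_alts=(1, 2, 3),
        )
        draws = am.build_draws(
            make_config(r=32, i=small_sim.panel.n_individuals, mode="none")
        )

        def symmetric_kernel(betas, panel):
            return -np.square(betas).sum(axis=-1)

        scan = am.quadrant_scan(
            small_sim.panel, params, draws, kernel=symmetric_kernel
        )
        assert scan.max_abs_difference <= 1e-10
        # the logit kernel on the same draws is not quadrant-invariant
        logit_scan = am.quadrant_scan(small_sim.panel, params, draws)
        assert logit_scan.max_abs_difference > 1e-6

    def test_rejects_non_canonical_factor(self, small_sim, small_params):
        from dataclasses import replace

        bad = replace(
            small_params, chol=am.flip_factor(small_params.chol, (-1, 1, 1))
        )
        draws = am.build_draws(
            make_config(r=8, i=small_sim.panel.n_individuals)
        )
        with pytest.raises(ValueError, match="canonical"):
            am.quadrant_scan(small_sim.panel, bad, draws)


class TestChoicePanelValidation:
    def test_requires_valid_chosen_indices(self):
        with pytest.raises(ValueError):
            toy_panel([[4]], n_alts=4)

    def test_counts_and_situations(self):
        panel = toy_panel([[0, 1, 1], [2]], n_alts=3)
        np.testing.assert_array_equal(panel.n_situations, [3, 1])
        np.testing.assert_array_equal(
            panel.choice_counts, [[1, 2, 0], [0, 0, 1]]
        )

    def test_attributes_enter_utilities(self):
        # one attribute with coefficient 2 shifts utilities like an ASC would
        chosen = [np.array([0, 1])]
        x = np.zeros((2, 2, 1))
        x[:, 1, 0] = 0.5  # alternative 1 carries attribute level 0.5
        panel = am.ChoicePanel(
            chosen=tuple(chosen), n_alts=2, attributes=(x,), attr_names=("z",)
        )
        params = am.MixingParams(
            means=[0.0], chol=[[0.0]], mixed_alts=(1,),
            fixed_coeffs=np.array([2.0]),
        )
        # utility of alt 1 = 0 + 2*0.5 = 1.0 in both situations
        p1 = am.logit_choice_prob(np.array([0.0, 1.0]))
        expect = np.log(p1[0]) + np.log(p1[1])
        assert conventional_loglik(panel, params) == pytest.approx(expect)
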