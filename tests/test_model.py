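"""BYM model: conditionals, validation, sampler behaviour, hyperprior analytics."""

import warnings

import numpy as np
import pytest
from numpy.random import default_rng

from icarmap import (
    AdjacencyList,
    ModelSpec,
    SamplerConfig,
    build_model,
    equal_weights,
    icar_conditional,
    implied_sd_prior,
    product_weights,
    run_mcmc,
)
from icarmap.model import tau_gibbs
from icarmap.weights import WeightSpec


class TestIcarConditional:
    def test_equal_weights_average(self, chain3):
        ws = equal_weights(chain3)
        S = np.array([0.2, 0.0, 0.4])
        mean, var = icar_conditional(1, S, ws, nu_s=0.8)
        assert mean == pytest.approx(0.3)
        assert var == pytest.approx(0.8 / 2)

    def test_single_neighbour_copies(self, chain3):
        ws = equal_weights(chain3)
        S = np.array([0.0, -1.7, 0.0])
        mean, var = icar_conditional(0, S, ws, nu_s=1.0)
        assert mean == pytest.approx(-1.7)
        assert var == pytest.approx(1.0)

    def test_weighted_average(self, chain3):
        ws = product_weights(chain3, [1.0, 1.0, 3.0])
        S = np.array([0.0, 0.0, 0.4])
        mean, var = icar_conditional(1, S, ws, nu_s=1.0)
        assert mean == pytest.approx(0.3)
        assert var == pytest.approx(1.0 / 4)

    def test_weight_doubling_with_variance_rescale_invariant(self, chain3):
        """Doubling all weights and nu_s leaves the conditional unchanged."""
        S = np.array([0.3, -0.1, 0.5])
        ws1 = equal_weights(chain3)
        ws2 = WeightSpec(chain3, {p: 2.0 for p in chain3.pairs()}, "custom")
        for i in range(3):
            m1, v1 = icar_conditional(i, S, ws1, nu_s=0.7)
            m2, v2 = icar_conditional(i, S, ws2, nu_s=1.4)
            assert m1 == pytest.approx(m2)
            assert v1 == pytest.approx(v2)

    def brute_force_conditional(self, i, S, ws, nu_s):
        """Quadratic-fit oracle: evaluate the joint pairwise-difference
        exponent at three values of s_i and complete the square."""

        def logjoint(si):
            s = S.copy()
            s[i] = si
            return -sum(
                w * (s[a] - s[b]) ** 2 for (a, b), w in ws.w.items()
            ) / (2 * nu_s)

        f0, f1, f2 = logjoint(0.0), logjoint(1.0), logjoint(2.0)
        a = (f2 - 2 * f1 + f0) / 2.0  # coefficient of si^2
        b = f1 - f0 - a
        return -b / (2 * a), -1 / (2 * a)

    @pytest.mark.parametrize(
        "edges, n",
        [
            ([(0, 1)], 2),
            ([(0, 1), (1, 2)], 3),
            ([(0, 1), (1, 2), (2, 3), (0, 2)], 4),
            ([(0, 1), (1, 2), (2, 3), (3, 4), (0, 4), (1, 3)], 5),
        ],
    )
    def test_conditional_matches_joint_density(self, edges, n):
        """Eq-form conditional equals the brute-force conditional of the
        joint pairwise-difference density on every node of small graphs."""
        adj = AdjacencyList.from_pairs(n, edges)
        rng = default_rng(5)
        values = rng.uniform(0.5, 2.0, n)
        ws = product_weights(adj, values)
        S = rng.normal(0, 1, n)
        nu = 0.37
        for i in range(n):
            mean, var = icar_conditional(i, S, ws, nu)
            bm, bv = self.brute_force_conditional(i, S, ws, nu)
            assert mean == pytest.approx(bm, abs=1e-10)
            assert var == pytest.approx(bv, abs=1e-10)


class TestBuildModel:
    def make_spec(self, adj, n, E=None):
        return ModelSpec(E=np.ones(n) if E is None else E, weights=equal_weights(adj))

    def test_no_covariates_accepted(self, chain3):
        m = build_model(np.array([1, 2, 0]), self.make_spec(chain3, 3))
        assert m.q == 0

    def test_island_named(self):
        adj = AdjacencyList.from_pairs(3, [(0, 1)])
        ws = WeightSpec(adj, {(0, 1): 1.0}, "custom")
        with pytest.raises(ValueError, match=r"\[2\]"):
            build_model(np.array([1, 1, 1]), ModelSpec(E=np.ones(3), weights=ws))

    def test_single_area_rejected(self):
        adj = AdjacencyList(1, [set()])
        ws = WeightSpec(adj, {}, "custom")
        with pytest.raises(ValueError, match="single area"):
            build_model(np.array([1]), ModelSpec(E=np.ones(1), weights=ws))

    def test_disconnected_rejected(self):
        adj = AdjacencyList.from_pairs(4, [(0, 1), (2, 3)])
        ws = WeightSpec(adj, {(0, 1): 1.0, (2, 3): 1.0}, "custom")
        with pytest.raises(ValueError, match="connected"):
            build_model(np.ones(4, dtype=int), ModelSpec(E=np.ones(4), weights=ws))

    def test_negative_counts_rejected(self, chain3):
        with pytest.raises(ValueError, match="negative"):
            build_model(np.array([1, -1, 0]), self.make_spec(chain3, 3))

    def test_zero_expected_floored_with_warning(self, chain3):
        E = np.array([1.0, 0.0, 1.0])
        with pytest.warns(UserWarning, match=r"\[1\]"):
            m = build_model(np.array([1, 0, 1]), self.make_spec(chain3, 3, E))
        assert m.spec.E[1] == m.spec.e_floor
        assert m.floored_areas == [1]

    def test_colour_groups_are_independent_sets(self, small_dataset):
        spec = ModelSpec(E=np.ones(25), weights=equal_weights(small_dataset.adjacency))
        m = build_model(np.ones(25, dtype=int), spec)
        pairs = small_dataset.adjacency.pairs()
        for idx in m.colour_groups:
            group = set(idx.tolist())
            assert not any((min(i, j), max(i, j)) in pairs
                           for i in group for j in group if i != j)


def tiny_model(seed_y=0):
    adj = AdjacencyList.from_pairs(4, [(0, 1), (1, 2), (2, 3), (0, 3)])
    Y = np.array([3, 1, 4, 2])
    return build_model(Y, ModelSpec(E=np.full(4, 2.0), weights=equal_weights(adj)))


class TestRunMcmc:
    def test_same_seed_bit_identical(self):
        cfg = SamplerConfig(n_chains=2, burn_in=200, keep=100, seed=31)
        a = run_mcmc(tiny_model(), cfg)
        b = run_mcmc(tiny_model(), cfg)
        for name in ("alpha", "beta", "S", "U", "nu_s", "nu_u", "deviance"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_sum_to_zero_every_retained_iteration(self):
        cfg = SamplerConfig(n_chains=2, burn_in=200, keep=200, seed=8)
        d = run_mcmc(tiny_model(), cfg)
        assert np.allclose(d.S.sum(axis=2), 0.0, atol=1e-10)
        assert np.all(d.nu_s > 0) and np.all(d.nu_u > 0)

    def test_null_data_risks_near_one(self):
        """Y = E on a 5x5 grid: smoothed risks all close to 1."""
        from icarmap import extract_queen_adjacency
        from tests.test_adjacency import unit_grid

        adj = extract_queen_adjacency(unit_grid(5, 5), 0.0)
        E = np.full(25, 10.0)
        Y = np.full(25, 10)
        model = build_model(Y, ModelSpec(E=E, weights=equal_weights(adj)))
        d = run_mcmc(model, SamplerConfig(n_chains=2, burn_in=2000, keep=1500, seed=4))
        post_mean = d.r.reshape(-1, 25).mean(axis=0)
        assert np.all((post_mean > 0.8) & (post_mean < 1.2))

    def test_equal_and_unit_product_weights_identical_chains(self):
        adj = AdjacencyList.from_pairs(4, [(0, 1), (1, 2), (2, 3), (0, 3)])
        Y = np.array([3, 1, 4, 2])
        E = np.full(4, 2.0)
        cfg = SamplerConfig(n_chains=2, burn_in=300, keep=200, seed=12)
        d1 = run_mcmc(build_model(Y, ModelSpec(E=E, weights=equal_weights(adj))), cfg)
        ws = product_weights(adj, np.ones(4))
        d2 = run_mcmc(build_model(Y, ModelSpec(E=E, weights=ws)), cfg)
        assert np.array_equal(d1.S, d2.S)
        assert np.array_equal(d1.alpha, d2.alpha)


class TestTauGibbs:
    def test_moments_match_gamma_conditional(self):
        """With S fixed, precision draws match the closed-form Gamma
        full conditional Gamma(a + (n-1)/2, b + quad/2) moments."""
        a, b = 0.5, 0.0005
        n, quad = 25, 3.7
        shape, rate = a + (n - 1) / 2.0, b + quad / 2.0
        rng = default_rng(77)
        draws = tau_gibbs(rng, a, b, (n - 1) / 2.0, quad, size=100_000)
        assert draws.mean() == pytest.approx(shape / rate, rel=0.02)
        assert draws.var() == pytest.approx(shape / rate**2, rel=0.02)


class TestImpliedSdPrior:
    def test_scaling_property(self):
        """Multiplying the rate by c multiplies the median sd by sqrt(c)."""
        m1, _, _ = implied_sd_prior(0.5, 0.0005)
        m2, _, _ = implied_sd_prior(0.5, 0.0005 * 4.0)
        assert m2 == pytest.approx(2.0 * m1, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        for a, b in [(0, 1), (1, 0), (-1, 1)]:
            with pytest.raises(ValueError):
                implied_sd_prior(a, b)
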