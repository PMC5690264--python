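"""Convergence diagnostics, DIC, risk summaries, exceedance probabilities."""

import numpy as np
import pytest
from numpy.random import default_rng
from scipy.special import digamma

from icarmap import (
    SamplerConfig,
    dic,
    exceedance_probabilities,
    gelman_rubin,
    mc_error,
    spatial_fraction,
    summarize_risks,
)
from icarmap.diagnostics import diagnostics_report
from icarmap.model import PosteriorDraws


def make_draws(r_draws, Y, E, S=None, U=None):
    """Wrap raw relative-risk draws (m, n) into a single-chain PosteriorDraws."""
    r_draws = np.asarray(r_draws, dtype=float)
    m, n = r_draws.shape
    alpha = np.zeros((1, m))
    S_arr = np.log(r_draws)[None] if S is None else np.asarray(S)[None]
    if S is None:
        U_arr = np.zeros((1, m, n))
    else:
        U_arr = np.asarray(U)[None]
    lam = np.asarray(E) * r_draws
    from scipy.special import gammaln

    dev = -2.0 * (
        np.asarray(Y) * np.log(lam) - lam - gammaln(np.asarray(Y) + 1.0)
    ).sum(axis=1)
    d = PosteriorDraws(
        alpha=alpha,
        beta=np.zeros((1, m, 0)),
        S=S_arr,
        U=U_arr,
        nu_s=np.ones((1, m)),
        nu_u=np.ones((1, m)),
        deviance=dev[None],
        Y=np.asarray(Y),
        E=np.asarray(E, dtype=float),
        config=SamplerConfig(n_chains=1, burn_in=1, keep=m),
        scheme_label="custom",
    )
    d._X = np.zeros((n, 0))
    return d


class TestGelmanRubin:
    def test_identical_chains_exactly_one(self):
        c = np.tile(default_rng(0).normal(size=500), (2, 1))
        assert gelman_rubin(c) == 1.0

    def test_disjoint_chains_large(self):
        rng = default_rng(1)
        c = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert gelman_rubin(c) > 3

    def test_same_distribution_near_one(self):
        rng = default_rng(2)
        c = rng.normal(size=(2, 5000))
        assert gelman_rubin(c) < 1.05

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestMcError:
    def test_iid_ratio_small(self):
        chain = default_rng(3).normal(size=100_000)
        mcse, ratio = mc_error(chain)
        assert ratio < 0.05
        assert mcse == pytest.approx(chain.std() / np.sqrt(chain.size), rel=0.5)

    def test_constant_chain_zero(self):
        mcse, ratio = mc_error(np.full(1000, 3.3))
        assert mcse == pytest.approx(0.0, abs=1e-12)

    def test_autocorrelated_chain_larger_ratio(self):
        rng = default_rng(4)
        n, phi = 20_000, 0.9
        eps = rng.normal(size=n)
        ar = np.empty(n)
        ar[0] = eps[0]
        for t in range(1, n):
            ar[t] = phi * ar[t - 1] + eps[t]
        _, r_ar = mc_error(ar)
        _, r_iid = mc_error(rng.normal(size=n))
        assert r_ar > r_iid

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            mc_error(np.arange(10))


class TestDic:
    def test_degenerate_posterior_zero_pd(self):
        Y, E = np.array([4, 2, 7]), np.array([3.0, 2.0, 5.0])
        r = np.tile([1.2, 0.9, 1.4], (200, 1))
        dbar, pd_, dic_ = dic(make_draws(r, Y, E))
        assert pd_ == pytest.approx(0.0, abs=1e-9)
        assert dic_ == pytest.approx(dbar)

    def test_poisson_gamma_conjugate_pd(self):
        """Single-area conjugate toy: with posterior lambda ~ Gamma(A, B),
        pD = 2 y (log A - digamma(A)) analytically."""
        a0, b0, y = 2.0, 1.0, 7
        A, B = a0 + y, b0 + 1.0
        rng = default_rng(6)
        lam = rng.gamma(A, 1.0 / B, size=100_000)
        d = make_draws(lam[:, None], np.array([y]), np.array([1.0]))
        _, pd_, _ = dic(d)
        analytic = 2.0 * y * (np.log(A) - digamma(A))
        assert pd_ == pytest.approx(analytic, rel=0.10)


class TestSummaries:
    def test_constant_risk(self):
        d = make_draws(np.ones((100, 3)), np.ones(3, dtype=int), np.ones(3))
        s = summarize_risks(d)
        assert np.allclose(s["per_area"]["mean"], 1.0)
        assert np.allclose(s["per_area"]["q2.5"], 1.0)
        assert np.allclose(s["per_area"]["q97.5"], 1.0)

    def test_quantiles_match_sort_oracle(self):
        rng = default_rng(7)
        r = rng.lognormal(size=(5000, 2))
        d = make_draws(r, np.ones(2, dtype=int), np.ones(2))
        s = summarize_risks(d)["per_area"]
        for j in range(2):
            assert s["median"][j] == pytest.approx(np.quantile(r[:, j], 0.5))
            assert s["q2.5"][j] == pytest.approx(np.quantile(r[:, j], 0.025))

    def test_region_order_statistics(self):
        rng = default_rng(8)
        d = make_draws(rng.lognormal(size=(500, 6)), np.ones(6, int), np.ones(6))
        reg = summarize_risks(d)["region"]
        assert reg["min"] <= reg["median"] <= reg["max"]


class TestExceedance:
    def test_all_above_counted_everywhere(self):
        d = make_draws(np.full((50, 4), 2.0), np.ones(4, int), np.ones(4))
        p, counts = exceedance_probabilities(d)
        assert np.all(p == 1.0)
        assert all(c == 4 for c in counts.values())

    def test_strict_inequality_at_threshold(self):
        """P_i exactly 0.5 must NOT be counted at the 0.5 threshold."""
        r = np.concatenate([np.full((50, 1), 2.0), np.full((50, 1), 0.5)])
        d = make_draws(r, np.ones(1, int), np.ones(1))
        p, counts = exceedance_probabilities(d, thresholds=(0.5,))
        assert p[0] == 0.5
        assert counts[0.5] == 0

    def test_hand_built_fractions(self):
        m = 100
        r = np.ones((m, 3))
        r[:80, 0] = 1.5   # P = 0.80
        r[:60, 1] = 1.5   # P = 0.60
        r[:40, 2] = 1.5   # P = 0.40
        d = make_draws(r, np.ones(3, int), np.ones(3))
        p, counts = exceedance_probabilities(d, thresholds=(0.5, 0.75))
        assert list(p) == [0.80, 0.60, 0.40]
        assert counts[0.5] == 2 and counts[0.75] == 1


class TestSpatialFraction:
    def make(self, S, U):
        m, n = S.shape
        r = np.exp(S + U)
        return make_draws(r, np.ones(n, int), np.ones(n), S=S, U=U)

    def test_pure_spatial(self):
        S = default_rng(9).normal(size=(50, 8))
        f, _ = spatial_fraction(self.make(S, np.zeros_like(S)))
        assert f == 1.0

    def test_pure_unstructured(self):
        U = default_rng(10).normal(size=(50, 8))
        f, _ = spatial_fraction(self.make(np.zeros_like(U), U))
        assert f == 0.0

    def test_symmetric_components_half(self):
        rng = default_rng(11)
        S = rng.normal(size=(400, 200))
        U = rng.normal(size=(400, 200))
        f, (lo, hi) = spatial_fraction(self.make(S, U))
        assert f == pytest.approx(0.5, abs=0.02)
        assert lo <= f <= hi


def test_full_report_on_model_fit(small_fit):
    rep = diagnostics_report(small_fit)
    assert rep.DIC == pytest.approx(rep.Dbar + rep.pD)
    assert 0 <= rep.spatial_fraction <= 1
    assert all(v >= 1.0 for v in rep.rhat.values())
    assert rep.pD > 0
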