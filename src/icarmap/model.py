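"""Poisson BYM convolution model with an ICAR spatial prior.

The model for area-level counts Y_i with offset E_i (expected counts) is

    Y_i ~ Poisson(lambda_i),   log lambda_i = log E_i + alpha + x_i' beta + S_i + U_i

with unstructured effects U_i ~ Normal(0, nu_u) and spatially structured
effects S given an intrinsic CAR prior under symmetric weights w_ij:

    S_i | S_{-i} ~ Normal( sum_j w_ij S_j / w_i+ ,  nu_s / w_i+ )

which is the rho = 1 limit of the proper CAR model (rho is fixed here).
Priors: improper flat on alpha, Normal(0, 1e4) on each beta, and Gamma(a, b)
on the precisions 1/nu_u and 1/nu_s, default (0.5, 0.0005).

Fitting is by Metropolis-within-Gibbs: scalar adaptive random-walk updates
for S (blocked by graph colour so whole independent sets update at once),
U, alpha and beta, and conjugate Gibbs draws for the two precisions.  S is
recentred to sum to zero every sweep, with the shift absorbed into alpha
(valid under the flat prior); this is the standard identifiability fix for
the improper ICAR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.special import gammaln
from scipy.stats import gamma as gamma_dist

from .weights import WeightSpec

RHO = 1.0  # ICAR: spatial dependency parameter fixed at its maximum

DEFAULT_PRECISION_PRIOR = (0.5, 0.0005)
ALT_PRECISION_PRIOR = (0.001, 0.001)


@dataclass
class ModelSpec:
    """Data and prior settings for one BYM fit."""

    E: np.ndarray
    weights: WeightSpec
    X: np.ndarray | None = None
    prior_precision: tuple = DEFAULT_PRECISION_PRIOR
    beta_prior_var: float = 1e4
    e_floor: float = 1e-4

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        n = self.E.shape[0]
        if self.X is None:
            self.X = np.zeros((n, 0))
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        a, b = self.prior_precision
        if a <= 0 or b <= 0:
            raise ValueError("Gamma hyperprior parameters must be positive")
        if self.e_floor <= 0:
            raise ValueError("e_floor must be positive")

    @property
    def rho(self) -> float:
        return RHO


@dataclass
class SamplerConfig:
    n_chains: int = 2
    burn_in: int = 20000
    keep: int = 10000
    thin: int = 1
    seed: int = 0
    adapt_window: int = 50
    target_acceptance: float = 0.44

    def __post_init__(self) -> None:
        if min(self.n_chains, self.burn_in, self.keep, self.thin) <= 0:
            raise ValueError("chain counts and lengths must be positive")


@dataclass
class BYMModel:
    """Validated internal state: data, weights, and precomputed structures."""

    Y: np.ndarray
    spec: ModelSpec
    floored_areas: list = field(default_factory=list)

    # filled in build_model
    W = None
    w_plus: np.ndarray = None
    colour_groups: list = None
    log_fact: np.ndarray = None

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def q(self) -> int:
        return self.spec.X.shape[1]


def build_model(Y: np.ndarray, spec: ModelSpec) -> BYMModel:
    """Validate data against the spec and precompute sampler structures.

    Rejects island areas (no neighbours) and disconnected maps: the ICAR
    rank correction n-1 assumes a single connected component.  Zero
    expected counts are floored at ``spec.e_floor`` with a warning naming
    the affected areas.
    """
    Y = np.asarray(Y)
    if np.any(Y < 0):
        raise ValueError("negative case counts")
    n = Y.shape[0]
    if n < 2:
        raise ValueError("ICAR is undefined for a single area")
    adj = spec.weights.adjacency
    if adj.n != n or spec.E.shape[0] != n or spec.X.shape[0] != n:
        raise ValueError("Y, E, X and adjacency sizes disagree")
    islands = adj.islands()
    if islands:
        raise ValueError(f"island areas (no neighbours): {islands}")
    if not adj.is_connected():
        comps = list(nx.connected_components(adj.to_graph()))
        raise ValueError(
            f"adjacency graph has {len(comps)} connected components; "
            "the ICAR sum-to-zero constraint assumes one"
        )
    if np.any(spec.E < 0):
        raise ValueError("negative expected counts")
    floored = [int(i) for i in np.where(spec.E == 0)[0]]
    E = spec.E.copy()
    if floored:
        warnings.warn(
            f"expected count 0 floored at {spec.e_floor} for areas {floored}",
            stacklevel=2,
        )
        E[floored] = spec.e_floor
    spec = ModelSpec(
        E=E,
        weights=spec.weights,
        X=spec.X,
        prior_precision=spec.prior_precision,
        beta_prior_var=spec.beta_prior_var,
        e_floor=spec.e_floor,
    )
    model = BYMModel(Y=Y, spec=spec, floored_areas=floored)
    model.W = spec.weights.to_sparse()
    model.w_plus = spec.weights.w_plus
    colours = nx.greedy_color(adj.to_graph(), strategy="largest_first")
    ncol = max(colours.values()) + 1
    model.colour_groups = [
        np.array(sorted(i for i, c in colours.items() if c == g), dtype=int)
        for g in range(ncol)
    ]
    model.log_fact = gammaln(Y + 1.0)
    return model


def icar_conditional(i: int, S: np.ndarray, ws: WeightSpec, nu_s: float):
    """Full-conditional mean and variance of S_i under the ICAR prior:
    Normal(sum_j w_ij S_j / w_i+, nu_s / w_i+)."""
    wp = ws.w_plus[i]
    if wp <= 0:
        raise ValueError(f"area {i} has zero total weight")
    m = sum(ws.pair_weight(i, j) * S[j] for j in ws.adjacency.neighbors[i])
    return m / wp, nu_s / wp


@dataclass
class PosteriorDraws:
    """Retained MCMC output, shaped (n_chains, keep, ...)."""

    alpha: np.ndarray
    beta: np.ndarray
    S: np.ndarray
    U: np.ndarray
    nu_s: np.ndarray
    nu_u: np.ndarray
    deviance: np.ndarray
    Y: np.ndarray
    E: np.ndarray
    config: SamplerConfig
    scheme_label: str = "custom"

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        """Retained draws per chain."""
        return self.alpha.shape[1]

    @property
    def n_areas(self) -> int:
        return self.S.shape[2]

    @property
    def r(self) -> np.ndarray:
        """Relative risks exp(alpha + x'beta + S + U), shape (C, m, n)."""
        eta = self.alpha[:, :, None] + self.S + self.U
        if self.beta.shape[2]:
            eta = eta + np.einsum("cmq,nq->cmn", self.beta, self._X)
        return np.exp(eta)

    _X: np.ndarray = None

    def flat(self, name: str) -> np.ndarray:
        """Stack chains: (C*m, ...)."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def lam(self) -> np.ndarray:
        return self.E * self.r


def tau_gibbs(rng, a, b, shape_add, quad, size=None):
    """Precision draw(s) from the Gamma full conditional
    Gamma(a + shape_add, rate b + quad/2), rate parameterisation."""
    return rng.gamma(a + shape_add, 1.0 / (b + 0.5 * quad), size)


def run_mcmc(model: BYMModel, config: SamplerConfig) -> PosteriorDraws:
    """Metropolis-within-Gibbs sampler; fixed seed gives bit-identical draws."""
    spec = model.spec
    Y = model.Y.astype(float)
    E = spec.E
    X = spec.X
    n, q = model.n, model.q
    a, b = spec.prior_precision
    logE = np.log(E)
    W = model.W
    w_plus = model.w_plus
    groups = [(idx, W[idx]) for idx in model.colour_groups]
    sumY = Y.sum()
    target = config.target_acceptance
    n_sweeps = config.burn_in + config.keep * config.thin

    chains = []
    for child in SeedSequence(config.seed).spawn(config.n_chains):
        rng = default_rng(child)
        # initial values, mildly overdispersed across chains
        alpha = float(np.log(max(sumY, 1.0) / E.sum()) + rng.normal(0, 0.3))
        beta = rng.normal(0, 0.05, q)
        S = np.zeros(n)
        U = np.zeros(n)
        nu_s = float(np.exp(rng.normal(np.log(0.1), 0.3)))
        nu_u = float(np.exp(rng.normal(np.log(0.1), 0.3)))
        step_S = np.full(n, 0.5)
        step_U = np.full(n, 0.5)
        step_a = 0.1
        step_b = np.full(q, 0.1)
        xb = X @ beta if q else np.zeros(n)

        out = {
            "alpha": np.empty(config.keep),
            "beta": np.empty((config.keep, q)),
            "S": np.empty((config.keep, n)),
            "U": np.empty((config.keep, n)),
            "nu_s": np.empty(config.keep),
            "nu_u": np.empty(config.keep),
            "deviance": np.empty(config.keep),
        }
        kept = 0
        for t in range(n_sweeps):
            adapting = t < config.burn_in
            gam = (1.0 + t / config.adapt_window) ** -0.6 if adapting else 0.0

            # (1) spatial effects, blocked by graph colour (independent sets)
            for idx, Wg in groups:
                m_w = Wg @ S  # sum_j w_ij S_j for the group
                wp = w_plus[idx]
                cond_mean = m_w / wp
                cur = S[idx]
                prop = cur + step_S[idx] * rng.standard_normal(idx.size)
                lam_cur = E[idx] * np.exp(alpha + xb[idx] + U[idx] + cur)
                logr = (
                    Y[idx] * (prop - cur)
                    - lam_cur * (np.exp(prop - cur) - 1.0)
                    - (wp / (2.0 * nu_s))
                    * ((prop - cond_mean) ** 2 - (cur - cond_mean) ** 2)
                )
                acc = np.log(rng.random(idx.size)) < logr
                S[idx] = np.where(acc, prop, cur)
                if adapting:
                    step_S[idx] *= np.exp(gam * (acc - target))
            shift = S.mean()
            S -= shift
            alpha += shift

            # (2) unstructured effects (conditionally independent given rest)
            lam = E * np.exp(alpha + xb + S + U)
            prop = U + step_U * rng.standard_normal(n)
            logr = (
                Y * (prop - U)
                - lam * (np.exp(prop - U) - 1.0)
                - (prop**2 - U**2) / (2.0 * nu_u)
            )
            acc = np.log(rng.random(n)) < logr
            U = np.where(acc, prop, U)
            if adapting:
                step_U *= np.exp(gam * (acc - target))

            # (3) intercept and regression coefficients
            lam = E * np.exp(alpha + xb + S + U)
            lam_sum = lam.sum()
            d = step_a * rng.standard_normal()
            logr = sumY * d - lam_sum * (np.exp(d) - 1.0)
            acc = np.log(rng.random()) < logr
            if acc:
                alpha += d
            if adapting:
                step_a *= np.exp(gam * (acc - target))
            for jcov in range(q):
                xj = X[:, jcov]
                d = step_b[jcov] * rng.standard_normal()
                logr = (
                    d * (Y @ xj)
                    - lam @ (np.exp(d * xj) - 1.0)
                    - ((beta[jcov] + d) ** 2 - beta[jcov] ** 2)
                    / (2.0 * spec.beta_prior_var)
                )
                acc = np.log(rng.random()) < logr
                if acc:
                    beta[jcov] += d
                    xb = xb + d * xj
                    lam = lam * np.exp(d * xj)
                if adapting:
                    step_b[jcov] *= np.exp(gam * (acc - target))

            # (4) conjugate precision updates
            nu_u = 1.0 / tau_gibbs(rng, a, b, n / 2.0, U @ U)
            quad = S @ (w_plus * S) - S @ (W @ S)
            nu_s = 1.0 / tau_gibbs(rng, a, b, (n - 1) / 2.0, quad)

            if not (np.isfinite(alpha) and nu_s > 0 and nu_u > 0 and np.isfinite(S @ S)):
                raise FloatingPointError(f"non-finite log-posterior at sweep {t}")

            if t >= config.burn_in and (t - config.burn_in) % config.thin == 0:
                loglam = logE + alpha + xb + S + U
                dev = -2.0 * float(Y @ loglam - np.exp(loglam).sum() - model.log_fact.sum())
                out["alpha"][kept] = alpha
                out["beta"][kept] = beta
                out["S"][kept] = S
                out["U"][kept] = U
                out["nu_s"][kept] = nu_s
                out["nu_u"][kept] = nu_u
                out["deviance"][kept] = dev
                kept += 1
        chains.append(out)

    draws = PosteriorDraws(
        alpha=np.stack([c["alpha"] for c in chains]),
        beta=np.stack([c["beta"] for c in chains]),
        S=np.stack([c["S"] for c in chains]),
        U=np.stack([c["U"] for c in chains]),
        nu_s=np.stack([c["nu_s"] for c in chains]),
        nu_u=np.stack([c["nu_u"] for c in chains]),
        deviance=np.stack([c["deviance"] for c in chains]),
        Y=model.Y,
        E=E,
        config=config,
        scheme_label=spec.weights.scheme_label,
    )
    draws._X = X
    return draws


def implied_sd_prior(a: float, b: float):
    """Analytics of the random-effect sd implied by a Gamma(a, b) precision prior.

    For precision tau ~ Gamma(shape a, rate b) and sd = tau**-0.5 returns
    (median_sd, P(sd < 0.01), P(sd > 2.5)), all via the Gamma distribution
    function (no sampling).
    """
    if a <= 0 or b <= 0:
        raise ValueError("shape and rate must be positive")
    dist = gamma_dist(a, scale=1.0 / b)
    median_sd = dist.ppf(0.5) ** -0.5
    p_below = dist.sf(0.01**-2)  # sd < 0.01  <=>  tau > 1e4
    p_above = dist.cdf(2.5**-2)  # sd > 2.5   <=>  tau < 0.16
    return float(median_sd), float(p_below), float(p_above)
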