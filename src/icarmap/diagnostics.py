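"""Convergence diagnostics, DIC, and posterior summaries.

DIC follows the stochastic-parents convention: pD = Dbar - D(lambda_bar)
with the plug-in deviance evaluated at the posterior means of the Poisson
means lambda_i, and the deviance includes the log(y!) terms so values are
comparable across weight schemes fitted to the same data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import PosteriorDraws


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` is (n_chains, n_draws).  Uses the standard finite-n form
    sqrt((W (m-1)/m + B/m) / W); values below 1 (possible at finite n,
    e.g. identical chains give sqrt((m-1)/m)) are clipped to 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    c, m = chains.shape
    if m < 10:
        raise ValueError("chains too short")
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = m * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = W * (m - 1) / m + B / m
    return float(max(np.sqrt(var_hat / W), 1.0))


def mc_error(chain: np.ndarray, n_batches: int = 30):
    """Batch-means Monte Carlo standard error and its ratio to posterior sd."""
    chain = np.asarray(chain, dtype=float).ravel()
    m = chain.size
    if m < 2 * n_batches:
        raise ValueError(f"chain too short for {n_batches} batches")
    batch = m // n_batches
    means = chain[: batch * n_batches].reshape(n_batches, batch).mean(axis=1)
    mcse = float(means.std(ddof=1) / np.sqrt(n_batches))
    sd = float(chain.std(ddof=1))
    return mcse, (mcse / sd if sd > 0 else 0.0)


def poisson_deviance(Y: np.ndarray, lam: np.ndarray) -> float:
    """-2 log-likelihood including log(y!) terms; lam may be (n,) or (m, n)."""
    Y = np.asarray(Y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    ll = Y * np.log(lam) - lam - gammaln(Y + 1.0)
    return -2.0 * float(ll.sum(axis=-1).mean() if lam.ndim > 1 else ll.sum())


def dic(draws: PosteriorDraws, Y=None, E=None):
    """(Dbar, pD, DIC) from retained draws.

    Dbar is the posterior mean deviance; the plug-in deviance is evaluated
    at the posterior mean of each lambda_i; pD = Dbar - Dhat; DIC = Dbar + pD.
    """
    Y = draws.Y if Y is None else np.asarray(Y)
    E = draws.E if E is None else np.asarray(E)
    dev = draws.flat("deviance")
    if dev.size == 0:
        raise ValueError("no deviance draws")
    dbar = float(dev.mean())
    lam_bar = E * draws.r.reshape(-1, draws.n_areas).mean(axis=0)
    dhat = poisson_deviance(Y, lam_bar)
    pd_ = dbar - dhat
    return dbar, pd_, dbar + pd_


def summarize_risks(draws: PosteriorDraws) -> dict:
    """Per-area and region-level posterior summaries of relative risk."""
    r = draws.r.reshape(-1, draws.n_areas)
    if r.size == 0:
        raise ValueError("no draws")
    qs = np.quantile(r, [0.025, 0.5, 0.975], axis=0)
    per_area = pd.DataFrame(
        {
            "mean": r.mean(axis=0),
            "sd": r.std(axis=0, ddof=1) if r.shape[0] > 1 else np.zeros(r.shape[1]),
            "q2.5": qs[0],
            "median": qs[1],
            "q97.5": qs[2],
        }
    )
    pm = per_area["mean"].to_numpy()
    region = {
        "mean": float(pm.mean()),
        "sd": float(pm.std(ddof=1)) if pm.size > 1 else 0.0,
        "median": float(np.median(pm)),
        "min": float(pm.min()),
        "max": float(pm.max()),
    }
    return {"per_area": per_area, "region": region}


DEFAULT_THRESHOLDS = (0.5, 0.75, 0.90, 0.95)


def exceedance_probabilities(draws: PosteriorDraws, thresholds=DEFAULT_THRESHOLDS):
    """Per-area P(r_i > 1) and, per threshold t, the count #{i : P_i > t}.

    The count uses a strict inequality at the threshold.
    """
    r = draws.r.reshape(-1, draws.n_areas)
    if r.size == 0:
        raise ValueError("no draws")
    p = (r > 1.0).mean(axis=0)
    counts = {t: int((p > t).sum()) for t in thresholds}
    return p, counts


def spatial_fraction(draws: PosteriorDraws, basis: str = "sd"):
    """Posterior mean (and 95% CI) of the spatial share of between-area
    random-effect variability, per iteration sd(S)/(sd(S)+sd(U)) using
    empirical area-level standard deviations (or variances, basis="var")."""
    S = draws.flat("S")
    U = draws.flat("U")
    s = S.std(axis=1, ddof=1)
    u = U.std(axis=1, ddof=1)
    if basis == "var":
        s, u = s**2, u**2
    elif basis != "sd":
        raise ValueError("basis must be 'sd' or 'var'")
    denom = s + u
    f = np.where(denom > 0, s / np.where(denom > 0, denom, 1.0), 0.0)
    lo, hi = np.quantile(f, [0.025, 0.975])
    return float(f.mean()), (float(lo), float(hi))


@dataclass
class DiagnosticsReport:
    """Scalar-parameter convergence measures plus model-fit summaries."""

    rhat: dict
    mc_error_ratio: dict
    Dbar: float
    pD: float
    DIC: float
    spatial_fraction: float
    spatial_fraction_ci: tuple
    scheme_label: str

    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def max_mc_ratio(self) -> float:
        return max(self.mc_error_ratio.values())

    def converged(self, rhat_limit: float = 1.1, mc_limit: float = 0.05) -> bool:
        return self.max_rhat() <= rhat_limit and self.max_mc_ratio() < mc_limit

    def as_dict(self) -> dict:
        return {
            "rhat": self.rhat,
            "mc_error_ratio": self.mc_error_ratio,
            "Dbar": self.Dbar,
            "pD": self.pD,
            "DIC": self.DIC,
            "spatial_fraction": self.spatial_fraction,
            "spatial_fraction_ci": list(self.spatial_fraction_ci),
            "scheme_label": self.scheme_label,
            "spatial_fraction_basis": "sd",
        }


def diagnostics_report(draws: PosteriorDraws) -> DiagnosticsReport:
    """Assemble convergence and fit diagnostics for the main scalars."""
    params = {"alpha": draws.alpha, "nu_s": draws.nu_s, "nu_u": draws.nu_u}
    for j in range(draws.beta.shape[2]):
        params[f"beta[{j}]"] = draws.beta[:, :, j]
    rhat = {k: gelman_rubin(v) for k, v in params.items()}
    ratio = {k: mc_error(v.ravel())[1] for k, v in params.items()}
    dbar, pd_, dic_ = dic(draws)
    frac, ci = spatial_fraction(draws)
    return DiagnosticsReport(
        rhat=rhat,
        mc_error_ratio=ratio,
        Dbar=dbar,
        pD=pd_,
        DIC=dic_,
        spatial_fraction=frac,
        spatial_fraction_ci=ci,
        scheme_label=draws.scheme_label,
    )
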