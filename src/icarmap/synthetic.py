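"""Synthetic small-area scenarios with known ground truth.

The real study data (an irregular map of ~300 census dissemination areas,
age-sex stratified senior populations and fall counts, and area-level
census covariates) are confidential, so this module generates datasets
with the same statistical structure: a perturbed lattice of irregular
polygons, 10 age-sex strata with rates rising steeply with age, a share
of areas with near-zero population at risk, spatially structured
covariates, and counts from the Poisson BYM model itself.

Vertex-coordinate discrepancies — the digital-map defect in which a vertex
shared by adjacent polygons is stored with close-but-different coordinates
in each ring, defeating exact-match contiguity detection — are reproduced
by duplicating a chosen fraction of shared lattice vertices with small
independent Normal perturbations per polygon.

One master seed drives per-stage independent streams (map, population,
covariates, spatial effects, unstructured effects, counts), recorded in
output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.random import SeedSequence, default_rng
from shapely.geometry import Polygon

from .adjacency import AdjacencyList, AreaMap
from .standardization import K, STRATA, StratumTable
from .weights import WeightSpec, equal_weights, product_weights

#: area total population below which an area counts as "near-zero at risk"
LOW_POP_FLOOR = 5

_STAGES = ("map", "population", "covariates", "icar", "unstructured", "counts")

#: default 5-year fall-hospitalisation risks per person, female then male,
#: ages 65-69 .. 85+; the 85+/65-69 ratio is 5, rates rise with age.
DEFAULT_STRATUM_RATES = (
    0.020, 0.030, 0.045, 0.070, 0.100,  # F
    0.016, 0.024, 0.036, 0.056, 0.080,  # M
)


@dataclass
class SyntheticScenario:
    """Complete description of one synthetic study; same seed, same bytes."""

    n_rows: int = 10
    n_cols: int = 10
    irregularity: float = 0.2
    vertex_jitter_sd: float = 0.0
    jitter_fraction: float = 0.0
    stratum_rates: Sequence[float] = DEFAULT_STRATUM_RATES
    population_range: tuple = (2, 30)
    population_gradient: float = 0.0
    low_pop_fraction: float = 0.05
    beta_true: Sequence[float] = (0.3, 0.02)
    alpha_true: float = 0.0
    nu_s_true: float = 0.3
    nu_u_true: float = 0.05
    weight_scheme_true: str = "equal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        if not 0 <= self.jitter_fraction <= 1:
            raise ValueError("jitter_fraction must lie in [0, 1]")
        if self.vertex_jitter_sd < 0:
            raise ValueError("vertex_jitter_sd must be >= 0")
        rates = np.asarray(self.stratum_rates, dtype=float)
        if rates.shape != (K,):
            raise ValueError(f"need {K} stratum rates")
        if np.any((rates < 0) | (rates > 1)):
            raise ValueError("rates must lie in [0, 1]")
        if self.nu_s_true <= 0 or self.nu_u_true <= 0:
            raise ValueError("variances must be positive")
        if not 0 <= self.low_pop_fraction <= 1:
            raise ValueError("low_pop_fraction must lie in [0, 1]")

    @property
    def n_areas(self) -> int:
        return self.n_rows * self.n_cols

    def stage_rng(self, stage: str):
        """Independent per-stage stream derived from the master seed."""
        idx = _STAGES.index(stage)
        return default_rng(SeedSequence(self.seed).spawn(len(_STAGES))[idx])

    def metadata(self) -> dict:
        return {
            "scenario": {
                k: (list(v) if isinstance(v, (tuple, list)) else v)
                for k, v in self.__dict__.items()
            },
            "seed_stages": list(_STAGES),
        }


@dataclass
class SyntheticMap:
    """A lattice map plus its pre-jitter ground-truth adjacency."""

    area_map: AreaMap
    truth: AdjacencyList
    jittered_nodes: list = field(default_factory=list)
    max_vertex_discrepancy: float = 0.0


def generate_lattice_map(scenario: SyntheticScenario) -> SyntheticMap:
    """Perturbed n_rows x n_cols lattice of quadrilateral areas.

    Grid nodes are displaced uniformly (amplitude ``irregularity`` < 0.5,
    so cells stay simple polygons and every shared node stays shared).
    Ground-truth queen adjacency is the 8-neighbour lattice.  When
    ``jitter_fraction`` > 0, that fraction of shared nodes is stored with
    an independent Normal(0, vertex_jitter_sd) offset in each incident
    polygon's ring, so exact-coordinate matching misses adjacencies that
    rely on those vertices.
    """
    R, C = scenario.n_rows, scenario.n_cols
    rng = scenario.stage_rng("map")
    amp = scenario.irregularity
    if not 0 <= amp < 0.5:
        raise ValueError("irregularity must lie in [0, 0.5)")
    node_xy = {
        (r, c): (c + rng.uniform(-amp, amp), r + rng.uniform(-amp, amp))
        for r in range(R + 1)
        for c in range(C + 1)
    }

    def cells_of(node):
        r, c = node
        return [
            (rr, cc)
            for rr in (r - 1, r)
            for cc in (c - 1, c)
            if 0 <= rr < R and 0 <= cc < C
        ]

    shared = [nd for nd in node_xy if len(cells_of(nd)) >= 2]
    n_jitter = int(round(scenario.jitter_fraction * len(shared)))
    jittered = []
    offsets: dict = {}  # (node, cell) -> perturbed coordinate
    if n_jitter:
        chosen = rng.choice(len(shared), size=n_jitter, replace=False)
        for k in sorted(chosen):
            nd = shared[k]
            jittered.append(nd)
            x, y = node_xy[nd]
            for cell in cells_of(nd):
                dx, dy = rng.normal(0.0, scenario.vertex_jitter_sd, 2)
                offsets[(nd, cell)] = (x + dx, y + dy)

    max_disc = 0.0
    for nd in jittered:
        pts = np.array([offsets[(nd, cell)] for cell in cells_of(nd)])
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                max_disc = max(max_disc, float(np.hypot(*(pts[i] - pts[j]))))

    ids, polys = [], []
    for r in range(R):
        for c in range(C):
            ring = []
            for nd in [(r, c), (r, c + 1), (r + 1, c + 1), (r + 1, c)]:
                ring.append(offsets.get((nd, (r, c)), node_xy[nd]))
            ids.append(r * C + c)
            polys.append(Polygon(ring))
    area_map = AreaMap(ids, polys)

    pairs = set()
    for r in range(R):
        for c in range(C):
            i = r * C + c
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (dr or dc) and 0 <= rr < R and 0 <= cc < C:
                        j = rr * C + cc
                        pairs.add((min(i, j), max(i, j)))
    truth = AdjacencyList.from_pairs(R * C, pairs)
    return SyntheticMap(area_map, truth, jittered, max_disc)


def generate_population(area_map: AreaMap, scenario: SyntheticScenario) -> StratumTable:
    """Per-stratum senior populations within ``population_range``, with a
    configured fraction of areas forced to near-zero totals (below
    :data:`LOW_POP_FLOOR`).

    ``population_gradient`` in [0, 1] blends a spatially smooth
    urban-to-rural density surface into the draws (0 = spatially uniform):
    real senior populations concentrate around town centres, which is what
    makes population- or expected-count-based weights spatially structured.
    """
    rng = scenario.stage_rng("population")
    n = area_map.n
    lo, hi = scenario.population_range
    g = scenario.population_gradient
    if not 0 <= g <= 1:
        raise ValueError("population_gradient must lie in [0, 1]")
    if g == 0:
        N = rng.integers(lo, hi + 1, size=(n, K))
    else:
        # smooth density surface: decay with distance from a random "town centre"
        cents = np.array([[p.centroid.x, p.centroid.y] for p in area_map.polygons])
        centre = cents[rng.integers(0, n)]
        dist = np.hypot(*(cents - centre).T)
        span = max(dist.max(), 1e-9)
        density = np.exp(-2.5 * dist / span)  # 1 at centre, ~0.08 at far edge
        p_area = g * density + (1 - g) * 0.5
        N = lo + rng.binomial(hi - lo, p_area[:, None], size=(n, K))
    n_low = int(round(scenario.low_pop_fraction * n))
    if n_low:
        low_areas = rng.choice(n, size=n_low, replace=False)
        for i in low_areas:
            # tiny but inhabited: 1-2 seniors in each of two strata
            N[i] = 0
            strata = rng.choice(K, size=2, replace=False)
            N[i, strata] = rng.integers(1, 3, size=2)
    return StratumTable(list(area_map.ids), N, np.zeros((n, K), dtype=int))


def generate_covariates(area_map: AreaMap, scenario: SyntheticScenario) -> np.ndarray:
    """Spatially structured area-level covariates, one column per beta_true.

    Each covariate is a smooth surface over polygon centroids (random
    direction and frequency) plus equal-variance Normal noise, so roughly a
    third of each covariate's variance is spatially structured - census
    covariates track geography but carry substantial area-level
    idiosyncrasy.  (Covariates that are nearly as smooth as the latent
    spatial field itself induce spatial confounding with the ICAR term and
    degrade coefficient inference; see the methods note.)  The second
    covariate is scaled by 10 to mimic an income-like variable measured in
    larger units.
    """
    rng = scenario.stage_rng("covariates")
    cents = np.array([[p.centroid.x, p.centroid.y] for p in area_map.polygons])
    span = max(cents.max(axis=0) - cents.min(axis=0))
    q = len(scenario.beta_true)
    X = np.empty((area_map.n, q))
    for j in range(q):
        theta = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(0.5, 1.5) * np.pi / max(span, 1.0)
        proj = cents @ np.array([np.cos(theta), np.sin(theta)])
        surf = np.sin(freq * proj + rng.uniform(0, 2 * np.pi))
        x = surf + rng.standard_normal(area_map.n)
        x = (x - x.mean()) / x.std()
        X[:, j] = x * (10.0 if j == 1 else 1.0)
    return X


def simulate_icar(
    adj: AdjacencyList, weights: WeightSpec, variance: float, rng
) -> np.ndarray:
    """Exact draw from the intrinsic Gaussian with joint density
    ∝ exp(-(1/2 nu_s) sum_{i<j} w_ij (s_i - s_j)^2) under sum(S) = 0.

    Uses the eigendecomposition of the weight Laplacian: the constrained
    covariance is ``variance`` times the pseudo-inverse of L = diag(w+) - W.
    """
    if variance <= 0:
        raise ValueError("variance must be positive")
    if not adj.is_connected():
        raise ValueError("adjacency graph must be connected")
    if isinstance(rng, (int, np.integer)):
        rng = default_rng(rng)
    L = np.diag(weights.w_plus) - weights.to_sparse().toarray()
    evals, evecs = np.linalg.eigh(L)
    pos = evals > 1e-10 * evals.max()
    z = rng.standard_normal(int(pos.sum()))
    S = evecs[:, pos] @ (np.sqrt(variance / evals[pos]) * z)
    return S - S.mean()  # exact zero mean (removes float residue)


def simulate_counts(E, X, alpha, beta, S, U, rng) -> np.ndarray:
    """Y_i ~ Poisson(E_i exp(alpha + x_i'beta + S_i + U_i)); E_i = 0 => Y_i = 0."""
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("expected counts must be nonnegative")
    if isinstance(rng, (int, np.integer)):
        rng = default_rng(rng)
    n = E.shape[0]
    X = np.zeros((n, 0)) if X is None else np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    beta = np.atleast_1d(np.asarray(beta, dtype=float)) if X.shape[1] else np.zeros(0)
    eta = alpha + (X @ beta if X.shape[1] else 0.0) + np.asarray(S) + np.asarray(U)
    if len(eta) != n:
        raise ValueError("length mismatch among E, X, S, U")
    return rng.poisson(E * np.exp(eta))


def recovery_scenario(seed: int) -> SyntheticScenario:
    """Covariate-effect recovery conditions: 10x10 lattice, two covariates
    (beta = 0.3 and 0.02), equal-weights spatial field (nu_s = 0.3,
    nu_u = 0.05)."""
    return SyntheticScenario(seed=seed)


def selection_scenario(seed: int) -> SyntheticScenario:
    """Weight-scheme selection conditions: spatial field generated under
    expected-count product weights over a strong urban-to-rural senior
    population gradient (expected counts spanning a >= 20-fold range),
    no covariates, strong spatial structure (nu_s = 0.5)."""
    return SyntheticScenario(
        seed=seed,
        weight_scheme_true="expected",
        beta_true=(),
        nu_s_true=0.5,
        population_gradient=1.0,
        population_range=(1, 45),
        low_pop_fraction=0.05,
    )


@dataclass
class SyntheticDataset:
    """Everything a downstream analysis consumes, plus the ground truth."""

    scenario: SyntheticScenario
    synthetic_map: SyntheticMap
    table: StratumTable
    X: np.ndarray
    truth: dict

    @property
    def area_map(self) -> AreaMap:
        return self.synthetic_map.area_map

    @property
    def adjacency(self) -> AdjacencyList:
        return self.synthetic_map.truth


#: generation-side floor for product weights, as a fraction of the median
#: positive product.  Larger than the analysis-side default on purpose: it
#: bounds the ICAR conditional variances of depopulated areas so simulated
#: log risks stay in a realistic range (|S| of a few units at most).
GENERATION_WEIGHT_FLOOR = 1e-2


def _true_weights(scenario, adj, table, E_true) -> WeightSpec:
    scheme = scenario.weight_scheme_true
    if scheme == "equal":
        return equal_weights(adj)
    if scheme == "population":
        values = table.population_totals.astype(float)
    elif scheme == "expected":
        values = E_true
    elif scheme == "density":
        # population over polygon area; lattice cells have area ~1
        values = table.population_totals.astype(float)
    else:
        raise ValueError(f"unknown weight_scheme_true {scheme!r}")
    products = [values[i] * values[j] for i, j in adj.pairs()]
    positive = [v for v in products if v > 0]
    if not positive:
        raise ValueError("cannot build product weights: all values zero")
    floor = GENERATION_WEIGHT_FLOOR * float(np.median(positive))
    return product_weights(adj, values, floor=floor, scheme_label=scheme)


def generate_dataset(scenario: SyntheticScenario) -> SyntheticDataset:
    """Full generative pipeline: map, populations, covariates, effects, counts.

    Counts are drawn at stratum level, Y_ik ~ Poisson(N_ik z_k r_i), whose
    area totals follow the aggregate Poisson model with true expected
    counts E_i = sum_k N_ik z_k.
    """
    smap = generate_lattice_map(scenario)
    table = generate_population(smap.area_map, scenario)
    X = generate_covariates(smap.area_map, scenario)
    z_true = np.asarray(scenario.stratum_rates, dtype=float)
    E_true = table.N @ z_true

    ws = _true_weights(scenario, smap.truth, table, E_true)
    # nu_s_true is specified on the equal-weights scale (mean pair weight 1).
    # The ICAR model is invariant under jointly rescaling weights and nu_s,
    # so for product schemes the conditional variance is multiplied by the
    # mean pair weight; otherwise the simulated field's marginal variability
    # would shrink with the (arbitrary) magnitude of the weight products.
    var_eff = scenario.nu_s_true * float(np.mean(list(ws.w.values())))
    S = simulate_icar(smap.truth, ws, var_eff, scenario.stage_rng("icar"))
    U = scenario.stage_rng("unstructured").normal(
        0.0, np.sqrt(scenario.nu_u_true), smap.area_map.n
    )
    beta = np.asarray(scenario.beta_true, dtype=float)
    r = np.exp(scenario.alpha_true + X @ beta + S + U)

    rng = scenario.stage_rng("counts")
    Yik = rng.poisson(table.N * z_true[None, :] * r[:, None])
    table = StratumTable(table.area_ids, table.N, Yik)
    truth = {
        "alpha": scenario.alpha_true,
        "beta": beta,
        "S": S,
        "U": U,
        "nu_s": scenario.nu_s_true,
        "nu_u": scenario.nu_u_true,
        "z": z_true,
        "E_true": E_true,
        "r": r,
        "weight_scheme": scenario.weight_scheme_true,
    }
    return SyntheticDataset(scenario, smap, table, X, truth)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write GeoJSON map, stratum CSV, covariate CSV, and ground-truth JSON."""
    import json
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = dataset.scenario.metadata()
    dataset.area_map.write_geojson(outdir / "map.geojson", **meta)
    dataset.table.to_long_frame().to_csv(outdir / "strata.csv", index=False)
    cov = pd.DataFrame(
        dataset.X, columns=[f"x{j+1}" for j in range(dataset.X.shape[1])]
    )
    cov.insert(0, "area_id", dataset.table.area_ids)
    cov.to_csv(outdir / "covariates.csv", index=False)
    truth = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in dataset.truth.items()
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump({"metadata": meta, "truth": truth}, fh)
    from .adjacency import write_winbugs_adjacency

    (outdir / "adjacency_true.txt").write_text(
        write_winbugs_adjacency(dataset.adjacency)
    )
    return {
        "map": str(outdir / "map.geojson"),
        "strata": str(outdir / "strata.csv"),
        "covariates": str(outdir / "covariates.csv"),
        "truth": str(outdir / "truth.json"),
        "adjacency_true": str(outdir / "adjacency_true.txt"),
    }
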