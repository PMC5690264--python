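"""Spatial weight specifications for the ICAR prior.

The ICAR conditional for area i is Normal(sum_j w_ij S_j / w_i+, nu_s / w_i+),
so a weight specification is a symmetric positive weight for every adjacent
pair plus the per-area totals w_i+.  Unnormalised weights are the canonical
stored form (the car.normal input contract); row-normalised weights are
derived for reporting only.

All variable schemes here are products of a per-area value: w_ij = v_i * v_j
with the value being seniors' population, population density, or expected
count; equal weights is the v = 1 limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .adjacency import AdjacencyList

SCHEMES = ("equal", "population", "density", "expected", "custom")


@dataclass
class WeightSpec:
    """Symmetric positive pair weights over an adjacency structure.

    ``w`` maps canonical pairs (i, j) with i < j to positive weights and must
    be defined exactly on the adjacent pairs.
    """

    adjacency: AdjacencyList
    w: dict
    scheme_label: str = "custom"
    w_plus: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.scheme_label not in SCHEMES:
            raise ValueError(f"unknown scheme label {self.scheme_label!r}")
        pairs = self.adjacency.pairs()
        keys = set(self.w)
        if keys != pairs:
            raise ValueError("weights must be defined exactly on adjacent pairs")
        for k, v in self.w.items():
            if not v > 0:
                raise ValueError(f"non-positive weight {v} for pair {k}")
        wp = np.zeros(self.adjacency.n)
        for (i, j), v in self.w.items():
            wp[i] += v
            wp[j] += v
        self.w_plus = wp

    @property
    def n(self) -> int:
        return self.adjacency.n

    def pair_weight(self, i: int, j: int) -> float:
        return self.w[(min(i, j), max(i, j))]

    def to_sparse(self) -> sp.csr_matrix:
        """Symmetric sparse weight matrix W (zero diagonal)."""
        rows, cols, vals = [], [], []
        for (i, j), v in self.w.items():
            rows += [i, j]
            cols += [j, i]
            vals += [v, v]
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def laplacian_quadratic(self, s: np.ndarray) -> float:
        """sum_{i<j} w_ij (s_i - s_j)^2 = s' (diag(w_plus) - W) s."""
        W = self.to_sparse()
        return float(s @ (self.w_plus * s) - s @ (W @ s))

    def to_edge_frame(self):
        """Edge list (i, j, w) as a DataFrame, i < j."""
        import pandas as pd

        items = sorted(self.w.items())
        return pd.DataFrame(
            {
                "i": [k[0] for k, _ in items],
                "j": [k[1] for k, _ in items],
                "w": [v for _, v in items],
            }
        )

    @classmethod
    def from_edge_frame(cls, adj: AdjacencyList, frame, scheme_label="custom"):
        w = {
            (min(int(r.i), int(r.j)), max(int(r.i), int(r.j))): float(r.w)
            for r in frame.itertuples()
        }
        return cls(adj, w, scheme_label)


def equal_weights(adj: AdjacencyList) -> WeightSpec:
    """Traditional equal weights: w_ij = 1 for every adjacent pair."""
    return WeightSpec(adj, {p: 1.0 for p in adj.pairs()}, scheme_label="equal")


def product_weights(
    adj: AdjacencyList,
    values: np.ndarray,
    floor: float | None = None,
    scheme_label: str = "custom",
) -> WeightSpec:
    """Variable weights from the product of a per-area value: w_ij = v_i v_j.

    Zero-valued areas would make their weights zero (and Eq-style ICAR
    conditionals undefined), so products are floored at ``floor``; the
    default floor is 1e-6 times the median positive product.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (adj.n,):
        raise ValueError("values must have one entry per area")
    if np.any(values < 0):
        raise ValueError("values must be nonnegative")
    raw = {(i, j): values[i] * values[j] for i, j in adj.pairs()}
    if floor is None:
        positive = [v for v in raw.values() if v > 0]
        if not positive:
            raise ValueError("all products are zero; supply an explicit floor")
        floor = 1e-6 * float(np.median(positive))
    if floor <= 0:
        raise ValueError("floor must be positive")
    w = {k: max(v, floor) for k, v in raw.items()}
    return WeightSpec(adj, w, scheme_label=scheme_label)


def normalized_rows(ws: WeightSpec) -> dict:
    """Row-stochastic weights w_ij / w_i+ keyed by directed pair (i, j).

    Reporting convenience only: the sampler consumes unnormalised w and w_plus.
    """
    islands = [i for i in range(ws.n) if ws.w_plus[i] == 0]
    if islands:
        raise ValueError(f"areas with zero total weight (islands): {islands}")
    out = {}
    for (i, j), v in ws.w.items():
        out[(i, j)] = v / ws.w_plus[i]
        out[(j, i)] = v / ws.w_plus[j]
    return out
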