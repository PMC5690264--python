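"""Queen-contiguity adjacency extraction, auditing, and WinBUGS-format I/O.

Areas are neighbours under queen contiguity when they share any boundary
point or vertex.  Digital maps frequently store the "same" vertex of two
adjacent polygons with slightly different coordinates, so extraction
supports both exact matching (after canonical rounding) and a distance
tolerance that re-merges such near-duplicate vertices.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, mapping, shape

#: decimal places used to canonicalise coordinates before exact matching,
#: guarding against pure float noise without hiding real discrepancies.
CANONICAL_DECIMALS = 9


@dataclass
class AreaMap:
    """Ordered collection of areas, each a polygon (exterior + holes).

    Parameters
    ----------
    ids : sequence
        Unique area identifiers, in analysis order.
    polygons : sequence of shapely.Polygon
        One polygon per area, closed rings with >= 3 distinct vertices.
    """

    ids: list
    polygons: list

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.polygons):
            raise ValueError("ids and polygons must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("area ids must be unique")
        for aid, poly in zip(self.ids, self.polygons):
            if not isinstance(poly, Polygon):
                raise TypeError(f"area {aid!r}: expected shapely Polygon")
            for ring in [poly.exterior, *poly.interiors]:
                coords = list(ring.coords)
                if coords[0] != coords[-1]:
                    raise ValueError(f"area {aid!r}: ring not closed")
                if len(set(coords)) < 3:
                    raise ValueError(f"area {aid!r}: ring has <3 distinct vertices")

    @property
    def n(self) -> int:
        return len(self.ids)

    def vertices(self, i: int) -> np.ndarray:
        """All ring vertices of area ``i`` (closing duplicate dropped)."""
        poly = self.polygons[i]
        pts = []
        for ring in [poly.exterior, *poly.interiors]:
            pts.extend(list(ring.coords)[:-1])
        return np.asarray(pts, dtype=float)

    def bounds(self) -> np.ndarray:
        """(n, 4) array of per-area bounding boxes (minx, miny, maxx, maxy)."""
        return np.asarray([p.bounds for p in self.polygons], dtype=float)

    # -- GeoJSON I/O ---------------------------------------------------

    def to_geojson(self, **metadata) -> dict:
        features = [
            {
                "type": "Feature",
                "properties": {"area_id": aid},
                "geometry": mapping(poly),
            }
            for aid, poly in zip(self.ids, self.polygons)
        ]
        out = {"type": "FeatureCollection", "features": features}
        if metadata:
            out["metadata"] = metadata
        return out

    def write_geojson(self, path, **metadata) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(**metadata), fh)

    @classmethod
    def from_geojson(cls, obj) -> "AreaMap":
        if isinstance(obj, (str, bytes)):
            with open(obj) as fh:
                obj = json.load(fh)
        ids, polys = [], []
        for k, feat in enumerate(obj["features"]):
            props = feat.get("properties") or {}
            ids.append(props.get("area_id", k))
            geom = shape(feat["geometry"])
            if not isinstance(geom, Polygon):
                raise ValueError(f"feature {k}: only Polygon geometries supported")
            polys.append(geom)
        return cls(ids, polys)


@dataclass
class AdjacencyList:
    """Symmetric neighbour structure over ``n`` areas (0-based indices)."""

    n: int
    neighbors: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.neighbors = [set(s) for s in self.neighbors]
        if len(self.neighbors) != self.n:
            raise ValueError("neighbors must have one entry per area")
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValueError(f"area {i} listed as its own neighbour")
            for j in nb:
                if not (0 <= j < self.n):
                    raise ValueError(f"neighbour index {j} out of range")
                if i not in self.neighbors[j]:
                    raise ValueError(f"asymmetric adjacency: {i}->{j}")

    @classmethod
    def from_pairs(cls, n: int, pairs: Iterable[tuple]) -> "AdjacencyList":
        nb = [set() for _ in range(n)]
        for i, j in pairs:
            if i == j:
                raise ValueError("self-adjacency not allowed")
            nb[i].add(j)
            nb[j].add(i)
        return cls(n, nb)

    @property
    def num(self) -> list:
        """Per-area neighbour counts."""
        return [len(s) for s in self.neighbors]

    @property
    def adj(self) -> list:
        """Flattened 1-based neighbour lists, WinBUGS ordering."""
        out = []
        for s in self.neighbors:
            out.extend(j + 1 for j in sorted(s))
        return out

    @property
    def total_entries(self) -> int:
        """Total directed neighbour entries (i->j and j->i both count)."""
        return sum(self.num)

    def pairs(self) -> set:
        """Undirected neighbour pairs as (i, j) with i < j."""
        return {(i, j) for i, nb in enumerate(self.neighbors) for j in nb if i < j}

    def islands(self) -> list:
        return [i for i, s in enumerate(self.neighbors) if not s]

    def to_graph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.pairs())
        return g

    def is_connected(self) -> bool:
        import networkx as nx

        return self.n > 0 and nx.is_connected(self.to_graph())


@dataclass
class DiscrepancyReport:
    """Audit of a generated adjacency list against a reference (true) one."""

    total_true: int
    total_generated: int
    missing_pairs: set
    extra_pairs: set

    @property
    def undercount_error(self) -> float:
        return undercount_error(self.total_true, self.total_generated)

    def as_dict(self) -> dict:
        return {
            "total_true": self.total_true,
            "total_generated": self.total_generated,
            "n_missing_pairs": len(self.missing_pairs),
            "n_extra_pairs": len(self.extra_pairs),
            "undercount_error": self.undercount_error,
        }


def undercount_error(total_true: int, total_generated: int) -> float:
    """Proportion of directed neighbour entries lost: (true - generated)/true."""
    if total_true <= 0:
        raise ValueError("total_true must be positive")
    return (total_true - total_generated) / total_true


def _canonical_vertex(x: float, y: float) -> tuple:
    return (round(x, CANONICAL_DECIMALS), round(y, CANONICAL_DECIMALS))


def extract_queen_adjacency(area_map: AreaMap, tolerance: float = 0.0) -> AdjacencyList:
    """Extract queen-contiguity adjacency by vertex matching.

    Two areas are adjacent iff some vertex of one lies within Euclidean
    distance ``tolerance`` of some vertex of the other.  ``tolerance=0``
    means exact coordinate match after rounding to ``CANONICAL_DECIMALS``
    decimal places.  Candidate pairs are pruned by bounding-box overlap
    (expanded by the tolerance); pruning cannot change the result because
    two areas with a vertex pair within ``tolerance`` necessarily have
    overlapping expanded boxes.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    n = area_map.n
    if tolerance == 0.0:
        by_vertex: dict = {}
        for i in range(n):
            for x, y in area_map.vertices(i):
                by_vertex.setdefault(_canonical_vertex(x, y), set()).add(i)
        pairs = set()
        for areas in by_vertex.values():
            ordered = sorted(areas)
            for a in range(len(ordered)):
                for b in range(a + 1, len(ordered)):
                    pairs.add((ordered[a], ordered[b]))
        return AdjacencyList.from_pairs(n, pairs)

    bounds = area_map.bounds()
    verts = [area_map.vertices(i) for i in range(n)]
    trees = [cKDTree(v) for v in verts]
    pairs = set()
    for i in range(n):
        bi = bounds[i]
        for j in range(i + 1, n):
            bj = bounds[j]
            # expanded bounding-box overlap prune
            if (
                bi[2] + tolerance < bj[0]
                or bj[2] + tolerance < bi[0]
                or bi[3] + tolerance < bj[1]
                or bj[3] + tolerance < bi[1]
            ):
                continue
            if any(trees[i].query_ball_tree(trees[j], r=tolerance)):
                pairs.add((i, j))
    return AdjacencyList.from_pairs(n, pairs)


def compare_adjacency(
    true_list: AdjacencyList, generated_list: AdjacencyList
) -> DiscrepancyReport:
    """Diff a generated adjacency list against the reference list."""
    if true_list.n != generated_list.n:
        raise ValueError("adjacency lists cover different numbers of areas")
    tp, gp = true_list.pairs(), generated_list.pairs()
    return DiscrepancyReport(
        total_true=true_list.total_entries,
        total_generated=generated_list.total_entries,
        missing_pairs=tp - gp,
        extra_pairs=gp - tp,
    )


# -- WinBUGS car.normal input format ----------------------------------

def write_winbugs_adjacency(adj_list: AdjacencyList, weights=None) -> str:
    """Serialise num/adj (and optionally weights) as a WinBUGS-style list.

    ``weights`` may be a WeightSpec (from :mod:`icarmap.weights`) or any
    object with a ``pair_weight(i, j)`` method; the weights vector is
    emitted aligned with ``adj``.
    """
    num = adj_list.num
    adj = adj_list.adj
    parts = [
        "list(",
        "num = c(" + ", ".join(str(v) for v in num) + "),",
        "adj = c(" + ", ".join(str(v) for v in adj) + "),",
    ]
    if weights is not None:
        wvec = []
        for i, s in enumerate(adj_list.neighbors):
            for j in sorted(s):
                wvec.append(weights.pair_weight(i, j))
        if len(wvec) != len(adj):
            raise ValueError("weight count does not match adjacency entries")
        parts.append("weights = c(" + ", ".join(repr(float(w)) for w in wvec) + "),")
    parts.append(f"sumNumNeigh = {sum(num)})")
    return "\n".join(parts)


def read_winbugs_adjacency(text: str):
    """Parse a WinBUGS-style adjacency list; inverse of the writer.

    Returns ``(AdjacencyList, WeightSpec or None)``.
    """
    from .weights import WeightSpec  # local import to avoid a cycle

    def vector(name, cast):
        m = re.search(rf"{name}\s*=\s*c\(([^)]*)\)", text, re.S)
        if m is None:
            return None
        body = m.group(1).strip()
        return [cast(t) for t in re.split(r"[,\s]+", body) if t]

    num = vector("num", int)
    adj = vector("adj", int)
    wvec = vector("weights", float)
    if num is None or adj is None:
        raise ValueError("missing num or adj vector")
    if sum(num) != len(adj):
        raise ValueError(f"length(adj)={len(adj)} does not equal sum(num)={sum(num)}")
    if wvec is not None and len(wvec) != len(adj):
        raise ValueError("weights vector length does not match adj")
    n = len(num)
    neighbors = []
    pos = 0
    wmap: dict = {}
    for i, k in enumerate(num):
        entries = adj[pos : pos + k]
        ws = wvec[pos : pos + k] if wvec is not None else [None] * k
        pos += k
        nb = set()
        for j1, w in zip(entries, ws):
            j = j1 - 1
            if not (0 <= j < n):
                raise ValueError(f"adjacency entry {j1} out of range")
            nb.add(j)
            if w is not None:
                key = (min(i, j), max(i, j))
                if key in wmap and not np.isclose(wmap[key], w):
                    raise ValueError(f"asymmetric weights for pair {key}")
                wmap[key] = w
        neighbors.append(nb)
    alist = AdjacencyList(n, neighbors)
    wspec = None
    if wvec is not None:
        wspec = WeightSpec(alist, wmap, scheme_label="custom")
    return alist, wspec
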