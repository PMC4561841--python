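"""Habitat graphs for wetland connectivity analysis.

Three graph constructions are supported, all sharing the same probabilistic
dispersal kernel:

* ``spatial`` — the occupied breeding wetlands only, node attribute equal to
  wetland area; a static snapshot of the breeding network.
* ``temporal`` — the same nodes, but each node's attribute is discounted by
  the fraction of years its snowpack category leaves it hydrologically
  available (low-snowpack wetlands are productive in low-snow years, high
  in high-snow years, neutral always).
* ``stepping_stone`` — occupied wetlands plus all unoccupied candidate
  wetlands larger than the smallest neutral breeding wetland (strictly
  > ``min_area``, default 400 m²), every node treated as always available.

Edges carry Euclidean inter-centroid distances; by default the graph is
complete, with an optional pruning cutoff so that indirect stepping-stone
routes can outcompete long direct hops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DispersalKernel",
    "calibrate_kernel",
    "TemporalAttribution",
    "classify_availability",
    "WetlandNetwork",
    "build_network",
]

SNOW_CATEGORIES = ("low", "high", "neutral")


@dataclass(frozen=True)
class DispersalKernel:
    """Negative-exponential dispersal kernel p(d) = exp(-theta * d).

    Calibrated so that a reference fraction ``p_ref`` of dispersers exceeds
    the reference distance ``d_ref`` (for the boreal chorus frog: 5% of
    individuals beyond the ~600 m observed dispersal maximum).
    """

    theta: float
    d_ref: float = 600.0
    p_ref: float = 0.05

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if abs(math.exp(-self.theta * self.d_ref) - self.p_ref) > 1e-12:
            raise ValueError("kernel does not satisfy exp(-theta*d_ref) = p_ref")

    def probability(self, distance) -> np.ndarray | float:
        """Dispersal probability at the given distance(s) in meters."""
        return np.exp(-self.theta * np.asarray(distance, dtype=float))

    __call__ = probability


def calibrate_kernel(d_ref: float = 600.0, p_ref: float = 0.05) -> DispersalKernel:
    """Calibrate the kernel decay rate: theta = -ln(p_ref) / d_ref."""
    if d_ref <= 0:
        raise ValueError("d_ref must be positive")
    if not 0 < p_ref < 1:
        raise ValueError("p_ref must lie strictly between 0 and 1")
    return DispersalKernel(theta=-math.log(p_ref) / d_ref, d_ref=d_ref, p_ref=p_ref)


@dataclass(frozen=True)
class TemporalAttribution:
    """Years of hydrological availability per snowpack category.

    ``available`` maps each category to the number of years (out of
    ``total_years``) in which a wetland of that category holds a breeding
    hydroperiod; neutral wetlands are available every year by definition.
    """

    available: dict
    total_years: int

    def __post_init__(self) -> None:
        for cat in SNOW_CATEGORIES:
            if cat not in self.available:
                raise ValueError(f"missing category {cat!r}")
            if not 0 <= self.available[cat] <= self.total_years:
                raise ValueError(f"available years for {cat!r} outside [0, total]")
        if self.available["neutral"] != self.total_years:
            raise ValueError("neutral wetlands must be available every year")

    def fraction(self, category: str) -> float:
        return self.available[category] / self.total_years


def classify_availability(snow_depths, threshold: float = 63.5) -> TemporalAttribution:
    """Classify a snowpack depth series into availability-year counts.

    Low-snowpack wetlands are productive in years with depth strictly below
    ``threshold`` (cm), high wetlands in the remaining years, and neutral
    wetlands in every year.
    """
    depths = np.asarray(snow_depths, dtype=float)
    if depths.size == 0:
        raise ValueError("snow series is empty")
    n_low = int(np.sum(depths < threshold))
    return TemporalAttribution(
        available={"low": n_low, "high": depths.size - n_low, "neutral": depths.size},
        total_years=int(depths.size),
    )


@dataclass
class WetlandNetwork:
    """Attribute-weighted wetland graph plus its dispersal kernel.

    ``nodes`` has one row per wetland with columns id, x, y, area_m2,
    snow_category, occupied, and the analysis attribute ``a`` (area, possibly
    availability-discounted). ``graph`` is an undirected networkx graph whose
    edges carry ``distance`` in meters.
    """

    nodes: pd.DataFrame
    graph: nx.Graph
    kernel: DispersalKernel
    kind: str

    @property
    def node_ids(self) -> list:
        return list(self.nodes["id"])

    @property
    def attributes(self) -> np.ndarray:
        return self.nodes["a"].to_numpy(dtype=float)

    def distance_matrix(self) -> np.ndarray:
        """Dense matrix of edge distances (inf where no edge, 0 on diagonal)."""
        ids = self.node_ids
        index = {nid: k for k, nid in enumerate(ids)}
        d = np.full((len(ids), len(ids)), np.inf)
        np.fill_diagonal(d, 0.0)
        for u, v, dist in self.graph.edges(data="distance"):
            d[index[u], index[v]] = d[index[v], index[u]] = dist
        return d

    def to_csv(self, nodes_path, edges_path) -> None:
        self.nodes.to_csv(nodes_path, index=False)
        rows = [
            {"id1": u, "id2": v, "distance_m": dist}
            for u, v, dist in self.graph.edges(data="distance")
        ]
        pd.DataFrame(rows, columns=["id1", "id2", "distance_m"]).to_csv(edges_path, index=False)

    def to_conefor(self, nodes_path, connections_path) -> None:
        """Export whitespace-delimited node (id attribute) and connection
        (id1 id2 distance) files in the habitat-availability tool convention."""
        with open(nodes_path, "w") as fh:
            for _, row in self.nodes.iterrows():
                fh.write(f"{row['id']} {row['a']:.6f}\n")
        with open(connections_path, "w") as fh:
            for u, v, dist in self.graph.edges(data="distance"):
                fh.write(f"{u} {v} {dist:.6f}\n")


def build_network(
    wetlands: pd.DataFrame,
    kernel: DispersalKernel,
    kind: str,
    attribution: TemporalAttribution | None = None,
    min_area: float = 400.0,
    edge_cutoff: float | None = None,
) -> WetlandNetwork:
    """Build a spatial, temporal, or stepping-stone wetland network.

    Parameters
    ----------
    wetlands : DataFrame with columns id, x, y, area_m2, snow_category, occupied.
    kind : {"spatial", "temporal", "stepping_stone"}
    attribution : required for the temporal network; discounts node
        attributes by availability fraction of the snow category.
    min_area : strict area filter (m²) for unoccupied stepping-stone
        candidates; occupied wetlands are always kept.
    edge_cutoff : optional pruning distance (m); edges longer than this are
        dropped. Default keeps the complete graph.
    """
    if kind not in {"spatial", "temporal", "stepping_stone"}:
        raise ValueError(f"unknown network kind {kind!r}")
    wl = wetlands.copy()
    occupied = wl[wl["occupied"].astype(bool)]
    if kind in {"spatial", "temporal"}:
        nodes = occupied.copy()
    else:
        candidates = wl[~wl["occupied"].astype(bool)]
        if candidates.empty:
            raise ValueError("stepping-stone network requires candidate wetlands")
        keep = candidates[candidates["area_m2"] > min_area]
        nodes = pd.concat([occupied, keep], ignore_index=True)

    if kind == "temporal":
        if attribution is None:
            raise ValueError("temporal network requires a TemporalAttribution")
        frac = nodes["snow_category"].map(attribution.fraction)
        nodes = nodes.assign(a=nodes["area_m2"].to_numpy(dtype=float) * frac.to_numpy(dtype=float))
    else:
        nodes = nodes.assign(a=nodes["area_m2"].to_numpy(dtype=float))

    nodes = nodes.reset_index(drop=True)
    if len(nodes) < 2:
        raise ValueError("fewer than 2 wetlands remain after filtering")
    if nodes["id"].duplicated().any():
        raise ValueError("wetland ids are not unique")

    g = nx.Graph()
    g.add_nodes_from(nodes["id"])
    xy = nodes[["x", "y"]].to_numpy(dtype=float)
    ids = list(nodes["id"])
    diffs = xy[:, None, :] - xy[None, :, :]
    dmat = np.hypot(diffs[..., 0], diffs[..., 1])
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            d = dmat[i, j]
            if d <= 0:
                raise ValueError(f"wetlands {ids[i]} and {ids[j]} are coincident")
            if edge_cutoff is not None and d > edge_cutoff:
                continue
            g.add_edge(ids[i], ids[j], distance=float(d))
    return WetlandNetwork(nodes=nodes, graph=g, kernel=kernel, kind=kind)
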