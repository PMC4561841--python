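"""Shared fixtures and graph-building helpers for the test suite."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from chorusnet.networks import DispersalKernel, WetlandNetwork, calibrate_kernel


@pytest.fixture
def kernel() -> DispersalKernel:
    return calibrate_kernel()


def make_network(
    coords,
    areas,
    kernel: DispersalKernel,
    kind: str = "spatial",
    drop_edges=(),
    occupied=None,
) -> WetlandNetwork:
    """Build a WetlandNetwork directly from coordinates and attributes.

    ``drop_edges`` is an iterable of (i, j) index pairs to prune from the
    otherwise complete Euclidean graph.
    """
    coords = np.asarray(coords, dtype=float)
    areas = np.asarray(areas, dtype=float)
    n = len(coords)
    ids = [f"n{k}" for k in range(n)]
    occupied = [True] * n if occupied is None else list(occupied)
    nodes = pd.DataFrame(
        {
            "id": ids,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "area_m2": areas,
            "snow_category": ["neutral"] * n,
            "occupied": occupied,
            "a": areas,
        }
    )
    dropped = {frozenset(e) for e in drop_edges}
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((i, j)) in dropped:
                continue
            d = float(np.hypot(*(coords[i] - coords[j])))
            g.add_edge(ids[i], ids[j], distance=d)
    return WetlandNetwork(nodes=nodes, graph=g, kernel=kernel, kind=kind)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (path enumeration; no shared code with the
# implementation under test)


def brute_pstar(dmat: np.ndarray, theta: float) -> np.ndarray:
    """Max path-product probabilities by exhaustive simple-path enumeration."""
    n = dmat.shape[0]
    out = np.zeros((n, n))
    np.fill_diagonal(out, 1.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            others = [k for k in range(n) if k not in (i, j)]
            best = 0.0
            for r in range(len(others) + 1):
                for mids in itertools.permutations(others, r):
                    path = (i,) + mids + (j,)
                    prob = 1.0
                    for a, b in zip(path[:-1], path[1:]):
                        d = dmat[a, b]
                        if not np.isfinite(d):
                            prob = 0.0
                            break
                        prob *= math.exp(-theta * d)
                    best = max(best, prob)
            out[i, j] = best
    return out


def brute_pc_num(areas: np.ndarray, pstar: np.ndarray) -> float:
    total = 0.0
    n = len(areas)
    for i in range(n):
        for j in range(n):
            total += areas[i] * areas[j] * pstar[i, j]
    return total


def brute_decomposition(dmat: np.ndarray, areas: np.ndarray, theta: float):
    """dPC/Intra/Flux/Connector (percent) by full re-enumeration per removal."""
    areas = np.asarray(areas, dtype=float)
    pstar = brute_pstar(dmat, theta)
    pc_num = brute_pc_num(areas, pstar)
    n = len(areas)
    rows = []
    for k in range(n):
        keep = [i for i in range(n) if i != k]
        sub = dmat[np.ix_(keep, keep)]
        pstar_k = brute_pstar(sub, theta)
        pc_k = brute_pc_num(areas[keep], pstar_k)
        dpc = 100.0 * (pc_num - pc_k) / pc_num
        intra = 100.0 * areas[k] ** 2 / pc_num
        flux = 100.0 * 2.0 * sum(areas[k] * areas[j] * pstar[k, j] for j in keep) / pc_num
        connector = (
            100.0
            * sum(
                areas[keep[x]] * areas[keep[y]] * (pstar[keep[x], keep[y]] - pstar_k[x, y])
                for x in range(n - 1)
                for y in range(n - 1)
            )
            / pc_num
        )
        rows.append((dpc, intra, flux, connector))
    return pc_num, np.array(rows)


def random_pruned_network(rng: np.random.Generator, n: int, kernel, keep_prob=0.6):
    """Random coordinates/areas with random edge pruning (helper for oracles)."""
    coords = rng.uniform(0, 1500, size=(n, 2))
    areas = rng.uniform(200, 20000, size=n)
    drops = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() > keep_prob
    ]
    return make_network(coords, areas, kernel, drop_edges=drops), coords, areas, drops
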