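"""Probability of connectivity (PC) and node-importance decomposition.

PC measures habitat availability at the landscape scale: over all ordered
node pairs (including i = j), sum a_i * a_j * p*_ij, where a is the node
attribute (habitat area, possibly availability-weighted) and p*_ij is the
maximum over paths of the product of per-edge dispersal probabilities.
The importance of node k, dPC_k, is the percent drop in that sum when k is
removed, and splits exactly into three fractions:

* **Intra** — the node's own attribute term a_k² (habitat it provides by
  itself, independent of position);
* **Flux** — area-weighted dispersal directly into/out of the node,
  2 * a_k * sum_j a_j p*_kj;
* **Connector** — connectivity between *other* node pairs that is lost when
  k stops serving as an irreplaceable step on their best path.

With a complete graph and a negative-exponential kernel, no multi-step path
can beat a direct edge (the triangle inequality in -ln p), so Connector is
identically zero; pruning edges (or physical gaps) is what lets
stepping-stone wetlands matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .networks import WetlandNetwork

__all__ = ["ConnectivityResult", "pstar_matrix", "pc", "dpc_decomposition", "report"]


def _pstar_from_distances(dmat: np.ndarray, theta: float) -> np.ndarray:
    """Best-path dispersal probabilities from an edge-distance matrix.

    ``dmat`` holds edge lengths (inf = no edge). Since -ln p_ij =
    theta * d_ij, the maximum-probability path is the shortest path in
    distance, so p* = exp(-theta * graph_distance). Unreachable pairs get 0.
    """
    if dmat.size == 0:
        return np.zeros((0, 0))
    if np.any(dmat[np.isfinite(dmat)] < 0):
        raise ValueError("negative edge distance")
    sp = shortest_path(dmat, method="D", directed=False)
    with np.errstate(over="ignore"):
        pstar = np.exp(-theta * sp)
    pstar[~np.isfinite(sp)] = 0.0
    np.fill_diagonal(pstar, 1.0)
    return pstar


def pstar_matrix(network: WetlandNetwork) -> np.ndarray:
    """Matrix of maximum path-product dispersal probabilities p*_ij.

    p*_ii = 1; pairs in different components get 0.
    """
    return _pstar_from_distances(network.distance_matrix(), network.kernel.theta)


def pc(network: WetlandNetwork, landscape_attribute: float | None = None) -> tuple[float, float]:
    """PC numerator and normalized PC for a wetland network.

    The numerator sums a_i * a_j * p*_ij over all ordered pairs including
    i = j; the normalized index divides by A_L² where A_L defaults to the
    summed node attribute (configurable to a fixed landscape area).
    """
    a = network.attributes
    if not np.any(a > 0):
        raise ValueError("all node attributes are zero")
    pstar = pstar_matrix(network)
    pc_num = float(a @ pstar @ a)
    a_l = float(np.sum(a)) if landscape_attribute is None else float(landscape_attribute)
    return pc_num, pc_num / a_l**2


@dataclass
class ConnectivityResult:
    """Per-node dPC (%) and its Intra/Flux/Connector split for one network."""

    pc_num: float
    a_total: float
    table: pd.DataFrame  # columns: id, dPC_pct, intra_pct, flux_pct, connector_pct
    network_kind: str


def dpc_decomposition(network: WetlandNetwork) -> ConnectivityResult:
    """Node-removal importance dPC_k with its exact three-way split.

    Each fraction is computed from its own definition (not by subtraction):
    dPC_k from the PC numerator of the graph with node k deleted, Intra and
    Flux from the intact p* matrix, and Connector from the loss of best-path
    probability between the remaining pairs. The identity
    dPC = Intra + Flux + Connector then holds to floating-point accuracy.
    """
    a = network.attributes
    n = len(a)
    if n < 2:
        raise ValueError("decomposition needs at least 2 nodes")
    dmat = network.distance_matrix()
    theta = network.kernel.theta
    pstar = _pstar_from_distances(dmat, theta)
    pc_num = float(a @ pstar @ a)
    if pc_num <= 0:
        raise ValueError("PC numerator is zero")

    rows = []
    idx = np.arange(n)
    for k in range(n):
        keep = idx[idx != k]
        sub = dmat[np.ix_(keep, keep)]
        pstar_k = _pstar_from_distances(sub, theta)
        a_k = a[keep]
        pc_removed = float(a_k @ pstar_k @ a_k)
        dpc = 100.0 * (pc_num - pc_removed) / pc_num
        intra = 100.0 * a[k] ** 2 / pc_num
        flux = 100.0 * 2.0 * a[k] * float(a_k @ pstar[keep, k]) / pc_num
        loss = pstar[np.ix_(keep, keep)] - pstar_k
        connector = 100.0 * float(a_k @ loss @ a_k) / pc_num
        rows.append(
            {
                "id": network.node_ids[k],
                "dPC_pct": dpc,
                "intra_pct": intra,
                "flux_pct": flux,
                "connector_pct": connector,
            }
        )
    table = pd.DataFrame(rows)
    return ConnectivityResult(
        pc_num=pc_num,
        a_total=float(np.sum(a)),
        table=table,
        network_kind=network.kind,
    )


def report(result: ConnectivityResult, subset=None) -> pd.DataFrame:
    """Connectivity table restricted to a node subset (e.g. sampled wetlands).

    Columns: id, PC (dPC %), Intra, Flux, Connector — all in percent.
    """
    table = result.table
    if subset is None:
        out = table.copy()
    else:
        subset = list(subset)
        unknown = set(subset) - set(table["id"])
        if unknown:
            raise KeyError(f"unknown node ids: {sorted(unknown)}")
        out = table.set_index("id").loc[subset].reset_index()
    out = out.rename(
        columns={
            "dPC_pct": "PC_pct",
            "intra_pct": "Intra_pct",
            "flux_pct": "Flux_pct",
            "connector_pct": "Connector_pct",
        }
    )
    out["network_kind"] = result.network_kind
    return out
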