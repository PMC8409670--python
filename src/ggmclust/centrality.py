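"""Node centrality and bridge centrality on weighted signed networks.

Conventions follow standard psychometric network practice: strength is
the sum of absolute incident edge weights and expected influence the
signed sum; closeness and betweenness are geodesic indexes computed with
edge lengths 1/|weight| (strong associations are short); bridge variants
restrict the one-step sums to edges crossing community (disorder)
boundaries. Indexes are reported raw and z-standardized across the nodes
of the network at hand.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .datatypes import WeightedNetwork, check_communities
from .exceptions import DegenerateValuesError


def strength(net: WeightedNetwork) -> np.ndarray:
    """Sum of absolute incident edge weights per node."""
    return np.abs(net.weights).sum(axis=1)


def expected_influence(net: WeightedNetwork) -> np.ndarray:
    """Signed sum of incident edge weights per node."""
    return net.weights.sum(axis=1)


def _lengths(net: WeightedNetwork) -> np.ndarray:
    with np.errstate(divide="ignore"):
        L = 1.0 / np.abs(net.weights)
    L[net.weights == 0.0] = np.inf
    return L


def shortest_path_lengths(net: WeightedNetwork) -> np.ndarray:
    """All-pairs geodesic distances with edge length 1/|w|; +inf when
    unreachable, 0 on the diagonal."""
    L = _lengths(net)
    finite = np.where(np.isfinite(L), L, 0.0)
    mask = np.isfinite(L)
    # dijkstra on a dense masked graph: zero entries outside the mask are
    # treated as absent edges
    from scipy.sparse import csr_matrix

    rows, cols = np.nonzero(mask)
    graph = csr_matrix((finite[rows, cols], (rows, cols)), shape=L.shape)
    return dijkstra(graph, directed=False)


def closeness(net: WeightedNetwork) -> np.ndarray:
    """1 / (sum of geodesic distances to all other nodes); 0 when any
    other node is unreachable."""
    D = shortest_path_lengths(net)
    p = net.p
    out = np.zeros(p)
    for i in range(p):
        d = np.delete(D[i], i)
        if np.all(np.isfinite(d)) and d.sum() > 0:
            out[i] = 1.0 / d.sum()
    return out


def _to_nx(net: WeightedNetwork) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(net.p))
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = net.weights[i, j]
            if w != 0.0:
                G.add_edge(i, j, length=1.0 / abs(w))
    return G


def betweenness(net: WeightedNetwork) -> np.ndarray:
    """Shortest-path betweenness (edge lengths 1/|w|): the number of
    geodesics between other node pairs passing through each node, tied
    geodesics counted fractionally, endpoints excluded, unnormalized."""
    G = _to_nx(net)
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    return np.array([bc[i] for i in range(net.p)])


def _cross_mask(net: WeightedNetwork, communities: Mapping[str, str]) -> np.ndarray:
    labels = check_communities(net, communities)
    return labels[:, None] != labels[None, :]


def bridge_strength(net: WeightedNetwork, communities: Mapping[str, str]) -> np.ndarray:
    """Per node, the sum of |weight| over edges into other communities."""
    return (np.abs(net.weights) * _cross_mask(net, communities)).sum(axis=1)


def bridge_expected_influence(
    net: WeightedNetwork, communities: Mapping[str, str]
) -> np.ndarray:
    """Per node, the signed sum of weights over edges into other communities."""
    return (net.weights * _cross_mask(net, communities)).sum(axis=1)


def z_standardize(values: Sequence[float]) -> np.ndarray:
    """(v - mean) / population SD; errors on constant input."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values to standardize")
    sd = v.std()
    if sd == 0:
        raise DegenerateValuesError("values are constant; z-scores undefined")
    return (v - v.mean()) / sd


_BASE_INDEXES = {
    "strength": strength,
    "closeness": closeness,
    "betweenness": betweenness,
    "expected_influence": expected_influence,
}


def centrality_table(
    net: WeightedNetwork,
    communities: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-node centrality indexes, raw and z-standardized.

    Columns: each index raw plus ``<index>_z``; bridge indexes are
    included when a community map is given, along with a ``community``
    column. z-columns are omitted for indexes that are constant across
    nodes (their z-score is undefined).
    """
    data: dict[str, np.ndarray] = {}
    for name, fn in _BASE_INDEXES.items():
        data[name] = fn(net)
    if communities is not None:
        data["bridge_strength"] = bridge_strength(net, communities)
        data["bridge_expected_influence"] = bridge_expected_influence(net, communities)
    table = pd.DataFrame(data, index=net.variable_names)
    table.index.name = "node"
    for name in list(table.columns):
        col = table[name].to_numpy()
        if col.std() > 0:
            table[name + "_z"] = z_standardize(col)
    if communities is not None:
        table.insert(0, "community", [communities[v] for v in net.variable_names])
    return table


def centrality_long(table: pd.DataFrame) -> pd.DataFrame:
    """Long format (node, index, value) for plotting front ends."""
    value_cols = [c for c in table.columns if c != "community"]
    long = table[value_cols].reset_index().melt(
        id_vars="node", var_name="index", value_name="value"
    )
    return long.sort_values(["index", "node"], kind="stable").reset_index(drop=True)
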