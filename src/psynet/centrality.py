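"""Node centrality for weighted partial-correlation networks.

Conventions follow network psychometrics: strength and expected influence
are one-step sums of (absolute resp. signed) edge weights; closeness and
betweenness are shortest-path centralities on edge lengths 1/|w|, with
unreachable nodes giving closeness 0 and equal-length paths split
fractionally (Brandes accumulation, endpoints excluded).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from ._utils import as_weight_matrix, net_labels

FIG2_COLUMNS = ["betweenness", "closeness", "strength", "expected_influence"]


def strength(net) -> np.ndarray:
    """strength(i) = sum_j |w_ij|."""
    W = as_weight_matrix(net)
    return np.abs(W).sum(axis=1) - np.abs(np.diag(W))


def expected_influence(net, steps: int = 1) -> np.ndarray:
    """One-step (default) or two-step signed expected influence."""
    W = as_weight_matrix(net).copy()
    np.fill_diagonal(W, 0.0)
    ei1 = W.sum(axis=1)
    if steps == 1:
        return ei1
    if steps == 2:
        return ei1 + W @ ei1
    raise ValueError("steps must be 1 or 2")


def _length_graph(W: np.ndarray) -> nx.Graph:
    p = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(p))
    iu, ju = np.triu_indices(p, 1)
    for i, j in zip(iu, ju):
        w = W[i, j]
        if w != 0.0:
            G.add_edge(int(i), int(j), length=1.0 / abs(w))
    return G


def closeness(net) -> np.ndarray:
    """closeness(i) = 1 / sum_j d(i,j) on lengths 1/|w|; 0 if any j unreachable."""
    W = as_weight_matrix(net)
    p = W.shape[0]
    G = _length_graph(W)
    out = np.zeros(p)
    for i in range(p):
        dists = nx.single_source_dijkstra_path_length(G, i, weight="length")
        if len(dists) < p:
            out[i] = 0.0
        else:
            total = sum(d for node, d in dists.items() if node != i)
            out[i] = 1.0 / total if total > 0 else 0.0
    return out


def betweenness(net) -> np.ndarray:
    """Weighted shortest-path betweenness (lengths 1/|w|), endpoints excluded."""
    W = as_weight_matrix(net)
    G = _length_graph(W)
    b = nx.betweenness_centrality(G, normalized=False, weight="length")
    return np.array([b[i] for i in range(W.shape[0])])


def _zscore(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    if sd == 0:
        warnings.warn("constant centrality column; z-scores reported as zeros")
        return np.zeros_like(col)
    return (col - col.mean()) / sd


def centrality_table(net, standardize: bool = True) -> pd.DataFrame:
    """All four indices per node, raw and (optionally) z-standardized."""
    W = as_weight_matrix(net)
    labels = net_labels(net, W.shape[0])
    table = pd.DataFrame(
        {
            "betweenness": betweenness(W),
            "closeness": closeness(W),
            "strength": strength(W),
            "expected_influence": expected_influence(W),
        },
        index=labels,
    )
    if standardize:
        for col in FIG2_COLUMNS:
            table[f"z_{col}"] = _zscore(table[col].to_numpy())
    return table
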