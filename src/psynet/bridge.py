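"""Bridge centrality across pre-specified item communities.

Communities are fixed a priori by instrument (self-efficacy items vs
depression items).  Bridge strength of a node is the sum of absolute edge
weights crossing into other communities; bridge expected influence is the
signed companion.  By construction bridge strength plus within-community
strength equals total node strength.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._utils import as_weight_matrix, net_labels
from .errors import ParameterError


def _community_vector(labels: list[str], communities) -> np.ndarray:
    if isinstance(communities, dict):
        missing = [lab for lab in labels if lab not in communities]
        if missing:
            raise ParameterError(f"nodes without a community: {', '.join(missing)}")
        return np.array([communities[lab] for lab in labels], dtype=object)
    comm = np.asarray(communities, dtype=object)
    if comm.shape[0] != len(labels):
        raise ParameterError("community vector length must match node count")
    return comm


def _cross_mask(labels, communities) -> np.ndarray:
    comm = _community_vector(labels, communities)
    return comm[:, None] != comm[None, :]


def bridge_strength(net, communities) -> np.ndarray:
    """Sum of |w_ij| over j in other communities, per node i."""
    W = as_weight_matrix(net)
    labels = net_labels(net, W.shape[0])
    cross = _cross_mask(labels, communities)
    return np.abs(W * cross).sum(axis=1)


def bridge_expected_influence(net, communities) -> np.ndarray:
    """Signed sum of w_ij over j in other communities, per node i."""
    W = as_weight_matrix(net)
    labels = net_labels(net, W.shape[0])
    cross = _cross_mask(labels, communities)
    return (W * cross).sum(axis=1)


def bridge_table(net, communities) -> pd.DataFrame:
    """Per-node bridge statistics, sorted in node order."""
    W = as_weight_matrix(net)
    labels = net_labels(net, W.shape[0])
    comm = _community_vector(labels, communities)
    cross = comm[:, None] != comm[None, :]
    return pd.DataFrame({
        "community": comm,
        "bridge_strength": np.abs(W * cross).sum(axis=1),
        "bridge_expected_influence": (W * cross).sum(axis=1),
    }, index=labels)


def cross_community_edges(net, communities) -> pd.DataFrame:
    """All nonzero cross-community edges, strongest (by |w|) first."""
    W = as_weight_matrix(net)
    labels = net_labels(net, W.shape[0])
    cross = _cross_mask(labels, communities)
    iu, ju = np.triu_indices(W.shape[0], 1)
    rows = [
        {"node_i": labels[i], "node_j": labels[j], "weight": float(W[i, j])}
        for i, j in zip(iu, ju)
        if cross[i, j] and W[i, j] != 0.0
    ]
    out = pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])
    if len(out):
        out = out.reindex(out["weight"].abs().sort_values(ascending=False).index)
        out = out.reset_index(drop=True)
    return out


def top_bridge_nodes(table: pd.DataFrame, k: int = 2) -> list[str]:
    """Nodes ranked by bridge strength (ties broken by label order)."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > len(table):
        warnings.warn(f"k={k} exceeds node count {len(table)}; truncated")
        k = len(table)
    ranked = table.sort_values(
        by=["bridge_strength"], ascending=False, kind="stable"
    )
    ranked = ranked[ranked["bridge_strength"] > 0]
    return list(ranked.index[:k])
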