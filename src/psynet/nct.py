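"""Permutation Network Comparison Test (NCT) between two groups.

Two invariance statistics are computed from independently estimated
group networks:

* M — network-structure invariance: the maximum absolute edge-weight
  difference, max_{i<j} |w_ij^A - w_ij^B|;
* S — global-strength invariance: |GS_A - GS_B| where GS = sum_{i<j} |w_ij|.

The null distribution pools the two samples and repeatedly re-splits the
rows into groups of the original sizes, re-running the full estimator
(penalty re-selected) for each side.  Pooled rows are canonicalized by
lexicographic sort and the smaller group is always drawn first, which makes
every permutation statistic — and hence the p-values — exactly invariant
under swapping the group labels.  Per-edge permutation tail probabilities
feed the change-profile table (strengthened / weakened / lost / new link),
with group A read as the control group and group B as the depressed group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import as_data_matrix, as_weight_matrix
from .errors import ComparisonError, ParameterError
from .ggm import estimate_network

log = logging.getLogger(__name__)

MAX_PERM_FAILURE_RATE = 0.05


def global_strength(net) -> float:
    """Sum of absolute edge weights over unordered node pairs."""
    W = as_weight_matrix(net)
    return float(np.abs(np.triu(W, 1)).sum())


@dataclass
class NCTResult:
    labels: list[str]
    weights_a: np.ndarray
    weights_b: np.ndarray
    m: float
    s: float
    p_m: float
    p_s: float
    gs_a: float
    gs_b: float
    iterations: int
    perm_m: np.ndarray
    perm_s: np.ndarray
    edge_p: np.ndarray  # per-edge permutation p-values (p x p, sym)
    seed: int | None = None
    n_failed: int = 0
    smooth_p: bool = True

    def summary(self) -> dict:
        return {
            "M": self.m, "S": self.s, "p_M": self.p_m, "p_S": self.p_s,
            "global_strength_a": self.gs_a, "global_strength_b": self.gs_b,
            "iterations": self.iterations, "failed_iterations": self.n_failed,
        }


def _p_value(count: int, total: int, smooth: bool) -> float:
    if smooth:
        return (count + 1) / (total + 1)
    return count / total if total else float("nan")


def nct(
    data_a,
    data_b,
    iterations: int = 1000,
    seed: int | None = None,
    estimator: dict | None = None,
    smooth_p: bool = True,
) -> NCTResult:
    """Permutation comparison of the networks behind two samples.

    ``estimator`` holds keyword arguments forwarded to
    :func:`psynet.ggm.estimate_network` (identical for both groups and for
    every permutation).
    """
    Xa, labels_a = as_data_matrix(data_a)
    Xb, labels_b = as_data_matrix(data_b)
    if labels_a != labels_b:
        raise ParameterError("both groups must share the same item set")
    if iterations < 100:
        log.warning("iterations=%d < 100; p-values will be coarse", iterations)
    est = estimator or {}
    p = Xa.shape[1]

    net_a = estimate_network(pd.DataFrame(Xa, columns=labels_a), **est)
    net_b = estimate_network(pd.DataFrame(Xb, columns=labels_b), **est)
    Wa, Wb = net_a.weights, net_b.weights
    obs_diff = np.abs(Wa - Wb)
    m_obs = float(obs_diff.max())
    gs_a, gs_b = global_strength(Wa), global_strength(Wb)
    s_obs = abs(gs_a - gs_b)

    pooled = np.vstack([Xa, Xb])
    # canonical order: permutation splits depend only on the pooled multiset
    order = np.lexsort(pooled.T[::-1])
    pooled = pooled[order]
    n_small = min(len(Xa), len(Xb))
    n_total = len(pooled)

    rng = np.random.default_rng(seed)
    perm_m = np.empty(iterations)
    perm_s = np.empty(iterations)
    ge_m = 0
    ge_s = 0
    edge_ge = np.zeros((p, p), dtype=np.int64)
    n_ok = 0
    n_failed = 0
    frame_cols = labels_a
    for _ in range(iterations):
        idx = rng.permutation(n_total)
        g1 = pooled[idx[:n_small]]
        g2 = pooled[idx[n_small:]]
        try:
            w1 = estimate_network(pd.DataFrame(g1, columns=frame_cols), **est).weights
            w2 = estimate_network(pd.DataFrame(g2, columns=frame_cols), **est).weights
        except Exception as exc:  # degenerate resample (e.g. constant item)
            n_failed += 1
            log.debug("permutation estimation failed: %s", exc)
            continue
        d = np.abs(w1 - w2)
        perm_m[n_ok] = d.max()
        perm_s[n_ok] = abs(global_strength(w1) - global_strength(w2))
        ge_m += perm_m[n_ok] >= m_obs
        ge_s += perm_s[n_ok] >= s_obs
        edge_ge += d >= obs_diff
        n_ok += 1
    if n_failed > MAX_PERM_FAILURE_RATE * iterations:
        raise ComparisonError(
            f"{n_failed}/{iterations} permutation re-estimations failed"
        )
    perm_m, perm_s = perm_m[:n_ok], perm_s[:n_ok]
    edge_p = np.ones((p, p))
    if n_ok:
        edge_p = (edge_ge + (1 if smooth_p else 0)) / (n_ok + (1 if smooth_p else 0))
    np.fill_diagonal(edge_p, 1.0)

    return NCTResult(
        labels=list(labels_a), weights_a=Wa, weights_b=Wb,
        m=m_obs, s=s_obs,
        p_m=_p_value(ge_m, n_ok, smooth_p),
        p_s=_p_value(ge_s, n_ok, smooth_p),
        gs_a=gs_a, gs_b=gs_b, iterations=n_ok,
        perm_m=perm_m, perm_s=perm_s, edge_p=edge_p,
        seed=seed, n_failed=n_failed, smooth_p=smooth_p,
    )


def classify_edge_change(w_a: float, w_b: float, significant: bool) -> str:
    """Change taxonomy with A = control, B = depressed."""
    if not significant:
        return "unchanged"
    if w_a != 0.0 and w_b == 0.0:
        return "lost"
    if w_a == 0.0 and w_b != 0.0:
        return "new link"
    if w_a == 0.0 and w_b == 0.0:
        return "unchanged"
    return "strengthened" if abs(w_b) > abs(w_a) else "weakened"


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def edge_difference_tests(
    result: NCTResult, alpha: float = 0.05, correction: str | None = None
) -> pd.DataFrame:
    """Per-edge difference table in the change-profile shape.

    ``correction`` may be ``None`` (raw permutation p-values, the default)
    or ``"holm"``.
    """
    p = len(result.labels)
    iu, ju = np.triu_indices(p, 1)
    pvals = result.edge_p[iu, ju]
    if correction == "holm":
        pvals = _holm(pvals)
    elif correction is not None:
        raise ParameterError(f"unknown correction: {correction}")
    rows = []
    for k, (i, j) in enumerate(zip(iu, ju)):
        wa = float(result.weights_a[i, j])
        wb = float(result.weights_b[i, j])
        sig = bool(pvals[k] <= alpha)
        rows.append({
            "node_i": result.labels[i], "node_j": result.labels[j],
            "weight_control": wa, "weight_depressed": wb,
            "abs_difference": abs(wa - wb), "p": float(pvals[k]),
            "significant": sig, "change": classify_edge_change(wa, wb, sig),
        })
    return pd.DataFrame(rows)
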