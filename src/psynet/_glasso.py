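"""Graphical-lasso kernel: blockwise coordinate descent on the covariance.

Solves, for a correlation/covariance matrix S and penalty ``lam``,

    maximize_Theta  log det Theta - tr(S Theta) - lam * sum_{i != j} |theta_ij|

with the diagonal unpenalized.  The solver sweeps over columns of the
working covariance W, solving each column's lasso subproblem by coordinate
descent (the classic W-update formulation).  Lambda paths are fitted
warm-started in descending order, which is what makes the permutation and
bootstrap loops elsewhere in the package affordable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .errors import EstimationError


@njit(cache=False, fastmath=False)
def _cd_sweeps(S, W, B, lam, tol, max_sweeps, inner_tol, max_inner):
    """In-place coordinate-descent sweeps; returns (n_sweeps, converged)."""
    p = S.shape[0]
    n_sweeps = 0
    converged = False
    for _ in range(max_sweeps):
        n_sweeps += 1
        max_delta = 0.0
        for j in range(p):
            # lasso subproblem for column j: 0.5 b'W11 b - s12'b + lam|b|_1
            for _ in range(max_inner):
                inner_delta = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j]
                    for l in range(p):
                        if l == j or l == k:
                            continue
                        r -= W[k, l] * B[l, j]
                    if r > lam:
                        b = (r - lam) / W[k, k]
                    elif r < -lam:
                        b = (r + lam) / W[k, k]
                    else:
                        b = 0.0
                    d = abs(b - B[k, j])
                    if d > inner_delta:
                        inner_delta = d
                    B[k, j] = b
                if inner_delta < inner_tol:
                    break
            for k in range(p):
                if k == j:
                    continue
                v = 0.0
                for l in range(p):
                    if l == j:
                        continue
                    v += W[k, l] * B[l, j]
                d = abs(v - W[k, j])
                if d > max_delta:
                    max_delta = d
                W[k, j] = v
                W[j, k] = v
        if max_delta < tol:
            converged = True
            break
    return n_sweeps, converged


@njit(cache=False, fastmath=False)
def _recover_precision(W, B):
    """Back out Theta from the converged (W, B); exact zeros preserved."""
    p = W.shape[0]
    Theta = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for k in range(p):
            if k != j:
                dot += W[k, j] * B[k, j]
        tjj = 1.0 / (W[j, j] - dot)
        Theta[j, j] = tjj
        for k in range(p):
            if k != j:
                Theta[k, j] = -B[k, j] * tjj
    for j in range(p):
        for k in range(j + 1, p):
            if B[k, j] == 0.0 and B[j, k] == 0.0:
                Theta[k, j] = 0.0
                Theta[j, k] = 0.0
            else:
                v = 0.5 * (Theta[k, j] + Theta[j, k])
                Theta[k, j] = v
                Theta[j, k] = v
    return Theta


def glasso_path(
    S: np.ndarray,
    lambdas,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
    inner_tol: float | None = None,
    max_inner: int = 1_000,
) -> list[np.ndarray]:
    """Fit the penalized precision along a descending lambda grid.

    Warm starts carry (W, B) from one lambda to the next.  Returns one
    precision matrix per lambda, in grid order.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(lambdas < 0):
        raise EstimationError("penalty values must be non-negative")
    if lambdas.size > 1 and np.any(np.diff(lambdas) > 0):
        raise EstimationError("lambda grid must be non-increasing for warm starts")
    if inner_tol is None:
        inner_tol = 0.1 * tol
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    out = []
    for lam in lambdas:
        # diagonal is unpenalized, so the working covariance keeps diag(S)
        np.fill_diagonal(W, np.diag(S))
        _, converged = _cd_sweeps(
            S, W, B, float(lam), tol, max_sweeps, inner_tol, max_inner
        )
        if not converged:
            raise EstimationError(
                f"coordinate descent did not converge at lambda={lam:g} "
                f"within {max_sweeps} sweeps (tol={tol:g})"
            )
        out.append(_recover_precision(W, B))
    return out


def glasso_fit(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Single-penalty fit; see :func:`glasso_path`."""
    return glasso_path(S, [float(lam)], tol=tol, max_sweeps=max_sweeps)[0]


def penalized_objective(Theta: np.ndarray, S: np.ndarray, lam: float) -> float:
    """The objective being maximized; used for diagnostics and oracles."""
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        return -np.inf
    off = np.abs(Theta).sum() - np.abs(np.diag(Theta)).sum()
    return float(logdet - np.trace(S @ Theta) - lam * off)
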