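"""Sparse partial-correlation network estimation (graphical lasso + EBIC).

The estimator follows the standard network-psychometrics recipe: compute an
item correlation matrix, fit an L1-penalized Gaussian graphical model along
a descending penalty path, and select the penalty by the extended Bayesian
information criterion (EBIC) with hyperparameter ``gamma``.  Edge weights
are regularized partial correlations

    w_ij = -theta_ij / sqrt(theta_ii * theta_jj)

where Theta is the selected precision matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._glasso import glasso_fit, glasso_path  # noqa: F401  (re-exported)
from ._utils import as_data_matrix, nearest_pd_correlation
from .errors import EstimationError

log = logging.getLogger(__name__)

MIN_SAMPLE_SIZE = 10


@dataclass
class CorrelationInput:
    """A correlation matrix plus the sample size behind it."""

    matrix: np.ndarray
    n: int
    method: str = "pearson"
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        p = self.matrix.shape[0]
        if self.matrix.shape != (p, p):
            raise EstimationError("correlation matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise EstimationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=1e-8):
            raise EstimationError("correlation matrix must have unit diagonal")
        if not self.labels:
            self.labels = [f"V{i + 1}" for i in range(p)]
        min_eig = np.linalg.eigvalsh(self.matrix).min()
        if min_eig < -1e-8:
            log.warning(
                "correlation matrix indefinite (min eigenvalue %.3g); "
                "repaired to nearest positive definite",
                min_eig,
            )
            self.matrix = nearest_pd_correlation(self.matrix)

    @property
    def p(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PartialCorrelationNetwork:
    """Estimated network: weights are regularized partial correlations."""

    labels: list[str]
    weights: np.ndarray
    precision: np.ndarray
    lambda_: float
    gamma: float
    ebic: float
    n: int

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def edge_count(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edge_list(self):
        """Upper-triangle nonzero edges as (label_i, label_j, weight)."""
        out = []
        iu, ju = np.triu_indices(self.p, 1)
        for i, j in zip(iu, ju):
            if self.weights[i, j] != 0.0:
                out.append((self.labels[i], self.labels[j], float(self.weights[i, j])))
        return out


@dataclass
class RegularizationPath:
    lambdas: np.ndarray
    ebics: np.ndarray
    edge_counts: np.ndarray
    precisions: list[np.ndarray] | None = None


def correlation_matrix(data, method: str = "pearson") -> CorrelationInput:
    """Pairwise item correlations, repaired to positive definite if needed."""
    X, labels = as_data_matrix(data)
    n, p = X.shape
    if n < 3:
        raise EstimationError("need at least 3 rows to correlate")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [labels[i] for i in np.flatnonzero(sds == 0)]
        raise EstimationError(f"constant item(s): {', '.join(bad)}")
    if method == "pearson":
        S = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        S = stats.spearmanr(X).statistic
        S = np.atleast_2d(S)
        if S.shape == (1, 1):  # p == 2 returns a scalar
            r = float(S)
            S = np.array([[1.0, r], [r, 1.0]])
    else:
        raise EstimationError(f"unknown correlation method: {method}")
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    return CorrelationInput(S, n=n, method=method, labels=labels)


def lambda_grid(
    S: CorrelationInput | np.ndarray,
    n_lambda: int = 100,
    min_ratio: float = 0.01,
) -> np.ndarray:
    """Log-spaced descending penalty grid from lambda_max = max|S_ij|, i!=j."""
    mat = S.matrix if isinstance(S, CorrelationInput) else np.asarray(S, float)
    p = mat.shape[0]
    lam_max = float(np.abs(mat - np.diag(np.diag(mat))).max())
    if lam_max == 0.0:
        warnings.warn("all off-diagonal correlations are zero; single-point grid")
        return np.array([0.0])
    if n_lambda == 1:
        return np.array([lam_max])
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def ebic(Theta: np.ndarray, S: np.ndarray, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a fitted precision matrix.

    EBIC = -2 L + E log n + 4 E gamma log p, with
    L = (n/2)(log det Theta - tr(S Theta)) and E the number of nonzero
    off-diagonal pairs.  gamma = 0 recovers the ordinary BIC penalty.
    """
    Theta = np.asarray(Theta, float)
    S = np.asarray(S, float)
    p = Theta.shape[0]
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        raise EstimationError("precision matrix must be positive definite")
    E = int(np.count_nonzero(np.triu(Theta, 1)))
    L = 0.5 * n * (logdet - float(np.trace(S @ Theta)))
    return float(-2.0 * L + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def precision_to_pcor(Theta: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix; zero diagonal."""
    d = 1.0 / np.sqrt(np.diag(Theta))
    P = -Theta * np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return 0.5 * (P + P.T)


def estimate_network(
    data,
    gamma: float = 0.5,
    method: str = "pearson",
    n_lambda: int = 100,
    min_ratio: float = 0.01,
    tol: float = 1e-6,
    return_path: bool = False,
):
    """EBIC-selected graphical-lasso network.

    ``data`` may be raw item responses (anything ``correlation_matrix``
    accepts) or a ready :class:`CorrelationInput`.  Ties in EBIC are broken
    toward the larger penalty (sparser model).  Returns the network, or
    ``(network, RegularizationPath)`` when ``return_path`` is true.
    """
    corr = data if isinstance(data, CorrelationInput) else correlation_matrix(data, method)
    if corr.n < MIN_SAMPLE_SIZE:
        raise EstimationError(f"need at least {MIN_SAMPLE_SIZE} rows, got {corr.n}")
    if corr.n < corr.p:
        warnings.warn(f"n={corr.n} < p={corr.p}; estimates rely on regularization")
    grid = lambda_grid(corr, n_lambda=n_lambda, min_ratio=min_ratio)
    thetas = glasso_path(corr.matrix, grid, tol=tol)
    ebics = np.array([ebic(T, corr.matrix, corr.n, gamma) for T in thetas])
    counts = np.array([int(np.count_nonzero(np.triu(T, 1))) for T in thetas])
    if np.any(np.diff(counts) < 0):
        # known glasso quirk on noisy small-sample paths; harmless for EBIC
        log.debug("edge count not monotone along the lambda path")
    best = int(np.argmin(ebics))  # grid descends, so first minimum = largest lambda
    Theta = thetas[best]
    net = PartialCorrelationNetwork(
        labels=list(corr.labels),
        weights=precision_to_pcor(Theta),
        precision=Theta,
        lambda_=float(grid[best]),
        gamma=float(gamma),
        ebic=float(ebics[best]),
        n=int(corr.n),
    )
    if return_path:
        return net, RegularizationPath(grid, ebics, counts, thetas)
    return net


def network_summary(net: PartialCorrelationNetwork) -> dict:
    """Edge counts, density and weight summaries in report shape."""
    p = net.p
    possible = p * (p - 1) // 2
    nz = net.edge_count()
    upper = np.triu(net.weights, 1)
    absw = np.abs(upper[upper != 0.0])
    return {
        "nodes": p,
        "possible_edges": possible,
        "nonzero_edges": nz,
        "pct_nonzero": 100.0 * nz / possible if possible else 0.0,
        "mean_abs_weight": float(absw.mean()) if nz else None,
        "global_strength": float(np.abs(upper).sum()),
        "lambda": net.lambda_,
        "gamma": net.gamma,
        "ebic": net.ebic,
        "n": net.n,
    }
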