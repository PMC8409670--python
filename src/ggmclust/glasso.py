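"""Regularized partial-correlation networks via graphical lasso + EBIC.

For each cluster's rows, the L1-penalized Gaussian precision matrix

    Omega_hat(lambda) = argmax  log det Omega - tr(S Omega) - lambda * sum_{i != j} |Omega_ij|

is computed along a descending lambda grid and the penalty is tuned by the
extended BIC, EBIC = -2 loglik + |E| log n + 4 gamma |E| log p. The
log-likelihood entering the EBIC is unpenalized: the graph-constrained
Gaussian MLE refit of each candidate's support, so shrinkage bias does not
distort the complexity comparison. The selected (regularized) precision is
reported as a partial-correlation network:
pcor(i, j) = -omega_ij / sqrt(omega_ii * omega_jj).

The inner graphical-lasso solve delegates to scikit-learn's coordinate
descent, which produces exact zeros on shrunk edges.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .config import EBICConfig
from .covsel import _fit_graph
from .datatypes import WeightedNetwork, as_matrix
from .exceptions import (
    EmptyClusterError,
    InvalidPrecisionError,
    NoConvergenceError,
    NotPositiveDefiniteError,
)
from .graphs import GraphStructure

_LOG_2PI = np.log(2.0 * np.pi)


def glasso_fit(
    S: np.ndarray, lam: float, tol: float = 1e-7, max_iter: int = 500
) -> np.ndarray:
    """L1-penalized precision estimate at penalty ``lam`` (off-diagonal only)."""
    S = np.asarray(S, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if np.any(np.diag(S) <= 0):
        raise ValueError("S must have a positive diagonal")
    if lam == 0.0:  # unpenalized MLE: plain inverse
        return np.linalg.inv(S)
    lam = float(lam)
    p = S.shape[0]

    # Stage 1: initial active set from scikit-learn's coordinate solver.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            _, precision = _sk_graphical_lasso(
                S, alpha=lam, mode="cd", tol=tol, max_iter=max_iter
            )
        except FloatingPointError:
            _, precision = _sk_graphical_lasso(
                S, alpha=lam, mode="lars", max_iter=max_iter
            )
    # entries at the solver's inner tolerance are shrunk-to-zero edges
    # sitting on the subgradient boundary, not active ones
    d = np.sqrt(np.abs(np.diag(precision)))
    precision[np.abs(precision) < 1e-6 * np.outer(d, d)] = 0.0
    signs = np.sign(precision)
    np.fill_diagonal(signs, 0.0)

    # Stage 2: working-set polish. At the optimum the solution restricted
    # to its active set is the graph-constrained Gaussian MLE for the
    # sign-shifted target S + lam * sign(Omega): Sigma matches that target
    # on the diagonal and active entries while Omega is zero elsewhere.
    # Solving that subproblem by IPS and refreshing the active set from
    # the KKT conditions gives exact zeros and a sharp KKT residual.
    off = ~np.eye(p, dtype=bool)
    kkt_tol = max(100.0 * tol, 1e-6) * max(1.0, float(np.abs(S).max()))
    for _ in range(30):
        graph = GraphStructure.from_adjacency(signs != 0)
        S_t = S + lam * signs
        Sigma, Omega = _fit_graph(S_t, graph, tol=min(tol, 1e-8), max_sweeps=10_000)
        R = Sigma - S
        active = signs != 0
        # keep active entries whose polished sign confirms the assumption;
        # drop flipped/vanished ones; inactive entries violating
        # |Sigma_ij - S_ij| <= lam enter with the stationarity sign
        new_signs = np.zeros_like(signs)
        keep = active & (np.sign(Omega) == signs)
        new_signs[keep] = signs[keep]
        viol = off & ~active & (np.abs(R) > lam + kkt_tol)
        new_signs[viol] = np.sign(R)[viol]
        if np.array_equal(new_signs, signs):
            return (Omega + Omega.T) / 2.0
        signs = new_signs
    raise NoConvergenceError(
        f"graphical lasso active set did not stabilize at lambda={lam:.4g}"
    )


def kkt_residual(
    S: np.ndarray, covariance: np.ndarray, precision: np.ndarray, lam: float
) -> float:
    """Worst violation of the penalized-likelihood stationarity conditions."""
    R = covariance - S
    off = ~np.eye(S.shape[0], dtype=bool)
    active = off & (precision != 0)
    inactive = off & (precision == 0)
    resid = float(np.abs(np.diag(R)).max())
    if active.any():
        resid = max(
            resid, float(np.abs(R[active] - lam * np.sign(precision[active])).max())
        )
    if inactive.any():
        resid = max(resid, max(0.0, float((np.abs(R[inactive]) - lam).max())))
    return resid


def precision_to_partial_correlations(
    omega: np.ndarray, variable_names: Sequence[str] | None = None
) -> WeightedNetwork:
    """Partial correlations -omega_ij / sqrt(omega_ii omega_jj), zero diagonal."""
    omega = np.asarray(omega, dtype=float)
    d = np.diag(omega)
    if np.any(d <= 0):
        raise InvalidPrecisionError("precision has a non-positive diagonal entry")
    scale = np.sqrt(np.outer(d, d))
    W = -omega / scale
    np.fill_diagonal(W, 0.0)
    W = np.clip((W + W.T) / 2.0, -1.0, 1.0)
    if variable_names is None:
        variable_names = [f"V{i + 1}" for i in range(omega.shape[0])]
    return WeightedNetwork(W, list(variable_names), scale="partial_correlation")


def gaussian_loglik(S: np.ndarray, omega: np.ndarray, n: int) -> float:
    """Unpenalized Gaussian log-likelihood of n observations with sample
    covariance S at precision omega."""
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        raise InvalidPrecisionError("precision is not positive definite")
    p = S.shape[0]
    return 0.5 * n * (logdet - float(np.sum(S * omega)) - p * _LOG_2PI)


def ebic_score(loglik: float, n_edges: int, n: int, p: int, gamma: float) -> float:
    """EBIC = -2 loglik + |E| log n + 4 gamma |E| log p (minimized)."""
    if n <= 0 or p <= 1:
        raise ValueError("need n > 0 and p > 1")
    return -2.0 * loglik + n_edges * np.log(n) + 4.0 * gamma * n_edges * np.log(p)


def _count_edges(omega: np.ndarray) -> int:
    iu = np.triu_indices_from(omega, k=1)
    return int(np.count_nonzero(omega[iu]))


class EBICGraphicalLasso(BaseEstimator):
    """Graphical lasso with the penalty tuned by extended BIC.

    Parameters
    ----------
    gamma : EBIC hyperparameter; 0 reduces to plain BIC, 0.5 is the
        conventional conservative default.
    n_lambdas, lambda_min_ratio : define the default descending log-spaced
        grid from lambda_max = max off-diagonal |S| down to
        lambda_min_ratio * lambda_max.
    lambdas : explicit grid overriding the automatic one.
    tol, max_iter : coordinate-descent convergence settings.

    Attributes
    ----------
    precision_ : selected penalized precision matrix.
    network_ : :class:`WeightedNetwork` of partial correlations.
    lambda_, ebic_ : selected penalty and its EBIC; ties along the grid
        resolve to the larger (sparser) lambda.
    lambdas_, ebics_, edge_counts_ : the full selection path.
    """

    def __init__(
        self,
        gamma: float = 0.5,
        *,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 0.01,
        lambdas: Sequence[float] | None = None,
        tol: float = 1e-7,
        max_iter: int = 500,
    ):
        self.gamma = gamma
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.lambdas = lambdas
        self.tol = tol
        self.max_iter = max_iter

    def _config(self) -> EBICConfig:
        grid = None if self.lambdas is None else np.asarray(self.lambdas, float)
        return EBICConfig(
            gamma=self.gamma,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            lambda_grid=grid,
            tol=self.tol,
        )

    def fit(self, X, y=None) -> "EBICGraphicalLasso":
        X_arr, names = as_matrix(X)
        n, p = X_arr.shape
        if n == 0:
            raise EmptyClusterError("cannot estimate a network from zero rows")
        if n < p + 1:
            warnings.warn(
                f"only {n} rows for {p} variables; network estimate will be unstable",
                stacklevel=2,
            )
        cfg = self._config()
        S = np.cov(X_arr, rowvar=False, bias=True)  # MLE denominator n
        grid = cfg.grid_for(S)

        best = None
        ebics, counts = [], []
        for lam in grid:
            omega = glasso_fit(S, float(lam), tol=cfg.tol, max_iter=self.max_iter)
            n_edges = _count_edges(omega)
            # EBIC uses the unpenalized Gaussian log-likelihood of the
            # selected support: the graph-constrained MLE refit of that
            # sparsity pattern, so shrinkage bias does not leak into the
            # model-complexity comparison
            support = GraphStructure.from_adjacency(omega != 0)
            try:
                _, om_refit = _fit_graph(S, support, tol=min(cfg.tol, 1e-8))
            except NotPositiveDefiniteError:
                ebics.append(np.inf)  # support unidentifiable at this n
                counts.append(n_edges)
                continue
            score = ebic_score(gaussian_loglik(S, om_refit, n), n_edges, n, p, cfg.gamma)
            ebics.append(score)
            counts.append(n_edges)
            if best is None or score < best[0] - 1e-12:  # ties keep larger lambda
                best = (score, float(lam), omega)
        if best is None:
            raise NoConvergenceError("no lambda admitted an identifiable refit")
        self.variable_names_ = names
        self.n_features_in_ = p
        self.n_samples_ = n
        self.covariance_ = S
        self.ebic_, self.lambda_, self.precision_ = best
        self.lambdas_ = np.asarray(grid, dtype=float)
        self.ebics_ = np.asarray(ebics)
        self.edge_counts_ = np.asarray(counts)
        self.network_ = precision_to_partial_correlations(self.precision_, names)
        return self

    def transform(self, X=None) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")
        return self.network_.weights


def select_network(data_subset, config: EBICConfig | None = None) -> WeightedNetwork:
    """EBIC-tuned partial-correlation network of one cluster's rows."""
    config = config or EBICConfig()
    est = EBICGraphicalLasso(
        gamma=config.gamma,
        n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio,
        lambdas=None if config.lambda_grid is None else list(config.lambda_grid),
        tol=config.tol,
    )
    est.fit(data_subset)
    return est.network_
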