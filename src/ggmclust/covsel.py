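"""Covariance selection: graph-constrained Gaussian MLE and structure search.

Given a sample covariance S and an undirected graph G, the constrained
maximum-likelihood covariance is the unique positive-definite matrix that
matches S on the diagonal and on every edge of G while its inverse is zero
off G. It is computed by iterative proportional scaling (IPS): sweeping
over the edges, each step matches the 2 x 2 marginal covariance of that
edge's pair to S by a rank-2 update of the precision matrix. IPS keeps the
iterate positive definite and converges to the constrained MLE for any
graph; on decomposable graphs it agrees with the clique-marginal closed
form.

Per-component graphs are chosen by maximizing a penalized profile
log-likelihood: the Gaussian log-likelihood at the constrained MLE minus a
per-edge penalty (1 + beta) * log(n_eff) / 2, which for beta = 0 is the
BIC edge cost at effective sample size n_eff.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from ._ips import NOT_PD, NO_CONVERGENCE, ips_sweeps
from .config import FitConfig
from .exceptions import NoConvergenceError, NotPositiveDefiniteError
from .graphs import GraphStructure

_LOG_2PI = np.log(2.0 * np.pi)


def _inv2(B: np.ndarray) -> np.ndarray:
    det = B[0, 0] * B[1, 1] - B[0, 1] * B[1, 0]
    if det <= 0.0 or B[0, 0] <= 0.0:
        raise NotPositiveDefiniteError("2x2 marginal not positive definite")
    return np.array([[B[1, 1], -B[0, 1]], [-B[1, 0], B[0, 0]]]) / det


def _validate_S(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if np.any(np.diag(S) <= 0):
        raise NotPositiveDefiniteError("S has a non-positive diagonal entry")
    return (S + S.T) / 2.0


def _fit_graph(
    S: np.ndarray,
    graph: GraphStructure,
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
    init_precision: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """IPS core. Returns (Sigma_hat, Omega_hat = Sigma_hat^-1)."""
    p = graph.p
    d = np.diag(S)

    if graph.is_complete:
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            raise NotPositiveDefiniteError("sample covariance not positive definite")
        return S.copy(), np.linalg.inv(S)

    edges = graph.edge_list()
    if not edges:
        return np.diag(d), np.diag(1.0 / d)

    adj = graph.adjacency()
    K = None
    if init_precision is not None:
        K = np.asarray(init_precision, dtype=float).copy()
        K[~adj & ~np.eye(p, dtype=bool)] = 0.0  # project onto the new support
        iso = ~adj.any(axis=1)
        K[iso, iso] = 1.0 / d[iso]
        try:
            np.linalg.cholesky(K)
        except np.linalg.LinAlgError:
            K = None
    if K is None:
        K = np.diag(1.0 / d)

    # 2x2 marginal feasibility: S must be PD on every edge
    for i, j in edges:
        if S[i, i] * S[j, j] - S[i, j] ** 2 <= 0.0:
            raise NotPositiveDefiniteError(f"S singular on edge ({i}, {j})")

    edges_arr = np.asarray(edges, dtype=np.int64)
    S = np.ascontiguousarray(S)
    K = np.ascontiguousarray(K)
    Sigma = np.linalg.inv(K)

    def _constraint_err(Sig: np.ndarray) -> float:
        return float(
            max(
                np.abs(np.diag(Sig) - d).max(),
                max((abs(Sig[i, j] - S[i, j]) for i, j in edges), default=0.0),
            )
        )

    # refresh the maintained inverse between kernel runs to wash out any
    # accumulated Woodbury drift before trusting the constraint check
    stalled = False
    for _ in range(5):
        status = ips_sweeps(S, edges_arr, K, Sigma, tol, max_sweeps)
        if status == NOT_PD:
            raise NotPositiveDefiniteError("IPS iterate lost positive definiteness")
        if status == NO_CONVERGENCE:
            stalled = True
            break
        Sigma = np.linalg.inv(K)
        if _constraint_err(Sigma) < tol:
            return (Sigma + Sigma.T) / 2.0, (K + K.T) / 2.0
    else:
        stalled = True
    if stalled:
        # pairwise sweeps converge slowly when a clique marginal of S is
        # near-singular; matching whole maximal-clique blocks fixes that
        Sigma, K = _clique_ips(S, graph, K, tol, max_sweeps)
        if _constraint_err(Sigma) < tol:
            return (Sigma + Sigma.T) / 2.0, (K + K.T) / 2.0
    raise NoConvergenceError(f"IPS did not reach tol {tol} in {max_sweeps} sweeps")


def _clique_ips(
    S: np.ndarray,
    graph: GraphStructure,
    K: np.ndarray,
    tol: float,
    max_sweeps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """IPS over maximal cliques (numpy path, used when edge sweeps stall)."""
    import networkx as nx

    G = nx.from_numpy_array(graph.adjacency())
    cliques = [np.array(sorted(c)) for c in nx.find_cliques(G) if len(c) >= 2]
    blocks = []
    for c in cliques:
        Scc = S[np.ix_(c, c)]
        try:
            np.linalg.cholesky(Scc)
        except np.linalg.LinAlgError:
            raise NotPositiveDefiniteError("S singular on a clique")
        blocks.append((c, np.linalg.inv(Scc)))
    K = K.copy()
    d = np.diag(S)
    adj = graph.adjacency()
    for _ in range(max_sweeps):
        for c, Sinv in blocks:
            blk = np.ix_(c, c)
            Sigma = np.linalg.inv(K)
            K[blk] += Sinv - np.linalg.inv(Sigma[blk])
        Sigma = np.linalg.inv(K)
        err = max(
            float(np.abs(np.diag(Sigma) - d).max()),
            float(np.abs((Sigma - S)[adj]).max()) if adj.any() else 0.0,
        )
        if err < tol:
            return Sigma, K
    raise NoConvergenceError("clique IPS did not converge")


def constrained_covariance_mle(
    S: np.ndarray,
    graph: GraphStructure,
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
    init_precision: np.ndarray | None = None,
) -> np.ndarray:
    """Maximum-likelihood covariance under the sparsity pattern of ``graph``.

    Parameters
    ----------
    S : sample covariance (symmetric, positive diagonal).
    graph : the precision sparsity pattern to enforce.
    tol : maximum allowed deviation |Sigma_ij - S_ij| on the diagonal and
        on graph edges at exit.
    init_precision : optional warm start (projected onto the graph).

    Raises
    ------
    NotPositiveDefiniteError
        if S is not positive definite on a required clique.
    NoConvergenceError
        if IPS exhausts ``max_sweeps``.
    """
    S = _validate_S(S)
    if graph.p != S.shape[0]:
        raise ValueError("graph size does not match S")
    Sigma, _ = _fit_graph(S, graph, tol=tol, max_sweeps=max_sweeps, init_precision=init_precision)
    return Sigma


def gaussian_profile_loglik(S: np.ndarray, Sigma: np.ndarray, Omega: np.ndarray, n_eff: float) -> float:
    """Gaussian log-likelihood of n_eff observations with sample covariance S
    evaluated at (any mean MLE and) covariance Sigma."""
    sign, logdet_omega = np.linalg.slogdet(Omega)
    if sign <= 0:
        raise NotPositiveDefiniteError("precision has non-positive determinant")
    p = S.shape[0]
    return -0.5 * n_eff * (p * _LOG_2PI - logdet_omega + float(np.sum(S * Omega)))


def penalized_score(loglik: float, n_edges: int, n_eff: float, beta: float = 0.0) -> float:
    """Structure score: log-likelihood minus (1 + beta) * log(n_eff)/2 per edge."""
    if n_eff <= 1:
        raise ValueError("n_eff must exceed 1")
    return loglik - (1.0 + beta) * 0.5 * np.log(n_eff) * n_edges


def _graph_score(
    S: np.ndarray,
    graph: GraphStructure,
    n_eff: float,
    beta: float,
    tol: float,
    max_sweeps: int,
    init_precision: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    Sigma, Omega = _fit_graph(S, graph, tol=tol, max_sweeps=max_sweeps, init_precision=init_precision)
    ll = gaussian_profile_loglik(S, Sigma, Omega, n_eff)
    return penalized_score(ll, graph.n_edges, n_eff, beta), Sigma, Omega


def structure_search(
    S: np.ndarray,
    n_eff: float,
    config: FitConfig | None = None,
    *,
    start: GraphStructure | None = None,
) -> GraphStructure:
    """Select the graph maximizing the penalized profile log-likelihood.

    ``greedy_stepwise`` starts from the empty graph (or ``start``) and
    repeatedly applies the single edge addition/removal that most improves
    the score, stopping when no toggle improves it. ``exhaustive``
    (p <= 5 only) enumerates every graph and returns the maximizer. Ties
    resolve toward fewer edges, then the lexicographically smallest edge
    set.
    """
    config = config or FitConfig()
    S = _validate_S(S)
    p = S.shape[0]

    if config.search_strategy == "exhaustive":
        if p > 5:
            raise ValueError("unsupported: exhaustive search is limited to p <= 5")
        return _exhaustive_search(S, n_eff, config)
    return _greedy_search(S, n_eff, config, start)[0]


def _tie_tol(score: float) -> float:
    return 1e-7 * (1.0 + abs(score))


def _exhaustive_search(S: np.ndarray, n_eff: float, config: FitConfig) -> GraphStructure:
    p = S.shape[0]
    pairs = list(combinations(range(p), 2))
    best_graph, best_score = None, -np.inf
    # Enumerate in (edge count, lexicographic) order so that accepting only
    # strict improvements realizes the tie-breaking rule.
    for r in range(len(pairs) + 1):
        for subset in combinations(pairs, r):
            graph = GraphStructure.from_edges(p, subset)
            try:
                score, _, _ = _graph_score(
                    S, graph, n_eff, config.beta, config.mle_tol, config.mle_max_sweeps
                )
            except NotPositiveDefiniteError:
                continue
            if score > best_score + _tie_tol(best_score if np.isfinite(best_score) else score):
                best_graph, best_score = graph, score
    if best_graph is None:
        raise NotPositiveDefiniteError("no graph admitted a positive definite fit")
    return best_graph


def _greedy_search(
    S: np.ndarray,
    n_eff: float,
    config: FitConfig,
    start: GraphStructure | None,
) -> tuple[GraphStructure, np.ndarray, np.ndarray]:
    p = S.shape[0]
    graph = start if start is not None else GraphStructure.empty(p)
    try:
        score, Sigma, Omega = _graph_score(
            S, graph, n_eff, config.beta, config.mle_tol, config.mle_max_sweeps
        )
    except NotPositiveDefiniteError:
        # warm start infeasible under this S; restart from independence
        graph = GraphStructure.empty(p)
        score, Sigma, Omega = _graph_score(
            S, graph, n_eff, config.beta, config.mle_tol, config.mle_max_sweeps
        )
    pairs = list(combinations(range(p), 2))

    while True:
        best = None  # (score, n_edges, edge_tuple, graph, Sigma, Omega)
        for i, j in pairs:
            cand = graph.toggled(i, j)
            try:
                sc, Sig_c, Om_c = _graph_score(
                    S, cand, n_eff, config.beta, config.mle_tol,
                    config.mle_max_sweeps, init_precision=Omega,
                )
            except NotPositiveDefiniteError:
                continue
            if sc <= score + _tie_tol(score):
                continue
            key = (cand.n_edges, tuple(cand.edge_list()))
            if (
                best is None
                or sc > best[0] + _tie_tol(best[0])
                or (abs(sc - best[0]) <= _tie_tol(best[0]) and key < (best[1], best[2]))
            ):
                best = (sc, cand.n_edges, tuple(cand.edge_list()), cand, Sig_c, Om_c)
        if best is None:
            return graph, Sigma, Omega
        score, _, _, graph, Sigma, Omega = best
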