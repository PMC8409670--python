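"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive — literal formulas, dense loops,
generic optimizers, exhaustive enumeration — and shares no code with the
implementation under test.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def mvn_logpdf_literal(x, mean, cov):
    """-(1/2)(p log 2pi + log det S + (x-m)' S^-1 (x-m)), by direct inversion."""
    x = np.asarray(x, float)
    mean = np.asarray(mean, float)
    cov = np.asarray(cov, float)
    p = mean.size
    diff = x - mean
    return -0.5 * (
        p * np.log(2 * np.pi)
        + np.log(np.linalg.det(cov))
        + diff @ np.linalg.inv(cov) @ diff
    )


def plain_gmm_em(X, resp0, max_iter=500, tol=1e-10):
    """Textbook unconstrained Gaussian-mixture EM from given one-hot
    responsibilities. Returns (loglik, means, covs, weights)."""
    X = np.asarray(X, float)
    n, p = X.shape
    resp = np.asarray(resp0, float).copy()
    K = resp.shape[1]
    ll_prev = -np.inf
    for _ in range(max_iter):
        nk = resp.sum(axis=0)
        w = nk / n
        mu = (resp.T @ X) / nk[:, None]
        covs = np.empty((K, p, p))
        for k in range(K):
            d = X - mu[k]
            covs[k] = (d * resp[:, [k]]).T @ d / nk[k]
        log_parts = np.empty((n, K))
        for k in range(K):
            log_parts[:, k] = np.log(w[k]) + mvn_logpdf_rows(X, mu[k], covs[k])
        m = log_parts.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_parts - m).sum(axis=1))
        ll = lse.sum()
        resp = np.exp(log_parts - lse[:, None])
        if abs(ll - ll_prev) < tol * abs(ll):
            break
        ll_prev = ll
    return ll, mu, covs, w


def mvn_logpdf_rows(X, mean, cov):
    p = mean.size
    diff = X - mean
    inv = np.linalg.inv(cov)
    maha = np.einsum("ij,jk,ik->i", diff, inv, diff)
    return -0.5 * (p * np.log(2 * np.pi) + np.log(np.linalg.det(cov)) + maha)


def constrained_mle_numeric(S, edges, x0_cov=None):
    """Maximize the Gaussian log-likelihood over precisions supported on
    the given edge set, by generic numeric optimization over the free
    entries (diagonal via log-Cholesky-free parametrization of Omega)."""
    S = np.asarray(S, float)
    p = S.shape[0]
    free = [(i, i) for i in range(p)] + [tuple(e) for e in edges]

    def unpack(theta):
        omega = np.zeros((p, p))
        for t, (i, j) in zip(theta, free):
            omega[i, j] = t
            omega[j, i] = t
        return omega

    def negll(theta):
        omega = unpack(theta)
        vals = np.linalg.eigvalsh(omega)
        if vals.min() <= 1e-10:
            return 1e10
        sign, logdet = np.linalg.slogdet(omega)
        return -(logdet - np.sum(S * omega))

    theta0 = np.array([1.0 / S[i, i] for i in range(p)] + [0.0] * len(edges))
    res = minimize(negll, theta0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 200000,
                            "maxfev": 200000})
    return np.linalg.inv(unpack(res.x))


def glasso_objective_numeric(S, lam):
    """Minimize -(log det O - tr(SO) - lam sum_offdiag |O_ij|) numerically.

    Off-diagonal entries are split O_ij = a_ij - b_ij with a, b >= 0 so
    the objective is smooth (|O_ij| <= a_ij + b_ij, tight at optimum) and
    a generic box-constrained quasi-Newton solver applies.
    """
    S = np.asarray(S, float)
    p = S.shape[0]
    diag_idx = [(i, i) for i in range(p)]
    off_idx = list(zip(*np.triu_indices(p, 1)))
    n_d, n_o = len(diag_idx), len(off_idx)

    def unpack(theta):
        omega = np.zeros((p, p))
        for t, (i, i2) in zip(theta[:n_d], diag_idx):
            omega[i, i2] = t
        for k, (i, j) in enumerate(off_idx):
            v = theta[n_d + k] - theta[n_d + n_o + k]
            omega[i, j] = omega[j, i] = v
        return omega

    def obj(theta):
        omega = unpack(theta)
        if np.linalg.eigvalsh(omega).min() <= 1e-10:
            return 1e10
        sign, logdet = np.linalg.slogdet(omega)
        l1 = 2.0 * theta[n_d:].sum()  # sum over i != j counts each pair twice
        return -(logdet - np.sum(S * omega) - lam * l1)

    theta0 = np.concatenate([[1.0 / S[i, i] for i in range(p)], np.zeros(2 * n_o)])
    bounds = [(1e-8, None)] * n_d + [(0.0, None)] * (2 * n_o)
    res = minimize(obj, theta0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 50000, "ftol": 1e-15, "gtol": 1e-12})
    return unpack(res.x)


def partial_corr_by_regression(X, i, j):
    """Partial correlation of columns i, j given all others, via the
    correlation of least-squares residuals."""
    X = np.asarray(X, float)
    others = [c for c in range(X.shape[1]) if c not in (i, j)]
    Z = np.column_stack([np.ones(X.shape[0]), X[:, others]])
    ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
    rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
    return float(np.corrcoef(ri, rj)[0, 1])


# -- brute-force path statistics on small weighted networks --------------


def _all_simple_paths(adj_lengths, s, t, p):
    """Yield (path, length) over all simple s-t paths; dense recursion."""
    stack = [([s], 0.0)]
    while stack:
        path, length = stack.pop()
        u = path[-1]
        if u == t:
            yield path, length
            continue
        for v in range(p):
            if v in path:
                continue
            l = adj_lengths[u][v]
            if np.isfinite(l):
                stack.append((path + [v], length + l))


def brute_force_geodesics(weights):
    """All-pairs shortest lengths (1/|w| edges) and the tied-geodesic sets,
    by enumerating every simple path."""
    W = np.asarray(weights, float)
    p = W.shape[0]
    with np.errstate(divide="ignore"):
        L = np.where(W != 0, 1.0 / np.abs(W), np.inf)
    dist = np.full((p, p), np.inf)
    np.fill_diagonal(dist, 0.0)
    geodesics = {}
    for s in range(p):
        for t in range(p):
            if s == t:
                continue
            best, paths = np.inf, []
            for path, length in _all_simple_paths(L, s, t, p):
                if length < best - 1e-12:
                    best, paths = length, [path]
                elif abs(length - best) <= 1e-12:
                    paths.append(path)
            dist[s, t] = best
            geodesics[(s, t)] = paths
    return dist, geodesics


def brute_force_closeness(weights):
    dist, _ = brute_force_geodesics(weights)
    p = dist.shape[0]
    out = np.zeros(p)
    for i in range(p):
        d = np.delete(dist[i], i)
        if np.all(np.isfinite(d)) and d.sum() > 0:
            out[i] = 1.0 / d.sum()
    return out


def brute_force_betweenness(weights):
    """Fractional counting over tied geodesics, endpoints excluded,
    unordered pairs counted once."""
    dist, geos = brute_force_geodesics(weights)
    p = dist.shape[0]
    out = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            paths = geos.get((s, t), [])
            if not paths or not np.isfinite(dist[s, t]):
                continue
            for path in paths:
                for v in path[1:-1]:
                    out[v] += 1.0 / len(paths)
    return out
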