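"""Gaussian graphical mixture models (GGMM) fitted by structural EM.

A GGMM is a finite mixture of multivariate Gaussians

    f(x) = sum_k tau_k * Phi(x | mu_k, Sigma_k),    Sigma_k in C+(G_k),

where each component covariance is constrained to an undirected graph
G_k: the inverse of Sigma_k must vanish off the edges of G_k. The graphs
are not fixed in advance — structural EM interleaves the usual E and M
steps with a per-component graph search that maximizes a penalized
profile likelihood, so clustering and per-cluster network estimation
happen in one model. The number of components is chosen by BIC
(minimized), and component counts whose fit degenerates (a covariance
losing positive definiteness, a component starving of observations) are
reported as typed failures rather than silently patched — exactly the
behavior model selection needs to survive.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .config import FitConfig
from .covsel import _fit_graph, _greedy_search, structure_search
from .datatypes import ComponentParams, DataMatrix, WeightedNetwork, as_matrix
from .exceptions import (
    FailureRecord,
    GGMMFitError,
    NotPositiveDefiniteError,
    NoValidModelError,
)
from .graphs import GraphStructure

_LOG_2PI = np.log(2.0 * np.pi)
_MIN_EIG = 1e-8  # positive-definiteness floor for component covariances


def _log_mvn_density(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Rows of X -> log Phi(x | mean, cov), via Cholesky."""
    try:
        chol, lower = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError("covariance is not positive definite")
    p = mean.size
    diff = np.atleast_2d(X) - mean
    solved = cho_solve((chol, lower), diff.T)
    maha = np.sum(diff.T * solved, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (p * _LOG_2PI + logdet + maha)


def gaussian_log_density(x: np.ndarray, component: ComponentParams) -> float:
    """log Phi(x | mu, Sigma) for one observation and one component."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != component.p:
        raise ValueError("x dimension does not match the component")
    return float(_log_mvn_density(x[None, :], component.mean, component.covariance)[0])


class GraphicalGaussianMixture(ClusterMixin, BaseEstimator):
    """Mixture of Gaussians with graph-constrained covariances.

    Parameters
    ----------
    n_components : number of mixture components K.
    beta : extra weight on the per-edge structure penalty
        (1 + beta) * log(n_eff) / 2; 0 gives the BIC-type penalty.
    tol : relative penalized log-likelihood change declaring convergence.
    max_iter : structural-EM iteration cap per restart.
    n_init : independent seeded k-means initializations; the best
        penalized fit is kept.
    search_strategy : 'greedy_stepwise' (default) or 'exhaustive' (p <= 5).
    fixed_graphs : skip structure search and constrain every component to
        the given graph(s): 'complete', a GraphStructure, or one per
        component. 'complete' reduces the model to an ordinary GMM.
    random_state : integer seed; all randomness (restart initializations)
        derives from it. Recorded in ``seed_``.

    Attributes
    ----------
    weights_ : mixing proportions tau_k, shape (K,).
    means_ : component means, shape (K, p).
    covariances_, precisions_ : shape (K, p, p); precisions are exactly
        supported on ``graphs_`` up to the IPS tolerance.
    graphs_ : list of K :class:`GraphStructure`.
    log_likelihood_, penalized_log_likelihood_, bic_, n_parameters_ :
        fit diagnostics; BIC = -2 LL + n_params log n, lower is better.
    labels_ : MAP cluster label (0-based) per training row.
    history_ : per-iteration records (penalized LL, structure changes)
        of the winning restart.
    """

    def __init__(
        self,
        n_components: int = 1,
        *,
        beta: float = 0.0,
        tol: float = 1e-6,
        max_iter: int = 500,
        n_init: int = 10,
        search_strategy: str = "greedy_stepwise",
        fixed_graphs=None,
        mle_tol: float = 1e-8,
        mle_max_sweeps: int = 10_000,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.beta = beta
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.search_strategy = search_strategy
        self.fixed_graphs = fixed_graphs
        self.mle_tol = mle_tol
        self.mle_max_sweeps = mle_max_sweeps
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _resolve_fixed_graphs(self, p: int) -> list[GraphStructure] | None:
        fg = self.fixed_graphs
        if fg is None:
            return None
        if isinstance(fg, str):
            if fg != "complete":
                raise ValueError("fixed_graphs string form must be 'complete'")
            return [GraphStructure.complete(p)] * self.n_components
        if isinstance(fg, GraphStructure):
            return [fg] * self.n_components
        graphs = list(fg)
        if len(graphs) != self.n_components:
            raise ValueError("need one fixed graph per component")
        return graphs

    def _config(self) -> FitConfig:
        return FitConfig(
            max_iterations=self.max_iter,
            tolerance=self.tol,
            n_restarts=self.n_init,
            seed=self.random_state,
            beta=self.beta,
            search_strategy=self.search_strategy,
            mle_tol=self.mle_tol,
            mle_max_sweeps=self.mle_max_sweeps,
        )

    # ------------------------------------------------------------------
    def fit(self, X, y=None) -> "GraphicalGaussianMixture":
        X_arr, names = as_matrix(X)
        n, p = X_arr.shape
        if not np.all(np.isfinite(X_arr)):
            raise ValueError("X contains missing or non-finite values")
        if n < 2 or p < 2:
            raise ValueError("need at least 2 rows and 2 columns")
        if np.any(X_arr.var(axis=0) <= 0):
            raise ValueError("X has a zero-variance column")
        K = int(self.n_components)
        if K < 1:
            raise ValueError("n_components must be >= 1")
        if n <= K * (p + 1):
            warnings.warn(
                f"n = {n} is small for K = {K} components of dimension {p}; "
                "expect degenerate components",
                stacklevel=2,
            )

        seed = self.random_state
        if seed is None:
            seed = int(np.random.SeedSequence().entropy % (2**31 - 1))
        rng = np.random.default_rng(seed)
        n_init = 1 if K == 1 else int(self.n_init)
        restart_seeds = rng.integers(0, 2**31 - 1, size=n_init)

        best = None
        first_failure: GGMMFitError | None = None
        for rs in restart_seeds:
            resp0 = self._init_responsibilities(X_arr, K, int(rs))
            try:
                state = self._fit_single(X_arr, resp0)
            except GGMMFitError as err:
                if first_failure is None:
                    first_failure = err
                continue
            if best is None or state["pll"] > best["pll"]:
                best = state
        if best is None:
            assert first_failure is not None
            raise first_failure

        self.variable_names_ = names
        self.n_features_in_ = p
        self.n_samples_ = n
        self.seed_ = int(seed)
        self.weights_ = best["tau"]
        self.means_ = best["mu"]
        self.covariances_ = best["Sigma"]
        self.precisions_ = best["Omega"]
        self.graphs_ = best["graphs"]
        self.log_likelihood_ = best["ll"]
        self.penalized_log_likelihood_ = best["pll"]
        self.n_iter_ = best["n_iter"]
        self.converged_ = best["converged"]
        self.history_ = best["history"]
        self.responsibilities_ = best["resp"]
        self.mstep_responsibilities_ = best["mstep_resp"]
        self.labels_ = np.argmax(best["resp"], axis=1)
        self.n_parameters_ = self._count_parameters()
        self.bic_ = -2.0 * self.log_likelihood_ + self.n_parameters_ * np.log(n)
        return self

    def _init_responsibilities(self, X: np.ndarray, K: int, seed: int) -> np.ndarray:
        n = X.shape[0]
        if K == 1:
            return np.ones((n, 1))
        km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(X)
        resp = np.zeros((n, K))
        resp[np.arange(n), km.labels_] = 1.0
        return resp

    def _fit_single(self, X: np.ndarray, resp: np.ndarray) -> dict:
        n, p = X.shape
        K = resp.shape[1]
        cfg = self._config()
        fixed = self._resolve_fixed_graphs(p)

        graphs: list[GraphStructure | None] = list(fixed) if fixed else [None] * K
        Omegas: list[np.ndarray | None] = [None] * K
        searching = fixed is None
        prev_pll = -np.inf
        history: list[dict] = []
        converged = False
        it = 0

        while it < self.max_iter:
            it += 1
            nk = resp.sum(axis=0)
            # the starvation guard applies to mixtures: a lone component
            # always holds the full sample and fails only through the MLE
            if K > 1 and np.any(nk < p + 1):
                raise GGMMFitError(
                    FailureRecord(
                        K,
                        "empty_component",
                        f"component weight {nk.min():.2f} below p + 1 = {p + 1}",
                    )
                )
            tau = nk / n
            mu = (resp.T @ X) / nk[:, None]
            resp_m = resp  # the weights the M-step parameters maximize

            Sigmas = np.empty((K, p, p))
            Omega_new: list[np.ndarray] = []
            graphs_changed = False
            ll_parts = np.empty((n, K))
            for k in range(K):
                Xc = X - mu[k]
                Sk = (Xc * resp[:, [k]]).T @ Xc / nk[k]
                Sk = (Sk + Sk.T) / 2.0
                try:
                    if searching:
                        if cfg.search_strategy == "exhaustive":
                            g_new = structure_search(Sk, nk[k], cfg)
                            Sig_k, Om_k = _fit_graph(
                                Sk, g_new, cfg.mle_tol, cfg.mle_max_sweeps
                            )
                        else:
                            g_new, Sig_k, Om_k = _greedy_search(
                                Sk, nk[k], cfg, start=graphs[k]
                            )
                        graphs_changed |= g_new != graphs[k]
                        graphs[k] = g_new
                    else:
                        Sig_k, Om_k = _fit_graph(
                            Sk,
                            graphs[k],
                            cfg.mle_tol,
                            cfg.mle_max_sweeps,
                            init_precision=Omegas[k],
                        )
                except NotPositiveDefiniteError as err:
                    raise GGMMFitError(
                        FailureRecord(K, "not_positive_definite", str(err))
                    ) from err
                if float(np.linalg.eigvalsh(Sig_k).min()) <= _MIN_EIG:
                    raise GGMMFitError(
                        FailureRecord(
                            K,
                            "not_positive_definite",
                            f"component {k} covariance eigenvalue <= {_MIN_EIG}",
                        )
                    )
                Sigmas[k] = Sig_k
                Omega_new.append(Om_k)
                ll_parts[:, k] = np.log(tau[k]) + _log_mvn_density(X, mu[k], Sig_k)
            Omegas = Omega_new

            row_ll = logsumexp(ll_parts, axis=1)
            ll = float(row_ll.sum())
            resp = np.exp(ll_parts - row_ll[:, None])
            penalty = sum(
                (1.0 + self.beta) * 0.5 * np.log(nk[k]) * graphs[k].n_edges
                for k in range(K)
            )
            pll = ll - penalty
            history.append(
                {
                    "iteration": it,
                    "loglik": ll,
                    "penalized_loglik": pll,
                    "searched": searching,
                    "graphs_changed": graphs_changed,
                }
            )

            small_change = (
                np.isfinite(prev_pll)
                and abs(pll - prev_pll) < self.tol * abs(prev_pll)
            )
            searched = searching
            if searched and not graphs_changed and fixed is None:
                searching = False  # structure stable: cheap parametric EM phase
            if small_change:
                if fixed is not None or (searched and not graphs_changed):
                    converged = True
                    break
                if not searched:
                    searching = True  # converged at fixed graphs: confirm structure
                # searched but structure still moving: keep iterating
            prev_pll = pll

        return {
            "tau": tau,
            "mu": mu,
            "Sigma": Sigmas,
            "Omega": np.array(Omegas),
            "graphs": list(graphs),
            "ll": ll,
            "pll": pll,
            "resp": resp,
            "mstep_resp": resp_m,
            "n_iter": it,
            "converged": converged,
            "history": history,
        }

    def _count_parameters(self) -> int:
        K, p = self.means_.shape
        return (K - 1) + K * p + sum(p + g.n_edges for g in self.graphs_)

    # ------------------------------------------------------------------
    @property
    def components_(self) -> list[ComponentParams]:
        return [
            ComponentParams(self.means_[k], self.covariances_[k], self.graphs_[k])
            for k in range(self.n_components)
        ]

    def _check_fitted(self) -> None:
        if not hasattr(self, "means_"):
            raise RuntimeError("model is not fitted")

    def _log_resp(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        self._check_fitted()
        if isinstance(X, DataMatrix):
            X_arr = X.values
        elif isinstance(X, pd.DataFrame):
            X_arr = X.to_numpy(dtype=float)
        else:
            X_arr = np.atleast_2d(np.asarray(X, dtype=float))
        if X_arr.ndim != 2 or X_arr.shape[1] != self.n_features_in_:
            raise ValueError("X has the wrong number of variables")
        K = self.weights_.size
        parts = np.empty((X_arr.shape[0], K))
        for k in range(K):
            parts[:, k] = np.log(self.weights_[k]) + _log_mvn_density(
                X_arr, self.means_[k], self.covariances_[k]
            )
        row_ll = logsumexp(parts, axis=1)
        return parts, row_ll

    def predict_proba(self, X) -> np.ndarray:
        parts, row_ll = self._log_resp(X)
        if not np.all(np.isfinite(row_ll)):
            raise FloatingPointError("density underflow: degenerate responsibilities")
        return np.exp(parts - row_ll[:, None])

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def score_samples(self, X) -> np.ndarray:
        return self._log_resp(X)[1]

    def score(self, X, y=None) -> float:
        return float(self.score_samples(X).mean())

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


# ----------------------------------------------------------------------
# Operation-level wrappers


def e_step(data, model: GraphicalGaussianMixture) -> np.ndarray:
    """Responsibility matrix: row r, column k = tau_k Phi(x_r) normalized
    over components (computed in log space; each row sums to 1)."""
    return model.predict_proba(as_matrix(data)[0])


def fit_ggmm(
    data, K: int, config: FitConfig | None = None
) -> GraphicalGaussianMixture:
    """Fit a K-component GGMM by structural EM; raises GGMMFitError with a
    FailureRecord when the fit degenerates."""
    config = config or FitConfig()
    model = GraphicalGaussianMixture(
        n_components=K,
        beta=config.beta,
        tol=config.tolerance,
        max_iter=config.max_iterations,
        n_init=config.n_restarts,
        search_strategy=config.search_strategy,
        mle_tol=config.mle_tol,
        mle_max_sweeps=config.mle_max_sweeps,
        random_state=config.seed,
    )
    return model.fit(data)


def model_bic(model: GraphicalGaussianMixture, n: int) -> float:
    """BIC = -2 log L + n_params log n (lower is better)."""
    model._check_fitted()
    return float(-2.0 * model.log_likelihood_ + model.n_parameters_ * np.log(n))


def select_model(
    data,
    K_range: Sequence[int],
    config: FitConfig | None = None,
) -> tuple[GraphicalGaussianMixture, list[FailureRecord]]:
    """Fit every K in ``K_range``; return the minimum-BIC fit among the
    component counts that fit successfully, plus the failure records of
    those that did not (e.g., a covariance turning not positive definite
    at too-large K)."""
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    if K_range != sorted(K_range):
        raise ValueError("K_range must be ascending")
    config = config or FitConfig()
    failures: list[FailureRecord] = []
    best: GraphicalGaussianMixture | None = None
    for K in K_range:
        try:
            model = fit_ggmm(data, K, config)
        except GGMMFitError as err:
            failures.append(err.failure)
            continue
        if best is None or model.bic_ < best.bic_:
            best = model
    if best is None:
        raise NoValidModelError(
            "no component count produced a valid fit: "
            + "; ".join(f"K={f.K}: {f.reason}" for f in failures)
        )
    return best, failures


def classify(model: GraphicalGaussianMixture, data) -> np.ndarray:
    """MAP cluster labels (0-based); ties go to the lowest component index."""
    return model.predict(as_matrix(data)[0])


def crosstab(labels: Iterable, groups: Iterable) -> pd.DataFrame:
    """Cluster-by-group contingency table with row/column totals.

    Rows are groups (e.g., diagnostic labels), columns cluster labels;
    margins are named 'Total' and the grand total equals len(labels).
    """
    labels = pd.Series(list(labels), name="cluster")
    groups = pd.Series(list(groups), name="group")
    if len(labels) != len(groups):
        raise ValueError("labels and groups must have equal length")
    return pd.crosstab(groups, labels, margins=True, margins_name="Total")


def component_covariance_network(
    model: GraphicalGaussianMixture, k: int
) -> WeightedNetwork:
    """Covariance network of component ``k`` (0-based): weight(i, j) is the
    fitted covariance where (i, j) is a graph edge, zero elsewhere."""
    model._check_fitted()
    if not 0 <= k < model.n_components:
        raise IndexError(f"component index {k} out of range 0..{model.n_components - 1}")
    W = np.where(model.graphs_[k].adjacency(), model.covariances_[k], 0.0)
    np.fill_diagonal(W, 0.0)
    return WeightedNetwork((W + W.T) / 2.0, model.variable_names_, scale="covariance")
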