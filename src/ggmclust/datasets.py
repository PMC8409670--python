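"""Synthetic graph-structured Gaussian mixture data with known truth.

Every other module is testable against data from this one: random sparse
graphs, precision matrices exactly supported on them, mixture sampling
with ground-truth labels, and a 12-variable 4-cluster fixture that
emulates the structure of a transdiagnostic symptom-score dataset
(depression, panic, social anxiety and obsessive-compulsive factor
scores). All numeric profiles in the fixture are invented package
constants chosen for clear recoverability, not estimates of any real
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .datatypes import DataMatrix
from .graphs import GraphStructure


def random_graph(p: int, density: float, seed: int) -> GraphStructure:
    """Erdos-Renyi graph: each of the p(p-1)/2 edges present independently
    with probability ``density``; deterministic per seed."""
    if p < 2:
        raise ValueError("need p >= 2")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = list(combinations(range(p), 2))
    keep = rng.random(len(pairs)) < density
    return GraphStructure.from_edges(p, [e for e, k in zip(pairs, keep) if k])


def graph_constrained_precision(
    graph: GraphStructure,
    weight_range: tuple[float, float] = (0.2, 0.6),
    seed: int = 0,
) -> np.ndarray:
    """Random precision matrix exactly supported on ``graph``.

    Off-graph entries are exactly zero; edge entries draw magnitudes from
    ``weight_range`` with random signs; each diagonal entry is set to its
    row's absolute off-diagonal sum plus a 0.1 margin, so the matrix is
    strictly diagonally dominant and hence positive definite.
    """
    lo, hi = weight_range
    if not 0 < lo <= hi:
        raise ValueError("weight_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    p = graph.p
    K = np.zeros((p, p))
    for i, j in graph.edge_list():
        w = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        K[i, j] = K[j, i] = w
    np.fill_diagonal(K, np.abs(K).sum(axis=1) + 0.1)
    return K


@dataclass
class TrueModel:
    """Ground-truth mixture: proportions, means, graphs and precisions
    (each exactly supported on its graph), plus an optional community map."""

    proportions: np.ndarray
    means: np.ndarray  # (K, p)
    graphs: list[GraphStructure]
    precisions: np.ndarray  # (K, p, p)
    variable_names: list[str] = field(default_factory=list)
    communities: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.precisions = np.asarray(self.precisions, dtype=float)
        K, p = self.means.shape
        if not np.isclose(self.proportions.sum(), 1.0, atol=1e-10):
            raise ValueError("proportions must sum to 1")
        if np.any(self.proportions <= 0):
            raise ValueError("proportions must be positive")
        if len(self.graphs) != K or self.precisions.shape != (K, p, p):
            raise ValueError("inconsistent component shapes")
        if not self.variable_names:
            self.variable_names = [f"V{i + 1}" for i in range(p)]
        for k in range(K):
            if float(np.linalg.eigvalsh(self.precisions[k]).min()) <= 0:
                raise ValueError(f"precision {k} is not positive definite")
            adj = self.graphs[k].adjacency()
            off = ~adj & ~np.eye(p, dtype=bool)
            if np.any(self.precisions[k][off] != 0.0):
                raise ValueError(f"precision {k} has mass off its graph")

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def p(self) -> int:
        return self.means.shape[1]

    @property
    def covariances(self) -> np.ndarray:
        return np.stack([np.linalg.inv(K_k) for K_k in self.precisions])


def sample_ggmm(
    model: TrueModel, n: int, seed: int
) -> tuple[DataMatrix, np.ndarray]:
    """Draw n rows: labels from the mixing proportions, then each row from
    its component's Gaussian. Deterministic per seed."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(model.K, size=n, p=model.proportions)
    covs = model.covariances
    X = np.empty((n, model.p))
    for k in range(model.K):
        idx = np.flatnonzero(labels == k)
        if idx.size:
            X[idx] = rng.multivariate_normal(
                model.means[k], covs[k], size=idx.size, method="cholesky"
            )
    if n == 1:  # a single row cannot satisfy DataMatrix invariants
        return X, labels
    return DataMatrix(X, list(model.variable_names)), labels


# ----------------------------------------------------------------------
# 12-variable, 4-cluster transdiagnostic fixture

_FIXTURE_VARIABLES = [
    "MDD1", "MDD2",            # cognitive/affective, somatic depression
    "PD1", "PD2", "PD3",       # physical, cognitive, social panic concerns
    "SAD",                     # fear of negative evaluation
    "OCD1", "OCD2", "OCD3", "OCD4", "OCD5", "OCD6",
]

_FIXTURE_COMMUNITIES = {
    "MDD1": "MDD", "MDD2": "MDD",
    "PD1": "PD", "PD2": "PD", "PD3": "PD",
    "SAD": "SAD",
    "OCD1": "OCD", "OCD2": "OCD", "OCD3": "OCD",
    "OCD4": "OCD", "OCD5": "OCD", "OCD6": "OCD",
}

# Severity levels (units: within-component SDs, variances are rescaled to
# 1). Adjacent levels are 3 SDs apart so every pair of component mean
# vectors is separated by at least 3 within-component SDs.
_WEAK, _MODERATE, _STRONG = 0.0, 3.0, 6.0

# Mean profiles: rows are components, in the order
#   0: strong OCD/PD, moderate MDD/SAD
#   1: moderate MDD/PD/SAD, weak OCD
#   2: weak everything
#   3: strong everything
_FIXTURE_LEVELS = {
    "MDD": [_MODERATE, _MODERATE, _WEAK, _STRONG],
    "PD": [_STRONG, _MODERATE, _WEAK, _STRONG],
    "SAD": [_MODERATE, _MODERATE, _WEAK, _STRONG],
    "OCD": [_STRONG, _WEAK, _WEAK, _STRONG],
}

# Mixing proportions mirror the published cluster shares (235, 357, 138,
# 791 of 1,521 patients).
_FIXTURE_PROPORTIONS = np.array([235, 357, 138, 791]) / 1521.0

_OCD_BLOCK = [
    (i, j)
    for i, j in combinations(range(12), 2)
    if _FIXTURE_VARIABLES[i].startswith("OCD") and _FIXTURE_VARIABLES[j].startswith("OCD")
]

# Per-component extra edges (beyond the always-present OCD clique); indices
# into _FIXTURE_VARIABLES. Invented to give each cluster a distinct topology.
_FIXTURE_EXTRA_EDGES = [
    [(0, 1), (2, 3), (3, 4), (4, 5)],                  # strong OCD/PD cluster
    [(0, 1), (0, 5), (2, 3), (2, 4), (3, 4), (5, 2)],  # moderate internalizing
    [(0, 1), (2, 3)],                                   # low-symptom cluster
    [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6)],  # strong-everything
]

_FIXTURE_EDGE_WEIGHT = -0.3  # negative precision entry -> positive association


def _fixture_precision(graph: GraphStructure) -> np.ndarray:
    p = graph.p
    K = np.zeros((p, p))
    for i, j in graph.edge_list():
        K[i, j] = K[j, i] = _FIXTURE_EDGE_WEIGHT
    np.fill_diagonal(K, np.abs(K).sum(axis=1) + 0.1)
    # rescale so implied variances are exactly 1 while zeros are preserved
    Sigma = np.linalg.inv(K)
    D = np.sqrt(np.diag(Sigma))
    K_std = K * np.outer(D, D)
    return (K_std + K_std.T) / 2.0


def true_fixture_model() -> TrueModel:
    """The generating model of :func:`psychopathology_fixture`."""
    p = len(_FIXTURE_VARIABLES)
    graphs = [
        GraphStructure.from_edges(p, _OCD_BLOCK + extra)
        for extra in _FIXTURE_EXTRA_EDGES
    ]
    means = np.array(
        [
            [
                _FIXTURE_LEVELS[_FIXTURE_COMMUNITIES[v]][k]
                for v in _FIXTURE_VARIABLES
            ]
            for k in range(4)
        ]
    )
    precisions = np.stack([_fixture_precision(g) for g in graphs])
    return TrueModel(
        proportions=_FIXTURE_PROPORTIONS.copy(),
        means=means,
        graphs=graphs,
        precisions=precisions,
        variable_names=list(_FIXTURE_VARIABLES),
        communities=dict(_FIXTURE_COMMUNITIES),
    )


def psychopathology_fixture(
    n: int = 1500, seed: int = 0
) -> tuple[DataMatrix, np.ndarray, TrueModel, dict[str, str]]:
    """Synthetic 12-variable, 4-cluster symptom-score dataset.

    Components mimic the qualitative cluster profiles of a comorbid
    depression/anxiety sample — one cluster strong on everything, one weak
    on everything, one strong on OCD/PD with moderate MDD/SAD, one
    moderate on MDD/PD/SAD with weak OCD — with the OCD variables mutually
    connected in every component's graph. Returns (data, true labels,
    generating model, community map).
    """
    model = true_fixture_model()
    data, labels = sample_ggmm(model, n, seed)
    return data, labels, model, dict(_FIXTURE_COMMUNITIES)
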