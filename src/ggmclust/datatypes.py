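"""In-memory containers: data matrices, fitted components, weighted networks.

The package works on subjects-by-variables matrices of continuous scores
(e.g., symptom factor scores). Pandas DataFrames are accepted everywhere a
:class:`DataMatrix` is; the class mainly enforces the invariants fitting
relies on (no missing values, non-constant columns).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import MissingCommunityError, NotPositiveDefiniteError
from .graphs import GraphStructure


@dataclass
class DataMatrix:
    """Subjects x variables matrix with unique variable names.

    Invariants: finite entries only, n >= 2 rows, p >= 2 columns, every
    column has nonzero sample variance.
    """

    values: np.ndarray
    variable_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.variable_names = [str(v) for v in self.variable_names]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValueError(f"need at least 2 rows and 2 columns, got {n} x {p}")
        if len(self.variable_names) != p:
            raise ValueError("variable_names length must match the column count")
        if len(set(self.variable_names)) != p:
            raise ValueError("variable names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain missing or non-finite entries")
        var = self.values.var(axis=0)
        if np.any(var <= 0):
            dead = [self.variable_names[i] for i in np.flatnonzero(var <= 0)]
            raise ValueError(f"columns with zero variance: {dead}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DataMatrix":
        return cls(df.to_numpy(dtype=float), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.variable_names)


def as_matrix(data) -> tuple[np.ndarray, list[str]]:
    """Coerce DataMatrix / DataFrame / array-like to (values, names)."""
    if isinstance(data, DataMatrix):
        return data.values, list(data.variable_names)
    if isinstance(data, pd.DataFrame):
        dm = DataMatrix.from_dataframe(data)
        return dm.values, dm.variable_names
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D data matrix")
    names = [f"V{i + 1}" for i in range(arr.shape[1])]
    return arr, names


@dataclass
class ComponentParams:
    """One mixture component: mean, graph-constrained covariance, graph.

    The covariance must be positive definite and its inverse must vanish
    (within ``precision_tol``) at every variable pair absent from the graph.
    """

    mean: np.ndarray
    covariance: np.ndarray
    graph: GraphStructure
    precision_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.covariance = np.asarray(self.covariance, dtype=float)
        p = self.mean.size
        if self.covariance.shape != (p, p):
            raise ValueError("covariance shape does not match mean")
        if self.graph.p != p:
            raise ValueError("graph node count does not match mean")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        eigmin = float(np.linalg.eigvalsh(self.covariance).min())
        if eigmin <= 1e-8:
            raise NotPositiveDefiniteError(
                f"covariance min eigenvalue {eigmin:.3e} <= 1e-8"
            )
        omega = self.precision
        adj = self.graph.adjacency()
        off = ~adj & ~np.eye(p, dtype=bool)
        worst = float(np.abs(omega[off]).max()) if off.any() else 0.0
        if worst >= self.precision_tol:
            raise ValueError(
                f"precision magnitude {worst:.3e} off the graph (tol {self.precision_tol})"
            )

    @property
    def p(self) -> int:
        return self.mean.size

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.covariance)


@dataclass
class WeightedNetwork:
    """Symmetric signed edge-weight matrix over named variables.

    ``scale`` records whether weights are covariances (the mixture's
    per-cluster networks) or regularized partial correlations.
    """

    weights: np.ndarray
    variable_names: list[str]
    scale: str = "covariance"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        p = self.weights.shape[0]
        if self.weights.shape != (p, p):
            raise ValueError("weights must be square")
        if len(self.variable_names) != p:
            raise ValueError("variable_names length must match weights")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weights must be symmetric within 1e-12")
        if np.any(np.abs(np.diag(self.weights)) > 1e-12):
            raise ValueError("diagonal must be zero")
        np.fill_diagonal(self.weights, 0.0)
        if self.scale not in ("covariance", "partial_correlation"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "partial_correlation" and np.any(np.abs(self.weights) > 1 + 1e-10):
            raise ValueError("partial correlations must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def edge_dataframe(self) -> pd.DataFrame:
        """Nonzero upper-triangle edges as (node_i, node_j, weight) rows."""
        rows = []
        p = self.p
        for i in range(p):
            for j in range(i + 1, p):
                w = self.weights[i, j]
                if w != 0.0:
                    rows.append((self.variable_names[i], self.variable_names[j], w))
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=self.variable_names, columns=self.variable_names
        )


def check_communities(
    net: WeightedNetwork, communities: Mapping[str, str]
) -> np.ndarray:
    """Community label per node, in node order; every node must be mapped."""
    missing = [v for v in net.variable_names if v not in communities]
    if missing:
        raise MissingCommunityError(f"nodes without a community: {missing}")
    return np.asarray([communities[v] for v in net.variable_names], dtype=object)
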