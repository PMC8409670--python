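"""Undirected simple graphs over the variables of a model.

A :class:`GraphStructure` is the sparsity pattern of one mixture
component's precision matrix: nodes are variables, an edge (i, j) means
the partial covariance of i and j given the rest is unrestricted, and a
missing edge forces the corresponding precision entry to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

Edge = tuple[int, int]


def _normalize_edge(i: int, j: int) -> Edge:
    if i == j:
        raise ValueError(f"self-loop ({i}, {i}) is not a valid edge")
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class GraphStructure:
    """Undirected simple graph on ``p`` nodes, edges as unordered pairs."""

    p: int
    edges: frozenset[Edge] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("graph needs at least one node")
        norm = frozenset(_normalize_edge(i, j) for i, j in self.edges)
        object.__setattr__(self, "edges", norm)
        for i, j in norm:
            if not (0 <= i < self.p and 0 <= j < self.p):
                raise ValueError(f"edge ({i}, {j}) outside 0..{self.p - 1}")

    # -- constructors -------------------------------------------------
    @classmethod
    def empty(cls, p: int) -> "GraphStructure":
        return cls(p, frozenset())

    @classmethod
    def complete(cls, p: int) -> "GraphStructure":
        return cls(p, frozenset(combinations(range(p), 2)))

    @classmethod
    def from_edges(cls, p: int, edges: Iterable[tuple[int, int]]) -> "GraphStructure":
        return cls(p, frozenset(_normalize_edge(i, j) for i, j in edges))

    @classmethod
    def from_adjacency(cls, adj: np.ndarray) -> "GraphStructure":
        adj = np.asarray(adj)
        p = adj.shape[0]
        edges = {(i, j) for i, j in combinations(range(p), 2) if adj[i, j]}
        return cls(p, frozenset(edges))

    # -- views --------------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def is_complete(self) -> bool:
        return self.n_edges == self.p * (self.p - 1) // 2

    def edge_list(self) -> list[Edge]:
        """Edges sorted lexicographically (the package's canonical order)."""
        return sorted(self.edges)

    def adjacency(self) -> np.ndarray:
        adj = np.zeros((self.p, self.p), dtype=bool)
        for i, j in self.edges:
            adj[i, j] = adj[j, i] = True
        return adj

    def has_edge(self, i: int, j: int) -> bool:
        return _normalize_edge(i, j) in self.edges

    # -- edits (return new graphs; instances are immutable) -----------
    def with_edge(self, i: int, j: int) -> "GraphStructure":
        return GraphStructure(self.p, self.edges | {_normalize_edge(i, j)})

    def without_edge(self, i: int, j: int) -> "GraphStructure":
        return GraphStructure(self.p, self.edges - {_normalize_edge(i, j)})

    def toggled(self, i: int, j: int) -> "GraphStructure":
        e = _normalize_edge(i, j)
        if e in self.edges:
            return GraphStructure(self.p, self.edges - {e})
        return GraphStructure(self.p, self.edges | {e})

    def permuted(self, perm: Sequence[int]) -> "GraphStructure":
        """Relabel nodes: new node ``perm[i]`` is old node ``i``."""
        perm = list(perm)
        if sorted(perm) != list(range(self.p)):
            raise ValueError("perm must be a permutation of 0..p-1")
        return GraphStructure.from_edges(
            self.p, ((perm[i], perm[j]) for i, j in self.edges)
        )
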