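"""Configuration records shared by the fitting and network stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FitConfig:
    """Settings for structural-EM mixture fitting.

    beta is the extra weight on the per-edge structure penalty
    (1 + beta) * log(n_eff) / 2; beta = 0 gives the BIC-type penalty used
    throughout by default.
    """

    max_iterations: int = 500
    tolerance: float = 1e-6
    n_restarts: int = 10
    seed: int | None = None
    beta: float = 0.0
    search_strategy: str = "greedy_stepwise"
    mle_tol: float = 1e-8
    mle_max_sweeps: int = 10_000

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.search_strategy not in ("greedy_stepwise", "exhaustive"):
            raise ValueError(f"unknown search_strategy {self.search_strategy!r}")


@dataclass
class EBICConfig:
    """Settings for GLASSO + EBIC network selection.

    gamma weights the extra EBIC edge penalty 4 * gamma * |E| * log p;
    gamma = 0 reduces to plain BIC. The lambda grid is descending so that
    ties in EBIC resolve to the sparser (more penalized) fit.
    """

    gamma: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    lambda_grid: np.ndarray | None = None
    tol: float = 1e-7

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.size == 0 or np.any(grid <= 0):
                raise ValueError("lambda_grid must be non-empty and strictly positive")
            self.lambda_grid = np.sort(grid)[::-1]

    def grid_for(self, S: np.ndarray) -> np.ndarray:
        """Lambda grid for a sample covariance: explicit grid if given, else
        n_lambdas log-spaced values from max off-diagonal |S| down."""
        if self.lambda_grid is not None:
            return self.lambda_grid
        off = np.abs(S - np.diag(np.diag(S)))
        lam_max = float(off.max())
        if lam_max <= 0:  # already diagonal; any positive lambda keeps it so
            lam_max = 1.0
        return np.geomspace(lam_max, self.lambda_min_ratio * lam_max, self.n_lambdas)
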