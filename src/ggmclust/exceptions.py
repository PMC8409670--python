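"""Typed errors raised across the package."""

from __future__ import annotations

from dataclasses import dataclass


class GGMClustError(Exception):
    """Base class for all package-specific errors."""


class NotPositiveDefiniteError(GGMClustError):
    """A covariance/precision matrix is not positive definite."""


class NoConvergenceError(GGMClustError):
    """An iterative fit exhausted its sweep/iteration budget."""


class InvalidPrecisionError(GGMClustError):
    """A precision matrix has a non-positive diagonal entry."""


class DegenerateValuesError(GGMClustError):
    """An operation received constant input where variation is required."""


class MissingCommunityError(GGMClustError):
    """A network node has no community assignment."""


class MissingDataError(GGMClustError):
    """Input table contains missing cells; locations are in the message."""


class ParseError(GGMClustError):
    """Input table contains non-numeric cells."""


class EmptyClusterError(GGMClustError):
    """A network was requested for a cluster with no members."""


class NoValidModelError(GGMClustError):
    """Every candidate number of clusters failed to fit."""


@dataclass(frozen=True)
class FailureRecord:
    """Why fitting a mixture with ``K`` components was aborted.

    ``reason`` is one of ``not_positive_definite`` (a component covariance
    lost positive definiteness, the failure mode model selection must
    survive), ``empty_component`` (a component's responsibility mass fell
    below p + 1 observations) or ``no_convergence``.
    """

    K: int
    reason: str
    detail: str = ""

    _REASONS = ("not_positive_definite", "empty_component", "no_convergence")

    def __post_init__(self) -> None:
        if self.reason not in self._REASONS:
            raise ValueError(f"unknown failure reason {self.reason!r}")


class GGMMFitError(GGMClustError):
    """Fitting at a fixed K aborted; carries the typed :class:`FailureRecord`."""

    def __init__(self, failure: FailureRecord):
        self.failure = failure
        super().__init__(f"K={failure.K}: {failure.reason} ({failure.detail})")
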