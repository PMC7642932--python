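"""Shared domain types.

The user-facing parameter frame is ``(n, m, theta)``: *n* sequences, *m*
distinct alleles observed, and theta the scaled mutation rate (in practice
the average pairwise nucleotide difference, theta-pi). The asymptotic
machinery internally shifts to a "theorem frame" ``(n-1, m-1)``; that shift
is confined to :mod:`fufs.asymptotic` and never leaks into these types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional

__all__ = ["ProblemParams", "FsResult", "SaddleSystem", "AlignmentSummary"]


@dataclass(frozen=True)
class ProblemParams:
    """One evaluation point of the allele-count tail statistic.

    Parameters
    ----------
    n : int
        Sample size (number of sequences), ``n >= 1``.
    m : int
        Observed number of distinct alleles, ``1 <= m <= n``.
    theta : float
        Positive scaled mutation rate (average pairwise difference).
    """

    n: int
    m: int
    theta: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 1 <= self.m <= self.n:
            raise ValueError(f"m must satisfy 1 <= m <= n={self.n}, got {self.m}")
        if not (self.theta > 0) or not math.isfinite(self.theta):
            raise ValueError(f"theta must be positive and finite, got {self.theta}")


@dataclass
class SaddleSystem:
    """Theorem-frame quantities for one asymptotic evaluation.

    ``n_prime = n - 1`` and ``m_prime = m - 1`` relative to the user frame.
    ``z0`` is the positive saddle point of phi, ``t0 = m'/(n'-m')`` the
    minimum of chi, ``tau`` the matched point with
    ``chi(tau) - chi(t0) = phi(theta) - phi(z0)`` on the branch fixed by
    ``sign(theta - z0) = sign(tau - t0)``, and ``x = tau/(1+tau)`` the
    incomplete-beta argument.
    """

    n_prime: int
    m_prime: int
    theta: float
    z0: float
    t0: float
    tau: float
    x: float
    residual_z0: float = 0.0
    residual_tau: float = 0.0


@dataclass
class FsResult:
    """S', T' and Fs for one evaluation, plus branch/method diagnostics.

    Exactly one of ``s_prime``/``t_prime`` is computed directly (the one
    the branch rule deems numerically safe); the other is its complement,
    so ``s_prime + t_prime == 1`` holds by construction. ``fs`` itself is
    always formed cancellation-free in log space and may be ``+inf`` at
    the degenerate ``m == 1``.
    """

    s_prime: float
    t_prime: float
    fs: float
    branch: str  # "S-branch" | "T-branch" | "closed-form"
    method: str  # "exact" | "asymptotic"
    diagnostics: Optional[dict[str, Any]] = field(default=None, repr=False)


@dataclass(frozen=True)
class AlignmentSummary:
    """(n, L, m, theta_pi) derived from an aligned set of sequences."""

    n: int
    L: int
    m: int
    theta_pi: float
    denominator_convention: str = "paper"
    comparison_policy: str = "pairwise-deletion"

    def params(self) -> ProblemParams:
        """The (n, m, theta_pi) triple as statistic inputs."""
        return ProblemParams(self.n, self.m, self.theta_pi)
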