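"""Exact, overflow-free evaluation of the allele-count tail distribution.

Under the neutral infinite-alleles model (Ewens sampling formula) the
probability that a sample of ``n`` sequences with scaled mutation rate
``theta`` contains at least ``m`` distinct alleles is

    S'_{n,m}(theta) = (1/(theta)_n) * sum_{k=m}^{n} c(n,k) theta^k,

where ``(theta)_n`` is the rising factorial and ``c(n,k)`` the unsigned
Stirling number of the first kind (the signed number is
``(-1)^(n-k) c(n,k)``; all addends above are nonnegative). Fu's Fs is the
logit ``ln(S'/(1-S'))``.

Stirling numbers overflow doubles already for ``n`` in the low hundreds,
so every mass here lives in natural-log space: a single row of
``ln c(n,k)`` is built by the magnitude recurrence

    c(n+1,k) = c(n,k-1) + n c(n,k)

via ``logaddexp``, and S', T' = 1 - S' and Fs are ratios/differences of
partial log-sum-exps over the same term set, which makes them
cancellation-free and normalizer-free (the Pochhammer factor cancels).
This module is the exact oracle against which the asymptotic estimator in
:mod:`fufs.asymptotic` is validated.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Union

import numpy as np
from scipy.special import gammaln, logsumexp

from .params import FsResult, ProblemParams

__all__ = [
    "MAX_EXACT_N",
    "log_unsigned_stirling_row",
    "unsigned_stirling_row_int",
    "signed_stirling_integer",
    "log_pochhammer_ratio",
    "log_pochhammer_ratio_recursive",
    "sprime_exact",
    "tprime_exact",
    "fs_exact",
    "sprime_rational",
]

#: Practical ceiling for the O(n^2) row recurrence; beyond this the oracle
#: refuses rather than silently taking minutes.
MAX_EXACT_N = 20_000

# Row memo: the O(n^2) build cost is paid once per n, then every (m, theta)
# evaluation at the same n is O(n). Keep a handful of rows only.
_ROW_CACHE: dict[int, np.ndarray] = {}
_ROW_CACHE_SLOTS = 8


def log_unsigned_stirling_row(n: int) -> np.ndarray:
    """Row ``n`` of unsigned Stirling numbers of the first kind, as logs.

    Returns a read-only array ``row`` of length ``n + 1`` with
    ``row[k] = ln c(n, k)``; ``row[0] = -inf`` for ``n >= 1``. Built
    iteratively from row 1, keeping one row in memory.

    >>> row = log_unsigned_stirling_row(10)
    >>> round(float(np.exp(row[5])))
    269325
    """
    if n < 1:
        raise ValueError(f"row index must be >= 1, got {n}")
    if n > MAX_EXACT_N:
        raise ValueError(
            f"n={n} exceeds the exact-oracle ceiling of {MAX_EXACT_N}; "
            "use the asymptotic estimator instead"
        )
    cached = _ROW_CACHE.get(n)
    if cached is not None:
        return cached

    row = np.array([-np.inf, 0.0])  # c(1,0)=0, c(1,1)=1
    for r in range(1, n):
        nxt = np.empty(r + 2)
        nxt[0] = -np.inf
        # c(r+1, k) = c(r, k-1) + r * c(r, k) for k = 1 .. r+1
        with_tail = np.append(row[1:], -np.inf)  # c(r,k), k = 1 .. r+1
        nxt[1:] = np.logaddexp(row, math.log(r) + with_tail)
        row = nxt
    row.setflags(write=False)
    if len(_ROW_CACHE) >= _ROW_CACHE_SLOTS:
        _ROW_CACHE.pop(next(iter(_ROW_CACHE)))
    _ROW_CACHE[n] = row
    return row


def unsigned_stirling_row_int(n: int) -> list[int]:
    """Row ``n`` of unsigned Stirling numbers as exact Python integers.

    Test oracle path (arbitrary precision, no rounding); intended for
    moderate ``n`` — the integers have ~``n log n`` digits.
    """
    if n < 1:
        raise ValueError(f"row index must be >= 1, got {n}")
    if n > 2000:
        raise ValueError(f"integer oracle limited to n <= 2000, got {n}")
    row = [0, 1]
    for r in range(1, n):
        nxt = [0] * (r + 2)
        for k in range(1, r + 2):
            nxt[k] = row[k - 1] + r * (row[k] if k <= r else 0)
        row = nxt
    return row


def signed_stirling_integer(n: int, k: int) -> int:
    """Exact signed Stirling number of the first kind, ``(-1)^(n-k) c(n,k)``.

    >>> signed_stirling_integer(10, 5)
    -269325
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, n={n}], got {k}")
    if n == 0:
        return 1  # S_0(0) = 1 (empty product)
    c = unsigned_stirling_row_int(n)[k]
    return c if (n - k) % 2 == 0 else -c


def log_pochhammer_ratio(theta: float, n: int) -> float:
    """``ln f_n(theta)`` where ``f_n(theta) = n! Gamma(theta) / Gamma(theta+n)``.

    The scaling ratio that controls overflow of the rising-factorial
    normalizer; satisfies ``f_0 = 1`` and ``f_n(theta) <= 1`` for
    ``theta >= 1``. Computed from log-gamma.
    """
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if n == 0:
        return 0.0
    return float(gammaln(n + 1) + gammaln(theta) - gammaln(theta + n))


def log_pochhammer_ratio_recursive(theta: float, n: int) -> float:
    """Cross-check path for :func:`log_pochhammer_ratio`.

    Applies the step ``f_{n+1} = (n+1)/(n+theta) f_n`` in log space.
    """
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    acc = 0.0
    for r in range(n):
        acc += math.log((r + 1) / (r + theta))
    return acc


def _partial_log_masses(p: ProblemParams) -> tuple[float, float]:
    """(LSE of terms k >= m, LSE of terms k < m) of ``ln c(n,k) + k ln theta``."""
    row = log_unsigned_stirling_row(p.n)
    ell = row + np.arange(p.n + 1) * math.log(p.theta)
    lse_hi = float(logsumexp(ell[p.m :]))
    lo = ell[: p.m]
    # k = 0 contributes nothing (c(n,0) = 0); m = 1 leaves an empty mass
    lse_lo = float(logsumexp(lo)) if p.m > 1 else -math.inf
    return lse_hi, lse_lo


def _as_params(p: Union[ProblemParams, tuple], m=None, theta=None) -> ProblemParams:
    if isinstance(p, ProblemParams):
        return p
    if m is not None:  # (n, m, theta) convenience signature
        return ProblemParams(int(p), int(m), float(theta))
    return ProblemParams(*p)


def sprime_exact(p: Union[ProblemParams, tuple], m=None, theta=None) -> float:
    """Probability of observing at least ``m`` alleles, exactly.

    Accepts a :class:`ProblemParams` or the triple ``(n, m, theta)``.

    >>> sprime_exact(3, 3, 2.0)  # 2^3 / (2*3*4)
    0.333333333333...
    """
    p = _as_params(p, m, theta)
    lse_hi, lse_lo = _partial_log_masses(p)
    return float(np.exp(lse_hi - np.logaddexp(lse_hi, lse_lo)))


def tprime_exact(p: Union[ProblemParams, tuple], m=None, theta=None) -> float:
    """Complement probability (fewer than ``m`` alleles), from its own sum.

    Computed directly from the ``k < m`` partial log-sum-exp rather than as
    ``1 - S'``, so it keeps full relative accuracy when ``S'`` is close to 1.
    """
    p = _as_params(p, m, theta)
    lse_hi, lse_lo = _partial_log_masses(p)
    return float(np.exp(lse_lo - np.logaddexp(lse_hi, lse_lo)))


def fs_exact(p: Union[ProblemParams, tuple], m=None, theta=None) -> FsResult:
    """Fu's Fs by the exact log-space oracle.

    ``Fs = ln(S'/T')`` is the difference of the two partial log-sum-exps,
    so neither branch of the logit ever subtracts nearly equal numbers.
    The stored probability is the smaller (directly computed) tail; at the
    degenerate ``m == 1`` the statistic is ``+inf`` with a closed-form flag.
    """
    p = _as_params(p, m, theta)
    if p.m == 1:
        return FsResult(1.0, 0.0, math.inf, branch="closed-form", method="exact")
    lse_hi, lse_lo = _partial_log_masses(p)
    lse_all = np.logaddexp(lse_hi, lse_lo)
    fs = lse_hi - lse_lo
    # S' >= 0.5 (mass at/above m dominates): store T' directly, T-branch.
    if lse_hi >= lse_lo:
        t = float(np.exp(lse_lo - lse_all))
        return FsResult(1.0 - t, t, float(fs), branch="T-branch", method="exact",
                        diagnostics={"lse_hi": lse_hi, "lse_lo": lse_lo})
    s = float(np.exp(lse_hi - lse_all))
    return FsResult(s, 1.0 - s, float(fs), branch="S-branch", method="exact",
                    diagnostics={"lse_hi": lse_hi, "lse_lo": lse_lo})


def sprime_rational(n: int, m: int, theta: Fraction) -> Fraction:
    """S' by exact rational arithmetic over the integer Stirling row.

    Independent oracle for the log-space path; ``theta`` must be a
    :class:`fractions.Fraction` so the result is exact.
    """
    if not isinstance(theta, Fraction):
        raise TypeError("theta must be a Fraction for the rational oracle")
    if not 1 <= m <= n:
        raise ValueError(f"m must lie in [1, n={n}], got {m}")
    row = unsigned_stirling_row_int(n)
    powers = [theta**k for k in range(n + 1)]
    total = sum(row[k] * powers[k] for k in range(n + 1))
    upper = sum(row[k] * powers[k] for k in range(m, n + 1))
    return upper / total
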