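"""Single-evaluation asymptotic estimator for the allele-count tail.

Instead of summing up to ``n`` Stirling-number terms, the tail probability
S'_{n,m}(theta) is approximated in one shot by a regularized incomplete
beta function plus a first-order correction, derived from a saddle-point
analysis of its contour-integral representation. With the index shift
``n' = n - 1``, ``m' = m - 1``:

    S'_{n,m}(theta) ~ I_x(m', n'-m'+1) + e^{-chi(tau)} C(n', m'-1) g(t0),
    x = tau / (1 + tau),

where

    phi(z) = lnGamma(z+n'+1) - lnGamma(z+1) - m' ln z,
    chi(t) = n' ln(1+t) - m' ln t,          t0 = m'/(n'-m'),

``z0`` is the positive root of ``phi'`` (the saddle point, also the value
of theta at which S' crosses 1/2), ``tau`` solves
``chi(tau) = chi(t0) + phi(theta) - phi(z0)`` on the branch with
``sign(theta - z0) = sign(tau - t0)``, and

    g(t0) = f(t0) - 1/(t0 - tau),
    f(t0) = sqrt(chi''(t0) / phi''(z0)) / (z0 - theta).

For ``theta < z0`` the S' form above is used with ``Fs = ln(S'/(1-S'))``;
for ``theta > z0`` the complementary ``T'`` form
``I_{1-x}(n'-m'+1, m') - R'`` with ``Fs = ln((1-T')/T')``. Probabilities
are assembled in log space throughout, so the estimator stays usable when
|Fs| exceeds the ~709 ceiling of a double-precision probability.
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import betainc, gammaln, logsumexp, polygamma, psi

from .params import FsResult, ProblemParams, SaddleSystem
from . import stirling

__all__ = [
    "phi", "phi_prime", "phi_second",
    "chi", "chi_prime", "chi_second",
    "solve_saddle_z0", "solve_tau", "build_saddle_system",
    "log_main_term", "main_term", "correction_term",
    "fs_asymptotic", "fs_auto",
]

#: |tau - t0| below this (relative to max(t0, 1)) counts as "at the
#: transition", where g(t0) is a difference of two diverging terms.
NEAR_TRANSITION_RTOL = 1e-4

#: Default n below which the convenience auto dispatcher prefers the oracle.
AUTO_EXACT_THRESHOLD = 50

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


# -- the two phase functions ------------------------------------------------

def phi(z: float, n: int, m: int) -> float:
    """``lnGamma(z+n+1) - lnGamma(z+1) - m ln z`` for ``z > 0``."""
    if not z > 0:
        raise ValueError(f"z must be positive, got {z}")
    return float(gammaln(z + n + 1) - gammaln(z + 1) - m * math.log(z))


def phi_prime(z: float, n: int, m: int) -> float:
    """``psi(z+n+1) - psi(z+1) - m/z``; its positive zero is the saddle z0."""
    if not z > 0:
        raise ValueError(f"z must be positive, got {z}")
    return float(psi(z + n + 1) - psi(z + 1) - m / z)


def phi_second(z: float, n: int, m: int) -> float:
    """``psi'(z+n+1) - psi'(z+1) + m/z^2`` (trigamma form)."""
    if not z > 0:
        raise ValueError(f"z must be positive, got {z}")
    return float(polygamma(1, z + n + 1) - polygamma(1, z + 1) + m / z**2)


def chi(t: float, n: int, m: int) -> float:
    """``n ln(1+t) - m ln t``; strictly convex on (0, inf) for 0 < m < n."""
    if not t > 0:
        raise ValueError(f"t must be positive, got {t}")
    return float(n * math.log1p(t) - m * math.log(t))


def chi_prime(t: float, n: int, m: int) -> float:
    """``((n-m) t - m) / (t (1+t))``; vanishes at ``t0 = m/(n-m)``."""
    if not t > 0:
        raise ValueError(f"t must be positive, got {t}")
    return float(((n - m) * t - m) / (t * (1.0 + t)))


def chi_second(t: float, n: int, m: int) -> float:
    """``-n/(1+t)^2 + m/t^2``; positive at t0."""
    if not t > 0:
        raise ValueError(f"t must be positive, got {t}")
    return float(-n / (1.0 + t) ** 2 + m / t**2)


# -- saddle and matching-point solvers --------------------------------------

def solve_saddle_z0(n: int, m: int) -> float:
    """Positive root of ``phi'(z) = psi(z+n+1) - psi(z+1) - m/z``.

    ``phi'`` runs from -inf at 0+ to 0+ at infinity and crosses zero once
    when ``0 < m < n``; bracketed Brent iteration makes the result
    deterministic for fixed (n, m).

    >>> round(solve_saddle_z0(100, 38), 2)
    22.81
    """
    if not 0 < m < n:
        raise ValueError(f"saddle point requires 0 < m < n, got m={m}, n={n}")
    f = lambda z: phi_prime(z, n, m)
    z_hi = float(max(m, 1))
    for _ in range(200):
        if f(z_hi) > 0:
            break
        z_hi *= 2.0
    else:  # pragma: no cover - phi' > 0 for z >~ m n always
        raise RuntimeError(f"failed to bracket saddle point for n={n}, m={m}")
    z_lo = min(1e-8, z_hi / 2)
    while f(z_lo) > 0:  # pragma: no cover - defensive
        z_lo /= 16.0
    z0 = brentq(f, z_lo, z_hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return float(z0)


def solve_tau(n: int, m: int, theta: float, z0: float) -> float:
    """Positive solution of ``chi(tau) = chi(t0) + phi(theta) - phi(z0)``.

    Two positive roots exist when ``theta != z0``; the branch with
    ``sign(tau - t0) = sign(theta - z0)`` is selected. ``theta == z0``
    gives ``tau = t0`` exactly.
    """
    if not 0 < m < n:
        raise ValueError(f"matching requires 0 < m < n, got m={m}, n={n}")
    t0 = m / (n - m)
    delta = phi(theta, n, m) - phi(z0, n, m)
    if delta < 0:
        if delta < -1e-9 * max(1.0, abs(phi(z0, n, m))):  # pragma: no cover
            raise RuntimeError(
                f"phi(theta) < phi(z0) by {delta}; saddle solve inconsistent"
            )
        delta = 0.0  # rounding at the minimum
    if delta == 0.0 or theta == z0:
        return t0
    target = chi(t0, n, m) + delta
    h = lambda t: chi(t, n, m) - target
    # local quadratic step as initial width
    w = math.sqrt(2.0 * delta / chi_second(t0, n, m))
    if theta < z0:  # branch (0, t0]
        t_lo = max(t0 - w, t0 * 0.5)
        for _ in range(2000):
            if h(t_lo) >= 0:
                break
            t_lo *= 0.5
        else:  # pragma: no cover
            raise RuntimeError(f"failed to bracket tau below t0 for n={n}, m={m}, theta={theta}")
        if t_lo == t0:
            return t0
        tau = brentq(h, t_lo, t0, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    else:  # branch [t0, inf)
        t_hi = t0 + w
        for _ in range(2000):
            if h(t_hi) >= 0:
                break
            t_hi = t0 + (t_hi - t0) * 2.0
        else:  # pragma: no cover
            raise RuntimeError(f"failed to bracket tau above t0 for n={n}, m={m}, theta={theta}")
        tau = brentq(h, t0, t_hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    return float(tau)


def build_saddle_system(n_prime: int, m_prime: int, theta: float) -> SaddleSystem:
    """Solve the saddle and matching equations in the theorem frame."""
    z0 = solve_saddle_z0(n_prime, m_prime)
    tau = solve_tau(n_prime, m_prime, theta, z0)
    t0 = m_prime / (n_prime - m_prime)
    target = chi(t0, n_prime, m_prime) + phi(theta, n_prime, m_prime) - phi(z0, n_prime, m_prime)
    return SaddleSystem(
        n_prime=n_prime,
        m_prime=m_prime,
        theta=theta,
        z0=z0,
        t0=t0,
        tau=tau,
        x=tau / (1.0 + tau),
        residual_z0=phi_prime(z0, n_prime, m_prime),
        residual_tau=chi(tau, n_prime, m_prime) - target,
    )


# -- estimator terms --------------------------------------------------------

def _log_binom_tail(n: int, lo: int, hi: int, tau: float) -> float:
    """``ln[(1+tau)^-n sum_{j=lo}^{hi} C(n,j) tau^j]`` by log-sum-exp.

    Finite-sum representation of the incomplete beta term; exact up to
    rounding, and valid far below double-precision underflow.
    """
    j = np.arange(lo, hi + 1)
    terms = gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1) + j * math.log(tau)
    return float(logsumexp(terms) - n * math.log1p(tau))


def log_main_term(s: SaddleSystem, branch: str) -> float:
    """Natural log of the incomplete-beta main term on the given branch.

    S-branch: ``ln I_x(m', n'-m'+1)``; T-branch: ``ln I_{1-x}(n'-m'+1, m')``
    with ``x = tau/(1+tau)``. Uses the regularized incomplete beta when the
    value is comfortably representable and the equivalent finite
    binomial-tail sum in log space otherwise.
    """
    n, m = s.n_prime, s.m_prime
    if branch == "S-branch":
        p = float(betainc(m, n - m + 1, s.x))
    elif branch == "T-branch":
        p = float(betainc(n - m + 1, m, 1.0 - s.x))
    else:
        raise ValueError(f"unknown branch {branch!r}")
    if p > 1e-250:
        return math.log(p)
    # underflow region: fall back to the exact finite sum
    if branch == "S-branch":
        return _log_binom_tail(n, m, n, s.tau)
    return _log_binom_tail(n, 0, m - 1, s.tau)


def main_term(s: SaddleSystem, branch: str = "S-branch") -> float:
    """Incomplete-beta main term as a probability in [0, 1]."""
    return math.exp(log_main_term(s, branch))


def correction_term(s: SaddleSystem) -> tuple[float, float]:
    """First-order correction ``R' = e^{-chi(tau)} C(n', m'-1) g(t0)``.

    Returned as ``(sign, log_magnitude)``; assembled entirely in log space
    so the huge binomial coefficient and the tiny exponential never meet
    as raw doubles. Requires ``tau != t0``; at the transition the caller
    must apply the fallback policy instead.
    """
    n, m = s.n_prime, s.m_prime
    if s.tau == s.t0:
        raise ValueError("correction term is singular at tau == t0 (theta == z0)")
    f_t0 = math.sqrt(chi_second(s.t0, n, m) / phi_second(s.z0, n, m)) / (s.z0 - s.theta)
    g_t0 = f_t0 - 1.0 / (s.t0 - s.tau)
    if g_t0 == 0.0:
        return 0.0, -math.inf
    log_binom = gammaln(n + 1) - gammaln(m) - gammaln(n - m + 2)  # C(n', m'-1)
    log_mag = -chi(s.tau, n, m) + float(log_binom) + math.log(abs(g_t0))
    return math.copysign(1.0, g_t0), log_mag


def _combine_log(log_a: float, sign_r: float, log_r: float) -> tuple[float, bool]:
    """``log(exp(log_a) + sign_r * exp(log_r))``; flags a nonpositive result."""
    if log_r == -math.inf:
        return log_a, False
    if sign_r > 0:
        return float(np.logaddexp(log_a, log_r)), False
    d = log_r - log_a
    if d >= 0:  # correction swamps the main term: clamp upstream
        return math.log(_P_FLOOR), True
    return log_a + math.log1p(-math.exp(d)), False


def _fs_from_log_tail(log_tail: float, branch: str) -> tuple[float, float, float, bool]:
    """(s_prime, t_prime, fs, clamped) from the log of the small tail."""
    clamped = False
    if log_tail > math.log(_P_CEIL):
        log_tail = math.log(_P_CEIL)
        clamped = True
    if log_tail == -math.inf:  # only from a degenerate combine
        log_tail = math.log(_P_FLOOR)
        clamped = True
    # logit of the small tail, cancellation-free; exp may underflow to 0.0
    # for |Fs| > ~709, in which case the logit is log_tail itself and only
    # the *reported probability* saturates, not Fs.
    tail = math.exp(log_tail)
    logit = log_tail - math.log1p(-tail)
    if branch == "S-branch":
        return tail, 1.0 - tail, logit, clamped
    return 1.0 - tail, tail, -logit, clamped


def fs_asymptotic(
    p: Union[ProblemParams, tuple],
    m=None,
    theta=None,
    *,
    near_transition_rtol: float = NEAR_TRANSITION_RTOL,
) -> FsResult:
    """Fu's Fs by the single-evaluation asymptotic estimator.

    Accepts a :class:`ProblemParams` or the triple ``(n, m, theta)`` in the
    user frame; the theorem-frame index shift ``(n-1, m-1)`` is applied
    here and nowhere else. Degenerate cases use closed forms: ``m == 1``
    gives ``Fs = +inf``; ``m == n`` gives the exact single-term
    ``S' = theta^n / (theta)_n`` in log space. Near the transition
    ``theta ~ z0`` the correction is singular and the implementation falls
    back to the exact oracle (or, beyond the oracle ceiling, to the main
    term alone); the ``diagnostics`` record says which.
    """
    p = stirling._as_params(p, m, theta)
    if p.m == 1:
        return FsResult(1.0, 0.0, math.inf, branch="closed-form", method="asymptotic")
    if p.m == p.n:
        log_s = p.n * math.log(p.theta) - float(
            gammaln(p.theta + p.n) - gammaln(p.theta)
        )
        s, t, fs, clamped = _fs_from_log_tail(log_s, "S-branch")
        return FsResult(s, t, fs, branch="closed-form", method="asymptotic",
                        diagnostics={"log_s": log_s, "clamped": clamped})

    sys = build_saddle_system(p.n - 1, p.m - 1, p.theta)
    diag: dict = {
        "z0": sys.z0, "t0": sys.t0, "tau": sys.tau, "x": sys.x,
        "residual_z0": sys.residual_z0, "residual_tau": sys.residual_tau,
        "fallback_used": None, "clamped": False,
    }

    if abs(sys.tau - sys.t0) < near_transition_rtol * max(sys.t0, 1.0):
        if p.n <= stirling.MAX_EXACT_N:
            res = stirling.fs_exact(p)
            diag["fallback_used"] = "exact-oracle"
            return FsResult(res.s_prime, res.t_prime, res.fs, branch=res.branch,
                            method="asymptotic", diagnostics=diag)
        diag["fallback_used"] = "main-term-only"
        branch = "S-branch" if p.theta < sys.z0 else "T-branch"
        log_main = log_main_term(sys, branch)
        s, t, fs, clamped = _fs_from_log_tail(log_main, branch)
        diag.update(log_main=log_main, clamped=clamped)
        return FsResult(s, t, fs, branch=branch, method="asymptotic", diagnostics=diag)

    branch = "S-branch" if p.theta < sys.z0 else "T-branch"
    log_main = log_main_term(sys, branch)
    sign_r, log_r = correction_term(sys)
    if branch == "T-branch":
        sign_r = -sign_r  # T' = I_{1-x} - R'
    log_tail, floored = _combine_log(log_main, sign_r, log_r)
    s, t, fs, clamped = _fs_from_log_tail(log_tail, branch)
    diag.update(
        log_main=log_main,
        correction_sign=sign_r,
        correction_log=log_r,
        clamped=clamped or floored,
    )
    return FsResult(s, t, fs, branch=branch, method="asymptotic", diagnostics=diag)


def fs_auto(
    p: Union[ProblemParams, tuple],
    m=None,
    theta=None,
    *,
    exact_below_n: int = AUTO_EXACT_THRESHOLD,
) -> FsResult:
    """Convenience dispatcher: exact oracle for small ``n``, asymptotic above.

    The estimator is already accurate at ``n = 25``, but the O(n^2) oracle
    is effectively free there; the crossover is configurable.
    """
    p = stirling._as_params(p, m, theta)
    if p.n < exact_below_n and p.n <= stirling.MAX_EXACT_N:
        return stirling.fs_exact(p)
    return fs_asymptotic(p)
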