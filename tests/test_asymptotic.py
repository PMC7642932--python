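"""Asymptotic estimator: phase functions, saddle solvers, beta term, Fs."""

import math

import numpy as np
import pytest
from scipy.special import betainc, comb

from fufs import fs_exact, mollified_error
from fufs.asymptotic import (
    build_saddle_system,
    chi,
    chi_prime,
    chi_second,
    correction_term,
    fs_asymptotic,
    fs_auto,
    log_main_term,
    main_term,
    phi,
    phi_prime,
    phi_second,
    solve_saddle_z0,
    solve_tau,
)
from fufs.params import ProblemParams


class TestPhaseFunctions:
    @pytest.mark.parametrize("z,n,m", [(5.0, 20, 7), (22.81, 100, 38), (0.3, 10, 2)])
    def test_phi_derivatives_match_central_differences(self, z, n, m):
        h = 1e-5 * max(z, 1.0)
        d1 = (phi(z + h, n, m) - phi(z - h, n, m)) / (2 * h)
        d2 = (phi_prime(z + h, n, m) - phi_prime(z - h, n, m)) / (2 * h)
        assert phi_prime(z, n, m) == pytest.approx(d1, rel=1e-6)
        assert phi_second(z, n, m) == pytest.approx(d2, rel=1e-6)

    def test_phi_monotone_when_m_zero(self):
        vals = [phi(z, 30, 0) for z in (0.5, 1.0, 2.0, 5.0, 20.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_chi_minimum_and_convexity(self):
        n, m = 100, 38
        t0 = m / (n - m)
        assert t0 == pytest.approx(0.61, abs=0.005)
        assert chi_prime(t0, n, m) == pytest.approx(0.0, abs=1e-12)
        assert chi_second(t0, n, m) > 0
        # strict convexity away from the minimum
        for t in (0.1, 0.3, 1.0, 5.0):
            assert chi(t, n, m) > chi(t0, n, m)

    def test_chi_at_one_with_m_zero(self):
        assert chi(1.0, 17, 0) == pytest.approx(17 * math.log(2), rel=1e-14)

    def test_domain_errors(self):
        for f in (phi, phi_prime, phi_second, chi, chi_prime, chi_second):
            with pytest.raises(ValueError):
                f(0.0, 10, 3)
            with pytest.raises(ValueError):
                f(-1.0, 10, 3)


class TestSaddleSolver:
    @pytest.mark.parametrize(
        "n,m,expected",
        [(100, 38, 22.81), (100, 75, 137.98), (500, 275, 251.58)],
    )
    def test_published_saddle_points(self, n, m, expected):
        assert solve_saddle_z0(n, m) == pytest.approx(expected, abs=0.005)

    def test_residual_and_determinism_sweep(self):
        rng = np.random.default_rng(20260929)
        for _ in range(40):
            n = int(rng.integers(50, 501))
            m = int(rng.integers(max(1, int(0.05 * n)), max(2, int(0.95 * n))))
            z0 = solve_saddle_z0(n, m)
            assert z0 > 0
            assert abs(phi_prime(z0, n, m)) <= 1e-10 * max(1.0, m / z0)
            assert solve_saddle_z0(n, m) == z0  # bitwise deterministic

    def test_rejects_degenerate_m(self):
        with pytest.raises(ValueError):
            solve_saddle_z0(10, 0)
        with pytest.raises(ValueError):
            solve_saddle_z0(10, 10)


class TestTauSolver:
    def test_theta_at_saddle_gives_t0(self):
        n, m = 100, 38
        z0 = solve_saddle_z0(n, m)
        assert solve_tau(n, m, z0, z0) == m / (n - m)

    @pytest.mark.parametrize("theta", [10.0, 40.0])
    def test_branch_and_residual(self, theta):
        n, m = 100, 38
        z0 = solve_saddle_z0(n, m)
        t0 = m / (n - m)
        tau = solve_tau(n, m, theta, z0)
        assert math.copysign(1, theta - z0) == math.copysign(1, tau - t0)
        resid = chi(tau, n, m) - chi(t0, n, m) - (phi(theta, n, m) - phi(z0, n, m))
        assert abs(resid) <= 1e-10 * max(1.0, abs(chi(t0, n, m)))

    def test_residual_sweep(self):
        rng = np.random.default_rng(4242)
        for _ in range(30):
            n = int(rng.integers(50, 501))
            m = int(rng.integers(max(1, n // 20), max(2, int(0.95 * n))))
            theta = float(rng.uniform(1.0, 500.0))
            z0 = solve_saddle_z0(n, m)
            tau = solve_tau(n, m, theta, z0)
            target = phi(theta, n, m) - phi(z0, n, m)
            resid = chi(tau, n, m) - chi(m / (n - m), n, m) - target
            assert abs(resid) <= 1e-10 * max(1.0, target)


class TestMainTerm:
    def test_finite_sum_identity(self):
        """I_{tau/(1+tau)}(m, n-m+1) equals the binomial tail sum."""
        n, m, tau = 10, 4, 0.5
        s = build_saddle_system(n, m, 1.0)
        s.tau, s.x = tau, tau / (1 + tau)  # pin the matching point directly
        direct = (1 + tau) ** -n * sum(
            comb(n, j, exact=True) * tau**j for j in range(m, n + 1)
        )
        assert main_term(s, "S-branch") == pytest.approx(direct, rel=1e-12)
        assert main_term(s, "S-branch") == pytest.approx(
            float(betainc(m, n - m + 1, s.x)), rel=1e-12
        )

    def test_complement_relation(self):
        n, m = 20, 7
        s = build_saddle_system(n, m, 3.0)
        total = main_term(s, "S-branch") + main_term(s, "T-branch")
        assert total == pytest.approx(1.0, abs=1e-14)

    def test_log_path_survives_underflow(self):
        """Far tails keep full log-space accuracy below double underflow."""
        s = build_saddle_system(500, 450, 10.0)
        lm = log_main_term(s, "S-branch")
        assert -2000 < lm < -600  # representable only in log space
        assert math.isfinite(lm)


class TestCorrectionTerm:
    def test_first_order_accuracy_against_oracle(self):
        """R' approximates (exact tail - main term) to ~20% at n=100."""
        p = ProblemParams(100, 75, 50.0)
        s = build_saddle_system(p.n - 1, p.m - 1, p.theta)
        exact_s = math.exp(
            fs_exact(p).diagnostics["lse_hi"]
            - np.logaddexp(
                fs_exact(p).diagnostics["lse_hi"], fs_exact(p).diagnostics["lse_lo"]
            )
        )
        sign, log_mag = correction_term(s)
        r = sign * math.exp(log_mag)
        residual = exact_s - main_term(s, "S-branch")
        assert r == pytest.approx(residual, rel=0.2)

    def test_correction_improves_on_main_term(self):
        """Corrected estimate beats main-term-only for >= 95% of a theta sweep."""
        n, m = 100, 75
        wins = total = 0
        for theta in np.linspace(10, 400, 60):
            p = ProblemParams(n, m, float(theta))
            s = build_saddle_system(n - 1, m - 1, p.theta)
            if abs(s.tau - s.t0) < 1e-3 * max(s.t0, 1.0):
                continue  # transition: correction intentionally not used there
            fe = fs_exact(p).fs
            fa = fs_asymptotic(p)
            if fa.diagnostics.get("fallback_used"):
                continue
            branch = fa.branch
            lm = log_main_term(s, branch)
            tail_main = math.exp(lm)
            fs_main = (lm - math.log1p(-tail_main)) * (1 if branch == "S-branch" else -1)
            total += 1
            if mollified_error(fe, fa.fs) <= mollified_error(fe, fs_main):
                wins += 1
        assert total > 30
        assert wins / total >= 0.95

    def test_singular_at_transition(self):
        n, m = 100, 38
        z0 = solve_saddle_z0(n, m)
        s = build_saddle_system(n, m, z0)
        with pytest.raises(ValueError):
            correction_term(s)


class TestFsAsymptotic:
    @pytest.mark.parametrize(
        "n,m,theta,published",
        [(25, 20, 9.39, -6.83168), (1000, 152, 9.07, -112.42500),
         (2001, 213, 9.03, -192.21835)],
    )
    def test_published_reference_values(self, n, m, theta, published):
        assert fs_asymptotic(n, m, theta).fs == pytest.approx(published, abs=2e-5)

    def test_closed_forms(self):
        assert fs_asymptotic(40, 1, 2.0).fs == math.inf
        res = fs_asymptotic(12, 12, 2.5)
        assert res.branch == "closed-form"
        assert res.fs == pytest.approx(fs_exact(12, 12, 2.5).fs, rel=1e-12)

    def test_branch_continuity_across_transition(self):
        """Fs is continuous through theta = z0 (S-branch vs T-branch)."""
        for n, m in ((100, 75), (500, 275)):
            z0 = solve_saddle_z0(n - 1, m - 1)
            eps = 0.01 * z0
            lo = fs_asymptotic(n, m, z0 - eps)
            hi = fs_asymptotic(n, m, z0 + eps)
            assert lo.branch in ("S-branch", "T-branch")
            exact_lo = fs_exact(n, m, z0 - eps).fs
            exact_hi = fs_exact(n, m, z0 + eps).fs
            assert mollified_error(exact_lo, lo.fs) < 1e-3
            assert mollified_error(exact_hi, hi.fs) < 1e-3
            # the two branch values straddle Fs = 0 smoothly
            assert abs((hi.fs - lo.fs) - (exact_hi - exact_lo)) < 1e-3

    def test_near_transition_falls_back_to_oracle(self):
        n, m = 100, 75
        z0 = solve_saddle_z0(n - 1, m - 1)
        res = fs_asymptotic(n, m, z0 * (1 + 1e-9))
        assert res.diagnostics["fallback_used"] == "exact-oracle"
        assert res.fs == pytest.approx(fs_exact(n, m, z0 * (1 + 1e-9)).fs, rel=1e-12)

    def test_extreme_tail_stays_in_log_space(self):
        """|Fs| beyond the double-precision probability range is still accurate."""
        fe = fs_exact(500, 450, 10.0).fs
        fa = fs_asymptotic(500, 450, 10.0).fs
        assert fe < -1000
        assert mollified_error(fe, fa) < 1e-3

    def test_auto_dispatch(self):
        assert fs_auto(25, 20, 9.39).method == "exact"
        assert fs_auto(100, 40, 9.37).method == "asymptotic"
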