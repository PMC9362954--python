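"""Jacobian, eigenvalue verdicts, closed-form inequalities, thresholds."""

import numpy as np
import pytest

from ecoevo import (
    assess_stability,
    equilibria_mutation_free,
    equilibria_with_mutation,
    jacobian,
    make_params,
    rhs,
    stability_threshold,
)
from ecoevo.equilibria import Equilibrium
from ecoevo.stability import MARGINAL_TOL, origin_margin

from conftest import sample_params, sample_state


def finite_difference_jacobian(x, y, params, h=1e-6):
    j = np.empty((2, 2))
    for col, (dx, dy) in enumerate([(h, 0.0), (0.0, h)]):
        plus = rhs((x + dx, y + dy), params)
        minus = rhs((x - dx, y - dy), params)
        j[0, col] = (plus.dx - minus.dx) / (2 * h)
        j[1, col] = (plus.dy - minus.dy) / (2 * h)
    return j


class TestJacobian:
    def test_origin_closed_form(self, rng):
        for _ in range(20):
            p = sample_params(rng)
            expected = [[p.sigma1 - p.xi - p.mu, p.mu], [p.mu, p.sigma2 - p.xi - p.mu]]
            np.testing.assert_allclose(jacobian((0.0, 0.0), p), expected, atol=1e-15)

    def test_matches_finite_differences(self, rng):
        for _ in range(1000):
            p = sample_params(rng)
            x, y = sample_state(rng)
            np.testing.assert_allclose(
                jacobian((x, y), p), finite_difference_jacobian(x, y, p), atol=1e-6
            )

    def test_defector_free_eigenvalues_sigma_free(self):
        """At (x*, 0) with sigma = mu = 0 the Jacobian is triangular with
        eigenvalues 2x* - 3x*^2 - xi and beta x* - beta x*^2 - xi = xi(beta-1)."""
        params = make_params(0.15, 1.4, 0.85, 0.3)
        for eq in equilibria_mutation_free(params):
            if eq.label != "E1":
                continue
            x = eq.x
            eigs = sorted(np.linalg.eigvals(jacobian((x, 0.0), params)).real)
            expected = sorted([2 * x - 3 * x**2 - 0.15, 0.15 * (1.4 - 1)])
            assert eigs == pytest.approx(expected, abs=1e-9)
            # the second eigenvalue is positive for any beta > 1:
            # a defector-free society is never stable without free-space help
            assert max(eigs) > 0


class TestAssessStability:
    def test_bistable_defector_free_pair(self, fig1a_params):
        e1 = sorted((e for e in equilibria_mutation_free(fig1a_params) if e.label == "E1"),
                    key=lambda e: e.x)
        small, large = (assess_stability(e, fig1a_params) for e in e1)
        assert small.verdict == "unstable" and small.stable_closed_form is False
        assert large.verdict == "stable" and large.stable_closed_form is True

    def test_extinction_with_mutation_closed_form(self, fig1d_params):
        """mu^2 < (xi+mu-s1)(xi+mu-s2) and 2(xi+mu) > s1+s2 at the bistable
        reference point: 0.0004 < 0.0024 and 0.64 > 0.50."""
        e0 = Equilibrium("E0", 0.0, 0.0, "origin", 0.0)
        rep = assess_stability(e0, fig1d_params)
        assert rep.stable_closed_form is True
        assert rep.verdict == "stable"
        assert rep.stable_eigen == (rep.margin < 0)

    def test_rejects_non_stationary_points(self, fig1a_params):
        fake = Equilibrium("E1", 0.5, 0.0, "plus", 1e-3)
        with pytest.raises(ValueError, match="residual"):
            assess_stability(fake, fig1a_params)

    def test_marginal_case_reported(self):
        # sigma1 = xi makes the origin's leading eigenvalue exactly zero
        p = make_params(0.25, 1.1, 0.85, 0.3, 0.0, 0.25, 0.1)
        rep = assess_stability(Equilibrium("E0", 0.0, 0.0, "origin", 0.0), p)
        assert abs(rep.margin) <= MARGINAL_TOL
        assert rep.verdict == "marginal"

    def test_trace_det_identity_at_origin(self, rng):
        """The printed extinction conditions are exactly {trace < 0, det > 0}
        of the origin Jacobian."""
        for _ in range(500):
            p = sample_params(rng)
            j = jacobian((0.0, 0.0), p)
            printed = (2 * (p.xi + p.mu) > p.sigma1 + p.sigma2) and (
                p.mu**2 < (p.xi + p.mu - p.sigma1) * (p.xi + p.mu - p.sigma2)
            )
            trace_det = (np.trace(j) < 0) and (np.linalg.det(j) > 0)
            assert printed == trace_det

    def test_coexistence_printed_conditions_sigma_free(self, rng):
        """The expanded sigma-free coexistence inequalities equal the
        trace/determinant verdict."""
        checked = 0
        while checked < 200:
            p = sample_params(rng, mu=0.0, sigma_free=True)
            for eq in equilibria_mutation_free(p):
                if eq.label != "E3":
                    continue
                x, y = eq.x, eq.y
                a = (2 * p.p - 1) * p.eta
                b = p.beta
                cond1 = 2 * p.xi > (2 + b) * x - (3 + b) * x**2 - 2 * (b + 1) * x * y \
                    + a * (2 * y - 3 * y**2 - 2 * x * y)
                cond2 = (2 * x - 3 * x**2 - 2 * x * y - p.xi) * (
                    b * x - b * x**2 - 2 * b * x * y + a * (2 * y - 3 * y**2 - 2 * x * y) - p.xi
                ) + x**2 * (b * y - b * y**2 - 2 * b * x * y - a * y**2) > 0
                rep = assess_stability(eq, p)
                if abs(rep.margin) <= 1e-8:
                    continue
                assert (cond1 and cond2) == rep.stable_eigen
                checked += 1

    @pytest.mark.parametrize("label", ["E0", "E1", "E2", "E3"])
    def test_closed_form_agrees_with_eigenvalues(self, rng, label):
        """Smoke version of the 1000-draw agreement check (see acceptance)."""
        checked = 0
        attempts = 0
        while checked < 100 and attempts < 3000:
            attempts += 1
            p = sample_params(rng, mu=0.0)
            for eq in equilibria_mutation_free(p):
                if eq.label != label:
                    continue
                rep = assess_stability(eq, p)
                if abs(rep.margin) <= 1e-8 or rep.stable_closed_form is None:
                    continue
                assert rep.stable_closed_form == rep.stable_eigen
                checked += 1
        assert checked >= 100


class TestThreshold:
    def test_extinction_boundary_in_sigma1(self):
        """mu^2 = (xi+mu-s1)(xi+mu-s2) with xi=0.25, mu=0.5, s2=0.25
        gives s1 = 0.25 exactly."""
        base = make_params(0.25, 1.1, 0.85, 0.65, 0.5, 0.75, 0.25)
        th = stability_threshold("sigma1", (0.0, 1.0), base, "E0")
        assert th == pytest.approx(0.25, abs=1e-6)

    def test_extinction_boundary_in_xi_without_mutation(self):
        """E0 is stable iff xi exceeds both subsidies: threshold max(s1, s2)."""
        base = make_params(0.38, 1.1, 0.85, 0.3, 0.0, 0.36, 0.25)
        th = stability_threshold("xi", (0.01, 1.0), base, "E0")
        assert th == pytest.approx(0.36, abs=1e-6)

    def test_no_sign_change_returns_none(self):
        # sigma = 0 < xi everywhere: extinction stays stable over all xi
        base = make_params(0.5, 1.1, 0.85, 0.3)
        assert stability_threshold("xi", (0.01, 1.0), base, "E0") is None

    def test_origin_margin_closed_form(self, rng):
        for _ in range(50):
            p = sample_params(rng)
            eig_max = np.linalg.eigvals(jacobian((0.0, 0.0), p)).real.max()
            assert origin_margin(p) == pytest.approx(eig_max, abs=1e-12)

    def test_margin_continuous_along_parameter_path(self):
        """The E0 margin varies continuously in sigma1 (sampled check)."""
        base = make_params(0.25, 1.1, 0.85, 0.65, 0.5, 0.75, 0.25)
        grid = np.linspace(0, 1, 201)
        margins = [origin_margin(base.replace(sigma1=v)) for v in grid]
        assert np.max(np.abs(np.diff(margins))) < 0.02
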