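"""Local stability analysis: Jacobian, eigenvalue verdicts, closed-form
inequalities, and threshold extraction in parameter space.

For a planar system local asymptotic stability of a hyperbolic rest point is
exactly {trace J < 0, det J > 0}.  The published closed-form conditions for
the boundary families (E0, E1, E2) are independent inequalities in the
parameters and the rest-point coordinate; for interior points they are the
trace/determinant pair expanded.  Both routes are computed and reported, and
their agreement on random parameter draws is the central correctness check
of the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .equilibria import (
    Equilibrium,
    RESIDUAL_TOL,
    equilibria_mutation_free,
    equilibria_with_mutation,
)
from .model_core import ModelParams, State, fitness_xy

__all__ = [
    "StabilityReport",
    "MARGINAL_TOL",
    "jacobian",
    "assess_stability",
    "origin_margin",
    "stability_threshold",
]

#: |margin| at or below this is reported as "marginal" rather than a verdict;
#: the closed-form inequalities are strict and say nothing there.
MARGINAL_TOL = 1e-8


def jacobian(state: State | tuple[float, float], params: ModelParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of the vector field at ``state``."""
    if isinstance(state, State):
        x, y = state.x, state.y
    else:
        x, y = float(state[0]), float(state[1])
    xi, beta, eta, p, mu, s1, s2 = params.as_tuple()
    z = 1.0 - x - y
    fc, fd = fitness_xy(x, y, beta, eta, p, s1, s2)
    a_mix = (2.0 * p - 1.0) * eta
    j11 = z * fc - xi - mu + x * (-fc + z * (1.0 - s1))
    j12 = x * (-fc - z * s1) + mu
    j21 = y * (-fd + z * (beta - s2)) + mu
    j22 = z * fd - xi - mu + y * (-fd + z * (a_mix - s2))
    return np.array([[j11, j12], [j21, j22]])


@dataclass
class StabilityReport:
    """Eigenvalue and closed-form verdicts at one equilibrium.

    margin is the maximum real part of the Jacobian eigenvalues; the verdict
    is "marginal" when |margin| <= MARGINAL_TOL (the printed inequalities are
    strict, so no closed-form claim is made there either).
    """

    label: str
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    margin: float
    stable_eigen: bool
    stable_closed_form: Optional[bool]

    @property
    def verdict(self) -> str:
        if abs(self.margin) <= MARGINAL_TOL:
            return "marginal"
        return "stable" if self.margin < 0 else "unstable"

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "eigenvalues": [{"re": float(e.real), "im": float(e.imag)}
                            for e in self.eigenvalues],
            "margin": self.margin,
            "stable_eigen": self.stable_eigen,
            "stable_closed_form": self.stable_closed_form,
            "verdict": self.verdict,
        }


def _closed_form_verdict(eq: Equilibrium, params: ModelParams) -> Optional[bool]:
    """The published stability inequalities for the equilibrium's family."""
    xi, beta, eta, p, mu, s1, s2 = params.as_tuple()
    x, y = eq.x, eq.y
    a_mix = (2.0 * p - 1.0) * eta
    if eq.label == "E0":
        if mu == 0.0:
            return s1 < xi and s2 < xi
        return (2.0 * (xi + mu) > s1 + s2) and (mu * mu < (xi + mu - s1) * (xi + mu - s2))
    if eq.label == "E1" and mu == 0.0:
        return (xi > (1.0 - s1) * (2.0 * x - 3.0 * x * x) + s1 * (1.0 - 2.0 * x)) and (
            xi > (beta - s2) * (x - x * x) + s2 * (1.0 - x)
        )
    if eq.label == "E2" and mu == 0.0:
        return (xi > s1 * (1.0 - y) - s1 * (y - y * y)) and (
            xi > s2 * (1.0 - 2.0 * y) + (a_mix - s2) * (2.0 * y - 3.0 * y * y)
        )
    if eq.label == "E3":
        # interior: trace negativity and determinant positivity of the
        # analytic Jacobian (the printed multi-line conditions expanded).
        j = jacobian((x, y), params)
        return (j[0, 0] + j[1, 1] < 0.0) and (np.linalg.det(j) > 0.0)
    return None


def assess_stability(eq: Equilibrium, params: ModelParams) -> StabilityReport:
    """Eigenvalue verdict (always) plus the closed-form verdict when one
    exists for the equilibrium's family."""
    if eq.residual > RESIDUAL_TOL:
        raise ValueError(
            f"equilibrium residual {eq.residual:g} exceeds {RESIDUAL_TOL:g}; "
            "refusing to assess a non-stationary point"
        )
    j = jacobian((eq.x, eq.y), params)
    eigs = np.linalg.eigvals(j)
    margin = float(np.max(eigs.real))
    return StabilityReport(
        label=eq.label,
        jacobian=j,
        eigenvalues=eigs,
        margin=margin,
        stable_eigen=margin < 0.0,
        stable_closed_form=_closed_form_verdict(eq, params),
    )


def origin_margin(params: ModelParams) -> float:
    """Stability margin of the extinction equilibrium (analytic).

    The origin Jacobian is [[s1 - xi - mu, mu], [mu, s2 - xi - mu]]
    (symmetric), so the margin is its larger eigenvalue in closed form.
    """
    xi, _, _, _, mu, s1, s2 = params.as_tuple()
    mean = 0.5 * (s1 + s2) - xi - mu
    half = 0.5 * (s1 - s2)
    return mean + np.sqrt(half * half + mu * mu)


def _family_margin(params: ModelParams, eq_label: str) -> float:
    """Margin of the most stable branch of a family; NaN if absent."""
    if eq_label == "E0":
        return float(origin_margin(params))
    if params.mu == 0.0:
        eqs = equilibria_mutation_free(params)
    else:
        eqs = equilibria_with_mutation(params, n_starts=8)
    margins = [
        assess_stability(eq, params).margin for eq in eqs if eq.label == eq_label
    ]
    return min(margins) if margins else np.nan


def stability_threshold(
    param_name: str,
    bounds: tuple[float, float],
    params: ModelParams,
    eq_label: str = "E0",
    n_scan: int = 101,
    xtol: float = 1e-6,
) -> Optional[float]:
    """Locate where the stability margin of an equilibrium family crosses
    zero along one parameter.

    Bisects the margin of ``eq_label`` (most stable branch) over
    ``param_name`` in ``bounds``; returns the sign-change location to
    ``xtol``, or None when the margin has no sign change in the interval.
    With several sign changes the first is returned with a warning.
    """
    lo, hi = bounds

    def margin_at(v: float) -> float:
        return _family_margin(params.replace(**{param_name: v}, unchecked=True), eq_label)

    grid = np.linspace(lo, hi, n_scan)
    vals = np.array([margin_at(v) for v in grid])
    finite = np.isfinite(vals)
    sign = np.sign(vals)
    # a grid point sitting exactly on the boundary is itself a crossing
    crossings: list[tuple[float, float] | float] = []
    for i in range(n_scan):
        if finite[i] and sign[i] == 0 and (not crossings or not isinstance(crossings[-1], float)):
            crossings.append(float(grid[i]))
        if i + 1 < n_scan and finite[i] and finite[i + 1] \
                and sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]:
            crossings.append((float(grid[i]), float(grid[i + 1])))
    if not crossings:
        return None
    if len(crossings) > 1:
        warnings.warn(
            f"margin of {eq_label} changes sign {len(crossings)} times over "
            f"{param_name} in {bounds}; returning the first crossing"
        )
    first = crossings[0]
    if isinstance(first, float):
        return first
    return float(optimize.brentq(margin_at, first[0], first[1], xtol=xtol))
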