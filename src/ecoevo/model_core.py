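"""Model definition: parameters, payoff structures, fitness, and the vector field.

The population consists of cooperators (density ``x``), defectors (density
``y``) and free space (``z = 1 - x - y``).  Each pairwise interaction is a
prisoner's dilemma with probability ``p`` and a snowdrift game with
probability ``1 - p``; the mixed 2x2 game has payoffs R = 1, S = 0, T = beta
and a mutual-defection payoff ``(2p - 1) * eta`` (+eta in the PD, -eta in the
SD).  Free space donates a payoff ``sigma1`` to cooperators and ``sigma2`` to
defectors while earning nothing itself, and gates reproduction: birth rates
are ``z * fitness``.  All individuals die at rate ``xi``, and a bidirectional
mutation at rate ``mu`` exchanges the two strategies.

The resulting planar vector field is

    dx/dt = x * [ z * fC - xi ] + mu * (y - x)
    dy/dt = y * [ z * fD - xi ] + mu * (x - y)

with fC = (1 - sigma1) x - sigma1 y + sigma1 and
fD = (beta - sigma2) x + ((2p - 1) eta - sigma2) y + sigma2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

__all__ = [
    "ModelParams",
    "State",
    "Fitness",
    "Derivative",
    "PARAM_DOMAINS",
    "PARAM_NAMES",
    "make_params",
    "pd_payoff_matrix",
    "sd_payoff_matrix",
    "multigame_payoff_matrix",
    "extended_payoff_matrix",
    "fitness",
    "fitness_xy",
    "rhs",
    "rhs_xy",
    "SIMPLEX_SLACK",
]

#: numerical slack tolerated on simplex membership (floating-point drift of
#: the integrator; the continuous system itself is forward invariant).
SIMPLEX_SLACK = 1e-9

# name -> (lower, upper, lower_closed, upper_closed)
PARAM_DOMAINS: dict[str, tuple[float, float, bool, bool]] = {
    "xi": (0.0, 1.0, False, True),      # death rate, (0, 1]
    "beta": (1.0, 2.0, False, False),   # temptation T, (1, 2)
    "eta": (0.0, 1.0, False, False),    # mutual-defection payoff magnitude, (0, 1)
    "p": (0.0, 1.0, True, True),        # probability of playing the PD, [0, 1]
    "mu": (0.0, 1.0, True, True),       # bidirectional mutation rate, [0, 1]
    "sigma1": (0.0, 1.0, True, True),   # free-space benefit to cooperators, [0, 1]
    "sigma2": (0.0, 1.0, True, True),   # free-space benefit to defectors, [0, 1]
}

PARAM_NAMES = tuple(PARAM_DOMAINS)


def _domain_repr(name: str) -> str:
    lo, hi, lc, hc = PARAM_DOMAINS[name]
    return f"{'[' if lc else '('}{lo:g}, {hi:g}{']' if hc else ')'}"


def _check_domain(name: str, value: float) -> bool:
    lo, hi, lc, hc = PARAM_DOMAINS[name]
    if not np.isfinite(value):
        return False
    if value < lo or (value == lo and not lc):
        return False
    if value > hi or (value == hi and not hc):
        return False
    return True


@dataclass(frozen=True)
class ModelParams:
    """The seven dimensionless parameters of the mutation-extended model.

    Construction validates every field against its legal domain unless
    ``unchecked=True``, in which case any finite values are accepted but the
    instance is flagged (some analyses deliberately probe boundary or
    out-of-domain values).
    """

    xi: float
    beta: float
    eta: float
    p: float
    mu: float = 0.0
    sigma1: float = 0.0
    sigma2: float = 0.0
    unchecked: bool = False

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if not self.unchecked and not _check_domain(name, value):
                raise ValueError(
                    f"parameter {name}={value:g} outside its legal domain "
                    f"{_domain_repr(name)}"
                )
            if self.unchecked and not np.isfinite(value):
                raise ValueError(f"parameter {name} must be finite, got {value!r}")

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float], unchecked: bool = False) -> "ModelParams":
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(mapping)
        if missing:
            raise ValueError(f"missing parameter(s): {sorted(missing)}")
        return cls(unchecked=unchecked, **{k: float(v) for k, v in mapping.items()})

    def replace(self, **changes: float) -> "ModelParams":
        return replace(self, **changes)

    def as_tuple(self) -> tuple[float, float, float, float, float, float, float]:
        """(xi, beta, eta, p, mu, sigma1, sigma2) for the numeric kernels."""
        return (self.xi, self.beta, self.eta, self.p, self.mu, self.sigma1, self.sigma2)


def make_params(
    xi: float,
    beta: float,
    eta: float,
    p: float,
    mu: float = 0.0,
    sigma1: float = 0.0,
    sigma2: float = 0.0,
    unchecked: bool = False,
) -> ModelParams:
    """Validated constructor for :class:`ModelParams` (positional convenience)."""
    return ModelParams(xi, beta, eta, p, mu, sigma1, sigma2, unchecked=unchecked)


@dataclass(frozen=True)
class State:
    """A point (x, y) on the population simplex; z = 1 - x - y is free space."""

    x: float
    y: float

    def __post_init__(self) -> None:
        x, y = float(self.x), float(self.y)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (np.isfinite(x) and np.isfinite(y)):
            raise ValueError(f"state must be finite, got ({x!r}, {y!r})")
        if x < -SIMPLEX_SLACK or y < -SIMPLEX_SLACK or x + y > 1.0 + SIMPLEX_SLACK:
            raise ValueError(
                f"state ({x:g}, {y:g}) violates the simplex constraint "
                f"x >= 0, y >= 0, x + y <= 1"
            )

    @property
    def z(self) -> float:
        return min(max(1.0 - self.x - self.y, 0.0), 1.0)

    def clipped(self) -> "State":
        """Project onto the closed simplex (used only at reporting time)."""
        x = min(max(self.x, 0.0), 1.0)
        y = min(max(self.y, 0.0), 1.0)
        s = x + y
        if s > 1.0:
            x, y = x / s, y / s
        return State(x, y)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Fitness:
    fC: float
    fD: float
    fF: float = 0.0  # free space never earns a payoff


@dataclass(frozen=True)
class Derivative:
    dx: float
    dy: float


# ---------------------------------------------------------------- payoffs

def pd_payoff_matrix(params: ModelParams) -> np.ndarray:
    """Prisoner's dilemma payoffs over (C, D): T = beta, R = 1, P = +eta, S = 0."""
    return np.array([[1.0, 0.0], [params.beta, params.eta]])


def sd_payoff_matrix(params: ModelParams) -> np.ndarray:
    """Snowdrift payoffs over (C, D): T = beta, R = 1, S = 0, P = -eta."""
    return np.array([[1.0, 0.0], [params.beta, -params.eta]])


def multigame_payoff_matrix(params: ModelParams) -> np.ndarray:
    """Mixed 2x2 game p*A + (1-p)*B: [[1, 0], [beta, (2p-1)*eta]]."""
    return np.array(
        [[1.0, 0.0], [params.beta, (2.0 * params.p - 1.0) * params.eta]]
    )


def extended_payoff_matrix(params: ModelParams) -> np.ndarray:
    """3x3 payoffs over (C, D, F): free space gives sigma1/sigma2, earns zero."""
    m = np.zeros((3, 3))
    m[:2, :2] = multigame_payoff_matrix(params)
    m[0, 2] = params.sigma1
    m[1, 2] = params.sigma2
    return m


# ---------------------------------------------------------------- dynamics

def fitness_xy(x, y, beta, eta, p, sigma1, sigma2):
    """Average payoffs (fC, fD); array-friendly, affine in (x, y)."""
    fc = (1.0 - sigma1) * x - sigma1 * y + sigma1
    fd = (beta - sigma2) * x + ((2.0 * p - 1.0) * eta - sigma2) * y + sigma2
    return fc, fd


def fitness(state: State, params: ModelParams) -> Fitness:
    fc, fd = fitness_xy(
        state.x, state.y, params.beta, params.eta, params.p, params.sigma1, params.sigma2
    )
    return Fitness(float(fc), float(fd), 0.0)


def rhs_xy(x, y, xi, beta, eta, p, mu, sigma1, sigma2):
    """Vector field (dx/dt, dy/dt); array-friendly."""
    z = 1.0 - x - y
    fc, fd = fitness_xy(x, y, beta, eta, p, sigma1, sigma2)
    dx = x * (z * fc - xi) + mu * (y - x)
    dy = y * (z * fd - xi) + mu * (x - y)
    return dx, dy


def rhs(state: State | tuple[float, float], params: ModelParams) -> Derivative:
    """Time derivative of the densities at ``state``.

    Accepts a bare (x, y) pair as well, so integrator internals may evaluate
    slightly off-simplex points without re-validation.
    """
    if isinstance(state, State):
        x, y = state.x, state.y
    else:
        x, y = float(state[0]), float(state[1])
    dx, dy = rhs_xy(x, y, *params.as_tuple())
    return Derivative(float(dx), float(dy))
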