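"""Fixed-step RK4 time integration and attractor classification.

The reference numerical protocol is classical RK4 with step length
``dt = 0.01`` run for 2e6 iterations, storing the final point to decide the
asymptotic state.  An optional early stop on the step-to-step change (default
tolerance 1e-12) is added on top: it changes no attractor label but cuts the
cost of grid scans by an order of magnitude.  Setting ``convergence_tol = 0``
disables it and reproduces the reference protocol exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from . import _kernel
from .model_core import ModelParams, State, SIMPLEX_SLACK

__all__ = [
    "IntegrationSpec",
    "SCAN_SPEC",
    "FULL_SPEC",
    "Trajectory",
    "AttractorLabel",
    "IntegrationError",
    "integrate",
    "integrate_final",
    "integrate_batch",
    "classify_attractor",
]

#: default density threshold below which a species counts as extinct when
#: classifying a final state; separates the reported equilibria (coordinates
#: >= 0.0899 or exactly 0) by two orders of magnitude.
CLASSIFY_TOL = 1e-3


class IntegrationError(RuntimeError):
    """Non-finite state during integration (records the failing step)."""

    def __init__(self, step: int, state: tuple[float, float]):
        self.step = step
        self.state = state
        super().__init__(f"non-finite state {state} at step {step}")


@dataclass(frozen=True)
class IntegrationSpec:
    """Numerical protocol for the fixed-step RK4 integrator.

    dt: step length; max_steps: iteration cap; record_every: thinning stride
    for trajectory storage; convergence_tol: early-stop threshold on the
    per-step state change (0 disables early stopping).
    """

    dt: float = 0.01
    max_steps: int = 2_000_000
    record_every: int = 100
    convergence_tol: float = 1e-12

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.max_steps < 1:
            raise ValueError(f"max_steps must be >= 1, got {self.max_steps}")
        if self.record_every < 1:
            raise ValueError(f"record_every must be >= 1, got {self.record_every}")
        if self.convergence_tol < 0:
            raise ValueError("convergence_tol must be >= 0")

    def to_dict(self) -> dict:
        return {
            "dt": self.dt,
            "max_steps": self.max_steps,
            "record_every": self.record_every,
            "convergence_tol": self.convergence_tol,
        }

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "IntegrationSpec":
        unknown = set(mapping) - {"dt", "max_steps", "record_every", "convergence_tol"}
        if unknown:
            raise ValueError(f"unknown integration key(s): {sorted(unknown)}")
        kwargs = dict(mapping)
        if "max_steps" in kwargs:
            kwargs["max_steps"] = int(kwargs["max_steps"])
        if "record_every" in kwargs:
            kwargs["record_every"] = int(kwargs["record_every"])
        return cls(**kwargs)


#: desk-scale default for grid scans (total time 2000 with early stop).
SCAN_SPEC = IntegrationSpec(max_steps=200_000)
#: the reference protocol: 2e6 steps of dt=0.01, no early stopping.
FULL_SPEC = IntegrationSpec(max_steps=2_000_000, convergence_tol=0.0)


class AttractorLabel(str, Enum):
    """Long-run outcome of a trajectory, matching the four-state color code
    (extinction=E0, defector_free=E1, cooperator_free=E2, coexistence=E3)."""

    EXTINCTION = "extinction"
    DEFECTOR_FREE = "defector_free"
    COOPERATOR_FREE = "cooperator_free"
    COEXISTENCE = "coexistence"
    UNRESOLVED = "unresolved"

    def __str__(self) -> str:  # plain value in CSV output
        return self.value


#: attractor label -> equilibrium family label
LABEL_TO_FAMILY = {
    AttractorLabel.EXTINCTION: "E0",
    AttractorLabel.DEFECTOR_FREE: "E1",
    AttractorLabel.COOPERATOR_FREE: "E2",
    AttractorLabel.COEXISTENCE: "E3",
}


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # shape (n, 2)
    final: State
    steps_taken: int
    converged: bool

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        x = self.states[:, 0]
        y = self.states[:, 1]
        return pd.DataFrame({"t": self.times, "x": x, "y": y, "z": 1.0 - x - y})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _final_state(x: float, y: float) -> State:
    # tolerate integrator round-off just outside the simplex, clip at reporting
    x = min(max(x, -SIMPLEX_SLACK), 1.0)
    y = min(max(y, -SIMPLEX_SLACK), 1.0)
    return State(x, y).clipped()


def integrate(
    state0: State | tuple[float, float],
    params: ModelParams,
    spec: IntegrationSpec = IntegrationSpec(),
) -> Trajectory:
    """RK4 trajectory from ``state0``; records every ``spec.record_every`` steps.

    Raises :class:`IntegrationError` if the state becomes non-finite.
    """
    s0 = state0 if isinstance(state0, State) else State(*state0)
    ts, xs, ys, count, steps, status = _kernel.rk4_record(
        s0.x, s0.y, *params.as_tuple(),
        spec.dt, spec.max_steps, spec.convergence_tol, spec.record_every,
    )
    if status == -1:
        raise IntegrationError(steps, (float(xs[count - 1]), float(ys[count - 1])))
    states = np.column_stack([xs[:count], ys[:count]])
    return Trajectory(
        times=ts[:count].copy(),
        states=states,
        final=_final_state(float(xs[count - 1]), float(ys[count - 1])),
        steps_taken=int(steps),
        converged=(status == 1),
    )


def integrate_final(
    state0: State | tuple[float, float],
    params: ModelParams,
    spec: IntegrationSpec = IntegrationSpec(),
) -> State:
    """Final state only (no trajectory storage) — the grid-scan workhorse."""
    s0 = state0 if isinstance(state0, State) else State(*state0)
    x, y, steps, status = _kernel.rk4_run(
        s0.x, s0.y, *params.as_tuple(), spec.dt, spec.max_steps, spec.convergence_tol
    )
    if status == -1:
        raise IntegrationError(steps, (float(x), float(y)))
    return _final_state(float(x), float(y))


def integrate_batch(
    states0: np.ndarray,
    params: ModelParams | Mapping[str, np.ndarray],
    spec: IntegrationSpec = IntegrationSpec(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate N trajectories; ``params`` may carry per-trajectory arrays.

    Parameters
    ----------
    states0 : (N, 2) array of initial conditions.
    params : a single :class:`ModelParams`, or a mapping of the seven
        parameter names to scalars/length-N arrays (scan modules vary
        parameters across the batch this way).

    Returns
    -------
    finals : (N, 2) array; steps : (N,) int array; converged : (N,) bool.
    """
    states0 = np.asarray(states0, dtype=float)
    n = states0.shape[0]
    if isinstance(params, ModelParams):
        vals = {k: np.full(n, v) for k, v in params.to_dict().items()}
    else:
        vals = {k: np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
                for k, v in params.items()}
    fx, fy, steps, status = _kernel.rk4_run_batch(
        np.ascontiguousarray(states0[:, 0]),
        np.ascontiguousarray(states0[:, 1]),
        vals["xi"], vals["beta"], vals["eta"], vals["p"],
        vals["mu"], vals["sigma1"], vals["sigma2"],
        spec.dt, spec.max_steps, spec.convergence_tol,
    )
    if np.any(status == -1):
        i = int(np.argmax(status == -1))
        raise IntegrationError(int(steps[i]), (float(fx[i]), float(fy[i])))
    return np.column_stack([fx, fy]), steps, status == 1


def classify_attractor(
    final_state: State | tuple[float, float],
    tol: float = CLASSIFY_TOL,
) -> AttractorLabel:
    """Map a final state to one of the four asymptotic outcomes.

    A coordinate below ``tol`` counts as extinct for that species.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if isinstance(final_state, State):
        x, y = final_state.x, final_state.y
    else:
        x, y = float(final_state[0]), float(final_state[1])
    if x < tol and y < tol:
        return AttractorLabel.EXTINCTION
    if y < tol:
        return AttractorLabel.DEFECTOR_FREE
    if x < tol:
        return AttractorLabel.COOPERATOR_FREE
    return AttractorLabel.COEXISTENCE
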