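"""Numerical experiments: basin-of-attraction grids, two-parameter phase
diagrams with stability-curve overlays, one-parameter sweeps, and transition
finders.

All experiments integrate the deterministic vector field with the fixed-step
RK4 protocol and classify the stored final point, so identical specifications
always produce identical label grids.  Phase diagrams are run from one fixed
initial condition (default (0.35, 0.35)); because the system is multistable,
simulated labels near stability boundaries can disagree with the analytic
curves — that caveat is stamped into the grid metadata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .integrator import (
    AttractorLabel,
    CLASSIFY_TOL,
    IntegrationSpec,
    SCAN_SPEC,
    classify_attractor,
    integrate_batch,
    integrate_final,
)
from .model_core import PARAM_NAMES, ModelParams, _check_domain
from .stability import _family_margin, origin_margin

__all__ = [
    "AxisSpec",
    "GridSpec",
    "LabelGrid",
    "SweepResult",
    "basin_scan",
    "phase_diagram",
    "overlay_stability_curves",
    "bifurcation_sweep",
    "find_transition",
]

#: label used for basin-grid cells with x0 + y0 > 1 (off the simplex).
INVALID = "invalid"

_COLOR_CODE = {  # the four-state color convention of the label maps
    "extinction": "red",
    "defector_free": "violet",
    "cooperator_free": "deepskyblue",
    "coexistence": "gold",
    "unresolved": "gray",
    INVALID: "white",
}


@dataclass(frozen=True)
class AxisSpec:
    name: str  # a parameter name, or "x0"/"y0" for basin grids
    lower: float
    upper: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not self.upper > self.lower:
            raise ValueError("upper must exceed lower")
        if self.name not in PARAM_NAMES and self.name not in ("x0", "y0"):
            raise ValueError(f"unknown axis name {self.name!r}")

    def values(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n_points)

    def to_dict(self) -> dict:
        return {"name": self.name, "lower": self.lower, "upper": self.upper,
                "n_points": self.n_points}

    @classmethod
    def from_dict(cls, d) -> "AxisSpec":
        unknown = set(d) - {"name", "lower", "upper", "n_points"}
        if unknown:
            raise ValueError(f"unknown axis key(s): {sorted(unknown)}")
        return cls(d["name"], float(d["lower"]), float(d["upper"]), int(d["n_points"]))


@dataclass(frozen=True)
class GridSpec:
    axis1: AxisSpec
    axis2: AxisSpec

    def to_dict(self) -> dict:
        return {"axis1": self.axis1.to_dict(), "axis2": self.axis2.to_dict()}

    @classmethod
    def from_dict(cls, d) -> "GridSpec":
        unknown = set(d) - {"axis1", "axis2"}
        if unknown:
            raise ValueError(f"unknown grid key(s): {sorted(unknown)}")
        return cls(AxisSpec.from_dict(d["axis1"]), AxisSpec.from_dict(d["axis2"]))


@dataclass
class LabelGrid:
    """Attractor labels over a 2-D grid; labels[i, j] pairs axis1[i], axis2[j]."""

    spec: GridSpec
    labels: np.ndarray  # dtype=object array of label strings
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (self.spec.axis1.n_points, self.spec.axis2.n_points)
        if self.labels.shape != expected:
            raise ValueError(f"labels shape {self.labels.shape} != grid {expected}")

    def label_set(self) -> set[str]:
        return {str(v) for v in self.labels.ravel() if str(v) != INVALID}

    def to_dataframe(self) -> pd.DataFrame:
        v1 = self.spec.axis1.values()
        v2 = self.spec.axis2.values()
        i, j = np.meshgrid(np.arange(len(v1)), np.arange(len(v2)), indexing="ij")
        return pd.DataFrame({
            self.spec.axis1.name: v1[i.ravel()],
            self.spec.axis2.name: v2[j.ravel()],
            "label": [str(v) for v in self.labels.ravel()],
        })

    def save(self, directory, stem: str = "labels") -> None:
        """Write the long-format CSV plus a JSON provenance sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(directory / f"{stem}.csv", index=False)
        with open(directory / f"{stem}.json", "w") as fh:
            json.dump({"grid": self.spec.to_dict(), **self.meta}, fh, indent=2,
                      default=str)

    def render(self, ax=None):
        """Color-map rendering with the four-state color code (optional)."""
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        names = [INVALID, "extinction", "defector_free", "cooperator_free",
                 "coexistence", "unresolved"]
        index = {n: k for k, n in enumerate(names)}
        img = np.vectorize(lambda v: index[str(v)])(self.labels)
        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(
            img.T, origin="lower", aspect="auto",
            cmap=ListedColormap([_COLOR_CODE[n] for n in names]),
            vmin=-0.5, vmax=len(names) - 0.5,
            extent=(self.spec.axis1.lower, self.spec.axis1.upper,
                    self.spec.axis2.lower, self.spec.axis2.upper),
        )
        ax.set_xlabel(self.spec.axis1.name)
        ax.set_ylabel(self.spec.axis2.name)
        return ax


@dataclass
class SweepResult:
    """Final densities along a one-parameter sweep from a fixed start."""

    param_name: str
    values: np.ndarray
    x_final: np.ndarray
    y_final: np.ndarray
    labels: list[AttractorLabel]

    def __post_init__(self) -> None:
        n = len(self.values)
        if not (len(self.x_final) == len(self.y_final) == len(self.labels) == n):
            raise ValueError("sweep arrays must have equal lengths")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.param_name: self.values,
            "x": self.x_final,
            "y": self.y_final,
            "label": [str(l) for l in self.labels],
        })


def basin_scan(
    params: ModelParams,
    spec: GridSpec,
    integration_spec: IntegrationSpec = SCAN_SPEC,
    tol: float = CLASSIFY_TOL,
) -> LabelGrid:
    """Classify the attractor reached from every initial condition on a grid.

    Axes must be "x0" and "y0"; cells with x0 + y0 > 1 are off the simplex
    and marked invalid.
    """
    if {spec.axis1.name, spec.axis2.name} != {"x0", "y0"}:
        raise ValueError("basin_scan axes must be x0 and y0")
    v1 = spec.axis1.values()
    v2 = spec.axis2.values()
    ii, jj = np.meshgrid(np.arange(len(v1)), np.arange(len(v2)), indexing="ij")
    x0 = v1[ii.ravel()] if spec.axis1.name == "x0" else v2[jj.ravel()]
    y0 = v2[jj.ravel()] if spec.axis2.name == "y0" else v1[ii.ravel()]
    valid = x0 + y0 <= 1.0 + 1e-12
    finals, _, converged = integrate_batch(
        np.column_stack([x0[valid], y0[valid]]), params, integration_spec
    )
    labels = np.full(x0.shape, INVALID, dtype=object)
    labels[valid] = [
        str(classify_attractor((fx, fy), tol)) for fx, fy in finals
    ]
    grid = LabelGrid(
        spec,
        labels.reshape(len(v1), len(v2)),
        meta={
            "kind": "basin",
            "params": params.to_dict(),
            "integration": integration_spec.to_dict(),
            "classify_tol": tol,
        },
    )
    return grid


def phase_diagram(
    spec: GridSpec,
    fixed_params: ModelParams,
    init: tuple[float, float] = (0.35, 0.35),
    integration_spec: IntegrationSpec = SCAN_SPEC,
    tol: float = CLASSIFY_TOL,
) -> LabelGrid:
    """Attractor label from a fixed start at every point of a parameter plane.

    Cells whose coordinates fall outside the legal parameter domains are run
    unchecked and listed under meta["out_of_domain"].
    """
    n1, n2 = spec.axis1.name, spec.axis2.name
    if n1 not in PARAM_NAMES or n2 not in PARAM_NAMES:
        raise ValueError("phase_diagram axes must be parameter names")
    v1 = spec.axis1.values()
    v2 = spec.axis2.values()
    ii, jj = np.meshgrid(np.arange(len(v1)), np.arange(len(v2)), indexing="ij")
    a1 = v1[ii.ravel()]
    a2 = v2[jj.ravel()]
    n = a1.size
    vals = {k: np.full(n, v) for k, v in fixed_params.to_dict().items()}
    vals[n1] = a1
    vals[n2] = a2
    out_of_domain = [
        (float(a), float(b))
        for a, b in zip(a1, a2)
        if not (_check_domain(n1, a) and _check_domain(n2, b))
    ]
    starts = np.tile(np.asarray(init, dtype=float), (n, 1))
    finals, _, _ = integrate_batch(starts, vals, integration_spec)
    labels = np.array(
        [str(classify_attractor((fx, fy), tol)) for fx, fy in finals], dtype=object
    ).reshape(len(v1), len(v2))
    return LabelGrid(
        spec,
        labels,
        meta={
            "kind": "phase_diagram",
            "params": fixed_params.to_dict(),
            "init": list(init),
            "integration": integration_spec.to_dict(),
            "classify_tol": tol,
            "out_of_domain": out_of_domain,
            "caveat": "multistable system: labels depend on the fixed initial "
                      "condition and may disagree with stability curves near "
                      "boundaries",
        },
    )


def overlay_stability_curves(
    grid: LabelGrid,
    families: Optional[tuple[str, ...]] = None,
) -> dict[str, list[np.ndarray]]:
    """Zero-level sets of the stability margin of each equilibrium family
    across a phase-diagram plane.

    The margin of the most stable branch of the family is evaluated on the
    grid's own axes and contoured with marching squares; returned polylines
    are (k, 2) arrays in axis coordinates.  Families absent everywhere in the
    plane yield empty lists.  By default all four families are traced for
    mu = 0 planes and only the extinction family for mu > 0 (the others do
    not exist there).
    """
    from skimage import measure

    if grid.meta.get("kind") != "phase_diagram":
        raise ValueError("stability curves overlay a phase diagram grid")
    base = ModelParams.from_dict(grid.meta["params"], unchecked=True)
    n1, n2 = grid.spec.axis1.name, grid.spec.axis2.name
    mu_varies = "mu" in (n1, n2)
    if families is None:
        if base.mu == 0.0 and not mu_varies:
            families = ("E0", "E1", "E2", "E3")
        else:
            families = ("E0",)
    v1 = grid.spec.axis1.values()
    v2 = grid.spec.axis2.values()
    curves: dict[str, list[np.ndarray]] = {}
    for fam in families:
        margin = np.full((len(v1), len(v2)), np.nan)
        for i, a in enumerate(v1):
            for j, b in enumerate(v2):
                p = base.replace(**{n1: a, n2: b}, unchecked=True)
                if fam == "E0":
                    margin[i, j] = origin_margin(p)
                else:
                    try:
                        margin[i, j] = _family_margin(p, fam)
                    except ValueError:
                        margin[i, j] = np.nan
        field = np.where(np.isfinite(margin), margin, 1.0)  # absent ~ unstable
        polylines = []
        for contour in measure.find_contours(field, 0.0):
            pts = np.column_stack([
                np.interp(contour[:, 0], np.arange(len(v1)), v1),
                np.interp(contour[:, 1], np.arange(len(v2)), v2),
            ])
            polylines.append(pts)
        curves[fam] = polylines
    return curves


def bifurcation_sweep(
    param_name: str,
    lower: float,
    upper: float,
    n: int,
    fixed_params: ModelParams,
    init: tuple[float, float] = (0.35, 0.35),
    integration_spec: IntegrationSpec = SCAN_SPEC,
    tol: float = CLASSIFY_TOL,
) -> SweepResult:
    """Record the long-run (x, y) from a fixed start along one parameter."""
    if param_name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {param_name!r}")
    values = np.linspace(lower, upper, n)
    vals = {k: np.full(n, v) for k, v in fixed_params.to_dict().items()}
    vals[param_name] = values
    starts = np.tile(np.asarray(init, dtype=float), (n, 1))
    finals, _, _ = integrate_batch(starts, vals, integration_spec)
    labels = [classify_attractor((fx, fy), tol) for fx, fy in finals]
    return SweepResult(param_name, values, finals[:, 0].copy(), finals[:, 1].copy(), labels)


_PREDICATES = ("x_equals_y", "extinction_onset")


def find_transition(
    param_name: str,
    bounds: tuple[float, float],
    predicate: str,
    fixed_params: ModelParams,
    init: tuple[float, float] = (0.35, 0.35),
    integration_spec: IntegrationSpec = SCAN_SPEC,
    n_prescan: int = 21,
    xtol: float = 1e-4,
    density_tol: float = CLASSIFY_TOL,
) -> Optional[float]:
    """Bisect for the parameter value where a long-run property flips.

    predicate "x_equals_y" tracks the sign of x_final - y_final (density
    crossing); "extinction_onset" tracks x_final + y_final - density_tol
    (survival boundary).  A coarse pre-scan brackets the sign change; None is
    returned when there is none, and with several changes the first is
    bisected with a warning.
    """
    if predicate not in _PREDICATES:
        raise ValueError(f"predicate must be one of {_PREDICATES}")

    def objective(v: float) -> float:
        p = fixed_params.replace(**{param_name: v}, unchecked=True)
        final = integrate_final(init, p, integration_spec)
        if predicate == "x_equals_y":
            return final.x - final.y
        return final.x + final.y - density_tol

    grid = np.linspace(bounds[0], bounds[1], n_prescan)
    starts = np.tile(np.asarray(init, dtype=float), (n_prescan, 1))
    vals = {k: np.full(n_prescan, v) for k, v in fixed_params.to_dict().items()}
    vals[param_name] = grid
    finals, _, _ = integrate_batch(starts, vals, integration_spec)
    if predicate == "x_equals_y":
        f = finals[:, 0] - finals[:, 1]
    else:
        f = finals[:, 0] + finals[:, 1] - density_tol
    sign = np.sign(f)
    brackets = [
        (grid[i], grid[i + 1])
        for i in range(n_prescan - 1)
        if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]
    ]
    if not brackets:
        return None
    if len(brackets) > 1:
        warnings.warn(
            f"{predicate} flips {len(brackets)} times over {param_name} in "
            f"{bounds}; returning the first transition"
        )
    a, b = brackets[0]
    return float(optimize.brentq(objective, a, b, xtol=xtol))
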