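"""Time integration of the compiled network and readout extraction.

Integration uses SciPy's stiff implicit solvers on the canonical rescaled
time axis of ``[0, 70000]`` AU.  State bounds are enforced by projection at
the reported output points (the solver's internal state is untouched);
controller measurements and all readouts are computed on the projected
trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .inputs import InputPolicy, resolve_inputs
from .model import ModelSpec, ReadoutDef, build_rhs

__all__ = [
    "IntegrationError",
    "SimulationConfig",
    "SimulationResult",
    "SteadyValue",
    "simulate",
    "compute_readouts",
    "steady_value",
]

# scipy has no TR-BDF2; Radau is the nearest one-step stiff implicit method.
_SOLVER_ALIASES = {"trbdf2": "Radau", "tr-bdf2": "Radau", "ode23tb": "Radau"}


class IntegrationError(RuntimeError):
    """Solver failure; carries the last time reached before the failure."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class SimulationConfig:
    t_span: tuple[float, float] = (0.0, 70000.0)
    n_points: int = 401
    solver: str = "LSODA"
    rel_tol: float = 1e-6
    abs_tol: float = 1e-8
    clip_states: bool = True
    # hold states inside their configured bounds during integration by
    # zeroing outward derivatives at a saturated bound (MATLAB-style value
    # restriction); without it, decay-inhibition feedbacks can run away
    # through physically meaningless state magnitudes
    bound_dynamics: bool = True

    def __post_init__(self) -> None:
        start, end = self.t_span
        if end <= start:
            raise ValueError("t_span end must exceed start")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")

    @property
    def method(self) -> str:
        return _SOLVER_ALIASES.get(self.solver.lower(), self.solver)

    def time_grid(self) -> np.ndarray:
        return np.linspace(self.t_span[0], self.t_span[1], self.n_points)


@dataclass
class SimulationResult:
    """Time grid, state/input trajectories, and derived readouts."""

    times: np.ndarray
    states: dict[str, np.ndarray]
    inputs: dict[str, np.ndarray]
    readouts: dict[str, np.ndarray] = field(default_factory=dict)
    # per-species (rate-constant value, driver input name) for flux readouts
    flux_coeffs: dict[str, tuple[float, str]] = field(default_factory=dict)
    controller_traces: dict[str, np.ndarray] = field(default_factory=dict)
    pattern_verdicts: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        columns: dict[str, np.ndarray] = {"time": self.times}
        for name, traj in self.states.items():
            columns[name] = traj
        for name, traj in self.inputs.items():
            columns[name] = traj
        for name, traj in self.readouts.items():
            columns[name] = traj
        for name, traj in self.controller_traces.items():
            columns[name] = traj
        return pd.DataFrame(columns)


class SteadyValue(NamedTuple):
    """Tail mean plus a settledness diagnostic (tail max - min)."""

    value: float
    spread: float


class _StateView(Mapping):
    """Read-only mapping view over a state vector (no copy per lookup)."""

    __slots__ = ("_y", "_index")

    def __init__(self, index: dict[str, int], y: np.ndarray):
        self._index = index
        self._y = y

    def rebind(self, y: np.ndarray) -> "_StateView":
        self._y = y
        return self

    def __getitem__(self, name: str) -> float:
        return self._y[self._index[name]]

    def __iter__(self):
        return iter(self._index)

    def __len__(self):
        return len(self._index)


def _zero_saturated_py(y, dy, lower, upper):
    dy[(y >= upper) & (dy > 0.0)] = 0.0
    dy[(y <= lower) & (dy < 0.0)] = 0.0


try:  # tight loops; jitted once per process, pure-numpy fallback otherwise
    import numba as _numba

    @_numba.njit(cache=False)
    def _zero_saturated(y, dy, lower, upper):  # pragma: no cover - trivial
        for i in range(y.shape[0]):
            if (y[i] >= upper[i] and dy[i] > 0.0) or (
                y[i] <= lower[i] and dy[i] < 0.0
            ):
                dy[i] = 0.0

except ImportError:  # pragma: no cover
    _zero_saturated = _zero_saturated_py


def bounded_rhs(rhs, lower: np.ndarray, upper: np.ndarray):
    """Evaluate the field on bound-projected states and zero outward
    derivative components at saturated bounds."""
    buf = np.empty_like(lower)

    def wrapped(t: float, y: np.ndarray) -> np.ndarray:
        np.clip(y, lower, upper, out=buf)
        dy = rhs(t, buf)
        _zero_saturated(y, dy, lower, upper)
        return dy

    return wrapped


def simulate(
    model: ModelSpec,
    policy: InputPolicy,
    config: SimulationConfig,
    initial_state: Mapping[str, float] | None = None,
    controller_values: Mapping[str, float] | None = None,
) -> SimulationResult:
    """Integrate the model under an input policy over ``config.t_span``.

    Deterministic for identical arguments.  Raises
    :class:`IntegrationError` if the solver cannot reach the end of the
    span, and ``FloatingPointError`` (naming the species) if the RHS goes
    non-finite.
    """
    init = dict(model.initial_state())
    if initial_state:
        init.update(initial_state)
    index = model.species_index()
    names = model.species_names
    y0 = np.array([init[n] for n in names], dtype=float)

    input_map_fn = resolve_inputs(policy, model, init, controller_values)
    view = _StateView(index, y0)

    def input_fn(t: float, y: np.ndarray) -> Mapping[str, float]:
        return input_map_fn(t, view.rebind(y))

    rhs = build_rhs(model, input_fn)
    if config.bound_dynamics:
        rhs = bounded_rhs(rhs, *model.bounds_arrays())
    grid = config.time_grid()
    sol = solve_ivp(
        rhs,
        config.t_span,
        y0,
        method=config.method,
        t_eval=grid,
        rtol=config.rel_tol,
        atol=config.abs_tol,
        dense_output=False,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else config.t_span[0]
        raise IntegrationError(
            f"integration failed at t={last}: {sol.message}", last_time=last
        )

    states_matrix = sol.y.T  # (n_points, n_species)
    if config.clip_states:
        lo, hi = model.bounds_arrays()
        states_matrix = np.clip(states_matrix, lo, hi)

    states = {n: states_matrix[:, index[n]].copy() for n in names}
    input_trajs = {name: np.zeros(len(grid)) for name in model.inputs}
    for i, t in enumerate(grid):
        u = input_fn(t, sol.y[:, i])
        for name in input_trajs:
            input_trajs[name][i] = u.get(name, 0.0)

    flux_coeffs: dict[str, tuple[float, str]] = {}
    for sp_name, term_list in model.terms.items():
        for term in term_list:
            if term.shape == "input_drive":
                flux_coeffs[sp_name] = (
                    model.parameters.rate(term.rate_constant),
                    term.driver,
                )

    result = SimulationResult(
        times=grid,
        states=states,
        inputs=input_trajs,
        flux_coeffs=flux_coeffs,
    )
    result.readouts = compute_readouts(result, model.readout_definitions)
    return result


def compute_readouts(
    result: SimulationResult,
    defs: Mapping[str, ReadoutDef],
    eps: float = 1e-12,
) -> dict[str, np.ndarray]:
    """Evaluate readout definitions pointwise on a finished trajectory.

    Ratio denominators are guarded with ``eps`` so an all-zero pool yields
    a 0 ratio instead of dividing by zero.
    """
    out: dict[str, np.ndarray] = {}
    for name, rdef in defs.items():
        if rdef.kind == "species":
            out[name] = result.states[rdef.species].copy()
        elif rdef.kind == "phospho_ratio":
            p = result.states[rdef.phospho]
            tot = p + result.states[rdef.total_partner]
            out[name] = p / np.maximum(tot, eps)
        elif rdef.kind == "raw_ratio":
            num = result.states[rdef.numerator]
            den = result.states[rdef.denominator]
            out[name] = num / np.maximum(den, eps)
        elif rdef.kind == "input_flux":
            try:
                k, driver = result.flux_coeffs[rdef.species]
            except KeyError:
                raise KeyError(
                    f"readout {name!r}: no input_drive flux recorded for "
                    f"species {rdef.species!r}"
                ) from None
            out[name] = k * result.inputs[driver]
        else:  # pragma: no cover - rejected at parse time
            raise ValueError(f"unknown readout kind {rdef.kind!r}")
    return out


def steady_value(trajectory: np.ndarray, tail_fraction: float = 0.1) -> SteadyValue:
    """Mean over the final ``tail_fraction`` of points, with tail max-min."""
    traj = np.asarray(trajectory, dtype=float)
    if traj.size == 0:
        raise ValueError("empty trajectory")
    if not (0.0 < tail_fraction <= 1.0):
        raise ValueError("tail_fraction must be in (0, 1]")
    count = max(1, math.ceil(tail_fraction * traj.size))
    tail = traj[-count:]
    return SteadyValue(float(tail.mean()), float(tail.max() - tail.min()))
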