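"""Discrete PID controllers closed around the ODE plant.

Two loops mirror the published controller pairing: loop 1 senses a UPR-arm
marker (pPERK) and actuates the ER-stress drive u1 with gains
``kp=0, ki=0.0691, kd=0``; loop 2 senses an insulin-arm marker (IRpY,
IRSpY or pAKT) and actuates the insulin drive u2 with gains
``kp=0.2134, ki=0.10329, kd=-0.1082``.  Controllers run at a fixed sample
interval with zero-order hold between samples; actuation is clamped at or
above zero because a negative drive has no physical meaning here.

The published error function carries an absolute value, which cannot steer
a readout downward; the default here is the signed error ``r - o`` with the
absolute mode retained for replication attempts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .inputs import InputPolicy, resolve_inputs
from .model import ModelSpec, ReadoutDef, build_rhs
from .simulate import (
    IntegrationError,
    SimulationConfig,
    SimulationResult,
    _StateView,
    bounded_rhs,
    compute_readouts,
    simulate,
)

__all__ = [
    "PIDConfig",
    "PIDController",
    "ControlLoop",
    "pid_step",
    "closed_loop_simulate",
    "UPR_ARM_MARKERS",
    "INSULIN_ARM_MARKERS",
]

UPR_ARM_MARKERS = frozenset({"pPERK"})
INSULIN_ARM_MARKERS = frozenset({"IRpY", "IRSpY", "pAKT"})


@dataclass(frozen=True)
class PIDConfig:
    """Gains, reference and discretization of one controller."""

    kp: float = 0.0
    ki: float = 0.0
    kd: float = 0.0  # negative kd permitted (controller 2 ships with one)
    reference: float = 0.0
    error_mode: str = "signed"
    output_limits: tuple[float, float] = (0.0, math.inf)
    anti_windup: bool = True
    sample_interval: float = 350.0
    derivative_smoothing: float = 0.0  # single-pole filter coefficient in [0,1)
    initial_output: float | None = None

    def __post_init__(self) -> None:
        if self.error_mode not in ("signed", "absolute"):
            raise ValueError(f"unknown error_mode {self.error_mode!r}")
        lo, hi = self.output_limits
        if lo > hi:
            raise ValueError("output_limits min exceeds max")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if not (0.0 <= self.derivative_smoothing < 1.0):
            raise ValueError("derivative_smoothing must be in [0, 1)")


class PIDController:
    """Stateful discrete PID; integral in error-time units, derivative on
    the measurement (first difference, optional single-pole smoothing)."""

    def __init__(self, config: PIDConfig):
        self.config = config
        self.integral = 0.0
        self.last_measurement: float | None = None
        self.last_error: float | None = None
        self.filtered_derivative = 0.0
        self.last_output = 0.0
        if config.initial_output is not None:
            self.preload(config.initial_output)

    def preload(self, output: float) -> None:
        """Seed the integral so the first emitted output starts near
        ``output`` (requires ki != 0; otherwise only last_output is set)."""
        if self.config.ki != 0.0:
            self.integral = output / self.config.ki
        self.last_output = output

    def step(self, measurement: float, dt: float, reference: float | None = None) -> float:
        cfg = self.config
        if dt <= 0:
            raise ValueError("dt must be positive")
        r = cfg.reference if reference is None else reference
        error = r - measurement
        if cfg.error_mode == "absolute":
            error = abs(error)

        if self.last_measurement is None:
            raw_derivative = 0.0
        else:
            # d(error)/dt with constant reference is -d(measurement)/dt
            raw_derivative = -(measurement - self.last_measurement) / dt
        alpha = cfg.derivative_smoothing
        self.filtered_derivative = (
            alpha * self.filtered_derivative + (1.0 - alpha) * raw_derivative
        )

        candidate_integral = self.integral + error * dt
        unclamped = (
            cfg.kp * error
            + cfg.ki * candidate_integral
            + cfg.kd * self.filtered_derivative
        )
        lo, hi = cfg.output_limits
        output = min(max(unclamped, lo), hi)

        saturated_high = unclamped > hi and error > 0
        saturated_low = unclamped < lo and error < 0
        if not (cfg.anti_windup and (saturated_high or saturated_low)):
            self.integral = candidate_integral

        self.last_measurement = measurement
        self.last_error = error
        self.last_output = output
        return output


def pid_step(
    controller: PIDController,
    measurement: float,
    reference: float,
    dt: float,
) -> float:
    """One controller update; see :meth:`PIDController.step`."""
    return controller.step(measurement, dt, reference=reference)


@dataclass
class ControlLoop:
    """Wiring of one controller: sensed readout -> actuated input."""

    controlled_readout: str
    actuated_input: str
    controller: PIDConfig

    def __post_init__(self) -> None:
        marker = self.controlled_readout
        if self.actuated_input == "u1" and marker in INSULIN_ARM_MARKERS:
            raise ValueError(
                f"u1 must sense a UPR-arm marker, not {marker!r}"
            )
        if self.actuated_input == "u2" and marker in UPR_ARM_MARKERS:
            raise ValueError(
                f"u2 must sense an insulin-arm marker, not {marker!r}"
            )


def _measurement_fn(model: ModelSpec, readout: str):
    """Pointwise readout evaluation on a (clipped) state vector."""
    index = model.species_index()
    rdef = model.readout_definitions.get(readout)
    if rdef is None:
        # fall back to a bare species name (used by synthetic test plants)
        if readout in index:
            rdef = ReadoutDef(kind="species", species=readout)
        else:
            raise KeyError(f"unknown controlled readout {readout!r}")
    if rdef.kind == "species":
        i = index[rdef.species]
        return lambda y: y[i]
    if rdef.kind == "phospho_ratio":
        ip, it = index[rdef.phospho], index[rdef.total_partner]
        return lambda y: y[ip] / max(y[ip] + y[it], 1e-12)
    if rdef.kind == "raw_ratio":
        inum, iden = index[rdef.numerator], index[rdef.denominator]
        return lambda y: y[inum] / max(y[iden], 1e-12)
    raise ValueError(f"readout {readout!r} ({rdef.kind}) cannot be a controlled variable")


def closed_loop_simulate(
    model: ModelSpec,
    loops: Sequence[ControlLoop],
    config: SimulationConfig,
    policy: InputPolicy | None = None,
    initial_state: Mapping[str, float] | None = None,
) -> SimulationResult:
    """Simulate with controllers in the loop (piecewise ZOH integration).

    With ``loops == []`` this is exactly :func:`ersim.simulate.simulate`.
    All loops must share one sample interval, and that interval must land
    on the output grid.  Controller error and actuation traces are returned
    as ``error_<readout>`` / ``u_<input>`` columns.
    """
    if policy is None:
        modes = {name: "steady_state_amplified" for name in model.inputs}
        for loop in loops:
            modes[loop.actuated_input] = "controller"
        policy = InputPolicy(modes=modes)
    if not loops:
        return simulate(model, policy, config, initial_state)

    dts = {loop.controller.sample_interval for loop in loops}
    if len(dts) != 1:
        raise ValueError("all control loops must share one sample_interval")
    dt = dts.pop()
    t0, t1 = config.t_span
    span = t1 - t0
    n_intervals = round(span / dt)
    if n_intervals < 1 or abs(n_intervals * dt - span) > 1e-9 * span:
        raise ValueError("sample_interval must divide the time span")
    if (config.n_points - 1) % n_intervals != 0:
        raise ValueError(
            "sample_interval must divide the output grid "
            f"({config.n_points - 1} grid steps vs {n_intervals} samples)"
        )
    pts_per_interval = (config.n_points - 1) // n_intervals

    init = dict(model.initial_state())
    if initial_state:
        init.update(initial_state)
    index = model.species_index()
    names = model.species_names
    y = np.array([init[n] for n in names], dtype=float)
    lo_b, hi_b = model.bounds_arrays()

    controller_values: dict[str, float] = {}
    controllers = [PIDController(loop.controller) for loop in loops]
    measure = [_measurement_fn(model, loop.controlled_readout) for loop in loops]

    input_map_fn = resolve_inputs(policy, model, init, controller_values)
    view = _StateView(index, y)

    def input_fn(t: float, yv: np.ndarray):
        return input_map_fn(t, view.rebind(yv))

    rhs = build_rhs(model, input_fn)
    if config.bound_dynamics:
        rhs = bounded_rhs(rhs, lo_b, hi_b)
    grid = config.time_grid()
    n_species = len(names)
    states_matrix = np.empty((config.n_points, n_species))
    states_matrix[0] = y
    error_traces = np.zeros((len(loops), config.n_points))
    output_traces = np.zeros((len(loops), config.n_points))

    for k in range(n_intervals):
        seg_start = t0 + k * dt
        seg_end = seg_start + dt
        y_clipped = np.clip(y, lo_b, hi_b)
        for j, (ctrl, meas_fn, loop) in enumerate(zip(controllers, measure, loops)):
            measurement = meas_fn(y_clipped)
            output = ctrl.step(measurement, dt)
            controller_values[loop.actuated_input] = output
            lo_grid = k * pts_per_interval
            hi_grid = (k + 1) * pts_per_interval + 1
            error_traces[j, lo_grid:hi_grid] = ctrl.last_error
            output_traces[j, lo_grid:hi_grid] = output

        seg_eval = grid[k * pts_per_interval : (k + 1) * pts_per_interval + 1]
        sol = solve_ivp(
            rhs,
            (seg_start, seg_end),
            y,
            method=config.method,
            t_eval=seg_eval,
            rtol=config.rel_tol,
            atol=config.abs_tol,
        )
        if not sol.success:
            last = float(sol.t[-1]) if sol.t.size else seg_start
            raise IntegrationError(
                f"integration failed in control interval {k} at t={last}: "
                f"{sol.message}",
                last_time=last,
            )
        states_matrix[k * pts_per_interval + 1 : (k + 1) * pts_per_interval + 1] = (
            sol.y.T[1:]
        )
        y = sol.y[:, -1].copy()

    if config.clip_states:
        states_matrix = np.clip(states_matrix, lo_b, hi_b)

    states = {n: states_matrix[:, index[n]].copy() for n in names}
    # reconstruct held input trajectories on the output grid
    input_trajs: dict[str, np.ndarray] = {
        name: np.zeros(config.n_points) for name in model.inputs
    }
    for j, loop in enumerate(loops):
        input_trajs[loop.actuated_input] = output_traces[j].copy()
    uncontrolled = [n for n in model.inputs if policy.modes.get(n) != "controller"]
    if uncontrolled:
        for i, t in enumerate(grid):
            u = input_fn(t, states_matrix[i])
            for name in uncontrolled:
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
    for j, loop in enumerate(loops):
        result.controller_traces[f"error_{loop.controlled_readout}"] = error_traces[j]
        result.controller_traces[f"u_{loop.actuated_input}"] = output_traces[j]
    return result
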