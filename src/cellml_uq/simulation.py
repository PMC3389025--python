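"""Compile a model into an executable ODE-IV plan and integrate it.

The plan is explicit: per-state rate closures, a topologically ordered list
of algebraic assignments, a constants table, and slots for the uncertain
parameters that a :class:`~cellml_uq.sampling.ParameterDraw` fills in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, ModelError, ValidationError
from .mathml import Apply, VariableRef, compile_expr, free_variables
from .model import ModelDocument, classify_variables
from .sampling import ParameterDraw


@dataclass
class SolverSettings:
    method: str = "RK45"
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: float = np.inf


@dataclass
class TimeCourseSpec:
    initial_time: float = 0.0
    output_start: float = 0.0
    output_end: float = 10.0
    number_of_points: int = 100
    solver: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self):
        if not (self.initial_time <= self.output_start <= self.output_end):
            raise ValidationError(
                "require initial_time <= output_start <= output_end, got "
                f"{self.initial_time}, {self.output_start}, {self.output_end}")
        if self.number_of_points < 1:
            raise ValidationError("number_of_points must be >= 1")

    def grid(self) -> np.ndarray:
        if self.output_start == self.output_end:
            return np.array([self.output_start])
        return np.linspace(self.output_start, self.output_end,
                           self.number_of_points + 1)


@dataclass
class Trajectory:
    times: np.ndarray
    columns: list            # variable display names, bound variable first
    values: np.ndarray       # shape (len(times), len(columns))
    draw: Optional[ParameterDraw] = None

    def column(self, name: str) -> np.ndarray:
        try:
            return self.values[:, self.columns.index(name)]
        except ValueError:
            raise ValidationError(f"variable {name!r} not reported") from None


class EvaluationPlan:
    """Side-effect-free right-hand-side evaluator for one model."""

    def __init__(self, model: ModelDocument):
        self.model = model
        parts = classify_variables(model)
        self.classification = parts
        self.parameter_slots = sorted(parts["uncertain"])
        self.bound_key = next(iter(parts["bound"]), None)

        # constants: numeric initial_value attributes + closed assignments
        constants = {}
        rhs_by_key = {}
        self.state_keys = []
        for lhs, rhs, _comp in model.assignments:
            if isinstance(lhs, Apply) and lhs.operator == "diff":
                key = model.canonical(lhs.operands[1].key)
                rhs_by_key[("rate", key)] = rhs
                self.state_keys.append(key)
            else:
                rhs_by_key[model.canonical(lhs.key)] = rhs
        for key in sorted(parts["constants"]):
            if key in rhs_by_key:
                constants[key] = compile_expr(rhs_by_key[key])({})
            else:
                raw = model.variable(key).initial_value
                try:
                    constants[key] = float(raw)
                except (TypeError, ValueError):
                    raise ModelError(
                        f"constant {key[1]!r} has non-numeric initial_value "
                        f"{raw!r}") from None
        self.constants = constants

        # algebraic assignments in dependency order
        algebraic = parts["algebraic"]
        order, placed = [], set()
        pending = {k: {model.canonical(d)
                       for d in free_variables(rhs_by_key[k])} & algebraic
                   for k in algebraic}
        while pending:
            ready = sorted(k for k, deps in pending.items()
                           if deps <= placed)
            if not ready:  # classify_variables already rejects true loops
                raise ModelError("could not order algebraic assignments")
            for k in ready:
                order.append(k)
                placed.add(k)
                del pending[k]
        self.algebraic_order = order
        self._algebraic_fns = [(k, compile_expr(rhs_by_key[k]))
                               for k in order]
        self._rate_fns = [compile_expr(rhs_by_key[("rate", k)])
                          for k in self.state_keys]

        # initial-value resolution for states: number or variable reference
        self._initials = []
        for key in self.state_keys:
            raw = model.variable(key).initial_value
            if raw is None:
                raise ModelError(
                    f"state {key[1]!r} has no initial_value attribute")
            try:
                self._initials.append(float(raw))
            except ValueError:
                ref = model.canonical((key[0], raw))
                self._initials.append(ref)

    # -- evaluation ----------------------------------------------------------

    def base_bindings(self, draw: Optional[ParameterDraw]) -> dict:
        bindings = dict(self.constants)
        if draw is not None:
            bindings.update(draw.values)
        missing = [k for k in self.parameter_slots if k not in bindings]
        if missing:
            raise ModelError(
                "parameter draw does not fill slot(s): "
                + ", ".join(v for _, v in missing))
        return bindings

    def initial_state(self, bindings: dict) -> np.ndarray:
        out = []
        for spec in self._initials:
            if isinstance(spec, tuple):
                if spec not in bindings:
                    raise ModelError(
                        f"initial value refers to unbound variable {spec[1]!r}")
                out.append(bindings[spec])
            else:
                out.append(spec)
        return np.array(out, dtype=float)

    def rhs(self, bindings: dict):
        bound_key = self.bound_key
        state_keys = self.state_keys
        algebraic = self._algebraic_fns
        rates = self._rate_fns

        def f(t, y):
            b = dict(bindings)
            if bound_key is not None:
                b[bound_key] = t
            for key, value in zip(state_keys, y):
                b[key] = value
            for key, fn in algebraic:
                b[key] = fn(b)
            return [fn(b) for fn in rates]
        return f


def compile_plan(model: ModelDocument) -> EvaluationPlan:
    """Build an :class:`EvaluationPlan`; fails on loops or missing pieces."""
    return EvaluationPlan(model)


def run_time_course(plan: EvaluationPlan, draw: Optional[ParameterDraw],
                    spec: TimeCourseSpec) -> Trajectory:
    """Integrate one time course on the uniform output grid."""
    bindings = plan.base_bindings(draw)
    y0 = plan.initial_state(bindings)
    grid = spec.grid()
    names = ([plan.bound_key[1]] if plan.bound_key else ["t"]) \
        + [k[1] for k in plan.state_keys]

    if spec.output_end == spec.initial_time or not plan.state_keys:
        times = grid
        values = np.column_stack(
            [times] + [np.full_like(times, v) for v in y0]) \
            if plan.state_keys else times.reshape(-1, 1)
        return Trajectory(times, names, values, draw)

    s = spec.solver
    sol = solve_ivp(plan.rhs(bindings), (spec.initial_time, spec.output_end),
                    y0, method=s.method, t_eval=grid, rtol=s.rel_tol,
                    atol=s.abs_tol, max_step=s.max_step)
    if not sol.success:
        last = sol.t[-1] if sol.t.size else spec.initial_time
        raise IntegrationError(
            f"ODE solver failed at t={last:g}: {sol.message}", estimate=last)
    values = np.column_stack([sol.t] + [sol.y[i] for i in
                                        range(len(plan.state_keys))])
    return Trajectory(sol.t, names, values, draw)
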