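"""State-space model representation, simulation and prediction.

A model is declared symbolically: an ODE right-hand side ``xdot = f(x, u, theta)``
per state, an observation map ``y = g(x, theta)``, initial values that may depend
on parameters, and per-observable Gaussian noise standard deviations.  Expressions
are parsed once with sympy and compiled to fast numpy callables; simulation uses a
stiff-capable LSODA integrator with an analytic ODE Jacobian.

A *prediction* ``z = F(D_pred, theta)`` is the model response for a prediction
condition ``D_pred = (t_pred, g_pred, u_pred)``: any expression over states and
parameters, evaluated on the integrated trajectory at one time point under one
stimulation condition.  Predictions need not coincide with measured observables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp
import yaml

__all__ = [
    "ModelDefinition",
    "ExperimentalDesign",
    "PredictionTarget",
    "StateTrajectory",
    "IntegrationError",
    "ModelConfigError",
    "integrate",
    "observe",
    "predict",
    "load_model",
    "save_model",
    "trajectory_to_csv",
]

# Solver tolerances: profile optimization needs the objective smooth well below
# the chi-square threshold scale (~1e-2), hence tolerances orders below that.
RTOL = 1e-8
ATOL = 1e-10

_TIME = sp.Symbol("t")


class ModelConfigError(ValueError):
    """A model declaration is internally inconsistent."""


class IntegrationError(RuntimeError):
    """ODE integration failed (stiffness, blow-up, non-finite state).

    Carries the offending parameter vector so optimizers can log and penalize
    the point instead of propagating silent NaNs.
    """

    def __init__(self, message: str, theta: np.ndarray | None = None):
        super().__init__(message)
        self.theta = None if theta is None else np.asarray(theta, dtype=float)


def _parse(expr: str | float, allowed: Mapping[str, sp.Symbol]) -> sp.Expr:
    if isinstance(expr, (int, float)):
        return sp.Float(expr)
    try:
        parsed = sp.sympify(expr, locals=dict(allowed))
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        raise ModelConfigError(f"cannot parse expression {expr!r}: {exc}") from exc
    extra = parsed.free_symbols - set(allowed.values()) - {_TIME}
    if extra:
        names = ", ".join(sorted(str(s) for s in extra))
        raise ModelConfigError(
            f"expression {expr!r} uses unknown symbol(s): {names} "
            "(must be a state, parameter, input, or t)"
        )
    return parsed


@dataclass(frozen=True)
class ExperimentalDesign:
    """A measurement design D = (times, observables, input condition)."""

    times: tuple[float, ...]
    observables: tuple[str, ...]
    input_id: str = "default"

    def __post_init__(self):
        times = tuple(float(t) for t in self.times)
        if any(t < 0 for t in times):
            raise ValueError("design times must be non-negative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("design times must be strictly increasing")
        if not self.observables:
            raise ValueError("design needs at least one observable")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "observables", tuple(self.observables))


@dataclass(frozen=True)
class PredictionTarget:
    """A prediction condition: expression ``g_pred`` at time ``t_pred`` under ``input_id``.

    ``g_pred`` may be any expression over states and parameters (a state name,
    a sum of states, a ratio of concentrations, ...) — it does not have to be a
    measured observable.
    """

    t_pred: float
    g_pred: str
    input_id: str = "default"

    def __post_init__(self):
        if self.t_pred < 0:
            raise ValueError("prediction time must be non-negative")


@dataclass(frozen=True)
class StateTrajectory:
    """Solution of the ODE system on a time grid (rows: times, cols: states)."""

    times: np.ndarray
    states: np.ndarray
    state_names: tuple[str, ...]

    def column(self, name: str) -> np.ndarray:
        try:
            return self.states[:, self.state_names.index(name)]
        except ValueError:
            raise KeyError(f"unknown state {name!r}") from None


class ModelDefinition:
    """Symbolic declaration of an ODE state-space model.

    Parameters
    ----------
    state_names, param_names:
        Ordered identifiers for dynamic states and free parameters.
    rhs:
        Mapping state -> expression string for its time derivative; expressions
        may use states, parameters, input names and ``t``.
    observation_map:
        Mapping observable name -> expression over states and parameters.
    initial_values:
        Mapping state -> number or expression in the parameters.
    noise_sd:
        Mapping observable -> fixed Gaussian noise SD (must be positive).
    inputs:
        Mapping input_id -> {input symbol: constant or [[t_start, value], ...]
        piecewise-constant segments}.  ``{"default": {}}`` if the model has no
        external input.
    default_theta, bounds:
        Reference parameter values and a (lower, upper) box used as fitting
        defaults.
    """

    def __init__(
        self,
        state_names: Sequence[str],
        param_names: Sequence[str],
        rhs: Mapping[str, str],
        observation_map: Mapping[str, str],
        initial_values: Mapping[str, str | float],
        noise_sd: Mapping[str, float] | None = None,
        inputs: Mapping[str, Mapping[str, object]] | None = None,
        default_theta: Sequence[float] | None = None,
        bounds: tuple[Sequence[float], Sequence[float]] | None = None,
        name: str = "model",
        rtol: float = RTOL,
        atol: float = ATOL,
    ):
        self.name = name
        # per-model solver tolerances: atol should sit a few orders below the
        # typical state magnitude (1e-10 is meant for O(1) concentrations)
        self.rtol = float(rtol)
        self.atol = float(atol)
        self.state_names = tuple(state_names)
        self.param_names = tuple(param_names)
        if set(rhs) != set(self.state_names):
            raise ModelConfigError(
                "rhs must define exactly one expression per state; "
                f"got {sorted(rhs)} for states {sorted(self.state_names)}"
            )
        self.inputs = {k: dict(v) for k, v in (inputs or {"default": {}}).items()}
        input_names: list[str] = []
        for spec in self.inputs.values():
            for u_name in spec:
                if u_name not in input_names:
                    input_names.append(u_name)
        self.input_names = tuple(input_names)

        dup = set(self.state_names) & set(self.param_names)
        if dup:
            raise ModelConfigError(f"names used as both state and parameter: {dup}")

        self._x_syms = sp.symbols(self.state_names) if self.state_names else ()
        self._p_syms = sp.symbols(self.param_names) if self.param_names else ()
        self._u_syms = sp.symbols(self.input_names) if self.input_names else ()
        if len(self.state_names) == 1:
            self._x_syms = (self._x_syms,) if isinstance(self._x_syms, sp.Symbol) else self._x_syms
        if len(self.param_names) == 1 and isinstance(self._p_syms, sp.Symbol):
            self._p_syms = (self._p_syms,)
        if len(self.input_names) == 1 and isinstance(self._u_syms, sp.Symbol):
            self._u_syms = (self._u_syms,)

        ns = {s: sym for s, sym in zip(self.state_names, self._x_syms)}
        ns.update({p: sym for p, sym in zip(self.param_names, self._p_syms)})
        ns.update({u: sym for u, sym in zip(self.input_names, self._u_syms)})
        ns["t"] = _TIME
        self._namespace = ns

        self.rhs = {s: str(rhs[s]) for s in self.state_names}
        self._rhs_exprs = [_parse(rhs[s], ns) for s in self.state_names]
        self.observation_map = {k: str(v) for k, v in observation_map.items()}
        self._obs_exprs = {k: _parse(v, ns) for k, v in observation_map.items()}
        self.initial_values = dict(initial_values)
        if set(self.initial_values) != set(self.state_names):
            raise ModelConfigError("initial_values must cover every state exactly")
        par_ns = {p: sym for p, sym in zip(self.param_names, self._p_syms)}
        self._init_exprs = [_parse(self.initial_values[s], par_ns) for s in self.state_names]

        self.noise_sd = {k: float(v) for k, v in (noise_sd or {}).items()}
        for obs, sd in self.noise_sd.items():
            if obs not in self.observation_map:
                raise ModelConfigError(f"noise_sd given for unknown observable {obs!r}")
            if not sd > 0:
                raise ModelConfigError(f"noise_sd for {obs!r} must be > 0, got {sd}")

        self.default_theta = (
            None if default_theta is None else np.asarray(default_theta, dtype=float)
        )
        if bounds is not None:
            lo, hi = (np.asarray(b, dtype=float) for b in bounds)
            if lo.shape != hi.shape or lo.size != len(self.param_names):
                raise ModelConfigError("bounds must match the number of parameters")
            if np.any(lo >= hi):
                raise ModelConfigError("lower bounds must be below upper bounds")
            self.bounds = (lo, hi)
        else:
            self.bounds = None

        self._compile()

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # -- compilation -------------------------------------------------------

    def _compile(self) -> None:
        x, p, u = self._x_syms, self._p_syms, self._u_syms
        args = (_TIME, list(x), list(p), list(u))
        f_vec = sp.Matrix(self._rhs_exprs)
        self._rhs_fn = sp.lambdify(args, list(f_vec), modules="numpy")
        jac = f_vec.jacobian(list(x)) if x else sp.Matrix([])
        self._jac_fn = sp.lambdify(args, jac, modules="numpy")
        self._init_fn = sp.lambdify((list(p),), list(self._init_exprs), modules="numpy")
        self._obs_fns: dict[str, Callable] = {
            name: sp.lambdify((list(x), list(p), _TIME), expr, modules="numpy")
            for name, expr in self._obs_exprs.items()
        }
        self._expr_cache: dict[str, Callable] = {}

    def compile_expression(self, expr: str) -> Callable:
        """Compile an expression over states/parameters/t to ``fn(x_cols, theta, t)``.

        ``x_cols`` is a sequence of per-state arrays (trajectory columns), so the
        returned callable broadcasts over the whole time grid.
        """
        if expr in self._obs_fns:
            return self._obs_fns[expr]
        fn = self._expr_cache.get(expr)
        if fn is None:
            parsed = _parse(expr, self._namespace)
            if any(sym in parsed.free_symbols for sym in self._u_syms):
                raise ModelConfigError(
                    f"prediction expression {expr!r} may not reference inputs directly"
                )
            fn = sp.lambdify(
                (list(self._x_syms), list(self._p_syms), _TIME), parsed, modules="numpy"
            )
            self._expr_cache[expr] = fn
        return fn

    def initial_state(self, theta: np.ndarray) -> np.ndarray:
        return np.asarray(self._init_fn(list(np.asarray(theta, dtype=float))), dtype=float)

    def input_values(self, input_id: str, t: float = 0.0) -> list[float]:
        try:
            spec = self.inputs[input_id]
        except KeyError:
            raise ModelConfigError(
                f"unknown input condition {input_id!r}; defined: {sorted(self.inputs)}"
            ) from None
        vals = []
        for u_name in self.input_names:
            v = spec.get(u_name, 0.0)
            if isinstance(v, (list, tuple)):  # piecewise-constant [[t_start, value], ...]
                current = v[0][1]
                for t_start, value in v:
                    if t >= t_start:
                        current = value
                vals.append(float(current))
            else:
                vals.append(float(v))
        return vals

    def _input_breakpoints(self, input_id: str) -> list[float]:
        spec = self.inputs.get(input_id, {})
        pts: set[float] = set()
        for v in spec.values():
            if isinstance(v, (list, tuple)):
                pts.update(float(seg[0]) for seg in v)
        return sorted(p for p in pts if p > 0)

    def default_bounds(self, decades: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
        """A log-space box of ±``decades`` orders of magnitude around default_theta."""
        if self.default_theta is None:
            raise ModelConfigError(f"model {self.name!r} has no default parameter values")
        if self.bounds is not None:
            return self.bounds
        th = np.abs(self.default_theta)
        return th * 10.0 ** (-decades), th * 10.0 ** (decades)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ModelDefinition({self.name!r}, {self.n_states} states, "
            f"{self.n_params} parameters, observables={list(self.observation_map)})"
        )


# -- simulation ------------------------------------------------------------


def integrate(
    model: ModelDefinition,
    theta: np.ndarray,
    times: Sequence[float],
    input_id: str = "default",
) -> StateTrajectory:
    """Integrate the ODE system at ``theta`` and return states at ``times``.

    Integration always starts from the initial condition at t=0.  Piecewise
    input breakpoints restart the integrator so discontinuities are handled
    exactly.  Failure raises :class:`IntegrationError` carrying ``theta``.
    """
    from scipy.integrate import odeint

    theta = np.asarray(theta, dtype=float)
    if theta.size != model.n_params:
        raise ValueError(
            f"theta has length {theta.size}, model has {model.n_params} parameters"
        )
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < 0:
        raise ValueError("times must be non-negative")

    x0 = model.initial_state(theta)
    if not np.all(np.isfinite(x0)):
        raise IntegrationError("non-finite initial state", theta)

    p = list(theta)
    breakpoints = model._input_breakpoints(input_id)
    # segment the requested grid at input discontinuities
    seg_edges = [0.0] + [b for b in breakpoints if b < times[-1]] + [float(times[-1])]
    seg_edges = sorted(set(seg_edges))

    out = np.empty((times.size, model.n_states), dtype=float)
    filled = np.zeros(times.size, dtype=bool)
    x_cur = x0
    if times[0] == 0.0:
        out[0] = x0
        filled[0] = True

    rhs_fn, jac_fn = model._rhs_fn, model._jac_fn

    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        u = model.input_values(input_id, t=(a + b) / 2.0 if b > a else a)

        def f(x, t, _u=u):
            return rhs_fn(t, x, p, _u)

        def jac(x, t, _u=u):
            return jac_fn(t, x, p, _u)

        mask = (times > a) & (times <= b)
        t_seg = np.concatenate(([a], times[mask]))
        if t_seg[-1] < b:
            t_seg = np.concatenate((t_seg, [b]))
        if t_seg.size < 2:
            continue
        sol, info = odeint(
            f, x_cur, t_seg, Dfun=jac, rtol=model.rtol, atol=model.atol,
            full_output=True, mxstep=10000,
        )
        if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
            raise IntegrationError(
                f"ODE integration failed on [{a}, {b}]: {info['message']}", theta
            )
        n_req = int(mask.sum())
        out[mask] = sol[1 : 1 + n_req]
        filled[mask] = True
        x_cur = sol[-1]

    if not np.all(filled):  # pragma: no cover - defensive
        raise IntegrationError("internal grid bookkeeping error", theta)
    return StateTrajectory(times=times, states=out, state_names=model.state_names)


def observe(
    model: ModelDefinition,
    traj: StateTrajectory,
    theta: np.ndarray,
    observables: Sequence[str],
) -> np.ndarray:
    """Noise-free observable values on a trajectory: one column per observable."""
    theta = np.asarray(theta, dtype=float)
    cols = []
    x_cols = [traj.states[:, i] for i in range(traj.states.shape[1])]
    for name in observables:
        if name not in model.observation_map:
            raise ModelConfigError(
                f"unknown observable {name!r}; defined: {sorted(model.observation_map)}"
            )
        vals = model._obs_fns[name](x_cols, list(theta), traj.times)
        cols.append(np.broadcast_to(np.asarray(vals, dtype=float), traj.times.shape))
    return np.column_stack(cols)


def evaluate_expression(
    model: ModelDefinition,
    expr: str,
    traj: StateTrajectory,
    theta: np.ndarray,
) -> np.ndarray:
    """Evaluate an arbitrary state/parameter expression along a trajectory."""
    fn = model.compile_expression(expr)
    x_cols = [traj.states[:, i] for i in range(traj.states.shape[1])]
    vals = fn(x_cols, list(np.asarray(theta, dtype=float)), traj.times)
    return np.broadcast_to(np.asarray(vals, dtype=float), traj.times.shape).copy()


def predict(
    model: ModelDefinition, theta: np.ndarray, target: PredictionTarget
) -> float:
    """Model prediction z = F(D_pred, theta): ``g_pred`` at ``t_pred``."""
    times = np.array([0.0, target.t_pred]) if target.t_pred > 0 else np.array([0.0])
    traj = integrate(model, theta, times, input_id=target.input_id)
    vals = evaluate_expression(model, target.g_pred, traj, theta)
    return float(vals[-1])


# -- persistence -----------------------------------------------------------


def load_model(path) -> ModelDefinition:
    """Load a model declaration from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return model_from_dict(cfg)


def model_from_dict(cfg: Mapping) -> ModelDefinition:
    bounds = cfg.get("bounds")
    if bounds is not None:
        bounds = (bounds["lower"], bounds["upper"])
    return ModelDefinition(
        state_names=cfg["states"],
        param_names=cfg["parameters"],
        rhs=cfg["rhs"],
        observation_map=cfg["observables"],
        initial_values=cfg["initial_values"],
        noise_sd=cfg.get("noise_sd"),
        inputs=cfg.get("inputs"),
        default_theta=cfg.get("default_theta"),
        bounds=bounds,
        name=cfg.get("name", "model"),
    )


def model_to_dict(model: ModelDefinition) -> dict:
    cfg = {
        "name": model.name,
        "states": list(model.state_names),
        "parameters": list(model.param_names),
        "rhs": dict(model.rhs),
        "observables": dict(model.observation_map),
        "initial_values": {
            k: (v if isinstance(v, str) else float(v))
            for k, v in model.initial_values.items()
        },
        "noise_sd": dict(model.noise_sd),
        "inputs": model.inputs,
    }
    if model.default_theta is not None:
        cfg["default_theta"] = [float(v) for v in model.default_theta]
    if model.bounds is not None:
        cfg["bounds"] = {
            "lower": [float(v) for v in model.bounds[0]],
            "upper": [float(v) for v in model.bounds[1]],
        }
    return cfg


def save_model(model: ModelDefinition, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def trajectory_to_csv(traj: StateTrajectory, path) -> None:
    """Write a trajectory as CSV with header ``time,<state1>,...,<stateN>``."""
    import pandas as pd

    df = pd.DataFrame(traj.states, columns=list(traj.state_names))
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False)
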