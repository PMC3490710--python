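"""Likelihood computation, maximum-likelihood fitting and parameter profiles.

For additive Gaussian noise with known per-record SDs the objective is the
residual sum of squares

    -2 LL(y | theta) = sum_i (y_i - F(t_i, u, theta))^2 / sigma_i^2

up to an additive constant that is dropped throughout (all interval
constructions threshold *differences* of -2 LL, so the constant cancels).

Fitting is multi-start weighted least squares.  Positivity of rates and
concentrations is enforced by optimizing in log-parameter space; results are
reported on the natural scale.  Parameter confidence intervals come from the
profile likelihood: each parameter is scanned while all others are
re-optimized, and the interval is the set of values whose -2 PL stays within a
chi-square(1) quantile of the global optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import chi2, qmc

from .model_core import (
    ExperimentalDesign,
    IntegrationError,
    ModelDefinition,
    PredictionTarget,
    evaluate_expression,
    integrate,
)

__all__ = [
    "Dataset",
    "FitResult",
    "ProfileCurve",
    "ConfidenceInterval",
    "FitError",
    "Objective",
    "neg2_loglik",
    "fit",
    "profile_parameter",
    "interval_from_curve",
    "read_data_csv",
    "write_data_csv",
]

_FAIL_RESIDUAL = 1e4  # sentinel residual magnitude when integration fails


class FitError(RuntimeError):
    """All optimization starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class Dataset:
    """Time-course measurements: records (time, observable, value, sigma).

    ``sigma`` is the known Gaussian noise SD of each record.  The associated
    :class:`ExperimentalDesign` identifies the stimulation condition.
    """

    records: pd.DataFrame
    design: ExperimentalDesign

    REQUIRED = ("time", "observable", "value", "sigma")

    def __post_init__(self):
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing column(s) {missing}")
        if not np.all(df["sigma"].to_numpy() > 0):
            raise ValueError("all sigma values must be > 0")
        if not np.all(np.isfinite(df[["time", "value", "sigma"]].to_numpy())):
            raise ValueError("dataset contains non-finite entries")
        object.__setattr__(
            self, "records", df.reset_index(drop=True)[list(self.REQUIRED)]
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def scale(self) -> float:
        """Typical magnitude of the data (robust max of |value|), used to set
        penalty SDs and plausibility limits for prediction scans."""
        v = np.abs(self.records["value"].to_numpy())
        return float(max(np.quantile(v, 0.95), np.max(self.records["sigma"]), 1e-12))


def write_data_csv(data: Dataset, path) -> None:
    data.records.to_csv(path, index=False)


def read_data_csv(path, input_id: str = "default") -> Dataset:
    """Read a measurement CSV (columns time,observable,value,sigma)."""
    df = pd.read_csv(path)
    times = np.unique(df["time"].to_numpy(dtype=float))
    design = ExperimentalDesign(
        times=tuple(times),
        observables=tuple(pd.unique(df["observable"])),
        input_id=input_id,
    )
    return Dataset(records=df, design=design)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start maximum-likelihood fit."""

    theta_hat: np.ndarray
    neg2LL_star: float
    n_starts: int
    converged_fraction: float
    seed: int
    bounds: tuple[np.ndarray, np.ndarray]
    log_scale: bool = True
    start_values: tuple[float, ...] = ()

    def __post_init__(self):
        if self.neg2LL_star < -1e-9:
            raise ValueError("residual sum of squares cannot be negative")


@dataclass
class ProfileCurve:
    """A scanned profile: grid of the profiled quantity vs -2 * profile-log-likelihood.

    ``kind`` distinguishes parameter profiles, prediction profiles (PPL) and
    validation profiles (VPL).  ``left_crossed`` / ``right_crossed`` record
    whether the curve exceeded the threshold (plus margin) before the scan
    limit; a side that never crossed signals an unbounded interval
    (non-observability / non-identifiability), unless the side terminated at a
    feasibility or domain boundary (``*_status == "boundary"``).
    """

    grid: np.ndarray
    neg2PL: np.ndarray
    neg2LL_star: float
    kind: str  # "parameter" | "prediction" | "validation"
    left_crossed: bool
    right_crossed: bool
    left_status: str = "crossed"  # "crossed" | "unbounded" | "boundary"
    right_status: str = "crossed"
    fitted_response: np.ndarray | None = None  # z' = F(D, theta*) per grid point
    data_rss: np.ndarray | None = None  # data-only RSS at each scan optimum
    thetas: list | None = None
    n_failed: int = 0
    unreliable: bool = False
    degenerate: bool = False  # prediction pinned by the model: zero-width interval
    label: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.neg2PL = np.asarray(self.neg2PL, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.neg2PL.shape:
            raise ValueError("grid and neg2PL must be 1-D arrays of equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("profile grid must be strictly increasing")
        if self.neg2PL.size and self.neg2PL.min() < self.neg2LL_star - 1e-6:
            raise ValueError(
                "profile dips below the global optimum: "
                f"min -2PL = {self.neg2PL.min():.6g} < -2LL* = {self.neg2LL_star:.6g}"
            )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"grid": self.grid, "neg2PL": self.neg2PL})
        if self.fitted_response is not None:
            df["fitted_response"] = self.fitted_response
        return df


@dataclass(frozen=True)
class ConfidenceInterval:
    """A likelihood-based interval at level alpha.

    An infinite bound (with the matching ``unbounded_*`` flag) means the
    profile never crossed the threshold on that side within the scan — the
    operational signature of practical non-identifiability (parameters) or
    non-observability (predictions).
    """

    lower: float
    upper: float
    alpha: float
    threshold_used: float
    unbounded_lower: bool = False
    unbounded_upper: bool = False

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if (
            math.isfinite(self.lower)
            and math.isfinite(self.upper)
            and self.lower > self.upper + 1e-12
        ):
            raise ValueError("interval lower bound exceeds upper bound")

    def contains(self, value: float) -> bool:
        lo = -math.inf if self.unbounded_lower else self.lower
        hi = math.inf if self.unbounded_upper else self.upper
        return lo <= value <= hi

    @property
    def width(self) -> float:
        if self.unbounded_lower or self.unbounded_upper:
            return math.inf
        return self.upper - self.lower

    def to_dict(self) -> dict:
        return {
            "lower": None if self.unbounded_lower else float(self.lower),
            "upper": None if self.unbounded_upper else float(self.upper),
            "alpha": float(self.alpha),
            "threshold": float(self.threshold_used),
            "unbounded_left": bool(self.unbounded_lower),
            "unbounded_right": bool(self.unbounded_upper),
        }


# -- objective -------------------------------------------------------------


class Objective:
    """Weighted-residual objective for a model/dataset pair.

    One ODE integration per parameter vector covers all measurement times and
    (optionally) a prediction time, shared between the data residuals and any
    validation penalty.  Integration failures yield a large constant residual
    vector so optimizers back away instead of crashing; failures are counted.
    """

    def __init__(
        self,
        model: ModelDefinition,
        data: Dataset | None,
        target: PredictionTarget | None = None,
    ):
        self.model = model
        self.data = data
        self.target = target
        self.n_failures = 0

        # group integration requests by input condition
        self._groups: list[dict] = []
        if data is not None and len(data):
            df = data.records
            times = np.unique(np.concatenate(([0.0], df["time"].to_numpy(dtype=float))))
            grp = {
                "input_id": data.design.input_id,
                "times": times,
                "time_index": {t: i for i, t in enumerate(times)},
                "data_rows": [],
                "pred": None,
            }
            t_idx = [grp["time_index"][t] for t in df["time"].to_numpy(dtype=float)]
            grp["data_rows"] = (
                np.asarray(t_idx, dtype=int),
                list(df["observable"]),
                df["value"].to_numpy(dtype=float),
                df["sigma"].to_numpy(dtype=float),
            )
            grp["obs_sel"] = {
                name: np.asarray(
                    [i for i, o in enumerate(df["observable"]) if o == name], dtype=int
                )
                for name in dict.fromkeys(df["observable"])
            }
            self._groups.append(grp)
        if target is not None:
            grp = next(
                (g for g in self._groups if g["input_id"] == target.input_id), None
            )
            if grp is None or target.t_pred not in grp["time_index"]:
                if grp is not None:
                    times = np.unique(np.append(grp["times"], target.t_pred))
                    grp["times"] = times
                    grp["time_index"] = {t: i for i, t in enumerate(times)}
                    t_old = self.data.records["time"].to_numpy(dtype=float)
                    grp["data_rows"] = (
                        np.asarray([grp["time_index"][t] for t in t_old], dtype=int),
                    ) + grp["data_rows"][1:]
                else:
                    times = np.unique(np.array([0.0, target.t_pred]))
                    grp = {
                        "input_id": target.input_id,
                        "times": times,
                        "time_index": {t: i for i, t in enumerate(times)},
                        "data_rows": None,
                        "pred": None,
                    }
                    self._groups.append(grp)
            grp["pred"] = (grp["time_index"][target.t_pred], target.g_pred)

        self.n_data = 0 if data is None else len(data)

    def simulate(self, theta: np.ndarray) -> tuple[np.ndarray, float | None]:
        """Return (weighted data residuals, prediction value or None)."""
        residuals = np.empty(self.n_data, dtype=float)
        pred_value: float | None = None
        pos = 0
        for grp in self._groups:
            traj = integrate(self.model, theta, grp["times"], input_id=grp["input_id"])
            if grp["data_rows"] is not None:
                t_idx, obs_names, values, sigmas = grp["data_rows"]
                sim = np.empty(len(obs_names), dtype=float)
                # evaluate each distinct observable once over the trajectory
                for name, sel in grp["obs_sel"].items():
                    col = evaluate_expression(self.model, name, traj, theta)
                    sim[sel] = col[t_idx[sel]]
                n = len(obs_names)
                residuals[pos : pos + n] = (values - sim) / sigmas
                pos += n
            if grp["pred"] is not None:
                i_pred, expr = grp["pred"]
                col = evaluate_expression(self.model, expr, traj, theta)
                pred_value = float(col[i_pred])
        return residuals, pred_value

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        try:
            r, _ = self.simulate(theta)
        except IntegrationError:
            self.n_failures += 1
            r = np.full(max(self.n_data, 1), _FAIL_RESIDUAL)
        return r

    def neg2_loglik(self, theta: np.ndarray) -> float:
        r = self.residuals(theta)
        return float(r @ r)

    def predict(self, theta: np.ndarray) -> float:
        if self.target is None:
            raise ValueError("objective was built without a prediction target")
        _, z = self.simulate(theta)
        return z


def neg2_loglik(model: ModelDefinition, theta: np.ndarray, data: Dataset) -> float:
    """-2 log-likelihood of the data (constant dropped): the weighted RSS."""
    return Objective(model, data).neg2_loglik(np.asarray(theta, dtype=float))


# -- fitting ---------------------------------------------------------------


def _to_internal(theta, log_scale):
    theta = np.asarray(theta, dtype=float)
    return np.log(theta) if log_scale else theta


def _from_internal(x, log_scale):
    return np.exp(x) if log_scale else np.asarray(x, dtype=float)


def _minimize_residuals(
    res_fn: Callable,
    x0: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    ftol: float = 1e-10,
    xtol: float = 1e-10,
    max_nfev: int | None = None,
):
    # Finite-difference Jacobian with an *absolute* step in the (log-scaled)
    # optimization variables: scipy's relative stepping collapses near x = 0
    # (log-parameters close to 1) and at the default ~1e-8 step it samples
    # ODE-integration error, not gradient.
    from scipy.optimize._numdiff import approx_derivative

    def jac(x):
        return approx_derivative(
            res_fn, x, method="2-point", abs_step=1e-5, bounds=(lb, ub)
        )

    x0 = np.clip(x0, lb, ub)
    return least_squares(
        res_fn, x0, bounds=(lb, ub), method="trf", jac=jac,
        xtol=xtol, ftol=ftol, gtol=1e-8, x_scale="jac", max_nfev=max_nfev,
    )


def fit(
    model: ModelDefinition,
    data: Dataset,
    n_starts: int = 20,
    seed: int = 0,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
    x0: Sequence[float] | None = None,
    log_scale: bool = True,
) -> FitResult:
    """Multi-start maximum-likelihood (weighted least-squares) fit.

    Starts are the initial guess ``x0`` (default: the model's reference
    parameters) plus ``n_starts - 1`` Latin-hypercube samples drawn in
    log-space inside the bounds box.  Deterministic for a given ``seed``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if bounds is None:
        bounds = model.default_bounds()
    lb_nat, ub_nat = (np.asarray(b, dtype=float) for b in bounds)
    if log_scale and np.any(lb_nat <= 0):
        raise ValueError("log-scale fitting requires strictly positive lower bounds")
    lb, ub = _to_internal(lb_nat, log_scale), _to_internal(ub_nat, log_scale)

    obj = Objective(model, data)

    def res_fn(x):
        return obj.residuals(_from_internal(x, log_scale))

    starts = []
    if x0 is not None:
        starts.append(_to_internal(x0, log_scale))
    elif model.default_theta is not None:
        starts.append(_to_internal(model.default_theta, log_scale))
    n_lhs = n_starts - len(starts)
    if n_lhs > 0:
        sampler = qmc.LatinHypercube(d=len(lb), seed=int(seed))
        unit = sampler.random(n_lhs)
        starts.extend(lb + unit * (ub - lb))
    starts = starts[:n_starts]

    best = None
    diagnostics = []
    n_ok = 0
    for k, s in enumerate(starts):
        try:
            sol = _minimize_residuals(res_fn, s, lb, ub)
        except Exception as exc:  # noqa: BLE001 - per-start robustness
            diagnostics.append({"start": k, "error": str(exc)})
            continue
        cost = 2.0 * sol.cost  # least_squares cost = 0.5 * sum r^2
        ok = bool(sol.success) and cost < (_FAIL_RESIDUAL**2) * max(len(data), 1) * 0.5
        diagnostics.append({"start": k, "neg2LL": cost, "success": ok})
        if ok:
            n_ok += 1
            if best is None or cost < best[0]:
                best = (cost, sol.x)
    if best is None:
        raise FitError("all optimization starts failed", diagnostics)

    theta_hat = _from_internal(best[1], log_scale)
    return FitResult(
        theta_hat=theta_hat,
        neg2LL_star=float(best[0]),
        n_starts=len(starts),
        converged_fraction=n_ok / len(starts),
        seed=int(seed),
        bounds=(lb_nat, ub_nat),
        log_scale=log_scale,
        start_values=tuple(float(d["neg2LL"]) for d in diagnostics if "neg2LL" in d),
    )


# -- adaptive profile marching --------------------------------------------


class PointInfeasible(Exception):
    """A scan point cannot satisfy its constraint (e.g. negative concentration).

    ``at_bounds=True`` means the failure happened with parameters pinned at
    the fitting-bounds box rather than at a structural limit of the model; the
    scan side is then reported unbounded (the box, not the model, stopped it).
    """

    def __init__(self, message: str, at_bounds: bool = False):
        super().__init__(message)
        self.at_bounds = at_bounds


def adaptive_march(
    evaluate: Callable,
    z0: float,
    q0: float,
    theta0: np.ndarray,
    *,
    direction: int,
    threshold: float,
    margin: float,
    target_fraction: float,
    init_step: float,
    min_step: float,
    max_step: float,
    max_steps: int,
    z_limits: tuple[float, float],
    limit_status: str = "unbounded",
    march_stat: Callable | None = None,
    refine: bool = True,
) -> dict:
    """March a profile outward from the optimum in one direction.

    ``evaluate(z, warm_theta) -> (q, theta, extra)`` re-optimizes the nuisance
    parameters at the scan point ``z``.  The step size adapts so each step
    raises -2 PL by roughly ``target_fraction * threshold``; the side stops
    once the curve exceeds ``q0 + threshold + margin`` (status ``crossed``),
    the scan budget or plausibility window is exhausted (``unbounded``), or
    the constraint becomes infeasible (``boundary``).

    ``march_stat(q, extra)``, when given, replaces ``q`` in the stopping and
    step-adaptation rules (the curve still stores ``q``); the penalized
    prediction-profile route uses it to march on the data-only RSS.

    With ``refine`` (default) each completed side gets a backward sweep:
    every point is re-optimized warm-started from its *outer* neighbor and
    the lower value kept.  Warm chains can switch likelihood branches along
    the scan (e.g. exchangeable-parameter models); the sweep recovers the
    lower envelope, and the march resumes if the threshold crossing dissolves.
    """
    zs: list[float] = []
    qs: list[float] = []
    thetas: list[np.ndarray] = []
    extras: list = []
    status = "unbounded"
    n_failed = 0

    stop_level = q0 + threshold + margin
    dz = init_step
    s0 = q0 if march_stat is None else march_stat(q0, None)
    z_prev, s_prev, warm = z0, s0, theta0
    lo, hi = z_limits
    target_dq = target_fraction * threshold

    def stat(q, extra):
        return q if march_stat is None else march_stat(q, extra)

    budget = max_steps

    for _round in range(4):
        # -- outward march ------------------------------------------------
        while budget > 0:
            budget -= 1
            z = z_prev + direction * dz
            if z < lo or z > hi:
                z = float(np.clip(z, lo, hi))
                if abs(z - z_prev) < min_step * 1e-3:
                    status = limit_status
                    break
            try:
                q, theta, extra = evaluate(z, warm)
                failed = False
            except PointInfeasible as exc:
                # the step may simply have overshot the feasible region
                # (flat profiles race to the maximum step); walk back to the
                # feasibility edge before declaring the side finished
                if dz > 4.0 * min_step:
                    dz *= 0.25
                    continue
                status = limit_status if exc.at_bounds else "boundary"
                break
            except IntegrationError:
                n_failed += 1
                failed = True
            if not failed:
                zs.append(float(z))
                qs.append(float(q))
                thetas.append(np.asarray(theta, dtype=float))
                extras.append(extra)
                warm = theta
                s = stat(q, extra)
                if s >= stop_level:
                    status = "crossed"
                    break
                ds = abs(s - s_prev)
                factor = target_dq / max(ds, target_dq / 10.0)
                dz = float(np.clip(dz * np.clip(factor, 0.3, 3.0), min_step, max_step))
                z_prev, s_prev = z, s
            else:
                # skip over a failing point; do not adapt on it
                z_prev = z
            if z_prev <= lo or z_prev >= hi:
                status = limit_status if status != "crossed" else status
                break
        else:
            status = limit_status if status not in ("crossed", "boundary") else status

        if not refine or len(zs) < 2:
            break
        # -- backward lower-envelope sweep --------------------------------
        improved = False
        for i in range(len(zs) - 2, -1, -1):
            try:
                q2, th2, ex2 = evaluate(zs[i], thetas[i + 1])
            except (PointInfeasible, IntegrationError):
                continue
            if q2 < qs[i] - 1e-9:
                qs[i], thetas[i], extras[i] = float(q2), np.asarray(th2, float), ex2
                improved = True
        if status != "crossed" or budget <= 0:
            break
        s_last = stat(qs[-1], extras[-1])
        if s_last >= stop_level:
            break
        # the crossing dissolved after refinement: resume marching outward
        status = "unbounded"
        z_prev, s_prev, warm = zs[-1], s_last, thetas[-1]

    return {
        "z": zs,
        "q": qs,
        "thetas": thetas,
        "extras": extras,
        "status": status,
        "n_failed": n_failed,
    }


def assemble_curve(
    left: dict,
    center: tuple[float, float, np.ndarray, object],
    right: dict,
    neg2LL_star: float,
    kind: str,
    label: str = "",
) -> ProfileCurve:
    """Combine one-sided marches and the central optimum into a ProfileCurve."""
    z0, q0, theta0, extra0 = center
    zs = left["z"][::-1] + [z0] + right["z"]
    qs = left["q"][::-1] + [q0] + right["q"]
    thetas = left["thetas"][::-1] + [theta0] + right["thetas"]
    extras = left["extras"][::-1] + [extra0] + right["extras"]

    order = np.argsort(zs, kind="stable")
    zs = np.asarray(zs)[order]
    qs = np.asarray(qs)[order]
    thetas = [thetas[i] for i in order]
    extras = [extras[i] for i in order]
    keep = np.concatenate(([True], np.diff(zs) > 0))
    zs, qs = zs[keep], qs[keep]
    thetas = [t for t, k in zip(thetas, keep) if k]
    extras = [e for e, k in zip(extras, keep) if k]

    n_failed = left["n_failed"] + right["n_failed"]
    n_total = len(zs) + n_failed
    fitted = None
    data_rss = None
    if extras and all(isinstance(e, tuple) and len(e) == 2 for e in extras):
        fitted = np.asarray([e[0] for e in extras], dtype=float)
        data_rss = np.asarray([e[1] for e in extras], dtype=float)
    # the scan may discover a marginally better optimum than the fit
    # (warm-started re-optimizations explore more of parameter space);
    # the improved value becomes the reference for thresholding
    neg2LL_star = min(float(neg2LL_star), float(np.min(qs)))
    if data_rss is not None:
        neg2LL_star = min(neg2LL_star, float(np.min(data_rss)))
    return ProfileCurve(
        grid=zs,
        neg2PL=qs,
        neg2LL_star=neg2LL_star,
        kind=kind,
        left_crossed=left["status"] == "crossed",
        right_crossed=right["status"] == "crossed",
        left_status=left["status"],
        right_status=right["status"],
        fitted_response=fitted,
        data_rss=data_rss,
        thetas=thetas,
        n_failed=n_failed,
        unreliable=(n_failed > 0.2 * max(n_total, 1)),
        label=label,
    )


# -- interval extraction ---------------------------------------------------


def _localize_crossing(
    z_in: float, q_in: float, z_out: float, q_out: float,
    z_in2: float | None, q_in2: float | None, level: float,
) -> float:
    """Crossing of the level inside the bracket [z_in, z_out].

    A local quadratic through the bracketing points and the next inner point
    localizes the crossing to high accuracy on smooth profiles; degenerate
    configurations fall back to linear interpolation on the bracket.
    """
    frac = (level - q_in) / (q_out - q_in)
    linear = z_in + frac * (z_out - z_in)
    if z_in2 is None or q_in2 is None:
        return float(linear)
    zs = np.array([z_in2, z_in, z_out])
    qs = np.array([q_in2, q_in, q_out])
    if len(set(zs)) < 3:
        return float(linear)
    try:
        coeffs = np.polyfit(zs - z_in, qs, 2)
    except np.linalg.LinAlgError:  # pragma: no cover
        return float(linear)
    coeffs = coeffs.copy()
    coeffs[2] -= level
    roots = np.roots(coeffs)
    roots = roots[np.isreal(roots)].real + z_in
    lo, hi = min(z_in, z_out), max(z_in, z_out)
    inside = [r for r in roots if lo - 1e-12 * (hi - lo + 1) <= r <= hi + 1e-12 * (hi - lo + 1)]
    if not inside:
        return float(linear)
    # the root nearest to the linear estimate within the bracket
    return float(min(inside, key=lambda r: abs(r - linear)))


def interval_from_curve(curve: ProfileCurve, threshold: float) -> ConfidenceInterval:
    """Threshold a profile curve into a likelihood-based confidence interval.

    The interval is ``{z : -2 profile(z) <= -2 LL* + threshold}``.  Crossings
    are localized inside the outermost bracketing grid points (conservative on
    a non-monotone side) by local quadratic interpolation.  A side that never
    crossed within the scan is flagged unbounded unless the scan stopped at a
    feasibility/domain boundary, in which case the boundary grid point bounds
    the interval.
    """
    alpha = float(chi2.cdf(threshold, df=1)) if threshold > 0 else 1e-12
    alpha = min(max(alpha, 1e-12), 1 - 1e-12)

    if curve.degenerate:
        z0 = float(curve.grid[int(np.argmin(curve.neg2PL))])
        return ConfidenceInterval(
            lower=z0, upper=z0, alpha=alpha, threshold_used=float(threshold)
        )
    if curve.grid.size < 3:
        raise ValueError("profile curve needs at least 3 points")
    level = curve.neg2LL_star + threshold
    q = curve.neg2PL
    z = curve.grid
    i_min = int(np.argmin(q))
    if q[i_min] > level + 1e-9:
        raise ValueError(
            "profile minimum lies above the threshold level; the curve does not "
            "touch its own optimum"
        )

    def cross(side: str) -> tuple[float, bool]:
        if side == "left":
            idx = list(range(0, i_min + 1))  # outermost first
            status = curve.left_status
        else:
            idx = list(range(len(z) - 1, i_min - 1, -1))
            status = curve.right_status
        # outermost grid point already inside the level set
        first_in = next(i for i in idx if q[i] <= level)
        pos = idx.index(first_in)
        if pos == 0:
            # the scan's edge is inside the interval: bound only if the side
            # ended at a hard boundary, else unbounded
            if status == "boundary":
                return float(z[first_in]), False
            return (-math.inf if side == "left" else math.inf), True
        j_out = idx[pos - 1]  # outer bracketing point, q > level
        j_in2 = idx[pos + 1] if pos + 1 < len(idx) else None
        value = _localize_crossing(
            float(z[first_in]), float(q[first_in]),
            float(z[j_out]), float(q[j_out]),
            None if j_in2 is None else float(z[j_in2]),
            None if j_in2 is None else float(q[j_in2]),
            level,
        )
        return value, False

    lower, unb_lo = cross("left")
    upper, unb_hi = cross("right")
    return ConfidenceInterval(
        lower=lower,
        upper=upper,
        alpha=alpha,
        threshold_used=float(threshold),
        unbounded_lower=unb_lo,
        unbounded_upper=unb_hi,
    )


# -- parameter profiles ----------------------------------------------------


@dataclass(frozen=True)
class ParameterScanConfig:
    """Stepping control for parameter profiles (log-space scan)."""

    target_fraction: float = 0.2
    max_steps_per_side: int = 200
    threshold_margin: float = 1.0
    init_step: float = 0.05  # log10-free: natural-log units
    min_step: float = 1e-4
    max_step: float = 1.0


def profile_parameter(
    model: ModelDefinition,
    data: Dataset,
    fit_result: FitResult,
    j: int,
    alpha: float = 0.9,
    scan: ParameterScanConfig | None = None,
) -> tuple[ProfileCurve, ConfidenceInterval]:
    """Profile likelihood of parameter ``j`` with a likelihood-based CI.

    At each grid value of theta_j all other parameters are re-optimized,
    warm-started from the neighboring point.  The scan is performed in
    log-space (multiplicative steps) and reported on the natural scale; a side
    that reaches the bounds box without crossing the threshold is flagged
    unbounded — the signature of practical non-identifiability.
    """
    scan = scan or ParameterScanConfig()
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    threshold = float(chi2.ppf(alpha, df=1))
    obj = Objective(model, data)
    log_scale = fit_result.log_scale
    lb_nat, ub_nat = fit_result.bounds
    lb, ub = _to_internal(lb_nat, log_scale), _to_internal(ub_nat, log_scale)
    x_hat = _to_internal(fit_result.theta_hat, log_scale)
    free = [i for i in range(len(x_hat)) if i != j]

    def evaluate(zj: float, warm: np.ndarray):
        x_full = np.asarray(warm, dtype=float).copy()
        x_full[j] = zj

        def res_fn(x_free):
            x_full[free] = x_free
            return obj.residuals(_from_internal(x_full, log_scale))

        if free:
            sol = _minimize_residuals(
                res_fn, x_full[free], lb[free], ub[free], ftol=1e-9, max_nfev=60
            )
            x_full[free] = sol.x
            q = 2.0 * sol.cost
        else:
            r = obj.residuals(_from_internal(x_full, log_scale))
            q = float(r @ r)
        return q, x_full, None

    common = dict(
        threshold=threshold,
        margin=scan.threshold_margin,
        target_fraction=scan.target_fraction,
        init_step=scan.init_step,
        min_step=scan.min_step,
        max_step=scan.max_step,
        max_steps=scan.max_steps_per_side,
        z_limits=(float(lb[j]), float(ub[j])),
    )
    z0, q0 = float(x_hat[j]), float(fit_result.neg2LL_star)
    left = adaptive_march(evaluate, z0, q0, x_hat, direction=-1, **common)
    right = adaptive_march(evaluate, z0, q0, x_hat, direction=+1, **common)
    curve_internal = assemble_curve(
        left, (z0, q0, x_hat, None), right, q0, kind="parameter",
        label=model.param_names[j],
    )
    # report on the natural scale
    grid_nat = _from_internal(curve_internal.grid, log_scale)
    curve = ProfileCurve(
        grid=grid_nat,
        neg2PL=curve_internal.neg2PL,
        neg2LL_star=q0,
        kind="parameter",
        left_crossed=curve_internal.left_crossed,
        right_crossed=curve_internal.right_crossed,
        left_status=curve_internal.left_status,
        right_status=curve_internal.right_status,
        thetas=[_from_internal(x, log_scale) for x in curve_internal.thetas],
        n_failed=curve_internal.n_failed,
        unreliable=curve_internal.unreliable,
        label=curve_internal.label,
    )
    ci = interval_from_curve(curve, threshold)
    return curve, ci
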