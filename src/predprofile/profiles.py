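"""Prediction and validation profile likelihood.

The prediction profile likelihood (PPL) for a prediction condition is the
maximum of the data likelihood over all parameter vectors constrained to
produce a given prediction value z:

    PPL(z) = max_{theta : F(D_pred, theta) = z} LL(y | theta)

Thresholding -2 PPL at the chi-square(1) alpha-quantile above the global
optimum yields the prediction confidence interval (PCI) — the set of
predictions consistent with the data at level alpha.  No parameter sampling
is involved: the one-dimensional prediction space is scanned directly and
each scan point is a constrained re-optimization, so the construction works
even when parameters are structurally or practically non-identifiable.

The validation profile likelihood (VPL) replaces the hard constraint by a
quadratic penalty that treats a hypothetical future measurement z with error
SD exactly like a data point:

    -2 VPL_SD(z) = min_theta [ RSS(theta | y) + (z - F(D_vali, theta))^2 / SD^2 ]

Its interval (VCI) covers the outcome of a *noisy* validation experiment and
always contains the PCI.  Because at the penalized optimum the penalty
gradient plays the role of the constraint's Lagrange multiplier, the data-only
RSS at each scan optimum *is* the prediction profile value at the fitted
response z' = F(D_vali, theta*):

    -2 PPL(z') = -2 VPL_SD(z) - (z - z')^2 / SD^2

With a small penalty SD this rescaling turns an ordinary least-squares scan
into the constrained profile, avoiding hard constraint optimization; the
direct equality-constrained scan is retained as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .estimation import (
    ConfidenceInterval,
    Dataset,
    FitResult,
    Objective,
    PointInfeasible,
    ProfileCurve,
    _from_internal,
    _minimize_residuals,
    _to_internal,
    adaptive_march,
    assemble_curve,
    fit as _fit,
    interval_from_curve,
)
from .model_core import (
    IntegrationError,
    ModelDefinition,
    PredictionTarget,
)

__all__ = [
    "ScanConfig",
    "ValidationSetup",
    "MonteCarloConfig",
    "vpl_scan",
    "ppl_scan",
    "rescale_vpl_to_ppl",
    "interval_from_curve",
    "threshold",
    "prediction_interval",
    "validation_interval",
]


@dataclass(frozen=True)
class ScanConfig:
    """Stepping control for prediction/validation profile scans.

    ``step_rule`` is the target increase of -2 PL per scan step as a fraction
    of the threshold; the scan of each side stops once the curve exceeds the
    stop threshold (the chi-square(1) ``alpha``-quantile) plus
    ``threshold_margin``, hits ``max_steps_per_side``, or leaves the
    plausibility window of ``plausibility_factor`` times the data scale
    (the latter two flag the side unbounded).  ``constraint_sd_fraction``
    sets the penalty SD of the penalized-constraint route as a fraction of
    the prediction scale.
    """

    step_rule: float = 0.2
    max_steps_per_side: int = 200
    threshold_margin: float = 1.0
    constraint_sd_fraction: float = 1e-3
    alpha: float = 0.9
    plausibility_factor: float = 10.0
    init_step_fraction: float = 0.01
    min_step_fraction: float = 1e-5
    max_step_fraction: float = 0.5
    refine: bool = True  # backward lower-envelope sweep (see adaptive_march)

    def __post_init__(self):
        if self.max_steps_per_side < 10:
            raise ValueError("max_steps_per_side must be >= 10")
        if not (0 < self.constraint_sd_fraction <= 0.01):
            raise ValueError("constraint_sd_fraction must be in (0, 0.01]")
        if self.threshold_margin < 0:
            raise ValueError("threshold_margin must be >= 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ValidationSetup:
    """A future validation measurement: its condition and measurement error SD."""

    target: PredictionTarget
    SD: float

    def __post_init__(self):
        if not self.SD > 0:
            raise ValueError("validation measurement SD must be > 0")


def _scan_profile(
    model: ModelDefinition,
    data: Dataset,
    target: PredictionTarget,
    fit_result: FitResult,
    scan: ScanConfig,
    SD: float,
    kind: str,
    march_on_data_rss: bool = False,
) -> ProfileCurve:
    """Shared penalized scan driving both VPL and the penalized PPL route.

    For the penalized prediction profile (``march_on_data_rss=True``) the
    stopping and step-adaptation rules follow the data-only RSS — the
    quantity that becomes the PPL after rescaling — and a scan point whose
    penalty term blows up (the model response cannot approach the requested
    z) terminates the side at the feasibility boundary.
    """
    obj = Objective(model, data, target=target)
    log_scale = fit_result.log_scale
    lb, ub = (
        _to_internal(fit_result.bounds[0], log_scale),
        _to_internal(fit_result.bounds[1], log_scale),
    )
    x_hat = _to_internal(fit_result.theta_hat, log_scale)
    z_hat = obj.predict(fit_result.theta_hat)
    q_star = float(fit_result.neg2LL_star)

    scale = max(abs(z_hat), data.scale)
    stop_threshold = float(chi2.ppf(scan.alpha, df=1))
    # a penalty this large means the model response cannot reach z at all
    penalty_cap = 50.0 * (stop_threshold + scan.threshold_margin)

    def evaluate(z: float, warm: np.ndarray):
        def res_fn(x):
            theta = _from_internal(x, log_scale)
            try:
                r, F = obj.simulate(theta)
            except IntegrationError:
                obj.n_failures += 1
                return np.full(obj.n_data + 1, 1e4)
            return np.append(r, (z - F) / SD)

        sol = _minimize_residuals(
            res_fn, np.asarray(warm, dtype=float), lb, ub, ftol=1e-9, max_nfev=60
        )
        theta_nat = _from_internal(sol.x, log_scale)
        r, F = obj.simulate(theta_nat)
        data_rss = float(r @ r)
        penalty = (z - F) ** 2 / SD**2
        if march_on_data_rss and penalty > penalty_cap:
            span = ub - lb
            pinned = bool(
                np.any((sol.x - lb) < 1e-6 * span) or np.any((ub - sol.x) < 1e-6 * span)
            )
            # a pinned stall right next to zero is the positivity limit of a
            # concentration-like prediction (the box merely truncates the
            # approach to 0); a pinned stall far from zero is a box artifact
            # and the side counts as unbounded
            near_zero = abs(z) <= 0.05 * scale
            raise PointInfeasible(
                f"model response cannot approach z={z:g} (reached {F:g})",
                at_bounds=pinned and not near_zero,
            )
        q = data_rss + penalty
        return q, sol.x, (float(F), data_rss)
    common = dict(
        threshold=stop_threshold,
        margin=scan.threshold_margin,
        target_fraction=scan.step_rule,
        init_step=scan.init_step_fraction * scale,
        min_step=scan.min_step_fraction * scale,
        max_step=scan.max_step_fraction * scale,
        max_steps=scan.max_steps_per_side,
        z_limits=(
            z_hat - scan.plausibility_factor * scale,
            z_hat + scan.plausibility_factor * scale,
        ),
        limit_status="unbounded",
        refine=scan.refine,
        march_stat=(lambda q, extra: q if extra is None else extra[1])
        if march_on_data_rss
        else None,
    )
    left = adaptive_march(evaluate, z_hat, q_star, x_hat, direction=-1, **common)
    right = adaptive_march(evaluate, z_hat, q_star, x_hat, direction=+1, **common)
    curve = assemble_curve(
        left,
        (z_hat, q_star, x_hat, (z_hat, q_star)),
        right,
        q_star,
        kind=kind,
        label=f"{target.g_pred} @ t={target.t_pred:g}",
    )
    curve.thetas = [_from_internal(x, log_scale) for x in curve.thetas]
    return curve


def vpl_scan(
    model: ModelDefinition,
    data: Dataset,
    setup: ValidationSetup,
    fit_result: FitResult,
    scan: ScanConfig | None = None,
) -> ProfileCurve:
    """Validation profile likelihood over candidate validation outcomes z.

    At each z all parameters are re-optimized against the joint objective
    (data RSS plus the validation penalty with the setup's measurement SD),
    warm-started from the neighboring grid point.  The curve records, per
    point, the fitted model response z' and the data-only RSS needed by
    :func:`rescale_vpl_to_ppl`.
    """
    scan = scan or ScanConfig()
    return _scan_profile(
        model, data, setup.target, fit_result, scan, SD=setup.SD, kind="validation"
    )


def rescale_vpl_to_ppl(
    curve: ProfileCurve,
    SD: float,
    model: ModelDefinition | None = None,
    data: Dataset | None = None,
    target: PredictionTarget | None = None,
) -> ProfileCurve:
    """Rescale a validation profile into the prediction profile.

    The penalized optimum at scanned z satisfies the constrained-optimum
    conditions at the fitted response z' = F(D_vali, theta*), so the
    prediction profile at z' equals the joint value minus the penalty
    contribution — i.e. the recorded data-only RSS.  The returned curve lives
    on the transformed abscissa z'.
    """
    if curve.kind != "validation":
        raise ValueError("rescaling applies to validation-kind curves")
    if curve.fitted_response is None or curve.data_rss is None:
        raise ValueError(
            "curve lacks recorded fitted responses; rerun the scan with recording"
        )
    z_prime = np.asarray(curve.fitted_response, dtype=float)
    penalty = (curve.grid - z_prime) ** 2 / SD**2
    ppl_vals = np.asarray(curve.data_rss, dtype=float)
    # consistency of the two equivalent forms (joint - penalty vs data RSS)
    mismatch = np.max(np.abs((curve.neg2PL - penalty) - ppl_vals))
    if mismatch > 1e-6 * max(1.0, float(np.max(np.abs(curve.neg2PL)))):
        ppl_vals = np.minimum(ppl_vals, curve.neg2PL - penalty)

    order = np.argsort(z_prime, kind="stable")
    z_sorted = z_prime[order]
    v_sorted = ppl_vals[order]
    thetas = [curve.thetas[i] for i in order] if curve.thetas else None
    tol = 1e-10 * max(1.0, float(np.max(np.abs(z_sorted))))
    keep = np.concatenate(([True], np.diff(z_sorted) > tol))
    z_sorted, v_sorted = z_sorted[keep], v_sorted[keep]
    if thetas is not None:
        thetas = [t for t, k in zip(thetas, keep) if k]
    if z_sorted.size < 3:
        # the model pins the prediction: all scanned z map to one response
        return ProfileCurve(
            grid=z_sorted[:1],
            neg2PL=v_sorted[:1],
            neg2LL_star=curve.neg2LL_star,
            kind="prediction",
            left_crossed=True,
            right_crossed=True,
            left_status="boundary",
            right_status="boundary",
            degenerate=True,
            label=curve.label,
        )
    neg2LL_star = min(float(curve.neg2LL_star), float(np.min(v_sorted)))
    return ProfileCurve(
        grid=z_sorted,
        neg2PL=v_sorted,
        neg2LL_star=neg2LL_star,
        kind="prediction",
        left_crossed=curve.left_crossed,
        right_crossed=curve.right_crossed,
        left_status=curve.left_status,
        right_status=curve.right_status,
        thetas=thetas,
        n_failed=curve.n_failed,
        unreliable=curve.unreliable,
        label=curve.label,
    )


def _constrained_scan(
    model: ModelDefinition,
    data: Dataset,
    target: PredictionTarget,
    fit_result: FitResult,
    scan: ScanConfig,
) -> ProfileCurve:
    """Direct equality-constrained PPL scan (SLSQP), the cross-check route."""
    from scipy.optimize import NonlinearConstraint, minimize

    obj = Objective(model, data, target=target)
    log_scale = fit_result.log_scale
    lb, ub = (
        _to_internal(fit_result.bounds[0], log_scale),
        _to_internal(fit_result.bounds[1], log_scale),
    )
    x_hat = _to_internal(fit_result.theta_hat, log_scale)
    z_hat = obj.predict(fit_result.theta_hat)
    q_star = float(fit_result.neg2LL_star)
    scale = max(abs(z_hat), data.scale)
    con_tol = 1e-6 * scale

    cache: dict = {}

    def sim(x):
        key = x.tobytes()
        if key not in cache:
            if len(cache) > 256:
                cache.clear()
            try:
                r, F = obj.simulate(_from_internal(x, log_scale))
                cache[key] = (float(r @ r), float(F))
            except IntegrationError:
                cache[key] = (1e8, np.nan)
        return cache[key]

    sd_c = scan.constraint_sd_fraction * scale

    def _penalized_start(z: float, warm: np.ndarray) -> np.ndarray:
        # cheap penalized pre-solve: robust against branch exchanges that can
        # trap the equality-constrained solver in a worse local basin
        def res_fn(x):
            theta = _from_internal(x, log_scale)
            try:
                r, F = obj.simulate(theta)
            except IntegrationError:
                return np.full(obj.n_data + 1, 1e4)
            return np.append(r, (z - F) / sd_c)

        return _minimize_residuals(
            res_fn, np.asarray(warm, dtype=float), lb, ub, ftol=1e-9, max_nfev=60
        ).x

    def evaluate(z: float, warm: np.ndarray):
        best = None
        for x0 in (np.asarray(warm, dtype=float), _penalized_start(z, warm)):
            sol = minimize(
                lambda x: sim(x)[0],
                x0,
                method="SLSQP",
                bounds=list(zip(lb, ub)),
                constraints=[{"type": "eq", "fun": lambda x: (sim(x)[1] - z) / scale}],
                options={"maxiter": 200, "ftol": 1e-10},
            )
            q, F = sim(sol.x)
            feasible = np.isfinite(F) and abs(F - z) <= max(con_tol, 1e-4 * scale)
            if feasible and (best is None or q < best[0]):
                best = (q, sol.x, F)
        if best is None:
            raise PointInfeasible(f"constraint F = {z:g} unattainable")
        q, x_best, F = best
        return q, x_best, (float(F), q)

    stop_threshold = float(chi2.ppf(scan.alpha, df=1))
    common = dict(
        threshold=stop_threshold,
        margin=scan.threshold_margin,
        target_fraction=scan.step_rule,
        init_step=scan.init_step_fraction * scale,
        min_step=scan.min_step_fraction * scale,
        max_step=scan.max_step_fraction * scale,
        max_steps=scan.max_steps_per_side,
        z_limits=(
            z_hat - scan.plausibility_factor * scale,
            z_hat + scan.plausibility_factor * scale,
        ),
        limit_status="unbounded",
        refine=scan.refine,
    )
    left = adaptive_march(evaluate, z_hat, q_star, x_hat, direction=-1, **common)
    right = adaptive_march(evaluate, z_hat, q_star, x_hat, direction=+1, **common)
    curve = assemble_curve(
        left,
        (z_hat, q_star, x_hat, (z_hat, q_star)),
        right,
        q_star,
        kind="prediction",
        label=f"{target.g_pred} @ t={target.t_pred:g}",
    )
    curve.thetas = [_from_internal(x, log_scale) for x in curve.thetas]
    return curve


def ppl_scan(
    model: ModelDefinition,
    data: Dataset,
    target: PredictionTarget,
    fit_result: FitResult,
    scan: ScanConfig | None = None,
    method: str = "penalized",
) -> ProfileCurve:
    """Prediction profile likelihood over candidate predictions z.

    ``method="penalized"`` (default) runs the validation-style scan with a
    small penalty SD (``constraint_sd_fraction`` of the prediction scale) and
    rescales it onto the constrained profile — ordinary least squares only.
    ``method="constrained"`` performs direct equality-constrained
    optimization at each grid point and serves as an independent cross-check.
    """
    scan = scan or ScanConfig()
    if method == "penalized":
        obj = Objective(model, data, target=target)
        z_hat = obj.predict(fit_result.theta_hat)
        sd_c = scan.constraint_sd_fraction * max(abs(z_hat), data.scale)
        vpl = _scan_profile(
            model, data, target, fit_result, scan, SD=sd_c, kind="validation",
            march_on_data_rss=True,
        )
        return rescale_vpl_to_ppl(vpl, sd_c, model, data, target)
    if method == "constrained":
        return _constrained_scan(model, data, target, fit_result, scan)
    raise ValueError(f"unknown method {method!r}; use 'penalized' or 'constrained'")


# -- thresholds ------------------------------------------------------------


@dataclass(frozen=True)
class MonteCarloConfig:
    """Parametric-bootstrap configuration for the Monte-Carlo threshold.

    Replicate datasets are simulated at the fitted parameters, refitted, and
    the profile statistic -2 (PPL(z_gen) - LL*) evaluated at the generating
    prediction; its empirical alpha-quantile replaces the asymptotic
    chi-square(1) quantile when the asymptotic assumption is in doubt.
    """

    model: ModelDefinition
    data: Dataset
    target: PredictionTarget
    fit_result: FitResult
    n_reps: int = 500
    seed: int = 0
    scan: ScanConfig | None = None

    def __post_init__(self):
        if self.n_reps < 100:
            raise ValueError(
                "Monte-Carlo threshold needs >= 100 replicates for a stable quantile"
            )


def _ppl_statistic_at(
    model: ModelDefinition,
    data: Dataset,
    target: PredictionTarget,
    fit_result: FitResult,
    z_value: float,
    sd_fraction: float = 1e-3,
) -> float:
    """-2 (PPL(z_value) - LL*): one penalized optimization, data-RSS readout."""
    obj = Objective(model, data, target=target)
    log_scale = fit_result.log_scale
    lb, ub = (
        _to_internal(fit_result.bounds[0], log_scale),
        _to_internal(fit_result.bounds[1], log_scale),
    )
    z_hat = obj.predict(fit_result.theta_hat)
    sd_c = sd_fraction * max(abs(z_hat), data.scale, abs(z_value))

    def res_fn(x):
        theta = _from_internal(x, log_scale)
        try:
            r, F = obj.simulate(theta)
        except IntegrationError:
            return np.full(obj.n_data + 1, 1e4)
        return np.append(r, (z_value - F) / sd_c)

    sol = _minimize_residuals(
        res_fn, _to_internal(fit_result.theta_hat, log_scale), lb, ub
    )
    r, _ = obj.simulate(_from_internal(sol.x, log_scale))
    return float(r @ r) - float(fit_result.neg2LL_star)


def threshold(
    alpha: float,
    method: str = "asymptotic",
    mc: MonteCarloConfig | None = None,
) -> float:
    """Confidence-interval threshold on the -2 log-likelihood scale.

    ``asymptotic`` returns the chi-square(1) alpha-quantile (exact for linear
    models, asymptotically valid otherwise).  ``montecarlo`` estimates the
    same quantile from the parametric-bootstrap distribution of the profile
    statistic under the fitted model.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if method == "asymptotic":
        return float(chi2.ppf(alpha, df=1))
    if method != "montecarlo":
        raise ValueError(f"unknown threshold method {method!r}")
    if mc is None:
        raise ValueError("montecarlo threshold requires a MonteCarloConfig")

    from .fixtures import NoiseSpec, simulate_dataset

    stats: list[float] = []
    theta_gen = mc.fit_result.theta_hat
    z_gen = Objective(mc.model, mc.data, target=mc.target).predict(theta_gen)
    n_failed = 0
    for rep in range(mc.n_reps):
        rep_seed = int(np.random.SeedSequence([mc.seed, rep]).generate_state(1)[0] % (2**31))
        noise = NoiseSpec(sigma=dict(mc.model.noise_sd), seed=rep_seed)
        data_rep = simulate_dataset(mc.model, theta_gen, mc.data.design, noise)
        try:
            fit_rep = _fit(
                mc.model, data_rep, n_starts=1, seed=rep_seed,
                bounds=mc.fit_result.bounds, x0=theta_gen,
                log_scale=mc.fit_result.log_scale,
            )
            stat = _ppl_statistic_at(mc.model, data_rep, mc.target, fit_rep, z_gen)
        except Exception:  # noqa: BLE001 - replicate-level robustness
            n_failed += 1
            continue
        stats.append(max(stat, 0.0))
    if n_failed > 0.1 * mc.n_reps:
        raise RuntimeError(
            f"{n_failed}/{mc.n_reps} bootstrap replicates failed; threshold unreliable"
        )
    return float(np.quantile(stats, alpha))


# -- convenience wrappers --------------------------------------------------


def prediction_interval(
    model: ModelDefinition,
    data: Dataset,
    fit_result: FitResult,
    target: PredictionTarget,
    alpha: float = 0.9,
    scan: ScanConfig | None = None,
    method: str = "penalized",
    threshold_value: float | None = None,
) -> tuple[ProfileCurve, ConfidenceInterval]:
    """PPL scan plus PCI extraction at level alpha."""
    scan = replace(scan or ScanConfig(), alpha=alpha)
    curve = ppl_scan(model, data, target, fit_result, scan, method=method)
    thr = threshold(alpha) if threshold_value is None else threshold_value
    return curve, interval_from_curve(curve, thr)


def validation_interval(
    model: ModelDefinition,
    data: Dataset,
    fit_result: FitResult,
    setup: ValidationSetup,
    alpha: float = 0.9,
    scan: ScanConfig | None = None,
    threshold_value: float | None = None,
) -> tuple[ProfileCurve, ConfidenceInterval]:
    """VPL scan plus VCI extraction at level alpha."""
    scan = replace(scan or ScanConfig(), alpha=alpha)
    curve = vpl_scan(model, data, setup, fit_result, scan)
    thr = threshold(alpha) if threshold_value is None else threshold_value
    return curve, interval_from_curve(curve, thr)
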