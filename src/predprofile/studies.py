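"""Confidence bands over time, observability classification, coverage
simulation and experimental-design ranking.

A confidence band strings per-time prediction (or validation) confidence
intervals together; unbounded intervals at any time flag the profiled
quantity as practically *non-observable* — the data, under the given design,
do not pin down the state even though the model structure might.  Coverage
simulations verify the frequentist calibration of the interval construction:
simulate data at known true parameters, fit, profile, and count how often
the true model response falls inside the interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .estimation import (
    ConfidenceInterval,
    Dataset,
    FitError,
    FitResult,
    Objective,
    fit,
    interval_from_curve,
)
from .fixtures import NoiseSpec, simulate_dataset
from .model_core import ExperimentalDesign, ModelDefinition, PredictionTarget
from .profiles import (
    ScanConfig,
    ValidationSetup,
    ppl_scan,
    threshold,
    vpl_scan,
)

__all__ = [
    "ConfidenceBand",
    "CoverageResult",
    "pci_band",
    "classify_observability",
    "ObservabilityReport",
    "coverage_study",
    "design_ranking",
]


@dataclass
class ConfidenceBand:
    """Per-time confidence intervals for one state/expression, with
    monotone cubic (PCHIP) interpolation between the profiled time points.

    Unbounded time points break the interpolated segments; ``quality`` marks
    per-point scan reliability.
    """

    state: str
    times: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    unbounded_lower: np.ndarray
    unbounded_upper: np.ndarray
    alpha: float
    fitted: np.ndarray
    quality: np.ndarray  # True where the profile scan was reliable
    interpolation: str = "pchip"
    mode: str = "prediction"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for name in ("lower", "upper", "fitted"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.unbounded_lower = np.asarray(self.unbounded_lower, dtype=bool)
        self.unbounded_upper = np.asarray(self.unbounded_upper, dtype=bool)
        self.quality = np.asarray(self.quality, dtype=bool)

    @property
    def widths(self) -> np.ndarray:
        w = self.upper - self.lower
        w[self.unbounded_lower | self.unbounded_upper] = math.inf
        return w

    def interpolate(self, t_dense: Sequence[float]) -> pd.DataFrame:
        """Evaluate the band bounds on a dense grid.

        Bounds are interpolated with a monotone-preserving piecewise cubic
        (no overshoot between knots); segments touching an unbounded knot
        yield NaN (infinite) bounds.
        """
        from scipy.interpolate import PchipInterpolator

        t_dense = np.asarray(t_dense, dtype=float)
        out = {"time": t_dense}
        for name, vals, unb in (
            ("lower", self.lower, self.unbounded_lower),
            ("upper", self.upper, self.unbounded_upper),
        ):
            finite = ~unb
            y = np.full_like(t_dense, np.nan, dtype=float)
            if finite.sum() >= 2:
                # interpolate inside each maximal run of bounded knots
                runs = np.split(np.arange(len(self.times)), np.where(~finite)[0])
                for run in runs:
                    run = run[finite[run]]
                    if run.size >= 2:
                        f = PchipInterpolator(self.times[run], vals[run])
                        sel = (t_dense >= self.times[run[0]]) & (
                            t_dense <= self.times[run[-1]]
                        )
                        y[sel] = f(t_dense[sel])
                    elif run.size == 1:
                        sel = np.isclose(t_dense, self.times[run[0]])
                        y[sel] = vals[run[0]]
            elif finite.sum() == 1:
                i = int(np.where(finite)[0][0])
                y[np.isclose(t_dense, self.times[i])] = vals[i]
            out[name] = y
        return pd.DataFrame(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "lower": self.lower,
                "upper": self.upper,
                "unbounded_l": self.unbounded_lower.astype(int),
                "unbounded_r": self.unbounded_upper.astype(int),
                "fitted": self.fitted,
                "reliable": self.quality.astype(int),
            }
        )


def pci_band(
    model: ModelDefinition,
    data: Dataset,
    fit_result: FitResult,
    state_or_expr: str,
    times: Sequence[float],
    alpha: float = 0.9,
    scan: ScanConfig | None = None,
    mode: str = "prediction",
    SD: float | None = None,
    threshold_value: float | None = None,
) -> ConfidenceBand:
    """Confidence band for a state (or expression) over a time grid.

    One profile scan per time point; interval bounds are interpolated with a
    monotone cubic between the profiled times.  ``mode="validation"``
    produces validation bands for a future measurement with error ``SD``.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("a band needs at least 2 time points")
    if mode not in ("prediction", "validation"):
        raise ValueError("mode must be 'prediction' or 'validation'")
    if mode == "validation" and (SD is None or SD <= 0):
        raise ValueError("validation bands need a positive SD")
    scan = replace(scan or ScanConfig(), alpha=max(alpha, (scan or ScanConfig()).alpha))
    thr = threshold(alpha) if threshold_value is None else threshold_value

    lowers, uppers, unb_l, unb_r, fitted, quality = [], [], [], [], [], []
    for t in times:
        target = PredictionTarget(
            t_pred=float(t), g_pred=state_or_expr, input_id=data.design.input_id
        )
        z_hat = Objective(model, data, target=target).predict(fit_result.theta_hat)
        if mode == "prediction":
            curve = ppl_scan(model, data, target, fit_result, scan)
        else:
            curve = vpl_scan(
                model, data, ValidationSetup(target=target, SD=SD), fit_result, scan
            )
        ci = interval_from_curve(curve, thr)
        lowers.append(ci.lower)
        uppers.append(ci.upper)
        unb_l.append(ci.unbounded_lower)
        unb_r.append(ci.unbounded_upper)
        fitted.append(z_hat)
        quality.append(not curve.unreliable)

    return ConfidenceBand(
        state=state_or_expr,
        times=times,
        lower=np.array(lowers),
        upper=np.array(uppers),
        unbounded_lower=np.array(unb_l),
        unbounded_upper=np.array(unb_r),
        alpha=float(alpha),
        fitted=np.array(fitted),
        quality=np.array(quality),
        mode=mode,
    )


@dataclass(frozen=True)
class ObservabilityReport:
    """Verdict for one band: observable iff every time point is bounded."""

    state: str
    observable: bool
    offending_times: tuple[float, ...]
    offending_sides: tuple[str, ...]
    alpha: float

    @property
    def verdict(self) -> str:
        return "observable" if self.observable else "non_observable"


def classify_observability(band: ConfidenceBand) -> ObservabilityReport:
    """Practical observability: bounded prediction intervals at every time.

    A single unbounded time point renders the quantity non-observable; the
    report lists the offending times and sides (times with bounded, even
    zero-width, intervals — e.g. an initial condition fixed by the model —
    are not offending).
    """
    bad_times, bad_sides = [], []
    for t, lo_unb, hi_unb in zip(band.times, band.unbounded_lower, band.unbounded_upper):
        if lo_unb or hi_unb:
            bad_times.append(float(t))
            if lo_unb and hi_unb:
                bad_sides.append("both")
            else:
                bad_sides.append("lower" if lo_unb else "upper")
    return ObservabilityReport(
        state=band.state,
        observable=not bad_times,
        offending_times=tuple(bad_times),
        offending_sides=tuple(bad_sides),
        alpha=band.alpha,
    )


@dataclass(frozen=True)
class CoverageResult:
    """Empirical coverage of an interval construction over noise replicates."""

    n_reps: int
    n_hit: int
    alpha: float
    n_failed: int
    binomial_ci: tuple[float, float]
    mode: str

    def __post_init__(self):
        if self.n_hit > self.n_reps:
            raise ValueError("hits cannot exceed replicates")

    @property
    def coverage(self) -> float:
        return self.n_hit / self.n_reps


def _replicate_seed(master: int, rep: int) -> int:
    """Counter-based per-replicate seed: independent and individually
    reproducible given the master seed."""
    return int(np.random.SeedSequence([int(master), int(rep)]).generate_state(1)[0] % (2**31))


def coverage_study(
    model: ModelDefinition,
    theta_true: Sequence[float],
    design: ExperimentalDesign,
    target: PredictionTarget,
    alpha: float = 0.9,
    n_reps: int = 200,
    seed: int = 0,
    mode: str = "prediction",
    SD: float | None = None,
    scan: ScanConfig | None = None,
    bounds=None,
    threshold_value: float | None = None,
) -> CoverageResult:
    """Monte-Carlo check of interval calibration at the true parameters.

    Per replicate: simulate data with fresh noise at ``theta_true``, fit
    (warm-started near the truth with a small multi-start fallback), scan the
    profile, build the interval, and test membership of the true model
    response (prediction mode) or of an independently drawn noisy validation
    point (validation mode).  Returns the hit frequency with an exact
    binomial 95% CI.  Fully reproducible given ``seed``.
    """
    if n_reps < 50:
        raise ValueError("coverage needs n_reps >= 50")
    if mode not in ("prediction", "validation"):
        raise ValueError("mode must be 'prediction' or 'validation'")
    if mode == "validation" and (SD is None or SD <= 0):
        raise ValueError("validation mode needs a positive SD")
    theta_true = np.asarray(theta_true, dtype=float)
    scan = replace(scan or ScanConfig(), alpha=max(alpha, (scan or ScanConfig()).alpha))
    thr = threshold(alpha) if threshold_value is None else threshold_value
    if bounds is None:
        bounds = model.default_bounds()

    # the quantity to cover
    obj_true = Objective(model, None, target=target)
    z_true = obj_true.predict(theta_true)

    n_hit = 0
    n_failed = 0
    n_done = 0
    for rep in range(n_reps):
        rep_seed = _replicate_seed(seed, rep)
        rng = np.random.default_rng(rep_seed)
        noise = NoiseSpec(sigma=dict(model.noise_sd), seed=rep_seed)
        data = simulate_dataset(model, theta_true, design, noise)
        try:
            # warm start at the truth with mild jitter; multi-start fallback
            jitter = theta_true * np.exp(rng.normal(0.0, 0.05, size=theta_true.size))
            fit_result = fit(
                model, data, n_starts=1, seed=rep_seed, bounds=bounds,
                x0=np.clip(jitter, bounds[0], bounds[1]),
            )
            expected = len(data)  # E[RSS] = n at the truth; guard against bad fits
            if fit_result.neg2LL_star > expected + 6 * math.sqrt(2 * expected):
                fit_result = fit(
                    model, data, n_starts=5, seed=rep_seed, bounds=bounds
                )
            if mode == "prediction":
                curve = ppl_scan(model, data, target, fit_result, scan)
                ci = interval_from_curve(curve, thr)
                hit = ci.contains(z_true)
            else:
                setup = ValidationSetup(target=target, SD=float(SD))
                curve = vpl_scan(model, data, setup, fit_result, scan)
                ci = interval_from_curve(curve, thr)
                z_val = float(rng.normal(z_true, SD))
                hit = ci.contains(z_val)
        except (FitError, ValueError, RuntimeError):
            n_failed += 1
            continue
        n_done += 1
        n_hit += int(hit)

    if n_failed > 0.1 * n_reps:
        raise RuntimeError(
            f"{n_failed}/{n_reps} replicates failed to fit; coverage study invalid"
        )
    ci95 = binomtest(n_hit, n_done).proportion_ci(confidence_level=0.95, method="exact")
    return CoverageResult(
        n_reps=n_done,
        n_hit=n_hit,
        alpha=float(alpha),
        n_failed=n_failed,
        binomial_ci=(float(ci95.low), float(ci95.high)),
        mode=mode,
    )


def design_ranking(bands: Sequence[ConfidenceBand]) -> pd.DataFrame:
    """Rank (state, time) conditions by interval width, widest first.

    Wide (or unbounded) prediction intervals mark conditions weakly specified
    by the existing data — the most informative candidates for new
    measurements.  Unbounded entries rank first with infinite width; ties
    break deterministically by (state, time).
    """
    if bands:
        alphas = {b.alpha for b in bands}
        if len(alphas) > 1:
            raise ValueError("all bands must share the same alpha")
    rows = []
    for band in bands:
        widths = band.widths
        for t, w in zip(band.times, widths):
            rows.append({"state": band.state, "time": float(t), "width": float(w)})
    df = pd.DataFrame(rows, columns=["state", "time", "width"])
    if len(df):
        df = df.sort_values(
            by=["width", "state", "time"],
            ascending=[False, True, True],
            kind="stable",
        ).reset_index(drop=True)
    return df
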