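"""Least-squares fitting of the four kinetic models and goodness-of-fit metrics.

All fits minimise Σ(Qt_obs − f(t))² on the untransformed percent scale.  The
straight-line models (zero-order, and Higuchi in √t) are solved in closed
form; the first-order exponential and the Korsmeyer–Peppas power law are
solved by Levenberg–Marquardt from deterministic starting values, with a
fixed-seed jittered-restart fallback.  The Korsmeyer–Peppas fit is preceded
by the 60 %-cutoff domain restriction (:func:`restrict_kp_domain`).

Four metrics are reported for every fit, matching the Origin-style metric
set: adjusted R², residual sum of squares (RSS), reduced χ² (RSS/dof with
unit observation weights) and Pearson's r between observed and predicted
values.

A log-linearised fitting mode (``fit_scale="linearized"``: log–log regression
for the power law, ln(b1 − Qt) regression for the exponential) is provided
for sensitivity checks only; metrics are always evaluated on the percent
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DomainError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from .models import BELOW_60_PERCENT, KineticModelSpec, get_model
from .quantitation import ReleaseCurve

__all__ = [
    "FitOptions",
    "FitResult",
    "restrict_kp_domain",
    "fit_model",
    "fit_all_models",
    "adj_r_square",
    "pearson_r",
    "reduced_chi_sq",
]


@dataclass(frozen=True)
class FitOptions:
    """Tunable fitting options (defaults reproduce the standard analysis)."""

    kp_cutoff_percent: float = 60.0
    fit_scale: str = "untransformed"  # or "linearized"
    max_restarts: int = 3
    seed: int = 0
    max_iter: int = 2000
    rel_tol: float = 1e-10

    def __post_init__(self):
        if self.fit_scale not in ("untransformed", "linearized"):
            raise ValueError("fit_scale must be 'untransformed' or 'linearized'")
        if self.kp_cutoff_percent <= 0:
            raise ValueError("kp_cutoff_percent must be positive")


DEFAULT_OPTIONS = FitOptions()


@dataclass
class FitResult:
    """One model's fitted parameters plus the four goodness-of-fit metrics."""

    model_name: str
    params: np.ndarray
    n_used: int
    dof: int
    rss: float
    reduced_chi_sq: float
    adj_r_square: float
    pearson_r: float
    converged: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def param_dict(self) -> dict[str, float]:
        spec = get_model(self.model_name)
        return dict(zip(spec.parameter_names, np.asarray(self.params, float)))


# ---------------------------------------------------------------------------
# metrics


def adj_r_square(observed, predicted, n_params: int) -> float:
    """Adjusted R² = 1 − (RSS/(N−p)) / (TSS/(N−1))."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = obs.size
    if n < n_params + 2:
        raise InsufficientDataError(
            f"adjusted R² needs at least n_params + 2 = {n_params + 2} points"
        )
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        raise UndefinedStatisticError("observed values are all equal: TSS = 0")
    rss = float(np.sum((obs - pred) ** 2))
    return 1.0 - (rss / (n - n_params)) / (tss / (n - 1))


def pearson_r(observed, predicted) -> float:
    """Sample Pearson correlation between observed and model-predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    return float(np.corrcoef(obs, pred)[0, 1])


def reduced_chi_sq(rss: float, n_used: int, n_params: int) -> float:
    """Reduced χ² with unit observation weights: RSS / (n_used − n_params)."""
    dof = n_used - n_params
    if dof <= 0:
        raise DomainError(f"non-positive degrees of freedom: {n_used} − {n_params}")
    if rss < 0:
        raise DomainError("RSS must be non-negative")
    return rss / dof


# ---------------------------------------------------------------------------
# domain restriction


def restrict_kp_domain(curve: ReleaseCurve, cutoff_percent: float = 60.0) -> ReleaseCurve:
    """Longest prefix of the curve strictly below the cumulative-release cutoff.

    The power law describes the early-time validity window, so every point at
    or after the first crossing of the cutoff is excluded even if later values
    dip back below it.  The minimum-points requirement for actually fitting
    the restricted curve (≥ 3) is enforced by :func:`fit_model`.
    """
    if len(curve) == 0:
        raise InsufficientDataError("empty curve")
    above = curve.qt >= cutoff_percent
    n_keep = int(np.argmax(above)) if above.any() else len(curve)
    if n_keep == 0:
        raise InsufficientDataError(
            f"no points below the {cutoff_percent:g} % cutoff"
        )
    if n_keep == len(curve):
        return curve
    return ReleaseCurve(
        curve.drug_id,
        curve.times[:n_keep],
        curve.qt[:n_keep],
        dict(curve.meta, kp_truncated_at=n_keep),
    )


# ---------------------------------------------------------------------------
# solvers


def _linear_lsq(x: np.ndarray, q: np.ndarray) -> np.ndarray:
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, q, rcond=None)
    return coef  # (slope, intercept)


def _kp_model(t, K, n):
    with np.errstate(invalid="ignore", divide="ignore"):
        out = K * np.power(t, n)
    return np.nan_to_num(out, nan=0.0, posinf=1e12, neginf=-1e12)


def _first_order_model(t, K1, a, b1):
    with np.errstate(over="ignore"):
        out = K1 * np.exp(np.clip(a * t, -700, 700)) + b1
    return out


def _kp_start(t: np.ndarray, q: np.ndarray) -> np.ndarray:
    """OLS on (ln t, ln Qt) over positive pairs."""
    mask = (t > 0) & (q > 0)
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(np.log(t[mask]), np.log(q[mask]), 1)
        return np.array([np.exp(intercept), slope])
    return np.array([max(q.max(), 1e-6) / np.sqrt(max(t.max(), 1.0)), 0.5])


def _first_order_starts(t: np.ndarray, q: np.ndarray) -> list[np.ndarray]:
    """Deterministic starts: profiled decay rate plus the plateau heuristic.

    For each candidate rate a the model is linear in (K1, b1), so the profile
    over a log grid of timescales gives a robust global start even when the
    plateau lies far above the observed range.
    """
    t_max = float(t.max())
    t_scale = max(t_max, 1.0)
    taus = np.geomspace(t_scale / 200.0, t_scale * 50.0, 60)
    best, best_rss = None, np.inf
    for tau in taus:
        e = np.exp(-t / tau)
        coef = _linear_lsq(e, q)
        rss = float(np.sum((coef[0] * e + coef[1] - q) ** 2))
        if rss < best_rss:
            best_rss = rss
            best = np.array([coef[0], -1.0 / tau, coef[1]])
    starts = [best]
    # plateau heuristic: b1 slightly above the largest observation
    b1 = 1.05 * float(q.max())
    resid = b1 - q
    if np.all(resid > 0):
        slope, intercept = np.polyfit(t, np.log(resid), 1)
        starts.append(np.array([-np.exp(intercept), slope, b1]))
    return starts


def _polish(model_fun, t, q, p0, options: FitOptions):
    """Levenberg–Marquardt refinement with fixed-seed jittered restarts.

    The deterministic start is tried first; jittered restarts run only if it
    fails to converge.  On total non-convergence the best point found is
    returned with ``converged=False``.
    """
    p0 = np.asarray(p0, dtype=float)
    rng = np.random.default_rng(options.seed)
    best_params = p0
    best_rss = float(np.sum((q - model_fun(t, *p0)) ** 2))
    converged = False
    for attempt in range(options.max_restarts + 1):
        start = p0 if attempt == 0 else p0 * (1.0 + 0.05 * rng.standard_normal(p0.size))
        try:
            popt, _ = curve_fit(model_fun, t, q, p0=start, maxfev=20 * options.max_iter)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((q - model_fun(t, *popt)) ** 2))
        if not converged or rss < best_rss:
            best_params, best_rss = np.asarray(popt, float), rss
        converged = True
        break  # any successful solve ends the restart ladder
    return best_params, converged


# ---------------------------------------------------------------------------
# public fitting entry points


def fit_model(
    curve: ReleaseCurve,
    model: "str | KineticModelSpec",
    options: FitOptions | None = None,
) -> FitResult:
    """Fit one kinetic model to a release curve and populate all four metrics."""
    spec = get_model(model)
    opts = options or DEFAULT_OPTIONS

    fitted = curve
    if spec.domain_rule == BELOW_60_PERCENT:
        fitted = restrict_kp_domain(curve, opts.kp_cutoff_percent)
    t, q = fitted.times, fitted.qt

    if spec.name == "korsmeyer_peppas" and np.any(t == 0):
        # the power law carries no information at the origin; keep t > 0
        keep = t > 0
        t, q = t[keep], q[keep]

    n_used = t.size
    if n_used < spec.n_params + 1:
        raise InsufficientDataError(
            f"{spec.name}: {n_used} usable points < n_params + 1 = "
            f"{spec.n_params + 1}"
        )

    converged = True
    if spec.name == "zero_order":
        params = _linear_lsq(t, q)
        pred = params[0] * t + params[1]
    elif spec.name == "higuchi":
        params = _linear_lsq(np.sqrt(t), q)
        pred = params[0] * np.sqrt(t) + params[1]
    elif spec.name == "korsmeyer_peppas":
        start = _kp_start(t, q)
        if opts.fit_scale == "linearized":
            params = start
        else:
            params, converged = _polish(_kp_model, t, q, start, opts)
        pred = _kp_model(t, *params)
    else:  # first_order
        starts = _first_order_starts(t, q)
        if opts.fit_scale == "linearized":
            params = starts[-1] if len(starts) > 1 else starts[0]
        else:
            candidates = []
            for p0 in starts:
                p_fit, ok = _polish(_first_order_model, t, q, p0, opts)
                rss = float(np.sum((q - _first_order_model(t, *p_fit)) ** 2))
                candidates.append((rss, ok, p_fit))
            rss_best, converged, params = min(candidates, key=lambda c: c[0])
        pred = _first_order_model(t, *params)

    rss = float(np.sum((q - pred) ** 2))
    dof = n_used - spec.n_params
    try:
        adj = adj_r_square(q, pred, spec.n_params)
    except (UndefinedStatisticError, InsufficientDataError):
        adj = float("nan")
    try:
        r = pearson_r(q, pred)
    except UndefinedStatisticError:
        r = float("nan")
    return FitResult(
        model_name=spec.name,
        params=np.asarray(params, dtype=float),
        n_used=n_used,
        dof=dof,
        rss=rss,
        reduced_chi_sq=reduced_chi_sq(rss, n_used, spec.n_params),
        adj_r_square=float(adj),
        pearson_r=float(r),
        converged=bool(converged),
        meta={"drug_id": curve.drug_id, "fit_scale": opts.fit_scale},
    )


def fit_all_models(
    curve: ReleaseCurve,
    models=None,
    options: FitOptions | None = None,
) -> dict[str, FitResult]:
    """Fit every requested model (default: all four); skip models whose
    domain restriction leaves too few points, recording nothing for them."""
    from .models import MODEL_ORDER

    out: dict[str, FitResult] = {}
    for name in models or MODEL_ORDER:
        try:
            out[name] = fit_model(curve, name, options)
        except InsufficientDataError:
            continue
    return out
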