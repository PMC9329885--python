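"""Continuous-endpoint dose-response models and benchmark-dose estimation.

The workhorse is the linear model ``R_i = a + b * D_i`` fitted to
individual fish pooled across replicates.  A wider candidate set (linear,
power, second-order polynomial, three-parameter exponential, Hill) is
fitted by constant-variance normal maximum likelihood and ranked by AIC.

The benchmark response (BMR) is a shift in the endpoint mean equal to a
multiple (default 1) of the control-group standard deviation; the BMD is
the dose producing that shift and the BMDL its one-sided 95% lower
confidence bound, obtained by profile likelihood (chi-square(1) 90%
two-sided cutoff, the usual BMDS convention) with a delta-method fallback
that is flagged in the result.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "LinearDRFit",
    "CurveFit",
    "BMDResult",
    "fit_linear",
    "fit_candidates",
    "compute_bmd",
    "exclude_nonmonotonic_top",
    "MODEL_NAMES",
    "DegenerateDesignError",
]

#: chi2(1) quantile giving a one-sided 95% profile bound (two-sided 90%)
_PROFILE_CUTOFF = stats.chi2.ppf(0.90, df=1)


class DegenerateDesignError(ValueError):
    """Raised when the dose design cannot identify the model."""


@dataclass
class LinearDRFit:
    """Ordinary-least-squares linear dose-response fit.

    Attributes
    ----------
    a, b:
        Intercept (endpoint units) and slope (endpoint units per ug/L).
    R0:
        Observed control-group mean response at dose 0 — the baseline for
        percent-response calculations (distinct from the intercept ``a``).
    control_sd:
        Standard deviation among control fish (defines the BMR).
    n, residual_sd, dose_range:
        Fit bookkeeping.
    doses, responses:
        The fitted data, retained so confidence procedures can re-profile.
    """

    a: float
    b: float
    R0: float
    control_sd: float = float("nan")
    n: int = 0
    residual_sd: float = float("nan")
    dose_range: tuple[float, float] = (float("nan"), float("nan"))
    doses: np.ndarray | None = field(default=None, repr=False)
    responses: np.ndarray | None = field(default=None, repr=False)

    def predict(self, dose):
        return self.a + self.b * np.asarray(dose, dtype=float)

    @classmethod
    def from_params(cls, a: float, b: float, R0: float,
                    control_sd: float = float("nan")) -> "LinearDRFit":
        """Build a fit object directly from reported (a, b, R0) parameters."""
        return cls(a=float(a), b=float(b), R0=float(R0), control_sd=float(control_sd))


@dataclass
class CurveFit:
    """One candidate model fitted by constant-variance normal MLE."""

    name: str
    params: dict[str, float]
    loglik: float
    aic: float
    converged: bool
    message: str = ""
    doses: np.ndarray | None = field(default=None, repr=False)
    responses: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.params) + 1  # + residual variance

    def predict(self, dose):
        theta = np.array(list(self.params.values()), dtype=float)
        return _MODELS[self.name].mean(np.asarray(dose, dtype=float), theta)


@dataclass
class BMDResult:
    """Benchmark dose summary for one fitted model."""

    model: str
    bmr_sd: float
    bmd: float
    bmdl: float
    aic: float
    scaled_residual: float
    qc_flag: str  # "ok" | "questionable_extrapolation"
    status: str = "ok"  # "ok" | "no_solution"
    bmdl_method: str = "profile"  # "profile" | "delta" | "none"


# ---------------------------------------------------------------------------
# model definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _ModelDef:
    param_names: tuple[str, ...]
    mean: Callable[[np.ndarray, np.ndarray], np.ndarray]
    init: Callable
    bounds: Callable
    min_dose_levels: int = 2
    closed_form: bool = False


def _lin_mean(d, th):
    return th[0] + th[1] * d


def _poly2_mean(d, th):
    return th[0] + th[1] * d + th[2] * d ** 2


def _power_mean(d, th):
    return th[0] + th[1] * np.power(d, th[2])


def _exp3_mean(d, th):
    # background * exp(rate * d^power); rate sign sets direction.
    # exponent clipped to keep the optimiser's wild steps finite
    return th[0] * np.exp(np.clip(th[1] * np.power(d, th[2]), -700.0, 700.0))


def _hill_mean(d, th):
    a, v, k, g = th
    d = np.asarray(d, dtype=float)
    num = np.power(d, g)
    return a + v * num / (np.power(k, g) + num)


def _ols_theta(d, y, degree):
    X = np.vander(d, degree + 1, increasing=True)
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return theta


def _slope_scale(d, y):
    span = d.max() - d.min()
    return (y[np.argmax(d)] - y[np.argmin(d)]) / span if span > 0 else 0.0


_MODELS: dict[str, _ModelDef] = {
    "linear": _ModelDef(("a", "b"), _lin_mean,
                        init=lambda d, y: _ols_theta(d, y, 1),
                        bounds=lambda d, y: None, closed_form=True),
    "polynomial2": _ModelDef(("a", "b1", "b2"), _poly2_mean,
                             init=lambda d, y: _ols_theta(d, y, 2),
                             bounds=lambda d, y: None, min_dose_levels=3,
                             closed_form=True),
    "power": _ModelDef(("a", "b", "g"), _power_mean,
                       init=lambda d, y: np.array([y[d == d.min()].mean(),
                                                   _slope_scale(d, y), 1.0]),
                       bounds=lambda d, y: ([-np.inf, -np.inf, 1.0],
                                            [np.inf, np.inf, 18.0]),
                       min_dose_levels=3),
    "exponential3": _ModelDef(("a", "b", "g"), _exp3_mean,
                              init=lambda d, y: np.array([
                                  max(y[d == d.min()].mean(), 1e-12),
                                  _slope_scale(d, y) / max(y.mean(), 1e-12), 1.0]),
                              bounds=lambda d, y: ([1e-12, -np.inf, 1.0],
                                                   [np.inf, np.inf, 18.0]),
                              min_dose_levels=4),
    "hill": _ModelDef(("a", "v", "k", "g"), _hill_mean,
                      init=lambda d, y: np.array([
                          y[d == d.min()].mean(),
                          y[d == d.max()].mean() - y[d == d.min()].mean(),
                          np.median(d[d > 0]) if np.any(d > 0) else 1.0, 1.0]),
                      bounds=lambda d, y: ([-np.inf, -np.inf, 1e-9, 1.0],
                                           [np.inf, np.inf, np.inf, 18.0]),
                      min_dose_levels=4),
}

MODEL_NAMES: tuple[str, ...] = tuple(_MODELS)


def _validate_xy(doses, responses):
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("doses and responses must be equal-length 1-D sequences")
    if not (np.isfinite(d).all() and np.isfinite(y).all()):
        raise ValueError("doses and responses must be finite")
    if np.unique(d).size < 2:
        raise DegenerateDesignError("need at least 2 distinct dose levels")
    return d, y


def _gauss_loglik(rss: float, n: int) -> float:
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_linear(doses: Sequence[float], responses: Sequence[float]) -> LinearDRFit:
    """Fit ``R = a + b * D`` by OLS (the constant-variance normal MLE).

    The control mean ``R0`` and control SD are computed from dose-0
    records only; if the data contain no dose-0 records they are NaN.
    """
    d, y = _validate_xy(doses, responses)
    a, b = np.polynomial.polynomial.polyfit(d, y, 1)
    resid = y - (a + b * d)
    ctrl = y[d == 0]
    R0 = float(ctrl.mean()) if ctrl.size else float("nan")
    control_sd = float(ctrl.std(ddof=1)) if ctrl.size >= 2 else float("nan")
    return LinearDRFit(
        a=float(a), b=float(b), R0=R0, control_sd=control_sd,
        n=int(d.size),
        residual_sd=float(np.sqrt((resid ** 2).sum() / max(d.size - 2, 1))),
        dose_range=(float(d.min()), float(d.max())),
        doses=d, responses=y,
    )


def linear_curvefit(fit: LinearDRFit) -> CurveFit:
    """View a :class:`LinearDRFit` as a :class:`CurveFit` (for BMD code)."""
    if fit.doses is None:
        return CurveFit("linear", {"a": fit.a, "b": fit.b}, float("nan"),
                        float("nan"), True)
    rss = float(((fit.responses - fit.predict(fit.doses)) ** 2).sum())
    ll = _gauss_loglik(rss, fit.n)
    return CurveFit("linear", {"a": fit.a, "b": fit.b}, ll, 2 * 3 - 2 * ll, True,
                    doses=fit.doses, responses=fit.responses)


def _fit_one(name: str, d: np.ndarray, y: np.ndarray) -> CurveFit:
    spec = _MODELS[name]
    if np.unique(d).size < spec.min_dose_levels:
        return CurveFit(name, dict.fromkeys(spec.param_names, float("nan")),
                        -np.inf, np.inf, False,
                        message=f"needs >= {spec.min_dose_levels} dose levels")
    n = d.size
    theta0 = np.asarray(spec.init(d, y), dtype=float)
    bounds = spec.bounds(d, y)
    if spec.closed_form:
        theta = theta0
        ok, msg = True, ""
    else:
        lo, hi = (np.array(bounds[0]), np.array(bounds[1]))
        theta0 = np.clip(theta0, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, theta0))

        def rss_fn(th):
            r = y - spec.mean(d, th)
            return float(r @ r)

        best = None
        # a few shape starts: power/steepness 1, 2 and 4
        starts = [theta0]
        for gval in (2.0, 4.0):
            t = theta0.copy()
            t[-1] = gval
            starts.append(t)
        if name == "hill" and np.any(d > 0):
            t = theta0.copy()
            t[2] = np.min(d[d > 0])
            starts.append(t)
        for t0 in starts:
            try:
                res = optimize.minimize(rss_fn, t0, method="L-BFGS-B",
                                        bounds=list(zip(lo, hi)))
            except Exception as exc:  # pragma: no cover - scipy internal failure
                res = None
                msg = str(exc)
            if res is not None and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            return CurveFit(name, dict.fromkeys(spec.param_names, float("nan")),
                            -np.inf, np.inf, False, message="optimizer failure")
        theta, ok, msg = best.x, bool(best.success), str(best.message)
    rss = float(((y - spec.mean(d, theta)) ** 2).sum())
    ll = _gauss_loglik(rss, n)
    k = len(spec.param_names) + 1
    return CurveFit(name, dict(zip(spec.param_names, map(float, theta))),
                    ll, 2 * k - 2 * ll, ok, message=msg, doses=d, responses=y)


def fit_candidates(doses: Sequence[float], responses: Sequence[float],
                   models: Sequence[str] = MODEL_NAMES) -> list[CurveFit]:
    """Fit each requested candidate model; return the list sorted by AIC.

    Non-converged models are kept in the list with ``converged=False``
    (AIC = inf if the optimiser failed outright) rather than dropped.
    """
    d, y = _validate_xy(doses, responses)
    fits = []
    for name in models:
        if name not in _MODELS:
            raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
        fits.append(_fit_one(name, d, y))
    fits.sort(key=lambda f: (not np.isfinite(f.aic), f.aic))
    return fits


# ---------------------------------------------------------------------------
# benchmark dose
# ---------------------------------------------------------------------------

def _bmd_from_mean(predict, shift: float, direction: str, d_max: float) -> float:
    """Smallest positive dose whose predicted mean departs from the dose-0
    prediction by ``shift`` in the adverse direction; NaN if never reached
    within 10x the maximum fitted dose."""
    sign = -1.0 if direction == "decrease" else 1.0
    mu0 = float(predict(0.0))

    def g(dose):
        return sign * (float(predict(dose)) - mu0) - shift

    hi = 10.0 * d_max if d_max > 0 else 1.0
    # bracket the first crossing on a log-ish grid, then refine
    grid = np.concatenate([[0.0], np.geomspace(max(d_max * 1e-9, 1e-12), hi, 400)])
    vals = np.array([g(x) for x in grid])
    idx = np.nonzero(vals >= 0)[0]
    if idx.size == 0:
        return float("nan")
    i = idx[0]
    if i == 0:
        return 0.0
    return float(optimize.brentq(g, grid[i - 1], grid[i], xtol=1e-12, rtol=1e-14))


def _profile_bmdl_linear(d, y, shift: float, direction: str) -> float:
    """Closed-form profile-likelihood lower bound for the linear model.

    Profiling the intercept and variance leaves a deviance
    ``n * log(RSS(b) / RSS(b_hat))``; solving deviance = cutoff gives a
    quadratic in ``b`` whose steeper root bounds the BMD from below.
    """
    n = d.size
    dx = d - d.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    sxy = float(dx @ dy)
    syy = float(dy @ dy)
    b_hat = sxy / sxx
    rss_hat = max(syy - sxy ** 2 / sxx, 1e-300)
    c = rss_hat * math.exp(_PROFILE_CUTOFF / n)
    disc = sxy ** 2 - sxx * (syy - c)
    if disc < 0:
        return float("nan")
    step = math.sqrt(disc) / sxx
    b_steep = b_hat - step if direction == "decrease" else b_hat + step
    if b_steep == 0:
        return float("nan")
    return shift / abs(b_steep)


def _profile_bmdl_general(fit: CurveFit, bmd_hat: float, shift: float,
                          direction: str) -> float:
    """Numeric profile bound: bisection on the BMD with an SLSQP inner
    maximisation constrained to hit the benchmark shift at the trial dose."""
    spec = _MODELS[fit.name]
    d, y = fit.doses, fit.responses
    n = d.size
    theta_hat = np.array(list(fit.params.values()), dtype=float)
    rss_hat = float(((y - spec.mean(d, theta_hat)) ** 2).sum())
    sign = -1.0 if direction == "decrease" else 1.0
    bounds = spec.bounds(d, y)
    # work in a normalised parameter space (theta = scale * z): the raw
    # parameters can differ by ten orders of magnitude, which defeats SLSQP
    scale = np.where(np.abs(theta_hat) > 1e-12, np.abs(theta_hat), 1.0)
    z_hat = theta_hat / scale
    z_bnds = ([(lo / s, hi / s) for lo, hi, s in zip(bounds[0], bounds[1], scale)]
              if bounds is not None else None)
    # normalise the objective too, so ftol is meaningful
    rss_scale = max(rss_hat, 1e-300)

    def deviance_at(bmd_try: float) -> float:
        def rss_fn(z):
            r = y - spec.mean(d, z * scale)
            return float(r @ r) / rss_scale

        def con(z):
            th = z * scale
            return (sign * (spec.mean(np.array([bmd_try]), th)[0]
                            - spec.mean(np.array([0.0]), th)[0]) - shift) / shift

        res = optimize.minimize(rss_fn, z_hat, method="SLSQP", bounds=z_bnds,
                                constraints=[{"type": "eq", "fun": con}],
                                options={"maxiter": 500, "ftol": 1e-10})
        if not res.success:
            raise RuntimeError(res.message)
        return n * math.log(max(res.fun * rss_scale, 1e-300) / rss_scale)

    lo, hi = bmd_hat * 1e-3, bmd_hat
    if deviance_at(lo) < _PROFILE_CUTOFF:
        return lo
    return float(optimize.brentq(lambda x: deviance_at(x) - _PROFILE_CUTOFF,
                                 lo, hi, xtol=bmd_hat * 1e-6))


def _delta_bmdl(fit: CurveFit, bmd_hat: float, shift: float, direction: str) -> float:
    """Wald/delta-method fallback: normal lower bound on log(BMD)."""
    spec = _MODELS[fit.name]
    d, y = fit.doses, fit.responses
    n = d.size
    theta_hat = np.array(list(fit.params.values()), dtype=float)
    rss = float(((y - spec.mean(d, theta_hat)) ** 2).sum())
    sigma2 = rss / n
    eps = np.maximum(np.abs(theta_hat) * 1e-5, 1e-8)

    def bmd_of(th):
        return _bmd_from_mean(lambda x: spec.mean(np.atleast_1d(x), th)[0],
                              shift, direction, float(d.max()))

    # gradient of BMD and Gauss-Newton covariance of theta
    grad = np.zeros_like(theta_hat)
    for j in range(theta_hat.size):
        tp, tm = theta_hat.copy(), theta_hat.copy()
        tp[j] += eps[j]
        tm[j] -= eps[j]
        grad[j] = (bmd_of(tp) - bmd_of(tm)) / (2 * eps[j])
    J = np.zeros((n, theta_hat.size))
    for j in range(theta_hat.size):
        tp, tm = theta_hat.copy(), theta_hat.copy()
        tp[j] += eps[j]
        tm[j] -= eps[j]
        J[:, j] = (spec.mean(d, tp) - spec.mean(d, tm)) / (2 * eps[j])
    try:
        cov = sigma2 * np.linalg.pinv(J.T @ J)
    except np.linalg.LinAlgError:
        return float("nan")
    var = float(grad @ cov @ grad)
    if var <= 0 or bmd_hat <= 0:
        return float("nan")
    # lognormal-scale bound keeps the limit positive
    se_log = math.sqrt(var) / bmd_hat
    return bmd_hat * math.exp(-stats.norm.ppf(0.95) * se_log)


def compute_bmd(fit: CurveFit | LinearDRFit, control_mean: float,
                control_sd: float, bmr_sd: float = 1.0,
                direction: str = "decrease") -> BMDResult:
    """Benchmark dose and one-sided 95% lower bound for a fitted model.

    The BMD solves ``|mean(BMD) - mean(0)| = bmr_sd * control_sd`` in the
    adverse ``direction``.  For the linear model this is the closed form
    ``bmr_sd * control_sd / |b|`` and the BMDL profile is analytic; other
    models are profiled numerically.  ``qc_flag`` marks fits whose BMD
    extrapolates more than 3-fold below the lowest nonzero dose.
    """
    if control_sd <= 0 or not np.isfinite(control_sd):
        raise ValueError("control_sd must be a positive finite number")
    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be 'decrease' or 'increase'")
    if isinstance(fit, LinearDRFit):
        fit = linear_curvefit(fit)
    shift = bmr_sd * control_sd
    d = fit.doses
    d_max = float(d.max()) if d is not None else 1.0 / max(abs(fit.params.get("b", 1.0)), 1e-30)

    if fit.name == "linear":
        b = fit.params["b"]
        adverse = b < 0 if direction == "decrease" else b > 0
        bmd = shift / abs(b) if (b != 0 and adverse) else float("nan")
    else:
        bmd = _bmd_from_mean(lambda x: float(fit.predict(x)), shift, direction, d_max)
    if not np.isfinite(bmd) or (d is not None and bmd > 10.0 * d_max):
        return BMDResult(fit.name, bmr_sd, float("nan"), float("nan"), fit.aic,
                         float("nan"), "ok", status="no_solution", bmdl_method="none")

    bmdl, method = float("nan"), "none"
    if d is not None:
        try:
            if fit.name == "linear":
                bmdl = _profile_bmdl_linear(d, fit.responses, shift, direction)
            else:
                bmdl = _profile_bmdl_general(fit, bmd, shift, direction)
            method = "profile"
        except Exception as exc:
            logger.warning("profile BMDL failed for %s (%s); using delta method",
                           fit.name, exc)
            bmdl = _delta_bmdl(fit, bmd, shift, direction)
            method = "delta"
        if np.isfinite(bmdl):
            bmdl = min(bmdl, bmd)

    scaled = float("nan")
    if d is not None:
        levels = np.unique(d)
        nearest = levels[np.argmin(np.abs(levels - bmd))]
        mask = d == nearest
        sigma = math.sqrt(max(float(((fit.responses - fit.predict(d)) ** 2).sum())
                              / d.size, 1e-300))
        scaled = float((fit.responses[mask].mean() - float(fit.predict(nearest)))
                       / (sigma / math.sqrt(mask.sum())))

    lowest = float(np.min(d[d > 0])) if d is not None and np.any(d > 0) else float("nan")
    qc = "questionable_extrapolation" if (np.isfinite(lowest) and bmd < lowest / 3.0) else "ok"
    return BMDResult(fit.name, bmr_sd, float(bmd), float(bmdl), fit.aic, scaled,
                     qc, status="ok", bmdl_method=method)


def exclude_nonmonotonic_top(group_means: Sequence[float], control_sd: float,
                             labels: Sequence[str] | None = None
                             ) -> tuple[list[int], bool]:
    """Decide whether the top dose group breaks an otherwise monotone trend.

    ``group_means`` are ordered by dose (control first).  The top group is
    dropped iff its step from the second-highest group opposes the overall
    trend direction (control to second-highest) and exceeds one control SD
    in magnitude.  Returns ``(retained indices, dropped flag)``.
    """
    means = np.asarray(group_means, dtype=float)
    if means.size < 3:
        raise ValueError("need at least 3 dose groups to judge the top group")
    if control_sd <= 0:
        raise ValueError("control_sd must be > 0")
    trend = means[-2] - means[0]
    step = means[-1] - means[-2]
    reversal = trend != 0 and np.sign(step) == -np.sign(trend) and abs(step) > control_sd
    idx = list(range(means.size - 1)) if reversal else list(range(means.size))
    if reversal:
        top = labels[-1] if labels is not None else f"group {means.size - 1}"
        logger.info("top dose group %s excluded: reversal %.4g exceeds control SD %.4g",
                    top, step, control_sd)
    return idx, bool(reversal)
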