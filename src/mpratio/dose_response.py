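"""Constrained logistic dose-response fitting and LCx estimation.

The model is the log(concentration)-vs-response logistic family with the lower
asymptote fixed at 0 and the upper at 1 (so fitted mortality runs from none to
complete), as used for comparable acute-immobilization curves:

    p(C) = 1 / (1 + (LC50 / C)**h)

with ``h`` the Hill slope.  On the log10 concentration scale this is the
standard two-parameter logistic in ``theta = log10 LC50`` and ``h``.  By
default only ``theta`` is free (``h`` fixed at 1); ``hill_fixed=False``
estimates the slope too.

Observed replicate mortalities are Abbott-corrected for background control
mortality before fitting; the fit is ordinary least squares on the corrected
proportions, one tube = one observation.  Confidence intervals come from
classical linearization (t critical value, df = n_obs - n_free) on the log10
scale and are exponentiated, so bounds are always positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LogisticModel",
    "DoseResponseFit",
    "FitError",
    "DegenerateDataError",
    "ConvergenceError",
    "abbott_correct",
    "fit_dose_response",
    "lcx",
    "lcx_ci",
    "compare_fits",
    "CIOverlap",
]

LN10 = math.log(10.0)


class FitError(RuntimeError):
    """A dose-response fit could not be performed."""


class DegenerateDataError(FitError):
    """The observations carry no dose-response signal (all identical)."""


class ConvergenceError(FitError):
    """The optimizer failed to converge within the bounded restarts."""


def abbott_correct(p_obs, p_control: float):
    """Abbott's correction for background control mortality.

    Returns ``(p_obs - p_control) / (1 - p_control)`` clipped to [0, 1].
    Accepts scalars or arrays.
    """
    p_obs = np.asarray(p_obs, dtype=float)
    if np.any(p_obs < 0) or np.any(p_obs > 1):
        raise ValueError("observed proportions must lie in [0, 1]")
    if not 0 <= p_control < 1:
        raise ValueError(f"control mortality must lie in [0, 1), got {p_control}")
    out = np.clip((p_obs - p_control) / (1.0 - p_control), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LogisticModel:
    """Fitted (or specified) constrained logistic dose-response model."""

    log10_lc50: float
    hill: float = 1.0
    bottom: float = 0.0
    top: float = 1.0
    hill_fixed: bool = True

    def __post_init__(self) -> None:
        if self.hill <= 0:
            raise ValueError(f"Hill slope must be > 0, got {self.hill}")

    @property
    def lc50(self) -> float:
        return 10.0 ** self.log10_lc50

    def predict(self, conc) -> np.ndarray:
        """Predicted mortality at concentration ``conc`` (mg/L, > 0)."""
        logc = np.log10(np.asarray(conc, dtype=float))
        frac = 1.0 / (1.0 + 10.0 ** (self.hill * (self.log10_lc50 - logc)))
        return self.bottom + (self.top - self.bottom) * frac


@dataclass(frozen=True)
class DoseResponseFit:
    """A converged fit for one %MP series, with LC50/LC10 and 95% CIs."""

    model: LogisticModel
    lc50: float
    lc50_ci: tuple[float, float]
    lc10: float
    lc10_ci: tuple[float, float]
    r_squared: float
    n_obs: int
    pct_mp: float = float("nan")
    ss_used: tuple[float, ...] = ()
    ci_level: float = 0.95
    # linearization internals needed to propagate CIs to arbitrary LCx
    cov: tuple = field(default=(), repr=False)  # covariance of free params
    df: int = 0

    def lcx_point(self, x: float) -> float:
        return lcx(self.model, x)

    def lcx_interval(self, x: float) -> tuple[float, float]:
        return lcx_ci(self, x)


def lcx(model: LogisticModel, x: float) -> float:
    """Concentration producing ``x``% effect: ``LC50 * (x/(100-x))**(1/h)``."""
    if not 0 < x < 100:
        raise ValueError(f"effect percentage must lie in (0, 100), got {x}")
    if not (model.bottom == 0.0 and model.top == 1.0):
        raise ValueError("lcx requires the bottom=0, top=1 configuration")
    return model.lc50 * (x / (100.0 - x)) ** (1.0 / model.hill)


def _log10_lcx_gradient(model: LogisticModel, x: float) -> np.ndarray:
    """Gradient of log10 LCx w.r.t. the free parameters (theta[, hill])."""
    r = math.log10(x / (100.0 - x))
    if model.hill_fixed:
        return np.array([1.0])
    return np.array([1.0, -r / model.hill**2])


def lcx_ci(fit: DoseResponseFit, x: float) -> tuple[float, float]:
    """95% CI for LCx, propagated from the fit's covariance on log10 scale.

    With the Hill slope fixed, log10 LCx is log10 LC50 plus a constant, so the
    LCx interval is the LC50 interval scaled by ``(x/(100-x))**(1/h)``.  With
    the slope estimated, the delta method on
    ``log10 LCx = theta + log10(x/(100-x))/h`` is used.
    """
    point = math.log10(lcx(fit.model, x))
    cov = np.atleast_2d(np.asarray(fit.cov, dtype=float))
    g = _log10_lcx_gradient(fit.model, x)
    var = float(g @ cov @ g)
    tcrit = stats.t.ppf(0.5 + fit.ci_level / 2.0, fit.df) if fit.df > 0 else float("inf")
    half = tcrit * math.sqrt(max(var, 0.0))
    return (10.0 ** (point - half), 10.0 ** (point + half))


def _residual_builder(logc: np.ndarray, y: np.ndarray, hill_fixed: bool, hill: float):
    if hill_fixed:

        def resid(params):
            p = 1.0 / (1.0 + 10.0 ** (hill * (params[0] - logc)))
            return p - y

        def jac(params):
            p = 1.0 / (1.0 + 10.0 ** (hill * (params[0] - logc)))
            return (-LN10 * hill * p * (1.0 - p))[:, None]

    else:

        def resid(params):
            theta, h = params
            p = 1.0 / (1.0 + 10.0 ** (h * (theta - logc)))
            return p - y

        def jac(params):
            theta, h = params
            p = 1.0 / (1.0 + 10.0 ** (h * (theta - logc)))
            core = -LN10 * p * (1.0 - p)
            return np.column_stack([core * h, core * (theta - logc)])

    return resid, jac


def fit_dose_response(
    conc: Sequence[float],
    mortality: Sequence[float],
    p_control: float = 0.0,
    hill_fixed: bool = True,
    hill: float = 1.0,
    pct_mp: float = float("nan"),
    ci_level: float = 0.95,
) -> DoseResponseFit:
    """Fit the constrained logistic to replicate-level mortalities.

    Parameters
    ----------
    conc, mortality : sequences
        One entry per tube: positive SS concentration (mg/L) and the observed
        proportion immobilized.  Controls must be excluded beforehand.
    p_control : float
        Pooled background mortality used for Abbott's correction.
    hill_fixed : bool
        If True (default) the Hill slope is held at ``hill`` and only
        log10 LC50 is estimated; otherwise the slope is estimated too.

    Notes
    -----
    log10 LC50 is bounded to [log10 min(C) - 2, log10 max(C) + 2] and the
    optimizer is restarted from three deterministic points spanning the bound,
    so the result carries no seed dependence.
    """
    conc = np.asarray(conc, dtype=float)
    y = abbott_correct(np.asarray(mortality, dtype=float), p_control)
    if conc.shape != y.shape or conc.ndim != 1:
        raise ValueError("conc and mortality must be 1-D sequences of equal length")
    if np.any(conc <= 0):
        raise ValueError("all concentrations must be positive (exclude controls)")
    if len(np.unique(conc)) < 2:
        raise FitError("need >= 2 distinct positive concentrations")
    if np.ptp(y) == 0.0:
        raise DegenerateDataError(
            f"all corrected mortalities identical ({y[0]:.3f}); no dose-response signal"
        )

    logc = np.log10(conc)
    lo, hi = logc.min() - 2.0, logc.max() + 2.0
    resid, jac = _residual_builder(logc, y, hill_fixed, hill)

    if hill_fixed:
        starts = [(t,) for t in np.linspace(lo, hi, 3)]
        bounds = ([lo], [hi])
        n_free = 1
    else:
        starts = [(t, h) for t in np.linspace(lo, hi, 3) for h in (0.5, 1.0, 2.0)]
        bounds = ([lo, 0.05], [hi, 20.0])
        n_free = 2

    best = None
    for x0 in starts:
        sol = optimize.least_squares(resid, x0, jac=jac, bounds=bounds, method="trf")
        if sol.success and (best is None or sol.cost < best.cost - 1e-14):
            best = sol
    if best is None:
        raise ConvergenceError(
            f"logistic fit did not converge for pct_mp={pct_mp!r}"
        )

    params = best.x
    model = LogisticModel(
        log10_lc50=float(params[0]),
        hill=hill if hill_fixed else float(params[1]),
        hill_fixed=hill_fixed,
    )

    n = len(y)
    df = n - n_free
    sse = float(np.sum(resid(params) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")

    J = jac(params)
    s2 = sse / df if df > 0 else float("nan")
    try:
        cov = s2 * np.linalg.pinv(J.T @ J)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pinv rarely fails
        raise ConvergenceError(f"singular linearization for pct_mp={pct_mp!r}") from exc

    fit = DoseResponseFit(
        model=model,
        lc50=model.lc50,
        lc50_ci=(float("nan"), float("nan")),
        lc10=lcx(model, 10.0),
        lc10_ci=(float("nan"), float("nan")),
        r_squared=r2,
        n_obs=n,
        pct_mp=pct_mp,
        ss_used=tuple(sorted(set(conc.tolist()))),
        ci_level=ci_level,
        cov=tuple(map(tuple, cov)),
        df=df,
    )
    # fill the standard intervals through the generic LCx propagation
    object.__setattr__(fit, "lc50_ci", lcx_ci(fit, 50.0))
    object.__setattr__(fit, "lc10_ci", lcx_ci(fit, 10.0))
    return fit


@dataclass(frozen=True)
class CIOverlap:
    """Verdict of the non-overlapping-confidence-interval comparison.

    ``gap`` is 0 when the intervals overlap; otherwise it is the separation
    between them, positive when fit A's interval lies wholly above fit B's and
    negative when wholly below.  A non-zero gap is read as evidence of a
    significant difference between the treatments.
    """

    overlaps: bool
    gap: float

    @property
    def significant(self) -> bool:
        return not self.overlaps


def compare_fits(fit_a: DoseResponseFit, fit_b: DoseResponseFit) -> CIOverlap:
    """Compare two LC50 95% confidence intervals for overlap."""
    lo_a, hi_a = fit_a.lc50_ci
    lo_b, hi_b = fit_b.lc50_ci
    if lo_a > hi_b:  # A wholly above B
        return CIOverlap(False, lo_a - hi_b)
    if lo_b > hi_a:  # A wholly below B
        return CIOverlap(False, -(lo_b - hi_a))
    return CIOverlap(True, 0.0)
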