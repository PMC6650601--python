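"""Effect-threshold derivation from the LCx-vs-%MP relationship.

The per-mixture LCx estimates (x = 10 by default) are modelled as a one-phase
exponential decay in the test particle's mass contribution:

    Y(m) = (Y0 - plateau) * exp(-k * m) + plateau

with ``m`` the %MP.  The no-observed-effect concentration (NOEC) for suspended
solids is operationalized as the lower bound of the reference (0% MP) LC10
95% confidence interval, and the no-effect percentage of the test particle
(NOE%MP) is the %MP at which the decay curve crosses that NOEC.  Above that
pair — more solids than the NOEC of which more than NOE%MP is the test
particle — significantly elevated mortality is predicted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .dose_response import DoseResponseFit
from .mixture import SubsampledFit

__all__ = [
    "DecayFit",
    "ThresholdResult",
    "ThresholdError",
    "DegenerateDecayWarning",
    "fit_decay",
    "solve_noe_pct",
    "derive_thresholds",
    "classify_scenario",
]


class ThresholdError(RuntimeError):
    """Threshold derivation is impossible for the given inputs."""


class DegenerateDecayWarning(UserWarning):
    """The decay fit is no better than a flat line; k is unidentifiable."""


@dataclass(frozen=True)
class DecayFit:
    """One-phase exponential decay of LCx against %MP.

    ``degenerate`` marks the flat fallback (no decaying fit improves on the
    constant model); then ``plateau == y0`` is the flat level and ``k`` is NaN.
    """

    y0: float
    plateau: float
    k: float
    r_squared: float
    x_level: float | None = None
    n_points: int = 0
    degenerate: bool = False

    def predict(self, pct_mp) -> np.ndarray:
        m = np.asarray(pct_mp, dtype=float)
        if self.degenerate:
            return np.full_like(m, self.y0, dtype=float)
        return (self.y0 - self.plateau) * np.exp(-self.k * m) + self.plateau


def fit_decay(
    pct_mp: Sequence[float],
    lcx_values: Sequence[float],
    weights: Sequence[float] | None = None,
    x_level: float | None = None,
) -> DecayFit:
    """Least-squares one-phase exponential decay fit, plateau constrained >= 0.

    ``weights`` (optional, e.g. inverse CI widths) multiply the residuals.
    When no decaying curve improves on the flat (constant) model — as for
    non-decreasing points — a :class:`DegenerateDecayWarning` is emitted and
    the flat alternative is returned.
    """
    m = np.asarray(pct_mp, dtype=float)
    y = np.asarray(lcx_values, dtype=float)
    if m.shape != y.shape or m.ndim != 1:
        raise ValueError("pct_mp and lcx_values must be 1-D and of equal length")
    if len(np.unique(m)) < 3:
        raise ThresholdError("need >= 3 distinct pct_mp values for the decay fit")
    if np.any(y <= 0):
        raise ValueError("all LCx values must be positive")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    mean = float(np.average(y, weights=w**2))
    sse_flat = float(np.sum((w * (y - mean)) ** 2))
    sst = float(np.sum((w * (y - np.average(y, weights=w**2))) ** 2))

    def resid(params):
        y0, plateau, k = params
        return w * ((y0 - plateau) * np.exp(-k * m) + plateau - y)

    span = float(m.max() - m.min())
    k_starts = [0.5 / span, 2.0 / span, 8.0 / span]
    y0_start = float(y[np.argmin(m)])
    plateau_start = float(max(y.min(), 1e-12))
    bounds = ([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf])

    best = None
    for k0 in k_starts:
        sol = optimize.least_squares(
            resid, [y0_start, plateau_start, k0], bounds=bounds, method="trf"
        )
        if sol.success and (best is None or sol.cost < best.cost - 1e-14):
            best = sol

    sse_decay = 2.0 * best.cost if best is not None else float("inf")
    if best is None or sse_decay >= sse_flat * (1.0 - 1e-12):
        warnings.warn(
            "no decaying fit improves on the flat model; returning the flat alternative",
            DegenerateDecayWarning,
            stacklevel=2,
        )
        r2 = 1.0 - sse_flat / sst if sst > 0 else 1.0
        return DecayFit(
            y0=mean,
            plateau=mean,
            k=float("nan"),
            r_squared=r2,
            x_level=x_level,
            n_points=len(m),
            degenerate=True,
        )

    y0, plateau, k = (float(v) for v in best.x)
    r2 = 1.0 - sse_decay / sst if sst > 0 else 1.0
    return DecayFit(y0, plateau, k, r2, x_level=x_level, n_points=len(m))


def solve_noe_pct(fit: DecayFit, noec: float) -> float:
    """%MP at which the decay curve crosses ``noec``.

    Returns 0 when the curve already starts at or below the threshold
    (``noec >= y0``) and ``math.inf`` when the curve never reaches it
    (``noec <= plateau``); otherwise the closed form
    ``-(1/k) * ln((noec - plateau) / (y0 - plateau))``.
    """
    if fit.degenerate:
        return 0.0 if noec >= fit.y0 else math.inf
    if not (fit.k > 0):
        raise ThresholdError(f"decay rate must be > 0, got {fit.k}")
    if noec >= fit.y0:
        return 0.0
    if noec <= fit.plateau:
        return math.inf
    return -math.log((noec - fit.plateau) / (fit.y0 - fit.plateau)) / fit.k


@dataclass(frozen=True)
class ThresholdResult:
    """NOEC and NOE%MP with full provenance.

    ``noec`` is the lower bound of the reference-level (0% MP) LCx confidence
    interval; ``noe_pct_mp`` is where the fitted decay crosses it
    (``math.inf`` when it never does — no %MP threshold within model range).
    """

    noec: float
    noe_pct_mp: float
    decay: DecayFit
    reference_fit: DoseResponseFit | SubsampledFit
    x_level: float
    points: tuple[tuple[float, float], ...]  # (pct_mp, lcx) pairs used


FitLike = DoseResponseFit | SubsampledFit


def _fits_by_pct(fits) -> dict[float, FitLike]:
    if isinstance(fits, Mapping):
        return dict(fits)
    return {f.pct_mp: f for f in fits}


def derive_thresholds(fits, x_level: float = 10.0) -> ThresholdResult:
    """Fit the LCx decay over %MP and derive (NOEC, NOE%MP).

    ``fits`` is a mapping ``pct_mp -> fit`` or an iterable of fits; the 0% MP
    reference level is required, and at least three levels in total.
    """
    by_pct = _fits_by_pct(fits)
    if 0.0 not in by_pct:
        raise ThresholdError("the 0% MP reference level is required to anchor the NOEC")
    if len(by_pct) < 3:
        raise ThresholdError("need >= 3 pct_mp levels for the decay fit")
    pcts = sorted(by_pct)
    points = tuple((p, by_pct[p].lcx_point(x_level)) for p in pcts)
    decay = fit_decay([p for p, _ in points], [v for _, v in points], x_level=x_level)
    ref = by_pct[0.0]
    noec = ref.lcx_interval(x_level)[0]
    noe = solve_noe_pct(decay, noec)
    return ThresholdResult(
        noec=noec,
        noe_pct_mp=noe,
        decay=decay,
        reference_fit=ref,
        x_level=x_level,
        points=points,
    )


def classify_scenario(fits) -> str:
    """Classify the mixture-test outcome from the LC50 confidence intervals.

    ``"B"`` (additive test-particle effect) when the highest-%MP LC50 interval
    lies wholly below the 0% reference interval; ``"C"`` (ameliorating) when
    wholly above; ``"A"`` (no test-particle effect) when they overlap.
    """
    by_pct = _fits_by_pct(fits)
    if len(by_pct) < 2:
        raise ThresholdError("need >= 2 pct_mp levels to classify the outcome")
    ref = by_pct[min(by_pct)]
    top = by_pct[max(by_pct)]
    lo_r, hi_r = ref.lc50_ci
    lo_t, hi_t = top.lc50_ci
    if hi_t < lo_r:
        return "B"
    if lo_t > hi_r:
        return "C"
    return "A"
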