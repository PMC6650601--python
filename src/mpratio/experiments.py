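"""Monte-Carlo parameter-recovery and design-power experiments.

These run the estimators on data drawn from :mod:`mpratio.synthetic` with
known ground truth, quantifying bias and spread of the LC50 estimate and of
the derived NOE%MP threshold at a given design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dose_response import FitError, fit_dose_response
from .mixture import FitOptions, SubsampleScheme, fit_all
from .synthetic import GeneratorConfig, expected_mortality, generate, true_lcx
from .threshold import ThresholdError, derive_thresholds

__all__ = [
    "recover_log10_lc50",
    "analytic_noe_reference",
    "noe_recovery",
    "NoeRecovery",
]


def _sim_seeds(seed: int, n: int) -> np.ndarray:
    """Per-simulation seeds derived from one master seed (all < 2**31)."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64) % (2**31)


def recover_log10_lc50(
    n_sims: int = 500,
    seed: int = 0,
    log10_lc50: float = 2.0,
    hill: float = 1.0,
    concs=(10.0, 31.6, 100.0, 316.0, 1000.0),
    n_replicates: int = 5,
    n_per_tube: int = 10,
) -> np.ndarray:
    """Estimation errors of log10 LC50 over repeated simulated series.

    Each simulation draws ``n_replicates`` binomial tubes per concentration
    from the true logistic and refits with the Hill slope fixed; the returned
    array holds ``estimate - truth`` per simulation.
    """
    lc50 = 10.0**log10_lc50
    conc = np.repeat(np.asarray(concs, dtype=float), n_replicates)
    p = 1.0 / (1.0 + (lc50 / conc) ** hill)
    errors = np.empty(n_sims)
    for i, s in enumerate(_sim_seeds(seed, n_sims)):
        rng = np.random.default_rng(int(s))
        mort = rng.binomial(n_per_tube, p) / n_per_tube
        fit = fit_dose_response(conc, mort, p_control=0.0, hill_fixed=True, hill=hill)
        errors[i] = fit.model.log10_lc50 - log10_lc50
    return errors


def analytic_noe_reference(config: GeneratorConfig, x_level: float = 10.0) -> float:
    """Closed-form (asymptotic) NOE%MP implied by a design and ground truth.

    The reference-level confidence bound that defines the NOEC is a sampling
    quantity, so the design-implied target is computed by first-order theory:
    the OLS variance of log10 LC50 at the 0% level under binomial tube noise
    gives the expected lower LCx bound, and the true LCx decay is solved at
    that bound.  Only the SS concentrations common to all %MP levels enter,
    matching the fitting rule.
    """
    common = set.intersection(
        *(set(config.design.ss_levels_by_pct[p]) for p in config.design.pct_mp_levels)
    )
    concs = np.array(sorted(common))
    reps = config.design.replicates_per_cell
    c = config.control_mortality
    h = config.true_hill

    p_model = np.array([  # corrected-scale expected mortality at 0% MP
        (expected_mortality(config, 0.0, C) - c) / (1.0 - c) for C in concs
    ])
    p_total = c + (1.0 - c) * p_model
    # tube-level residual variance on the corrected scale
    var_tube = p_total * (1.0 - p_total) / config.n_per_tube / (1.0 - c) ** 2
    sigma2 = float(np.mean(np.repeat(var_tube, reps)))
    grad = math.log(10.0) * h * p_model * (1.0 - p_model)
    var_theta = sigma2 / float(np.sum(reps * grad**2))
    n = len(concs) * reps
    tcrit = stats.t.ppf(0.975, n - 1)
    noec = true_lcx(config, 0.0, x_level) / 10.0 ** (tcrit * math.sqrt(var_theta))

    y0, plateau, k = config.true_decay
    scale = (x_level / (100.0 - x_level)) ** (1.0 / h)
    y0x, plx = y0 * scale, plateau * scale
    if noec >= y0x:
        return 0.0
    if noec <= plx:
        return math.inf
    return -math.log((noec - plx) / (y0x - plx)) / k


@dataclass
class NoeRecovery:
    """Distribution of end-to-end NOE%MP estimates against the design target."""

    estimates: np.ndarray  # finite estimates only
    n_unbounded: int  # simulations that returned the +inf sentinel
    n_failed: int  # simulations where a fit or threshold stage errored
    reference: float  # analytic design-implied NOE%MP

    @property
    def median(self) -> float:
        return float(np.median(self.estimates))

    @property
    def median_rel_err(self) -> float:
        return abs(self.median - self.reference) / self.reference

    @property
    def rel_rmse(self) -> float:
        return float(
            np.sqrt(np.mean((self.estimates - self.reference) ** 2)) / self.reference
        )


def noe_recovery(
    n_sims: int = 200,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    x_level: float = 10.0,
) -> NoeRecovery:
    """Run the full pipeline on ``n_sims`` synthetic datasets and collect NOE%MP."""
    base = config or GeneratorConfig()
    reference = analytic_noe_reference(base, x_level)
    options = FitOptions(subsample=SubsampleScheme(seed=seed))
    estimates: list[float] = []
    n_unbounded = 0
    n_failed = 0
    for s in _sim_seeds(seed, n_sims):
        ds = generate(base.with_seed(int(s)))
        try:
            fits = fit_all(ds, options)
            result = derive_thresholds(fits.fits, x_level=x_level)
        except (FitError, ThresholdError):
            n_failed += 1
            continue
        if math.isinf(result.noe_pct_mp):
            n_unbounded += 1
        else:
            estimates.append(result.noe_pct_mp)
    return NoeRecovery(np.asarray(estimates), n_unbounded, n_failed, reference)
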