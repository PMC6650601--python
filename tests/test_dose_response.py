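"""Abbott correction, constrained logistic fits, LCx algebra, CI propagation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from mpratio.dose_response import (
    DegenerateDataError,
    LogisticModel,
    abbott_correct,
    compare_fits,
    fit_dose_response,
    lcx,
    lcx_ci,
)

CONCS5 = np.array([10.0, 31.6, 100.0, 316.0, 1000.0])


def clean_series(lc50=100.0, hill=1.0, concs=CONCS5, reps=1):
    conc = np.repeat(concs, reps)
    p = 1.0 / (1.0 + (lc50 / conc) ** hill)
    return conc, p


def sse_grid_search(conc, y, hill=1.0, lo=-1.0, hi=5.0, step=1e-4):
    """Brute-force minimizer of the 1-parameter logistic SSE on a theta grid."""
    thetas = np.arange(lo, hi + step, step)
    p = 1.0 / (1.0 + 10.0 ** (hill * (thetas[:, None] - np.log10(conc)[None, :])))
    sse = np.sum((p - y[None, :]) ** 2, axis=1)
    i = int(np.argmin(sse))
    return thetas[i], sse[i]


class TestAbbott:
    @pytest.mark.parametrize(
        "p_obs,p_c,expected",
        [(0.55, 0.0, 0.55), (0.55, 0.10, 0.50), (0.05, 0.10, 0.0), (1.0, 0.5, 1.0)],
    )
    def test_closed_forms(self, p_obs, p_c, expected):
        assert abbott_correct(p_obs, p_c) == pytest.approx(expected)

    def test_full_control_mortality_rejected(self):
        with pytest.raises(ValueError):
            abbott_correct(0.5, 1.0)

    @given(p=st.floats(0, 1))
    def test_identity_without_background(self, p):
        assert abbott_correct(p, 0.0) == p

    @given(
        p1=st.floats(0, 1), p2=st.floats(0, 1), pc=st.floats(0, 0.99)
    )
    def test_monotone_in_observed(self, p1, p2, pc):
        lo, hi = sorted((p1, p2))
        assert abbott_correct(lo, pc) <= abbott_correct(hi, pc)


class TestLogisticFit:
    def test_noiseless_recovery_exact(self):
        conc, p = clean_series(lc50=100.0, hill=1.0)
        fit = fit_dose_response(conc, p)
        assert fit.lc50 == pytest.approx(100.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.model.predict(100.0) == pytest.approx(0.5)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(20):
            theta = rng.uniform(0.5, 3.5)
            conc = CONCS5
            p = 1.0 / (1.0 + 10.0 ** (theta - np.log10(conc)))
            y = np.clip(p + rng.normal(0, 0.08, size=p.shape), 0, 1)
            fit = fit_dose_response(conc, y)
            theta_grid, _ = sse_grid_search(conc, y)
            assert fit.model.log10_lc50 == pytest.approx(theta_grid, abs=2e-4)

    def test_abbott_applied_before_fitting(self):
        conc, p = clean_series(lc50=100.0)
        pc = 0.1
        observed = pc + (1 - pc) * p  # background composed independently
        fit = fit_dose_response(conc, observed, p_control=pc)
        assert fit.lc50 == pytest.approx(100.0, rel=1e-6)

    def test_degenerate_series_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_dose_response([10.0, 100.0, 1000.0], [0.4, 0.4, 0.4])

    def test_needs_two_distinct_concentrations(self):
        with pytest.raises(Exception, match="distinct"):
            fit_dose_response([10.0, 10.0], [0.1, 0.9])

    def test_scale_equivariance(self, rng):
        conc, p = clean_series(lc50=100.0)
        y = np.clip(p + rng.normal(0, 0.05, size=p.shape), 0, 1)
        f1 = fit_dose_response(conc, y)
        f2 = fit_dose_response(conc * 7.0, y)
        assert f2.lc50 == pytest.approx(7.0 * f1.lc50, rel=1e-6)
        assert f2.lc50_ci[0] == pytest.approx(7.0 * f1.lc50_ci[0], rel=1e-6)
        assert f2.lc50_ci[1] == pytest.approx(7.0 * f1.lc50_ci[1], rel=1e-6)

    def test_monotonicity_in_observed_mortality(self, rng):
        for _ in range(10):
            conc, p = clean_series(lc50=rng.uniform(50, 500))
            y = np.clip(p + rng.normal(0, 0.05, size=p.shape), 0, 0.9)
            low = fit_dose_response(conc, y).lc50
            high = fit_dose_response(conc, np.clip(y + 0.05, 0, 1)).lc50
            assert high <= low + 1e-9

    def test_hill_free_recovers_slope(self):
        conc, p = clean_series(lc50=100.0, hill=2.0, reps=3)
        fit = fit_dose_response(conc, p, hill_fixed=False)
        assert fit.model.hill == pytest.approx(2.0, rel=1e-4)
        assert fit.lc50 == pytest.approx(100.0, rel=1e-4)

    def test_ci_bracket_ordering(self, rng):
        conc, p = clean_series(lc50=100.0, reps=5)
        y = np.clip(p + rng.normal(0, 0.08, size=p.shape), 0, 1)
        fit = fit_dose_response(conc, y)
        lo, hi = fit.lc50_ci
        assert 0 < lo <= fit.lc50 <= hi
        assert fit.lc10 < fit.lc50
        assert fit.r_squared <= 1.0


class TestLCx:
    def test_x50_is_lc50(self):
        for hill in (0.5, 1.0, 3.0):
            m = LogisticModel(2.0, hill=hill)
            assert lcx(m, 50.0) == pytest.approx(m.lc50)

    def test_hill1_lc10_is_ninth(self):
        m = LogisticModel(2.0, hill=1.0)
        assert lcx(m, 10.0) == pytest.approx(100.0 / 9.0)

    def test_hill2_closed_form_vs_numeric_inversion(self):
        m = LogisticModel(2.0, hill=2.0)
        val = lcx(m, 10.0)
        assert val == pytest.approx(100.0 * (1 / 9) ** 0.5, rel=1e-12)
        root = brentq(lambda c: m.predict(c) - 0.10, 1e-3, 1e6)
        assert val == pytest.approx(root, rel=1e-9)

    @pytest.mark.parametrize("x", [0.0, 100.0, -5.0, 120.0])
    def test_effect_level_domain(self, x):
        with pytest.raises(ValueError):
            lcx(LogisticModel(2.0), x)


class TestLCxCI:
    def test_fixed_hill_interval_scales(self, rng):
        conc, p = clean_series(lc50=100.0, reps=5)
        y = np.clip(p + rng.normal(0, 0.05, size=p.shape), 0, 1)
        fit = fit_dose_response(conc, y)
        lo50, hi50 = fit.lc50_ci
        lo10, hi10 = lcx_ci(fit, 10.0)
        assert lo10 == pytest.approx(lo50 / 9.0, rel=1e-9)
        assert hi10 == pytest.approx(hi50 / 9.0, rel=1e-9)

    def test_x50_interval_is_lc50_interval(self, rng):
        conc, p = clean_series(lc50=100.0, reps=5)
        y = np.clip(p + rng.normal(0, 0.05, size=p.shape), 0, 1)
        fit = fit_dose_response(conc, y, hill_fixed=False)
        assert lcx_ci(fit, 50.0) == pytest.approx(fit.lc50_ci)

    def test_delta_method_matches_parametric_bootstrap(self, rng):
        """Hill estimated: delta interval vs a 2000-draw residual bootstrap."""
        conc, p = clean_series(lc50=100.0, hill=1.3, reps=5)
        y = np.clip(p + rng.normal(0, 0.06, size=p.shape), 0, 1)
        fit = fit_dose_response(conc, y, hill_fixed=False)
        resid = y - fit.model.predict(conc)
        s = np.sqrt(np.sum(resid**2) / fit.df)
        draws = []
        for _ in range(2000):
            y_star = np.clip(fit.model.predict(conc) + rng.normal(0, s, size=y.shape), 0, 1)
            try:
                f_star = fit_dose_response(conc, y_star, hill_fixed=False)
            except Exception:
                continue
            draws.append(np.log10(lcx(f_star.model, 10.0)))
        boot = 10.0 ** np.percentile(draws, [2.5, 97.5])
        lo, hi = lcx_ci(fit, 10.0)
        assert lo == pytest.approx(boot[0], rel=0.10)
        assert hi == pytest.approx(boot[1], rel=0.10)


class TestCompare:
    def test_disjoint_significant(self):
        a = _fit_with_ci((300.0, 520.0))
        b = _fit_with_ci((40.0, 80.0))
        verdict = compare_fits(a, b)
        assert not verdict.overlaps and verdict.significant
        assert verdict.gap == pytest.approx(220.0)

    def test_overlapping_not_significant(self):
        verdict = compare_fits(_fit_with_ci((50.0, 100.0)), _fit_with_ci((90.0, 140.0)))
        assert verdict.overlaps and verdict.gap == 0.0

    def test_identical_fits(self):
        f = _fit_with_ci((90.0, 140.0))
        verdict = compare_fits(f, f)
        assert verdict.overlaps and verdict.gap == 0.0


def _fit_with_ci(ci):
    from mpratio.dose_response import DoseResponseFit

    mid = float(np.sqrt(ci[0] * ci[1]))
    m = LogisticModel(np.log10(mid))
    return DoseResponseFit(
        model=m, lc50=mid, lc50_ci=ci, lc10=mid / 9, lc10_ci=(ci[0] / 9, ci[1] / 9),
        r_squared=1.0, n_obs=10,
    )
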