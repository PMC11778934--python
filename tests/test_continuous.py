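"""Continuous-outcome criteria: golden values, minimality, simulation oracles."""

import numpy as np
import pytest
from scipy import stats

from valsampsize import (
    ContinuousValidationDesign,
    ciw_r2_for_n,
    n_for_citl,
    n_for_r2,
    n_for_resvar,
    n_for_slope_cont,
)
from valsampsize.continuous import (
    resvar_mmoe,
    se_citl,
    se_r2,
    se_slope_cont,
)


class TestGoldenValues:
    """Published pain-intensity worked example (R² 0.40, SD 22.30)."""

    @pytest.mark.parametrize("r2, expected", [(0.40, 886), (0.30, 905)])
    def test_r2_criterion(self, r2, expected):
        assert n_for_r2(r2, 0.1) == expected

    @pytest.mark.parametrize("r2, expected", [(0.40, 184), (0.30, 214)])
    def test_citl_criterion(self, r2, expected):
        assert n_for_citl(497.29, r2, 5) == expected

    @pytest.mark.parametrize("r2, expected", [(0.40, 258), (0.30, 400)])
    def test_slope_criterion(self, r2, expected):
        assert n_for_slope_cont(497.29, r2, 1, 0.3) == expected

    def test_resvar_criterion_independent_of_fit(self):
        # the default-margin requirement is scale-relative: 235 regardless of
        # the assumed R-squared or outcome variance
        assert n_for_resvar() == 235

    def test_anticipated_r2_interval_at_258(self):
        lo, hi = ciw_r2_for_n(0.40, 258)
        assert (round(lo, 2), round(hi, 2)) == (0.31, 0.49)

    def test_solve_reports_binding_criterion(self, pain_design):
        result = pain_design.solve()
        assert result.n_required == 886
        assert result.binding_criterion == "r_squared"
        assert [c.n for c in result.per_criterion] == [886, 184, 258, 235]

    def test_sensitivity_analysis_binding(self, pain_design):
        result = pain_design.replace(r_squared=0.30).solve()
        assert result.n_required == 905
        assert [c.n for c in result.per_criterion] == [905, 214, 400, 235]


class TestContracts:
    def test_quartering_width_roughly_quadruples_n(self):
        # SE ~ 1/sqrt(n) so n scales with 1/width^2
        n_wide = n_for_r2(0.40, 0.2)
        assert n_for_r2(0.40, 0.1) / n_wide == pytest.approx(4.0, rel=0.02)

    @pytest.mark.parametrize(
        "solver, se_fn",
        [
            (lambda w: n_for_r2(0.40, w), lambda n: se_r2(0.40, n)),
            (lambda w: n_for_citl(497.29, 0.40, w), lambda n: se_citl(497.29, 0.40, n)),
            (
                lambda w: n_for_slope_cont(497.29, 0.40, 1, w),
                lambda n: se_slope_cont(0.40, 1, n),
            ),
        ],
    )
    @pytest.mark.parametrize("width", [0.08, 0.1, 0.3, 1.0, 5.0])
    def test_minimality_and_monotonicity(self, solver, se_fn, width):
        n = solver(width)
        target = round(width / 3.92, 4)
        assert se_fn(n) <= target
        if n > 10:  # floor not binding
            assert se_fn(n - 1) > target
        assert solver(width * 1.5) <= n

    def test_resvar_minimality(self):
        n = n_for_resvar(1.1)
        assert resvar_mmoe(n) <= 1.1 < resvar_mmoe(n - 1)

    def test_inverse_consistency_r2(self):
        n = n_for_r2(0.40, 0.1)
        lo, hi = ciw_r2_for_n(0.40, n)
        assert hi - lo <= 0.1

    def test_r2_interval_shrinks_to_zero(self):
        lo, hi = ciw_r2_for_n(0.40, 10_000_000)
        assert hi - lo < 1e-3

    def test_tiny_outcome_variance_hits_floor(self):
        assert n_for_citl(1e-12, 0.40, 5) == 10

    @pytest.mark.parametrize("r2", [0.0, 1.0, -0.2])
    def test_degenerate_r2_rejected(self, r2):
        with pytest.raises(ValueError, match="r_squared"):
            n_for_r2(r2, 0.1)

    def test_design_accepts_sd_in_place_of_variance(self):
        d = ContinuousValidationDesign(
            r_squared=0.40, sd_y=22.30, ciw_citl=5, ciw_slope=0.3
        )
        assert d.var_y == pytest.approx(497.29)
        assert d.solve().n_required == 886

    def test_design_requires_exactly_one_scale_input(self):
        with pytest.raises(ValueError, match="var_y or sd_y"):
            ContinuousValidationDesign(r_squared=0.4, ciw_citl=5, ciw_slope=0.3)


class TestSimulationOracles:
    """Empirical SEs from simulated validation studies match the analytic SEs."""

    def test_slope_se_against_monte_carlo(self):
        # validation datasets drawn under the assumed truth: outcomes equal
        # predictions plus normal residuals
        rng = np.random.default_rng(2024)
        n, reps = 258, 6000
        sd_pred = np.sqrt(0.40 * 497.29)
        sd_res = np.sqrt(0.60 * 497.29)
        pred = rng.normal(0.0, sd_pred, (reps, n))
        y = pred + rng.normal(0.0, sd_res, (reps, n))
        pc = pred - pred.mean(axis=1, keepdims=True)
        slopes = (pc * y).sum(axis=1) / (pc * pc).sum(axis=1)
        analytic = se_slope_cont(0.40, 1, n)
        assert analytic == pytest.approx(0.0765, abs=5e-4)  # the quoted target SE
        assert slopes.std(ddof=1) == pytest.approx(analytic, rel=0.05)

    def test_citl_se_against_monte_carlo(self):
        rng = np.random.default_rng(7)
        n, reps = 184, 20_000
        resid = rng.normal(0.0, np.sqrt(0.60 * 497.29), (reps, n))
        analytic = se_citl(497.29, 0.40, n)
        assert resid.mean(axis=1).std(ddof=1) == pytest.approx(analytic, rel=0.03)

    def test_resvar_chisquare_interval_coverage(self):
        # the margin-of-error criterion is equivalent to a chi-square CI for
        # the residual variance; its coverage at n=235 should be ~95%
        rng = np.random.default_rng(99)
        n, reps, sigma2 = 235, 20_000, 298.374
        nu = n - 2
        s2 = sigma2 * rng.chisquare(nu, reps) / nu
        lo = s2 * nu / stats.chi2.ppf(0.975, nu)
        hi = s2 * nu / stats.chi2.ppf(0.025, nu)
        coverage = np.mean((lo <= sigma2) & (sigma2 <= hi))
        assert coverage == pytest.approx(0.95, abs=0.01)
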