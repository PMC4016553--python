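"""Survivor/mortality integrals, the mortality-vs-cutoff curve, and optimization."""

import math

import numpy as np
import pytest

from hcc_alloc import (
    CohortParams,
    ModelParams,
    crossing_size,
    equivalent_threshold,
    grafts_used,
    mortality_curve,
    mortality_slope,
    nontransplanted_survivors,
    optimal_threshold,
    total_mortality,
    total_survivors,
    transplanted_survivors,
    transplanted_survivors_closed_form,
)

# Closed-form reference values in the baseline scenario, derived analytically:
#   TS(inf)  = F e^{-a0 T} lam/(lam + d2 T)               = 357.5581
#   NTS(0)/N = e^{-2 a0 T}(e^{a0 T} - 1)/(a0 T)  (lam = delta1)
M0_CLOSED = 1500 * (1 - math.exp(-0.48) * (math.exp(0.24) - 1) / 0.24)        # 450.9721
TS_INF = 500 * math.exp(-0.24) * 0.3 / (0.3 + 0.006 * 5)                       # 357.5581
M_INF_CLOSED = 1500 - TS_INF - 1000 * math.exp(-0.48) * (math.exp(0.24) - 1) / 0.24


class TestTransplantedSurvivors:
    @pytest.mark.parametrize("s0", [0.5, 2.0, 5.0, 7.0, 12.0, np.inf])
    def test_quadrature_matches_closed_form(self, s0, baseline_model, baseline_cohort):
        num = transplanted_survivors(s0, baseline_model, baseline_cohort)
        ana = transplanted_survivors_closed_form(s0, baseline_model, baseline_cohort)
        assert num == pytest.approx(ana, rel=1e-8)

    def test_limits(self, baseline_model, baseline_cohort):
        assert transplanted_survivors(0.0, baseline_model, baseline_cohort) == 0.0
        assert transplanted_survivors(np.inf, baseline_model, baseline_cohort) == (
            pytest.approx(TS_INF, rel=1e-8)
        )

    def test_zero_horizon_equals_grafts_used(self, baseline_cohort):
        p0 = ModelParams(T=0.0)
        for s0 in (1.0, 5.0, 10.0):
            assert transplanted_survivors(s0, p0, baseline_cohort) == pytest.approx(
                grafts_used(s0, baseline_cohort, p0.lam), rel=1e-10
            )


class TestNontransplantedSurvivors:
    def test_no_transplant_closed_form(self, baseline_model, baseline_cohort):
        # lam = delta1 = 0.3 admits a closed form via u = exp(-delta1 s)
        expect = 1500 * math.exp(-0.48) * (math.exp(0.24) - 1) / 0.24  # 1049.03
        assert nontransplanted_survivors(0.0, baseline_model, baseline_cohort) == (
            pytest.approx(expect, rel=1e-8)
        )

    def test_zero_horizon_complement(self, baseline_cohort):
        p0 = ModelParams(T=0.0)
        for s0 in (0.0, 3.0, 8.0):
            assert nontransplanted_survivors(s0, p0, baseline_cohort) == pytest.approx(
                baseline_cohort.N - grafts_used(s0, baseline_cohort, p0.lam), rel=1e-10
            )

    def test_cutoff_dependence_scales_with_graft_supply(self, baseline_model):
        # the policy's imprint on NTS is proportional to F
        def effect(F):
            c = CohortParams(F=F)
            return (nontransplanted_survivors(0.0, baseline_model, c)
                    - nontransplanted_survivors(6.0, baseline_model, c))

        assert effect(200) == pytest.approx(2 * effect(100), rel=1e-8)


class TestTotals:
    def test_baseline_extremes_match_closed_forms(self, baseline_model, baseline_cohort):
        assert total_mortality(0.0, baseline_model, baseline_cohort) == (
            pytest.approx(M0_CLOSED, abs=1e-6)
        )
        assert total_mortality(np.inf, baseline_model, baseline_cohort) == (
            pytest.approx(M_INF_CLOSED, abs=1e-6)
        )
        assert total_survivors(0.0, baseline_model, baseline_cohort) == (
            pytest.approx(1500 - M0_CLOSED, abs=1e-6)
        )

    def test_zero_horizon_nobody_dies(self, baseline_cohort):
        p0 = ModelParams(T=0.0)
        assert total_survivors(4.0, p0, baseline_cohort) == pytest.approx(1500, rel=1e-10)
        assert total_mortality(4.0, p0, baseline_cohort) == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("s0", [0.0, 1.0, 5.0, 7.03, 12.0])
    def test_conservation(self, s0, baseline_model, baseline_cohort):
        total = (total_survivors(s0, baseline_model, baseline_cohort)
                 + total_mortality(s0, baseline_model, baseline_cohort))
        assert total == pytest.approx(baseline_cohort.N, abs=1e-9 * baseline_cohort.N)


class TestMortalityCurve:
    def test_shape_around_the_optimum(self, baseline_model, baseline_cohort):
        curve = mortality_curve((4.0, 10.0, 0.05), baseline_model, baseline_cohort)
        s, d = curve.thresholds, curve.deaths
        assert np.all(np.diff(d[s <= 7.0]) < 0)       # decreasing up to the crossing
        assert np.all(np.diff(d[s >= 7.05]) > 0)      # increasing beyond it
        assert d[np.isclose(s, 6.0)][0] < d[np.isclose(s, 5.0)][0]

    def test_invariants(self, baseline_model, baseline_cohort):
        curve = mortality_curve((0.0, 15.0, 0.25), baseline_model, baseline_cohort)
        N, F = baseline_cohort.N, baseline_cohort.F
        assert np.allclose(curve.deaths + curve.survivors, N, atol=1e-9 * N)
        assert np.all((curve.deaths >= 0) & (curve.deaths <= N))
        assert np.all(curve.grafts <= F + 1e-9)

    def test_flat_when_transplant_changes_nothing(self, baseline_cohort):
        # matched-slope limit: alpha_t approximates alpha_nt to O((delta1*s)^2)
        d1 = 1e-6
        p = ModelParams(delta1=d1, delta2=0.048 * d1)
        curve = mortality_curve((0.0, 15.0, 1.0), p, baseline_cohort)
        assert np.ptp(curve.deaths) < 1e-6

    def test_empty_and_unordered_grids_rejected(self, baseline_model, baseline_cohort):
        with pytest.raises(ValueError, match="non-empty"):
            mortality_curve(np.array([]), baseline_model, baseline_cohort)
        with pytest.raises(ValueError, match="ordered"):
            mortality_curve(np.array([3.0, 1.0]), baseline_model, baseline_cohort)


class TestOptimization:
    def test_slope_matches_finite_difference(self, baseline_model, baseline_cohort):
        h = 1e-5
        for s0 in (1.0, 5.0, 7.0, 10.0):
            fd = (total_mortality(s0 + h, baseline_model, baseline_cohort)
                  - total_mortality(s0 - h, baseline_model, baseline_cohort)) / (2 * h)
            assert mortality_slope(s0, baseline_model, baseline_cohort) == (
                pytest.approx(fd, abs=1e-6)
            )

    def test_optimum_sits_at_hazard_crossing(self, baseline_model, baseline_cohort):
        s_star, m_star = optimal_threshold(baseline_model, baseline_cohort)
        assert s_star == pytest.approx(crossing_size(baseline_model), abs=1e-6)
        assert m_star == pytest.approx(
            total_mortality(s_star, baseline_model, baseline_cohort), rel=1e-12
        )
        # and the same identity holds away from the baseline parameters
        for p in (ModelParams(alpha0=0.06, delta1=0.2, delta2=0.004),
                  ModelParams(alpha0=0.03, delta1=0.4, delta2=0.008, lam=0.4)):
            s_opt, _ = optimal_threshold(p, baseline_cohort, grid=(0.0, 20.0, 0.1))
            assert s_opt == pytest.approx(crossing_size(p), abs=1e-6)

    def test_boundary_minimum_when_transplant_never_helps(
            self, flat_hazard_model, baseline_cohort):
        s_star, m_star = optimal_threshold(flat_hazard_model, baseline_cohort)
        assert s_star == 0.0
        assert m_star == pytest.approx(
            total_mortality(0.0, flat_hazard_model, baseline_cohort), rel=1e-12
        )

    def test_equivalent_threshold(self, baseline_model, baseline_cohort):
        s_eq = equivalent_threshold(baseline_model, baseline_cohort)
        s_star, _ = optimal_threshold(baseline_model, baseline_cohort)
        assert s_eq is not None and s_eq > s_star
        m_ref = total_mortality(baseline_cohort.S_M, baseline_model, baseline_cohort)
        residual = total_mortality(s_eq, baseline_model, baseline_cohort) - m_ref
        assert abs(residual) < 1e-6 * baseline_cohort.N
        assert s_eq == pytest.approx(10.186, abs=0.01)

    def test_equivalent_threshold_undefined_cases(
            self, flat_hazard_model, baseline_cohort):
        assert equivalent_threshold(flat_hazard_model, baseline_cohort) is None
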