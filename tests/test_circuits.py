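"""Promoter layer, split-operon gates, comparator and ODR statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from luxcircuit import (
    DoseResponse,
    GateTruthTable,
    LuxReactionParams,
    PPGateParams,
    PromoterParams,
    ThresholdUndefinedError,
    comparator_transfer,
    detection_threshold,
    gate_truth_table,
    local_loglog_slope,
    min_gate_output,
    odr,
    pp_gate_output,
    promoter_activity,
    soft_min,
    wildtype_operon_response,
)
from luxcircuit.fitting import threshold_series

nonneg = st.floats(min_value=0.0, max_value=1e6)


class TestPromoterActivity:
    def test_zero_inducer_zero_basal_is_silent(self):
        p = PromoterParams(vmax=3.0, K=2.0, n=2.0, basal=0.0)
        assert promoter_activity(p, 0.0) == 0.0

    @pytest.mark.parametrize("n", [1.0, 2.0, 4.0])
    def test_half_activation_at_K(self, n):
        p = PromoterParams(vmax=2.0, K=5.0, n=n, basal=0.0)
        assert promoter_activity(p, 5.0) == pytest.approx(1.0)

    def test_saturates_at_vmax(self):
        p = PromoterParams(vmax=7.0, K=1.0, n=1.0, basal=0.05)
        assert promoter_activity(p, 1e9) == pytest.approx(7.0, rel=1e-6)

    def test_negative_inducer_rejected(self, leaky_promoter):
        with pytest.raises(ValueError):
            promoter_activity(leaky_promoter, -1.0)


class TestWildtypeOperon:
    def analytic_slope(self, x, params, scale_F, scale_R):
        gamma = params.K_F * scale_F / (params.K_R * scale_R)
        return 1.0 + 1.0 / (1.0 + gamma * x)

    def test_output_strictly_increasing(self, unit_lux, six_decade_grid):
        dr = wildtype_operon_response(six_decade_grid, unit_lux)
        assert np.all(np.diff(dr.outputs) > 0)

    @pytest.mark.parametrize("scale_F, scale_R", [(1.0, 1.0), (0.3, 2.0), (5.0, 0.5)])
    def test_slopes_match_analytic_formula(self, unit_lux, scale_F, scale_R):
        x = np.logspace(-3, 3, 200)
        dr = wildtype_operon_response(x, unit_lux, scale_F, scale_R)
        slopes = local_loglog_slope(dr)
        expected = self.analytic_slope(x[1:-1], unit_lux, scale_F, scale_R)
        assert np.abs(slopes - expected).max() < 1e-3

    def test_slopes_strictly_between_one_and_two(self, unit_lux, six_decade_grid):
        dr = wildtype_operon_response(six_decade_grid, unit_lux)
        slopes = local_loglog_slope(dr)
        assert slopes.min() > 1.0 and slopes.max() < 2.0

    def test_slope_limits_two_at_low_one_at_high_drive(self, unit_lux):
        x = np.logspace(-6, 6, 400)
        slopes = local_loglog_slope(wildtype_operon_response(x, unit_lux))
        assert slopes[0] == pytest.approx(2.0, abs=1e-3)
        assert slopes[-1] == pytest.approx(1.0, abs=1e-3)


class TestLocalLogLogSlope:
    def test_exact_power_law_recovered(self):
        x = np.logspace(-1, 2, 30)
        slopes = local_loglog_slope(DoseResponse(x, x**1.45))
        assert np.allclose(slopes, 1.45)

    def test_constant_output_gives_zero_slope(self):
        x = np.logspace(0, 2, 10)
        slopes = local_loglog_slope(DoseResponse(x, np.full_like(x, 3.0)))
        assert np.allclose(slopes, 0.0)

    def test_nonpositive_values_rejected(self):
        x = np.logspace(0, 1, 5)
        with pytest.raises(ValueError):
            local_loglog_slope(DoseResponse(x, np.array([1, 2, 0, 4, 5.0])))


class TestSoftMin:
    @pytest.mark.parametrize(
        "a, b, expected", [(1.0, 1.0, 0.5), (0.0, 5.0, 0.0), (3.0, 6.0, 2.0)]
    )
    def test_values(self, a, b, expected):
        assert soft_min(a, b) == pytest.approx(expected)

    def test_both_zero(self):
        assert soft_min(0.0, 0.0) == 0.0

    @given(a=nonneg, b=nonneg)
    @settings(max_examples=200, deadline=None)
    def test_sandwich_bound(self, a, b):
        # soft minimum lies between min/2 and min
        out = soft_min(a, b)
        m = min(a, b)
        tol = 1e-9 * max(m, 1.0)
        assert m / 2 - tol <= out <= m + tol


class TestLogicGates:
    def test_min_gate_off_corner_is_softmin_of_leaks(self, leaky_promoter):
        leak = leaky_promoter.vmax * leaky_promoter.basal
        out = min_gate_output(0.0, 0.0, leaky_promoter, leaky_promoter)
        assert out == pytest.approx(soft_min(leak, leak))

    def test_min_gate_symmetric_high_corner(self, leaky_promoter):
        hi = 100 * leaky_promoter.K
        h = promoter_activity(leaky_promoter, hi)
        out = min_gate_output(hi, hi, leaky_promoter, leaky_promoter)
        assert out == pytest.approx(h / 2)

    def test_min_gate_bounded_by_smaller_branch(self, leaky_promoter):
        rng = np.random.default_rng(0)
        for arab, ahl in rng.uniform(0, 50, size=(20, 2)):
            out = min_gate_output(arab, ahl, leaky_promoter, leaky_promoter)
            cap = min(
                promoter_activity(leaky_promoter, arab),
                promoter_activity(leaky_promoter, ahl),
            )
            assert out <= cap + 1e-12

    def test_pp_gate_zero_activity_silences(self):
        p0 = PromoterParams(basal=0.0)
        assert pp_gate_output(0.0, 10.0, p0, p0, PPGateParams()) == 0.0

    def test_pp_gate_symmetric_square(self, leaky_promoter):
        hi = 100 * leaky_promoter.K
        h = promoter_activity(leaky_promoter, hi)
        out = pp_gate_output(hi, hi, leaky_promoter, leaky_promoter, PPGateParams(K_AB=1.0))
        assert out == pytest.approx(h**2)

    def test_pp_gate_bilinear_scaling(self):
        p1 = PromoterParams(vmax=1.0, basal=0.1)
        p2 = PromoterParams(vmax=2.0, basal=0.1)
        gp = PPGateParams()
        # scaling both branch vmax by s scales output by s^2
        assert pp_gate_output(1.0, 1.0, p2, p2, gp) == pytest.approx(
            4 * pp_gate_output(1.0, 1.0, p1, p1, gp)
        )

    def test_truth_table_corners_use_basal_and_saturation(self, leaky_promoter):
        gate = lambda a, b: min_gate_output(a, b, leaky_promoter, leaky_promoter)
        table = gate_truth_table(gate, leaky_promoter, leaky_promoter)
        assert table.I11 > table.I10 == table.I01 > table.I00 > 0


class TestODR:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (GateTruthTable(1, 1, 1, 1), 0.0),
            (GateTruthTable(1, 1, 1, 10), 1.0),
            (GateTruthTable(1, 1, 50, 100), np.log10(2)),
        ],
    )
    def test_values(self, table, expected):
        assert odr(table) == pytest.approx(expected)

    @given(
        i00=st.floats(1e-3, 1e3), i01=st.floats(1e-3, 1e3),
        i10=st.floats(1e-3, 1e3), i11=st.floats(1e-3, 1e3),
        scale=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, i00, i01, i10, i11, scale):
        t1 = GateTruthTable(i00, i01, i10, i11)
        t2 = GateTruthTable(scale * i00, scale * i01, scale * i10, scale * i11)
        assert odr(t2) == pytest.approx(odr(t1), abs=1e-9)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            GateTruthTable(0.0, 1.0, 1.0, 1.0)


class TestComparator:
    @pytest.fixture
    def promoters(self):
        return PromoterParams(K=1.0, basal=0.02), PromoterParams(K=1.0, basal=0.02)

    @pytest.mark.parametrize("design", ["luxCDE-luxAB", "luxA-luxC"])
    def test_threshold_rises_with_ahl(self, unit_lux, promoters, design):
        p_bad, p_lux = promoters
        arab = np.logspace(-3, 3, 60)
        curves = {
            ahl: comparator_transfer(arab, ahl, design, p_bad, p_lux, unit_lux)
            for ahl in (0.5, 1.0, 2.0, 4.0)
        }
        pairs = threshold_series(curves)
        thresholds = [thr for _, thr in pairs]
        assert np.all(np.diff(thresholds) >= 0)

    def test_plateau_proportional_to_reverse_drive(self, promoters):
        # at saturating Arabinose the output tracks E_R: use saturating AHL
        # levels scaled via vmax so the reverse drive doubles exactly
        arab = np.logspace(-3, 4, 80)
        lo = PromoterParams(K=1.0, basal=0.02, vmax=1.0)
        hi = PromoterParams(K=1.0, basal=0.02, vmax=2.0)
        big_ahl = 1e6
        p_bad = PromoterParams(K=1.0, basal=0.02)
        lux = LuxReactionParams(K_R=1e-3)  # keep K_deff well below max E_F
        i_lo = comparator_transfer(arab, big_ahl, "luxCDE-luxAB", p_bad, lo, lux)
        i_hi = comparator_transfer(arab, big_ahl, "luxCDE-luxAB", p_bad, hi, lux)
        assert i_hi.outputs[-1] == pytest.approx(2 * i_lo.outputs[-1], rel=1e-2)

    def test_fold_change_constant_in_subthreshold_regime(self, promoters):
        # with E_F << K_deff the output is proportional to E_F and the
        # reverse drive cancels, so ON/OFF fold change is 1/basal at any AHL
        p_bad, p_lux = promoters
        arab = np.logspace(-3, 3, 60)
        lux = LuxReactionParams(K_R=1000.0)
        folds = []
        for ahl in (0.5, 4.0):
            dr = comparator_transfer(arab, ahl, "luxA-luxC", p_bad, p_lux, lux)
            folds.append(dr.outputs.max() / dr.outputs.min())
        assert folds[0] == pytest.approx(folds[1], rel=0.01)
        assert folds[0] == pytest.approx(1 / p_bad.basal, rel=0.1)

    def test_unknown_design_rejected(self, unit_lux, promoters):
        p_bad, p_lux = promoters
        with pytest.raises(ValueError):
            comparator_transfer(np.logspace(0, 1, 5), 1.0, "luxE-only", p_bad, p_lux, unit_lux)


class TestDetectionThreshold:
    def test_hill_curve_recovers_K(self):
        # grid wide enough that the observed range spans ~0 to ~vmax, so the
        # half-height input coincides with the half-activation constant
        x = np.logspace(-2, 5, 200)
        dr = DoseResponse(x, x / (x + 30.0))
        assert detection_threshold(dr) == pytest.approx(30.0, rel=1e-2)

    def test_input_rescaling_rescales_threshold(self):
        x = np.logspace(-1, 3, 100)
        y = x / (x + 30.0)
        t1 = detection_threshold(DoseResponse(x, y))
        t2 = detection_threshold(DoseResponse(10 * x, y))
        assert t2 == pytest.approx(10 * t1, rel=1e-9)

    def test_flat_curve_has_no_threshold(self):
        x = np.logspace(0, 2, 10)
        with pytest.raises(ThresholdUndefinedError):
            detection_threshold(DoseResponse(x, np.full_like(x, 5.0)))

    def test_nonmonotone_curve_rejected(self):
        x = np.logspace(0, 2, 5)
        with pytest.raises(ThresholdUndefinedError):
            detection_threshold(DoseResponse(x, np.array([1.0, 5.0, 3.0, 8.0, 9.0])))
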