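import math

import numpy as np
import pytest

from magbead import calibration as cal

A_REF, B_REF = 355.7, 0.069


def _points(conc, A=A_REF, B=B_REF, noise=None, rng=None):
    out = []
    for c in conc:
        val = cal.saturation_model(A, B, c)
        if noise:
            val += rng.normal(0.0, noise)
        out.append(cal.CalibrationPoint(c, val))
    return out


class TestSaturationModel:
    def test_passes_through_origin(self):
        assert cal.saturation_model(A_REF, B_REF, 0.0) == 0.0

    def test_asymptote(self):
        assert cal.saturation_model(A_REF, B_REF, 1e9) == pytest.approx(A_REF)

    def test_value_against_plain_math_oracle(self):
        # independent high-precision evaluation at C = 10
        expected = A_REF * (1.0 - math.exp(-B_REF * 10.0))
        assert cal.saturation_model(A_REF, B_REF, 10.0) == pytest.approx(
            expected, rel=1e-15)

    def test_monotone_in_C(self):
        c = np.linspace(0, 100, 200)
        vals = cal.saturation_model(A_REF, B_REF, c)
        assert np.all(np.diff(vals) > 0)


class TestFitFull:
    def test_noiseless_recovery(self):
        fit = cal.fit_full(_points([5.0, 10.0, 20.0, 40.0, 75.0]))
        assert fit.A == pytest.approx(A_REF, rel=1e-6)
        assert fit.B == pytest.approx(B_REF, rel=1e-6)

    def test_zero_concentration_excluded(self):
        pts = _points([0.0, 5.0, 10.0, 20.0, 40.0, 75.0])
        pts[0] = cal.CalibrationPoint(0.0, 1e6)  # poisoned origin, must be ignored
        fit = cal.fit_full(pts)
        assert fit.A == pytest.approx(A_REF, rel=1e-6)

    def test_two_exact_points_interpolate(self):
        fit = cal.fit_full(_points([10.0, 40.0]))
        assert fit.residual_norm < 1e-8
        assert fit.A_uncertainty == 0.0 and fit.B_uncertainty == 0.0

    def test_needs_two_distinct_nonzero(self):
        with pytest.raises(ValueError):
            cal.fit_full(_points([0.0, 10.0]))

    def test_noisy_recovery_unbiased(self, rng):
        # simulation study: mean recovered parameters within 2 SE of truth
        As, Bs = [], []
        for _ in range(200):
            fit = cal.fit_full(_points([5.0, 10.0, 20.0, 40.0, 75.0],
                                       noise=5.0, rng=rng))
            As.append(fit.A)
            Bs.append(fit.B)
        for vals, truth in ((As, A_REF), (Bs, B_REF)):
            se = np.std(vals, ddof=1) / math.sqrt(len(vals))
            assert abs(np.mean(vals) - truth) < 2.0 * se + 1e-12

    def test_uncertainty_coverage(self, rng):
        # ~68% of fits should bracket the truth within 1 reported sigma
        hits = 0
        n = 300
        for _ in range(n):
            fit = cal.fit_full(_points([5.0, 10.0, 20.0, 40.0, 75.0],
                                       noise=5.0, rng=rng))
            hits += abs(fit.A - A_REF) < fit.A_uncertainty
        # binomial 3-sigma band around 0.68 for n = 300 (+ slack for the
        # linearization at n_points = 5)
        assert 0.50 < hits / n < 0.90


class TestFitAFixedB:
    def test_noiseless_recovery(self):
        fit = cal.fit_A_fixed_B(_points([20.0, 40.0, 75.0]), B_REF)
        assert fit.A == pytest.approx(A_REF, rel=1e-12)
        assert fit.B_fixed

    def test_single_point_closed_form(self):
        c, i = 30.0, 200.0
        fit = cal.fit_A_fixed_B([cal.CalibrationPoint(c, i)], B_REF,
                                include_origin=False)
        assert fit.A == pytest.approx(i / (1.0 - math.exp(-B_REF * c)),
                                      rel=1e-12)

    def test_origin_only_adds_dof(self):
        pts = _points([20.0, 40.0, 75.0])
        with_o = cal.fit_A_fixed_B(pts, B_REF, include_origin=True)
        without = cal.fit_A_fixed_B(pts, B_REF, include_origin=False)
        assert with_o.A == pytest.approx(without.A, rel=1e-12)
        assert with_o.n_points == without.n_points + 1

    def test_requires_nonzero_point(self):
        with pytest.raises(ValueError):
            cal.fit_A_fixed_B([cal.CalibrationPoint(0.0, 0.0)], B_REF)

    def test_reference_run_magnitudes(self):
        # the published run reports A = 355.7 +/- 16.3 ERF with B frozen at
        # 0.069; qualitative reproduction only (raw channel values unprinted)
        fit = cal.fit_A_fixed_B(_points([20.0, 40.0, 75.0]), B_REF, 0.006)
        assert 300.0 < fit.A < 400.0


class TestInversion:
    def test_zero_signal_zero_concentration(self):
        fit = cal.CalibrationFit(A_REF, 16.3, B_REF, 0.006)
        assert cal.invert_concentration(fit, cal.QuantInput(0.0)) == 0.0

    def test_round_trip(self):
        fit = cal.CalibrationFit(A_REF, 0.0, B_REF, 0.0)
        for c in (1.0, 10.0, 100.0, 500.0):
            i = cal.saturation_model(A_REF, B_REF, c * 0.1 / 1.6)
            inp = cal.QuantInput(i, dilution=0.1, mass_ratio=1.6)
            assert cal.invert_concentration(fit, inp) == pytest.approx(
                c, rel=1e-12)

    def test_forward_consistency(self):
        fit = cal.CalibrationFit(A_REF, 0.0, B_REF, 0.0)
        inp = cal.QuantInput(267.0, 0.1, 1.6)
        cx = cal.invert_concentration(fit, inp)
        assert cal.saturation_model(A_REF, B_REF, cx * 0.1 / 1.6) == \
            pytest.approx(267.0, rel=1e-12)

    def test_printed_inputs_direct_evaluation(self):
        # direct plain-math evaluation of the inversion at the reference
        # inputs (the published 241 ng/mL is not reproduced by the formula;
        # the direct value is asserted instead)
        fit = cal.CalibrationFit(A_REF, 16.3, B_REF, 0.006)
        inp = cal.QuantInput(267.0, 0.1, 1.6)
        expected = (1.6 / (B_REF * 0.1)) * math.log(A_REF / (A_REF - 267.0))
        got = cal.invert_concentration(fit, inp)
        assert got == pytest.approx(expected, rel=1e-14)
        assert got == pytest.approx(322.0, abs=0.1)

    def test_saturated_signal_rejected(self):
        fit = cal.CalibrationFit(A_REF, 0.0, B_REF, 0.0)
        with pytest.raises(cal.SaturationError):
            cal.invert_concentration(fit, cal.QuantInput(360.0))

    def test_negative_signal_needs_flag(self):
        fit = cal.CalibrationFit(A_REF, 0.0, B_REF, 0.0)
        with pytest.raises(ValueError):
            cal.invert_concentration(fit, cal.QuantInput(-1.0))
        assert cal.invert_concentration(fit, cal.QuantInput(-1.0),
                                        allow_negative=True) < 0

    def test_monotone_in_signal_and_asymptote(self):
        fit = cal.CalibrationFit(A_REF, 0.0, B_REF, 0.0)
        big = cal.CalibrationFit(2 * A_REF, 0.0, B_REF, 0.0)
        c1 = cal.invert_concentration(fit, cal.QuantInput(100.0))
        c2 = cal.invert_concentration(fit, cal.QuantInput(150.0))
        c3 = cal.invert_concentration(big, cal.QuantInput(100.0))
        assert c2 > c1 > c3


class TestErrorBudget:
    def test_zero_uncertainty_zero_error(self):
        fit = cal.CalibrationFit(A_REF, 0.0, B_REF, 0.0)
        total, contrib = cal.propagate_error(fit, cal.QuantInput(267.0))
        assert total == 0.0 and all(v == 0.0 for v in contrib.values())

    def test_B_relative_contribution_under_10_percent(self):
        fit = cal.CalibrationFit(A_REF, 0.0, B_REF, 0.006)
        inp = cal.QuantInput(267.0)
        cx = cal.invert_concentration(fit, inp)
        total, contrib = cal.propagate_error(fit, inp)
        rel = contrib["B"] / cx
        assert rel == pytest.approx(0.006 / 0.069, rel=1e-12)
        assert rel < 0.10

    def test_printed_total_error_reproduced(self):
        # quadrature through dA = 16.3, dB = 0.006 at the direct-evaluation
        # concentration gives the published ~43 ng/mL absolute error
        fit = cal.CalibrationFit(A_REF, 16.3, B_REF, 0.006)
        total, _ = cal.propagate_error(fit, cal.QuantInput(267.0))
        assert total == pytest.approx(43.0, abs=1.0)

    def test_partials_match_finite_differences(self):
        fit = cal.CalibrationFit(A_REF, 1.0, B_REF, 0.001)
        inp = cal.QuantInput(267.0, 0.1, 1.6, I_x_uncertainty=1.0)
        _, contrib = cal.propagate_error(fit, inp)

        def cx(A, B, I):
            return (1.6 / (B * 0.1)) * math.log(A / (A - I))

        h = 1e-6
        dA = (cx(A_REF + h, B_REF, 267.0) - cx(A_REF - h, B_REF, 267.0)) / (2 * h)
        dB = (cx(A_REF, B_REF + 1e-9, 267.0) - cx(A_REF, B_REF - 1e-9, 267.0)) / 2e-9
        dI = (cx(A_REF, B_REF, 267.0 + h) - cx(A_REF, B_REF, 267.0 - h)) / (2 * h)
        assert contrib["A"] == pytest.approx(abs(dA) * 1.0, rel=1e-6)
        assert contrib["B"] == pytest.approx(abs(dB) * 0.001, rel=1e-6)
        assert contrib["I_x"] == pytest.approx(abs(dI) * 1.0, rel=1e-6)

    def test_monte_carlo_agrees_with_quadrature(self, rng):
        dA, dB = 3.0, 0.0006  # small relative errors -> first order regime
        fit = cal.CalibrationFit(A_REF, dA, B_REF, dB)
        inp = cal.QuantInput(267.0)
        total, _ = cal.propagate_error(fit, inp)
        n = 60000
        As = rng.normal(A_REF, dA, n)
        Bs = rng.normal(B_REF, dB, n)
        mc = (1.6 / (Bs * 0.1)) * np.log(As / (As - 267.0))
        assert np.std(mc) == pytest.approx(total, rel=0.05)


class TestDetectionLimit:
    def test_zero_negative_control(self):
        fit = cal.CalibrationFit(A_REF, 0.0, B_REF, 0.0)
        assert cal.detection_limit(fit, 0.0) == 0.0

    def test_below_lod_flagged_out_of_range(self):
        fit = cal.CalibrationFit(A_REF, 0.0, B_REF, 0.0)
        # negative-control fluorescence chosen so c_min = 5 ng/mL
        neg_I = cal.saturation_model(A_REF, B_REF, 5.0 * 0.1 / 1.6)
        cmin = cal.detection_limit(fit, neg_I)
        assert cmin == pytest.approx(5.0, rel=1e-9)
        sample_I = cal.saturation_model(A_REF, B_REF, 3.0 * 0.1 / 1.6)
        res = cal.quantify(fit, cal.QuantInput(sample_I),
                           negative_control_I=neg_I)
        assert res.C_x == pytest.approx(3.0, rel=1e-9)
        assert not res.in_range

    def test_monotone_in_negative_control(self):
        fit = cal.CalibrationFit(A_REF, 0.0, B_REF, 0.0)
        lods = [cal.detection_limit(fit, i) for i in (0.0, 10.0, 50.0, 100.0)]
        assert all(a < b for a, b in zip(lods, lods[1:]))

    def test_saturated_sample_flagged_not_crashed(self):
        fit = cal.CalibrationFit(A_REF, 0.0, B_REF, 0.0)
        res = cal.quantify(fit, cal.QuantInput(400.0))
        assert res.saturated and not res.in_range
        assert math.isnan(res.C_x)
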