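import numpy as np
import pytest
from scipy import integrate, optimize

import fdgki as f
from fdgki.errors import (
    DegenerateInputError,
    InsufficientDataError,
    ValidationError,
)

from conftest import draw_separated_triexp


def point_sample_tac(p, schedule, label="blood"):
    """TAC holding model point samples at mid-times (no frame averaging)."""
    return f.TimeActivityCurve(schedule, f.eval_triexp(p, schedule.mid), label=label)


class TestAppearance:
    def test_first_supra_threshold_mid_time(self):
        sched = f.FrameSchedule(np.arange(0, 1, 0.1), np.arange(0.1, 1.05, 0.1))
        vals = np.where(sched.mid > 0.2, 10.0, 0.0)
        tac = f.TimeActivityCurve(sched, vals)
        assert f.detect_first_appearance(tac) == pytest.approx(0.25)

    def test_aarhus_like_bolus_onset_detected_within_one_frame(self, aarhus, p_default):
        idif = f.simulate_idif(p_default, aarhus, 0.0, 1)
        assert abs(f.detect_first_appearance(idif) - 0.24) <= 0.1
        assert f.time_to_peak(idif) >= f.detect_first_appearance(idif)

    def test_flat_zero_curve_is_degenerate(self, aarhus):
        tac = f.TimeActivityCurve(aarhus, np.zeros(len(aarhus)))
        with pytest.raises(DegenerateInputError):
            f.detect_first_appearance(tac)


class TestTailFit:
    def test_exact_monoexponential_recovered(self, aarhus):
        p = f.TriExpParams(A=0, B=0, C=5.0, lambda1=1.0, lambda2=0.1,
                           lambda3=0.012, t_appear=0.0)
        tac = point_sample_tac(p, aarhus)
        c, lam = f.fit_loglinear_tail(tac, (35, 67))
        assert c == pytest.approx(5.0, rel=1e-10)
        assert lam == pytest.approx(0.012, rel=1e-10)

    def test_contaminated_tail_matches_nonlinear_oracle_within_1pct(self, aarhus):
        t = aarhus.mid
        vals = 5.0 * np.exp(-0.012 * t) + 0.05 * np.exp(-0.15 * t)
        tac = f.TimeActivityCurve(aarhus, vals)
        _, lam = f.fit_loglinear_tail(tac, (35, 67))
        assert lam == pytest.approx(0.012, rel=0.01)
        # independent oracle: nonlinear LSQ of a biexponential on the samples
        popt, _ = optimize.curve_fit(
            lambda tt, c, l3, b, l2: c * np.exp(-l3 * tt) + b * np.exp(-l2 * tt),
            t, vals, p0=[4.0, 0.010, 0.1, 0.2], maxfev=10000,
        )
        assert lam == pytest.approx(popt[1], rel=0.01)

    def test_too_few_frames_in_window_errors(self, aarhus, p_default):
        tac = point_sample_tac(p_default, aarhus)
        with pytest.raises(InsufficientDataError):
            f.fit_loglinear_tail(tac, (60, 61))

    def test_nonpositive_tail_value_errors(self, aarhus):
        vals = np.full(len(aarhus), 2.0)
        vals[-1] = 0.0
        tac = f.TimeActivityCurve(aarhus, vals)
        with pytest.raises(ValidationError):
            f.fit_loglinear_tail(tac, (35, 67))


class TestDecomposition:
    def test_pure_monoexponential_degrades_with_flags(self, aarhus):
        p = f.TriExpParams(A=0, B=0, C=10.0, lambda1=1.0, lambda2=0.1,
                           lambda3=0.01, t_appear=0.0)
        d = f.decompose_triexp(point_sample_tac(p, aarhus))
        assert d.A == 0.0 and d.B == 0.0
        assert set(d.flags) == {"no_intermediate_phase", "no_fast_phase"}
        assert d.C == pytest.approx(10.0, rel=1e-6)
        assert d.lambda3 == pytest.approx(0.01, rel=1e-6)

    def test_reference_triexp_matches_nonlinear_oracle(self, aarhus):
        """Peeling vs full nonlinear LSQ of the tri-exponential model."""
        p = f.TriExpParams(A=40, B=8, C=5, lambda1=3.0, lambda2=0.15,
                           lambda3=0.012, t_appear=0.2)
        idif = f.simulate_idif(p, aarhus, 0.0, 1)
        d = f.decompose_triexp(idif)
        use = idif.mid > 0.4  # past the appearance transient
        popt, _ = optimize.curve_fit(
            lambda t, a, l1, b, l2, c, l3: (
                a * np.exp(-l1 * t) + b * np.exp(-l2 * t) + c * np.exp(-l3 * t)
            ),
            idif.mid[use], idif.value[use],
            p0=[30.0, 2.0, 5.0, 0.1, 4.0, 0.01], maxfev=20000,
        )
        a_o, l1_o, b_o, l2_o, c_o, l3_o = popt
        assert d.C == pytest.approx(c_o, rel=0.02)
        assert d.lambda3 == pytest.approx(l3_o, rel=0.02)
        assert d.B == pytest.approx(b_o, rel=0.10)
        assert d.lambda2 == pytest.approx(l2_o, rel=0.10)

    def test_property_terminal_phase_recovered_within_2pct(self, aarhus):
        """Well-separated noiseless draws: C and lambda3 within 2%."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            p = draw_separated_triexp(rng)
            d = f.decompose_triexp(f.simulate_idif(p, aarhus, 0.0, 1))
            assert d.C == pytest.approx(p.C, rel=0.02)
            assert d.lambda3 == pytest.approx(p.lambda3, rel=0.02)

    def test_negative_tail_is_validation_error(self, aarhus):
        vals = np.full(len(aarhus), 1e-12)
        vals[:20] = 10.0
        tac = f.TimeActivityCurve(aarhus, vals)
        with pytest.raises((ValidationError, InsufficientDataError,
                            f.errors.DecompositionError)):
            f.decompose_triexp(tac)


class TestEvalAndAuc:
    def test_eval_half_life_identity(self):
        p = f.TriExpParams(A=0, B=0, C=1.0, lambda1=1.0, lambda2=0.1,
                           lambda3=0.01, t_appear=0.0)
        assert f.eval_triexp(p, 0.0) == pytest.approx(1.0)
        assert f.eval_triexp(p, 100.0 * np.log(2)) == pytest.approx(0.5)

    def test_eval_matches_term_by_term_sum(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = draw_separated_triexp(rng)
            t = rng.uniform(p.t_appear, 67.0, size=5)
            brute = sum(amp * np.exp(-lam * t) for amp, lam in p.terms)
            np.testing.assert_allclose(f.eval_triexp(p, t), brute, rtol=1e-12)
            assert f.eval_triexp(p, p.t_appear / 2) == 0.0

    def test_trapezoid_constant_curve_is_rectangle(self):
        sched = f.FrameSchedule(np.arange(0.5, 10), np.arange(1.5, 11))
        tac = f.TimeActivityCurve(sched, np.full(10, 2.0))
        assert f.auc_trapezoid(tac, 1, 10) == pytest.approx(18.0)
        assert f.auc_trapezoid(tac, 3, 3) == 0.0

    def test_trapezoid_matches_exponential_closed_form(self):
        edges = np.arange(0.0, 67.01, 0.05)
        sched = f.FrameSchedule(edges[:-1], edges[1:])
        tac = f.TimeActivityCurve(sched, np.exp(-0.01 * sched.mid))
        expected = (1 / 0.01) * (np.exp(-0.005) - np.exp(-0.67))
        assert f.auc_trapezoid(tac, 0.5, 67) == pytest.approx(expected, rel=1e-3)

    def test_analytic_closed_form_and_degenerate_window(self):
        p = f.TriExpParams(A=0, B=0, C=1.0, lambda1=1.0, lambda2=0.1,
                           lambda3=0.01, t_appear=0.0)
        assert f.auc_analytic(p, 0, 67) == pytest.approx(100 * (1 - np.exp(-0.67)))
        assert f.auc_analytic(p, 5, 5) == 0.0

    def test_analytic_agrees_with_quadrature_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            p = draw_separated_triexp(rng)
            val, err = integrate.quad(
                lambda t: f.eval_triexp(p, t), p.t_appear, 67.0,
                epsabs=1e-12, epsrel=1e-12, limit=400,
            )
            assert f.auc_analytic(p, p.t_appear, 67.0) == pytest.approx(val, rel=1e-8)


class TestMetrics:
    def test_theta_identity_holds_exactly(self, small_cohort):
        subjects, _ = small_cohort
        for s in subjects:
            d = f.decompose_triexp(s.idif)
            m = f.compute_metrics(s.idif, d)
            assert m.theta_52_67 * m.ca_52_67 == pytest.approx(m.auc_0_67, rel=1e-12)

    def test_recovery_ordering_and_near_complete_triexp(self, aarhus):
        rng = np.random.default_rng(21)
        for _ in range(20):
            p = draw_separated_triexp(rng)
            tac = point_sample_tac(p, aarhus)
            m = f.compute_metrics(tac, f.decompose_triexp(tac))
            assert 0 < m.recovery_mono <= m.recovery_bi <= m.recovery_tri
            assert abs(m.recovery_tri - 100.0) <= 2.0

    def test_pure_monoexponential_recovers_full_auc(self, aarhus):
        p = f.TriExpParams(A=0, B=0, C=5.0, lambda1=1.0, lambda2=0.1,
                           lambda3=0.012, t_appear=0.0)
        tac = point_sample_tac(p, aarhus)
        m = f.compute_metrics(tac, f.decompose_triexp(tac))
        assert m.recovery_mono == pytest.approx(m.recovery_tri, abs=1e-9)
        assert m.recovery_tri == pytest.approx(100.0, abs=0.5)

    def test_constant_curve_algebra(self, aarhus):
        k = 3.7
        tac = f.TimeActivityCurve(aarhus, np.full(len(aarhus), k))
        # lambda3 ~ 0 makes the model effectively constant
        p = f.TriExpParams(A=0, B=0, C=k, lambda1=1.0, lambda2=0.1,
                           lambda3=1e-9, t_appear=0.5)
        m = f.compute_metrics(tac, p)
        assert m.ca_52_67 == pytest.approx(k)
        assert m.auc_0_67 == pytest.approx(66.5 * k, rel=1e-3)
        assert m.theta_52_67 == pytest.approx(66.5, rel=1e-3)

    def test_no_late_frames_errors(self, p_default):
        sched = f.FrameSchedule(np.arange(0, 30), np.arange(1, 31))
        tac = point_sample_tac(p_default, sched)
        with pytest.raises(InsufficientDataError):
            f.compute_metrics(tac, p_default)
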