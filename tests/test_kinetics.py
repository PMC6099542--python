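import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petkin import (
    DegenerateModelError,
    KineticParameters,
    UndefinedMacroparameterError,
    impulse_response,
    macroparameters,
    model_tac,
)
from petkin.kinetics import TacModel, exp_conv

from _oracles import ode_tissue_response
from conftest import random_params

rates = st.floats(0.001, 5.0)


class TestImpulseResponse:
    def test_one_tissue_limit(self):
        p = KineticParameters(K1=0.5, k2=0.3, k3=0.0, k4=0.0, Kb=0.0, vB=0.0)
        a1, a2, A1, A2 = impulse_response(p)
        # h(t) = K1 * exp(-k2 t): single exponential at rate k2
        assert (a1, A1) == (0.0, 0.0)
        assert a2 == pytest.approx(0.3)
        assert A2 == pytest.approx(0.5)

    @given(rates, rates, rates)
    @settings(deadline=None)
    def test_vieta_identities(self, k2, k3, k4):
        p = KineticParameters(K1=1.0, k2=k2, k3=k3, k4=k4, Kb=0.0)
        a1, a2, _, _ = impulse_response(p)
        assert a1 + a2 == pytest.approx(k2 + k3 + k4, rel=1e-9)
        assert a1 * a2 == pytest.approx(k2 * k4, rel=1e-9, abs=1e-12)
        assert 0.0 <= a1 <= a2

    def test_eigenrates_at_control_means(self, control_params):
        a1, a2, _, _ = impulse_response(control_params)
        assert a1 == pytest.approx(0.0473, abs=5e-4)
        assert a2 == pytest.approx(0.3697, abs=5e-4)

    def test_all_zero_rates_degenerate(self):
        p = KineticParameters(K1=0.5, k2=0.0, k3=0.0, k4=0.0, Kb=0.0)
        with pytest.raises(DegenerateModelError):
            impulse_response(p)


class TestMacroparameters:
    def test_control_means_give_vt_2_22(self, control_params):
        m = macroparameters(control_params)
        assert m.VT == pytest.approx((0.58 / 0.35) * 1.34, rel=1e-12)
        assert m.VT == pytest.approx(2.22, abs=0.005)
        assert m.BPND == pytest.approx(0.34)

    def test_lps_means_give_vt_3_85(self, lps_params):
        assert macroparameters(lps_params).VT == pytest.approx(3.85, abs=0.005)

    def test_one_tissue_limit(self):
        p = KineticParameters(K1=0.5, k2=0.25, k3=0.0, k4=0.05, Kb=0.0)
        assert macroparameters(p).VT == pytest.approx(2.0)

    def test_undefined_when_k2_or_k4_zero(self):
        with pytest.raises(UndefinedMacroparameterError):
            macroparameters(KineticParameters(K1=0.5, k2=0.0, k3=0.1, k4=0.05, Kb=0.0))
        with pytest.raises(UndefinedMacroparameterError):
            macroparameters(KineticParameters(K1=0.5, k2=0.3, k3=0.1, k4=0.0, Kb=0.0))


class TestExpConv:
    def test_constant_input_closed_form(self):
        dt, alpha = 0.01, 0.7
        f = np.ones(2001)
        t = np.arange(2001) * dt
        np.testing.assert_allclose(
            exp_conv(alpha, f, dt), (1.0 - np.exp(-alpha * t)) / alpha, rtol=1e-10, atol=1e-12
        )

    def test_zero_rate_is_cumulative_integral(self):
        dt = 0.01
        t = np.arange(1001) * dt
        f = np.sin(t) + 1.0
        from scipy.integrate import cumulative_trapezoid

        np.testing.assert_allclose(
            exp_conv(0.0, f, dt),
            cumulative_trapezoid(f, dx=dt, initial=0.0),
            rtol=1e-9,
            atol=1e-12,
        )


class TestModelTac:
    def test_zero_parameters_give_zero_tac(self, aif, schedule):
        p = KineticParameters(K1=0.0, k2=0.1, k3=0.0, k4=0.0, Kb=0.0, vB=0.0)
        tac = model_tac(p, aif, schedule)
        np.testing.assert_allclose(tac.value, 0.0, atol=1e-15)

    def test_matches_ode_oracle(self, aif, schedule):
        rng = np.random.default_rng(11)
        model = TacModel(aif, schedule)
        for _ in range(5):  # the full 50-draw sweep runs in the acceptance suite
            p = random_params(rng, vB=0.0)
            t_ode, c_ode = ode_tissue_response(p, aif, schedule.end)
            mine = np.interp(t_ode, model.t, model.continuous(p))
            assert np.max(np.abs(mine - c_ode)) < 1e-4 * c_ode.max()

    def test_pure_trapping_term(self, aif, schedule):
        # all k = 0, Kb > 0: late value is vB*(Cwb + Kb * cumulative AUC of Cwb)
        p = KineticParameters(K1=0.0, k2=0.0, k3=0.0, k4=0.0, Kb=0.4, vB=0.05)
        model = TacModel(aif, schedule)
        c = model.continuous(p)
        from scipy.integrate import cumulative_trapezoid

        expected = 0.05 * (model.cwb + 0.4 * cumulative_trapezoid(model.cwb, model.t, initial=0.0))
        np.testing.assert_allclose(c, expected, rtol=1e-10, atol=1e-14)
        vals = model.frame_values(p)
        assert np.all(np.diff(vals[-10:]) >= 0)  # trapping accumulates

    def test_linearity_in_input(self, aif, schedule, plasma_samples, plasma_pf, control_params):
        from dataclasses import replace

        from petkin import build_aif

        doubled = build_aif(
            replace(plasma_samples, total_plasma=2.0 * plasma_samples.total_plasma), plasma_pf
        )
        t1 = model_tac(control_params, aif, schedule)
        t2 = model_tac(control_params, doubled, schedule)
        np.testing.assert_allclose(t2.value, 2.0 * t1.value, rtol=1e-10)

    def test_non_negative(self, aif, schedule):
        rng = np.random.default_rng(4)
        for _ in range(10):
            tac = model_tac(random_params(rng), aif, schedule)
            assert np.all(tac.value >= -1e-12)

    def test_grid_convergence(self, aif, schedule, control_params):
        v1 = model_tac(control_params, aif, schedule, dt=1 / 120).value
        v2 = model_tac(control_params, aif, schedule, dt=1 / 240).value
        assert np.max(np.abs(v2 - v1) / np.abs(v2)) < 5e-4

    def test_confluent_case_continuity(self, aif, schedule):
        # k3 = 0, k2 = k4 makes the eigenrates coincide exactly
        k = 0.3
        base = KineticParameters(K1=0.6, k2=k, k3=0.0, k4=k, Kb=0.2, vB=0.05)
        v0 = model_tac(base, aif, schedule).value
        for eps in (-1e-6, 1e-6):
            p = KineticParameters(K1=0.6, k2=k, k3=0.0, k4=k + eps, Kb=0.2, vB=0.05)
            v = model_tac(p, aif, schedule).value
            assert np.max(np.abs(v - v0)) < 1e-4 * v0.max()

    def test_extrapolation_warning(self, aif, caplog):
        from petkin import FrameSchedule

        sched = FrameSchedule(start=[0.0, 700.0], duration=[700.0, 700.0])
        with caplog.at_level("WARNING"):
            TacModel(aif, sched)
        assert any("tail extrapolation" in r.message for r in caplog.records)
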