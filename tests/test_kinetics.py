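import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from hpurea import PhysioParams, VIFParams, ees_concentration, model_signal, vif_concentration


class TestVIF:
    def test_zero_before_onset(self):
        vif = VIFParams(onset=5.0)
        assert vif_concentration(4.0, vif) == 0.0
        assert vif_concentration(-10.0, vif) == 0.0

    def test_peak_location_and_value(self):
        vif = VIFParams(amplitude=3.7, shape=2.5, timescale=2.5, onset=1.0)
        assert vif_concentration(vif.peak_time, vif) == pytest.approx(3.7, rel=1e-12)
        # the peak is a maximum
        t = np.linspace(0, 60, 2000)
        assert vif_concentration(t, vif).max() <= 3.7 * (1 + 1e-12)

    def test_closed_form_point(self):
        # direct symbolic evaluation of the normalized gamma-variate at
        # t = onset + timescale: (1/shape)^shape * exp(shape - 1)
        vif = VIFParams(amplitude=1.0, shape=2.5, timescale=2.5, onset=0.0)
        expected = (1.0 / 2.5) ** 2.5 * np.exp(2.5 - 1.0)
        assert vif_concentration(2.5, vif) == pytest.approx(expected, rel=1e-12)

    def test_continuous_at_onset(self):
        vif = VIFParams(onset=2.0)
        eps = 1e-9
        assert vif_concentration(2.0 + eps, vif) < 1e-6

    def test_nonfinite_time_rejected(self):
        with pytest.raises(ValueError):
            vif_concentration(np.nan, VIFParams())


class TestEESConcentration:
    def test_pure_decay_when_no_transfer(self):
        p = PhysioParams(kve=0.0, vb=0.1, vee=0.3, t1=20.0)
        got = ees_concentration(VIFParams(), p, 0.0, 2.0, 10.0)
        assert got == pytest.approx(2.0 * np.exp(-10.0 / 20.0), rel=1e-9)

    def test_step_input_closed_form(self):
        p = PhysioParams(kve=0.02, vb=0.0, vee=0.3, t1=20.0)
        K = 1.7
        alpha = p.alpha
        t = 12.0
        expected = (p.kve / p.vee) * K * (1 - np.exp(-alpha * t)) / alpha
        got = ees_concentration(lambda tt: K * np.ones_like(np.asarray(tt, float)), p, 0.0, 0.0, t)
        assert got == pytest.approx(expected, rel=1e-7)

    def test_matches_adaptive_ode_oracle(self):
        """Quadrature agrees with adaptive ODE integration to <= 1e-6 relative
        on random draws spanning the simulated physiological ranges."""
        rng = np.random.default_rng(42)
        vif = VIFParams()
        for _ in range(100):
            kve = rng.uniform(0.002, 0.5)
            vb = rng.uniform(0.02, 0.5)
            vee = rng.uniform(0.02, min(0.5, 1.0 - vb))
            p = PhysioParams(kve, vb, vee, 20.0)
            alpha = p.alpha
            sol = solve_ivp(
                lambda t, y: kve / vee * vif_concentration(t, vif) - alpha * y,
                [0.0, 30.0],
                [0.0],
                rtol=1e-11,
                atol=1e-15,
                max_step=0.5,
            )
            oracle = sol.y[0, -1]
            got = ees_concentration(vif, p, 0.0, 0.0, 30.0)
            assert got == pytest.approx(oracle, rel=1e-6)

    def test_errors(self):
        p = PhysioParams(kve=0.02, vb=0.1, vee=0.0, t1=20.0)
        with pytest.raises(ValueError):
            ees_concentration(VIFParams(), p, 0.0, 0.0, 5.0)
        with pytest.raises(ValueError):
            ees_concentration(VIFParams(), PhysioParams(), 5.0, 0.0, 1.0)


class TestModelSignal:
    def test_model_I_with_zero_vb_equals_model_II(self):
        p1 = PhysioParams(kve=0.05, vb=0.0, vee=0.25, t1=20.0)
        for t in (3.0, 10.0, 30.0):
            assert model_signal("I", p1, VIFParams(), 0.0, 0.0, t) == pytest.approx(
                model_signal("II", p1, VIFParams(), 0.0, 0.0, t), rel=1e-12
            )

    def test_model_I_with_full_extravascular_space_equals_model_III(self):
        p = PhysioParams(kve=0.05, vb=0.2, vee=0.8, t1=20.0)
        for t in (3.0, 10.0, 30.0):
            assert model_signal("I", p, VIFParams(), 0.0, 0.0, t) == pytest.approx(
                model_signal("III", p, VIFParams(), 0.0, 0.0, t), rel=1e-12
            )

    def test_model_I_default_point_matches_ode_oracle(self):
        p = PhysioParams()  # kve 0.02 s^-1, vb 9%, vee 30%, T1 20 s
        vif = VIFParams()
        alpha = p.alpha
        sol = solve_ivp(
            lambda t, y: p.kve / p.vee * vif_concentration(t, vif) - alpha * y,
            [0.0, 10.0],
            [0.0],
            rtol=1e-11,
            atol=1e-15,
            max_step=0.5,
        )
        expected = p.vb * vif_concentration(10.0, vif) + p.vee * sol.y[0, -1]
        assert model_signal("I", p, vif, 0.0, 0.0, 10.0) == pytest.approx(expected, rel=1e-6)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            model_signal("IV", PhysioParams(), VIFParams(), 0.0, 0.0, 1.0)

    def test_static_limit(self):
        # as T1 -> inf and kve -> 0 the signal tracks vb*Cb(t) + vee*Ce0
        p = PhysioParams(kve=0.0, vb=0.1, vee=0.3, t1=1e12)
        vif = VIFParams()
        ce0 = 0.5
        for t in (2.0, 20.0, 50.0):
            expected = 0.1 * vif_concentration(t, vif) + 0.3 * ce0
            assert model_signal("I", p, vif, 0.0, ce0, t) == pytest.approx(expected, rel=1e-9)


class TestInvariants:
    def test_volume_conservation(self):
        p = PhysioParams(kve=0.02, vb=0.09, vee=0.30)
        assert p.vb + p.vee + p.vc == pytest.approx(1.0, abs=1e-15)

    def test_invalid_physio_rejected(self):
        with pytest.raises(ValueError):
            PhysioParams(kve=-0.1)
        with pytest.raises(ValueError):
            PhysioParams(vb=0.6, vee=0.5)
        with pytest.raises(ValueError):
            PhysioParams(t1=0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        kve=st.floats(0.0, 0.5),
        vb=st.floats(0.0, 0.5),
        vee=st.floats(0.01, 0.5),
        t=st.floats(0.0, 60.0),
    )
    def test_nonnegative_signal(self, kve, vb, vee, t):
        p = PhysioParams(kve=kve, vb=vb, vee=vee, t1=20.0)
        assert model_signal("I", p, VIFParams(), 0.0, 0.0, t) >= 0.0
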