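"""Closed-form curve values, derived quantities and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

import tkburden as tk

rates = st.floats(min_value=0.05, max_value=10.0, allow_nan=False)


def oral_params(k_a, k_e, scale_target, dose=1.0):
    """Parameters whose dose/(V/F) equals scale_target µg/ml."""
    v = dose * 1000.0 / scale_target
    return (
        tk.TKParameters(k_a=k_a, k_e=k_e, v_over_f=v, route="oral"),
        tk.DoseSpec(dose, "oral"),
    )


class TestIVCurve:
    def test_initial_concentration_is_dose_over_v(self):
        p = tk.TKParameters(k_e=0.26, v_over_f=500.0, route="iv")
        d = tk.DoseSpec(0.5, "iv")
        assert tk.iv_concentration(p, d, 0.0) == pytest.approx(1.0)

    def test_one_half_life_halves_concentration(self):
        p = tk.TKParameters(k_e=0.26, v_over_f=500.0, route="iv")
        d = tk.DoseSpec(0.5, "iv")
        t_half = math.log(2) / 0.26
        assert tk.iv_concentration(p, d, t_half) == pytest.approx(0.5)

    def test_against_ode_integration(self):
        # independent oracle: integrate dC/dt = -k_e C from C(0) = dose/V
        p = tk.TKParameters(k_e=0.5, v_over_f=250.0, route="iv")
        d = tk.DoseSpec(0.5, "iv")  # dose/V = 2
        sol = solve_ivp(
            lambda t, c: -0.5 * c, (0, 4), [2.0], rtol=1e-10, atol=1e-12
        )
        assert tk.iv_concentration(p, d, 4.0) == pytest.approx(2 * math.exp(-2), rel=1e-9)
        assert tk.iv_concentration(p, d, 4.0) == pytest.approx(sol.y[0, -1], rel=1e-7)

    @settings(derandomize=True, max_examples=50)
    @given(ke=rates, t=st.floats(min_value=0.0, max_value=40.0))
    def test_halving_property_at_every_t(self, ke, t):
        p = tk.TKParameters(k_e=ke, v_over_f=100.0, route="iv")
        d = tk.DoseSpec(1.0, "iv")
        c1 = tk.iv_concentration(p, d, t)
        c2 = tk.iv_concentration(p, d, t + math.log(2) / ke)
        assert c2 == pytest.approx(c1 / 2, rel=1e-9)

    def test_negative_time_rejected(self):
        p = tk.TKParameters(k_e=0.26, v_over_f=500.0, route="iv")
        with pytest.raises(ValueError):
            tk.iv_concentration(p, tk.DoseSpec(0.5, "iv"), -1.0)


class TestOralCurve:
    def test_zero_at_time_zero(self):
        p, d = oral_params(2.2, 0.25, 1563.0)
        assert tk.oral_concentration(p, d, 0.0) == 0.0

    def test_bateman_peak_value(self):
        # peak of the curve with k_a = 2.2, k_e = 0.25 and dose/(V/F) = 1563,
        # cross-checked against fine-grid ODE integration of the gut->blood
        # system below
        p, d = oral_params(2.2, 0.25, 1563.0)
        tmax = math.log(2.2 / 0.25) / (2.2 - 0.25)
        assert tmax == pytest.approx(1.1153, abs=1e-4)
        assert tk.oral_concentration(p, d, tmax) == pytest.approx(1182.7, abs=0.1)

    def test_against_ode_integration(self):
        # oracle: dG/dt = -ka G, dC/dt = ka G - ke C with G(0) = dose/(V/F)
        ka, ke, scale = 2.2, 0.25, 1563.0
        p, d = oral_params(ka, ke, scale)
        tmax = math.log(ka / ke) / (ka - ke)
        sol = solve_ivp(
            lambda t, y: [-ka * y[0], ka * y[0] - ke * y[1]],
            (0, tmax),
            [scale, 0.0],
            rtol=1e-11,
            atol=1e-9,
        )
        assert tk.oral_concentration(p, d, tmax) == pytest.approx(sol.y[1, -1], rel=1e-7)

    def test_equal_rate_limit(self):
        # k_a = k_e = 1 with dose/(V/F) = e gives k t e^{-kt} e = 1 at t = 1
        p, d = oral_params(1.0, 1.0, math.e)
        assert tk.oral_concentration(p, d, 1.0) == pytest.approx(1.0, rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(ka=rates, ke=rates, t=st.floats(min_value=0.0, max_value=30.0))
    def test_flip_flop_equivalence(self, ka, ke, t):
        # the (k_a, k_e, D) curve equals the (k_e, k_a, D·k_a/k_e) curve:
        # the two branches of the identifiability ambiguity are one curve
        p1, d = oral_params(ka, ke, 1000.0)
        p2, _ = oral_params(ke, ka, 1000.0 * ka / ke)
        c1 = tk.oral_concentration(p1, d, t)
        c2 = tk.oral_concentration(p2, d, t)
        assert c2 == pytest.approx(c1, rel=1e-7, abs=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            tk.TKParameters(k_a=-1.0, k_e=0.2, v_over_f=1.0, route="oral")
        with pytest.raises(ValueError):
            tk.TKParameters(k_e=0.0, v_over_f=1.0, route="iv")
        with pytest.raises(ValueError):
            tk.TKParameters(k_a=1.0, k_e=0.2, v_over_f=-5.0, route="oral")


class TestHalfLife:
    @pytest.mark.parametrize(
        "k, printed",
        [(0.26, 160.0), (0.50, 83.2), (2.1, 19.8), (60 * math.log(2), 1.0)],
    )
    def test_printed_half_lives(self, k, printed):
        assert round(tk.half_life(k), 1) == printed

    @settings(derandomize=True, max_examples=50)
    @given(k=rates)
    def test_identity(self, k):
        assert tk.half_life(k) * k == pytest.approx(60 * math.log(2), rel=1e-12)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            tk.half_life(0.0)


class TestTimeOfCmax:
    def test_worst_case_value_and_golden_section_oracle(self):
        from scipy.optimize import minimize_scalar

        p, d = oral_params(2.2, 0.25, 1563.0)
        tmax = tk.time_of_cmax(p)
        assert tmax == pytest.approx(1.1153, abs=1e-4)
        res = minimize_scalar(
            lambda t: -tk.oral_concentration(p, d, t), bracket=(0.1, 1.0, 5.0),
            method="golden", options={"xtol": 1e-10},
        )
        assert tmax == pytest.approx(res.x, abs=1e-6)

    def test_symmetric_under_rate_exchange(self):
        p1, _ = oral_params(2.2, 0.25, 1.0)
        p2, _ = oral_params(0.25, 2.2, 1.0)
        assert tk.time_of_cmax(p1) == pytest.approx(tk.time_of_cmax(p2), rel=1e-12)

    def test_equal_rate_limit(self):
        p, _ = oral_params(2.0, 2.0, 1.0)
        assert tk.time_of_cmax(p) == pytest.approx(0.5)

    def test_iv_peak_is_at_zero(self):
        p = tk.TKParameters(k_e=0.26, v_over_f=500.0, route="iv")
        d = tk.DoseSpec(0.5, "iv")
        c0, t0 = tk.cmax(p, d)
        assert t0 == 0.0
        assert c0 == pytest.approx(1.0)


class TestModelAUC:
    def test_iv_value(self):
        # dose/V = 1.3, k_e = 0.26 -> AUC = 5
        p = tk.TKParameters(k_e=0.26, v_over_f=1000.0, route="iv")
        d = tk.DoseSpec(1.3, "iv")
        assert tk.model_auc(p, d) == pytest.approx(5.0)

    def test_dose_linearity(self):
        p = tk.TKParameters(k_a=2.0, k_e=0.3, v_over_f=100.0, route="oral")
        a1 = tk.model_auc(p, tk.DoseSpec(1.0, "oral"))
        a2 = tk.model_auc(p, tk.DoseSpec(2.0, "oral"))
        assert a2 == pytest.approx(2 * a1)

    @pytest.mark.parametrize("ka", [0.5, 1.0, 2.0, 4.0])
    @pytest.mark.parametrize("ke", [0.1, 0.25, 0.5])
    def test_matches_quadrature(self, ka, ke):
        p, d = oral_params(ka, ke, 100.0)
        num, _ = quad(
            lambda t: tk.oral_concentration(p, d, t), 0, 200.0 / ke, limit=500
        )
        assert tk.model_auc(p, d) == pytest.approx(num, rel=1e-4)
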