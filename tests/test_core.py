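"""Single-cell kinetics: rate laws, parameter validation, state invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from capouch import (
    CellState,
    ModelParameters,
    calcium_rhs,
    er_calcium,
    ip3_rhs,
    plc_production,
    receptor_rhs,
)
from capouch.core import single_cell_rhs


class TestModelParameters:
    def test_defaults_match_published_baseline(self, params):
        expected = {
            "k5P": 0.66, "K_PLC": 0.2, "beta": 0.185, "V_SERCA": 0.9,
            "K_SERCA": 0.1, "k1": 1.11, "k2": 0.0203, "Ka": 0.08,
            "Kr": 0.4, "Kp": 0.13, "tau_max": 800.0, "k_tau": 1.5,
            "Fp": 0.005, "Fc": 0.0005, "c_tot": 2.0,
        }
        for key, value in expected.items():
            assert getattr(params, key) == value
        assert params.receptor_variant == "modified"

    @pytest.mark.parametrize(
        "bad",
        [{"k5P": -1.0}, {"beta": 0.0}, {"beta": 1.5}, {"c_tot": 0.0},
         {"Fp": -0.1}, {"receptor_variant": "bogus"},
         {"receptor_variant": "constant_tau"}],  # missing tau_r
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParameters(**bad)

    def test_dict_round_trip_and_unknown_keys(self, params):
        assert ModelParameters.from_dict(params.to_dict()) == params
        with pytest.raises(ValueError, match="unknown"):
            ModelParameters.from_dict({"V_PLC": 1.0})

    def test_json_round_trip(self, params, tmp_path):
        path = tmp_path / "params.json"
        params.replace(k_tau=0.75).to_json(path)
        assert ModelParameters.from_json(path).k_tau == 0.75


class TestPlcProduction:
    def test_reference_values(self, params):
        assert plc_production(0.0, 1.0, params) == 0.0
        assert plc_production(0.2, 0.66, params) == pytest.approx(0.33)
        assert plc_production(2.0, 1.0, params) == pytest.approx(100 / 101)

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            plc_production(-0.1, 1.0, params)
        with pytest.raises(ValueError):
            plc_production(0.1, -1.0, params)

    @given(
        c=st.floats(0, 5, allow_subnormal=False),
        dc=st.floats(0, 5, allow_subnormal=False),
        v=st.floats(0, 2, allow_subnormal=False),
        dv=st.floats(0, 2, allow_subnormal=False),
    )
    @settings(deadline=None, max_examples=200)
    def test_monotone_in_calcium_and_drive(self, c, dc, v, dv):
        # tolerances at ULP scale: the inequalities are exact in real
        # arithmetic but each evaluation carries ~2 float roundings
        p = ModelParameters()
        eps = 1e-12 * max(v, 1.0)
        assert plc_production(c + dc, v, p) >= plc_production(c, v, p) - eps
        assert plc_production(c, v + dv, p) >= plc_production(c, v, p) - eps
        assert plc_production(c, v, p) <= v * (1 + 1e-12)


class TestErCalcium:
    def test_reference_values(self, params):
        assert er_calcium(params.c_tot, params) == 0.0
        assert er_calcium(0.0, params) == pytest.approx(2.0 / 0.185)

    @given(c=st.floats(0, 2.0))
    @settings(deadline=None)
    def test_conservation_identity(self, c):
        p = ModelParameters()
        s = er_calcium(c, p)
        assert c + p.beta * s == pytest.approx(p.c_tot, abs=1e-12)

    def test_overfull_cytosol_rejected(self, params):
        with pytest.raises(ValueError):
            er_calcium(params.c_tot + 0.01, params)


class TestRateLaws:
    def test_calcium_rhs_zero_calcium_is_pure_leak(self, params):
        state = CellState(p=0.7, c=0.0, r=0.5)
        s = er_calcium(0.0, params)
        assert calcium_rhs(state, 0.0, params) == pytest.approx(params.k2 * s)
        assert calcium_rhs(state, 0.0, params) >= 0

    def test_calcium_rhs_without_receptors_is_leak_minus_serca(self, params):
        state = CellState(p=0.5, c=0.3, r=0.0)
        s = er_calcium(0.3, params)
        serca = params.V_SERCA * 0.3**2 / (0.3**2 + params.K_SERCA**2)
        expected = params.k2 * (s - 0.3) - serca
        assert calcium_rhs(state, 0.0, params) == pytest.approx(expected)

    def test_calcium_rhs_against_exact_rational_arithmetic(self, params):
        # independent high-precision evaluation of the full rate law
        from fractions import Fraction as F

        p, c, r = F(1, 2), F(3, 10), F(1, 2)
        s = (F(2) - c) / F(185, 1000)
        gate = r * c / (F(8, 100) + c) * p / (F(13, 100) + p)
        release = (F(111, 100) * gate**3 + F(203, 10000)) * (s - c)
        serca = F(9, 10) * c**2 / (c**2 + F(1, 100))
        expected = float(release - serca)
        state = CellState(p=0.5, c=0.3, r=0.5)
        assert calcium_rhs(state, 0.0, params) == pytest.approx(
            expected, rel=1e-12
        )

    def test_ip3_rhs_zero_state_and_flux_linearity(self, params):
        assert ip3_rhs(CellState(0.0, 0.0, 1.0), 0.0, 0.0, params) == 0.0
        state = CellState(p=0.4, c=0.3, r=0.5)
        base = ip3_rhs(state, 1.0, 0.0, params)
        assert ip3_rhs(state, 1.0, 0.25, params) == pytest.approx(base + 0.25)

    def test_ip3_steady_state_at_half_activation(self, params):
        # dp/dt = 0 at p* = plc/k5P; at c = K_PLC and v = 0.66, p* = 0.5
        state = CellState(p=0.5, c=params.K_PLC, r=0.5)
        assert ip3_rhs(state, 0.66, 0.0, params) == pytest.approx(0.0, abs=1e-14)

    def test_receptor_nullcline_both_variants(self, params):
        c = 0.6
        r_eq = params.Kr / (params.Kr + c)
        state = CellState(p=0.1, c=c, r=r_eq)
        assert receptor_rhs(state, params) == pytest.approx(0.0, abs=1e-14)
        const = params.replace(receptor_variant="constant_tau", tau_r=50.0)
        assert receptor_rhs(state, const) == pytest.approx(0.0, abs=1e-14)

    def test_receptor_rate_doubles_at_k_tau(self, params):
        # at c = k_tau the Ca2+-dependent factor is (k_tau^4+k_tau^4)/k_tau^4 = 2
        state = CellState(p=0.1, c=params.k_tau, r=0.0)
        assert receptor_rhs(state, params) == pytest.approx(2.0 / params.tau_max)

    def test_variants_coincide_at_zero_calcium(self, params):
        const = params.replace(receptor_variant="constant_tau",
                               tau_r=params.tau_max)
        state = CellState(p=0.1, c=0.0, r=0.3)
        assert receptor_rhs(state, params) == pytest.approx(
            receptor_rhs(state, const)
        )

    def test_invalid_states_rejected(self, params):
        for bad in (CellState(-0.1, 0.1, 0.5), CellState(0.1, 2.5, 0.5),
                    CellState(0.1, 0.1, 1.5)):
            with pytest.raises(ValueError):
                calcium_rhs(bad, 0.0, params)


class TestIsolatedCellDynamics:
    @given(
        p0=st.floats(0, 2), c0=st.floats(0.001, 1.999),
        r0=st.floats(0.01, 1.0), v=st.floats(0, 1.5),
    )
    @settings(deadline=None, max_examples=25)
    def test_state_box_is_forward_invariant(self, p0, c0, r0, v):
        params = ModelParameters()
        sol = solve_ivp(
            single_cell_rhs, (0, 600), [p0, c0, r0], args=(v, params),
            method="LSODA", rtol=1e-8, atol=1e-10,
        )
        assert sol.success
        tol = 1e-7
        assert sol.y[0].min() >= -tol
        assert -tol <= sol.y[1].min() and sol.y[1].max() <= params.c_tot + tol
        assert -tol <= sol.y[2].min() and sol.y[2].max() <= 1 + tol

    @pytest.mark.parametrize("c_fixed", [0.1, 0.5, 1.5])
    def test_receptor_relaxes_exponentially_at_fixed_calcium(self, params,
                                                             c_fixed):
        # with c held fixed, r -> Kr/(Kr+c) with time constant
        # tau_max * k_tau^4 / (k_tau^4 + c^4)
        tau = params.tau_max * params.k_tau**4 / (params.k_tau**4 + c_fixed**4)
        r_eq = params.Kr / (params.Kr + c_fixed)
        r0 = 1.0

        def rhs(t, y):
            from capouch.core import _receptor_rate

            return [_receptor_rate(c_fixed, y[0], params)]

        # the relaxation rate towards r_eq is (Kr+c)/(Kr * tau_eff)
        rate = (params.Kr + c_fixed) / (params.Kr * tau)
        t_end = 2.0 / rate
        sol = solve_ivp(rhs, (0, t_end), [r0], rtol=1e-10, atol=1e-12)
        expected = r_eq + (r0 - r_eq) * np.exp(-rate * sol.t[-1])
        assert sol.y[0, -1] == pytest.approx(expected, rel=1e-6)
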