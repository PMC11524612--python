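"""Unit tests for the algebraic model layer (gating, closures, fluxes, rhs)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cldyn import (
    DomainViolationError,
    ModelParams,
    NeuronState,
    closures,
    cotransporter_fluxes,
    flux_charge_residual,
    gaba_reversal,
    gating_rates,
    pump_rate,
    reversal_potentials,
    rhs,
    steady_gating,
)
from cldyn.model import STATE_NAMES

P = ModelParams(eps_k=0.0)


class TestGatingRates:
    @pytest.mark.parametrize("V,index,expected", [
        (-52.0, 4, 0.16),    # alpha_n at its removable singularity (L'Hopital)
        (-57.0, 5, 0.5),     # beta_n with exponent exactly zero
        (-50.0, 2, 0.128),   # alpha_h with exponent exactly zero
        (-27.0, 3, 2.0),     # beta_h logistic at midpoint
        (-54.0, 0, 1.28),    # alpha_m singular limit
        (-27.0, 1, 1.4),     # beta_m singular limit
    ])
    def test_exact_values(self, V, index, expected):
        assert gating_rates(V)[index] == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("V_sing", [-54.0, -27.0, -52.0])
    def test_continuous_across_singularities(self, V_sing):
        V = V_sing + np.arange(-1e-3, 1e-3, 1e-6)
        for k in range(6):
            vals = np.array([gating_rates(v)[k] for v in V])
            assert np.all(np.isfinite(vals))
            assert np.max(np.abs(np.diff(vals))) < 1e-4

    def test_nonnegative_and_finite_over_range(self):
        for v in np.linspace(-120.0, 60.0, 3601):
            r = gating_rates(float(v))
            assert all(math.isfinite(x) and x >= 0 for x in r)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            gating_rates(float("nan"))

    def test_steady_gating_in_unit_interval(self):
        for v in (-90.0, -65.0, -30.0, 0.0):
            assert all(0.0 <= g <= 1.0 for g in steady_gating(v))


class TestClosures:
    def test_reference_point(self):
        K_i, Na_o, Cl_o = closures(20.0, 6.0, P)
        assert (K_i, Na_o, Cl_o) == (86.0, 135.0, 145.0)

    def test_volume_ratio_scaling(self):
        _, Na_o, Cl_o = closures(21.0, 7.0, P)
        assert Na_o == 135.0 - 7.0
        assert Cl_o == 145.0 - 7.0

    @pytest.mark.parametrize("na,cl", [(40.0, 5.0), (20.0, 27.0), (-1.0, 6.0)])
    def test_raises_outside_validity_region(self, na, cl):
        with pytest.raises(DomainViolationError):
            closures(na, cl, P)


class TestReversalPotentials:
    def test_chloride_reference(self):
        st_ = NeuronState.with_steady_gating(-70.0, 2.99, 20.0, 6.0)
        _, _, E_Cl = reversal_potentials(st_, P)
        assert E_Cl == pytest.approx(26.64 * math.log(6.0 / 145.0), rel=1e-12)
        assert E_Cl == pytest.approx(-84.85, abs=0.01)

    def test_potassium_reference(self):
        st_ = NeuronState.with_steady_gating(-70.0, 2.99, 20.0, 6.0)
        _, E_K, _ = reversal_potentials(st_, P)
        assert E_K == pytest.approx(26.64 * math.log(2.99 / 86.0), rel=1e-12)
        assert E_K == pytest.approx(-89.5, abs=0.05)

    def test_ecl_zero_when_symmetric(self):
        # Cl_i = Cl_o requires Cl_i = 145 + 42 - 7 Cl_i -> Cl_i = 187/8
        cl = 187.0 / 8.0
        st_ = NeuronState.with_steady_gating(-70.0, 3.0, 20.0, cl)
        _, _, E_Cl = reversal_potentials(st_, P)
        assert E_Cl == pytest.approx(0.0, abs=1e-12)

    def test_ecl_strictly_increasing_in_cl(self):
        cls = np.linspace(1.0, 25.0, 200)
        vals = []
        for c in cls:
            st_ = NeuronState.with_steady_gating(-70.0, 3.0, 20.0, float(c))
            vals.append(reversal_potentials(st_, P)[2])
        assert np.all(np.diff(vals) > 0)

    def test_ek_strictly_increasing_in_ko(self):
        vals = []
        for k in np.linspace(2.0, 12.0, 100):
            st_ = NeuronState.with_steady_gating(-70.0, float(k), 20.0, 6.0)
            vals.append(reversal_potentials(st_, P)[1])
        assert np.all(np.diff(vals) > 0)


class TestGabaReversal:
    def test_equals_ehco3_when_ecl_matches(self):
        assert gaba_reversal(-13.0, P) == pytest.approx(-13.0)

    def test_reference_value(self):
        assert gaba_reversal(-84.85, P) == pytest.approx((-84.85 - 2.6) / 1.2, rel=1e-12)

    def test_pure_chloride_limit(self):
        p0 = P.replace(r_hco3=0.0)
        assert gaba_reversal(-77.3, p0) == -77.3

    @settings(max_examples=200, deadline=None)
    @given(e_cl=st.floats(-120.0, 0.0), r=st.floats(0.0, 1.0))
    def test_affine_weighted_average(self, e_cl, r):
        p = ModelParams(r_hco3=r)
        e = gaba_reversal(e_cl, p)
        assert e == pytest.approx((e_cl + r * p.E_hco3) / (1.0 + r), rel=1e-12)
        lo, hi = min(e_cl, p.E_hco3), max(e_cl, p.E_hco3)
        assert lo - 1e-9 <= e <= hi + 1e-9


class TestPumpRate:
    def test_half_activation_point(self):
        # both logistic factors are exactly 1/2
        assert pump_rate(25.0, 3.5, P) == pytest.approx(0.25 * P.rho, rel=1e-12)

    def test_saturation(self):
        assert pump_rate(1e3, 1e3, P) == pytest.approx(P.rho, rel=1e-9)

    def test_resting_value(self):
        expected = 0.8 / (1 + math.exp((25 - 20.06) / 3)) / (1 + math.exp(3.5 - 2.99))
        assert pump_rate(20.06, 2.99, P) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0485, abs=2e-4)

    def test_monotone_in_both_arguments(self):
        na = np.linspace(5.0, 40.0, 50)
        assert np.all(np.diff([pump_rate(float(x), 3.0, P) for x in na]) > 0)
        ko = np.linspace(1.0, 12.0, 50)
        assert np.all(np.diff([pump_rate(20.0, float(x), P) for x in ko]) > 0)


class TestCotransporters:
    def test_nkcc1_activation_midpoint(self):
        st_ = NeuronState.with_steady_gating(-70.0, 16.0, 20.0, 6.0)
        _, _, f = cotransporter_fluxes(st_, P)
        assert f == pytest.approx(0.5, rel=1e-12)

    def test_kcc2_zero_at_equilibrium_products(self):
        # find Cl with K_i*Cl_i = K_o*Cl_o at Na=20: (80+Cl)*Cl = K_o*(187-7Cl)
        from scipy.optimize import brentq
        ko = 3.0
        cl = brentq(lambda c: (80.0 + c) * c - ko * (187.0 - 7.0 * c), 1.0, 20.0)
        st_ = NeuronState.with_steady_gating(-70.0, ko, 20.0, cl)
        rho_k, _, _ = cotransporter_fluxes(st_, P)
        assert rho_k == pytest.approx(0.0, abs=1e-12)

    def test_nkcc1_reference_value(self):
        st_ = NeuronState.with_steady_gating(-70.0, 2.99, 20.0, 6.0)
        _, rho_n, f = cotransporter_fluxes(st_, P)
        expected = 0.1 / (1 + math.exp(16 - 2.99)) * (
            math.log((2.99 * 145.0) / (86.0 * 6.0))
            + math.log((135.0 * 145.0) / (20.0 * 6.0)))
        assert rho_n == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.1e-6, rel=0.05)

    def test_kcc2_sign_follows_log_ratio(self, random_states):
        for st_ in random_states[:30]:
            K_i, _, Cl_o = closures(st_.Na_i, st_.Cl_i, P)
            rho_k, _, _ = cotransporter_fluxes(st_, P)
            assert np.sign(rho_k) == np.sign(math.log(K_i * st_.Cl_i / (st_.K_o * Cl_o)))


class TestRhs:
    def test_null_model_has_zero_derivatives(self):
        # every conductance, pump and transporter off, gating at steady state
        p0 = ModelParams(gNa=0, gK=0, gNaL=0, gKL=0, gClL=0, rho=0,
                         U_kcc2=0, U_nkcc1=0, eps_k=0)
        y = NeuronState.with_steady_gating(-60.0, 3.0, 20.0, 6.0).as_array()
        assert np.allclose(rhs(0.0, y, p0), 0.0, atol=1e-15)

    def test_steady_gating_components_vanish(self):
        st_ = NeuronState.with_steady_gating(-55.0, 4.0, 18.0, 9.0)
        d = rhs(0.0, st_.as_array(), P)
        assert np.allclose(d[1:4], 0.0, atol=1e-15)

    def test_flux_charge_consistency_at_random_states(self, random_states):
        rng = np.random.default_rng(7)
        worst = 0.0
        for st_ in random_states:
            g = float(rng.uniform(0.0, 2.0))
            worst = max(worst, abs(flux_charge_residual(st_, P, g_gaba=g)))
        assert worst < 1e-9

    def test_literal_gaba_sign_flips_gaba_current(self):
        st_ = NeuronState.with_steady_gating(-60.0, 3.0, 20.0, 6.0)
        d_neg = rhs(0.0, st_.as_array(), P, g_gaba=0.5)
        d_pos = rhs(0.0, st_.as_array(), P.replace(literal_gaba_sign=True), g_gaba=0.5)
        d_off = rhs(0.0, st_.as_array(), P, g_gaba=0.0)
        gaba_part = d_neg[0] - d_off[0]
        assert d_pos[0] - d_off[0] == pytest.approx(-gaba_part, rel=1e-12)

    def test_ko_beta_scaling_multiplies_flux(self):
        st_ = NeuronState.with_steady_gating(-60.0, 3.2, 19.0, 8.0)
        d_on = rhs(0.0, st_.as_array(), P)
        d_off = rhs(0.0, st_.as_array(), P.replace(ko_beta_scaling=False))
        assert d_on[4] == pytest.approx(P.beta * d_off[4], rel=1e-12)
        assert d_on[[0, 5, 6]] == pytest.approx(d_off[[0, 5, 6]], rel=1e-12)


class TestKernelAgreement:
    def test_compiled_rhs_matches_reference(self, random_states):
        from cldyn import _kernels
        from cldyn.stimulus import StepProtocol, pack_protocol

        p = ModelParams(eps_k=0.25, K_bath=3.0)
        stim = pack_protocol(StepProtocol(G_gaba=0.3, t0=0.0, tn=1e9))
        out = np.empty(7)
        for st_ in random_states[:40]:
            y = st_.as_array()
            _kernels.rhs_packed(5.0, y, p.pack(), stim, out)
            ref = rhs(5.0, y, p, g_gaba=0.3)
            np.testing.assert_allclose(out, ref, rtol=1e-13, atol=1e-18)


class TestParamsSerialization:
    def test_table_roundtrip_is_bit_exact(self):
        p = ModelParams.from_table()
        d = ModelParams()
        for name in ("C", "gNa", "gK", "gNaL", "gKL", "gClL", "gamma", "rho",
                     "U_nkcc1", "U_kcc2", "eps_k", "K_bath", "beta"):
            assert getattr(p, name) == getattr(d, name)

    def test_mapping_roundtrip(self):
        p = ModelParams(eps_k=0.0, r_hco3=0.4, tau_ion=500.0)
        assert ModelParams.from_mapping(p.to_mapping()) == p

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            ModelParams.from_mapping({"gNa": 30.0, "bogus": 1.0})

    @pytest.mark.parametrize("kwargs", [
        {"r_hco3": 1.5}, {"beta": 0.0}, {"gNa": -1.0}, {"tau_ion": -5.0},
    ])
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)


class TestNeuronState:
    def test_array_roundtrip(self):
        st_ = NeuronState.with_steady_gating(-64.0, 3.1, 19.5, 7.7)
        assert NeuronState.from_array(st_.as_array()) == st_
        assert [getattr(st_, n) for n in STATE_NAMES] == list(st_.as_array())

    def test_validate_rejects_bad_gates_and_concentrations(self):
        with pytest.raises(DomainViolationError):
            NeuronState(-60, 1.5, 0.1, 0.1, 3.0, 20.0, 6.0).validate(P)
        with pytest.raises(DomainViolationError):
            NeuronState(-60, 0.5, 0.1, 0.1, -1.0, 20.0, 6.0).validate(P)
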