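import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import leafheat as lh
from leafheat.physics import (
    air_density,
    conductance_to_molar,
    molar_to_conductance,
    psychrometric_state,
    series_conductance,
)


def make_env(T_air=293.15, RH=0.5, T_reflect=None, P=101325.0, I_s=0.0):
    return lh.EnvironmentState(
        T_air=T_air, RH_air=RH,
        T_reflect=T_air if T_reflect is None else T_reflect,
        P_atm=P, I_s=I_s,
    )


class TestSaturationVapourPressure:
    # hand evaluations of the Tetens formula 610.78*exp(17.27 tc/(tc+237.3))
    @pytest.mark.parametrize("T, expected", [
        (273.15, 610.78),
        (293.15, 2338.3),
    ])
    def test_reference_values(self, T, expected):
        assert lh.saturation_vapour_pressure(T) == pytest.approx(
            expected, rel=1e-3
        )

    @given(st.floats(min_value=250.0, max_value=390.0))
    def test_monotone_increasing(self, T):
        assert lh.saturation_vapour_pressure(T + 1.0) > \
            lh.saturation_vapour_pressure(T) > 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lh.saturation_vapour_pressure(150.0)


class TestPsychrometrics:
    def test_saturated_isothermal_has_zero_vpd(self):
        psy = psychrometric_state(293.15, make_env(RH=1.0))
        assert psy.VPD == pytest.approx(0.0, abs=1e-9)

    def test_vpd_from_humidity_deficit(self):
        # isothermal at 20 C, RH 0.7: VPD = 0.3 * es(20 C)
        psy = psychrometric_state(293.15, make_env(RH=0.7))
        assert psy.VPD == pytest.approx(0.3 * 2338.3, rel=1e-3)

    def test_air_density_ideal_gas(self):
        # 101325 * 0.0289647 / (8.3145 * 293.15)
        assert air_density(293.15, 101325.0) == pytest.approx(1.204, abs=2e-3)

    def test_all_outputs_positive(self):
        psy = psychrometric_state(295.0, make_env(RH=0.3))
        assert psy.es > 0 and psy.rho_air > 0 and psy.C_s > 0 and psy.lam > 0


class TestSeriesConductance:
    def test_closed_stomata_blocks_pathway(self):
        assert series_conductance(0.0, 0.01) == 0.0
        assert series_conductance(0.01, 0.0) == 0.0

    def test_equal_conductances_halve(self):
        assert series_conductance(0.004, 0.004) == pytest.approx(0.002)

    def test_hand_computed_example(self):
        # 1/(1/0.003 + 1/0.010870) = 1/425.33
        assert series_conductance(0.003, 0.010870) == pytest.approx(
            0.002351, rel=1e-3
        )

    @given(
        st.floats(min_value=1e-6, max_value=0.1),
        st.floats(min_value=1e-6, max_value=0.1),
    )
    def test_never_exceeds_either_branch(self, a, b):
        assert series_conductance(a, b) <= min(a, b)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            series_conductance(-0.001, 0.01)


class TestMolarConversion:
    def test_zero_maps_to_zero(self):
        assert conductance_to_molar(0.0, 293.15, 101325.0) == 0.0

    def test_reference_value(self):
        # P/(RT) = 41.57 mol/m3 at 20 C, 1 atm
        assert conductance_to_molar(0.01, 293.15, 101325.0) == pytest.approx(
            0.4157, rel=1e-3
        )

    def test_stomatal_variant_applies_092(self):
        plain = conductance_to_molar(0.01, 293.15, 101325.0)
        gsw = conductance_to_molar(0.01, 293.15, 101325.0, include_092=True)
        assert gsw == pytest.approx(plain / 0.92)

    @given(st.floats(min_value=1e-5, max_value=0.1), st.booleans())
    def test_round_trip(self, g, with_092):
        molar = conductance_to_molar(g, 293.15, 101325.0, include_092=with_092)
        back = molar_to_conductance(molar, 293.15, 101325.0, include_092=with_092)
        assert back == pytest.approx(g, rel=1e-12)


class TestConductancesType:
    def test_gbw_derived_exactly(self):
        c = lh.Conductances(g_bh=0.0092, g_sw=0.001)
        assert c.g_bw == pytest.approx(0.01)
        assert c.g_bh / c.g_bw == pytest.approx(0.92)


class TestFluxComponents:
    def test_full_equilibrium_all_zero(self):
        cond = lh.Conductances(g_bh=0.01, g_sw=0.0)
        f = lh.flux_components(293.15, make_env(), lh.OpticalProperties(0.98, 0.96), cond)
        assert all(abs(v) < 1e-12 for v in f.values())

    def test_absorbed_shortwave_is_alpha_times_irradiance(self):
        cond = lh.Conductances(g_bh=0.01, g_sw=0.0)
        f = lh.flux_components(
            293.15, make_env(I_s=270.0), lh.OpticalProperties(0.98, 0.96), cond
        )
        assert f["SW_abs"] == pytest.approx(264.6)

    def test_warm_object_loses_longwave(self):
        cond = lh.Conductances(g_bh=0.01, g_sw=0.0)
        f = lh.flux_components(
            296.15, make_env(), lh.OpticalProperties(0.98, 0.96), cond
        )
        assert f["LW_net"] < 0


class TestEnergyBalanceRhs:
    def test_zero_at_equilibrium(self):
        cond = lh.Conductances(g_bh=0.01, g_sw=0.0)
        rhs = lh.energy_balance_rhs(
            293.15, make_env(), lh.OpticalProperties(0.98, 0.96), cond, k=2971.0
        )
        assert rhs == pytest.approx(0.0, abs=1e-12)

    def test_plate_onset_slope_is_alpha_I_over_k(self):
        # plate in dark equilibrium, instant of pulse onset: only the
        # short-wave term is nonzero, so dT/dt = alpha*I/k
        cond = lh.Conductances(g_bh=0.01, g_sw=0.0)
        k = 0.001335 * 2484.0 * 896.0
        rhs = lh.energy_balance_rhs(
            293.15, make_env(I_s=270.0), lh.OpticalProperties(0.98, 0.96),
            cond, k=k,
        )
        assert rhs == pytest.approx(0.98 * 270.0 / k)
        assert rhs == pytest.approx(0.0891, abs=2e-4)

    @given(st.floats(min_value=100.0, max_value=10000.0))
    def test_inverse_proportionality_in_k(self, k):
        cond = lh.Conductances(g_bh=0.008, g_sw=0.002)
        env = make_env(RH=0.4, I_s=150.0)
        optics = lh.OpticalProperties(0.9, 0.95)
        r1 = lh.energy_balance_rhs(294.0, env, optics, cond, k=k)
        r2 = lh.energy_balance_rhs(294.0, env, optics, cond, k=2 * k)
        assert r1 == pytest.approx(2 * r2, rel=1e-12)

    def test_nonpositive_k_rejected(self):
        cond = lh.Conductances(g_bh=0.01, g_sw=0.0)
        with pytest.raises(ValueError):
            lh.energy_balance_rhs(
                293.15, make_env(), lh.OpticalProperties(0.98, 0.96), cond, k=0.0
            )


class TestEquilibriumTemperature:
    def test_dark_dry_object_sits_at_air_temperature(self):
        cond = lh.Conductances(g_bh=0.01, g_sw=0.0)
        Teq = lh.equilibrium_temperature(
            make_env(), lh.OpticalProperties(0.98, 0.96), cond
        )
        assert Teq == pytest.approx(293.15, abs=1e-8)

    def test_transpiring_leaf_cools_below_air(self):
        cond = lh.Conductances(g_bh=0.01, g_sw=0.003)
        Teq = lh.equilibrium_temperature(
            make_env(RH=0.5), lh.OpticalProperties(0.92, 0.97), cond
        )
        assert Teq < 293.15

    def test_energy_conserved_at_root(self):
        cond = lh.Conductances(g_bh=0.012, g_sw=0.002)
        env = make_env(RH=0.4, I_s=200.0)
        optics = lh.OpticalProperties(0.9, 0.96)
        Teq = lh.equilibrium_temperature(env, optics, cond)
        f = lh.flux_components(Teq, env, optics, cond)
        assert abs(sum(
            [f["SW_abs"], f["LW_net"], -f["H_sensible"], -f["LE_latent"]]
        )) < 1e-8

    def test_rhs_locally_decreasing_in_temperature(self):
        # stability: finite-difference slope of the rhs is negative
        cond = lh.Conductances(g_bh=0.01, g_sw=0.002)
        env = make_env(RH=0.5, I_s=100.0)
        optics = lh.OpticalProperties(0.92, 0.97)
        Teq = lh.equilibrium_temperature(env, optics, cond)
        d = 0.01
        up = lh.energy_balance_rhs(Teq + d, env, optics, cond, k=1000.0)
        dn = lh.energy_balance_rhs(Teq - d, env, optics, cond, k=1000.0)
        assert up < 0 < dn

    def test_gbh_zero_rejected(self):
        cond = lh.Conductances(g_bh=0.0, g_sw=0.0)
        with pytest.raises(ValueError):
            lh.equilibrium_temperature(
                make_env(), lh.OpticalProperties(0.98, 0.96), cond
            )


class TestTypeValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(T_air=150.0, RH_air=0.5, T_reflect=293.0, P_atm=1e5, I_s=0.0),
        dict(T_air=293.0, RH_air=1.5, T_reflect=293.0, P_atm=1e5, I_s=0.0),
        dict(T_air=293.0, RH_air=0.5, T_reflect=293.0, P_atm=-1.0, I_s=0.0),
        dict(T_air=293.0, RH_air=0.5, T_reflect=293.0, P_atm=1e5, I_s=-5.0),
    ])
    def test_environment_invariants(self, kwargs):
        with pytest.raises(ValueError):
            lh.EnvironmentState(**kwargs)

    def test_absorptance_above_one_warns_not_raises(self):
        with pytest.warns(UserWarning):
            optics = lh.OpticalProperties(alpha=1.078, epsilon=0.96)
        assert optics.alpha == pytest.approx(1.078)

    def test_cp_derived_from_k_and_mass_per_area(self):
        p = lh.EnergyBalanceParams(
            k=2968.0, conductances=lh.Conductances(0.01, 0.0),
            mass_per_area=0.001335 * 2484.0,
        )
        assert p.C_p == pytest.approx(895.0, abs=0.2)
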