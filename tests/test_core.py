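"""Body-fluid state, initialisation and the osmotic water-exchange step."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import hydrorat as hr
from hydrorat.core import GRADIENT_TOL, effective_ecf_osmolality


def brentq_equilibrium(state: hr.BodyState, params: hr.ModelParams) -> float:
    """Independent oracle: ICF volume at osmotic equilibrium via bracketing."""
    total = state.ecf_v + state.icf_v

    def gradient(icf_v: float) -> float:
        ecf_v = total - icf_v
        return (2000.0 * state.ecf_na / ecf_v + params.osmole_correction
                - 1000.0 * state.icf_osmoles / icf_v)

    return brentq(gradient, 1e-6, total - 1e-6, xtol=1e-12, rtol=1e-15)


class TestInitState:
    def test_absolute_volumes_scale_with_weight(self, params, baseline):
        assert baseline.ecf_v == pytest.approx(58.65)
        assert baseline.icf_v == pytest.approx(117.3)
        assert baseline.ecf_na == pytest.approx(8.211)

    def test_per_100g_identity_at_100g(self):
        p = hr.ModelParams(weight=100.0)
        s = hr.init_state(p)
        assert s.ecf_v == pytest.approx(23.0)
        assert s.icf_v == pytest.approx(46.0)

    def test_initial_state_is_osmotic_fixed_point(self, params, baseline):
        eq = hr.equilibrate_water(baseline, params)
        assert eq.icf_v == pytest.approx(baseline.icf_v, abs=1e-9)
        assert eq.ecf_v == pytest.approx(baseline.ecf_v, abs=1e-9)

    def test_digestive_compartments_start_empty(self, baseline):
        assert baseline.stomach_v == 0.0
        assert baseline.intestine_v == 0.0
        assert not baseline.drinking_locked

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(hr.ConfigError):
            hr.ModelParams(weight=-5.0)


class TestConcentrationAndOsmolality:
    @pytest.mark.parametrize("na, v, expected", [
        (8.211, 58.65, 140.0),
        (9.211, 58.65, 157.05),
        (0.0, 58.65, 0.0),
    ])
    def test_ecf_na_conc(self, baseline, na, v, expected):
        s = dataclasses.replace(baseline, ecf_na=na, ecf_v=v)
        assert hr.ecf_na_conc(s) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("na_conc, corr, expected", [
        (140.0, 14.0, 294.0),
        (0.0, 14.0, 14.0),
        (137.5, 14.0, 289.0),
    ])
    def test_effective_osmolality(self, na_conc, corr, expected):
        assert effective_ecf_osmolality(na_conc, corr) == pytest.approx(expected)


class TestEquilibrateWater:
    def test_sodium_load_shifts_water_out_of_cells(self, params, baseline):
        loaded = hr.apply_fluxes(baseline, 0.0, 1.0)
        eq = hr.equilibrate_water(loaded, params)
        icf_oracle = brentq_equilibrium(loaded, params)
        assert eq.icf_v == pytest.approx(icf_oracle, abs=1e-6)
        # ~3.8 % cell shrinkage and ~146 mmol/L from a 1 mmol load
        assert eq.icf_v == pytest.approx(112.8, abs=0.1)
        assert eq.ecf_v == pytest.approx(63.15, abs=0.1)
        assert hr.ecf_na_conc(eq) == pytest.approx(145.9, abs=0.1)

    def test_water_removal_raises_concentration_both_pools_shrink(self, params, baseline):
        dry = hr.apply_fluxes(baseline, -5.0, 0.0)
        eq = hr.equilibrate_water(dry, params)
        assert eq.ecf_v < baseline.ecf_v
        assert eq.icf_v < baseline.icf_v
        assert hr.ecf_na_conc(eq) > 140.0
        total = dry.ecf_v + dry.icf_v
        assert eq.ecf_v + eq.icf_v == pytest.approx(total, abs=1e-9)

    @given(d_na=st.floats(-2.0, 4.0), d_w=st.floats(-20.0, 30.0))
    @settings(max_examples=60, deadline=None)
    def test_idempotent_and_conservative(self, d_na, d_w):
        params = hr.ModelParams()
        s = hr.apply_fluxes(hr.init_state(params), d_w, d_na)
        once = hr.equilibrate_water(s, params)
        twice = hr.equilibrate_water(once, params)
        assert twice.icf_v == pytest.approx(once.icf_v, abs=1e-8)
        assert once.ecf_v + once.icf_v == pytest.approx(s.ecf_v + s.icf_v, abs=1e-9)
        assert once.ecf_na == s.ecf_na
        assert once.icf_osmoles == s.icf_osmoles
        osm_ecf = effective_ecf_osmolality(hr.ecf_na_conc(once), params.osmole_correction)
        osm_icf = 1000.0 * once.icf_osmoles / once.icf_v
        assert abs(osm_ecf - osm_icf) < GRADIENT_TOL


class TestApplyFluxes:
    def test_water_only_conserves_sodium(self, params, baseline):
        out = hr.equilibrate_water(hr.apply_fluxes(baseline, 1.0, 0.0), params)
        assert out.ecf_v + out.icf_v == pytest.approx(
            baseline.ecf_v + baseline.icf_v + 1.0, abs=1e-9)
        assert out.ecf_na == baseline.ecf_na

    def test_sodium_only(self, baseline):
        out = hr.apply_fluxes(baseline, 0.0, 1.0)
        assert out.ecf_na == pytest.approx(9.211)

    def test_insensible_loss_rate_over_a_day(self, params, baseline):
        s = baseline
        for _ in range(1440):
            s = hr.apply_fluxes(s, params.unregulated_balance_flux, 0.0)
        lost = baseline.ecf_v - s.ecf_v
        assert lost == pytest.approx(0.0108 * 1440, abs=1e-9)  # 15.55 ml/day

    def test_emptying_the_ecf_is_an_error(self, baseline):
        with pytest.raises(hr.SimulationError):
            hr.apply_fluxes(baseline, -baseline.ecf_v - 1.0, 0.0)
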