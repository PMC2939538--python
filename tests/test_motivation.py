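"""Drinking decisions: the thirst latch, the need-free bout process and dominance."""

import dataclasses

import numpy as np
import pytest

import hydrorat as hr
from hydrorat.motivation import (NEED_INDUCED, NONE, UNREGULATED,
                                 DrinkController, rule1_need,
                                 rule2_probability)
from hydrorat.params import DrinkingParams


def state_with_conc(baseline, conc, locked=False):
    return dataclasses.replace(
        baseline, ecf_na=conc * baseline.ecf_v / 1000.0, drinking_locked=locked)


class TestRule1:
    def test_threshold_is_four_percent_above_setpoint(self):
        assert rule1_need(146.0, 140.0, active=False, locked=False)
        assert not rule1_need(145.0, 140.0, active=False, locked=False)

    def test_latch_persists_until_restored(self):
        active = rule1_need(146.0, 140.0, active=False, locked=False)
        assert rule1_need(144.0, 140.0, active=active, locked=False, stop_conc=143.0)
        assert not rule1_need(142.9, 140.0, active=active, locked=False, stop_conc=143.0)

    def test_full_stomach_suppresses_drinking(self):
        assert not rule1_need(150.0, 140.0, active=True, locked=True)


class TestRule2Probability:
    def test_extremes_at_two_am_and_two_pm(self):
        d = DrinkingParams()
        probs = [rule2_probability(t, d) for t in range(1440)]
        assert int(np.argmax(probs)) == 120   # 02:00
        assert int(np.argmin(probs)) == 840   # 14:00

    def test_zero_amplitude_is_constant(self):
        d = DrinkingParams(unregulated_amplitude=0.0)
        assert rule2_probability(0, d) == rule2_probability(777, d) == d.unregulated_p_base

    def test_daily_expectation_identity(self):
        """The sinusoid integrates out: expected daily volume = p_base*1440*bout."""
        d = DrinkingParams()
        total = sum(rule2_probability(t, d) for t in range(1440)) * d.bout_volume_ml
        assert total == pytest.approx(d.unregulated_p_base * 1440 * d.bout_volume_ml,
                                      rel=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rule2_probability(-1)


class TestDecideIntake:
    def test_rule1_dominates_and_delivers_low_sodium_water(self, params, baseline):
        ctl = DrinkController(rule1_active=True)
        s = state_with_conc(baseline, 150.0)
        rng = np.random.default_rng(0)
        kinds = set()
        for _ in range(50):
            cmd = ctl.decide_intake(s, params, rng, time_of_day=600)
            kinds.add(cmd.kind)
            if cmd.kind == NEED_INDUCED:
                assert cmd.na_conc == 0.0
        assert kinds <= {NEED_INDUCED, NONE}
        assert NEED_INDUCED in kinds

    def test_rule2_fires_in_the_normal_band_with_sodium_water(self, params, baseline):
        ctl = DrinkController()
        s = state_with_conc(baseline, 141.0)
        rng = np.random.default_rng(1)
        cmds = [ctl.decide_intake(s, params, rng, time_of_day=120) for _ in range(300)]
        fired = [c for c in cmds if c.kind == UNREGULATED]
        assert fired
        assert all(c.na_conc == params.drinking.unregulated_na_conc for c in fired)

    def test_rule2_never_fires_above_the_thirst_threshold(self, params, baseline):
        ctl = DrinkController()
        s = state_with_conc(baseline, params.rule1_threshold + 1.0)
        rng = np.random.default_rng(2)
        for _ in range(300):
            cmd = ctl.decide_intake(s, params, rng, time_of_day=120)
            assert cmd.kind != UNREGULATED

    def test_gating_and_lock_stop_all_intake(self, params, baseline):
        rng = np.random.default_rng(3)
        ctl = DrinkController(rule1_active=True)
        s = state_with_conc(baseline, 150.0, locked=True)
        for _ in range(50):
            assert ctl.decide_intake(s, params, rng, 600).kind == NONE
        ctl = DrinkController(rule1_active=True)
        s = state_with_conc(baseline, 150.0)
        for _ in range(50):
            assert ctl.decide_intake(s, params, rng, 600,
                                     water_access=False).kind == NONE

    def test_forced_bout_is_delivered(self, params, baseline):
        ctl = DrinkController()
        ctl.force_bout(2.0)
        rng = np.random.default_rng(4)
        s = state_with_conc(baseline, 140.0)
        vol = sum(ctl.decide_intake(s, params, rng, 840).volume_this_minute
                  for _ in range(5))
        assert vol >= 2.0  # the queued draught plus any spontaneous bouts


class TestReproducibility:
    def test_same_seed_same_decision_sequence(self, params):
        a = hr.simulate(params, hr.control(), days=1, seed=99)
        b = hr.simulate(params, hr.control(), days=1, seed=99)
        assert a.frame.equals(b.frame)

    def test_most_unregulated_bouts_fall_in_the_waking_period(self, control_run_20d):
        f = control_run_20d.frame
        unreg = f[f.intake_kind == 2]
        waking_fraction = (unreg.minute_of_day >= 720).mean()
        assert waking_fraction > 0.5
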