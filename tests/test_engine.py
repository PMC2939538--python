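"""The per-minute scheduler: conservation, analysis operations and scenarios."""

import numpy as np
import pandas as pd
import pytest

import hydrorat as hr
from hydrorat.engine import NIGHT_WINDOW, CircadianProfile


def ledger_residuals(series: hr.TimeSeries):
    """Per-minute water and sodium balance residuals, from the recorded state."""
    f = series.frame
    p = series.params
    total_w = f.ecf_v + f.icf_v + f.stomach_v + f.intestine_v
    ecf_na = f.na_conc * f.ecf_v / 1000.0
    total_na = ecf_na + f.stomach_na + f.intestine_na
    dw = total_w.diff().iloc[1:]
    dna = total_na.diff().iloc[1:]
    expect_w = (f.intake_ml - f.urine_flow + p.unregulated_balance_flux).iloc[1:]
    infused = pd.Series(0.0, index=f.index)
    expect_na = (f.intake_na - f.urine_na).iloc[1:] + infused.iloc[1:]
    return (dw - expect_w).abs().max(), (dna - expect_na).abs().max()


class TestConservation:
    def test_water_and_sodium_ledgers_close_every_minute(self, params):
        series = hr.simulate(params, hr.control(), days=2, seed=21)
        w_err, na_err = ledger_residuals(series)
        assert w_err < 1e-9
        assert na_err < 1e-12

    def test_ledgers_close_under_the_saline_challenge(self, params):
        series = hr.simulate(params, hr.saline_challenge(), days=1, seed=21)
        f = series.frame
        total_w = f.ecf_v + f.icf_v + f.stomach_v + f.intestine_v
        dw = total_w.diff().iloc[1:]
        expect_w = (f.intake_ml - f.urine_flow + params.unregulated_balance_flux).iloc[1:]
        assert (dw - expect_w).abs().max() < 1e-9  # the infusion adds no water

    def test_cumulative_columns_are_monotone(self, control_run_20d):
        f = control_run_20d.frame
        for col in ("cum_urine_ml", "cum_intake_ml", "cum_intake_na"):
            assert (f[col].diff().iloc[1:] >= -1e-12).all()

    def test_row_count_and_determinism(self, params):
        a = hr.simulate(params, hr.control(), days=2, seed=33)
        assert len(a) == 2 * 1440
        b = hr.simulate(params, hr.control(), days=2, seed=33)
        assert a.frame.equals(b.frame)


class TestCircadianProfile:
    def test_profile_mean_equals_overall_mean(self, control_run_20d):
        prof = hr.circadian_profile(control_run_20d)
        assert prof.frame["na_conc_mean"].mean() == pytest.approx(
            control_run_20d.frame["na_conc"].mean())

    def test_constant_series_has_zero_sd(self, params):
        f = hr.simulate(params, hr.control(), days=2, seed=0).frame.copy()
        f["avp"] = 2.0
        const = hr.TimeSeries(frame=f, params=params, protocol=hr.control(),
                              seed=0, days=2)
        prof = hr.circadian_profile(const)
        assert (prof.frame["avp_sd"] == 0).all()

    def test_avp_peak_near_the_sleep_wake_transition(self, control_run_20d):
        prof = hr.circadian_profile(control_run_20d)
        peak_minute = int(prof.frame["avp_mean"].idxmax())
        assert 480 <= peak_minute <= 900   # 16:00 .. 23:00

    def test_needs_at_least_two_days(self, params):
        one = hr.simulate(params, hr.control(), days=1, seed=0)
        with pytest.raises(ValueError):
            hr.circadian_profile(one)


class TestDetectPhases:
    @staticmethod
    def synthetic_profile(values):
        frame = pd.DataFrame({"avp_mean": values,
                              "avp_sd": np.zeros(1440)})
        return CircadianProfile(frame=frame, night_avp_day_means=np.array([1.0, 1.0]),
                                days=2)

    def test_exact_first_crossing_on_constructed_profile(self):
        minutes = np.arange(1440)
        values = np.where(minutes < 700, 1.0 + minutes / 700.0, 2.0 - (minutes - 700) / 400.0)
        values = np.clip(values, 0.5, None)
        prof = self.synthetic_profile(values)
        det = hr.detect_phases(prof)
        assert det.restoration_onset == 700
        window = values[NIGHT_WINDOW[0]:NIGHT_WINDOW[1]]
        thr = window.mean() + 1.96 * window.std(ddof=1)
        crossing = next(m for m in range(701, 1440) if values[m] <= thr)
        assert det.maintenance_onset == crossing
        assert det.maintenance_threshold == pytest.approx(thr)

    def test_flat_profile_at_threshold_starts_right_after_peak(self):
        values = np.full(1440, 2.0)
        values[700] = 3.0
        prof = self.synthetic_profile(values)
        det = hr.detect_phases(prof)
        assert det.restoration_onset == 700
        assert det.maintenance_onset == 701

    def test_late_drop_crosses_at_the_window_start(self):
        values = np.full(1440, 5.0)
        values[NIGHT_WINDOW[0]:] = 1.0   # profile only reaches steady level at 02:00
        values[700] = 6.0
        prof = self.synthetic_profile(values)
        det = hr.detect_phases(prof)
        assert det.maintenance_onset == NIGHT_WINDOW[0]  # crossing at window start


class TestSummarize:
    def test_per_100g_conversion(self, control_run_20d):
        summ = hr.summarize(control_run_20d)
        f = control_run_20d.frame
        assert summ.means["ecf_v_per100g"] == pytest.approx(
            f.groupby("day")["ecf_v"].mean().mean() / 2.55)

    def test_long_run_sodium_is_stable(self, control_run_20d):
        summ = hr.summarize(control_run_20d)
        assert summ.sds["ecf_na_conc"] < 2.0

    def test_sleeping_period_is_antidiuretic(self, control_run_20d):
        summ = hr.summarize(control_run_20d)
        f = control_run_20d.frame
        assert summ.sleeping["urine_flow_mean"] < f["urine_flow"].mean()
        assert summ.sleeping["avp_mean"] > summ.means["avp_maintenance"]
        assert summ.sleeping["na_conc_mean"] > summ.waking["na_conc_mean"]


class TestScenarios:
    @pytest.mark.parametrize("seed", [3, 5, 9])
    def test_blocking_icf_exchange_destabilises_sodium(self, params, seed):
        ctrl = hr.simulate(params, hr.control(), days=1, seed=seed)
        abl = hr.simulate(params, hr.no_icf_exchange_scenario(), days=1, seed=seed)
        thr = params.rule1_threshold

        def crossings(frame):
            above = (frame.na_conc > thr).to_numpy()
            return int(((~above[:-1]) & above[1:]).sum())

        assert crossings(abl.frame) > crossings(ctrl.frame)
        assert abl.frame.intake_ml.sum() > ctrl.frame.intake_ml.sum()
        # the ICF volume is genuinely frozen while blocked
        assert abl.frame.icf_v.nunique() == 1

    @pytest.mark.parametrize("seed", [2, 4, 7])
    def test_forced_morning_drink_lowers_the_sleeping_avp_peak(self, params, seed):
        ctrl = hr.simulate(params, hr.control(), days=1, seed=seed)
        forced = hr.simulate(params, hr.forced_drink_scenario(), days=1, seed=seed)
        sleep_ctrl = ctrl.frame[ctrl.frame.minute_of_day < 720]
        sleep_forced = forced.frame[forced.frame.minute_of_day < 720]
        assert sleep_forced.avp.max() < sleep_ctrl.avp.max()
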