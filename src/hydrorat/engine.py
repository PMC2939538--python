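"""The 1-minute scheduler composing all modules, plus the analysis operations.

Update order within each minute: (1) protocol events, (2) drinking decision
and ingestion, (3) gut transit, (4) the constant insensible water balance,
(5) renal output (or the furosemide override), (6) osmotic re-equilibration,
(7) the AVP controller, (8) recording.  The AVP controller reads the
post-flux state, so the equilibrium level responds to the minute's net
changes; the kidney reads the previous minute's hormone level and sodium
concentration, reflecting the one-minute delay of the renal response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import avp as avp_mod
from . import challenges as chal
from .core import (BodyState, SimulationError, apply_fluxes, ecf_na_conc,
                   equilibrate_water, init_state)
from .digestive import gut_step, ingest
from .kidney import kidney_step
from .motivation import DrinkController
from .params import ModelParams

__all__ = [
    "TimeSeries",
    "CircadianProfile",
    "PhaseDetection",
    "SimulationSummary",
    "Engine",
    "simulate",
    "circadian_profile",
    "detect_phases",
    "summarize",
]

MIN_PER_DAY = 1440
DAY_START_TOD = 480          # minute 0 of a run-day is 08:00 (sleep onset)
NIGHT_WINDOW = (1080, 1440)          # 02:00-08:00, the steady pre-sleep window

_KIND_CODE = {"none": 0, "need_induced": 1, "unregulated": 2}

_COLUMNS = [
    "t_min", "day", "minute_of_day", "time_of_day", "na_conc", "ecf_v", "icf_v",
    "avp", "avp_base", "urine_flow", "urine_na", "ald_factor", "anp_factor",
    "intake_ml", "intake_na", "intake_kind", "stomach_v", "stomach_na",
    "intestine_v", "intestine_na",
    "cum_urine_ml", "cum_intake_ml", "cum_intake_na", "drinking_locked",
    "water_access", "furosemide_active",
]


@dataclass
class TimeSeries:
    """Per-minute record of a simulation run."""

    frame: pd.DataFrame
    params: ModelParams
    protocol: chal.Protocol
    seed: int | None
    days: int

    def __len__(self) -> int:
        return len(self.frame)

    def day_slice(self, day: int) -> pd.DataFrame:
        f = self.frame
        return f[f["day"] == day]


@dataclass
class CircadianProfile:
    """Minute-of-day mean +/- SD across days, plus the per-day night-window AVP means."""

    frame: pd.DataFrame            # index: minute of the run-day (0 = 08:00)
    night_avp_day_means: np.ndarray
    days: int


@dataclass
class PhaseDetection:
    restoration_onset: int              # minute of the run-day with peak mean AVP
    maintenance_onset: int | None       # first minute after the peak below threshold
    maintenance_threshold: float        # pg/ml


@dataclass
class SimulationSummary:
    """Daily means/SDs of the headline parameters and the detected phases."""

    means: dict[str, float]
    sds: dict[str, float]
    daily: pd.DataFrame
    phases: PhaseDetection | None
    sleeping: dict[str, float]
    waking: dict[str, float]
    config: dict[str, Any] = field(default_factory=dict)


class Engine:
    """Stateful stepper for one simulation run."""

    def __init__(self, params: ModelParams, protocol: chal.Protocol,
                 n_minutes: int, rng: np.random.Generator):
        self.params = params
        self.protocol = protocol
        self.rng = rng
        self.state = init_state(params)
        self.ecf_v0 = self.state.ecf_v
        self.controller = DrinkController()
        self.n_minutes = n_minutes
        self._build_schedule(n_minutes)
        # running totals
        self.cum_urine_w = 0.0
        self.cum_urine_na = 0.0
        self.cum_intake_w = 0.0
        self.cum_intake_na = 0.0
        self.cum_insensible = 0.0
        self.cum_infused_na = 0.0

    # -- protocol expansion ------------------------------------------------

    def _build_schedule(self, n: int) -> None:
        p = self.params
        self.access = np.ones(n, dtype=bool)
        self.icf_on = np.ones(n, dtype=bool)
        self.infusion = np.zeros(n)          # mmol/min into the ECF
        self.need_conc = np.zeros(n)         # distilled water by default
        self.unreg_conc = np.full(n, p.drinking.unregulated_na_conc)
        self.forced: dict[int, float] = {}
        self.injections: list[int] = []
        for ev in self.protocol.events:
            t0 = ev.start_min
            if t0 >= n and ev.kind != chal.ICF_EXCHANGE:
                continue
            if ev.kind == chal.NA_INFUSION:
                dur = int(ev.payload["duration_min"])
                rate = ev.payload["total_mmol"] / dur
                self.infusion[t0:min(t0 + dur, n)] += rate
            elif ev.kind == chal.WATER_ACCESS:
                self.access[t0:] = bool(ev.payload["on"])
            elif ev.kind == chal.ICF_EXCHANGE:
                if t0 < n:
                    self.icf_on[t0:] = bool(ev.payload["on"])
            elif ev.kind == chal.DIET:
                if "need_na_conc" in ev.payload:
                    self.need_conc[t0:] = float(ev.payload["need_na_conc"])
                if "unregulated_na_conc" in ev.payload:
                    self.unreg_conc[t0:] = float(ev.payload["unregulated_na_conc"])
            elif ev.kind == chal.FORCED_DRINK:
                vol = float(ev.payload.get("volume", p.drinking.need_bout_volume_ml))
                self.forced[t0] = self.forced.get(t0, 0.0) + vol
            elif ev.kind == chal.FUROSEMIDE_INJECTION:
                self.injections.append(t0)

    # -- one minute --------------------------------------------------------

    def step(self) -> tuple:
        """Advance one minute; returns the recorded row."""
        s = self.state
        p = self.params
        t = s.t_min
        if t >= self.n_minutes:
            raise SimulationError("stepping past the scheduled horizon")
        tod = (t + DAY_START_TOD) % MIN_PER_DAY
        icf_on = bool(self.icf_on[t])

        # (1) protocol events
        if self.infusion[t] > 0.0:
            s = apply_fluxes(s, 0.0, self.infusion[t])
            self.cum_infused_na += self.infusion[t]
        if t in self.forced:
            self.controller.force_bout(self.forced[t])

        # (2) drinking decision and ingestion
        cmd = self.controller.decide_intake(
            s, p, self.rng, tod,
            water_access=bool(self.access[t]),
            need_water_na_conc=float(self.need_conc[t]),
            unregulated_na_conc=float(self.unreg_conc[t]),
            ecf_v0=self.ecf_v0,
        )
        if cmd.volume_this_minute > 0.0:
            before = s.stomach_v
            s = ingest(s, cmd.volume_this_minute, cmd.na_conc, p)
            poured = s.stomach_v - before
            self.cum_intake_w += poured
            self.cum_intake_na += poured * cmd.na_conc / 1000.0

        # (3) gut transit
        s, _fluxes = gut_step(s, p)
        if icf_on:
            s = equilibrate_water(s, p)

        # (4) insensible water balance (net non-renal loss)
        s = apply_fluxes(s, p.unregulated_balance_flux, 0.0)
        self.cum_insensible -= p.unregulated_balance_flux

        # (5) kidney (previous minute's hormone level and [Na+])
        dts = [float(t - inj) for inj in self.injections]
        override = chal.furosemide_output(dts, p.furosemide) if self.injections else None
        circulating_prev = avp_mod.circulating_avp(s.avp, tod, p)
        renal = kidney_step(s, p, self.ecf_v0, override=override,
                            circulating_avp=circulating_prev)
        s = apply_fluxes(s, -renal.urine_water, -renal.urine_na)
        self.cum_urine_w += renal.urine_water
        self.cum_urine_na += renal.urine_na

        # (6) osmotic re-equilibration
        if icf_on:
            s = equilibrate_water(s, p)

        # (7) AVP controller on the post-flux state
        conc = ecf_na_conc(s)
        dv_frac = (s.ecf_v - self.ecf_v0) / self.ecf_v0
        target = avp_mod.avp_target(conc, dv_frac)
        s.avp = avp_mod.avp_update(s.avp, target, p.avp_clearance_frac_per_min)
        circulating = avp_mod.circulating_avp(s.avp, tod, p)

        # (8) record and advance the clock
        row = (
            t, t // MIN_PER_DAY, t % MIN_PER_DAY, tod, conc, s.ecf_v, s.icf_v,
            circulating, s.avp, renal.urine_water, renal.urine_na,
            renal.ald_factor, renal.anp_factor, cmd.volume_this_minute,
            cmd.volume_this_minute * cmd.na_conc / 1000.0,
            _KIND_CODE[cmd.kind], s.stomach_v, s.stomach_na,
            s.intestine_v, s.intestine_na,
            self.cum_urine_w, self.cum_intake_w, self.cum_intake_na,
            s.drinking_locked, bool(self.access[t]), override is not None,
        )
        s.t_min = t + 1
        self.state = s
        return row


def simulate(params: ModelParams | None = None,
             protocol: chal.Protocol | None = None,
             days: int = 20, seed: int | None = 0) -> TimeSeries:
    """Run ``days`` simulated days at 1-minute resolution.

    Deterministic for a given (params, protocol, seed): the only stochastic
    element is the need-free drinking schedule.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    p = params or ModelParams()
    proto = protocol or chal.control()
    rng = np.random.default_rng(seed)
    n = days * MIN_PER_DAY
    eng = Engine(p, proto, n, rng)
    rows = [eng.step() for _ in range(n)]
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    return TimeSeries(frame=frame, params=p, protocol=proto, seed=seed, days=days)


# -- analysis ---------------------------------------------------------------

_PROFILE_PARAMS = ("na_conc", "avp", "ecf_v", "icf_v", "urine_flow")


def circadian_profile(series: TimeSeries, days: int | None = None) -> CircadianProfile:
    """Minute-of-day mean and SD of each headline parameter across days.

    Averaging the same minute over all days removes the inter-day drinking
    randomness and exposes the circadian trend, the 1440-point analogue of
    sparse experimental sampling.
    """
    days = days if days is not None else series.days
    if days < 2:
        raise ValueError("circadian averaging needs at least 2 days")
    f = series.frame[series.frame["day"] < days]
    g = f.groupby("minute_of_day")
    out = {}
    for parm in _PROFILE_PARAMS:
        out[f"{parm}_mean"] = g[parm].mean()
        out[f"{parm}_sd"] = g[parm].std(ddof=1).fillna(0.0)
    prof = pd.DataFrame(out)
    night = f[(f["minute_of_day"] >= NIGHT_WINDOW[0])
              & (f["minute_of_day"] < NIGHT_WINDOW[1])]
    night_means = night.groupby("day")["avp"].mean().to_numpy()
    return CircadianProfile(frame=prof, night_avp_day_means=night_means, days=days)


def detect_phases(profile: CircadianProfile) -> PhaseDetection:
    """Locate the restoration and maintenance phases from the AVP profile.

    The restoration phase starts at the peak of the mean AVP profile; the
    maintenance phase starts at the first subsequent minute where mean AVP
    drops to the upper bound of the 95 % band of the steady 02:00-08:00
    window (mean +/- 1.96 SD of the window's minute means, the band that
    contains ~95 % of the steady-period values).
    """
    avp_mean = profile.frame["avp_mean"]
    restoration = int(avp_mean.idxmax())
    window = avp_mean.loc[NIGHT_WINDOW[0]:NIGHT_WINDOW[1] - 1]
    if len(window) < 2:
        raise ValueError("phase detection needs the 02:00-08:00 window in the profile")
    threshold = float(window.mean() + 1.96 * window.std(ddof=1))
    maintenance: int | None = None
    for m in range(restoration + 1, MIN_PER_DAY):
        if avp_mean.loc[m] <= threshold:
            maintenance = m
            break
    return PhaseDetection(restoration_onset=restoration,
                          maintenance_onset=maintenance,
                          maintenance_threshold=threshold)


def summarize(series: TimeSeries, params: ModelParams | None = None) -> SimulationSummary:
    """Daily means/SDs of the six headline parameters plus phase statistics.

    Volumes, urine and intake are reported per 100 g body weight; ECF [Na+]
    is the time-mean over the whole run; AVP is averaged over the detected
    maintenance phase (from its onset to the end of the waking period).
    """
    p = params or series.params
    scale = p.scale
    f = series.frame
    by_day = f.groupby("day")

    daily = pd.DataFrame({
        "urine_ml_per100g": by_day["urine_flow"].sum() / scale,
        "intake_ml_per100g": by_day["intake_ml"].sum() / scale,
        "na_intake_mmol_per100g": by_day["intake_na"].sum() / scale,
        "ecf_na_conc": by_day["na_conc"].mean(),
        "ecf_v_per100g": by_day["ecf_v"].mean() / scale,
        "icf_v_per100g": by_day["icf_v"].mean() / scale,
    })

    phases: PhaseDetection | None = None
    maint_avp_mean = float("nan")
    maint_avp_sd = float("nan")
    if series.days >= 2:
        profile = circadian_profile(series)
        phases = detect_phases(profile)
        if phases.maintenance_onset is not None:
            lo, hi = phases.maintenance_onset, MIN_PER_DAY
            win = f[(f["minute_of_day"] >= lo) & (f["minute_of_day"] < hi)]
            maint_by_day = win.groupby("day")["avp"].mean()
            maint_avp_mean = float(maint_by_day.mean())
            maint_avp_sd = float(maint_by_day.std(ddof=1)) if len(maint_by_day) > 1 else 0.0

    def _sd(col: pd.Series) -> float:
        return float(col.std(ddof=1)) if len(col) > 1 else 0.0

    means = {
        "ecf_v_per100g": float(daily["ecf_v_per100g"].mean()),
        "ecf_na_conc": float(f["na_conc"].mean()),
        "avp_maintenance": maint_avp_mean,
        "urine_ml_per100g": float(daily["urine_ml_per100g"].mean()),
        "intake_ml_per100g": float(daily["intake_ml_per100g"].mean()),
        "na_intake_mmol_per100g": float(daily["na_intake_mmol_per100g"].mean()),
        "icf_v_per100g": float(daily["icf_v_per100g"].mean()),
    }
    sds = {
        "ecf_v_per100g": _sd(daily["ecf_v_per100g"]),
        "ecf_na_conc": _sd(daily["ecf_na_conc"]),
        "avp_maintenance": maint_avp_sd,
        "urine_ml_per100g": _sd(daily["urine_ml_per100g"]),
        "intake_ml_per100g": _sd(daily["intake_ml_per100g"]),
        "na_intake_mmol_per100g": _sd(daily["na_intake_mmol_per100g"]),
        "icf_v_per100g": _sd(daily["icf_v_per100g"]),
    }

    sleep = f[f["minute_of_day"] < 720]
    wake = f[f["minute_of_day"] >= 720]

    def _period_stats(part: pd.DataFrame) -> dict[str, float]:
        return {
            "avp_mean": float(part["avp"].mean()),
            "avp_max_day_mean": float(part.groupby("day")["avp"].max().mean()),
            "na_conc_mean": float(part["na_conc"].mean()),
            "na_conc_max_day_mean": float(part.groupby("day")["na_conc"].max().mean()),
            "urine_flow_mean": float(part["urine_flow"].mean()),
            "intake_ml_mean": float(part.groupby("day")["intake_ml"].sum().mean()),
        }

    return SimulationSummary(
        means=means, sds=sds, daily=daily, phases=phases,
        sleeping=_period_stats(sleep), waking=_period_stats(wake),
    )
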