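"""Per-minute drinking decisions.

Two rules drive intake.  Need-induced drinking (Rule 1) engages when ECF
[Na+] exceeds the set-point by 4 % and keeps the animal drinking distilled
(or tap) water until the concentration is restored to the set-point, pausing
while the stomach-full lock is engaged.  Need-free ("unregulated") drinking
(Rule 2) delivers bouts of sodium-containing water at random minutes whose
probability follows a sinusoid peaking in the middle of the waking period
(02:00) with its minimum at 14:00; it only fires when ECF [Na+] is at or
below the normal band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import BodyState, ecf_na_conc
from .params import DrinkingParams, ModelParams

__all__ = ["IntakeCommand", "DrinkController", "rule1_need", "rule2_probability"]

NONE, NEED_INDUCED, UNREGULATED = "none", "need_induced", "unregulated"


@dataclass(frozen=True)
class IntakeCommand:
    kind: str = NONE                 # none | need_induced | unregulated
    volume_this_minute: float = 0.0  # ml
    na_conc: float = 0.0             # mmol/L of the ingested water


def rule1_need(na_conc: float, setpoint: float, active: bool, locked: bool,
               threshold_frac: float = 0.04, stop_conc: float | None = None) -> bool:
    """Need-induced drinking latch.

    Engages when [Na+] exceeds ``setpoint*(1+threshold_frac)``; once engaged
    it stays on until [Na+] is restored to ``stop_conc`` (the normal level;
    defaults to the set-point).  The stomach-full lock suppresses drinking
    without clearing the latch.
    """
    if stop_conc is None:
        stop_conc = setpoint
    if na_conc > setpoint * (1.0 + threshold_frac):
        active = True
    elif na_conc <= stop_conc:
        active = False
    return active and not locked


def rule2_probability(time_of_day: float, drinking: DrinkingParams | None = None) -> float:
    """Per-minute probability of starting a need-free bout.

    ``p(t) = p_base * (1 + a*sin(2*pi*(t - t0)/1440))`` with the phase set so
    the maximum falls at the configured peak time (02:00 by default) and the
    minimum 12 h later.  ``time_of_day`` is minutes past midnight.
    """
    if not 0 <= time_of_day < 1440:
        raise ValueError(f"time_of_day must lie in [0, 1440), got {time_of_day}")
    d = drinking or DrinkingParams()
    phase = 2.0 * math.pi * (time_of_day - d.unregulated_peak_min) / 1440.0
    p = d.unregulated_p_base * (1.0 + d.unregulated_amplitude * math.cos(phase))
    return max(p, 0.0)


@dataclass
class DrinkController:
    """Holds the latch/bout state that spans minutes within one simulation."""

    rule1_active: bool = False
    bout_remaining: float = 0.0   # ml still to deliver of the current bout
    bout_kind: str = NONE
    forced_queue: float = field(default=0.0)  # ml queued by a forced-drink event

    def force_bout(self, volume: float) -> None:
        self.forced_queue += volume

    def decide_intake(self, state: BodyState, params: ModelParams,
                      rng: np.random.Generator, time_of_day: float,
                      water_access: bool = True,
                      need_water_na_conc: float = 0.0,
                      unregulated_na_conc: float | None = None,
                      ecf_v0: float | None = None) -> IntakeCommand:
        """Decide this minute's intake.

        Rule 1 dominates and delivers distilled (or tap) water in bouts with
        an elevated per-minute start probability while the latch is on; Rule 2
        delivers sodium-containing bouts at the circadian-modulated base
        probability.  A bout spans consecutive minutes at the ingestion rate
        until its volume is delivered or the stomach locks.  A protocol can
        gate water access entirely or change the sodium content of either
        water source.
        """
        d = params.drinking
        if unregulated_na_conc is None:
            unregulated_na_conc = d.unregulated_na_conc
        rate = d.ingestion_rate_ml_per_min

        conc = ecf_na_conc(state)
        # Strong volume depletion adds a hypovolemic component to thirst:
        # the latch then only releases once [Na+] is back at the set-point.
        stop = d.rule1_stop_conc
        if ecf_v0 is not None and (ecf_v0 - state.ecf_v) / ecf_v0 >= d.hypovolemia_frac:
            stop = d.rule1_setpoint
        drink_need = rule1_need(conc, d.rule1_setpoint, self.rule1_active,
                                state.drinking_locked, params.drink_threshold_frac,
                                stop)
        # keep the latch itself up to date independent of the lock
        if conc > d.rule1_setpoint * (1.0 + params.drink_threshold_frac):
            self.rule1_active = True
        elif conc <= stop:
            self.rule1_active = False

        if not water_access or state.drinking_locked:
            self.bout_remaining = 0.0
            self.bout_kind = NONE
            return IntakeCommand()

        if drink_need:
            # Rule 1 dominates: any sodium-water bout in progress is abandoned.
            if self.bout_kind != NEED_INDUCED:
                self.bout_remaining = 0.0
            if self.bout_remaining <= 0.0:
                if rng.random() >= d.need_bout_p:
                    self.bout_kind = NONE
                    return IntakeCommand()
                self.bout_remaining = d.need_bout_volume_ml
            self.bout_kind = NEED_INDUCED
            vol = min(rate, self.bout_remaining)
            self.bout_remaining -= vol
            return IntakeCommand(NEED_INDUCED, vol, need_water_na_conc)

        if self.bout_kind == NEED_INDUCED:
            self.bout_remaining = 0.0  # latch released mid-bout
            self.bout_kind = NONE

        if self.forced_queue > 0.0:
            vol = min(rate, self.forced_queue)
            self.forced_queue -= vol
            return IntakeCommand(UNREGULATED, vol, unregulated_na_conc)

        if self.bout_remaining > 0.0:
            vol = min(rate, self.bout_remaining)
            self.bout_remaining -= vol
            self.bout_kind = UNREGULATED
            return IntakeCommand(UNREGULATED, vol, unregulated_na_conc)

        if conc <= d.rule2_setpoint and rng.random() < rule2_probability(time_of_day, d):
            vol = min(rate, d.bout_volume_ml)
            self.bout_remaining = d.bout_volume_ml - vol
            self.bout_kind = UNREGULATED
            return IntakeCommand(UNREGULATED, vol, unregulated_na_conc)

        return IntakeCommand()
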