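"""Protocols: timed schedules of external events applied to a simulation.

A protocol is pure data — an ordered list of events — so two runs with the
same protocol and seed are identical.  Presets cover the two dehydration
challenges (hypertonic-saline infusion; furosemide plus a sodium-deficient
diet) and the two ablation scenarios (one forced drinking bout at sleep
onset; blocked ICF-ECF water exchange).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .params import FurosemideParams, ModelParams

__all__ = [
    "Event",
    "Protocol",
    "control",
    "saline_challenge",
    "furosemide_challenge",
    "forced_drink_scenario",
    "no_icf_exchange_scenario",
    "furosemide_output",
    "PRESETS",
]

MIN_PER_DAY = 1440

# Event kinds
NA_INFUSION = "na_infusion"            # payload: total_mmol, duration_min
FUROSEMIDE_INJECTION = "furosemide_injection"
WATER_ACCESS = "water_access"          # payload: on (bool)
DIET = "diet"                          # payload: need_na_conc, unregulated_na_conc (mmol/L)
FORCED_DRINK = "forced_drink"          # payload: volume (ml)
ICF_EXCHANGE = "icf_exchange"          # payload: on (bool)

_KINDS = {NA_INFUSION, FUROSEMIDE_INJECTION, WATER_ACCESS, DIET,
          FORCED_DRINK, ICF_EXCHANGE}


@dataclass(frozen=True)
class Event:
    start_min: int
    kind: str
    payload: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.start_min < 0:
            raise ValueError("event start must be non-negative")
        if self.kind == NA_INFUSION:
            if self.payload.get("duration_min", 0) <= 0:
                raise ValueError("infusion duration must be positive")


@dataclass(frozen=True)
class Protocol:
    """Time-ordered schedule of external events."""

    events: tuple[Event, ...] = ()
    name: str = "control"

    def __post_init__(self) -> None:
        starts = [e.start_min for e in self.events]
        if starts != sorted(starts):
            raise ValueError("protocol events must be time-ordered")

    def events_of(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]


def control() -> Protocol:
    """Balanced hydromineral conditions: no external events."""
    return Protocol(name="control")


def saline_challenge(start_min: int = 240, total_mmol: float = 1.0,
                     duration_min: int = 10) -> Protocol:
    """Hypertonic-saline infusion: sodium only, no water, into the ECF.

    Defaults to 1 mmol over 10 min starting at 12:00 (mid-sleeping period,
    outside the morning circadian AVP reduction), mimicking a short jugular
    injection.
    """
    return Protocol(
        events=(Event(start_min, NA_INFUSION,
                      {"total_mmol": total_mmol, "duration_min": duration_min}),),
        name="saline",
    )


def furosemide_challenge(params: ModelParams | None = None,
                         day1_unregulated_na_conc: float = 10.0) -> Protocol:
    """Furosemide plus sodium-deficient diet, preceded by one control day.

    Day 0 runs as its own control.  On day 1, furosemide is injected at 08:00
    and 10:00 (kidney override for each injection's time-course), water and
    food are withheld for the first 4 h, and from 12:00 the animal drinks ad
    libitum: need-induced bouts take tap water, and need-free bouts carry a
    reduced sodium content (default 10 mmol/L) so the day's sodium intake
    matches the ~2 mg/100 g bw the sodium-deficient diet provides.
    """
    p = params or ModelParams()
    unreg = day1_unregulated_na_conc
    d1 = MIN_PER_DAY
    return Protocol(
        events=(
            Event(d1, FUROSEMIDE_INJECTION),
            Event(d1, WATER_ACCESS, {"on": False}),
            Event(d1 + 120, FUROSEMIDE_INJECTION),
            Event(d1 + 240, WATER_ACCESS, {"on": True}),
            Event(d1 + 240, DIET, {"need_na_conc": p.tap_water_na_conc,
                                   "unregulated_na_conc": unreg}),
        ),
        name="furosemide",
    )


def forced_drink_scenario(volume: float = 2.0) -> Protocol:
    """One additional drinking bout forced at the onset of the sleeping period."""
    return Protocol(events=(Event(0, FORCED_DRINK, {"volume": volume}),),
                    name="forced-drink")


def no_icf_exchange_scenario(duration_min: int = MIN_PER_DAY) -> Protocol:
    """Block osmotic water exchange between ICF and ECF for the given span."""
    return Protocol(
        events=(Event(0, ICF_EXCHANGE, {"on": False}),
                Event(duration_min, ICF_EXCHANGE, {"on": True})),
        name="no-icf-exchange",
    )


def furosemide_output(minutes_since_injections: list[float],
                      furo: FurosemideParams) -> tuple[float, float] | None:
    """Combined furosemide override for the current minute, or None if expired.

    Each injection contributes its table value at its own elapsed time;
    overlapping injections combine by element-wise maximum flow, taking the
    urine [Na+] of the dominant injection.
    """
    best: tuple[float, float] | None = None
    for dt in minutes_since_injections:
        if dt < 0 or dt > furo.horizon_min:
            continue
        flow = furo.flow_table(dt)
        conc = (furo.isonatriuric_conc if furo.isonatriuric
                else furo.urine_na_table(dt))
        if best is None or flow > best[0]:
            best = (flow, conc)
    return best


PRESETS = {
    "control": control,
    "saline": saline_challenge,
    "furosemide": furosemide_challenge,
    "forced-drink": forced_drink_scenario,
    "no-icf-exchange": no_icf_exchange_scenario,
}
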