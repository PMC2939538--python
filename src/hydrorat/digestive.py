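"""Stomach and intestine transit of ingested water and sodium.

A two-compartment gut with first-order kinetics: the stomach empties into the
intestine and exchanges a little water passively with the ECF; the intestine
absorbs water and sodium (the latter with an additional active component).
Water fluxes carry sodium at the local concentration, so gut mass balance is
exact.  The stomach-fullness hysteresis (lock at 5 ml, release below 3.1 ml)
lives here because it is driven purely by stomach volume.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import BodyState
from .params import ModelParams

__all__ = ["GutFluxes", "ingest", "gut_step"]


@dataclass(frozen=True)
class GutFluxes:
    """Per-minute gut fluxes (all non-negative in the direction named)."""

    stomach_to_intestine_w: float = 0.0   # ml/min
    stomach_to_ecf_w: float = 0.0         # ml/min, passive diffusion
    intestine_to_ecf_w: float = 0.0       # ml/min
    stomach_to_intestine_na: float = 0.0  # mmol/min
    stomach_to_ecf_na: float = 0.0        # mmol/min
    intestine_to_ecf_na: float = 0.0      # mmol/min

    @property
    def to_ecf_w(self) -> float:
        return self.stomach_to_ecf_w + self.intestine_to_ecf_w

    @property
    def to_ecf_na(self) -> float:
        return self.stomach_to_ecf_na + self.intestine_to_ecf_na


def ingest(state: BodyState, volume: float, na_conc: float,
           params: ModelParams) -> BodyState:
    """Pour ``volume`` ml of water with ``na_conc`` mmol/L sodium into the stomach.

    Intake is truncated at the 5 ml stomach capacity; hitting capacity (or
    already being at it) engages the drinking lock, which only releases once
    the stomach drains below the comfort level.
    """
    if volume < 0:
        raise ValueError("ingested volume must be non-negative")
    out = state.copy()
    room = params.stomach_full_ml - state.stomach_v
    poured = min(volume, max(room, 0.0))
    out.stomach_v = state.stomach_v + poured
    out.stomach_na = state.stomach_na + poured * na_conc / 1000.0
    if out.stomach_v >= params.stomach_full_ml - 1e-12:
        out.drinking_locked = True
    return out


def gut_step(state: BodyState, params: ModelParams) -> tuple[BodyState, GutFluxes]:
    """One minute of gut transit; returns the updated state and the fluxes.

    The returned state has the fluxes applied to the gut compartments and the
    ECF water/sodium contents; the caller re-equilibrates osmotic water
    afterwards (or skips it when ICF exchange is ablated).  Clears the
    drinking lock when the stomach drains below the comfort level.
    """
    g = params.gut
    sv, sna = state.stomach_v, state.stomach_na
    iv, ina = state.intestine_v, state.intestine_na

    s_conc = sna / sv if sv > 1e-12 else 0.0   # mmol/ml
    i_conc = ina / iv if iv > 1e-12 else 0.0

    w_si = g.k_stomach_to_intestine * sv
    w_se = g.k_stomach_to_ecf * sv
    w_ie = g.k_intestine_to_ecf * iv

    na_si = w_si * s_conc
    na_se = w_se * s_conc
    na_ie = w_ie * i_conc + g.k_intestine_na_active * ina

    # Clamp so no compartment is driven below zero within the minute.
    out_w_s = w_si + w_se
    if out_w_s > sv:
        scale = sv / out_w_s
        w_si, w_se, na_si, na_se = (x * scale for x in (w_si, w_se, na_si, na_se))
    na_ie = min(na_ie, ina + na_si)
    w_ie = min(w_ie, iv + w_si)

    fluxes = GutFluxes(
        stomach_to_intestine_w=w_si,
        stomach_to_ecf_w=w_se,
        intestine_to_ecf_w=w_ie,
        stomach_to_intestine_na=na_si,
        stomach_to_ecf_na=na_se,
        intestine_to_ecf_na=na_ie,
    )

    out = state.copy()
    out.stomach_v = sv - w_si - w_se
    out.stomach_na = sna - na_si - na_se
    out.intestine_v = iv + w_si - w_ie
    out.intestine_na = ina + na_si - na_ie
    out.ecf_v = state.ecf_v + fluxes.to_ecf_w
    out.ecf_na = state.ecf_na + fluxes.to_ecf_na
    for name in ("stomach_v", "stomach_na", "intestine_v", "intestine_na"):
        v = getattr(out, name)
        if -1e-12 < v < 0.0:  # float round-off only; real negatives are a bug
            setattr(out, name, 0.0)
    if out.drinking_locked and out.stomach_v < params.stomach_comfort_ml:
        out.drinking_locked = False
    return out, fluxes
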