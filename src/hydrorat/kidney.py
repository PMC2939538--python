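"""Renal output: AVP-dependent urine flow and factor-modulated sodium excretion.

Urine flow falls hyperbolically with circulating AVP through two printed
anchors (138 ul/min/100 g at zero AVP; 6 ul/min/100 g at the 2.3 pg/ml basal
level).  Sodium leaves with a constant clearance, modulated by an aldosterone
retention factor (volume deficit) and an ANP natriuresis factor (volume
expansion).  A furosemide override can replace the whole output for the
duration of its time-course.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import BodyState, ecf_na_conc
from .params import ModelParams

__all__ = [
    "RenalOutput",
    "urine_flow",
    "ald_factor",
    "anp_factor",
    "sodium_excretion",
    "kidney_step",
]


@dataclass(frozen=True)
class RenalOutput:
    urine_water: float    # ml/min
    urine_na: float       # mmol/min
    ald_factor: float     # dimensionless in [0.2, 1]
    anp_factor: float     # dimensionless >= 1

    @property
    def urine_na_conc(self) -> float:
        """Urine sodium concentration, mmol/L (0 for zero flow)."""
        if self.urine_water <= 0:
            return 0.0
        return self.urine_na / self.urine_water * 1000.0


def urine_flow(avp: float, weight: float, params: ModelParams) -> float:
    """Urine flow in ml/min for the whole animal, hyperbolic in circulating AVP.

    F(avp) = F_max / (1 + k*avp) per 100 g, with k chosen so the curve passes
    through both printed anchors exactly; scaled by weight/100.
    """
    avp = max(avp, 0.0)
    f_max = params.urine_flow_max          # ul/min/100 g
    k = (params.urine_flow_max / params.urine_flow_basal - 1.0) / params.urine_flow_basal_avp
    per100g_ul = f_max / (1.0 + k * avp)
    return per100g_ul / 1000.0 * (weight / 100.0)


def ald_factor(ecf_v: float, ecf_v0: float, params: ModelParams) -> float:
    """Aldosterone sodium-retention factor for an ECF volume deficit.

    Two-stage lookup: fractional deficit below the set-point -> plasma
    aldosterone (ng/100 ml) -> factor, linear between 1.0 at 0 ng/100 ml and
    0.2 at 200 ng/100 ml.  Returns 1.0 at or above the set-point.
    """
    if ecf_v <= 0 or ecf_v0 <= 0:
        raise ValueError("volumes must be positive")
    if ecf_v >= ecf_v0:
        return 1.0
    deficit = (ecf_v0 - ecf_v) / ecf_v0
    ald_conc = params.ald_volume_table(deficit)
    factor = params.ald_factor_table(ald_conc)
    return min(max(factor, 0.2), 1.0)


def anp_factor(ecf_v: float, ecf_v0: float, params: ModelParams) -> float:
    """ANP natriuresis factor for an ECF volume expansion.

    Two-stage lookup: fractional expansion -> plasma ANP (pg/ml, capped at
    2000) -> multiplicative factor >= 1.  Returns 1.0 at or below the
    set-point.
    """
    if ecf_v <= 0 or ecf_v0 <= 0:
        raise ValueError("volumes must be positive")
    if ecf_v <= ecf_v0:
        return 1.0
    expansion = (ecf_v - ecf_v0) / ecf_v0
    anp = min(params.anp_volume_table(expansion), params.anp_cap)
    return max(params.anp_factor_table(anp), 1.0)


def sodium_excretion(na_conc: float, c_na: float, ald: float, anp: float) -> float:
    """Sodium excretion rate (mmol/min): [Na+]*C_Na+*ALD_factor*ANP_factor."""
    return (na_conc / 1000.0) * c_na * ald * anp


def kidney_step(state: BodyState, params: ModelParams, ecf_v0: float,
                override: tuple[float, float] | None = None,
                circulating_avp: float | None = None) -> RenalOutput:
    """Renal output for the current minute.

    ``override``, when given, is a furosemide (flow ml/min/100 g, urine [Na+]
    mmol/L) pair that replaces the normal model for this minute.  ``ecf_v0``
    is the ECF volume set-point the ALD/ANP controllers compare against.
    ``circulating_avp`` lets the caller supply the circadian-modulated plasma
    level; by default the state's post-clearance level is used.
    """
    ald = ald_factor(state.ecf_v, ecf_v0, params)
    anp = anp_factor(state.ecf_v, ecf_v0, params)
    if override is not None:
        flow_per100g, na_conc_urine = override
        water = max(flow_per100g, 0.0) * (params.weight / 100.0)
        na = water * max(na_conc_urine, 0.0) / 1000.0
    else:
        circulating = state.avp if circulating_avp is None else circulating_avp
        water = urine_flow(circulating, params.weight, params)
        na = sodium_excretion(ecf_na_conc(state), params.na_clearance, ald, anp)
    # Never excrete more than the compartment holds (safety clamp; unreachable
    # for physiological states at 1-min resolution).
    water = min(water, 0.5 * state.ecf_v)
    na = min(na, state.ecf_na)
    return RenalOutput(urine_water=water, urine_na=na, ald_factor=ald, anp_factor=anp)
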