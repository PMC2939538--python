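"""The vasopressin controller.

Circulating AVP is modelled as an equilibrium level set by plasma sodium and
ECF volume: the target is linear in osmolality with a volume-dependent slope
plus an exponential volume term, secretion upward is instantaneous, decay is
limited by a fixed 15 %/min clearance, and a scheduled pre-sleep circadian
reduction (nadir -30 %) multiplies the circulating level.
"""

from __future__ import annotations

import math

from .params import CircadianAvpParams, ModelParams

__all__ = ["avp_target", "avp_update", "circadian_factor", "circulating_avp"]

# Osmolality-response constants fitted to classic rat dose-response data:
# AVP [pg/ml] = (0.91 - 11*v) * 200 * ([Na+] mol/L - 0.1375) + 1.3 * exp(-17*v)
# where v <= 0 is the fractional ECF volume deficit.
_BASE_SLOPE = 0.91
_SLOPE_VOLUME_GAIN = 11.0
_OSM_GAIN = 200.0
_NA_OFFSET_MOL = 0.1375
_EXP_SCALE = 1.3
_EXP_VOLUME_GAIN = 17.0


def avp_target(na_conc: float, ecf_dv_frac: float) -> float:
    """Equilibrium AVP level (pg/ml) for a given ECF [Na+] and volume deviation.

    Parameters
    ----------
    na_conc : ECF sodium concentration, mmol/L.
    ecf_dv_frac : (ECF_V(t) - ECF_V(0)) / ECF_V(0); positive deviations are
        clamped to zero (volume expansion does not suppress the osmotic drive
        in this formulation), and the output is clamped to be non-negative.
    """
    v = min(ecf_dv_frac, 0.0)
    n = na_conc / 1000.0  # mol/L
    level = ((_BASE_SLOPE - _SLOPE_VOLUME_GAIN * v) * (_OSM_GAIN * (n - _NA_OFFSET_MOL))
             + _EXP_SCALE * math.exp(-_EXP_VOLUME_GAIN * v))
    return max(level, 0.0)


def avp_update(current: float, target: float,
               clearance_frac: float = 0.15) -> float:
    """One-minute update of the post-clearance AVP level.

    Secretion is instantaneous (rises jump to the target); reduction is
    limited by the fractional clearance per minute, flooring at the target.
    """
    if target >= current:
        return target
    return max(target, current * (1.0 - clearance_frac))


def circadian_factor(time_of_day: float,
                     circ: CircadianAvpParams | None = None) -> float:
    """Multiplicative circadian factor on circulating AVP.

    ``time_of_day`` is in minutes past midnight.  The factor ramps linearly
    from 1.0 at the window start down to ``1 - depth`` at the nadir, then back
    to 1.0 by the window end; it is 1.0 outside the window.
    """
    if not 0 <= time_of_day < 1440:
        raise ValueError(f"time_of_day must lie in [0, 1440), got {time_of_day}")
    c = circ or CircadianAvpParams()
    if time_of_day < c.start_min or time_of_day >= c.end_min:
        return 1.0
    if time_of_day < c.nadir_min:
        frac = (time_of_day - c.start_min) / (c.nadir_min - c.start_min)
        return 1.0 - c.depth * frac
    frac = (time_of_day - c.nadir_min) / (c.end_min - c.nadir_min)
    return 1.0 - c.depth * (1.0 - frac)


def circulating_avp(avp_base: float, time_of_day: float, params: ModelParams) -> float:
    """Observable plasma AVP: the post-clearance level times the circadian factor."""
    return avp_base * circadian_factor(time_of_day, params.circadian_avp)
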