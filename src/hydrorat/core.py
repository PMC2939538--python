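"""Body-fluid state and the osmotic water exchange between ICF and ECF.

The body is reduced to two exchangeable water pools: the extracellular fluid
(ECF), whose effective osmolality is ``2*[Na+] + correction`` (the factor 2
counts the accompanying anion, the correction the non-electrolyte solutes),
and the intracellular fluid (ICF), represented by a fixed effective osmole
content calibrated at t=0 so the initial gradient is exactly zero.  Water
redistributes between the pools within one time step; solutes never cross.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .params import ModelParams

__all__ = [
    "BodyState",
    "SimulationError",
    "init_state",
    "ecf_na_conc",
    "effective_ecf_osmolality",
    "equilibrate_water",
    "apply_fluxes",
]

GRADIENT_TOL = 1e-9  # mosmol/L


class SimulationError(RuntimeError):
    """Raised when the state leaves its physical domain."""


@dataclass
class BodyState:
    """Mutable per-minute body state (absolute whole-animal quantities)."""

    t_min: int              # minutes since start; minute 0 = 08:00 of day 0
    ecf_v: float            # ml
    icf_v: float            # ml
    ecf_na: float           # mmol of ECF sodium
    icf_osmoles: float      # mosmol, fixed effective ICF osmole content
    avp: float              # pg/ml, post-clearance controller level
    stomach_v: float = 0.0  # ml
    stomach_na: float = 0.0  # mmol
    intestine_v: float = 0.0  # ml
    intestine_na: float = 0.0  # mmol
    drinking_locked: bool = False  # stomach-full hysteresis flag

    def copy(self) -> "BodyState":
        return replace(self)

    @property
    def total_water(self) -> float:
        """All simulated water, ml (body pools plus gut contents)."""
        return self.ecf_v + self.icf_v + self.stomach_v + self.intestine_v

    @property
    def total_na(self) -> float:
        """All simulated sodium, mmol."""
        return self.ecf_na + self.stomach_na + self.intestine_na


def ecf_na_conc(state: BodyState) -> float:
    """ECF sodium concentration in mmol/L."""
    if state.ecf_v <= 0:
        raise SimulationError("ECF volume is not positive")
    return state.ecf_na / state.ecf_v * 1000.0


def effective_ecf_osmolality(na_conc: float, correction: float) -> float:
    """Effective ECF osmolality (mosmol/L): 2*[Na+] plus the non-Na+ correction."""
    return 2.0 * na_conc + correction


def _gradient(icf_v: float, total: float, na: float, osmoles: float,
              correction: float) -> float:
    """ECF minus ICF effective osmolality for a trial ICF volume (mosmol/L)."""
    ecf_v = total - icf_v
    return (2000.0 * na / ecf_v + correction) - 1000.0 * osmoles / icf_v


def equilibrate_water(state: BodyState, params: ModelParams) -> BodyState:
    """Redistribute water between ICF and ECF until the osmotic gradient vanishes.

    Solves ``2000*Na/(T - V_I) + c = 1000*O/V_I`` for the ICF volume ``V_I``
    with the total exchangeable water ``T = ecf_v + icf_v`` conserved.  The
    condition rearranges to a quadratic whose physical root seeds a Newton
    polish down to |gradient| < 1e-9 mosmol/L.  Solute contents are untouched.
    """
    total = state.ecf_v + state.icf_v
    na = state.ecf_na
    osm = state.icf_osmoles
    c = params.osmole_correction
    if total <= 0 or osm <= 0:
        raise SimulationError("cannot equilibrate: empty fluid pools")

    if c == 0.0:
        icf_v = total * osm / (osm + 2.0 * na)
    else:
        # c*V^2 - (c*T + 2000*Na + 1000*O)*V + 1000*O*T = 0; the smaller root
        # lies in (0, T) because the product of the roots is 1000*O*T/c > T^2
        # only for the larger one.
        b = c * total + 2000.0 * na + 1000.0 * osm
        disc = b * b - 4.0 * c * 1000.0 * osm * total
        if disc < 0:
            raise SimulationError("no osmotic equilibrium in (0, total water)")
        icf_v = (b - math.sqrt(disc)) / (2.0 * c)

    if not 0.0 < icf_v < total:
        raise SimulationError("osmotic equilibrium fell outside (0, total water)")

    # Newton polish; the gradient is strictly increasing in V_I.
    for _ in range(8):
        g = _gradient(icf_v, total, na, osm, c)
        if abs(g) < GRADIENT_TOL:
            break
        dg = 2000.0 * na / (total - icf_v) ** 2 + 1000.0 * osm / icf_v ** 2
        icf_v -= g / dg
        icf_v = min(max(icf_v, 1e-12), total - 1e-12)
    else:
        if abs(_gradient(icf_v, total, na, osm, c)) >= GRADIENT_TOL:
            raise SimulationError("osmotic equilibration did not converge")

    out = state.copy()
    out.icf_v = icf_v
    out.ecf_v = total - icf_v
    return out


def apply_fluxes(state: BodyState, d_water_ecf: float, d_na_ecf: float) -> BodyState:
    """Add water (ml) and sodium (mmol) deltas to the ECF compartment.

    All renal, insensible and infusion fluxes route through here; the caller
    is responsible for re-equilibrating water afterwards.
    """
    out = state.copy()
    out.ecf_v = state.ecf_v + d_water_ecf
    out.ecf_na = state.ecf_na + d_na_ecf
    if out.ecf_v <= 0:
        raise SimulationError(
            f"flux {d_water_ecf:+.4f} ml would empty the ECF at t={state.t_min} "
            f"(ecf_v={state.ecf_v:.4f} ml)")
    if out.ecf_na < 0:
        raise SimulationError(
            f"flux {d_na_ecf:+.5f} mmol would make ECF sodium negative at t={state.t_min}")
    return out


def init_state(params: ModelParams) -> BodyState:
    """Build the t=0 state from the parameter set.

    Volumes are the per-100 g initial values scaled by body weight; the ICF
    osmole content is calibrated so the osmotic gradient at t=0 is exactly
    zero, making the initial state a fixed point of :func:`equilibrate_water`.
    """
    ecf_v = params.ecf_v_init
    icf_v = params.icf_v_init
    ecf_na = params.ecf_na_conc_init * ecf_v / 1000.0
    osm0 = effective_ecf_osmolality(params.ecf_na_conc_init, params.osmole_correction)
    icf_osmoles = osm0 * icf_v / 1000.0
    return BodyState(
        t_min=0,
        ecf_v=ecf_v,
        icf_v=icf_v,
        ecf_na=ecf_na,
        icf_osmoles=icf_osmoles,
        avp=params.avp_init,
    )
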