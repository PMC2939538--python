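"""Model parameters: physiological constants, lookup tables and behavioural settings.

All quantities use the package's internal unit conventions: volumes in ml,
solute amounts in mmol, concentrations in mmol/L (mosmol/L for osmolality),
hormone levels in pg/ml, time in minutes.  Parameters printed per 100 g body
weight are scaled by ``weight / 100`` when absolute quantities are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PiecewiseTable",
    "CircadianAvpParams",
    "DrinkingParams",
    "GutParams",
    "FurosemideParams",
    "ModelParams",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a parameter set or lookup table is invalid."""


@dataclass(frozen=True)
class PiecewiseTable:
    """Piecewise-linear lookup table defined by ordered (x, y) knots.

    Evaluation clamps to the first/last y outside the knot range, matching how
    the dose-response curves it encodes saturate at their measured extremes.
    """

    knots: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.knots) < 2:
            raise ConfigError("lookup table needs at least two knots")
        xs = [k[0] for k in self.knots]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ConfigError(f"lookup table x-knots must be strictly increasing: {xs}")

    def __call__(self, x: float) -> float:
        xs = [k[0] for k in self.knots]
        ys = [k[1] for k in self.knots]
        return float(np.interp(x, xs, ys))

    @property
    def x_max(self) -> float:
        return self.knots[-1][0]

    @classmethod
    def from_pairs(cls, pairs: Sequence[Sequence[float]]) -> "PiecewiseTable":
        return cls(tuple((float(x), float(y)) for x, y in pairs))


@dataclass(frozen=True)
class CircadianAvpParams:
    """Pre-sleep reduction of circulating AVP (nocturia avoidance).

    The level is reduced linearly by 5 %/h from ``start_min`` to a ``depth``
    (30 %) nadir at ``nadir_min``, then restored linearly by ``end_min``.
    Times are minutes past midnight.
    """

    start_min: int = 120   # 02:00
    nadir_min: int = 480   # 08:00
    end_min: int = 660     # 11:00
    depth: float = 0.30

    def validate(self) -> None:
        if not (0 <= self.start_min < self.nadir_min < self.end_min < 1440):
            raise ConfigError("circadian anchors must satisfy 0 <= start < nadir < end < 1440")
        if not 0.0 <= self.depth < 1.0:
            raise ConfigError("circadian depth must lie in [0, 1)")


@dataclass(frozen=True)
class DrinkingParams:
    """Drinking-behaviour constants for the motivation module.

    ``unregulated_p_base`` and ``unregulated_amplitude`` define the sinusoidal
    per-minute probability of a need-free drinking bout (maximum at 02:00,
    minimum at 14:00); they are calibrated so the long-run daily water and
    sodium intake match a healthy 255 g rat.
    """

    bout_volume_ml: float = 0.5
    ingestion_rate_ml_per_min: float = 1.0
    unregulated_p_base: float = 0.052
    unregulated_amplitude: float = 0.7
    unregulated_peak_min: int = 120          # 02:00, minutes past midnight
    unregulated_na_conc: float = 50.0        # mmol/L, surrogate for dietary Na+
    rule1_setpoint: float = 140.0            # mmol/L, need-induced threshold base
    rule1_stop_conc: float = 143.0           # mmol/L, [Na+] at which need-drinking stops
    need_bout_p: float = 0.20                # per-minute bout probability while need latch is on
    need_bout_volume_ml: float = 2.0         # ml per need-induced draught (thirst draughts are larger)
    rule2_setpoint: float = 145.0            # mmol/L, upper bound for need-free bouts
    hypovolemia_frac: float = 0.08           # ECF deficit engaging hypovolemic thirst

    def validate(self) -> None:
        if self.bout_volume_ml <= 0 or self.ingestion_rate_ml_per_min <= 0:
            raise ConfigError("bout volume and ingestion rate must be positive")
        if not 0.0 <= self.unregulated_p_base <= 1.0:
            raise ConfigError("unregulated_p_base must be a probability")
        if not 0.0 <= self.unregulated_amplitude <= 1.0:
            raise ConfigError("unregulated_amplitude must lie in [0, 1]")
        if self.unregulated_na_conc < 0 or self.rule1_setpoint <= 0 or self.rule2_setpoint <= 0:
            raise ConfigError("drinking concentrations/set-points must be non-negative")
        if self.rule1_stop_conc < self.rule1_setpoint:
            raise ConfigError("rule1_stop_conc must not be below rule1_setpoint")
        if not 0.0 < self.need_bout_p <= 1.0:
            raise ConfigError("need_bout_p must lie in (0, 1]")
        if self.need_bout_volume_ml <= 0:
            raise ConfigError("need_bout_volume_ml must be positive")
        if not 0.0 < self.hypovolemia_frac < 1.0:
            raise ConfigError("hypovolemia_frac must lie in (0, 1)")


@dataclass(frozen=True)
class GutParams:
    """First-order rate constants (per minute) of the digestive module.

    Calibrated defaults standing in for the stomach/intestine transit constants
    of the classical two-compartment gut model: stomach empties into the
    intestine with ~10 min half-life, exchanges a little water with the ECF by
    passive diffusion, and the intestine absorbs water and (actively) sodium.
    """

    k_stomach_to_intestine: float = 0.18
    k_stomach_to_ecf: float = 0.01
    k_intestine_to_ecf: float = 0.40
    k_intestine_na_active: float = 0.40

    def validate(self) -> None:
        for name in ("k_stomach_to_intestine", "k_stomach_to_ecf",
                     "k_intestine_to_ecf", "k_intestine_na_active"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1] per minute, got {v}")


# Furosemide diuresis time-course after one subcutaneous 10 mg/kg injection.
# Calibrated piecewise-linear tables (the pharmacokinetic source figures are
# not reproduced here): urine flow in ml/min/100 g bw versus minutes since
# injection, and urine [Na+] in mmol/L over the same horizon.  Two overlapping
# injections combine by element-wise maximum flow.
_FURO_FLOW_KNOTS = (
    (0.0, 0.006),
    (15.0, 0.030),
    (45.0, 0.024),
    (90.0, 0.009),
    (120.0, 0.004),
    (180.0, 0.002),
    (240.0, 0.0015),
)
_FURO_NA_KNOTS = (
    (0.0, 24.0),
    (30.0, 36.0),
    (90.0, 31.5),
    (180.0, 27.0),
    (240.0, 24.0),
)


@dataclass(frozen=True)
class FurosemideParams:
    """Kidney-override time-course used by the extracellular-dehydration protocol."""

    flow_table: PiecewiseTable = field(
        default_factory=lambda: PiecewiseTable(_FURO_FLOW_KNOTS))
    urine_na_table: PiecewiseTable = field(
        default_factory=lambda: PiecewiseTable(_FURO_NA_KNOTS))
    horizon_min: float = 240.0
    isonatriuric: bool = False           # force urine [Na+] ~ plasma level
    isonatriuric_conc: float = 140.0

    def validate(self) -> None:
        if self.horizon_min <= 0:
            raise ConfigError("furosemide horizon must be positive")
        if any(y < 0 for _, y in self.flow_table.knots):
            raise ConfigError("furosemide flow table must be non-negative")
        if any(y < 0 for _, y in self.urine_na_table.knots):
            raise ConfigError("furosemide urine [Na+] table must be non-negative")


# Volume-feedback tables for active natriuresis / Na+ retention.  Both are
# two-stage: fractional ECF volume deviation -> hormone level -> multiplicative
# factor on Na+ excretion.  Hormone-to-factor anchors are printed physiology
# (ALD 0 ng/100 ml -> 1.0, 200 ng/100 ml -> 0.2; ANP capped at 2000 pg/ml);
# the volume-to-hormone stages are calibrated defaults.
_ALD_VOLUME_KNOTS = ((0.0, 0.0), (0.03, 40.0), (0.07, 120.0), (0.12, 200.0))
_ALD_FACTOR_KNOTS = ((0.0, 1.0), (200.0, 0.2))
_ANP_VOLUME_KNOTS = ((0.0, 0.0), (0.01, 0.0), (0.06, 1000.0), (0.11, 2000.0))
_ANP_FACTOR_KNOTS = ((0.0, 1.0), (1000.0, 1.5), (2000.0, 2.5))


@dataclass(frozen=True)
class ModelParams:
    """All fixed constants of the simulator (defaults reproduce the reference rat).

    Initial compartment volumes are expressed per 100 g body weight and scaled
    by ``weight`` when the absolute state is initialised.
    """

    weight: float = 255.0                    # g body weight (W)
    icf_k_conc: float = 112.0                # mmol/L, fixed ICF [K+]
    ecf_na_conc_init: float = 140.0          # mmol/L at t=0
    avp_init: float = 1.0                    # pg/ml at t=0
    ecf_v_init_per100g: float = 23.0         # ml/100 g bw
    icf_v_init_per100g: float = 46.0         # ml/100 g bw
    na_clearance: float = 0.0086             # ml/min, renal Na+ clearance C_Na+
    osmole_correction: float = 14.0          # mosmol/L from sugar/protein/urea
    drink_threshold_frac: float = 0.04       # need-induced drinking threshold
    stomach_full_ml: float = 5.0
    stomach_comfort_ml: float = 3.1
    unregulated_balance_flux: float = -0.0108   # ml/min, net insensible water loss
    urine_flow_basal_avp: float = 2.3        # pg/ml giving the basal flow
    urine_flow_basal: float = 6.0            # ul/min/100 g at basal AVP
    urine_flow_max: float = 138.0            # ul/min/100 g at zero AVP
    avp_clearance_frac_per_min: float = 0.15
    tap_water_na_conc: float = 0.4           # mmol/L (~0.001 % sodium)

    circadian_avp: CircadianAvpParams = field(default_factory=CircadianAvpParams)
    drinking: DrinkingParams = field(default_factory=DrinkingParams)
    gut: GutParams = field(default_factory=GutParams)
    furosemide: FurosemideParams = field(default_factory=FurosemideParams)

    ald_volume_table: PiecewiseTable = field(
        default_factory=lambda: PiecewiseTable(_ALD_VOLUME_KNOTS))
    ald_factor_table: PiecewiseTable = field(
        default_factory=lambda: PiecewiseTable(_ALD_FACTOR_KNOTS))
    anp_volume_table: PiecewiseTable = field(
        default_factory=lambda: PiecewiseTable(_ANP_VOLUME_KNOTS))
    anp_factor_table: PiecewiseTable = field(
        default_factory=lambda: PiecewiseTable(_ANP_FACTOR_KNOTS))
    anp_cap: float = 2000.0                  # pg/ml

    def __post_init__(self) -> None:
        positive = (
            "weight", "icf_k_conc", "ecf_na_conc_init", "ecf_v_init_per100g",
            "icf_v_init_per100g", "na_clearance", "stomach_full_ml",
            "stomach_comfort_ml", "urine_flow_basal_avp", "urine_flow_basal",
            "urine_flow_max",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if self.avp_init < 0 or self.osmole_correction < 0 or self.tap_water_na_conc < 0:
            raise ConfigError("avp_init, osmole_correction and tap_water_na_conc must be >= 0")
        if not 0.0 < self.avp_clearance_frac_per_min < 1.0:
            raise ConfigError("avp_clearance_frac_per_min must lie in (0, 1)")
        if not 0.0 < self.drink_threshold_frac < 1.0:
            raise ConfigError("drink_threshold_frac must lie in (0, 1)")
        if self.urine_flow_max <= self.urine_flow_basal:
            raise ConfigError("urine_flow_max must exceed urine_flow_basal")
        if self.stomach_comfort_ml >= self.stomach_full_ml:
            raise ConfigError("stomach comfort level must be below the full level")
        self.circadian_avp.validate()
        self.drinking.validate()
        self.gut.validate()
        self.furosemide.validate()
        for tbl, mono in (("ald_factor_table", -1), ("anp_factor_table", +1)):
            ys = [y for _, y in getattr(self, tbl).knots]
            if any(mono * (b - a) < 0 for a, b in zip(ys, ys[1:])):
                raise ConfigError(f"{tbl} must be monotone")

    # -- convenience -------------------------------------------------------

    @property
    def scale(self) -> float:
        """Body-weight scale factor (weight / 100 g)."""
        return self.weight / 100.0

    @property
    def ecf_v_init(self) -> float:
        """Absolute initial ECF volume, ml."""
        return self.ecf_v_init_per100g * self.scale

    @property
    def icf_v_init(self) -> float:
        """Absolute initial ICF volume, ml."""
        return self.icf_v_init_per100g * self.scale

    @property
    def rule1_threshold(self) -> float:
        """ECF [Na+] (mmol/L) above which need-induced drinking engages."""
        return self.drinking.rule1_setpoint * (1.0 + self.drink_threshold_frac)

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given top-level fields replaced."""
        return replace(self, **changes)
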