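# Model and methods

## Scope and state

`hydrorat` simulates the hydromineral balance of a single laboratory rat
(default 255 g) as a discrete-time system with a fixed one-minute step.  The
state is: the extracellular fluid volume (ECF, vascular + interstitial
merged, since solute exchange between them is faster than one step), the ECF
sodium content, the intracellular fluid volume (ICF), the plasma AVP level,
and the water/sodium contents of the stomach and intestine.  The ICF
potassium concentration (112 mmol/L) is a constant parameter, not a state:
cell-volume changes are driven entirely by ECF tonicity.  Internal units are
ml, mmol, pg/ml and minutes; initial compartment volumes are specified per
100 g of body weight and scaled by `weight/100`.

The clock starts at 08:00, the onset of the rat's sleeping period
(08:00–20:00, lights on); the waking period runs 20:00–08:00.

## Osmotic coupling between ICF and ECF

The effective ECF osmolality is taken as `2·[Na⁺] + c`, where the factor 2
counts the accompanying anion and `c = 14 mosmol/L` is a fixed correction for
sugars, proteins and urea.  The ICF is represented by a fixed effective
osmole content `O`, calibrated at t = 0 so the gradient is exactly zero
(`O = (2·140 + 14)·V_ICF(0)/1000`).  Each minute, after all fluxes, water
redistributes instantaneously: the ICF volume solves

```
2000·Na/(T − V_I) + c = 1000·O/V_I,      T = V_ECF + V_ICF conserved,
```

a quadratic whose physical root is polished by Newton iteration to a residual
gradient below 1e−9 mosmol/L.  Solutes never cross the cell membrane.  This
scheme is a modelling choice: the true ICF osmole bookkeeping is unknown at
this level of description, and an absolute `2·[K⁺]` (224 mosmol/L) would not
match the ECF side, so only the calibrated-offset form keeps the initial
state at equilibrium.  Under this scheme a 1 mmol sodium load shrinks the
cells by ~3.8 %; the commonly quoted "~3 %" response should be read as the
magnitude the shrinkage *reaches*, which the tests assert as a bound.

Mass balance is exact by construction: per minute,
`Δ(total water) = intake − urine + insensible` to 1e−9 ml and
`Δ(total sodium) = ingested − excreted (+ infused)` to 1e−12 mmol; the test
suite checks both ledgers at every step.

## The AVP controller

The equilibrium ("target") plasma AVP is

```
AVP* = (0.91 − 11·v) · 200·(n − 0.1375) + 1.3·e^(−17·v)     [pg/ml]
```

with `n` the ECF [Na⁺] in mol/L and `v = min(ΔV_ECF/V_ECF(0), 0)` the
fractional ECF volume deviation, clamped so expansion does not suppress the
osmotic drive; negative targets clamp to zero.  Secretion upward is
instantaneous; downward the level decays at most 15 %/min (hepatic/renal
clearance), flooring at the target.  Note that at small deviations the
exponential volume term is slightly *stronger* than an equal-percentage
osmotic excursion; what distinguishes the osmotic drive is that it acts in
both directions while the volume drive is one-sided.

A circadian modulation multiplies the post-clearance level: from 02:00 the
circulating AVP is reduced linearly by 5 %/h to a −30 % nadir at 08:00, then
restored linearly by 11:00 (the restoration slope is not separately
constrained; linearity is chosen for continuity at both anchors).  The
kidney and all observables see the modulated (circulating) level; the
controller state stores the unmodulated level so the modulation does not
compound through the clearance dynamics.

## Kidney

Urine flow falls hyperbolically with circulating AVP:
`F = F_max/(1 + k·a)` per 100 g bw, with `F_max = 138 µl/min/100 g` and `k`
fixed by the second anchor (6 µl/min/100 g at 2.3 pg/ml), scaled by body
weight.  The hyperbola is the simplest monotone two-parameter form through
both anchors; the functional form is configurable.

Sodium leaves at `[Na⁺]·C_Na·ALD·ANP` with a constant clearance
`C_Na = 0.0086 ml/min` (AVP dependence of sodium clearance is negligible at
this scale).  The two feedback factors are two-stage piecewise-linear
lookups on the fractional ECF volume deviation from its set-point (the
initial volume):

* **ALD (retention, deficit side):** deficit → plasma aldosterone
  (ng/100 ml) → factor, linear between 1.0 at 0 ng/100 ml and 0.2 at
  200 ng/100 ml, clamped to [0.2, 1].
* **ANP (natriuresis, expansion side):** expansion → plasma ANP (pg/ml,
  capped at 2000 to avoid extrapolation error) → factor ≥ 1.

The hormone-to-factor anchors are printed physiology; the volume-to-hormone
stages are **calibrated defaults** (the source dose-response figures are not
reproduced here).  They were chosen so that the 20-day control run holds the
long-run daily means of all six regulated quantities inside their reference
bands, which demands ALD engaging gently below ~3 % deficit and ANP staying
quiet inside ±1 % of the set-point: a tighter ANP dead zone lets the body
hold its sodium content near the set-point overnight, which is what pins the
mean ECF volume.

## Digestive tract

A two-compartment gut with first-order kinetics per minute: stomach →
intestine emptying (`k = 0.18`), a small passive stomach → ECF water leak
(`0.01`), intestinal water absorption (`0.40`) and an additional active
intestinal sodium uptake (`0.40`); water fluxes carry sodium at the local
concentration, so gut mass balance is exact.  These rate constants are
calibrated defaults: fast enough that a drinking bout is mostly absorbed
within ~15 min (so need-induced drinking does not grossly overshoot its
stop level through gut residue), slow enough that less than half of a bolus
reaches the ECF in the first minute, preserving the obligatory oral-systemic
delay.  The stomach locks further intake at 5 ml and unlocks below the
3.1 ml comfort level.

## Drinking behaviour

Two rules, both delivering discrete bouts at a 1 ml/min ingestion rate —
"allowing" intake rather than forcing it, so responses spread over time:

* **Need-induced (osmotic thirst).**  A latch engages when ECF [Na⁺]
  exceeds the 140 mmol/L set-point by 4 % (145.6 mmol/L) and releases when
  the concentration is restored to 143 mmol/L, just above the normal level;
  the remaining distance to the set-point is covered by the water still in
  transit through the gut and by need-free drinking, so the concentration
  lands near 140 without overshooting.  While latched, 2-ml draughts of
  plain (or tap) water start with probability 0.2/min.  Under strong
  hypovolemia (ECF deficit ≥ 8 %) the latch instead releases only at the
  set-point itself — a minimal stand-in for the hypovolemic component of
  thirst that matters only for severe extracellular dehydration.
* **Need-free ("unregulated").**  When ECF [Na⁺] is at or below the normal
  band (≤ 145 mmol/L), 0.5-ml bouts of 50 mmol/L sodium water start with
  probability `p(t) = 0.052·(1 + 0.7·cos(2π(t − t_peak)/1440))` per minute,
  peaking at 02:00 and bottoming at 14:00.  The sodium content stands in for
  food sodium (feeding and drinking co-occur in the rat; the model has no
  food).  The band bound matters: a gate much below the thirst threshold
  leaves a dead interval in which neither rule may drink, and the model then
  ratchets into severe hypernatremia every afternoon.

`p_base`, the amplitude, the bout volumes and the Rule-1 stop level are
calibrated jointly so the 20-day control run reproduces the reference daily
water (≈15–18 ml/100 g) and sodium (≈0.7 mmol/100 g) intakes together with a
142 mmol/L mean ECF [Na⁺]; these three observables are tightly coupled
through the kidney, so they cannot be tuned independently.

A constant −0.0108 ml/min (−15.5 ml/day) insensible water balance (sweat and
feces minus food and metabolic water) drains the ECF every minute.

## Per-minute update order

(1) protocol events (infusions, access gating, forced bouts); (2) drinking
decision and ingestion; (3) gut transit; (4) insensible balance; (5) renal
output — reading the previous minute's hormone level and sodium
concentration, a one-minute renal delay — or the furosemide override;
(6) osmotic re-equilibration (skipped when ICF exchange is ablated);
(7) AVP target → clearance-limited update → circadian factor, reading the
post-flux state; (8) recording.  All randomness flows through one
`numpy.random.Generator` seeded per run, so runs are bit-reproducible.

## Analysis operations

* **Circadian profile:** mean ± SD of each observable at each minute-of-day
  across the days of a run (1440 points per parameter), the high-resolution
  analogue of sparse experimental sampling.
* **Phase detection:** the *restoration* phase begins at the peak of the
  mean AVP profile (late sleeping period).  The *maintenance* threshold is
  the upper bound of the 95 % band of the steady 02:00–08:00 window —
  mean + 1.96 SD over the window's minute means, the band containing ~95 %
  of the steady-period values (with the circadian reduction inside the
  window this spans roughly 1.2–2 pg/ml, so the threshold lands near
  2 pg/ml).  The maintenance phase starts at the first minute after the
  peak where the mean profile falls to the threshold, and runs to the end
  of the waking period; the reported maintenance AVP is the mean over that
  span.  A SEM-based bound was rejected: it falls below the pre-02:00
  plateau and then detects no crossing at all.
* **Summary:** daily means/SDs of the six regulated quantities (volumes,
  urine and intake per 100 g bw; ECF [Na⁺] as the time-mean over the run),
  plus sleeping/waking sub-statistics.

## Challenge protocols

* **Hypertonic saline (intracellular dehydration):** 1 mmol Na⁺, no water,
  infused into the ECF over 10 min, by default at 12:00 — mid-sleeping
  period and outside the morning circadian AVP ramp, which would otherwise
  scale down the evoked peak.  The challenge-evoked AVP peak is read within
  4 h of infusion onset (later maxima belong to the normal end-of-sleep
  wave, not the challenge).
* **Furosemide + sodium-deficient diet (extracellular dehydration):** one
  control day, then injections at 08:00 and 10:00 of day 1.  Each injection
  replaces the kidney output with a piecewise-linear diuresis time-course
  (4 h horizon; overlapping injections take the element-wise maximum flow);
  the two-injection course integrates to ≈4 ml/100 g over the 4-h depletion.
  The urine sodium time-course is calibrated to ~24–36 mmol/L: the reported
  end-of-depletion state (≈150 mmol/L ECF [Na⁺] at a ~10 % ECF deficit)
  closes its sodium mass balance only with urine this dilute, although
  higher furosemide natriuresis values appear in the literature — an
  `isonatriuric` toggle (~140 mmol/L urine) is provided for that variant.
  Water and food are withheld for the first 4 h; from 12:00 need-induced
  bouts take tap water (0.4 mmol/L) and need-free bouts carry 10 mmol/L
  sodium, delivering ≈0.1 mmol/100 g over the 20-h rehydration — the scale
  of the ~2 mg/100 g bw a sodium-deficient diet provides.  Rehydration
  without sodium ends the day hyponatremic (~134 mmol/L) with over-filled
  cells.
* **Ablations:** one forced 2-ml bout at sleep onset (lowers the
  end-of-sleep AVP peak); blocked ICF-ECF exchange for 24 h (the thirst
  threshold is then crossed repeatedly and total intake rises) — both run
  against a same-seed control so differences are attributable.

## What the defaults do and do not emulate

The stochastic drinking schedule is the only random element; it emulates the
circadian clustering and day-to-day variability of intake, not individual
licking microstructure (bout sizes are fixed).  Passing the long-run checks
shows the closed feedback loop holds realistic set-points and circadian
excursions under the stated conditions; it does not validate the model for
pathophysiology outside its envelope (hemorrhage, severe dehydration,
potassium disturbances, pregnancy), for blood-pressure mechanics, or for
solid-food digestion, none of which are represented.

## Numerical choices and edge cases

Osmotic equilibration: closed-form quadratic root + ≤8 Newton polish steps,
residual < 1e−9 mosmol/L (an independent bracketing root-finder is used as
the test oracle).  Renal outflow is clamped to at most half the ECF volume
and the available sodium per minute (unreachable in physiological runs).
Gut compartments clamp float round-off below 1e−12 to zero.  Degenerate
inputs (non-positive volumes, out-of-range times, malformed tables,
non-positive parameters) raise typed errors naming the offending quantity.
Ties in phase detection resolve to the earliest minute.

## Problem sizes

The test suite runs one shared 20-day control simulation plus one- and
two-day challenge runs (a 20-day run is 28,800 steps, ~1 s).  The acceptance
script averages three 20-day control replicates, 160 two-day furosemide runs
and 64 one-day saline runs — ensemble sizes chosen to make the reported
means stable to well under their day-to-day SDs — and completes in well
under a minute on one CPU.

## Known limitations

* Under combined hypernatremia and a ≥10 % volume deficit (the furosemide
  depletion) the exponential volume term drives the modelled AVP peak near
  10 pg/ml, above the commonly reported ~8 pg/ml; the equation was fitted to
  moderate deviations and saturates nowhere.
* Daily water turnover sits in the lower half of the reference band: the
  hyperbolic flow curve at maintenance AVP levels bounds the urine side, and
  intake must match it.
* The Rule-2 sodium-water surrogate ties sodium intake rigidly to need-free
  water volume; real rats decouple the two (food, graded sodium appetite).
* No renin-angiotensin axis, no blood-pressure regulation, no potassium
  handling: volume sensing acts only through the ALD/ANP lookups and the
  one-sided AVP volume term.
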