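"""Twenty days of balanced hydromineral conditions.

Runs the control protocol for 20 simulated days at 1-minute resolution and
prints the long-run daily means of the six regulated quantities.  Under the
default 255 g reference rat these should hover near the physiological
set-points: ECF [Na+] ~142 mmol/L, ECF ~23 and ICF ~45 ml/100 g, maintenance
AVP ~1.5-2 pg/ml, with ~15 ml/100 g of water drunk and ~9-12 ml/100 g of
urine voided per day.
"""

import hydrorat as hr

series = hr.simulate(days=20, seed=1)
summary = hr.summarize(series)

print(f"{'parameter':28s} {'mean':>8s} {'sd':>6s}")
for key, value in summary.means.items():
    print(f"{key:28s} {value:8.2f} {summary.sds[key]:6.2f}")

print("\nsleeping vs waking:")
print(f"  AVP mean          {summary.sleeping['avp_mean']:5.2f} vs "
      f"{summary.waking['avp_mean']:5.2f} pg/ml")
print(f"  urine flow        {summary.sleeping['urine_flow_mean'] * 1000:5.1f} vs "
      f"{summary.waking['urine_flow_mean'] * 1000:5.1f} ul/min")
print(f"  ECF [Na+]         {summary.sleeping['na_conc_mean']:6.1f} vs "
      f"{summary.waking['na_conc_mean']:6.1f} mmol/L")
print("\nThe sleeping period (08:00-20:00) concentrates the body fluids and"
      "\nraises AVP; drinking during the waking period restores the balance.")
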