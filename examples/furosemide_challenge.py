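"""Extracellular (hypovolemic) dehydration: furosemide + sodium-deficient diet.

Day 0 is a control day.  On day 1 the loop diuretic is injected at 08:00 and
10:00, replacing the kidney output with its measured diuresis time-course;
water is withheld for 4 h (about 4 ml/100 g of urine is lost), then the rat
rehydrates on low-sodium water for 20 h.  Rehydration without sodium drives
the ECF [Na+] down to ~134 mmol/L (hyponatremia) and over-fills the cells.
"""

import hydrorat as hr

params = hr.ModelParams()
series = hr.simulate(params, hr.furosemide_challenge(params), days=2, seed=1)
f = series.frame
scale = params.scale

for day in (0, 1):
    d = series.day_slice(day)
    four_h = d[d.minute_of_day < 240]
    tag = "control " if day == 0 else "furosemide"
    print(f"day {day} ({tag}):")
    print(f"  4 h urine        {four_h.urine_flow.sum() / scale:5.2f} ml/100 g")
    print(f"  24 h urine       {d.urine_flow.sum() / scale:5.2f} ml/100 g")
    print(f"  24 h water drunk {d.intake_ml.sum() / scale:5.2f} ml/100 g")
    print(f"  AVP peak         {d.avp.max():5.1f} pg/ml")
    print(f"  end-of-day [Na+] {d.na_conc.iloc[-1]:6.1f} mmol/L")

d1 = series.day_slice(1)
print(f"\nday-1 extremes: ECF {min(d1.ecf_v) / params.ecf_v_init * 100 - 100:+.1f} %, "
      f"ICF {min(d1.icf_v) / params.icf_v_init * 100 - 100:+.1f} % (depletion), "
      f"ICF {max(d1.icf_v) / params.icf_v_init * 100 - 100:+.1f} % (overload at day end)")
print("Diuresis + sodium-free rehydration ends in hyponatremia with swollen cells.")
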