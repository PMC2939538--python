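"""Circadian averaging and the restoration/maintenance phases.

Averaging every minute-of-day over 20 days removes the randomness of the
drinking schedule and exposes the circadian AVP wave.  The restoration phase
starts at the wave's peak (near the sleep/wake transition at 20:00); the
maintenance phase starts where the profile first returns to the steady
02:00-08:00 band, whose upper 95 % bound is the detection threshold
(~2 pg/ml).
"""

import hydrorat as hr

series = hr.simulate(days=20, seed=1)
profile = hr.circadian_profile(series)
phases = hr.detect_phases(profile)


def clock(minute_of_run_day: int) -> str:
    tod = (minute_of_run_day + 480) % 1440
    return f"{tod // 60:02d}:{tod % 60:02d}"


peak = profile.frame["avp_mean"].max()
print(f"AVP profile peak:        {peak:.2f} pg/ml at {clock(phases.restoration_onset)}")
print(f"maintenance threshold:   {phases.maintenance_threshold:.2f} pg/ml")
print(f"restoration onset:       {clock(phases.restoration_onset)}")
if phases.maintenance_onset is not None:
    print(f"maintenance onset:       {clock(phases.maintenance_onset)}")

print("\nmean profile every 2 h (AVP pg/ml, ECF [Na+] mmol/L):")
for m in range(0, 1440, 120):
    row = profile.frame.loc[m]
    print(f"  {clock(m)}  AVP {row['avp_mean']:5.2f} +/- {row['avp_sd']:4.2f}   "
          f"[Na+] {row['na_conc_mean']:6.1f}")
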