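"""Photoperiod at a UK residence across the year.

Computes day length (sunrise-to-sunset, hours) from latitude and date via
the standard sunrise equation, as used to assign each participant a
photoperiod on their scan date.
"""

from seasonmed import day_length

LAT, LON = 53.4, -2.2   # near the scanning centre

for date in ("2015-03-21", "2015-06-21", "2015-09-21", "2015-12-21"):
    hours = day_length(LAT, LON, date)
    print(f"{date}: {hours:5.2f} h of daylight")

print("\nThe June/December values bracket the ~7.3-17.2 h seasonal range a")
print("UK cohort experiences; longitude shifts clock times but not duration.")
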