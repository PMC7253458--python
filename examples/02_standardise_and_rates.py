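"""Standardising a mixed-year census to a national reference total.

Two units report 200 t and 800 t from an old census, but the national
estimate for the reference year is 1,500 t.  Each unit is rescaled
proportionally, then divided by its rural population to give the
per-capita rate that drives pixel allocation.
"""

from dasycrop import CensusRecord, NationalTotal, per_capita_rates, standardize_to_national

census = [
    CensusRecord("north", "CA", "production", 200.0, census_year=2002),
    CensusRecord("south", "CA", "production", 800.0, census_year=2002),
]
totals = [NationalTotal("CA", "production", 1500.0)]

adjusted = standardize_to_national(census, totals)
rural_pop = {"north": 1500.0, "south": 10000.0}
rates = per_capita_rates(adjusted, rural_pop)

for a, r in zip(adjusted, rates):
    print(f"{a.unit_id}: raw {a.raw_value:6.0f} t -> adjusted {a.adjusted_value:6.0f} t"
          f"  -> rate {r.rate:.3f} t/person")
print(f"country sum after adjustment: {sum(a.adjusted_value for a in adjusted):.0f} t"
      f" (equals the national total)")
# Adjusted values keep the units' relative proportions (1:4) while the
# country now sums exactly to the 2014-style reference estimate.
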