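"""Capped water-filling on a single saturated unit.

One admin unit with 10 pixels: a town of 1,000 people and nine villages
of 100.  Allocating 8,000 t of production linearly by population gives
the town pixel 4,210 t — far above the 1,000 t/pixel capacity — so the
excess is deducted and re-spread over the village pixels in proportion
to their population until every pixel is within the cap.
"""

import numpy as np

from dasycrop import allocate_linear, redistribute_capped

pops = np.array([1000.0] + [100.0] * 9)
total = 8000.0
rate = total / pops.sum()

linear = allocate_linear(rate, pops)
capped, iterations, residual = redistribute_capped(linear, pops, cap=1000.0)

print(f"per-capita rate:    {rate:.4f} t/person")
print(f"linear allocation:  {np.round(linear, 1)}")
print(f"after water-fill:   {np.round(capped, 1)}")
print(f"iterations={iterations}  residual={residual:.2e}  "
      f"total={capped.sum():.1f} (conserved)")
# The town pixel is clipped to the 1,000 t cap; the deducted 3,210 t
# moves to the villages, which rise from 421 t to 778 t each.
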