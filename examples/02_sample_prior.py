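"""Draw channel parameters from the constrained uniform prior.

Every accepted draw satisfies the four physiological rate bounds: at the
extreme command voltages (-120 / +60 mV) each transition rate must lie
between one event per minute (0.0167 1/s) and 1e6 1/s.  The printout shows
how the constraint concentrates the voltage sensitivities at small values
while the prefactors span ten decades.
"""

import numpy as np

import hergfit as hf
from hergfit.priors import constraint_rates

arr = hf.sample_params_array(n=2000, seed=0)
spec = hf.PriorSpec()

rates = np.stack([constraint_rates(row, spec) for row in arr])
print(f"{len(arr)} accepted draws; extreme-voltage rates within "
      f"({spec.rate_bounds[0]}, {spec.rate_bounds[1]:.0e}) 1/s: "
      f"{np.all((rates > spec.rate_bounds[0]) & (rates < spec.rate_bounds[1]))}")

print(f"g_Kr:  {arr[:, 0].min():9.3g} .. {arr[:, 0].max():9.3g} pA/V")
print(f"p1:    {arr[:, 1].min():9.3g} .. {arr[:, 1].max():9.3g} 1/s "
      f"({np.log10(arr[:, 1].max() / arr[:, 1].min()):.1f} decades)")
print(f"p2 mean: {arr[:, 2].mean():6.1f} 1/V (box midpoint 200 — the rate "
      "bounds pull sensitivities toward zero)")

norm = hf.NormalizationSpec.from_prior(spec)
v = hf.to_normalized(arr[0], norm)
back = hf.from_normalized(v, norm).as_array()
print(f"normalization round-trip max rel error: {np.abs(back / arr[0] - 1).max():.2e}")
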