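"""Explore the parameter posterior with adaptive Metropolis.

Gaussian likelihood with the known noise SD (10.84 pA) times the
constrained uniform prior, sampled in the normalized space.  The proposal
covariance adapts to the chain history; a healthy random-walk run accepts
roughly 10-50% of proposals.  Credible intervals are tightest for the
parameters the staircase protocol pins down best.
"""

import numpy as np

import hergfit as hf

protocol = hf.build_default_staircase()
(trace, truth), = hf.generate_cells(1, seed=8)

chain = hf.adaptive_metropolis(trace, protocol, truth, n_samples=8000, seed=1)
post = chain.samples[2000:]          # drop burn-in
true_n = hf.to_normalized(truth)

print(f"acceptance rate: {chain.acceptance_rate:.2f}")
print("normalized posterior (mean +/- sd) vs truth:")
names = ("g_kr", "p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8")
for j, name in enumerate(names):
    m, s = post[:, j].mean(), post[:, j].std()
    print(f"  {name:5s} {m:.4f} +/- {s:.4f}   true {true_n[j]:.4f}   "
          f"z = {(m - true_n[j]) / s:+.2f}")
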