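"""Generate a labelled synthetic dataset and featurize one trace.

Each example is simulate -> add N(0, 10.84^2 pA) noise -> decimate by 50
(77,000 -> 1,540 samples), paired with the normalized parameter vector.
The STFT front-end (n_fft=256, hop=12, win=48, centered) maps the 1,540
samples to a 129x129 log-magnitude spectrogram — the regressor's input.
"""

import numpy as np

import hergfit as hf

ds = hf.generate_dataset(25, seed=1)
print(f"dataset: {len(ds)} examples, traces {ds.traces.shape}, "
      f"targets {ds.targets.shape} (all in [0,1]: "
      f"{ds.targets.min() >= 0 and ds.targets.max() <= 1})")
print(f"manifest: sigma={ds.manifest['sigma']} pA, "
      f"factor={ds.manifest['downsample_factor']}, seed={ds.manifest['seed']}")

ex = ds.example(0)
spec = hf.stft_spectrogram(ex.trace)
print(f"trace 0: {len(ex.trace)} samples at {ex.trace.sample_rate:.0f} Hz")
print(f"spectrogram: {spec.resolution[0]} freq bins x {spec.resolution[1]} frames, "
      f"entries in [{spec.grid.min():.3f}, {spec.grid.max():.3f}]")

small = hf.resize_spectrogram(spec, 97, 97)
print(f"resized for stage-1 training: {small.resolution}")
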