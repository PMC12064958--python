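"""Synthesize degraded network inputs from an angiogram and noise slice.

Shows the superposition rule S = norm(alpha*E + beta*C) on a tiny
hand-checkable example, then assembles a full training set with the
noise-only and black pairs included.
"""

import numpy as np

from octa3d import PhantomConfig, SynthesisWeights, avascular_cscan, \
    build_training_set, generate_clean_volume, synthesize_input
from octa3d.phantom import add_speckle
from octa3d.projection import mip

E = np.array([[0.0, 0.5], [1.0, 0.0]])
C = np.array([[1.0, 0.0], [0.0, 0.0]])
S = synthesize_input(E, C, SynthesisWeights(alpha=0.25, beta=0.75))
print("tiny worked example, alpha=0.25, beta=0.75:")
print(S)  # [[1, 1/6], [1/3, 0]] — the weighted sum, min-max normalized

cfg = PhantomConfig(shape=(16, 64, 64), seed=7)
pairs = []
for v in range(5):
    clean, _ = generate_clean_volume(PhantomConfig(shape=(16, 64, 64), seed=v))
    noisy = add_speckle(clean, cfg, seed=100 + v)
    pairs.append((mip(noisy), mip(clean)))
noise_pool = [avascular_cscan(cfg, seed=s) for s in range(4)]

dataset = build_training_set(pairs, noise_pool, SynthesisWeights(),
                             n_noise_only=2, n_black=2, seed=0)
tags = [p.tag for p in dataset]
print(f"\ndataset: {len(dataset)} pairs "
      f"({tags.count('vascular')} vascular, {tags.count('noise_only')} noise-only, "
      f"{tags.count('black')} black)")
# the noise-only and black pairs teach the network to map structureless
# input to darkness instead of hallucinating vessels
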