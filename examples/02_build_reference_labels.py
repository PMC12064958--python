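"""Build a high-quality reference label from repeated acquisitions.

Simulates 10 acquisitions of the same tissue with rigid motion drift,
registers their en face projections with SIFT + RANSAC, crops the common
valid region and averages. Prints the recovered drift accuracy and the
CNR/VC gain of the average over the best single shot.
"""

import numpy as np

from octa3d import DriftParams, PhantomConfig, generate_clean_volume, \
    simulate_repeat_acquisitions
from octa3d.metrics import evaluate_image
from octa3d.projection import average_registered, mip, register_enface

cfg = PhantomConfig(shape=(32, 128, 128), seed=4)
clean, _ = generate_clean_volume(cfg)
repeats = simulate_repeat_acquisitions(
    clean, 10, DriftParams(max_shift=3.0, max_rotation=1.5, seed=5), cfg)

result = register_enface([mip(r.volume) for r in repeats], reference_index=0)
label = average_registered(result)

centre = np.array([63.5, 63.5, 1.0])
errs = []
for k in range(1, 10):
    true = repeats[k].matrix @ np.linalg.inv(repeats[0].matrix)
    errs.append(np.linalg.norm((result.transforms[k] @ centre)[:2]
                               - (true @ centre)[:2]))
print(f"median drift-recovery error: {np.median(errs):.2f} px")
print(f"common crop box (top, left, h, w): {result.crop_box}")

avg_report = evaluate_image(label)
best_single = max(evaluate_image(im).cnr for im in result.registered_images)
best_vc = max(evaluate_image(im).vc for im in result.registered_images)
print(f"CNR: averaged {avg_report.cnr:.2f} vs best single {best_single:.2f}")
print(f"VC:  averaged {avg_report.vc:.3f} vs best single {best_vc:.3f}")
# averaging suppresses the independent noise of each repeat (~1/10 of the
# background variance) while registration keeps the vessels aligned, so
# contrast and skeleton continuity both rise — that is what makes the
# average usable as a training label
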