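"""Visualise what the patch classifier attends to.

Trains a small stage-1 classifier, renders a noise-free three-lobed
non-NETotic nucleus, and prints where the guided-backprop and guided
Grad-CAM maps concentrate relative to the nuclear lobes.
"""

import numpy as np

import netquant as nq
from netquant.nn import TrainConfig, build_pl_stage1, train
from netquant.patches import PatchSet, split_patches, training_arrays
from netquant.saliency import guided_backprop, guided_grad_cam

patches, labels = nq.make_patch_arrays(
    ["background", "non_netotic", "netotic"], 150, 32, 0.0, seed=11)
ps = split_patches(PatchSet(patches, labels, 32), (0.7, 0.1, 0.2), seed=0)
x, y = training_arrays(ps, "train")
model = build_pl_stage1(width=8, seed=0)
train(model, x, y, TrainConfig(epochs=12, seed=0))

nucleus = nq.NucleusSpec(phenotype="non_netotic", lobe_count=3, radius=6.5,
                         peak_intensity=30000, blur_sigma=0.8, rng_key=4)
raw = nq.render_patch(nucleus, 32, noise=False)
patch = raw.astype(np.float32) / 65535.0
lobes = raw.astype(float) > 0.3 * raw.max()

for fn in (guided_backprop, guided_grad_cam):
    m = fn(model, patch, target_class=1)
    k = m.values.size // 10
    top = np.zeros_like(lobes)
    idx = np.unravel_index(np.argsort(m.values, axis=None)[-k:],
                           m.values.shape)
    top[idx] = True
    jacc = (top & lobes).sum() / (top | lobes).sum()
    print(f"{m.method}: top-decile pixels overlap the lobe mask with "
          f"Jaccard {jacc:.2f} (lobes cover {lobes.mean():.0%} of the "
          f"patch)")
# Jaccard well above the ~10% chance level means the classifier bases its
# non-NETotic call on the lobulated chromatin, not on the background.
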