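"""Segment one biased, noisy phantom with K-means, FCM, and the level set.

Intensity-only clustering mixes tissue classes once a strong bias field
spreads the histogram; the level-set method estimates the bias jointly with
the partition and recovers the dark SC lumen.  Dice is computed against the
phantom's ground-truth SC mask.
"""

import numpy as np

from ubmseg import (
    ClusteringConfig,
    PhantomSpec,
    dice,
    fcm_segment,
    generate_phantom,
    harden_memberships,
    kmeans_segment,
    segment_levelset,
    select_regions,
)

truth = generate_phantom(PhantomSpec(seed=3))
img = truth.observed_image

results = {}
for name, mask in [
    ("kmeans", kmeans_segment(img, ClusteringConfig())),
    ("fcm", harden_memberships(fcm_segment(img, ClusteringConfig()))),
]:
    try:
        sel = select_regions(mask)
        results[name] = dice(sel.sc_mask, truth.sc_mask)
    except ValueError:
        results[name] = 0.0

out = segment_levelset(img)
sel = select_regions(out.label_mask)
results["levelset"] = dice(sel.sc_mask, truth.sc_mask)

bt = truth.true_bias / truth.true_bias.mean()
be = out.state.bias / out.state.bias.mean()
bias_corr = np.corrcoef(bt.ravel(), be.ravel())[0, 1]

for name, d in results.items():
    print(f"SC Dice vs truth, {name:8s}: {d:.3f}")
print(f"bias-field correlation with truth: {bias_corr:.3f}")
print(f"level-set outer iterations: {out.state.iterations_run}")
# Dice near 1 for the level set and near 0 for the clustering baselines is
# the expected picture at bias amplitude 0.3: only the bias-aware model
# keeps the lumen separable from the locally darkened background.
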