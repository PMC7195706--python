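"""Derive detector anchor boxes from annotated box shapes by K-means.

Anchors are prior (width, height) shapes a grid detector parameterizes its
output boxes against; clustering the training annotations (K = 9, distance
1 - IoU of center-aligned boxes) yields anchors matched to the assay's
object sizes — small compact seed boxes and smaller radicle-onset squares.
"""

from strigacount import SimConfig, kmeans_anchors, simulate_dataset
from strigacount.anchors import anchor_objective

config = SimConfig(
    image_size=900, filter_diameter=860, n_seeds=20,
    germination_fraction=0.4, radicle_length_px=(20, 70), debris_density=0,
)
scenes, _ = simulate_dataset(config, 10, rng_seed=2)
boxes = [b for s in scenes for b in s.annotation.boxes]
print(f"clustering {len(boxes)} annotated boxes")

anchors = kmeans_anchors(boxes, K=9, rng_seed=0)
print("anchor (width, height) pairs, area-ascending:")
for w, h in anchors:
    print(f"  {w:6.1f} x {h:6.1f}")
print(f"mean 1-IoU to nearest anchor: "
      f"{anchor_objective(boxes, anchors):.3f}")
# lower is better: 0 would mean every annotated box matches an anchor shape
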