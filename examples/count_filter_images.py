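"""Count seeds and germination on a small batch of assay images.

Runs the full counting chain — classical detection, objectness filter at
the P = 0.06 operating point, class-wise NMS, per-image counting — and
prints the four-column results record next to the known ground truth.
"""

from strigacount import (
    SimConfig,
    count_image,
    detect_classical,
    nms,
    objectness_filter,
    simulate_dataset,
)

config = SimConfig(
    image_size=900, filter_diameter=860, n_seeds=20,
    germination_fraction=0.4, radicle_length_px=(20, 70), debris_density=0,
)
scenes, manifest = simulate_dataset(config, 3, rng_seed=5)

print(f"{'sample':10} {'seeds':>6} {'radicles':>9} {'germ %':>8}   truth")
for scene in scenes:
    dets = detect_classical(scene.image)
    kept = nms(objectness_filter(dets, 0.06), 0.45)
    r = count_image(scene.annotation.image_id, kept)
    gt = scene.ground_truth
    print(f"{r.sample:10} {r.total_seeds:>6} {r.n_radicles:>9} "
          f"{r.germination_pct:>8.2f}   ({gt.n_seeds}, {gt.n_radicles})")
# each row is one filter image: total seeds detected, radicle onsets
# (= germinated seeds), and their ratio as the germination percentage
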