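"""Select the objectness threshold P by sweeping it against hand counts.

Detections below the confidence threshold P are discarded; choosing P too
low admits false positives, too high drops true seeds.  The sweep evaluates
the average germination difference (mean |predicted - true| germination, in
percentage points) on a grid P = 0.01 ... 0.10 and picks the minimizer.
Here false positives are planted at objectness 0.015-0.055, so P = 0.06 is
the first grid point that recovers the exact counts.
"""

from strigacount import Box, Detection, GroundTruthCount, sweep_threshold


def det(k, label, obj):
    x0 = 15.0 * k
    other = "radicle" if label == "seed" else "seed"
    return Detection(Box(x0, 5, x0 + 10, 15, label), obj,
                     {label: obj, other: 0.01})


truth = [GroundTruthCount(s, 10, 4) for s in ("a", "b", "c")]
fp_scores = (0.015, 0.025, 0.035, 0.045, 0.055)
score_sets = {
    t.sample: (
        [det(k, "seed", 0.9) for k in range(10)]
        + [det(100 + k, "radicle", 0.9) for k in range(4)]
        + [det(200 + k, "seed", s) for k, s in enumerate(fp_scores)]
    )
    for t in truth
}

result = sweep_threshold(score_sets, truth)
print(result.as_frame().to_string(index=False))
print(f"\nselected P = {result.selected.setting:.2f} "
      f"(avg germination difference "
      f"{result.selected.avg_germ_diff:.2f} points)")
# seed_deviation / radicle_deviation are signed pooled-count errors in %:
# positive = undercount; negative = overcount from surviving false positives
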