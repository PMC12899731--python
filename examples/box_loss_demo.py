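"""EnWIoU loss anatomy on hand-picked box pairs.

Shows how the outlier-degree focusing gain and the orientation/aspect
modulation shape the loss for elongated particles.
"""

from shrimpdet.enwiou import EnWIoUConfig, enwiou

cfg = EnWIoUConfig()          # tau_aspect = 2.0, eta = 0.1, alpha = 1.9, delta = 3

cases = [
    ("perfect prediction",               (2, 2, 4, 1),   (2, 2, 4, 1)),
    ("shifted square",                   (1.0, 0.5, 1, 1), (0.5, 0.5, 1, 1)),
    ("elongated, consistent direction",  (0.4, 0, 4, 1), (0, 0, 3.6, 1)),
    ("elongated, rotated 90 deg",        (0, 0.4, 1, 4), (0, 0, 3.6, 1)),
]

print(f"{'case':34s} {'IoU':>6s} {'beta':>6s} {'r':>6s} {'gamma':>6s} {'loss':>7s}")
for name, pred, gt in cases:
    b = enwiou(pred, gt, cfg)
    print(f"{name:34s} {b.iou:6.3f} {b.beta_outlier:6.3f} "
          f"{b.r_gain:6.3f} {b.gamma:6.2f} {b.loss:7.4f}")

print("\nreading the table: gamma = 0.9 rewards a prediction that matches an"
      "\nelongated target's principal direction, gamma = 1.1 penalises a 90-deg"
      "\nmismatch, and r (the focusing gain) down-weights both near-perfect and"
      "\nbadly-off anchors so ordinary-quality ones dominate the gradient.")
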