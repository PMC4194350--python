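"""Benchmark detection and ROD classification against ground truth.

Generates 20 seeded plates (30 round + 30 oblong deposits each), runs
the default pipeline and scores it against the generator's truth table:
recall and precision of spot detection, and the accuracy of the
circularity-cutoff ROD classification.
"""

import numpy as np

from flyspot import SynthSpec, analyze_image, generate_plate, score_detection

scores = []
for seed in range(20):
    image, truth = generate_plate(SynthSpec(seed=seed))
    deposits = analyze_image(image, plate_id=f"plate{seed}")
    s = score_detection(truth, deposits)
    scores.append((s.recall, s.precision, s.rod_accuracy))

recall, precision, rod_acc = np.array(scores).T
print(f"plates:            {len(scores)}")
print(f"recall:            {recall.mean():.3f} (min {recall.min():.3f})")
print(f"precision:         {precision.mean():.3f} (min {precision.min():.3f})")
print(f"ROD accuracy:      {100 * rod_acc.mean():.2f}% (min {100 * rod_acc.min():.2f}%)")

# Recall/precision ~1 means every generated deposit is found and nothing
# spurious (specks stay below the size filter); ROD accuracy is the
# fraction of matched deposits whose shape class the 0.5 circularity
# cutoff reproduces.
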