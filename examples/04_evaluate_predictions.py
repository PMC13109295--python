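"""Score instance segmentations with AP@IoU and image fidelity with MAE.

Uses a generated plant's ground-truth masks, simulates an imperfect
segmenter by shifting every mask a few pixels, and reports AP@50/AP@75 in
both variants plus the foreground MAE between a degraded and the original
image.
"""

import numpy as np

from leafgen import GenerationConfig, generate_dataset
from leafgen.evalmetrics import ap_at_iou, foreground_mae

record = generate_dataset(
    GenerationConfig(grammar="rosette", count=1, seed=5, image_size=(256, 256))
)[0]
gts = [record.masks.visible_masks[k] for k in record.masks.instance_ids]
preds = [np.roll(g, shift=(3, -2), axis=(0, 1)) for g in gts]
scores = list(np.linspace(0.95, 0.6, len(preds)))

for tau in (0.5, 0.75):
    prec = ap_at_iou(preds, gts, tau, scores=scores)
    coco = ap_at_iou(preds, gts, tau, scores=scores, variant="coco")
    print(f"AP@{int(tau * 100)}: precision-variant {prec:.1f}, coco-variant {coco:.1f}")
print("A 3-4 px shift keeps most instances above IoU 0.5 but drops some "
      "below 0.75, so AP@75 falls first.")

noisy = np.clip(record.image.astype(int) + 12, 0, 255).astype(np.uint8)
fg = record.masks.label_image > 0
mae = foreground_mae(noisy, record.image, fg)
print(f"\nforeground MAE of a +12 brightness shift: {mae:.2f} "
      "(mean |difference| over leaf pixels only)")
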