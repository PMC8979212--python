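"""Sliding-window tiling, score assembly and thresholding arithmetic.

Shows the closed-form window tiling (every voxel covered, final window
clamped to the border), the two-stage score assembly S = w*S1 + (1-w)*S2
inside the fine-stage ROI with S1 elsewhere, and the inclusive 0.6
threshold.
"""

import numpy as np

from gtvcascade import ROIBox, ScoreMap, assemble, binarize_and_restore, window_origins

for extent in (128, 192, 200):
    o = window_origins(extent, 128, 64)
    print(f"axis extent {extent}, window 128, stride 64 -> origins {o}")
print("a 192x192x96 volume therefore needs 2*2*2 = 8 windows "
      "(stride 64x64x32, window 128x128x64)")

s1 = ScoreMap(np.full((32, 32, 16), 0.8, np.float32))
s2 = ScoreMap(np.full((8, 8, 8), 0.4, np.float32), provenance="stage2")
roi = ROIBox(center=(16, 16, 8), size=(8, 8, 8))
s = assemble(s1, s2, roi, weight=0.5)
print(f"inside ROI: 0.5*0.8 + 0.5*0.4 = {s.data[16, 16, 8]:.2f}; "
      f"outside ROI stage-1 score kept: {s.data[0, 0, 0]:.2f}")

meta = {"crop_offset": (0, 0, 0), "cropped_shape": (32, 32, 16),
        "original_shape": (32, 32, 16), "original_spacing": (1.0, 1.0, 1.0)}
mask = binarize_and_restore(s, threshold=0.6, meta=meta)
print(f"threshold 0.6 is inclusive: assembled score 0.6 inside the ROI -> "
      f"{int(mask.data[16, 16, 8])} (foreground), outside 0.8 -> "
      f"{int(mask.data[0, 0, 0])} (foreground)")
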