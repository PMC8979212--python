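"""Evaluate a prediction against ground truth with the five case metrics.

DSC/PPR/SEN measure volumetric overlap; ASSD and HD95 measure surface
distances in physical mm (here on an anisotropic 1 x 1 x 3 mm grid).
"""

import numpy as np

from gtvcascade import BinaryMask, cohort_report, evaluate_case

g = np.zeros((20, 20, 10), np.uint8)
g[5:15, 5:15, 3:7] = 1
a = np.zeros_like(g)
a[6:16, 5:15, 3:7] = 1  # prediction shifted one voxel in x

gm = BinaryMask(g, spacing=(1.0, 1.0, 3.0))
am = BinaryMask(a, spacing=(1.0, 1.0, 3.0))
r = evaluate_case(gm, am, "shifted")
print(f"DSC {100 * r.dsc:.1f}%  PPR {100 * r.ppr:.1f}%  SEN {100 * r.sen:.1f}%  "
      f"ASSD {r.assd_mm:.2f} mm  HD95 {r.hd95_mm:.2f} mm")
print("a one-voxel in-plane shift of a 10x10x4 block keeps DSC at 90% and "
      "sub-voxel mean surface distance")

df = cohort_report([r, evaluate_case(gm, gm, "identity")])
print("\ncohort table (per case + mean/sd rows):")
print(df.to_string(index=False))
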