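"""The transfer-function kernel itself: shape, peak time, normalization.

The kernel linking a neuronal calcium trace to a vascular response is a
gamma density with a pure time shift and an amplitude scale:

    TF(t) = H(t - p3) * p4 * (t - p3)^(p1-1) * p2^p1 * exp(-p2 (t - p3)) / Gamma(p1)

This script evaluates the standard microscopic kernel (calcium -> capillary
red-blood-cell velocity) on a fine grid and checks its two closed-form
properties: the peak sits at (p1-1)/p2 + p3, and the kernel integrates
to p4.
"""

import numpy as np

from nvctf import TFParams, evaluate_tf, tf_peak_time

standard = TFParams(p1=1.3, p2=0.5, p3=0.27, p4=0.19)

grid = 0.001 * np.arange(10_001)  # 0..10 s at 1 ms
values = evaluate_tf(standard, grid)

numeric_peak = grid[int(np.argmax(values))]
print(f"standard microscopic kernel: {standard}")
print(f"numeric peak time   : {numeric_peak:.3f} s  (1 ms grid)")
print(f"closed-form peak    : {tf_peak_time(standard):.3f} s  ((p1-1)/p2 + p3)")

integral = float(np.trapezoid(values, grid))
print(f"integral over 0-10 s: {integral:.5f}  (p4 = {standard.p4}; tail past 10 s accounts for the rest)")

# A slower, lower-amplitude kernel: the mesoscopic (calcium -> fUS voxel) one
meso = TFParams(p1=1.99, p2=1.27, p3=0.11, p4=0.045)
print(f"\nmesoscopic kernel   : {meso}")
print(f"closed-form peak    : {tf_peak_time(meso):.3f} s")
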