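"""Estimate myocardial T1 and T2 from synthetic mapping series.

T1 comes from a variable-flip-angle FLASH series (2-14 degrees, TR 5.8 ms)
fitted to the Ernst equation on the ROI-mean signal; T2 from a six-echo
decay fitted pixel-wise (log-linear) and averaged over the ROI.
"""

import numpy as np

from glucocest.phantom import (
    ECHO_TIMES_MS,
    FLIP_ANGLES_DEG,
    VFA_TR_MS,
    CohortSpec,
    generate_cardiac_phantom,
)
from glucocest.relaxometry import VfaSeries, fit_t1_vfa, roi_t2_mean

animals = generate_cardiac_phantom(CohortSpec(n_healthy=1, n_mi=1, seed=7))

for animal in animals:
    for region, mask in sorted(animal.rois.items()):
        signals = np.array(
            [animal.vfa_stack[j][mask].mean() for j in range(len(FLIP_ANGLES_DEG))]
        )
        t1 = fit_t1_vfa(VfaSeries(signals, FLIP_ANGLES_DEG, VFA_TR_MS))
        t2 = roi_t2_mean(animal.me_stack, ECHO_TIMES_MS, mask)
        true_t1 = animal.truth["t1_ms"][region]
        true_t2 = animal.truth["t2_ms"][region]
        print(
            f"{animal.animal_id}/{region:8s}  "
            f"T1 {t1.time_ms:6.1f} ms (truth {true_t1:6.1f})   "
            f"T2 {t2:5.2f} ms (truth {true_t2:5.2f})"
        )

print(
    "\nInfarcted myocardium shows the longest T2 (edema); the recovered "
    "values track\nthe generator's ground truth to within a few percent at "
    "the default noise level."
)
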