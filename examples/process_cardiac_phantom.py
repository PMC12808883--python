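"""Quantify glucoCEST contrast on a synthetic infarcted heart.

Generates one infarcted-animal phantom (96x96 short-axis slice, MI sector
plus remote myocardium, smooth B0 field, Rician noise, Rabi ripple), runs
each region's pixels through the chain — S0 normalization, B0 correction,
DOSE filtering, MTR asymmetry — and prints the band contrast per region
and state.
"""

import numpy as np

from glucocest.phantom import CohortSpec, generate_cardiac_phantom
from glucocest.pipeline import mtr_asym, roi_spectrum

spec = CohortSpec(n_healthy=1, n_mi=1, seed=42)
animals = generate_cardiac_phantom(spec)
mi_animal = next(a for a in animals if a.group == "mi")

print(f"animal {mi_animal.animal_id}: regions {sorted(mi_animal.rois)}")
for region, mask in sorted(mi_animal.rois.items()):
    print(f"\n{region} ({int(mask.sum())} pixels)")
    for state, raw in (("pre", mi_animal.raw_pre), ("post", mi_animal.raw_post)):
        spec_roi = roi_spectrum(raw, mask)
        res = mtr_asym(spec_roi)
        print(
            f"  {state:4s}: band integral {res.contrast:+.4f}  "
            f"band mean {res.contrast_mean:+.4f}  "
            f"B0 shift {spec_roi.b0_shift_ppm:+.3f} ppm"
        )

print(
    "\nExpected pattern: the infarct (mi) contrast rises after glucose "
    "infusion while\nthe remote myocardium (rm) barely changes — infarcted "
    "tissue accumulates\ncirculating glucose, remote tissue clears it."
)
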