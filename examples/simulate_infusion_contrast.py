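"""Simulate the glucose-infusion contrast of the cardiac tissue model.

Builds the five-pool cardiac tissue (water, semisolid MT, glucose
hydroxyl, amine, amide) at pre- and post-infusion glucose levels, runs the
Bloch-McConnell simulator with the 9.4 T saturation scheme (140 ms block
pulse at 2 uT, TR 398 ms, cumulative steady state), and prints the
band-integrated MTR asymmetry over the 0.5-2 ppm hydroxyl band.
"""

from glucocest import SequenceParams, cardiac_tissue, glucose_hydroxyl_fraction
from glucocest.simulator import simulated_contrast

seq = SequenceParams()  # cumulative saturation, Table-style cardiac preset

contrasts = {}
for mM in (10.0, 22.0, 35.0):
    c = simulated_contrast(cardiac_tissue(mM), seq)
    contrasts[mM] = c
    print(
        f"{mM:4.0f} mM glucose (hydroxyl fraction {glucose_hydroxyl_fraction(mM):.6f})"
        f" -> glucoCEST contrast {c:.6f}"
    )

print(f"\ndelta contrast 22 vs 10 mM: {contrasts[22.0] - contrasts[10.0]:.6f}")
print(f"delta contrast 35 vs 10 mM: {contrasts[35.0] - contrasts[10.0]:.6f}")
print(
    "\nThe deltas are the simulated post-minus-pre infusion contrast of "
    "myocardium;\npositive values mean the hydroxyl band's asymmetry grew "
    "with tissue glucose."
)
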