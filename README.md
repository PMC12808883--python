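# glucocest

Quantification of glucose-weighted chemical exchange saturation transfer
(glucoCEST) MRI in the mouse heart: Bloch-McConnell simulation of
multi-pool Z-spectra, the Z-spectrum processing chain (S0 normalization,
B0 correction, DOSE ripple filtering, MTR asymmetry and
Lorentzian-difference quantification), variable-flip-angle T1 and
multi-echo T2 relaxometry, and a synthetic-cohort generator for
end-to-end validation — aimed at preclinical CEST MRI researchers who
want a tested, scriptable reimplementation of this analysis.

## Background

CEST MRI saturates labile protons at their chemical shift and reads out
the transferred saturation on the water signal. The Z-spectrum is the
normalized water signal as a function of saturation offset,
`Z(Δω) = S(Δω)/S0`. Glucose contributes five exchangeable hydroxyl
protons resonating near +1.5 ppm, so the glucoCEST contrast is the
asymmetry of the Z-spectrum integrated over the hydroxyl band:

    MTR_asym(Δω) = [S(−Δω) − S(Δω)] / S0
    glucoCEST contrast = ∫_{0.5 ppm}^{2 ppm} MTR_asym(Δω) dΔω

and the infusion effect is `ΔglucoCEST = contrast_post − contrast_pre`.
An alternative route fits a single Lorentzian reference
`Z_ref(Δω) = c − a·(b²/4)/(b²/4 + Δω²)` to the corrected Z-spectrum and
integrates the residual `MTR_res = Z_ref − Z` over the same band.

The forward model is the Bloch-McConnell equations for water plus dilute
exchanging pools (semisolid MT, hydroxyl, amine, amide), evolved exactly
per block pulse via matrix exponentials, with the cumulative steady state
of a short saturation pulse (140 ms, 2 µT) repeated at short TR (398 ms).
In infarcted myocardium the contrast rises after glucose infusion, in
healthy myocardium it falls, and remote myocardium stays near zero — the
group-level pattern this package reproduces on synthetic cohorts.

## Worked example

```python
from glucocest import SequenceParams, cardiac_tissue
from glucocest.simulator import simulated_contrast

seq = SequenceParams()          # 9.4 T cardiac preset, cumulative mode
pre  = simulated_contrast(cardiac_tissue(10.0), seq)
post = simulated_contrast(cardiac_tissue(35.0), seq)
print(f"{pre:.6f} {post:.6f} {post - pre:.6f}")
```

prints

```
0.009884 0.032748 0.022863
```

the band-integrated MTR asymmetry of the cardiac tissue model at 10 mM
and 35 mM glucose and their difference — the simulated infusion contrast.
The scripts in `examples/` walk through each capability (simulation,
phantom processing, relaxometry, the full cohort study) and print what
the numbers mean; a thin CLI (`glucocest simulate|phantom|process|relax|report`)
wraps the same functions for shell use.

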