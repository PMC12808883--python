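# Methods

## Forward model: Bloch-McConnell simulation

A tissue is bulk water plus dilute solute pools, each with proton
fraction `f` (relative to water), relaxation times T1/T2, solute-to-water
exchange rate `k` (Hz) and chemical shift `δ` (ppm). The coupled
magnetization obeys the Bloch-McConnell equations; exchange respects
detailed balance (water→solute rate = `f·k`). The semisolid MT pool is an
ordinary Bloch pool with T2 = 40 µs: a Lorentzian absorption line is
exactly the Bloch-pool lineshape, so no separate lineshape machinery is
needed.

Because the saturation pulse is a constant-amplitude block, the generator
is time-invariant and each interval is evolved exactly with one matrix
exponential (in homogeneous coordinates, so relaxation recovery is part
of the same linear map) — no ODE stepping, no tolerance coupling.

Two saturation regimes:

- **single_shot** — one Tsat pulse from thermal equilibrium.
- **cumulative** (default) — the TR block (saturate → spoil transverse →
  readout flip on water → recover for TR−Tsat) is iterated to its fixed
  point (tolerance 1e-6 on z, at most 200 blocks). A 140 ms pulse at
  398 ms TR saturates weakly in one shot but builds up across
  repetitions; the cumulative mode is what makes the short-pulse cardiac
  protocol work, and it is the mode whose simulated infusion contrasts
  match the model's reference values. The segmented readout train is
  collapsed into a single effective flip (15° by default, configurable);
  the residual difference between the two modes brackets the uncertainty
  from unmodeled readout detail.

Z values are normalized to the mean of the simulation at the two S0
offsets (±15 ppm). ppm↔Hz conversion uses 400.2 MHz (9.4 T); the
acquisition's Hz offset list (±2000 Hz in 200 Hz steps, interleaved
high-to-low, on-resonance last) is treated as the operational truth and
spans ≈ ±5 ppm.

The glucose hydroxyl proton fraction is `5c/111 M` — five exchangeable
hydroxyls per molecule against the 111 M proton content of water — giving
0.00045 at 10 mM, 0.000991 at 22 mM, 0.00158 at 35 mM.

### Simulator-level contrast

`simulated_contrast` interpolates the simulated spectrum onto the
standard 4001-point grid and integrates the asymmetry over 0.5–2 ppm with
a **known zero** B0 shift: a simulation has no field error, and running a
minimum-search on a CEST-bearing spectrum would inject an artificial,
amplitude-dependent shift.

## Processing chain

Order: normalize → B0-correct → DOSE → quantify (asymmetry and/or
Lorentzian difference). All steps deterministic.

1. **Normalization** — each pixel's per-offset signal divided by the mean
   of its two S0 images; pixels with non-positive S0 are excluded and
   counted.
2. **B0 correction** — natural cubic spline onto a 4001-point grid over
   the acquired range; the grid is translated so the spectral minimum
   sits at 0 ppm; points whose source falls outside the acquired range
   become missing (never extrapolated). Minima on the range boundary or
   shifts beyond 1 ppm flag the pixel invalid.

   The minimum is *located* on the parity-split average of the spectrum
   (the same construction as the DOSE filter below). The band contrast is
   steeply sensitive to the estimated shift (≈0.4 contrast-integral
   units per ppm of error, because the dip flank crosses 0.5 ppm), and a
   raw fine-grid argmin locks onto spurious ripple minima half an
   acquired step off resonance when ripple, noise and a field shift
   coincide. The parity-average estimator is stable under all three; its
   small smooth-spectrum interpolation bias is common to every state
   being compared and is absorbed into the generator calibration.
3. **DOSE filtering** — the sorted acquired samples are split into two
   downsampled sub-spectra (every other point), each spline-interpolated
   onto the fine grid, and averaged. Ripple alternating between
   neighbouring sorted offsets (the Rabi signature of a short block
   pulse) lands with opposite sign in the two halves and cancels; smooth
   spectra pass through up to the interpolation error of the half-rate
   sampling (<1e-3 when the dip is well sampled; a few 1e-3 at the
   0.5 ppm cardiac spacing). Sub-spectra with fewer than 3 points skip
   the filter with a warning.
4. **MTR asymmetry** — `z(−Δω) − z(Δω)` on the fine grid; contrast is the
   trapezoidal integral over 0.5–2 ppm with endpoints included by linear
   sub-interpolation. Both the integral (primary) and the band mean
   (integral / 1.5 ppm) are reported, since group-level values are most
   naturally compared as band means.
5. **Lorentzian difference** — trust-region least squares of
   `c − a·(b²/4)/(b²/4+Δω²)` over all valid grid points, deterministic
   initialization (`a₀ = 1−min z`, `b₀ = 1 ppm`, `c₀ = max z`), bounds
   a,c ∈ [0, 1.2], b ∈ (0, 20] ppm; the residual `Z_ref − Z` is
   integrated over the band. `b` equals the FWHM of the fitted dip
   analytically. An optional exclusion band exists but defaults to off.

ROI spectra are the mean of per-pixel processed spectra (per-pixel B0
correction first); the ROI-level fit/integration happens on that mean.

## Relaxometry

- **T1 (VFA)** — Ernst equation fit on ROI-mean signals over flip angles
  2–14° at TR 5.8 ms; start values from the `S/sinθ` vs `S/tanθ`
  linearization, bounded nonlinear refinement over (M0, T1). Flat series
  or degenerate linearization slopes are flagged invalid.
- **T2 (multi-echo)** — pixel-wise log-linear fit of `ln S` vs TE over
  six echoes (11.3–124.3 ms); ROI summary is the mean of valid pixel T2.
  Non-positive signals or non-decaying pixels are excluded. A nonlinear
  polish is available behind a flag but the log-linear estimator is the
  default for determinism.
- No Rician noise-floor correction anywhere — a deliberate match to the
  analysis being reimplemented. Consequently the estimators are accurate
  (≤2% at per-measurement SNR 50) only while signals stay well above the
  floor; late echoes and tiny flip angles at low image SNR bias T2/T1
  upward (the residual T2 bias at the generator's defaults is ≈4%).

## Statistics

Paired comparisons use the Wilcoxon signed-rank test, unpaired the
Mann-Whitney U, both two-sided, no multiple-testing correction. For
n ≤ 25 pairs the signed-rank null distribution is computed exactly by
dynamic programming over doubled midranks, which handles ties exactly and
zero differences by the zero-split convention — identical samples give
p = 1 rather than an error, so the null case stays usable in pipelines.
Unpaired exact p-values come from the exact U distribution (tie-free
case); ties or large samples fall back to the normal approximation with
tie correction. Both tests are verified against full enumeration (sign
patterns / group assignments) for all n ≤ 8.

## Synthetic data generator

The cardiac phantom is a stylized short-axis slice: a myocardial annulus
(inner/outer radii 13/21 px on a 96×96 matrix), with a 90° infarct sector
and remote myocardium for infarcted animals. Default cohort: 8 healthy,
6 infarcted. Per region and infusion state the tissue is the five-pool
cardiac model with the hydroxyl fraction set from a calibration table;
spectra come from the Bloch-McConnell simulator, shifted per pixel by a
smooth random B0 field (amplitude 0.3 ppm), with optional
parity-alternating ripple (amplitude 0.01) and Rician noise (σ = 0.02 of
S0 on the CEST images).

**Calibrated fractions.** The per-region/state hydroxyl fractions are
fitted constants, chosen once so the noiseless simulator→pipeline chain
lands the band-mean contrast of each region at the group means the
analysis is meant to resolve (healthy 0.035→0.009, MI 0.017→0.054, RM
0.017→0.019). They stand in for unavailable in vivo tissue states — the
healthy post-infusion drop emulates washout/vasodilation and is a
modeling stand-in, not a measured mechanism. Between-animal variability
is a log-normal scale (σ=0.3) shared across states within an animal plus
a smaller per-state jitter (σ=0.05), so each animal's Δ sign is driven by
the effect, not the variability.

**Relaxometry series.** Region T1/T2 defaults: healthy 512/29.2 ms, MI
556/36.3 ms, remote 548/28.6 ms (pre-contrast-agent regime), with ±3%
per-animal jitter. Noise is referenced to each series' brightest image
(receiver gain normalizes each acquisition) and scaled for the series'
signal averages and sequence efficiency: the VFA series runs at σ·√2
(single average), the multi-echo RARE at σ/2 (four averages and a
refocused spin-echo signal versus the 15° FLASH readout).

**Tube phantoms.** Water plus a single hydroxyl pool per concentration;
pH/temperature effects are folded into the exchange rate (3500 Hz). The
tube water T2 is an effective 0.1 s: with the seconds-long T2 of neat
water the 140 ms block pulse's Rabi transient never damps and the
21-offset spectrum aliases it fatally, whereas the protocol's usable
phantom spectra imply an effectively damped transient.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: cardiac and respiratory motion, B1
inhomogeneity, k-space/readout artefacts, partial-volume and blood-pool
contamination, anatomy beyond the annulus stylization, and contrast-agent
kinetics. The power and sign-pattern results certify the pipeline's
sensitivity under the generator's assumptions, not in vivo effect sizes.

A fast ROI-level cohort path (one spectrum trace per region/state, noise
scaled as an 800-pixel ROI average, one B0 shift per animal) feeds
replicate-heavy power checks; it runs the identical simulator and
processing chain, only skipping per-pixel image assembly. Sizes were
chosen so the whole suite, including 200 cohort replicates, runs in a few
minutes on one CPU.

## Numerical choices and degenerate inputs

- Integrals: trapezoidal rule on the 4001-point grid, band endpoints by
  linear sub-interpolation.
- Splines: natural cubic throughout.
- Spoiling is ideal (transverse magnetization zeroed); the readout flip
  acts on water longitudinal magnetization only (solute pools are dilute
  enough that flipping them too changes nothing at the reported
  precision).
- Flat spectra have no interior minimum → flagged invalid at B0
  correction. Flat relaxometry series → invalid fits, excluded from ROI
  summaries. Empty ROIs and masks raise immediately.
- Same seed ⇒ byte-identical phantoms; the study report records seed,
  config and a config hash in `provenance.json`.

## Known limitations

- The readout train is a single effective flip; simulated absolute
  contrasts carry a mode/readout uncertainty of order 10% (bracketed by
  the two saturation modes).
- The B0 estimator trades a small smooth-spectrum bias for stability;
  absolute single-state contrasts inherit that bias, differences and
  group comparisons largely cancel it.
- No B1 correction, no motion/registration, no noise-floor correction —
  faithful to the analysis being reimplemented, and the dominant caveats
  for transferring conclusions to real scans.
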