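"""Synthetic cardiac and tube phantoms with the structure the pipeline assumes.

The cardiac phantom is a stylized short-axis slice: a myocardial annulus on
a 96x96 matrix, split for infarcted animals into a 90-degree infarct (MI)
sector and the remote myocardium (RM).  Each region's Z-spectrum is
generated by the Bloch-McConnell simulator from the five-pool cardiac
tissue model, with the glucose hydroxyl fraction set per region and state
(pre/post infusion), then degraded by a smooth B0 offset field, optional
parity-alternating Rabi ripple, and Rician magnitude noise.  VFA T1 and
multi-echo T2 series are generated from region relaxation times.  Ground
truth (fractions, expected contrast signs, B0 field, T1/T2) travels with
every dataset.

Hydroxyl fractions per region/state are *fitted* calibration constants:
they were chosen once so that the noiseless simulator-to-pipeline chain
lands the band-mean MTR_asym contrast of each region near the group means
the analysis is meant to resolve (healthy 0.035 -> 0.009, MI 0.017 ->
0.054, RM 0.017 -> 0.019).  They are stand-ins for in vivo tissue states,
not measured tissue parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .pipeline import RawCestSeries
from .pools import SequenceParams, cardiac_tissue, tube_tissue
from .simulator import simulate_zspectrum

__all__ = [
    "CohortSpec",
    "AnimalDataset",
    "CALIBRATED_FRACTIONS",
    "REGION_T1_MS",
    "REGION_T2_MS",
    "add_rician_noise",
    "b0_field",
    "generate_cardiac_phantom",
    "generate_roi_cohort",
    "generate_tube_phantom",
]

#: Fitted hydroxyl proton fractions per region and infusion state (see
#: module docstring).  Labeled calibration constants, not tissue physics.
CALIBRATED_FRACTIONS: dict[str, dict[str, float]] = {
    "healthy": {"pre": 4.963289e-03, "post": 1.099424e-03},
    "mi": {"pre": 2.220738e-03, "post": 8.679533e-03},
    "rm": {"pre": 2.220738e-03, "post": 2.559179e-03},
}

#: Pre-contrast-agent myocardial T1 per region, ms.
REGION_T1_MS = {"healthy": 512.0, "mi": 556.0, "rm": 548.0}
#: Myocardial T2 per region, ms (edema raises the infarct value).
REGION_T2_MS = {"healthy": 29.2, "mi": 36.3, "rm": 28.6}

ECHO_TIMES_MS = (11.30, 33.89, 56.48, 79.07, 101.66, 124.26)
FLIP_ANGLES_DEG = (2.0, 5.0, 8.0, 11.0, 14.0)
VFA_TR_MS = 5.8

#: Signal averages per acquisition (CEST FLASH, VFA Ig-FLASH, multi-echo
#: RARE).  ``noise_sigma`` refers to the 2-average CEST images; the
#: relaxometry series are scaled by sqrt(2/averages).
SERIES_AVERAGES = {"cest": 2, "vfa": 1, "multiecho": 4}


@dataclass(frozen=True)
class CohortSpec:
    """Everything that defines one synthetic cohort, reproducible per seed."""

    n_healthy: int = 8
    n_mi: int = 6
    image_size: tuple[int, int] = (96, 96)
    annulus_radii: tuple[float, float] = (13.0, 21.0)  # pixels, inner/outer
    mi_sector_deg: float = 90.0
    b0_amplitude_ppm: float = 0.3
    noise_sigma: float = 0.02  # Rician sigma relative to S0
    ripple_amplitude: float = 0.01  # parity-alternating ripple on z
    animal_scale_sigma: float = 0.3  # log-normal spread of per-animal CEST scale
    state_jitter_sigma: float = 0.05  # extra per-state multiplicative jitter
    fractions: dict = field(default_factory=lambda: CALIBRATED_FRACTIONS)
    t1_ms: dict = field(default_factory=lambda: REGION_T1_MS)
    t2_ms: dict = field(default_factory=lambda: REGION_T2_MS)
    s0_intensity: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 1 or self.n_mi < 1:
            raise ValueError("group sizes must be >= 1")
        if self.noise_sigma < 0 or self.ripple_amplitude < 0:
            raise ValueError("noise and ripple amplitudes must be >= 0")
        if self.annulus_radii[1] > min(self.image_size) / 2:
            raise ValueError("annulus does not fit inside the image")


@dataclass
class AnimalDataset:
    """One synthetic animal: CEST series pre/post, relaxometry, ROIs, truth."""

    animal_id: str
    group: str  # "healthy" or "mi"
    raw_pre: RawCestSeries
    raw_post: RawCestSeries
    vfa_stack: np.ndarray  # (n_flip, H, W)
    me_stack: np.ndarray  # (n_echo, H, W)
    rois: dict[str, np.ndarray]
    b0_field_ppm: np.ndarray
    truth: dict


def add_rician_noise(
    image: np.ndarray, sigma: float, rng: np.random.Generator | int, s0: float = 1.0
) -> np.ndarray:
    """Rician magnitude noise: ``sqrt((x+n1)^2 + n2^2)``, n ~ N(0, sigma*s0).

    ``sigma`` is relative to the reference intensity ``s0``; sigma 0 is the
    identity.  For a zero signal the output mean is ``sigma*s0*sqrt(pi/2)``
    (Rayleigh).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.asarray(image, dtype=float).copy()
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    sd = sigma * s0
    n1 = rng.normal(0.0, sd, size=np.shape(image))
    n2 = rng.normal(0.0, sd, size=np.shape(image))
    return np.sqrt((np.asarray(image, dtype=float) + n1) ** 2 + n2**2)


def b0_field(shape: tuple[int, int], amplitude_ppm: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth pseudo-random B0 offset field in ppm, peak |value| = amplitude."""
    if amplitude_ppm == 0:
        return np.zeros(shape)
    raw = rng.normal(size=shape)
    smooth = gaussian_filter(raw, sigma=min(shape) / 4.0, mode="reflect")
    peak = np.abs(smooth).max()
    if peak == 0:
        return np.zeros(shape)
    return amplitude_ppm * smooth / peak


def _region_masks(spec: CohortSpec, infarcted: bool) -> dict[str, np.ndarray]:
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    annulus = (r >= spec.annulus_radii[0]) & (r <= spec.annulus_radii[1])
    if not infarcted:
        return {"healthy": annulus}
    theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
    sector = theta < spec.mi_sector_deg
    return {"mi": annulus & sector, "rm": annulus & ~sector}


def _seq_kwargs(seq: SequenceParams) -> dict:
    return {
        "b1": seq.b1,
        "tsat": seq.tsat,
        "tr": seq.tr,
        "flip_angle": seq.flip_angle,
        "s0_offsets_ppm": seq.s0_offsets_ppm,
        "reference_frequency_mhz": seq.reference_frequency_mhz,
        "saturation_mode": seq.saturation_mode,
        "max_blocks": seq.max_blocks,
        "convergence_tol": seq.convergence_tol,
    }


def _ripple_signs(offsets_hz: tuple[float, ...]) -> np.ndarray:
    """+1/-1 alternating with position in the offset-sorted spectrum."""
    order = np.argsort(np.argsort(offsets_hz))
    return np.where(order % 2 == 0, 1.0, -1.0)


def _cest_series(
    spec: CohortSpec,
    seq: SequenceParams,
    masks: dict[str, np.ndarray],
    fractions: dict[str, float],
    field_ppm: np.ndarray,
    rng: np.random.Generator,
) -> RawCestSeries:
    h, w = spec.image_size
    offsets = np.asarray(seq.offsets_hz)
    stack = np.zeros((len(offsets), h, w))
    shift_hz = field_ppm * seq.reference_frequency_mhz
    signs = _ripple_signs(seq.offsets_hz)
    for name, mask in masks.items():
        margin = 400.0
        dense = np.arange(offsets.min() - margin, offsets.max() + margin + 1, 100.0)
        tissue = cardiac_tissue(10.0).with_solute("hydroxyl", fraction=fractions[name])
        sim = simulate_zspectrum(
            tissue, SequenceParams(offsets_hz=tuple(dense), **_seq_kwargs(seq))
        )
        spline = CubicSpline(dense, sim.z_values)
        sh = shift_hz[mask]
        for i, off in enumerate(offsets):
            stack[i][mask] = spline(off - sh)
    if spec.ripple_amplitude > 0:
        stack += spec.ripple_amplitude * signs[:, None, None] * (stack > 0)
    stack *= spec.s0_intensity
    s0 = np.zeros((2, h, w))
    union = np.zeros((h, w), dtype=bool)
    for mask in masks.values():
        union |= mask
    s0[:, union] = spec.s0_intensity
    if spec.noise_sigma > 0:
        stack = add_rician_noise(stack, spec.noise_sigma, rng, s0=spec.s0_intensity)
        s0 = add_rician_noise(s0, spec.noise_sigma, rng, s0=spec.s0_intensity)
    return RawCestSeries(
        stack=stack,
        s0_images=s0,
        offsets_hz=seq.offsets_hz,
        ref_freq_mhz=seq.reference_frequency_mhz,
        mask=union,
    )


def generate_cardiac_phantom(
    spec: CohortSpec, seq: SequenceParams | None = None
) -> list[AnimalDataset]:
    """Generate the full synthetic cohort, deterministic per seed.

    Each animal gets pre- and post-infusion CEST series, a VFA series, a
    multi-echo series, ROI label masks and a ground-truth record with the
    region fractions, B0 field, relaxation times and expected Δ-contrast
    sign (healthy negative, MI positive, RM near zero).
    """
    seq = seq or SequenceParams()
    rng = np.random.default_rng(spec.seed)
    animals: list[AnimalDataset] = []
    groups = ["healthy"] * spec.n_healthy + ["mi"] * spec.n_mi
    for i, group in enumerate(groups):
        infarcted = group == "mi"
        masks = _region_masks(spec, infarcted)
        field_ppm = b0_field(spec.image_size, spec.b0_amplitude_ppm, rng)
        scale = float(np.exp(rng.normal(0.0, spec.animal_scale_sigma)))
        fracs: dict[str, dict[str, float]] = {}
        for state in ("pre", "post"):
            jit = float(np.exp(rng.normal(0.0, spec.state_jitter_sigma)))
            fracs[state] = {
                name: min(spec.fractions[name][state] * scale * jit, 0.045)
                for name in masks
            }
        raw = {
            state: _cest_series(spec, seq, masks, fracs[state], field_ppm, rng)
            for state in ("pre", "post")
        }

        h, w = spec.image_size
        union = raw["pre"].mask
        t1_img = np.zeros((h, w))
        t2_img = np.zeros((h, w))
        t1_true, t2_true = {}, {}
        for name, mask in masks.items():
            t1_true[name] = spec.t1_ms[name] * float(np.exp(rng.normal(0, 0.03)))
            t2_true[name] = spec.t2_ms[name] * float(np.exp(rng.normal(0, 0.03)))
            t1_img[mask] = t1_true[name]
            t2_img[mask] = t2_true[name]
        vfa = np.zeros((len(FLIP_ANGLES_DEG), h, w))
        for j, th in enumerate(FLIP_ANGLES_DEG):
            with np.errstate(divide="ignore", invalid="ignore"):
                e1 = np.where(union, np.exp(-VFA_TR_MS / np.where(union, t1_img, 1.0)), 0.0)
            th_r = np.deg2rad(th)
            vfa[j] = np.where(
                union,
                spec.s0_intensity * np.sin(th_r) * (1 - e1) / (1 - e1 * np.cos(th_r)),
                0.0,
            )
        me = np.zeros((len(ECHO_TIMES_MS), h, w))
        for j, te in enumerate(ECHO_TIMES_MS):
            me[j] = np.where(
                union, spec.s0_intensity * np.exp(-te / np.where(union, t2_img, 1.0)), 0.0
            )
        if spec.noise_sigma > 0:
            # noise referenced to each series' brightest image (receiver
            # noise scales with the acquired intensity range; the VFA
            # signal at TR 5.8 ms is far below the notional M0) and scaled
            # by the series' signal averages relative to the CEST scan
            sig_vfa = spec.noise_sigma * np.sqrt(
                SERIES_AVERAGES["cest"] / SERIES_AVERAGES["vfa"]
            )
            # RARE refocuses close to the full magnetization per echo while
            # the CEST FLASH readout tips only sin(15 deg) of it, so on top
            # of its 4 signal averages the T2 series runs at roughly half
            # the relative noise of the CEST images
            sig_me = spec.noise_sigma / 2.0
            vfa = add_rician_noise(vfa, sig_vfa, rng, s0=float(vfa.max()))
            me = add_rician_noise(me, sig_me, rng, s0=float(me.max()))

        expected_sign = {"healthy": -1, "mi": +1, "rm": 0}
        truth = {
            "animal_id": f"{group}{i:02d}",
            "group": group,
            "cest_scale": scale,
            "fractions": fracs,
            "t1_ms": t1_true,
            "t2_ms": t2_true,
            "expected_delta_sign": {n: expected_sign[n] for n in masks},
        }
        animals.append(
            AnimalDataset(
                animal_id=truth["animal_id"],
                group=group,
                raw_pre=raw["pre"],
                raw_post=raw["post"],
                vfa_stack=vfa,
                me_stack=me,
                rois=masks,
                b0_field_ppm=field_ppm,
                truth=truth,
            )
        )
    return animals


def generate_roi_cohort(
    spec: CohortSpec, seq: SequenceParams | None = None, n_pixels: int = 800
) -> list[dict]:
    """Fast ROI-level cohort: one noisy Z-spectrum trace per region/state.

    Emulates the ROI average of ``n_pixels`` independent pixels: the
    Rician noise of the pixel average is approximated as Gaussian with
    standard deviation ``noise_sigma/sqrt(n_pixels)``, and the whole ROI
    shares one B0 shift drawn within the field amplitude.  Used for
    replicate-heavy statistical checks where generating full image stacks
    would dominate runtime; the spectra still pass through the identical
    simulator and processing chain.
    """
    seq = seq or SequenceParams()
    rng = np.random.default_rng(spec.seed)
    sd = spec.noise_sigma / np.sqrt(n_pixels)
    signs = _ripple_signs(seq.offsets_hz)
    groups = ["healthy"] * spec.n_healthy + ["mi"] * spec.n_mi
    out = []
    for i, group in enumerate(groups):
        regions = ["healthy"] if group == "healthy" else ["mi", "rm"]
        scale = float(np.exp(rng.normal(0.0, spec.animal_scale_sigma)))
        shift_ppm = float(rng.uniform(-spec.b0_amplitude_ppm, spec.b0_amplitude_ppm))
        rec = {"animal_id": f"{group}{i:02d}", "group": group, "regions": {}}
        for state in ("pre", "post"):
            jit = float(np.exp(rng.normal(0.0, spec.state_jitter_sigma)))
            for name in regions:
                frac = min(spec.fractions[name][state] * scale * jit, 0.045)
                shifted = tuple(
                    o - shift_ppm * seq.reference_frequency_mhz for o in seq.offsets_hz
                )
                tissue = cardiac_tissue(10.0).with_solute("hydroxyl", fraction=frac)
                sim = simulate_zspectrum(
                    tissue, SequenceParams(offsets_hz=shifted, **_seq_kwargs(seq))
                )
                z = sim.z_values + spec.ripple_amplitude * signs
                if sd > 0:
                    z = z + rng.normal(0.0, sd, size=z.shape)
                rec["regions"].setdefault(name, {})[state] = RawCestSeries(
                    stack=z * spec.s0_intensity,
                    s0_images=np.full((2,), spec.s0_intensity),
                    offsets_hz=seq.offsets_hz,
                    ref_freq_mhz=seq.reference_frequency_mhz,
                )
        out.append(rec)
    return out


def generate_tube_phantom(
    concentrations_mM: list[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
    seq: SequenceParams | None = None,
    image_size: tuple[int, int] = (48, 48),
    tube_radius: float = 5.0,
    s0_intensity: float = 1000.0,
) -> tuple[RawCestSeries, dict[float, np.ndarray]]:
    """In vitro glucose tubes in PBS: one disc region per concentration.

    Returns the raw CEST series and a mask per concentration.  Each tube's
    Z-spectrum comes from a water+hydroxyl two-pool simulation with the
    hydroxyl fraction set by the concentration; deterministic per seed.
    """
    if len(concentrations_mM) == 0:
        raise ValueError("need at least one concentration")
    if any(c < 0 for c in concentrations_mM):
        raise ValueError("concentrations must be >= 0")
    seq = seq or SequenceParams()
    rng = np.random.default_rng(seed)
    h, w = image_size
    n = len(concentrations_mM)
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    yy, xx = np.mgrid[0:h, 0:w]
    stack = np.zeros((len(seq.offsets_hz), h, w))
    masks: dict[float, np.ndarray] = {}
    for k, conc in enumerate(concentrations_mM):
        cy = (k // ncol + 0.5) * h / nrow
        cx = (k % ncol + 0.5) * w / ncol
        mask = np.hypot(yy - cy, xx - cx) <= tube_radius
        masks[conc] = mask
        sim = simulate_zspectrum(tube_tissue(conc), seq)
        for i in range(len(seq.offsets_hz)):
            stack[i][mask] = sim.z_values[i]
    union = np.zeros((h, w), dtype=bool)
    for m in masks.values():
        union |= m
    stack *= s0_intensity
    s0 = np.zeros((2, h, w))
    s0[:, union] = s0_intensity
    if noise_sigma > 0:
        stack = add_rician_noise(stack, noise_sigma, rng, s0=s0_intensity)
        s0 = add_rician_noise(s0, noise_sigma, rng, s0=s0_intensity)
    raw = RawCestSeries(
        stack=stack,
        s0_images=s0,
        offsets_hz=seq.offsets_hz,
        ref_freq_mhz=seq.reference_frequency_mhz,
        mask=union,
    )
    return raw, masks
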