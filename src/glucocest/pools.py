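"""Tissue and sequence descriptions for Bloch-McConnell CEST simulation.

A tissue is a bulk-water pool plus a list of dilute exchanging solute pools.
Each pool carries its relaxation times, its exchangeable-proton fraction
relative to water, the first-order solute-to-water exchange rate, and the
chemical shift of its resonance from water.  A sequence preset carries the
saturation module (block-pulse amplitude and duration), the repetition time,
the readout flip angle and the frequency-offset scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

GAMMA_HZ_PER_UT = 42.577  # proton gyromagnetic ratio, Hz per microtesla

#: Water proton concentration (mol/L of exchangeable-equivalent protons):
#: 55.5 M water x 2 protons.
WATER_PROTON_M = 111.0

#: Exchangeable hydroxyl protons per glucose molecule.
GLUCOSE_OH_PROTONS = 5


def glucose_hydroxyl_fraction(concentration_mM: float) -> float:
    """Proton fraction of the glucose hydroxyl pool at a given concentration.

    Five exchangeable hydroxyl protons per glucose molecule, referenced to
    the 111 M proton content of pure water.  10 mM glucose gives a fraction
    of about 4.5e-4.

    Parameters
    ----------
    concentration_mM : float
        Glucose concentration in millimolar.  Must be non-negative.
    """
    if concentration_mM < 0:
        raise ValueError(f"negative glucose concentration: {concentration_mM} mM")
    return GLUCOSE_OH_PROTONS * concentration_mM * 1e-3 / WATER_PROTON_M


@dataclass(frozen=True)
class PoolSpec:
    """One proton pool: fraction, relaxation, exchange and shift.

    ``fraction`` is the pool's exchangeable-proton concentration relative to
    water (water itself has fraction 1).  ``exchange_rate`` is the
    solute-to-water rate in Hz; the reverse rate follows from detailed
    balance as ``fraction * exchange_rate``.  ``chemical_shift`` is in ppm
    relative to the water resonance.  Only a Lorentzian lineshape is
    supported; a semisolid MT pool with a Lorentzian line is represented
    exactly by an ordinary Bloch pool with a very short T2.
    """

    name: str
    fraction: float
    t1: float  # seconds
    t2: float  # seconds
    exchange_rate: float = 0.0  # Hz, solute -> water
    chemical_shift: float = 0.0  # ppm relative to water
    lineshape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise ValueError(f"pool {self.name!r}: fraction must be >= 0")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError(f"pool {self.name!r}: T1 and T2 must be > 0")
        if self.exchange_rate < 0:
            raise ValueError(f"pool {self.name!r}: exchange rate must be >= 0")
        if self.lineshape != "lorentzian":
            raise ValueError(f"unsupported lineshape {self.lineshape!r}")


@dataclass(frozen=True)
class TissueModel:
    """A water pool plus an ordered list of dilute solute pools."""

    water: PoolSpec
    solutes: tuple[PoolSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.water.fraction != 1 or self.water.chemical_shift != 0:
            raise ValueError("water pool must have fraction 1 and shift 0 ppm")
        for p in self.solutes:
            if p.fraction >= 0.05:
                raise ValueError(
                    f"solute pool {p.name!r} fraction {p.fraction} outside dilute regime"
                )
        object.__setattr__(self, "solutes", tuple(self.solutes))

    @property
    def pools(self) -> tuple[PoolSpec, ...]:
        return (self.water, *self.solutes)

    def with_solute(self, name: str, **changes) -> "TissueModel":
        """Return a copy with the named solute pool's fields replaced."""
        found = False
        new = []
        for p in self.solutes:
            if p.name == name:
                new.append(replace(p, **changes))
                found = True
            else:
                new.append(p)
        if not found:
            raise KeyError(f"no solute pool named {name!r}")
        return TissueModel(water=self.water, solutes=tuple(new))

    def to_dict(self) -> dict:
        def pool_d(p: PoolSpec) -> dict:
            return {
                "name": p.name,
                "fraction": p.fraction,
                "t1_s": p.t1,
                "t2_s": p.t2,
                "exchange_rate_hz": p.exchange_rate,
                "chemical_shift_ppm": p.chemical_shift,
                "lineshape": p.lineshape,
            }

        return {"water": pool_d(self.water), "solutes": [pool_d(p) for p in self.solutes]}

    @classmethod
    def from_dict(cls, d: dict) -> "TissueModel":
        def pool(pd: dict) -> PoolSpec:
            return PoolSpec(
                name=pd["name"],
                fraction=pd["fraction"],
                t1=pd["t1_s"],
                t2=pd["t2_s"],
                exchange_rate=pd.get("exchange_rate_hz", 0.0),
                chemical_shift=pd.get("chemical_shift_ppm", 0.0),
                lineshape=pd.get("lineshape", "lorentzian"),
            )

        return cls(water=pool(d["water"]), solutes=tuple(pool(pd) for pd in d["solutes"]))


#: Interleaved acquisition order, high offsets first, alternating -/+ and
#: finishing on resonance.  21 offsets covering +/-2000 Hz in 200 Hz steps.
INTERLEAVED_OFFSETS_HZ: tuple[float, ...] = tuple(
    float(v)
    for pair in ((-o, o) for o in range(2000, 0, -200))
    for v in pair
) + (0.0,)


@dataclass(frozen=True)
class SequenceParams:
    """Saturation/readout scheme of the cardiac CEST acquisition.

    Defaults follow the 9.4 T cardiac protocol: a single 140 ms block pulse
    at 2 uT per TR of 398 ms, 15 degree FLASH readout, 21 interleaved
    offsets over +/-2000 Hz, and S0 references at +/-15 ppm.
    """

    b1: float = 2.0  # microtesla
    tsat: float = 0.140  # seconds
    tr: float = 0.398  # seconds
    flip_angle: float = 15.0  # degrees
    offsets_hz: tuple[float, ...] = INTERLEAVED_OFFSETS_HZ
    s0_offsets_ppm: tuple[float, float] = (15.0, -15.0)
    reference_frequency_mhz: float = 400.2  # 9.4 T proton Larmor frequency
    saturation_mode: str = "cumulative"  # or "single_shot"
    max_blocks: int = 200
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.tsat > self.tr:
            raise ValueError("tsat must not exceed tr")
        if self.b1 < 0:
            raise ValueError("b1 must be >= 0")
        if len(self.offsets_hz) == 0:
            raise ValueError("offsets_hz must be non-empty")
        if self.reference_frequency_mhz <= 0:
            raise ValueError("reference frequency must be > 0")
        if self.saturation_mode not in ("single_shot", "cumulative"):
            raise ValueError(f"unknown saturation mode {self.saturation_mode!r}")
        object.__setattr__(self, "offsets_hz", tuple(float(o) for o in self.offsets_hz))

    def ppm_to_hz(self, ppm: float) -> float:
        return ppm * self.reference_frequency_mhz

    def hz_to_ppm(self, hz: float) -> float:
        return hz / self.reference_frequency_mhz

    def to_dict(self) -> dict:
        return {
            "b1_uT": self.b1,
            "tsat_ms": self.tsat * 1e3,
            "tr_ms": self.tr * 1e3,
            "flip_angle_deg": self.flip_angle,
            "offsets_hz": list(self.offsets_hz),
            "s0_offsets_ppm": list(self.s0_offsets_ppm),
            "ref_freq_mhz": self.reference_frequency_mhz,
            "saturation_mode": self.saturation_mode,
            "max_blocks": self.max_blocks,
            "convergence_tol": self.convergence_tol,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceParams":
        return cls(
            b1=d["b1_uT"],
            tsat=d["tsat_ms"] / 1e3,
            tr=d["tr_ms"] / 1e3,
            flip_angle=d.get("flip_angle_deg", 15.0),
            offsets_hz=tuple(d["offsets_hz"]),
            s0_offsets_ppm=tuple(d.get("s0_offsets_ppm", (15.0, -15.0))),
            reference_frequency_mhz=d.get("ref_freq_mhz", 400.2),
            saturation_mode=d.get("saturation_mode", "cumulative"),
            max_blocks=d.get("max_blocks", 200),
            convergence_tol=d.get("convergence_tol", 1e-6),
        )


def load_preset(name_or_path: str | Path) -> tuple[TissueModel, SequenceParams]:
    """Load a (tissue, sequence) preset from a bundled name or a JSON path."""
    p = Path(name_or_path)
    if p.suffix == ".json" and p.exists():
        doc = json.loads(p.read_text())
    else:
        ref = resources.files("glucocest").joinpath(f"presets/{name_or_path}.json")
        doc = json.loads(ref.read_text())
    return TissueModel.from_dict(doc["tissue"]), SequenceParams.from_dict(doc["sequence"])


def cardiac_tissue(glucose_mM: float = 10.0) -> TissueModel:
    """The five-pool cardiac tissue model at a given glucose concentration.

    Water, a semisolid MT pool, glucose hydroxyl protons (fraction set from
    ``glucose_mM``), and fixed amine and amide pools.
    """
    return TissueModel(
        water=PoolSpec("water", 1.0, 1.429, 0.029),
        solutes=(
            PoolSpec("mt", 0.01, 1.0, 4.0e-5, 30.0, -3.0),
            PoolSpec("hydroxyl", glucose_hydroxyl_fraction(glucose_mM), 1.0, 0.1, 3500.0, 1.5),
            PoolSpec("amine", 0.000090, 1.0, 0.1, 5000.0, 3.0),
            PoolSpec("amide", 0.000135, 1.0, 0.1, 50.0, 3.5),
        ),
    )


def tube_tissue(glucose_mM: float) -> TissueModel:
    """PBS glucose tube: water plus a single hydroxyl pool.

    The water T2 is an effective value (0.1 s) short enough that the Rabi
    transient of the 140 ms block pulse damps out within the pulse, as the
    usable phantom spectra of this protocol imply; with the seconds-long T2
    of neat water the 21-point spectrum would alias the undamped
    oscillation and no offset sampling could recover it.
    """
    return TissueModel(
        water=PoolSpec("water", 1.0, 3.0, 0.1),
        solutes=(
            PoolSpec("hydroxyl", glucose_hydroxyl_fraction(glucose_mM), 1.0, 0.1, 3500.0, 1.5),
        ),
    )
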