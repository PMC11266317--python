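"""HU to 177Lu mu-map conversion and resampling to the SPECT grid.

The conversion follows the standard bilinear model with a breakpoint at
HU = 0: below it, attenuation scales as a water/air mixture,
``mu = mu_water * (HU + 1000) / 1000`` (clipped at 0); above it, a
kVp-dependent bone slope applies, ``mu = mu_water + HU * slope(kVp)``.  The
bone slopes are calibrated in-repo from two reference materials (water and a
cortical-bone-like solid) at each tube potential's effective CT energy; the
vendor's exact conversion curve is proprietary, so this is an emulation of
its behaviour, not a transcription.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ct import EFFECTIVE_ENERGY_KEV
from .grids import HUVolume, MuMap, VoxelGrid, resample_trilinear
from .physics import LU177_KEV, linear_attenuation, load_material_registry

__all__ = ["BilinearModel", "default_bilinear_model", "hu_to_mu", "resample_mu"]


@dataclass(frozen=True)
class BilinearModel:
    """Piecewise-linear HU -> mu(208.4 keV) conversion."""

    mu_water: float  # cm^-1 at the target (emission) energy
    bone_slope: dict[int, float] = field(default_factory=dict)  # cm^-1 per HU, per kVp
    breakpoint_hu: float = 0.0
    energy_kev: float = LU177_KEV

    def __post_init__(self) -> None:
        if self.mu_water <= 0:
            raise ValueError("mu_water must be positive")
        if any(s <= 0 for s in self.bone_slope.values()):
            raise ValueError("bone slopes must be positive")

    @property
    def soft_slope(self) -> float:
        """Slope of the soft-tissue branch (cm^-1 per HU)."""
        return self.mu_water / 1000.0

    @classmethod
    def calibrate(
        cls,
        registry=None,
        energy_kev: float = LU177_KEV,
        effective_energies: dict[int, float] | None = None,
        bone_material: str = "cortical_bone",
    ) -> "BilinearModel":
        """Calibrate from water plus one bone-like material per kVp."""
        reg = registry or load_material_registry()
        eff = effective_energies or EFFECTIVE_ENERGY_KEV
        mu_w_t = linear_attenuation(reg["water"], energy_kev)
        mu_b_t = linear_attenuation(reg[bone_material], energy_kev)
        slopes = {}
        for kvp, e in eff.items():
            mu_w = linear_attenuation(reg["water"], e)
            hu_bone = 1000.0 * (linear_attenuation(reg[bone_material], e) - mu_w) / mu_w
            slopes[kvp] = (mu_b_t - mu_w_t) / hu_bone
        return cls(mu_water=mu_w_t, bone_slope=slopes, energy_kev=energy_kev)


_DEFAULT_MODEL: BilinearModel | None = None


def default_bilinear_model() -> BilinearModel:
    """The packaged calibration (cached)."""
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = BilinearModel.calibrate()
    return _DEFAULT_MODEL


def hu_to_mu(hu: HUVolume, model: BilinearModel | None = None, kvp: int = 130) -> MuMap:
    """Convert a HU volume to a mu-map at the model's emission energy."""
    model = model or default_bilinear_model()
    if kvp not in model.bone_slope:
        raise KeyError(f"no bone slope calibrated for {kvp} kVp")
    v = np.asarray(hu.values, dtype=float)
    soft = np.maximum(model.mu_water * (v + 1000.0) / 1000.0, 0.0)
    bone = model.mu_water + v * model.bone_slope[kvp]
    mu = np.where(v <= model.breakpoint_hu, soft, bone)
    return MuMap(hu.grid, mu, energy_kev=model.energy_kev)


def resample_mu(mu: MuMap, target: VoxelGrid, outside: str = "error") -> MuMap:
    """Trilinear resampling of a mu-map (e.g. CT grid -> SPECT grid).

    ``outside='fill'`` pads beyond the source extent with mu = 0 (air), for
    target grids with a larger field of view than the CT.
    """
    values = resample_trilinear(mu, target, outside=outside, fill=0.0)
    return MuMap(target, np.maximum(values, 0.0), energy_kev=mu.energy_kev)
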