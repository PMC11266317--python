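"""Low-dose CT emulation: HU synthesis, noise model and CTDI_vol fixture.

The emulator stands in for the scanner and its iterative CT reconstruction.
For a given tube potential (kVp) and quality-reference mAs (QRM) it produces

* an ideal HU volume, ``HU = 1000 (mu_mat(E_eff) - mu_water(E_eff)) /
  mu_water(E_eff)``, evaluated at the setting's effective monoenergetic
  energy (a packaged per-kVp constant representing spectrum plus filtration
  plus beam-hardening calibration);
* Gaussian voxel noise of a per-setting sigma (HU), strictly decreasing with
  both kVp and QRM;
* a per-acquisition global HU offset emulating scan-to-scan calibration
  drift — the component that dominates the between-repetition variability of
  mu-map VOI means at clinical VOI sizes.

The offset sigma is not a free dial: it is derived in closed form per setting
from a packaged target coefficient of variation of repeated mu-map VOI means
(spanning 2.95e-3 to 3.8e-3 across the seven studied settings), propagated
through the bilinear HU-to-mu conversion; see :func:`offset_sigma_hu`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.stats import norm

from .grids import HUVolume, LabelVolume
from .physics import LU177_KEV, MaterialSpec, linear_attenuation, load_material_registry

__all__ = [
    "EFFECTIVE_ENERGY_KEV",
    "STUDIED_SETTINGS",
    "ScanSetting",
    "studied_settings",
    "emulate_ct",
    "ctdi_lookup",
    "offset_sigma_hu",
]

#: Effective monoenergetic CT energy per tube potential (keV).
EFFECTIVE_ENERGY_KEV = {80: 58.0, 110: 66.0, 130: 72.0}

#: The seven (kVp, QRM) combinations studied.
STUDIED_SETTINGS: tuple[tuple[int, int], ...] = (
    (80, 20), (80, 35), (80, 50), (110, 20), (110, 35), (130, 20), (130, 35),
)

#: Per-setting HU voxel-noise sigma (strictly decreasing in kVp and QRM).
VOXEL_SIGMA_HU = {
    (80, 20): 35.0, (80, 35): 28.0, (80, 50): 24.0,
    (110, 20): 22.0, (110, 35): 18.0,
    (130, 20): 18.0, (130, 35): 15.0,
}

#: Target coefficient of variation of repeated mu-map VOI means, used to
#: derive the calibration-drift sigma (see module docstring).
TARGET_COV = {
    (80, 20): 3.55e-3, (80, 35): 3.45e-3, (80, 50): 3.35e-3,
    (110, 20): 3.30e-3, (110, 35): 3.20e-3,
    (130, 20): 3.25e-3, (130, 35): 3.15e-3,
}

#: CTDI_vol anchors (mGy); other QRM values scale linearly in mAs.
_CTDI_ANCHORS = {(80, 20): 0.9, (110, 20): 1.5, (130, 20): 2.0, (130, 35): 3.6}


def ctdi_lookup(kvp: int, qrm: float) -> float:
    """CTDI_vol (mGy) for a setting; linear-in-mAs at fixed kVp off-anchor."""
    if kvp not in EFFECTIVE_ENERGY_KEV:
        raise ValueError(f"kVp {kvp} not in {sorted(EFFECTIVE_ENERGY_KEV)}")
    if (kvp, qrm) in _CTDI_ANCHORS:
        return _CTDI_ANCHORS[(kvp, qrm)]
    ref_qrm = max(q for k, q in _CTDI_ANCHORS if k == kvp)
    return _CTDI_ANCHORS[(kvp, ref_qrm)] * qrm / ref_qrm


def _c4(n: int) -> float:
    """Unbiasing constant E[sample SD]/sigma for a normal sample of size n."""
    return math.sqrt(2.0 / (n - 1)) * math.gamma(n / 2) / math.gamma((n - 1) / 2)


def offset_sigma_hu(
    kvp: int,
    qrm: int,
    repetitions: int = 10,
    voi_voxels: int = 8000,
) -> float:
    """Per-acquisition HU calibration-drift sigma for a studied setting.

    Solves the packaged target COV for the drift sigma: the expected sample
    SD (over ``repetitions`` scans) of the plastic-water VOI mean of the
    mu-map, divided by its mean, propagated through the piecewise-linear
    HU-to-mu conversion around the plastic-water operating point.
    """
    from .mumap import default_bilinear_model  # local import: avoids a cycle

    model = default_bilinear_model()
    reg = load_material_registry()
    e_eff = EFFECTIVE_ENERGY_KEV[kvp]
    mu_w = linear_attenuation(reg["water"], e_eff)
    m = 1000.0 * (linear_attenuation(reg["plastic_water"], e_eff) - mu_w) / mu_w
    s_vox = VOXEL_SIGMA_HU[(kvp, qrm)]
    s_soft = model.soft_slope
    s_bone = model.bone_slope[kvp]
    p_lo = norm.cdf(-m / s_vox)
    p_hi = 1.0 - p_lo
    phi = norm.pdf(m / s_vox)
    # Mean mu and mean local slope of the conversion at the operating point.
    mu_mean = (
        model.mu_water
        + s_soft * (m * p_lo - s_vox * phi)
        + s_bone * (m * p_hi + s_vox * phi)
    )
    slope_eff = s_soft * p_lo + s_bone * p_hi
    # Voxel-noise contribution to the SD of a repetition's VOI mean.
    sd_vox_mu = s_vox * math.sqrt(s_soft**2 * p_lo + s_bone**2 * p_hi) / math.sqrt(voi_voxels)
    target_sd = TARGET_COV[(kvp, qrm)] * mu_mean / _c4(repetitions)
    return math.sqrt(max(target_sd**2 - sd_vox_mu**2, 0.0)) / slope_eff


@dataclass(frozen=True)
class ScanSetting:
    """One (kVp, QRM) acquisition configuration of the CT emulator."""

    kvp: int
    qrm: int
    ctdi_vol_mgy: float
    sigma_hu: float
    offset_sigma_hu: float
    effective_energy_kev: float
    smoothing_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kvp not in EFFECTIVE_ENERGY_KEV:
            raise ValueError(f"kVp {self.kvp} not in {sorted(EFFECTIVE_ENERGY_KEV)}")
        if self.sigma_hu < 0 or self.offset_sigma_hu < 0:
            raise ValueError("noise sigmas must be non-negative")

    @classmethod
    def from_protocol(cls, kvp: int, qrm: int, seed: int = 0, **overrides) -> "ScanSetting":
        """Build a setting from the packaged scanner model.

        Only the seven studied (kVp, QRM) combinations are packaged; anything
        else requires explicit ``sigma_hu``/``offset_sigma_hu`` overrides.
        """
        if (kvp, qrm) in STUDIED_SETTINGS:
            base = dict(
                ctdi_vol_mgy=ctdi_lookup(kvp, qrm),
                sigma_hu=VOXEL_SIGMA_HU[(kvp, qrm)],
                offset_sigma_hu=offset_sigma_hu(kvp, qrm),
                effective_energy_kev=EFFECTIVE_ENERGY_KEV[kvp],
            )
        else:
            if not {"sigma_hu", "offset_sigma_hu"} <= overrides.keys():
                raise ValueError(
                    f"({kvp}, {qrm}) is not a studied combination; "
                    "supply sigma_hu and offset_sigma_hu explicitly"
                )
            base = dict(
                ctdi_vol_mgy=overrides.get("ctdi_vol_mgy", ctdi_lookup(kvp, qrm)),
                effective_energy_kev=EFFECTIVE_ENERGY_KEV[kvp],
            )
        base.update(overrides)
        return cls(kvp=kvp, qrm=qrm, seed=seed, **base)

    def with_seed(self, seed: int) -> "ScanSetting":
        return replace(self, seed=seed)


def studied_settings(seed: int = 0) -> list[ScanSetting]:
    """The seven packaged scan settings, sharing a base seed."""
    return [ScanSetting.from_protocol(k, q, seed=seed) for k, q in STUDIED_SETTINGS]


def emulate_ct(
    labels: LabelVolume,
    setting: ScanSetting,
    registry: dict[str, MaterialSpec] | None = None,
    rng: np.random.Generator | None = None,
) -> HUVolume:
    """Emulated CT acquisition of a label volume under one scan setting.

    Ideal per-material HU at the setting's effective energy, plus a global
    per-acquisition offset, plus voxel noise, plus optional in-plane Gaussian
    smoothing.  Reproducible: a given ``setting.seed`` (or an explicit
    ``rng``) yields a bit-identical volume.
    """
    reg = registry or load_material_registry()
    e_eff = setting.effective_energy_kev
    mu_w = linear_attenuation(reg["water"], e_eff)
    lut = np.zeros(int(max(labels.legend)) + 1)
    for lab, mat in labels.legend.items():
        lut[lab] = 1000.0 * (linear_attenuation(reg[mat], e_eff) - mu_w) / mu_w
    hu = lut[labels.values]

    if rng is None:
        rng = np.random.default_rng(setting.seed)
    if setting.offset_sigma_hu > 0:
        hu = hu + rng.normal(0.0, setting.offset_sigma_hu)
    if setting.sigma_hu > 0:
        hu = hu + rng.normal(0.0, setting.sigma_hu, size=hu.shape)
    if setting.smoothing_sigma_mm > 0:
        sig = [setting.smoothing_sigma_mm / s for s in labels.grid.spacing[:2]] + [0.0]
        hu = ndimage.gaussian_filter(hu, sigma=sig)
    return HUVolume(labels.grid, np.maximum(hu, -1024.0))
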