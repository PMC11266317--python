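"""Theoretical photon attenuation of elements and tissue-equivalent mixtures.

Linear attenuation coefficients are obtained from packaged elemental mass
attenuation tables via the standard mixture rule

    (mu/rho)_mixture(E) = sum_i w_i * (mu/rho)_i(E),
    mu(E) = rho * (mu/rho)_mixture(E),

with ``w_i`` the elemental mass fractions and ``rho`` the bulk density.  The
primary use is evaluating the reference mu of phantom materials at the
208.4 keV gamma emission of 177Lu, against which CT-derived mu-maps are
compared.

Elemental tables are plain-text package data covering 40-400 keV; lookups
between grid points use log-log linear interpolation, the standard scheme for
photon cross sections in this energy range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "LU177_KEV",
    "AttenuationTable",
    "MaterialSpec",
    "ElementNotFoundError",
    "EnergyRangeError",
    "load_attenuation_tables",
    "lookup_mass_attenuation",
    "mixture_mass_attenuation",
    "linear_attenuation",
    "theoretical_mu_table",
    "load_material_registry",
]

#: Main gamma emission of 177Lu (keV).
LU177_KEV = 208.4


class ElementNotFoundError(KeyError):
    """No packaged attenuation table for the requested element."""


class EnergyRangeError(ValueError):
    """Requested energy outside the tabulated grid (no extrapolation)."""


@dataclass(frozen=True)
class AttenuationTable:
    """Mass attenuation coefficients of one element on an energy grid."""

    element: str
    energies_kev: np.ndarray  # strictly increasing
    mu_over_rho: np.ndarray  # cm^2/g, aligned to the grid

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_kev, dtype=float)
        v = np.asarray(self.mu_over_rho, dtype=float)
        if e.ndim != 1 or e.shape != v.shape:
            raise ValueError("energy grid and values must be 1-D and aligned")
        if not np.all(np.diff(e) > 0):
            raise ValueError(f"energy grid for {self.element} must be strictly increasing")
        if not np.all(v > 0):
            raise ValueError(f"attenuation values for {self.element} must be positive")
        object.__setattr__(self, "energies_kev", e)
        object.__setattr__(self, "mu_over_rho", v)

    def __call__(self, energy_kev: float) -> float:
        """Log-log interpolated mass attenuation at ``energy_kev`` (cm^2/g)."""
        e, v = self.energies_kev, self.mu_over_rho
        if energy_kev < e[0] or energy_kev > e[-1]:
            raise EnergyRangeError(
                f"{energy_kev} keV outside [{e[0]:g}, {e[-1]:g}] keV grid of {self.element}"
            )
        i = int(np.searchsorted(e, energy_kev))
        if e[min(i, len(e) - 1)] == energy_kev:
            return float(v[min(i, len(e) - 1)])
        if i > 0 and e[i - 1] == energy_kev:
            return float(v[i - 1])
        lo, hi = i - 1, i
        t = (math.log(energy_kev) - math.log(e[lo])) / (math.log(e[hi]) - math.log(e[lo]))
        return float(math.exp((1 - t) * math.log(v[lo]) + t * math.log(v[hi])))


@dataclass(frozen=True)
class MaterialSpec:
    """Elemental mass fractions and mass density of one material."""

    name: str
    mass_fractions: dict[str, float] = field(default_factory=dict)
    density_g_cm3: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mass fractions of {self.name!r} sum to {total}, not 1")
        if self.density_g_cm3 < 0:
            raise ValueError(f"negative density for {self.name!r}")


_TABLES: dict[str, AttenuationTable] | None = None


def load_attenuation_tables() -> dict[str, AttenuationTable]:
    """Packaged elemental tables, keyed by element symbol (cached)."""
    global _TABLES
    if _TABLES is None:
        raw: dict[str, list[tuple[float, float]]] = {}
        text = resources.files("muquant.data").joinpath("elements.tsv").read_text()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("element\t"):
                continue
            sym, e_kev, val = line.split("\t")
            raw.setdefault(sym, []).append((float(e_kev), float(val)))
        _TABLES = {
            sym: AttenuationTable(sym, np.array([e for e, _ in rows]), np.array([v for _, v in rows]))
            for sym, rows in raw.items()
        }
    return _TABLES


def lookup_mass_attenuation(element: str, energy_kev: float) -> float:
    """Elemental mass attenuation coefficient (cm^2/g) at ``energy_kev``."""
    tables = load_attenuation_tables()
    try:
        table = tables[element]
    except KeyError:
        raise ElementNotFoundError(element) from None
    return table(energy_kev)


def mixture_mass_attenuation(material: MaterialSpec, energy_kev: float) -> float:
    """Mixture-rule mass attenuation (cm^2/g): sum_i w_i (mu/rho)_i."""
    return float(
        sum(w * lookup_mass_attenuation(el, energy_kev) for el, w in material.mass_fractions.items())
    )


def linear_attenuation(material: MaterialSpec, energy_kev: float = LU177_KEV) -> float:
    """Theoretical linear attenuation coefficient mu (cm^-1) of a material."""
    return material.density_g_cm3 * mixture_mass_attenuation(material, energy_kev)


def theoretical_mu_table(
    materials: list[MaterialSpec], energy_kev: float = LU177_KEV
) -> dict[str, float]:
    """Batch mu lookup: one ``name -> mu (cm^-1)`` entry per material."""
    if not materials:
        raise ValueError("empty material list")
    names = [m.name for m in materials]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate material names: {dupes}")
    return {m.name: linear_attenuation(m, energy_kev) for m in materials}


def load_material_registry(path: str | None = None) -> dict[str, MaterialSpec]:
    """Material registry (name -> :class:`MaterialSpec`).

    With no ``path``, loads the packaged registry of tissue surrogates,
    phantom plastics and reference media.  A user file with the same YAML
    schema (e.g. a manufacturer datasheet transcription) can be supplied
    instead.
    """
    import yaml

    if path is None:
        text = resources.files("muquant.data").joinpath("materials.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    registry = {}
    for name, spec in doc["materials"].items():
        registry[name] = MaterialSpec(
            name=name,
            mass_fractions=dict(spec["composition"]),
            density_g_cm3=float(spec["density"]),
        )
    return registry
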