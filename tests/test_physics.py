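"""Elemental lookups, the mixture rule and theoretical mu values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from muquant.physics import (
    LU177_KEV,
    ElementNotFoundError,
    EnergyRangeError,
    MaterialSpec,
    linear_attenuation,
    load_attenuation_tables,
    load_material_registry,
    lookup_mass_attenuation,
    mixture_mass_attenuation,
    theoretical_mu_table,
)


def test_grid_energies_reproduce_tabulated_values_exactly():
    for table in load_attenuation_tables().values():
        for e, v in zip(table.energies_kev, table.mu_over_rho):
            assert lookup_mass_attenuation(table.element, float(e)) == v


def test_interpolation_is_monotone_bracketing():
    # Compton-dominated region: values decrease with energy, so any
    # off-grid energy must fall strictly between its bracketing entries.
    v200 = lookup_mass_attenuation("O", 200.0)
    v300 = lookup_mass_attenuation("O", 300.0)
    v = lookup_mass_attenuation("O", LU177_KEV)
    assert v300 < v < v200


def test_log_log_interpolation_matches_hand_evaluation():
    # Independent 3-line oracle: exp of linear interpolation in log-log space.
    t = load_attenuation_tables()["H"]
    e_lo, e_hi = 200.0, 300.0
    v_lo = float(t.mu_over_rho[list(t.energies_kev).index(e_lo)])
    v_hi = float(t.mu_over_rho[list(t.energies_kev).index(e_hi)])
    frac = (math.log(250.0) - math.log(e_lo)) / (math.log(e_hi) - math.log(e_lo))
    expected = math.exp(math.log(v_lo) + frac * (math.log(v_hi) - math.log(v_lo)))
    assert lookup_mass_attenuation("H", 250.0) == pytest.approx(expected, rel=1e-12)


def test_lookup_errors():
    with pytest.raises(ElementNotFoundError):
        lookup_mass_attenuation("Xx", 200.0)
    with pytest.raises(EnergyRangeError):
        lookup_mass_attenuation("O", 10.0)
    with pytest.raises(EnergyRangeError):
        lookup_mass_attenuation("O", 1000.0)


def test_single_element_mixture_degenerates_to_lookup():
    m = MaterialSpec("pure_carbon", {"C": 1.0}, 2.0)
    assert mixture_mass_attenuation(m, 150.0) == pytest.approx(
        lookup_mass_attenuation("C", 150.0), rel=1e-14
    )


def test_water_mixture_matches_bruteforce_sum():
    w = MaterialSpec("w", {"H": 0.1119, "O": 0.8881}, 0.998)
    expected = 0.1119 * lookup_mass_attenuation("H", LU177_KEV) + 0.8881 * lookup_mass_attenuation(
        "O", LU177_KEV
    )
    assert mixture_mass_attenuation(w, LU177_KEV) == pytest.approx(expected, rel=1e-14)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    w=st.floats(0.01, 0.99),
    energy=st.floats(45.0, 395.0),
)
def test_mixture_bounded_by_elemental_values(w, energy):
    m = MaterialSpec("mix", {"H": w, "C": 1.0 - w}, 1.0)
    lo = min(lookup_mass_attenuation(e, energy) for e in ("H", "C"))
    hi = max(lookup_mass_attenuation(e, energy) for e in ("H", "C"))
    assert lo - 1e-12 <= mixture_mass_attenuation(m, energy) <= hi + 1e-12


def test_linear_attenuation_scales_with_density():
    comp = {"H": 0.1119, "O": 0.8881}
    base = linear_attenuation(MaterialSpec("w1", comp, 1.0), LU177_KEV)
    assert linear_attenuation(MaterialSpec("w0", comp, 0.0), LU177_KEV) == 0.0
    assert linear_attenuation(MaterialSpec("w2", comp, 2.0), LU177_KEV) == pytest.approx(
        2 * base, rel=1e-12
    )


def test_material_invariants_enforced():
    with pytest.raises(ValueError):
        MaterialSpec("bad", {"H": 0.6, "O": 0.3}, 1.0)  # fractions sum to 0.9
    with pytest.raises(ValueError):
        MaterialSpec("bad", {"H": 1.0}, -1.0)


def test_mu_table_full_registry(registry):
    table = theoretical_mu_table(list(registry.values()))
    assert len(table) == len(registry) == 19
    # Air mu is computed (N/O/Ar at 1.2 mg/cm^3), not asserted as zero.
    assert 0.0 < table["air"] < 2e-4


def test_mu_table_errors(registry):
    with pytest.raises(ValueError):
        theoretical_mu_table([])
    w = registry["water"]
    with pytest.raises(ValueError, match="duplicate"):
        theoretical_mu_table([w, w])
    single = theoretical_mu_table([w])
    assert single == {"water": linear_attenuation(w)}


def test_soft_tissue_mass_attenuation_in_compton_band(registry):
    # At 208.4 keV all soft-tissue surrogates sit in the Compton-dominated
    # 0.12-0.15 cm^2/g band.
    soft = ["lung_inhale", "lung_exhale", "adipose", "breast", "muscle",
            "liver", "soft_tissue", "water", "plastic_water"]
    for name in soft:
        assert 0.12 <= mixture_mass_attenuation(registry[name], LU177_KEV) <= 0.15
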