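"""Shared fixtures: registry electrolytes and synthetic systems.

Everything is generated programmatically; the only on-disk inputs are the
package's own registry files.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from monoion.bulk import ElectrolyteSpec, IonSpec, PropertyTable
from monoion.io import load_electrolyte
from monoion.isotherm import (
    build_field,
    induced_adsorption_isobaric,
    induced_adsorption_isochemical,
)
from monoion.synthetic import build_system, sample_isotherms


def make_11_electrolyte(R0_cat=0.98e-10, R0_an=1.81e-10, *,
                        gamma_table=None, name="test-1:1", V_el=0.0,
                        eps_table=None, molar_mass=0.0,
                        density_model=None) -> ElectrolyteSpec:
    """Minimal 1:1 electrolyte for targeted unit tests."""
    if gamma_table is None:
        m = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        gamma_table = PropertyTable(m, np.ones_like(m), name="unit gamma")
    return ElectrolyteSpec(
        name=name,
        cation=IonSpec("cat+", 1, R0_cat, "cation"),
        anion=IonSpec("an-", 1, R0_an, "anion"),
        nu_plus=1, nu_minus=1, V_el=V_el, molar_mass=molar_mass,
        activity_table=gamma_table, eps_table=eps_table,
        density_model=density_model)


@pytest.fixture(scope="session")
def nacl():
    return load_electrolyte("NaCl")


@pytest.fixture(scope="session")
def kbr():
    return load_electrolyte("KBr")


@pytest.fixture(scope="session")
def cacl2():
    return load_electrolyte("CaCl2")


@pytest.fixture(scope="session")
def system():
    return build_system(seed=0)


@pytest.fixture(scope="session")
def sampled(system):
    return sample_isotherms(system)


@pytest.fixture(scope="session")
def field(system, sampled):
    curves, series = sampled
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_field(curves, series, system.spec)


@pytest.fixture(scope="session")
def profiles(field):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        A = induced_adsorption_isochemical(field)
        B = induced_adsorption_isobaric(field)
    return A, B
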