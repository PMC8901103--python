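"""Shared fixtures: grid profiles, cached toy systems, synthetic wavefunction files."""

import numpy as np
import pytest

import iqfcp as q
from iqfcp.coulomb import CoulombEngine
from iqfcp.qtaim import assign_basins
from iqfcp.toys import make_toy_dimer, toy_preset

#: reduced profile used for tolerance-bearing checks
TEST_SPEC = q.AtomGridSpec.test_profile()
#: very small profile for plumbing-only tests (no tight tolerances asserted)
CHEAP_SPEC = q.AtomGridSpec(inner_angular=50, inner_radial=30,
                            outer_angular=110, outer_radial=45)


@pytest.fixture(scope="session")
def test_spec():
    return TEST_SPEC


@pytest.fixture(scope="session")
def cheap_spec():
    return CHEAP_SPEC


@pytest.fixture(scope="session")
def hf_system():
    """Heteronuclear 2-atom contact dimer with grid/partition/engine (test profile)."""
    a, b, frag = make_toy_dimer(toy_preset("hf"))
    rho0 = q.ComplexDensity([a, b])
    grid = q.build_grid(rho0, TEST_SPEC)
    part = assign_basins(rho0, grid, frag)
    return a, b, rho0, grid, part, CoulombEngine(part, grid)


@pytest.fixture(scope="session")
def disp_system():
    """Mirror-symmetric apolar dimer with grid/partition/engine (test profile)."""
    a, b, frag = make_toy_dimer(toy_preset("disp"))
    rho0 = q.ComplexDensity([a, b])
    grid = q.build_grid(rho0, TEST_SPEC)
    part = assign_basins(rho0, grid, frag)
    return a, b, rho0, grid, part, CoulombEngine(part, grid)


def _norm_s(alpha: float) -> float:
    return (2.0 * alpha / np.pi) ** 0.75


@pytest.fixture()
def h_atom_wfx(tmp_path):
    """Synthetic 1-electron, 1-primitive wfx file (exact count 1.0)."""
    alpha = 0.8
    c = _norm_s(alpha)
    text = f"""<Number of Nuclei>
 1
</Number of Nuclei>
<Atomic Numbers>
 1
</Atomic Numbers>
<Nuclear Cartesian Coordinates>
 0.0 0.0 0.0
</Nuclear Cartesian Coordinates>
<Number of Occupied Molecular Orbitals>
 1
</Number of Occupied Molecular Orbitals>
<Molecular Orbital Occupation Numbers>
 1.0
</Molecular Orbital Occupation Numbers>
<Primitive Centers>
 1
</Primitive Centers>
<Primitive Types>
 1
</Primitive Types>
<Primitive Exponents>
 {alpha}
</Primitive Exponents>
<Molecular Orbital Primitive Coefficients>
<MO Number>
 1
</MO Number>
 {c}
</Molecular Orbital Primitive Coefficients>
"""
    p = tmp_path / "h_synthetic.wfx"
    p.write_text(text)
    return p


@pytest.fixture()
def h2_wfx(tmp_path):
    """Synthetic H2-like wfx: one doubly occupied bonding MO (count 2.0)."""
    alpha, R = 1.8, 1.4
    S = np.exp(-alpha * R**2 / 2.0)
    c = _norm_s(alpha) / np.sqrt(2.0 * (1.0 + S))
    text = f"""<Number of Nuclei>
 2
</Number of Nuclei>
<Atomic Numbers>
 1 1
</Atomic Numbers>
<Nuclear Cartesian Coordinates>
 0.0 0.0 0.0
 0.0 0.0 {R}
</Nuclear Cartesian Coordinates>
<Molecular Orbital Occupation Numbers>
 2.0
</Molecular Orbital Occupation Numbers>
<Primitive Centers>
 1 2
</Primitive Centers>
<Primitive Types>
 1 1
</Primitive Types>
<Primitive Exponents>
 {alpha} {alpha}
</Primitive Exponents>
<Molecular Orbital Primitive Coefficients>
<MO Number>
 1
</MO Number>
 {c} {c}
</Molecular Orbital Primitive Coefficients>
"""
    p = tmp_path / "h2_synthetic.wfx"
    p.write_text(text)
    return p


@pytest.fixture()
def h2_molden(tmp_path):
    """Synthetic minimal molden file: two H, one s shell each, one doubly occupied MO."""
    alpha, R = 1.8, 1.4
    S = np.exp(-alpha * R**2 / 2.0)
    c = 1.0 / np.sqrt(2.0 * (1.0 + S))
    text = f"""[Molden Format]
[Atoms] AU
H 1 1 0.0 0.0 0.0
H 2 1 0.0 0.0 {R}
[GTO]
1 0
 s 1 1.00
  {alpha} 1.0

2 0
 s 1 1.00
  {alpha} 1.0

[MO]
Sym= A
Ene= -0.5
Spin= Alpha
Occup= 2.0
  1 {c}
  2 {c}
"""
    p = tmp_path / "h2_synthetic.molden"
    p.write_text(text)
    return p
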