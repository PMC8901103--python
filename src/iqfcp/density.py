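"""Charge-density models: nuclei plus atom-centered spherical Gaussian clouds.

A fragment density is represented as point nuclei (+Z_I at R_I) together with
an electron density written as a sum of spherical Gaussian primitives, each
integrating to its population q:

    rho_e(r) = sum_k q_k (alpha_k / pi)^{3/2} exp(-alpha_k |r - c_k|^2)

This "promolecular" form is a synthetic stand-in for ab initio monomer
densities: it is nonnegative, integrates to a prescribed electron count, has
analytic gradients and analytic Coulomb potentials (via the error function),
and can be given an intramolecular dipole by splitting an atom's population
over two displaced primitives (the *polarized* mode).

All positions and exponents are in atomic units; geometry input helpers
convert from angstrom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ATOMIC_NUMBER, BOHR_PER_ANGSTROM, DEFAULT_EXPONENTS
from .errors import GeometryError, ParameterizationError

__all__ = [
    "Nucleus",
    "GaussianPrimitive",
    "GaussianDensity",
    "ComplexDensity",
    "build_promolecule",
    "polarize_atom",
    "evaluate_density",
    "evaluate_gradient",
    "analytic_potential",
    "read_xyz",
    "write_xyz",
]

_MIN_NUCLEAR_SEPARATION = 1e-6  # bohr

#: process-unique tokens identifying density objects in downstream caches
#: (id() is unsafe: it can be reused after garbage collection)
_CACHE_TOKEN = itertools.count()


@dataclass(frozen=True)
class Nucleus:
    """A point nucleus: element symbol, charge Z (e) and position (bohr)."""

    symbol: str
    Z: float
    position: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.Z <= 0:
            raise GeometryError(f"nuclear charge must be positive, got Z={self.Z}")
        if not np.all(np.isfinite(self.position)) or self.position.shape != (3,):
            raise GeometryError("nuclear position must be a finite 3-vector")


@dataclass(frozen=True)
class GaussianPrimitive:
    """Spherical Gaussian cloud integrating to ``population`` electrons."""

    center: np.ndarray
    exponent: float
    population: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.exponent <= 0:
            raise ParameterizationError(f"Gaussian exponent must be > 0, got {self.exponent}")
        if self.population < 0:
            raise ParameterizationError("primitive population must be >= 0 (density nonnegativity)")


@dataclass
class GaussianDensity:
    """A fragment: nuclei plus a Gaussian electron-density expansion."""

    nuclei: list[Nucleus]
    primitives: list[GaussianPrimitive]
    label: str = ""

    def __post_init__(self):
        self._cache_token = next(_CACHE_TOKEN)
        pos = self.positions
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if np.linalg.norm(pos[i] - pos[j]) <= _MIN_NUCLEAR_SEPARATION:
                    raise GeometryError(
                        f"nuclei {i} and {j} of fragment '{self.label}' coincide"
                    )

    # -- basic views ---------------------------------------------------
    @property
    def positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nuclei]).reshape(-1, 3)

    @property
    def charges(self) -> np.ndarray:
        return np.array([n.Z for n in self.nuclei])

    @property
    def electron_count(self) -> float:
        return float(sum(p.population for p in self.primitives))

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum() - self.electron_count)

    def _prim_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        c = np.array([p.center for p in self.primitives]).reshape(-1, 3)
        a = np.array([p.exponent for p in self.primitives])
        q = np.array([p.population for p in self.primitives])
        return c, a, q

    # -- evaluation ----------------------------------------------------
    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Electron density (e/bohr^3) at (N, 3) points."""
        pts = _check_points(points)
        c, a, q = self._prim_arrays()
        if len(q) == 0:
            return np.zeros(pts.shape[0])
        d2 = np.sum((pts[:, None, :] - c[None, :, :]) ** 2, axis=2)
        amp = q * (a / np.pi) ** 1.5
        return np.exp(-d2 * a[None, :]) @ amp

    def gradient(self, points: np.ndarray) -> np.ndarray:
        """Analytic density gradient (e/bohr^4) at (N, 3) points."""
        pts = _check_points(points)
        c, a, q = self._prim_arrays()
        if len(q) == 0:
            return np.zeros_like(pts)
        diff = pts[:, None, :] - c[None, :, :]
        d2 = np.sum(diff**2, axis=2)
        amp = q * (a / np.pi) ** 1.5
        terms = np.exp(-d2 * a[None, :]) * amp[None, :]  # (N, K)
        return np.einsum("nk,nkx->nx", terms * (-2.0 * a[None, :]), diff)

    def density_and_gradient(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fused density + gradient evaluation (used heavily by basin ascent)."""
        pts = _check_points(points)
        c, a, q = self._prim_arrays()
        if len(q) == 0:
            return np.zeros(pts.shape[0]), np.zeros_like(pts)
        diff = pts[:, None, :] - c[None, :, :]
        d2 = np.sum(diff**2, axis=2)
        amp = q * (a / np.pi) ** 1.5
        terms = np.exp(-d2 * a[None, :]) * amp[None, :]
        rho = terms.sum(axis=1)
        grad = np.einsum("nk,nkx->nx", terms * (-2.0 * a[None, :]), diff)
        return rho, grad

    def electron_potential(self, points: np.ndarray) -> np.ndarray:
        """Coulomb potential magnitude of the electron cloud (hartree/e).

        Per primitive ``q erf(sqrt(alpha) r)/r`` with the analytic limit
        ``q * 2 sqrt(alpha/pi)`` at r = 0.  The sign convention is "cloud
        treated as positive charge"; energy assembly applies electron signs.
        """
        from scipy.special import erf

        pts = _check_points(points)
        c, a, q = self._prim_arrays()
        if len(q) == 0:
            return np.zeros(pts.shape[0])
        r = np.linalg.norm(pts[:, None, :] - c[None, :, :], axis=2)
        sa = np.sqrt(a)[None, :]
        small = r < 1e-12
        rsafe = np.where(small, 1.0, r)
        v = erf(sa * rsafe) / rsafe
        v = np.where(small, 2.0 * sa / np.sqrt(np.pi), v)
        return v @ q

    def nuclear_potential(self, points: np.ndarray) -> np.ndarray:
        """Point-nuclei Coulomb potential Z/r (hartree/e)."""
        pts = _check_points(points)
        r = np.linalg.norm(pts[:, None, :] - self.positions[None, :, :], axis=2)
        return (1.0 / np.maximum(r, 1e-12)) @ self.charges

    def esp(self, points: np.ndarray) -> np.ndarray:
        """Physical electrostatic potential: nuclei minus electron cloud."""
        return self.nuclear_potential(points) - self.electron_potential(points)

    def translated(self, shift: np.ndarray) -> "GaussianDensity":
        """Rigidly translated copy (shift in bohr)."""
        shift = np.asarray(shift, dtype=float)
        return GaussianDensity(
            nuclei=[replace(n, position=n.position + shift) for n in self.nuclei],
            primitives=[replace(p, center=p.center + shift) for p in self.primitives],
            label=self.label,
        )


@dataclass
class ComplexDensity:
    """Two-or-more-fragment density.

    In ``zeroth_order`` mode the complex density is, pointwise, the sum of the
    unrelaxed fragment densities rho0 = sum_F rho_F.  In ``relaxed`` mode the
    fragments carry relaxed (e.g. synthetically polarized) densities but the
    container semantics are identical; the mode flag records provenance.
    """

    fragments: list[GaussianDensity]
    mode: str = "zeroth_order"

    def __post_init__(self):
        self._cache_token = next(_CACHE_TOKEN)
        if self.mode not in ("zeroth_order", "relaxed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        all_nuc = self.nuclei  # triggers duplicate check across fragments
        pos = np.array([n.position for n in all_nuc]).reshape(-1, 3)
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if np.linalg.norm(pos[i] - pos[j]) <= _MIN_NUCLEAR_SEPARATION:
                    raise GeometryError("nuclei of different fragments coincide")

    @property
    def nuclei(self) -> list[Nucleus]:
        return [n for f in self.fragments for n in f.nuclei]

    @property
    def positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nuclei]).reshape(-1, 3)

    @property
    def charges(self) -> np.ndarray:
        return np.array([n.Z for n in self.nuclei])

    @property
    def fragment_of_atom(self) -> list[str]:
        return [f.label for f in self.fragments for _ in f.nuclei]

    @property
    def electron_count(self) -> float:
        return float(sum(f.electron_count for f in self.fragments))

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        return sum(f.evaluate(points) for f in self.fragments)

    def gradient(self, points: np.ndarray) -> np.ndarray:
        return sum(f.gradient(points) for f in self.fragments)

    def density_and_gradient(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        parts = [f.density_and_gradient(points) for f in self.fragments]
        return sum(p[0] for p in parts), sum(p[1] for p in parts)

    def electron_potential(self, points: np.ndarray) -> np.ndarray:
        return sum(f.electron_potential(points) for f in self.fragments)

    def esp(self, points: np.ndarray) -> np.ndarray:
        return sum(f.esp(points) for f in self.fragments)


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def build_promolecule(
    symbols: list[str],
    coords_angstrom: np.ndarray,
    params: dict[str, float] | None = None,
    populations: list[float] | None = None,
    label: str = "",
) -> GaussianDensity:
    """Build a promolecular density: one spherical Gaussian per atom.

    Parameters
    ----------
    symbols, coords_angstrom
        Standard XYZ content; coordinates are converted to bohr.
    params
        Per-element exponent table (bohr^-2); defaults to
        :data:`iqfcp.constants.DEFAULT_EXPONENTS`.
    populations
        Per-atom electron populations; default q = Z (neutral atoms, hence a
        neutral fragment).
    """
    exps = dict(DEFAULT_EXPONENTS)
    if params:
        exps.update(params)
    coords = np.asarray(coords_angstrom, dtype=float)
    if coords.shape != (len(symbols), 3) or not np.all(np.isfinite(coords)):
        raise GeometryError("coordinates must be a finite (n_atoms, 3) array")
    nuclei, prims = [], []
    for i, (sym, xyz) in enumerate(zip(symbols, coords)):
        if sym not in ATOMIC_NUMBER:
            raise ParameterizationError(f"unknown element {sym!r} (atom {i + 1})")
        if sym not in exps:
            raise ParameterizationError(f"no exponent parameter for element {sym!r}")
        pos = xyz * BOHR_PER_ANGSTROM
        z = float(ATOMIC_NUMBER[sym])
        q = float(populations[i]) if populations is not None else z
        nuclei.append(Nucleus(sym, z, pos))
        prims.append(GaussianPrimitive(pos, float(exps[sym]), q))
    return GaussianDensity(nuclei, prims, label=label)


def polarize_atom(
    density: GaussianDensity,
    atom_index: int,
    fraction: float,
    shift_bohr: np.ndarray,
    exponent: float | None = None,
) -> GaussianDensity:
    """Split one atom's population over two primitives to emulate relaxation.

    A fraction of the atom's cloud is moved to a displaced center, giving the
    fragment an intramolecular dipole without any SCF machinery.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ParameterizationError("polarization fraction must be in [0, 1]")
    shift = np.asarray(shift_bohr, dtype=float)
    prims = list(density.primitives)
    p = prims[atom_index]
    prims[atom_index] = replace(p, population=p.population * (1.0 - fraction))
    prims.append(
        GaussianPrimitive(p.center + shift, exponent or p.exponent, p.population * fraction)
    )
    return GaussianDensity(density.nuclei, prims, label=density.label)


# ---------------------------------------------------------------------------
# functional wrappers (module-level operation surface)
# ---------------------------------------------------------------------------

def evaluate_density(d, points: np.ndarray) -> np.ndarray:
    """Evaluate a fragment or complex density at points (bohr)."""
    return d.evaluate(points)


def evaluate_gradient(d, points: np.ndarray) -> np.ndarray:
    """Evaluate the analytic density gradient at points (bohr)."""
    return d.gradient(points)


def analytic_potential(d: GaussianDensity, points: np.ndarray) -> np.ndarray:
    """Electron-cloud Coulomb potential of a Gaussian expansion (hartree/e)."""
    return d.electron_potential(points)


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------

def read_xyz(path) -> tuple[list[str], np.ndarray, str]:
    """Read a standard XYZ file; returns (symbols, coords in angstrom, comment)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GeometryError(f"empty XYZ file: {path}")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise GeometryError(f"bad XYZ atom count line in {path}") from exc
    comment = lines[1] if len(lines) > 1 else ""
    symbols, coords = [], []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        if len(parts) < 4:
            raise GeometryError(f"bad XYZ atom line: {ln!r}")
        symbols.append(parts[0].capitalize())
        coords.append([float(x) for x in parts[1:4]])
    if len(symbols) != n:
        raise GeometryError(f"XYZ declares {n} atoms but provides {len(symbols)}")
    return symbols, np.array(coords), comment


def write_xyz(path, symbols: list[str], coords_angstrom: np.ndarray, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(symbols)}\n{comment}\n")
        for s, (x, y, z) in zip(symbols, np.asarray(coords_angstrom)):
            fh.write(f"{s} {x:.10f} {y:.10f} {z:.10f}\n")


def _check_points(points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[-1] != 3 or not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite with trailing dimension 3")
    return pts
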