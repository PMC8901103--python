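"""Wavefunction-density adapter: minimal wfx and molden readers.

Builds a grid-evaluable density rho(r) = sum_i occ_i |phi_i(r)|^2 from
Cartesian Gaussian primitives, exposing the same evaluate/gradient surface as
the promolecular model so grids, basins and restricted-potential machinery
work unchanged.  Coverage is deliberately minimal: wfx files with primitive
types s/p/d (types 1-10) and molden files with s/p contracted shells; any
other record raises a parse error naming it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import SYMBOL_OF_Z
from .density import Nucleus
from .errors import WavefunctionParseError

__all__ = ["MolecularOrbitalDensity", "read_wavefunction_density", "read_wfx", "read_molden"]

# wfx/wfn primitive type -> cartesian powers (ax, ay, az)
_TYPE_POWERS = {
    1: (0, 0, 0),
    2: (1, 0, 0), 3: (0, 1, 0), 4: (0, 0, 1),
    5: (2, 0, 0), 6: (0, 2, 0), 7: (0, 0, 2),
    8: (1, 1, 0), 9: (1, 0, 1), 10: (0, 1, 1),
}


@dataclass
class MolecularOrbitalDensity:
    """Occupied-orbital density over Cartesian Gaussian primitives."""

    nuclei: list[Nucleus]
    centers: np.ndarray    # (P, 3) bohr
    exponents: np.ndarray  # (P,)
    powers: np.ndarray     # (P, 3) int
    coeffs: np.ndarray     # (M, P) — include primitive normalization
    occupations: np.ndarray  # (M,)
    label: str = ""

    def __post_init__(self):
        from .density import _CACHE_TOKEN

        self._cache_token = next(_CACHE_TOKEN)

    @property
    def positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nuclei]).reshape(-1, 3)

    @property
    def charges(self) -> np.ndarray:
        return np.array([n.Z for n in self.nuclei])

    @property
    def electron_count(self) -> float:
        return float(self.occupations.sum())

    def _chi(self, pts: np.ndarray):
        d = pts[:, None, :] - self.centers[None, :, :]       # (N, P, 3)
        r2 = np.einsum("npx,npx->np", d, d)
        g = np.exp(-self.exponents[None, :] * r2)
        mono = np.ones_like(g)
        for ax in range(3):
            p = self.powers[:, ax]
            if p.max(initial=0) > 0:
                mono = mono * d[:, :, ax] ** p[None, :]
        return d, g, mono

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        _, g, mono = self._chi(pts)
        phi = (mono * g) @ self.coeffs.T                      # (N, M)
        return np.einsum("m,nm->n", self.occupations, phi**2)

    def gradient(self, points: np.ndarray) -> np.ndarray:
        return self.density_and_gradient(points)[1]

    def density_and_gradient(self, points: np.ndarray):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d, g, mono = self._chi(pts)
        chi = mono * g
        phi = chi @ self.coeffs.T
        grad_phi = np.empty((pts.shape[0], self.coeffs.shape[0], 3))
        for ax in range(3):
            p = self.powers[:, ax].astype(float)
            x = d[:, :, ax]
            with np.errstate(divide="ignore", invalid="ignore"):
                poly = np.where(
                    p[None, :] > 0,
                    p[None, :] * np.where(x != 0, mono / np.where(x != 0, x, 1.0), 0.0),
                    0.0,
                )
            # p * x^(p-1) fails at x=0 when p>1 handled above (term -> 0 for p>1)
            lower = np.where((p[None, :] == 1), mono / np.where(x != 0, x, 1.0), poly)
            lower = np.where((p[None, :] == 1) & (x == 0), 1.0, lower)
            dchi = (lower - 2.0 * self.exponents[None, :] * x * mono) * g
            grad_phi[:, :, ax] = dchi @ self.coeffs.T
        rho = np.einsum("m,nm->n", self.occupations, phi**2)
        grad = 2.0 * np.einsum("m,nm,nmx->nx", self.occupations, phi, grad_phi)
        return rho, grad


# ---------------------------------------------------------------------------
# wfx
# ---------------------------------------------------------------------------

def _wfx_section(text: str, name: str) -> str:
    open_tag, close_tag = f"<{name}>", f"</{name}>"
    i = text.find(open_tag)
    j = text.find(close_tag)
    if i < 0 or j < 0 or j < i:
        raise WavefunctionParseError(f"missing or malformed wfx record <{name}>")
    return text[i + len(open_tag): j].strip()


def read_wfx(path) -> MolecularOrbitalDensity:
    with open(path) as fh:
        text = fh.read()
    try:
        n_nuc = int(_wfx_section(text, "Number of Nuclei"))
        z = [float(v) for v in _wfx_section(text, "Atomic Numbers").split()]
        xyz = np.array(
            [float(v) for v in _wfx_section(text, "Nuclear Cartesian Coordinates").split()]
        ).reshape(-1, 3)
    except ValueError as exc:
        raise WavefunctionParseError(f"unparseable numeric field in wfx header: {exc}") from exc
    if len(z) != n_nuc or xyz.shape[0] != n_nuc:
        raise WavefunctionParseError("inconsistent <Number of Nuclei> vs coordinate records")
    nuclei = [Nucleus(SYMBOL_OF_Z.get(int(zi), "X"), zi, p) for zi, p in zip(z, xyz)]

    centers_idx = [int(v) for v in _wfx_section(text, "Primitive Centers").split()]
    types = [int(v) for v in _wfx_section(text, "Primitive Types").split()]
    exps = np.array([float(v.replace("D", "E").replace("d", "e"))
                     for v in _wfx_section(text, "Primitive Exponents").split()])
    bad = sorted({t for t in types if t not in _TYPE_POWERS})
    if bad:
        raise WavefunctionParseError(
            f"unsupported primitive types {bad} in <Primitive Types> (s/p/d only)"
        )
    occs = np.array(
        [float(v) for v in _wfx_section(text, "Molecular Orbital Occupation Numbers").split()]
    )
    import re

    coeff_block = _wfx_section(text, "Molecular Orbital Primitive Coefficients")
    coeff_block = re.sub(r"<MO Number>.*?</MO Number>", " ", coeff_block, flags=re.S)
    try:
        vals = [float(tok.replace("D", "E").replace("d", "e"))
                for tok in coeff_block.split()]
    except ValueError as exc:
        raise WavefunctionParseError(
            f"bad token in <Molecular Orbital Primitive Coefficients>: {exc}"
        ) from exc
    P = len(types)
    if len(vals) != occs.size * P:
        raise WavefunctionParseError(
            "wrong coefficient count in <Molecular Orbital Primitive Coefficients>"
        )
    return MolecularOrbitalDensity(
        nuclei=nuclei,
        centers=xyz[np.array(centers_idx) - 1],
        exponents=exps,
        powers=np.array([_TYPE_POWERS[t] for t in types]),
        coeffs=np.array(vals).reshape(occs.size, P),
        occupations=occs,
        label="wfx",
    )


# ---------------------------------------------------------------------------
# molden (minimal: [Atoms], [GTO] with s/p shells, [MO])
# ---------------------------------------------------------------------------

def read_molden(path) -> MolecularOrbitalDensity:
    from .constants import ATOMIC_NUMBER, BOHR_PER_ANGSTROM

    with open(path) as fh:
        lines = [ln.rstrip() for ln in fh]

    def _find(tag: str) -> int:
        for i, ln in enumerate(lines):
            s = ln.strip().lower()
            if s.startswith(f"[{tag.lower()}]") or s.startswith(f"[{tag.lower()} "):
                return i
        raise WavefunctionParseError(f"missing molden record [{tag}]")

    ia = _find("Atoms")
    unit = lines[ia].lower()
    to_bohr = 1.0 if "au" in unit else BOHR_PER_ANGSTROM
    nuclei = []
    i = ia + 1
    while i < len(lines) and not lines[i].strip().startswith("["):
        parts = lines[i].split()
        if len(parts) >= 6:
            sym, z = parts[0].capitalize(), float(parts[2])
            pos = np.array([float(v) for v in parts[3:6]]) * to_bohr
            nuclei.append(Nucleus(sym, z, pos))
        i += 1

    ig = _find("GTO")
    centers, exps, powers, basis_map = [], [], [], []  # basis_map: (prim slice per AO)
    i = ig + 1
    atom_order = []
    while i < len(lines) and not lines[i].strip().startswith("["):
        head = lines[i].split()
        if not head:
            i += 1
            continue
        atom_idx = int(head[0]) - 1
        atom_order.append(atom_idx)
        i += 1
        while i < len(lines) and lines[i].strip() and not lines[i].strip().startswith("["):
            sh = lines[i].split()
            shell, nprim = sh[0].lower(), int(sh[1])
            if shell not in ("s", "p"):
                raise WavefunctionParseError(
                    f"unsupported shell type {shell!r} in molden [GTO] (s/p only)"
                )
            prims = []
            for k in range(nprim):
                i += 1
                a, c = (float(v.replace("D", "E")) for v in lines[i].split()[:2])
                prims.append((a, c))
            pos = nuclei[atom_idx].position
            if shell == "s":
                ao = []
                for a, c in prims:
                    centers.append(pos); exps.append(a); powers.append((0, 0, 0))
                    ao.append((len(exps) - 1, c * (2.0 * a / np.pi) ** 0.75))
                basis_map.append(ao)
            else:  # p -> px, py, pz
                for comp in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
                    ao = []
                    for a, c in prims:
                        centers.append(pos); exps.append(a); powers.append(comp)
                        norm = (2.0 * a / np.pi) ** 0.75 * 2.0 * np.sqrt(a)
                        ao.append((len(exps) - 1, c * norm))
                    basis_map.append(ao)
            i += 1
        i += 1

    im = _find("MO")
    occs, mo_rows = [], []
    i = im + 1
    cur: dict[int, float] | None = None
    while i <= len(lines):
        ln = lines[i] if i < len(lines) else "[end]"
        s = ln.strip()
        if s.lower().startswith("occup"):
            if cur is not None:
                mo_rows.append(cur)
            occs.append(float(s.split("=")[1]))
            cur = {}
        elif s.startswith("[") or i == len(lines):
            if cur is not None:
                mo_rows.append(cur)
            break
        elif cur is not None and s and "=" not in s:
            parts = s.split()
            cur[int(parts[0]) - 1] = float(parts[1])
        i += 1
    if not occs:
        raise WavefunctionParseError("no occupations found in molden [MO]")

    P = len(exps)
    coeffs = np.zeros((len(occs), P))
    for m, row in enumerate(mo_rows):
        for ao_idx, c_mo in row.items():
            if ao_idx >= len(basis_map):
                raise WavefunctionParseError(
                    f"molden [MO] references basis function {ao_idx + 1} beyond [GTO]"
                )
            for prim_idx, c_prim in basis_map[ao_idx]:
                coeffs[m, prim_idx] += c_mo * c_prim
    return MolecularOrbitalDensity(
        nuclei=nuclei,
        centers=np.array(centers),
        exponents=np.array(exps),
        powers=np.array(powers, dtype=int),
        coeffs=coeffs,
        occupations=np.array(occs),
        label="molden",
    )


def read_wavefunction_density(path) -> MolecularOrbitalDensity:
    """Dispatch on extension: .wfx or .molden/.mold/.input-style molden."""
    p = str(path).lower()
    if p.endswith(".wfx"):
        return read_wfx(path)
    if p.endswith((".molden", ".mold", ".molden.input")):
        return read_molden(path)
    raise WavefunctionParseError(f"unrecognized wavefunction file extension: {path}")
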