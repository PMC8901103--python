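"""Synthetic two-fragment model systems ("toy dimers").

The presets emulate the three interaction classes of noncovalent benchmark
sets — hydrogen-bond-like (polar, dipole-aligned), dispersion-like (apolar,
closed-shell contact) and mixed — using promolecular Gaussian fragments whose
per-atom populations encode bond polarity and whose optional split primitives
encode intramolecular polarization.  Geometries are in bohr; each preset fixes
an equilibrium separation ``R_eq`` between fragment anchors, and an optional
seeded jitter perturbs atom positions reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import GaussianDensity, GaussianPrimitive, Nucleus, polarize_atom
from .errors import GeometryError, ParameterizationError
from .qtaim import Fragmentation

__all__ = ["ToyAtom", "ToyDimerSpec", "make_toy_dimer", "toy_preset", "PRESETS"]


@dataclass(frozen=True)
class ToyAtom:
    symbol: str
    Z: float
    position: tuple[float, float, float]   # bohr, fragment frame
    exponent: float
    population: float
    # optional second displaced primitive: (fraction, shift vector bohr)
    polarization: tuple[float, tuple[float, float, float]] | None = None


@dataclass(frozen=True)
class ToyDimerSpec:
    name: str
    fragment_a: tuple[ToyAtom, ...]
    fragment_b: tuple[ToyAtom, ...]
    separation: float                      # R_eq along +z between fragment frames
    jitter: float = 0.0                    # bohr, uniform per-coordinate amplitude
    seed: int | None = None

    def __post_init__(self):
        if self.separation <= 0:
            raise GeometryError("separation must be positive")
        for frag in (self.fragment_a, self.fragment_b):
            if not frag:
                raise GeometryError("fragments must contain at least one atom")
            for at in frag:
                if sum(p for p in [at.population]) < 0:
                    raise ParameterizationError("negative population")


def _build_fragment(atoms: tuple[ToyAtom, ...], offset: np.ndarray,
                    rng: np.random.Generator | None, jitter: float,
                    label: str) -> GaussianDensity:
    nuclei, prims = [], []
    for at in atoms:
        pos = np.asarray(at.position, dtype=float) + offset
        if rng is not None and jitter > 0:
            pos = pos + rng.uniform(-jitter, jitter, 3)
        nuclei.append(Nucleus(at.symbol, at.Z, pos))
        prims.append(GaussianPrimitive(pos, at.exponent, at.population))
    d = GaussianDensity(nuclei, prims, label=label)
    for i, at in enumerate(atoms):
        if at.polarization is not None:
            frac, shift = at.polarization
            d = polarize_atom(d, i, frac, np.asarray(shift, dtype=float))
    return d


def make_toy_dimer(spec: ToyDimerSpec
                   ) -> tuple[GaussianDensity, GaussianDensity, Fragmentation]:
    """Build both fragment densities at the complex geometry.

    Fragment B sits ``spec.separation`` along +z from fragment A's frame;
    deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed) if spec.seed is not None else None
    a = _build_fragment(spec.fragment_a, np.zeros(3), rng, spec.jitter, "A")
    b = _build_fragment(spec.fragment_b, np.array([0.0, 0.0, spec.separation]),
                        rng, spec.jitter, "B")
    da = np.linalg.norm(a.positions[:, None, :] - b.positions[None, :, :], axis=2)
    if np.any(da < 0.5):
        raise GeometryError("fragments overlap (nuclei closer than 0.5 bohr)")
    labels = ["A"] * len(a.nuclei) + ["B"] * len(b.nuclei)
    return a, b, Fragmentation(tuple(labels))


# ---------------------------------------------------------------------------
# presets — the package's standard study conditions
# ---------------------------------------------------------------------------

def _hb() -> ToyDimerSpec:
    # O-H...O-H chain; +-0.45 e bond polarity gives ~1 e bohr fragment dipoles.
    # The intramolecular O-H contact is kept soft (2.4 bohr, compact clouds) so
    # every basin interface carries noncovalent-scale density (< 0.05 e/bohr^3)
    frag = (
        ToyAtom("O", 8.0, (0.0, 0.0, 0.0), 2.6, 8.45),
        ToyAtom("H", 1.0, (0.0, 0.0, 2.4), 1.4, 0.55),
    )
    return ToyDimerSpec("hb", frag, frag, separation=5.6)


def _disp() -> ToyDimerSpec:
    # closed-shell apolar contact (neon-like diffuse atoms)
    a = (ToyAtom("Ne", 10.0, (0.0, 0.0, 0.0), 1.6, 10.0),)
    return ToyDimerSpec("disp", a, a, separation=5.8)


def _mixed() -> ToyDimerSpec:
    frag_a = (
        ToyAtom("O", 8.0, (0.0, 0.0, 0.0), 2.6, 8.45),
        ToyAtom("H", 1.0, (0.0, 0.0, 2.4), 1.4, 0.55),
    )
    frag_b = (ToyAtom("Ne", 10.0, (0.6, 0.0, 0.0), 1.6, 10.0),)
    return ToyDimerSpec("mixed", frag_a, frag_b, separation=6.0)


def _polar() -> ToyDimerSpec:
    # single-site dipolar fragments (split primitive) for multipole-decay
    # studies; deliberately inequivalent fragments, so no odd-order
    # interaction terms cancel by symmetry
    a = (ToyAtom("N", 7.0, (0.0, 0.0, 0.0), 2.2, 7.0,
                 polarization=(0.1, (0.0, 0.0, 0.9))),)
    b = (ToyAtom("O", 8.0, (0.0, 0.0, 0.0), 2.6, 8.0,
                 polarization=(0.16, (0.0, 0.0, 0.6))),)
    return ToyDimerSpec("polar", a, b, separation=5.0)


def _hf() -> ToyDimerSpec:
    # strongly heteronuclear contact pair: unequal sizes, asymmetric basins
    a = (ToyAtom("F", 9.0, (0.0, 0.0, 0.0), 2.8, 9.3),)
    b = (ToyAtom("H", 1.0, (0.0, 0.0, 0.0), 1.2, 0.7),)
    return ToyDimerSpec("hf", a, b, separation=3.2)


PRESETS = {"hb": _hb, "disp": _disp, "mixed": _mixed, "polar": _polar, "hf": _hf}


def toy_preset(name: str, seed: int | None = None, jitter: float = 0.0,
               separation: float | None = None) -> ToyDimerSpec:
    """A named preset, optionally with seeded jitter or a different separation."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    spec = PRESETS[name]()
    from dataclasses import replace

    kw = {"seed": seed, "jitter": jitter}
    if separation is not None:
        kw["separation"] = separation
    return replace(spec, **kw)
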