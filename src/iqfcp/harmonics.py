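"""Real spherical harmonics and regular solid harmonics.

Conventions
-----------
Real orthonormal spherical harmonics ``S_lm`` on the unit sphere, ordered per
degree ``l`` as ``m = 0, (1,c), (1,s), (2,c), (2,s), ...`` so that the flat
index of ``(l, m)`` is ``l**2 + (0 | 2m-1 | 2m)`` for ``(m=0 | mc | ms)``.

Regular solid harmonics use Racah normalization,
``R_lm(r) = sqrt(4 pi / (2 l + 1)) * r**l * S_lm(r_hat)`` — so ``R_00 = 1``,
``R_10 = z``, ``R_11c = x``, ``R_20 = (3 z^2 - r^2) / 2`` etc., matching the
GDMA/QTAIM multipole convention Q_lm = sum_i q_i R_lm(r_i).
"""

from __future__ import annotations

from math import factorial

import numpy as np


def n_lm(l_max: int) -> int:
    """Number of real (l, m) components with l <= l_max."""
    return (l_max + 1) ** 2


def lm_index(l: int, m: int, kind: str = "c") -> int:
    """Flat index of a real component; ``m=0`` ignores *kind* ('c'|'s')."""
    if m == 0:
        return l * l
    return l * l + (2 * m - 1 if kind == "c" else 2 * m)


def lm_table(l_max: int) -> list[tuple[int, int, str]]:
    """(l, m, kind) triples in flat-index order."""
    out: list[tuple[int, int, str]] = []
    for l in range(l_max + 1):
        out.append((l, 0, "c"))
        for m in range(1, l + 1):
            out.append((l, m, "c"))
            out.append((l, m, "s"))
    return out


def degree_of_index(l_max: int) -> np.ndarray:
    """Array mapping flat lm index -> degree l."""
    return np.array([l for l, _, _ in lm_table(l_max)], dtype=int)


def real_sph_harm(l_max: int, unit_vecs: np.ndarray) -> np.ndarray:
    """Evaluate all real orthonormal S_lm, l <= l_max, at unit vectors.

    Parameters
    ----------
    unit_vecs : (N, 3) array of unit direction vectors.

    Returns
    -------
    (n_lm, N) array.
    """
    u = np.atleast_2d(np.asarray(unit_vecs, dtype=float))
    z = np.clip(u[:, 2], -1.0, 1.0)
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    # azimuthal cos/sin(m phi) by recurrence (phase-free for s = 0)
    rxy = np.maximum(s, 1e-300)
    cphi = np.where(s > 0, u[:, 0] / rxy, 1.0)
    sphi = np.where(s > 0, u[:, 1] / rxy, 0.0)
    n = u.shape[0]
    out = np.empty((n_lm(l_max), n))
    # associated Legendre P_l^m without Condon-Shortley phase, by recurrence
    P = {}
    P[(0, 0)] = np.ones(n)
    for m in range(1, l_max + 1):
        P[(m, m)] = (2 * m - 1) * s * P[(m - 1, m - 1)]
    for m in range(l_max + 1):
        if m + 1 <= l_max:
            P[(m + 1, m)] = (2 * m + 1) * z * P[(m, m)]
        for l in range(m + 2, l_max + 1):
            P[(l, m)] = ((2 * l - 1) * z * P[(l - 1, m)]
                         - (l + m - 1) * P[(l - 2, m)]) / (l - m)
    cm, sm = np.ones(n), np.zeros(n)   # cos/sin(m phi), m = 0
    for m in range(l_max + 1):
        if m > 0:
            cm, sm = cm * cphi - sm * sphi, sm * cphi + cm * sphi
        for l in range(m, l_max + 1):
            if m == 0:
                out[lm_index(l, 0)] = np.sqrt((2 * l + 1) / (4.0 * np.pi)) * P[(l, 0)]
            else:
                norm = np.sqrt((2 * l + 1) / (2.0 * np.pi)
                               * factorial(l - m) / factorial(l + m))
                out[lm_index(l, m, "c")] = norm * P[(l, m)] * cm
                out[lm_index(l, m, "s")] = norm * P[(l, m)] * sm
    return out


def regular_solid_harm(l_max: int, vecs: np.ndarray) -> np.ndarray:
    """Racah-normalized regular solid harmonics R_lm at displacement vectors.

    Returns (n_lm, N); rows follow :func:`lm_table` ordering.
    """
    v = np.atleast_2d(np.asarray(vecs, dtype=float))
    r = np.linalg.norm(v, axis=1)
    safe = np.where(r > 0, r, 1.0)
    s = real_sph_harm(l_max, v / safe[:, None])
    out = np.empty_like(s)
    for l, m, kind in lm_table(l_max):
        i = lm_index(l, m, kind)
        out[i] = np.sqrt(4.0 * np.pi / (2 * l + 1)) * safe**l * s[i]
        if l > 0:
            out[i] = np.where(r > 0, out[i], 0.0)
        else:
            out[i] = 1.0
    return out
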