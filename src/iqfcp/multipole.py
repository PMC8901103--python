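"""Point-charge and distributed-multipole electrostatics (l_max <= 2).

Per-site moments are real-solid-harmonic (Racah-normalized) multipoles
Q_lm — charge (e), dipole (e bohr), traceless quadrupole (e bohr^2) — the
convention of QTAIM/DMA practice.  Site-site interactions are evaluated by
converting each site's moments to Cartesian tensors (Buckingham traceless
quadrupole) and contracting the dipole/quadrupole with the gradient and
Hessian of the partner's multipolar potential, which keeps every l1, l2 <=
l_max term (through quadrupole-quadrupole), the common multipolar force-field
truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .constants import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM, VDW_RADII_ANGSTROM
from .errors import InconsistencyError, ParameterizationError
from .harmonics import lm_index, n_lm

__all__ = ["MultipoleSet", "mtp_interaction", "esp_grid", "fit_charges", "atom_pair_compare"]


@dataclass
class MultipoleSet:
    """Distributed multipoles: site positions (bohr) and Q_lm rows per site."""

    sites: np.ndarray                 # (n, 3) bohr
    Q: np.ndarray                     # (n, (l_max+1)^2)
    l_max: int
    labels: list[str] = field(default_factory=list)
    convention: str = "real solid harmonics, traceless quadrupole"

    def __post_init__(self):
        self.sites = np.atleast_2d(np.asarray(self.sites, dtype=float))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        if self.l_max not in (0, 1, 2) and self.Q.shape[1] != n_lm(self.l_max):
            raise InconsistencyError("Q width does not match l_max")
        if self.Q.shape != (self.sites.shape[0], n_lm(self.l_max)):
            raise InconsistencyError(
                f"Q shape {self.Q.shape} != (n_sites, {n_lm(self.l_max)})"
            )

    @property
    def n_sites(self) -> int:
        return self.sites.shape[0]

    @property
    def total_charge(self) -> float:
        return float(self.Q[:, 0].sum())

    def truncated(self, l_max: int) -> "MultipoleSet":
        """Copy keeping only moments with l <= l_max."""
        l_max = min(l_max, self.l_max)
        return replace(self, Q=self.Q[:, : n_lm(l_max)].copy(), l_max=l_max)

    def translated(self, shift_bohr: np.ndarray) -> "MultipoleSet":
        return replace(self, sites=self.sites + np.asarray(shift_bohr, dtype=float))

    # -- Cartesian views ------------------------------------------------
    def cartesian(self, i: int) -> tuple[float, np.ndarray, np.ndarray]:
        """(charge, dipole vector, Buckingham traceless quadrupole) of site i."""
        q = float(self.Q[i, 0])
        mu = np.zeros(3)
        theta = np.zeros((3, 3))
        if self.l_max >= 1:
            mu[:] = (
                self.Q[i, lm_index(1, 1, "c")],
                self.Q[i, lm_index(1, 1, "s")],
                self.Q[i, lm_index(1, 0)],
            )
        if self.l_max >= 2:
            q20 = self.Q[i, lm_index(2, 0)]
            q21c = self.Q[i, lm_index(2, 1, "c")]
            q21s = self.Q[i, lm_index(2, 1, "s")]
            q22c = self.Q[i, lm_index(2, 2, "c")]
            q22s = self.Q[i, lm_index(2, 2, "s")]
            s3 = np.sqrt(3.0)
            theta = np.array(
                [
                    [-q20 / 2 + s3 / 2 * q22c, s3 / 2 * q22s, s3 / 2 * q21c],
                    [s3 / 2 * q22s, -q20 / 2 - s3 / 2 * q22c, s3 / 2 * q21s],
                    [s3 / 2 * q21c, s3 / 2 * q21s, q20],
                ]
            )
        return q, mu, theta

    # -- plain-text exchange format (GDMA-style ordering) ---------------
    def to_text(self) -> str:
        lines = [f"! distributed multipoles, l_max={self.l_max}, units: e, bohr^l; xyz in angstrom"]
        for i in range(self.n_sites):
            sym = self.labels[i] if i < len(self.labels) else "X"
            x, y, z = self.sites[i] * ANGSTROM_PER_BOHR
            lines.append(f"{sym} {x:.8f} {y:.8f} {z:.8f}")
            lines.append("  " + " ".join(f"{v: .10e}" for v in self.Q[i]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "MultipoleSet":
        rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("!")]
        sites, Q, labels = [], [], []
        for site_line, q_line in zip(rows[0::2], rows[1::2]):
            parts = site_line.split()
            labels.append(parts[0])
            sites.append([float(v) * BOHR_PER_ANGSTROM for v in parts[1:4]])
            Q.append([float(v) for v in q_line.split()])
        width = len(Q[0])
        l_max = int(np.sqrt(width)) - 1
        return cls(np.array(sites), np.array(Q), l_max=l_max, labels=labels)


# ---------------------------------------------------------------------------
# multipolar potential of one site and its derivatives
# ---------------------------------------------------------------------------

def _site_potential_derivs(q, mu, theta, R):
    """V, grad V, hess V of a site's multipoles at displacement(s) R (N, 3)."""
    R = np.atleast_2d(R)
    r2 = np.einsum("na,na->n", R, R)
    r = np.sqrt(r2)
    r3, r5, r7, r9 = r**3, r**5, r**7, r**9
    eye = np.eye(3)

    V = q / r
    G = -q * R / r3[:, None]
    H = q * (3 * np.einsum("na,nb->nab", R, R) / r5[:, None, None] - eye[None] / r3[:, None, None])

    mur = R @ mu
    V = V + mur / r3
    G = G + mu[None, :] / r3[:, None] - 3 * mur[:, None] * R / r5[:, None]
    H = H - 3 * (
        mur[:, None, None] * eye[None]
        + np.einsum("a,nb->nab", mu, R)
        + np.einsum("na,b->nab", R, mu)
    ) / r5[:, None, None] + 15 * mur[:, None, None] * np.einsum("na,nb->nab", R, R) / r7[:, None, None]

    TR = R @ theta
    S = np.einsum("na,na->n", TR, R)
    V = V + S / r5
    G = G + 2 * TR / r5[:, None] - 5 * S[:, None] * R / r7[:, None]
    H = (
        H
        + 2 * theta[None] / r5[:, None, None]
        - 10 * (np.einsum("na,nb->nab", TR, R) + np.einsum("na,nb->nab", R, TR)) / r7[:, None, None]
        - 5 * S[:, None, None] * eye[None] / r7[:, None, None]
        + 35 * S[:, None, None] * np.einsum("na,nb->nab", R, R) / r9[:, None, None]
    )
    return V, G, H


def mtp_interaction(setA: MultipoleSet, setB: MultipoleSet) -> tuple[float, np.ndarray]:
    """Multipolar interaction energy (hartree) and the site-pair matrix."""
    d = np.linalg.norm(setA.sites[:, None, :] - setB.sites[None, :, :], axis=2)
    if np.any(d < 1e-3):
        raise InconsistencyError("coincident sites across multipole sets")
    pair = np.zeros((setA.n_sites, setB.n_sites))
    for i in range(setA.n_sites):
        qa, mua, tha = setA.cartesian(i)
        R = setB.sites - setA.sites[i]
        V, G, H = _site_potential_derivs(qa, mua, tha, R)
        for j in range(setB.n_sites):
            qb, mub, thb = setB.cartesian(j)
            pair[i, j] = (
                qb * V[j] + mub @ G[j] + np.einsum("ab,ab->", thb, H[j]) / 3.0
            )
    return float(pair.sum()), pair


# ---------------------------------------------------------------------------
# ESP surface and constrained charge fitting
# ---------------------------------------------------------------------------

def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def esp_grid(
    density,
    shells: tuple[float, ...] = (1.4, 1.6, 1.8, 2.0),
    points_per_bohr2: float = 1.0,
) -> np.ndarray:
    """Deterministic golden-spiral shells at scaled vdW radii (bohr points).

    Points inside any atom's scaled sphere (same shell scale) are excluded.
    """
    positions = density.positions
    radii = []
    for nuc in density.nuclei:
        if nuc.symbol not in VDW_RADII_ANGSTROM:
            raise ParameterizationError(f"no vdW radius for element {nuc.symbol!r}")
        radii.append(VDW_RADII_ANGSTROM[nuc.symbol] * BOHR_PER_ANGSTROM)
    radii = np.array(radii)
    out = []
    for scale in shells:
        for i, (pos, rv) in enumerate(zip(positions, radii)):
            r = scale * rv
            n = max(8, int(np.ceil(points_per_bohr2 * 4.0 * np.pi * r**2)))
            pts = pos[None, :] + r * _golden_spiral(n)
            dist = np.linalg.norm(pts[:, None, :] - positions[None, :, :], axis=2)
            keep = np.all(dist >= scale * radii[None, :] * (1.0 - 1e-9), axis=1)
            out.append(pts[keep])
    return np.concatenate(out)


def fit_charges(density, esp_points: np.ndarray, total_charge: float | None = None) -> MultipoleSet:
    """Least-squares atomic charges reproducing the density's ESP.

    Minimizes sum (V_model - V_true)^2 under the single linear constraint
    sum q = Q (Lagrange multiplier); V_true is the full nuclei + electron
    potential of the density.  No hyperbolic restraint is applied.
    """
    pts = np.atleast_2d(np.asarray(esp_points, dtype=float))
    positions = density.positions
    n_at = positions.shape[0]
    if pts.shape[0] < n_at:
        raise InconsistencyError("need at least as many ESP points as atoms")
    if total_charge is None:
        total_charge = float(density.total_charge)
    A = 1.0 / np.linalg.norm(pts[:, None, :] - positions[None, :, :], axis=2)
    b = density.esp(pts)
    if np.linalg.matrix_rank(A, tol=1e-10) < n_at:
        raise InconsistencyError(
            "rank-deficient ESP design matrix; add more shells or points"
        )
    kkt = np.zeros((n_at + 1, n_at + 1))
    kkt[:n_at, :n_at] = 2.0 * A.T @ A
    kkt[:n_at, n_at] = 1.0
    kkt[n_at, :n_at] = 1.0
    rhs = np.concatenate([2.0 * A.T @ b, [total_charge]])
    sol = np.linalg.solve(kkt, rhs)
    q = sol[:n_at]
    labels = [getattr(n, "symbol", "X") for n in getattr(density, "nuclei", [])]
    return MultipoleSet(sites=positions.copy(), Q=q[:, None], l_max=0, labels=labels)


# ---------------------------------------------------------------------------
# pairwise comparison statistics
# ---------------------------------------------------------------------------

def atom_pair_compare(
    iqa_matrix: np.ndarray,
    mm_pair_matrix: np.ndarray,
    labels: tuple[list[str], list[str]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-pair differences and summary statistics (R^2, Spearman rho, RMS)."""
    a = np.asarray(iqa_matrix, dtype=float)
    b = np.asarray(mm_pair_matrix, dtype=float)
    if a.shape != b.shape:
        raise InconsistencyError(f"shape mismatch {a.shape} vs {b.shape}")
    ii, jj = np.unravel_index(np.arange(a.size), a.shape)
    rows = pd.DataFrame(
        {
            "site_i": [labels[0][i] if labels else i for i in ii],
            "site_j": [labels[1][j] if labels else j for j in jj],
            "E_ref": a.ravel(),
            "E_mm": b.ravel(),
            "delta": b.ravel() - a.ravel(),
        }
    )
    rows["abs_delta"] = rows["delta"].abs()
    rows = rows.sort_values("abs_delta", ascending=False).reset_index(drop=True)
    x, y = a.ravel(), b.ravel()
    if np.ptp(x) > 0 and np.ptp(y) > 0:
        r2 = float(stats.linregress(x, y).rvalue ** 2)
        rho = float(stats.spearmanr(x, y).statistic)
    else:
        r2 = 1.0 if np.allclose(x, y) else 0.0
        rho = 1.0 if np.allclose(x, y) else 0.0
    summary = {
        "R2": r2,
        "spearman_rho": rho,
        "RMS": float(np.sqrt(np.mean((x - y) ** 2))),
    }
    return rows, summary
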