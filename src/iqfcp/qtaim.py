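"""QTAIM attraction basins of a density's gradient field.

Every grid point is assigned to a basin by steepest-ascent trajectories of the
electron density (fixed initial step, step halving on density decrease), with
two cheap short-cuts that do not change the result: points inside an atom's
beta-sphere are pre-assigned to that atom (the beta-sphere lies inside the
basin by construction), and points where the density is below a floor of
1e-12 e/bohr^3 — which carry no measurable charge — go to the nearest
attractor directly.  Trajectories that stall on an interatomic surface are
assigned to the nearest attractor and counted; a stall at a genuine local
maximum away from every nucleus raises a non-nuclear-attractor error, since
such topologies are outside the supported systems.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InconsistencyError, NonNuclearAttractorError
from .grids import MolecularGrid
from .harmonics import lm_table, regular_solid_harm

__all__ = ["Fragmentation", "BasinPartition", "assign_basins", "basin_population", "basin_multipoles"]

DENSITY_FLOOR = 1e-12   # e/bohr^3; below this a point carries no charge
CAPTURE_RADIUS = 0.3    # bohr
MAX_STEPS = 500
INITIAL_STEP = 0.1      # bohr
MIN_STEP = 1e-4         # bohr; smaller means the trajectory has stalled


@dataclass(frozen=True)
class Fragmentation:
    """Atom index -> fragment label map for a two-fragment complex."""

    labels: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.labels)) != 2:
            raise InconsistencyError(
                f"exactly two fragment labels required, got {sorted(set(self.labels))}"
            )

    @classmethod
    def from_spec(cls, spec: str, n_atoms: int) -> "Fragmentation":
        """Parse e.g. ``A=1-8,B=9-16`` (1-based inclusive atom ranges)."""
        labels: list[str | None] = [None] * n_atoms
        for chunk in spec.split(","):
            m = re.fullmatch(r"\s*(\w+)=(\d+)(?:-(\d+))?\s*", chunk)
            if not m:
                raise InconsistencyError(f"bad fragment chunk {chunk!r} (expected LABEL=i-j)")
            lab, lo, hi = m.group(1), int(m.group(2)), int(m.group(3) or m.group(2))
            for i in range(lo, hi + 1):
                if not 1 <= i <= n_atoms:
                    raise InconsistencyError(f"atom index {i} outside 1..{n_atoms}")
                if labels[i - 1] is not None:
                    raise InconsistencyError(f"atom {i} assigned to two fragments")
                labels[i - 1] = lab
        if any(l is None for l in labels):
            missing = [i + 1 for i, l in enumerate(labels) if l is None]
            raise InconsistencyError(f"atoms {missing} not assigned to any fragment")
        return cls(tuple(labels))  # type: ignore[arg-type]

    @property
    def fragment_names(self) -> tuple[str, str]:
        seen: list[str] = []
        for l in self.labels:
            if l not in seen:
                seen.append(l)
        return tuple(seen)  # type: ignore[return-value]

    def atoms_of(self, label: str) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == label]


@dataclass
class BasinPartition:
    """Basin ownership of a molecular grid plus a membership oracle.

    Basins are indexed by atom index (one nuclear attractor per atom); the
    ``owner`` array gives the basin of each grid point.  ``membership`` runs
    the same ascent for arbitrary points, so downstream restricted-density
    projections share the exact basin definition used on the grid.
    """

    density: object
    grid: MolecularGrid
    attractors: np.ndarray          # (n_atoms, 3)
    owner: np.ndarray               # (n_points,)
    fragmentation: Fragmentation | None = None
    n_stalled: int = 0
    label: str = ""

    @property
    def n_basins(self) -> int:
        return self.attractors.shape[0]

    @property
    def atom_to_basin(self) -> dict[int, int]:
        return {i: i for i in range(self.n_basins)}

    def mask(self, basins) -> np.ndarray:
        """Boolean grid mask for a basin id or iterable of ids."""
        basins = np.atleast_1d(np.asarray(basins, dtype=int))
        bad = [b for b in basins if not 0 <= b < self.n_basins]
        if bad:
            raise KeyError(f"unknown basin ids {bad}")
        return np.isin(self.owner, basins)

    def basins_of_fragment(self, frag_label: str) -> list[int]:
        if self.fragmentation is None:
            raise InconsistencyError("partition carries no fragmentation")
        return self.fragmentation.atoms_of(frag_label)

    def membership(self, points: np.ndarray) -> np.ndarray:
        """Basin index of arbitrary points (same trajectory rules as the grid)."""
        return _ascent_assign(
            self.density, np.atleast_2d(points), self.attractors,
            self.grid.beta_radii, self.grid.nuclei_positions,
        )[0]

    def dump(self, path) -> None:
        """Whitespace table: point index -> basin."""
        np.savetxt(path, np.column_stack([np.arange(self.owner.size), self.owner]), fmt="%d")


# ---------------------------------------------------------------------------
# gradient ascent
# ---------------------------------------------------------------------------

def _locate_attractors(density, positions: np.ndarray) -> np.ndarray:
    """Refine each nucleus to the nearby density maximum.

    For promolecular and near-nuclear densities the maximum sits essentially
    on the nucleus; a maximum further than the capture radius means the
    nucleus is not an attractor of this density (unsupported topology).
    """
    x = positions.copy()
    step = np.full(x.shape[0], 0.02)
    for _ in range(200):
        rho, g = density.density_and_gradient(x)
        gn = np.linalg.norm(g, axis=1)
        live = (gn > 1e-12) & (step > 1e-8)
        if not live.any():
            break
        d = np.zeros_like(x)
        d[live] = g[live] / gn[live, None]
        xn = x + step[:, None] * d
        rhon = density.evaluate(xn)
        ok = live & (rhon > rho)
        x[ok] = xn[ok]
        step[~ok & live] *= 0.5
    moved = np.linalg.norm(x - positions, axis=1)
    if np.any(moved > CAPTURE_RADIUS):
        i = int(np.argmax(moved))
        raise NonNuclearAttractorError(
            f"density maximum near atom {i} lies {moved[i]:.2f} bohr from the nucleus"
        )
    return x


def _ascent_assign(
    density,
    points: np.ndarray,
    attractors: np.ndarray,
    beta_radii: np.ndarray,
    positions: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Assign points to basins; returns (owner array, n_stalled)."""
    n = points.shape[0]
    owner = np.full(n, -1, dtype=int)

    dist = np.linalg.norm(points[:, None, :] - positions[None, :, :], axis=2)
    nearest = np.argmin(
        np.linalg.norm(points[:, None, :] - attractors[None, :, :], axis=2), axis=1
    )
    # beta-sphere pre-assignment
    inside = dist <= beta_radii[None, :]
    has = inside.any(axis=1)
    owner[has] = np.argmax(inside[has], axis=1)

    # negligible-density points: nearest attractor
    todo = owner < 0
    if todo.any():
        rho0 = density.evaluate(points[todo])
        negl = np.zeros(n, dtype=bool)
        negl[np.flatnonzero(todo)[rho0 < DENSITY_FLOOR]] = True
        owner[negl] = nearest[negl]

    active_idx = np.flatnonzero(owner < 0)
    x = points[active_idx].copy()
    step = np.full(active_idx.size, INITIAL_STEP)
    n_stalled = 0
    for _ in range(MAX_STEPS):
        if active_idx.size == 0:
            break
        rho, g = density.density_and_gradient(x)
        gn = np.linalg.norm(g, axis=1)
        d = g / np.maximum(gn, 1e-300)[:, None]
        xn = x + step[:, None] * d
        rhon = density.evaluate(xn)
        ok = rhon > rho
        x[ok] = xn[ok]
        step[~ok] *= 0.5

        da = np.linalg.norm(x[:, None, :] - attractors[None, :, :], axis=2)
        db = np.linalg.norm(x[:, None, :] - positions[None, :, :], axis=2)
        captured = (da <= CAPTURE_RADIUS).any(axis=1) | (db <= beta_radii[None, :]).any(axis=1)
        stalled = (step < MIN_STEP) & ~captured
        if stalled.any():
            n_stalled += _resolve_stalled(
                density, x[stalled], active_idx[stalled], attractors, owner, nearest=None
            )
        if captured.any():
            which = np.where(
                (da[captured] <= CAPTURE_RADIUS).any(axis=1),
                np.argmin(da[captured], axis=1),
                np.argmax(db[captured] <= beta_radii[None, :], axis=1),
            )
            owner[active_idx[captured]] = which
        done = captured | stalled
        if done.any():
            keep = ~done
            active_idx, x, step = active_idx[keep], x[keep], step[keep]
    if active_idx.size:  # exceeded max steps
        warnings.warn(f"{active_idx.size} trajectories exceeded {MAX_STEPS} steps; "
                      "assigned to nearest attractor")
        owner[active_idx] = nearest[active_idx]
        n_stalled += active_idx.size
    return owner, n_stalled


def _resolve_stalled(density, x, idx, attractors, owner, nearest=None) -> int:
    """Stalled trajectories: saddle stalls go to the nearest attractor; a stall
    at a genuine off-nucleus maximum is a non-nuclear attractor (error)."""
    delta = 0.05
    probes = x[:, None, :] + delta * np.concatenate([np.eye(3), -np.eye(3)])[None, :, :]
    rho_x = density.evaluate(x)
    rho_p = density.evaluate(probes.reshape(-1, 3)).reshape(x.shape[0], 6)
    is_max = (rho_p < rho_x[:, None]).all(axis=1) & (rho_x > 1e-8)
    if is_max.any():
        raise NonNuclearAttractorError(
            "gradient ascent converged to a density maximum with no nucleus within "
            f"{CAPTURE_RADIUS} bohr (at {x[is_max][0]})"
        )
    da = np.linalg.norm(x[:, None, :] - attractors[None, :, :], axis=2)
    owner[idx] = np.argmin(da, axis=1)
    return int(x.shape[0])


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def assign_basins(density, grid: MolecularGrid, fragmentation: Fragmentation | None = None,
                  label: str = "") -> BasinPartition:
    """Partition the grid into attraction basins of ``density``."""
    attractors = _locate_attractors(density, grid.nuclei_positions)
    owner, n_stalled = _ascent_assign(
        density, grid.points, attractors, grid.beta_radii, grid.nuclei_positions
    )
    if n_stalled:
        warnings.warn(f"{n_stalled} grid points stalled on interatomic surfaces "
                      "(assigned to nearest attractor)")
    return BasinPartition(
        density=density, grid=grid, attractors=attractors, owner=owner,
        fragmentation=fragmentation, n_stalled=n_stalled, label=label,
    )


def basin_population(partition: BasinPartition, density, grid: MolecularGrid | None = None,
                     basin=None):
    """Electrons of ``density`` inside a basin (or all basins if ``basin`` is None).

    ``density`` need not be the density that defined the basins: integrating a
    monomer density over the partner fragment's basins yields the mutual
    charge-penetration electron count.
    """
    grid = grid or partition.grid
    rho = density.evaluate(grid.points)
    if basin is None:
        return np.array(
            [float(grid.weights[partition.mask(b)] @ rho[partition.mask(b)])
             for b in range(partition.n_basins)]
        )
    m = partition.mask(basin)
    return float(grid.weights[m] @ rho[m])


def basin_multipoles(partition: BasinPartition, density, grid: MolecularGrid | None = None,
                     l_max: int = 2, origin_convention: str = "nucleus"):
    """Real-solid-harmonic basin multipoles of nuclei + electrons.

    Q_lm(I) = Z_I delta_l0 - int_{Omega_I} rho_e(r) R_lm(r - R_I) dr, with the
    origin at each basin's nucleus; the monopole is the QTAIM atomic charge.
    """
    from .multipole import MultipoleSet

    if l_max < 0:
        raise ValueError("l_max must be >= 0")
    if origin_convention != "nucleus":
        raise ValueError("only the 'nucleus' origin convention is supported")
    grid = grid or partition.grid
    rho = density.evaluate(grid.points)
    nuc = grid.nuclei_positions
    charges = getattr(density, "charges", None)
    if charges is None or len(charges) != partition.n_basins:
        raise InconsistencyError("density nuclei do not match the partition")
    Q = np.zeros((partition.n_basins, (l_max + 1) ** 2))
    for b in range(partition.n_basins):
        m = partition.mask(b)
        R = regular_solid_harm(l_max, grid.points[m] - nuc[b])  # (n_lm, n_pts)
        Q[b] = -(R * (grid.weights[m] * rho[m])[None, :]).sum(axis=1)
        Q[b, 0] += charges[b]
    syms = [getattr(n, "symbol", "X") for n in getattr(density, "nuclei", [])]
    return MultipoleSet(sites=nuc.copy(), Q=Q, l_max=l_max, labels=syms,
                        convention="real solid harmonics, traceless quadrupole")
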