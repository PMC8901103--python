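# Methods

## Model

`iqfcp` analyses the electrostatic channel of a noncovalent two-fragment
complex A···B in real space. The total charge density is the electron density
plus point nuclei,

    rho_tot(r) = -rho_e(r) + sum_I Z_I delta(r - R_I),

and space is partitioned into QTAIM attraction basins Omega_I of the electron
density's gradient field, one per nucleus. Restricting density pieces to
basins and summing basins into fragments gives the interacting-quantum-
fragments (IQF) picture of the electrostatic energy: intra-basin self terms
and basin-pair interaction terms whose sum is the total Coulomb energy.

For *unrelaxed* monomer densities placed at the complex geometry
(rho0 = rhoA0 + rhoB0, the zeroth-order density), the electrostatic formation
energy equals the Coulomb interaction of the two monomer distributions
(E0_ele, the first-order/SAPT-like electrostatic energy). Crossing the basin
partition of rho0 with the monomer decomposition leaves exactly four terms:

| term        | pieces                                              | behaviour |
|-------------|-----------------------------------------------------|-----------|
| E_inter_AB  | rhoA0 in Omega_A  x  rhoB0 in Omega_B (with nuclei) | the ordinary interfragment term; -> E0 at long range |
| E_intra_A   | rhoA0+nuclei in Omega_A  x  rhoB0 tail in Omega_A   | stabilizing; nuclear attraction beats cloud repulsion |
| E_intra_B   | symmetric to E_intra_A                              | idem |
| E_tail_tail | the two penetrated tails in opposite basins         | pure e-e, >= 0, small |

The last three vanish with separation and define the basin-resolved charge
penetration energy `E_pen_IQF`. The classical multipole-reference penetration
energy is `E_pen = E0_ele - E_mtp` at a stated truncation order `l_max`
(0, 1 or 2), with `E_mtp` from distributed per-site multipoles; both
definitions are computed side by side, and the record stores the truncation
order because truncation and penetration effects mix in `E_pen`.

Assumptions: every attractor is nuclear (non-nuclear attractors are rejected,
not merged), fragments do not share nuclei, and only the electrostatic
channel is treated — no exchange-correlation, kinetic or dispersion terms.

## Densities

The built-in density model is promolecular: one spherical Gaussian cloud per
atom, `rho(r) = q (alpha/pi)^{3/2} exp(-alpha r^2)`, with populations q
encoding bond polarity and an optional split of a cloud over two displaced
primitives emulating intramolecular polarization ("polarized" mode). The
model is nonnegative, integrates to a prescribed electron count, and has
closed-form gradients and Coulomb potentials (error functions), which supply
the independent oracles for every numerical path. A minimal wavefunction
adapter (`iqfcp.wfn`) evaluates occupied-orbital densities from wfx files
(s/p/d primitives) and molden files (s/p contracted shells) behind the same
evaluate/gradient interface; these densities run through the identical grid,
basin and restricted-potential machinery, only losing the analytic-potential
shortcuts.

## Quadrature grids

Two zones per atom. The beta-sphere radius is 60% of the distance from the
nucleus to its nearest internuclear density saddle (dense 1-D scan refined by
bounded minimization; fallbacks: half the nearest-neighbour distance when no
saddle brackets, 0.2 r_max for isolated atoms). Radial quadrature uses
Gauss-Legendre nodes in the mapped variable `r = R0 q^2/(1-q)^2` applied per
zone (inner: 0..beta; outer: beta..r_max, default r_max = 15 bohr). Angular
rules are named by standard Lebedev point counts and realized internally as
Gauss-Legendre (polar) x uniform (azimuth) product grids of the matching
algebraic degree. Becke cell weights multiply all points — inside a
beta-sphere the owner's cell weight is ~1, so the two-zone picture is kept
while overlapping shells integrate each region exactly once.

Two profiles are used throughout:

| profile    | inner ang/rad | outer ang/rad | use |
|------------|---------------|---------------|-----|
| production | 974 / 382     | 5810 / 512    | heavy reference settings |
| test       | 110 / 60      | 266 / 90      | shipped analyses, test suite |

The test profile conserves the electron count of the toy systems to ~1e-6 e
(asserted at 1e-3 e) and carries all tolerances quoted below.

## Basin assignment

Grid points are assigned by steepest ascent of the density: initial step
0.1 bohr, halved whenever the density would decrease, capture radius
0.3 bohr around an attractor, at most 500 steps. Two shortcuts change
nothing: points inside a beta-sphere are pre-assigned to its atom, and points
with density below 1e-12 e/bohr^3 (carrying no measurable charge) go to the
nearest attractor. Trajectories stalling on an interatomic surface are
assigned to the nearest attractor and counted; a stall at a genuine
off-nucleus maximum raises an error. Attractors are located by refining each
nucleus to its nearby maximum; a maximum further than the capture radius from
every nucleus is unsupported topology. The same membership routine serves
arbitrary points, so the projection meshes below share the exact basin
definition with the grid.

## Restricted potentials (one-center Laplace machinery)

A density restricted to a basin is projected shell-by-shell onto real
orthonormal spherical harmonics about the basin's nucleus (default
l_max = 10, radial mesh of 300 mapped nodes, 28x56 angular projection grid).
The potential follows from the standard radial bracket; cumulative radial
integrals use cumulative Simpson, and the bracket is interpolated with a
cubic Hermite spline whose nodal derivatives are known analytically
(O(h^4)). Projected coefficients below 1e-13 of the global coefficient scale
are zeroed: they are quadrature noise that the `r^{l+2}` / `s^{1-l}` weights
would otherwise amplify catastrophically.

Two accuracy-driven evaluation policies, both pure bookkeeping (they never
change what quantity is computed, only which algebraically equivalent form
evaluates it):

* **Complement form.** For Gaussian densities the restricted potential can be
  written as the analytic full potential minus the expansions of the left-out
  basins. The direct sum's error scales with the (possibly large) piece
  itself, the complement's with the (usually tiny) penetrated tails, so the
  complement is used when the left-out part is a clear electron-count
  minority, or when two comparable halves are evaluated away from the
  left-out region.
* **Orientation policy.** In a piece-piece energy the nucleus-centered
  ("own") piece supplies the potential and the partner supplies grid-side
  density values (which are exact); symmetric pairings average both
  orientations, which makes A<->B relabeling an exact symmetry.

Energies: e-e terms are weighted grid sums of rho x V over the second
piece's region; e-n terms evaluate restricted potentials at point nuclei;
n-n is the exact point sum. A piece paired with itself takes the 1/2 e-e
factor and no nuclear self-interaction. The basin-pair matrix stores half the
pair interaction on each off-diagonal side so the plain matrix sum equals the
scalar total; `E^IJ = M[I,J] + M[J,I]`.

The recorded `E0_ele` of a decomposition is the component-wise sum of the
four terms — the closure identity is therefore exact bookkeeping — and its
*accuracy* is validated against the closed-form Coulomb interaction of the
unrelaxed Gaussian fragments (`zeroth_order_interaction`). At the test
profile the absolute agreement is ~1e-4 hartree for single-site dimers and
~2e-4..1.5e-3 hartree for the multi-atom polar presets; whole-space
(unrestricted) pair interactions are exact to <1e-8 hartree because they take
the analytic route. The sum over all basin-pair pieces reproduces the
analytic total Coulomb energy of a ~185-hartree toy complex to ~5e-4 hartree
(asserted at 1e-3); reaching far below that requires the production radial
orders.

## Multipolar comparators

Basin multipoles are real-solid-harmonic (Racah) moments of nuclei plus
electrons about each basin's nucleus; the monopole is the QTAIM atomic
charge. Site-site interactions convert to Cartesian tensors (Buckingham
traceless quadrupole) and contract dipole/quadrupole with the gradient and
Hessian of the partner's multipolar potential — all l1, l2 <= l_max terms
through quadrupole-quadrupole, the common force-field truncation. ESP-fitted
charges minimize the squared deviation from the density's full potential on
deterministic golden-spiral shells at 1.4/1.6/1.8/2.0 x Bondi radii under a
single total-charge constraint; no hyperbolic restraint is applied (a stated
difference from RESP protocols). Pair-level comparisons report R^2
(linear-regression coefficient of determination), Spearman's rho and the RMS
difference.

## Synthetic study conditions

The toy presets fix the package's standard conditions; they emulate the
noncovalent interaction classes of the benchmark dimer sets, not any specific
complex:

| preset | fragments | R_eq (bohr) | emulates |
|--------|-----------|-------------|----------|
| hb     | two O-H units, +-0.45 e bond polarity, aligned | 5.6 | polar H-bond chain |
| disp   | two neutral Ne-like clouds | 5.8 | dispersion contact |
| mixed  | O-H unit + Ne-like cloud, offset | 6.0 | mixed polar/apolar |
| polar  | two *inequivalent* single-site dipoles (split primitives) | 5.0 | multipole-decay studies |
| hf     | F-like anion-ish + H-like cation-ish (0.3 e transfer) | 3.2 | strong heteronuclear contact |

Two deliberate choices: the intramolecular O-H contacts are kept soft
(2.4 bohr) so every basin interface carries noncovalent-scale density
(<~0.05 e/bohr^3) — covalent-scale interfaces (~0.4 e/bohr^3) are resolvable
only with production-profile angular orders, exactly why the heavy settings
exist; and the `polar` fragments are inequivalent because identical aligned
fragments cancel all odd-order (l1+l2 odd) multipole terms by symmetry, which
would make truncation-error comparisons degenerate. Scans rigidly translate
fragment B along the centroid axis to factors of R_eq (default
0.90...2.00, the eight-point convention of scanned benchmark sets; the list
is configurable). Optional seeded jitter perturbs atom positions
reproducibly.

What passing tests on these toys do *not* show: promolecular Gaussians have
no shell structure, no covalent bonding density and no relaxation, so the
absolute energies are not comparable to ab initio complexes; the tests
validate the decomposition identities, limits, signs and the numerical
machinery, which are density-agnostic.

## Numerical parameters (defaults)

| parameter | default | meaning |
|-----------|---------|---------|
| beta_fraction | 0.60 | beta radius / distance to nearest saddle |
| r_max | 15 bohr | outer radial cutoff |
| radial map R0 | 1.0 bohr | scale of r = R0 q^2/(1-q)^2 |
| capture radius | 0.3 bohr | ascent termination near an attractor |
| ascent step | 0.1 bohr, halved on decrease | trajectory step |
| density floor | 1e-12 e/bohr^3 | nearest-attractor shortcut |
| l_max (Laplace) | 10 | restricted-potential truncation |
| projection mesh | 300 radial x (28x56) angular | f_lm sampling |
| coefficient floor | 1e-13 (relative) | projection noise gate |
| l_max (multipoles) | 2 | comparator truncation |
| ESP shells | 1.4/1.6/1.8/2.0 x Bondi | fitting surface |

Energies are reported in kcal/mol (627.509474 kcal/mol per hartree) with
hartree kept alongside for numerical work; geometry I/O is in angstrom,
internals in atomic units.

## Known limitations

* Only the electrostatic channel: no exchange-correlation, kinetic,
  dispersion or deformation energies beyond the electrostatic bookkeeping.
* Nuclear attractors only; cage/bond maxima raise errors.
* The one-center Laplace path replaces short-range bipolar expansions; its
  absolute accuracy at the test profile is the ~1e-4..1e-3 hartree quoted
  above, and basin interfaces through high density need production grids.
* The molden reader covers s/p shells, the wfx reader s/p/d primitives.
* Relaxed-density analyses accept synthetic polarized densities; no SCF is
  performed anywhere.
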