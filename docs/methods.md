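# Methods

This note records the models implemented in cspkit, the defaults and the
reasoning behind them, what the synthetic fixtures do and do not emulate,
and the numerical choices that make results reproducible.

## Units and constants

Internal units are Å, eV, amu, K, and elementary charge. Relative lattice
energies are reported in kJ/mol **per molecule** via 1 eV = 96.48533 kJ/mol;
the per-molecule convention is an explicit choice (landscapes divide the
cell energy by Z) and is flagged in the landscape table. Constants:
k_B = 8.617333262e-5 eV/K, ħ = 6.582119569e-16 eV·s,
e²/4πε₀ = 14.3996 eV·Å. Frequencies convert via
ω[rad/s] = √(λ[eV/Å²/amu]) × 9.82269e13.

Element data (masses, Bondi/Alvarez-style van der Waals radii, Cordero
covalent radii) ship as a single packaged table used consistently by volume
estimation, contact checking, and bond perception.

## Structure generation

A candidate cell is drawn inside a ±15 % volume window around
`Z·(Σ_atoms 4/3·π·r_vdW³)/0.55` (0.55 is a typical packing coefficient of
organic crystals). Cell shapes are sampled by log-normal length ratios
(σ = 0.25) with angles uniform on [60°, 120°] where the lattice system
permits; monoclinic and orthorhombic systems pin the constrained angles at
90°. The first molecule gets a uniform random quaternion orientation and a
uniform fractional position; the space-group operators (general positions
only, taken from the tabulated groups) replicate it. Candidates violating
`d_AB ≤ s_r(r_A + r_B)` for any intermolecular pair — including contacts of
a molecule with its own periodic images — are rejected and re-sampled up to
`max_attempts` (default 2000).

Intramolecular pairs are identified against the *unwrapped* molecular
geometry: for two sites of the same molecule, the one image vector that
realizes the bond-graph displacement is exempt; all other images count as
intermolecular contacts. This makes the check correct for molecules
straddling the cell boundary.

**Rigid press.** The cell volume is first multiplied by `expansion_factor`
(default 1.6); the algorithm then repeatedly proposes an isotropic 4 %
volume shrink and re-minimizes the smooth overlap penalty
`Σ max(0, s_r(r_A+r_B) − d)²` over 6 strain components plus 6 rigid-body
degrees of freedom per molecule (L-BFGS on the penalty; molecules stay
internally rigid by construction). A shrink is accepted only when the
penalty returns to zero *and* the volume actually decreased; on failure the
step is halved, and the run stops when the volume step falls below 0.1 %.
Space-group symmetry is not preserved by the press. Because the objective
contains no attractive term, the fixed point can be a strongly sheared cell;
that is acceptable for its role here (densification before relaxation).

## Energy models

* **Pair potentials** (Lennard-Jones, Buckingham) sum over *all* lattice
  images within the cutoff — not merely the nearest image — so energies are
  exactly extensive under supercell replication. Forces, the virial stress
  `σ = (1/V) Σ φ′(r)/r · r⊗r`, and the pair Hessian are analytic.
  An optional *bonded* channel maps species pairs closer than
  1.2×(sum of covalent radii) onto a harmonic bond ½k(r−r₀)²: this is what
  lets a classical pair potential act as a stable teacher for molecular
  crystals (nonbonded LJ would crush or burst covalent bonds). The
  classification is distance-based and therefore discontinuous at the
  bonding threshold; trajectories and relaxations never approach it in
  practice.
* **Ewald summation** uses the standard real/reciprocal/self split with the
  splitting parameter derived from the requested relative accuracy
  (default 1e-8) and real-space cutoff (default 15 Å); if the user pins the
  splitting parameter, the real-space cutoff is extended so the truncation
  error still meets the accuracy target (this is what makes the
  splitting-invariance property hold to 1e-7). Cells must be neutral.
* **Dispersion**: Becke–Johnson-style rational damping
  `f(r) = r⁶/(r⁶+r₀⁶)` on the two-body `−C6/r⁶` term (used during
  optimization); the Axilrod–Teller–Muto three-body term is evaluated only
  as a post-optimization single-point correction, with user-supplied
  uniform or per-triple C9 (no coefficient generation machinery).
* **Surrogate**: per-atom linear regression over radial descriptors —
  Gaussians (8 centers on 0.8–5 Å, width = spacing) times a cosine cutoff,
  accumulated per neighbor element. Energy is a sum of atomic
  contributions, so predictions are exactly invariant to permutation,
  rotation, and translation. Training minimizes per-atom energy residuals
  plus force residuals (weight 0.1) by a closed-form regularized
  least-squares solve; the normal equations are normalized by the row count
  so duplicating the sample set leaves the solution exactly unchanged.
  Default regularization 1e-8.

The teacher/student split used throughout testing mirrors the production
roles: teacher = pair potential (plus Ewald for ionic toys), student =
surrogate ensemble.

## Cluster sampling and active learning

A molecular shell contains every whole, unwrapped molecule (distinct
periodic images count separately) with any atom within the cutoff of any
central-molecule atom. *n*-mers (n = 1–8) take the central molecule plus
n−1 shell members: the nearest set first (ranked by minimum intermolecular
atom–atom distance — centroid distance misorders elongated molecules), then
seeded random combinations without duplicates.

Tethered sampling runs BAOAB-split Langevin dynamics (default 300 K,
1 fs steps, friction 0.01 fs⁻¹, stride 100) with a per-atom harmonic tether
`k_tether·|x−x₀|²` (default k = 0.005 eV/Å²) and no bond constraints. The
integrator automatically substeps when the tether frequency would exceed
~0.2 rad per step, so stiff-tether probes remain stable.

Active learning trains 4 surrogates on independent 80 % subsets, computes
`σ = E_std/√N` per cluster, selects `σ > 2·median(σ)` (median over the
current order's full pool; strict inequality), labels with the teacher,
and retrains — one pass per order, previously processed orders are not
revisited. Teacher failures skip the sample and are logged. One practical
caveat, verified experimentally: once the pool's median σ reaches the
ensemble's subset-resampling noise floor (a few 1e-4 eV in the test
fixture), a labelling cycle no longer reliably reduces it; the
uncertainty-reduction property is therefore probed from a deliberately
sparse seed set where the ensemble starts genuinely uncertain.

## Relaxation, symmetry, deduplication

The relaxer is a BFGS with Armijo backtracking over the 9 cell components
plus all fractional coordinates simultaneously; the cell gradient is
`dE/dh = h⁻ᵀ·V·σ`, so forces and stress share one quasi-Newton step and
pure rotations of the cell are gradient-free. Convergence requires RMS
atomic force ≤ 0.001 eV/Å and (in cell modes) RMS cell-vector gradient ≤
0.1× that — the tighter cell criterion keeps relaxed lattice constants
reproducible to ~1e-4 Å. Accepted steps never increase the objective; a
failed line search restarts once from steepest descent before giving up.
Fixed-volume mode renormalizes det(h) exactly at every evaluation and
projects the volume-changing component out of the gradient analytically.
External pressure enters as +p·V.

Symmetry detection enumerates integer fractional rotation matrices
(entries −1..1) that preserve the metric, searches translations against
site matching within symprec (default 0.2 Å), averages sites over the found
orbit (idempotent by construction), and identifies the group by matching
the operator set — over a few candidate origin shifts (inversion centers,
first sites) — against the tabulated space groups, falling back to P1.

Deduplication Niggli-reduces both lattices (Krivy–Gruber), compares sorted
lengths (fractional tolerance 0.2) and angles (5°), then searches origin
translations anchored on same-species sites with optimal species-aware
assignment (Hungarian algorithm on minimum-image distances) plus mean-shift
refinement; structures match when the worse of the two directed site-RMS
values is ≤ 0.2 Å. Site comparison maps the second structure's fractional
coordinates into the first lattice, which assumes matching cell settings —
sufficient for relaxed duplicates, not a general-setting matcher.
Representatives are lowest-energy when energies are given, else first seen.

## Phonons and thermodynamics

Force constants come from the Hessian of a supercell whose multiplicities
are the smallest integers making every lattice vector ≥ 10 Å (analytic
Hessian when the calculator provides one, else ±0.005 Å central
differences of forces). The reference-cell block is symmetrized and the
acoustic sum rule enforced on the self terms; the Einstein-crystal fixture
disables the sum rule since its on-site springs deliberately break
translation invariance. The dynamical matrix uses minimum-image-wrapped
supercell translations in its phases, so Fourier interpolation uses the
shortest pair vectors; it is exact at q commensurate with the supercell and
an interpolation elsewhere. Negative eigenvalues are reported as imaginary
modes; modes below ~1e-3 THz are treated as acoustic zeros.

F_vib follows the harmonic formula (ZPE + Kirchhoff term) on a Γ-centered
uniform q-mesh with equal weights (default 8×8×8; symmetry reduction is not
applied — correctness over speed at this scale). The quasi-harmonic scan
defaults to the 17-point inclusive grid 0.95, 0.9625, …, 1.15 (the stated
16-optimization count and the stated 0.0125 step over 0.95–1.15 are
mutually inconsistent; the factor list is exposed explicitly and the
inclusive 17-point grid adopted). The window is interpreted in volume, not
linear, scale. Per volume: fixed-volume variable-cell relaxation → force
constants → F(T,V) = U(V) + F_vib(T,V). Points with imaginary modes are
dropped and logged (policy configurable to strict); fewer than 5 surviving
points is an error. Each isotherm is fitted to the third-order
Birch–Murnaghan form (initialized from a local quadratic; a fit whose V₀
leaves the scanned range is a failure signal); G(T,p) is the fitted minimum
(+pV via bounded scalar minimization when p ≠ 0) and V(T) its argmin.
Rankings are computed at p = 0, where Helmholtz and Gibbs energies
coincide. C_p = −T·∂²G/∂T² by central differences on a uniform grid
(default ΔT = 10 K; endpoints one-sided).

## Ranking and comparison

Landscapes report E_rel = (E − min E)×96.48533 kJ/mol per molecule, sorted
ascending with ties broken by structure id. Agreement metrics: MAE, RMSE,
tie-aware Kendall τ-b, matched-% via the deduplication criterion, and a
molecular-cluster RMSD: clusters of up to `n_molecules` (default 15,
hydrogens excluded by default) are aligned by principal-axis candidate
rotations of the whole cluster (single-molecule alignment is ambiguous for
linear or symmetric central molecules) followed by iterated greedy centroid
matching and full-cluster least-squares superposition; both directions are
computed and the larger RMSD reported. This measure is comparable in
spirit, not numerically, to proprietary packing-similarity tools.

## Synthetic fixtures — what they emulate and what they do not

* `lj_fcc` — a close-packed atomic solid; the 1 eV well depth (σ = 3.4 Å)
  deliberately makes 300 K a moderate temperature so the 0–400 K
  quasi-harmonic scan probes solid-state thermal expansion rather than
  melting. Argon-strength parameters (ε = 0.0104 eV) are used where the
  natural stiffness matters (finite-displacement truncation checks).
* `rigid_diatomic_crystal` — two N₂-like rigid diatomics related by
  inversion in a skewed cell, with the bonded-LJ teacher; exercises
  molecule perception, shells, generation, and relaxation.
* `einstein_crystal` — on-site springs with a known ω₀; closed-form F_vib
  and the Dulong–Petit limit. Its pinning-medium variant (zero energy,
  k·I curvature) combined with a volume-only energy term gives a rigid
  fixture whose frequencies are volume-independent — the zero-thermal-
  expansion control.
* `rocksalt_ions` — ±1e point charges at rocksalt sites; the Madelung
  constant against an Evjen-weighted direct sum is the Ewald oracle.
* `one_d_chain` — nearest-neighbor springs; the textbook dispersion
  2√(k/m)|sin(qa/2)|.

These fixtures have no conformational flexibility, no electrostatic
multipoles, no hydrogen bonding, and molecule sizes far below drug-like
targets. Passing tests therefore demonstrate the correctness of the
machinery — sums, derivatives, selection rules, thermodynamic identities —
not the chemical accuracy of any surrogate on real molecular crystals.

## Problem sizes

The default test and acceptance runs use: 4-atom LJ cells with 2×2×2
supercells and 3³–4³ q-meshes; 9–17 point volume scans; pools of 200 dimers
and 100 trimers with a 40-monomer seed set and 10 paired seeds for the
active-learning experiment; 100 random crystals for the contact-rule
brute-force check; 4–6 structures per pipeline smoke run. These sizes keep
the full suite in a few minutes while leaving every algorithmic path
exercised at full fidelity.

## Known limitations

* General positions only; no Wyckoff special positions or point-group-based
  space-group compatibility analysis.
* The structure matcher assumes comparable cell settings after Niggli
  length/angle screening; it is not a general-purpose crystal matcher.
* Fourier interpolation of force constants picks one image at the supercell
  boundary (no half-weight splitting), adequate for interactions shorter
  than half the supercell.
* The rigid press has no attractive term and can terminate in sheared
  cells; it is a densification pre-stage, not an energy minimizer.
* No LO–TO splitting, no anharmonicity beyond the quasi-harmonic volume
  dependence, no charged-fragment enumeration heuristics beyond formal
  charge tags.
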