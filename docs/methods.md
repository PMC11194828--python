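# Methods

## Model

`iwmgb` computes the hydration free energy (HFE) of a small molecule as

    dG_solv = dG_el + dG_np,        dG_el = dG_el_dipole + dG_el_corr,
    dG_np   = dG_cavity + dG_vdW,

within the linear-response, fixed-boundary implicit-solvent picture. The
solute (dielectric eps_in, default 1) is separated from the solvent
(eps_out, default 80) by the solvent-excluded surface (SES), which acts as
the dielectric boundary; the solvent-accessible surface (SAS) sits one
probe radius further out.

### Dipole level (generalized Born / ALPB)

The "ground state" electrostatics is the ALPB flavor of the generalized
Born model,

    dG_el_dipole = -(ke/2) (1/eps_in) (1 - beta e^{-kappa f_ij})/(1 + alpha beta)
                   * sum_ij q_i q_j [ 1/f_ij + alpha beta / A ],

with beta = eps_in/eps_out, alpha = 0.580127, ke = 332.0636 kcal·Å/mol/e²,
A the electrostatic size of the solute, kappa the inverse Debye length
(0 by default — parametrization assumes ion-free water), and
f_ij = sqrt(r_ij² + R_i R_j exp(-r_ij²/4R_iR_j)) the smooth pair function
over effective Born radii. For a centered charge in a sphere with R = A the
expression collapses exactly to the Born formula; this limit is enforced by
tests and by the acceptance script.

Effective Born radii use the "R6" surface-integral definition,
R_i^{-3} = (1/4pi) ∮ n·(r-r_i)/|r-r_i|⁶ dA, discretized with the
triangle-centroid rule, exact on spheres. A uniform correction
B = 0.028 Å⁻¹ is applied as 1/R = 1/R_raw − B (enlarging radii, which
compensates the R6 underestimate for buried atoms); the sign and placement
live in a single constant (`constants.R6_UNIFORM_CORRECTION_B`) so the
convention can be flipped in one place. The corrected inverse radius is
clamped at 1/(10·max rho) to keep deeply buried atoms finite.

The electrostatic size A is the capacitance-equivalent radius of the
volume-weighted inertia-equivalent ellipsoid: atoms contribute as solid
spheres to a gyration tensor, its eigenvalues give ellipsoid semi-axes
a_k = sqrt(5 lambda_k), and A = 1/R_F(a1², a2², a3²) via the Carlson
symmetric elliptic integral. This is exact for a sphere (A = rho),
scale-equivariant, and grows with elongation at fixed volume. A cruder
fallback (radius of gyration + mean atomic radius) is available behind a
flag for degenerate geometries.

### Apparent surface charge density

Instead of a Poisson solve, the SCD induced at the boundary by solvent
dipole polarization is evaluated analytically at each mesh vertex,

    sigma(r') = -(1/4pi)(1/eps_in)(1-beta)/(1+alpha beta)
                * sum_i q_i [ n·(r'-r_i)/|r'-r_i|³ + alpha beta/(A |r'-r_i|) ],

then averaged to triangles (mean of the three vertex values) and to atoms
(unweighted mean over the triangles owned by an atom; ownership = nearest
atom to the triangle's first vertex, ties to the lowest index). The
alpha·beta/A term mirrors the ALPB energy kernel; for the centered Born
sphere the expression is exact (uniform sigma integrating to
-q(1-beta)/eps_in). Buried atoms (owning no triangles) carry NaN averages,
never silent zeros.

### Water-multipole corrections

Water molecules carry quadrupole and octupole moments whose first-shell
orientational polarization is invisible to dipole-only continuum theory.
With the first shell collapsed onto the SES, the corrections are surface
sums (see `multipoles.KERNEL_TABLE`):

    dG_el_corr = ke sum_i q_i sum_T A_T [ F0 |s_T|/d⁴ + F1 s_T/d³ + F2 s_T/d⁴ ],

d = |r_i - r_T| to the triangle centroid. F1 (Å²) weights the quadrupole
(reaction field ~ 1/r³), F2 (Å³) the linear octupole (~1/r⁴), and F0 (Å³)
the cubic octupole responsible for charge hydration asymmetry (CHA): its
kernel uses |s_T|, so the term is odd under a global charge flip while the
F1/F2 terms are even. These parities, the decay orders, and the printed
units of F0–F2 jointly fix the kernel forms; the correction is linear in
(F0, F1, F2), which the optimizer exploits. Any constant prefactor is
absorbed into the optimizable weights.

### Nonpolar terms and polar/nonpolar coupling

    dG_np = sum_{T' in SAS} gamma(s_T') A_T'  -  sum_i xi_i a_i / (R_i + |D_i|)³

The dispersion prefactor a_i = (16pi/3) rho_water eps_iw sigma_iw⁶ is the
half-space integral of the attractive LJ tail against TIP3P water oxygen
(Lorentz–Berthelot combination; generic per-element LJ defaults ship in
`constants.DEFAULT_ELEMENT_LJ` and are overridable per parameter file,
since published parametrizations do not tabulate a_i).

Two variants:

* **NC (no coupling)** — gamma = gamma0 constant, D_i = rho_w, one xi per
  element.
* **WC (with coupling)** — gamma(s) = gamma0 (1 + g1 s² + g2 s⁴) with s the
  formal SCD evaluated on the SAS, and D_i(s_i) = |rho_w (1 + c1 s_i² +
  c2 s_i⁴)| with s_i the per-atom SES average; one shared xi. Both
  functions are even (the boundary shift cannot depend on the field's
  sign) with gamma(0) = gamma0 and D(0) = rho_w, so the coupling vanishes
  quadratically as charges go to zero; the absolute value keeps the
  effective SAS outside the dielectric boundary. Buried atoms fall back to
  s_i = 0 with a logged count.

### Surfaces

SES/SAS triangulations are built on a Cartesian grid (default spacing
0.5 Å, configurable): the SAS is the zero level of the exact distance
field of the probe-inflated atom spheres; the SES is recovered by eroding
the probe-center region back by rho_w, using exact point-to-triangle
distances to the SAS mesh (KD-tree prefilter, vectorized closest-point) so
the erosion field is sub-voxel accurate. Marching cubes extracts both
level sets; orientation is repaired to outward (positive signed volume)
per connected component. Disjoint atom clusters are meshed on independent
local grids, so widely separated fragments cost nothing extra. Interior
cavity components are kept. On spheres the SES area converges to 4·pi·r²
at second order (−0.9% at 0.25 Å for r = 2 Å); exact icosphere fixtures
are available where discretization error must be excluded. External OFF/PLY
meshes can be imported (watertightness enforced, inward normals fixed,
zero-area triangles dropped with a warning).

## Parameter presets

* `nc` — the fully published optimized set: radii (H, O, N, C) =
  (0.82, 1.02, 1.57, 1.63) Å, rho_w = 0.80 Å, F0 = 5.788e-2 Å³,
  F1 = −1.452 Å², F2 = 9.528e-1 Å³, gamma0 = 4.017e-2 kcal/mol/Å²,
  xi = (6.802e-2, 5.000e-2, 5.981e-1, 1.254e-1).
* `wc`, `balanced` — published radii/probe ((1.26, 1.12, 1.18, 1.95)/0.70 Å
  and (1.20, 1.01, 1.09, 1.90)/0.90 Å respectively), but **synthetic**
  non-radii defaults: the coupled model's non-radii optima are not
  reproducible here, so values were chosen once to match the documented
  qualitative behaviour (surface tension rising ~4x and the DB–SAS offset
  shrinking ~0.3 Å near a strongly charged oxygen) and are not revisited.
  Quantitative WC energies therefore carry preset-level uncertainty;
  the functional forms and symmetries are exact.

Sulfur is accepted in input but has no preset radius; every preset
requires a user-supplied custom S radius.

## Parametrization pipeline

Three nested levels, mirroring the published procedure: Level 1 scans
rho_w over {0.60 + 0.05 n, 0 ≤ n ≤ 16} Å; Level 2A runs differential
evolution (scipy, seeded) over atomic radii, bounded per element to
[max(floor, R_min − rho_w), R_max − rho_w] with floors 0.6 Å (H) / 1.0 Å
(heavy) — the (R_min, R_max) windows describe the first peak of the
atom–water-oxygen RDF and ship as synthetic defaults bracketing all three
preset radii sets; Level 2B runs an inner DE over the non-radii parameters
on geometry cached from 2A (meshes, SCD fields, Born radii, and the three
multipole surface sums are content-hash cached, making a 2B evaluation a
few dot products). Non-radii bounds default to boxes bracketing the NC
optima by ≥ 3x. The objective is the train-set RMSE vs reference HFEs;
full-scale DE settings (pop, gen) = (15, 15) for 2A and (30, 5000) for 2B
are recorded in `optimizer.DE_DEFAULTS`, while tests and the acceptance
script use reduced settings (pop 10, gen 60, single probe, fixed radii)
that the linearity of the NC model in its non-radii parameters makes
sufficient for exact recovery. `balanced_rerank` re-scores fit candidates
by train RMSE + weight·auxiliary RMSE (default weight 1 — "same weight"
interpreted as an unweighted sum, exposed as a parameter), ties keeping
input order.

## Synthetic data

`fixtures.make_toy_set` emulates a neutral rigid small-molecule set:
2–12 atoms of H/O/N/C attached at bonded distances (1.0–1.5 Å, minimum
separation 0.9 Å), uniform partial charges recentred to exact neutrality,
deterministic per seed. It does not emulate real chemistry — no force-field
atom types, no AM1-BCC charge correlations, no conjugation or hydrogen-bond
geometry — so passing tests demonstrate numerical and structural
correctness of the model pipeline, not chemical accuracy on experimental
HFEs. `fixtures.oracle_energy` recomputes every quantity with plain Python
double loops (and the electrostatic size by direct numerical quadrature of
the capacitance integral) on the same meshes; it shares no code path with
the vectorized pipeline beyond the mesh geometry itself.

## Numerical choices

* Units: Å, e, kcal/mol; ke = 332.0636 (AMBER convention).
* SCD at vertices then averaged to triangles; multipole distances to
  triangle centroids.
* Nearest-atom ties break to the lowest atom index (determinism).
* Vertex within 1e-6 Å of a charge, coincident atom centers, and
  non-watertight imported meshes are hard errors.
* Salt screening enters as beta -> beta e^{-kappa f_ij} inside the pair
  kernel (reduces exactly to the salt-free form at kappa = 0, monotonically
  more favorable with kappa); kappa from molarity via 0.3287 sqrt(I) Å⁻¹
  at 298 K.
* DE seeds derive from a single SeedSequence; fixed seed gives bit-identical
  fits. CLI JSON uses sorted keys and fixed-format floats.

## Known limitations

* The WC/balanced non-radii presets are synthetic (above); WC totals are
  form-correct but not a published parametrization.
* The SCD is a one-shot analytical approximation — no induced-charge
  self-consistency; accuracy inherits ALPB's sphere-anchored form.
* Grid SES misses sub-grid crevices; 0.5 Å default matches the scale used
  for parametrization, halve it for convergence checks.
* Single conformation only; no trajectory averaging, no conformational
  sampling.
* Elements beyond H/O/N/C(/S with custom radius) are rejected rather than
  guessed.
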