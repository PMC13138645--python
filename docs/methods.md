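# Methods

This note documents the models implemented in `ggcflow`, the parameters
that matter, the numerical choices behind them, and what the synthetic-data
suites do and do not demonstrate.

## Geometric eigenmodes

The shape of a closed surface is summarized by the eigenfunctions of its
Laplace–Beltrami operator, obtained by solving the Helmholtz problem
`A ψ = λ B ψ` on the triangulated mesh. We use linear (P1) finite
elements: the classical cotangent stiffness matrix `A` (zero row sums, so
constants are in the null space) and the consistent mass matrix `B`
(entries `area/6` and `area/12` per triangle; total sum equals the surface
area). On a closed connected mesh the first eigenvalue is zero with a
constant eigenfunction; we label it Mode 1 and number upward, so "Mode 2"
is the first mode with spatial contrast.

**Contract and validation.** The deliverable is the *spectrum*, not the
element order: on a unit icosphere (subdivision 4, 2,562 vertices) the P1
discretization reproduces the analytic sphere eigenvalues ℓ(ℓ+1) — 2 with
multiplicity 3 and 6 with multiplicity 5 — within 2%, and the error
decreases under mesh refinement. Higher-order elements are an extension
point, not a requirement at these mesh scales.

**Numerics.** The generalized eigenproblem is solved by shift-invert
Lanczos (shift −1e−8, so the zero mode is extracted robustly; residual
tolerance 1e−10). Two non-obvious choices: the Lanczos basis size is at
least 2k+1 (floor k+40) because the default basis can drop one copy of a
tightly degenerate cluster (observed on the sphere's ℓ=2 quintet), and the
start vector is a fixed deterministic vector because the library default
is random and would make otherwise-identical runs differ in the last bits.
Modes are mass-orthonormal; the sign of each mode is fixed by requiring
its largest-|value| vertex to be positive. Within a degenerate eigenvalue
group the returned basis is arbitrary, so comparisons on symmetric meshes
must use eigenvalue-grouped subspace criteria — the tests do, and users
comparing single modes on near-symmetric surfaces should too.

## Connectivity gradients

Nodes are spatially coherent micro-clusters from K-means on raw 3D
coordinates (k-means++ initialization, 50 restarts, explicit seed;
default K = 400 for real connectomes, smaller in the desk-scale suites).
Node connectivity profiles are sparsified per row to the top
`kept_fraction` entries (default 0.10, exposed as a parameter since no
canonical value exists), correlated pairwise (Pearson), and mapped through
the normalized-angle kernel `s = 1 − arccos(r)/π`, a scale-invariant
similarity in [0, 1].

Diffusion-map embedding then eigendecomposes the Markov operator of the
α-normalized affinity (`α = 0.5`, the standard anisotropic-diffusion
default). Components are computed exactly via the symmetric conjugate
matrix and a dense Hermitian eigensolver (connectome-scale matrices are at
most a few thousand nodes, so the dense route is both exact and
deterministic), scaled by λ/(1−λ) at diffusion time 0 (automatic
multiscale weighting) or by λᵗ otherwise, and sign-fixed by the same
positive-maximum convention as eigenmodes — all gradient comparisons use
|r|, so the sign convention is cosmetic. Explained variance of component k
is λₖ divided by the sum of all positive nontrivial eigenvalues, so the
fractions of a full embedding sum to 1 and a truncated embedding reports
the same per-component values.

## Geometry–gradient coupling

For one gradient map and K eigenmodes, the correlation spectrum is
|corr(gradient, mode k)| for each k, with the entry for the constant
Mode 1 defined as 0 — this preserves conventional mode numbering while
excluding the contrast-free mode from any peak search. Peak coupling is
the spectrum argmax (lowest index on ties). Across gradients, the
coupling–variance relation is the Pearson correlation between peak |r| and
explained variance. Descriptive spectra default to Pearson; spin-test
inference defaults to Spearman. When gradients live on nodes and modes on
vertices, modes are region-averaged onto nodes (never the reverse: nodes
are coarser, so that direction is well-posed).

## Spin test

Smooth maps inflate naive correlation tests, so significance comes from a
spatial permutation that preserves autocorrelation: vertices are projected
radially onto the centroid-centered unit sphere (valid for star-shaped
surfaces; strongly non-star-shaped structures need externally supplied
spherical coordinates, which every function accepts), the sphere is
rotated by Haar-uniform rotations, and the probe map is remapped to the
nearest rotated neighbor (chordal = angular ordering; exact ties break to
the lowest index). Only the probe is rotated; the reference stays fixed.
The p-value is the add-one estimator
`p = (#{|r_null| ≥ |r_obs|} + 1)/(n_perm + 1)`, hence always in
[1/(n_perm+1), 1]; the default is n_perm = 10,000 for production use and
500 in the calibration suites. Rotation matrices come from scipy's
Haar-uniform sampler driven by an explicit generator. Permutation index
arrays can be precomputed once per sphere and shared across many tests.

## Synthetic data: what it emulates, and what it does not

The generators target the *statistical structure* of surface-derived data,
not the imaging physics — no diffusion signal, tractography, or
registration is simulated. All generators are pure functions of their
arguments including the seed.

- **Bumpy spheres** stand in for folded cortex. The radial perturbation is
  `r(v) = R(1 + a·b(v))` with `b` a fixed product of cosine lobes along
  the three Cartesian axes with small phase offsets. This form was chosen
  over lobes in spherical angles after measurement: angular lobes fold
  mostly along rings, so the convex hull inflates nearly as fast as the
  pial surface and the gyrification index stays ≈ 1; the Cartesian product
  folds in all tangent directions (GI 1.34 at subdivision 3, amplitude
  0.3, frequency 6) and GI is monotone in amplitude. The phase offsets
  break rotational/mirror symmetry so the low spectrum is non-degenerate,
  which single-mode recovery tests require. Amplitude must be < 1
  (self-intersection risk); the pattern is deterministic given frequency.
- **Planted connectomes** give each node a latent coordinate (the node
  mean of a chosen eigenmode, index ≥ 2) and a 64-point Gaussian response
  profile centered on it (bandwidth 0.5 × sd(latent)), plus optional
  N(0, noise_sd) profile noise; the matrix is `P Pᵀ` clipped to ≥ 0 with
  zero diagonal, hence exactly symmetric and itself a *local* kernel in
  the latent coordinate. Recovery is therefore measured by diffusion
  embedding of this matrix directly: noise-free |r(SG1, latent)| > 0.99,
  median ≈ 0.98 over 20 seeds at noise 0.25, ≥ 0.9 at noise 0.5, with the
  planted mode index recovered 20/20. The normalized-angle route is also
  exercised end to end, but that kernel assigns uncorrelated profiles a
  baseline similarity of ≈ 0.45, which globally couples distant nodes and
  caps Pearson recovery near 0.97 noise-free — a property of the kernel,
  not a defect of the embedding, and worth knowing when interpreting
  absolute coupling values on real data.
- **Smooth null maps** are random eigenmode mixtures `Σ wₖ·modeₖ` (k ≥ 2,
  wₖ ~ N(0, e^(−decay·k))): spatially autocorrelated but with no preferred
  mode alignment. Calibration uses decay 0.1 over 60 modes on an
  icosphere — on a sphere, rotations are exact isometries, so this is the
  cleanest setting for testing type-I control; measured rejection at
  α = 0.05 is 0.05–0.07 across seeds (200 replicates, 500 permutations),
  inside the 95% binomial band [0.022, 0.089].
- **Cohort tables** draw lognormal individual totals with a target
  coefficient of variation around a 3,252 mm³ brain and split them by
  Dirichlet-perturbed region fractions (relative jitter 0.02 by default;
  0 gives exact fractions).

Passing these suites demonstrates that each operator does what it claims
on data with known truth; it does not demonstrate robustness to real-data
failure modes (registration error, tractography bias, non-spherical
topology, partial coverage), which are out of scope.

## Morphometry conventions

- **Gyrification index** = pial surface area / convex-hull area of the
  vertex set; ≥ 1 for closed meshes, 1 for convex shapes, scale-invariant.
  The hull is the parameter-free choice of outer contour; morphological
  closing is deliberately not offered.
- **Vertex areas** use the barycentric one-third rule (not Voronoi):
  simpler, always positive, and exactly conserving — vertex and regional
  sums reproduce the total area to 1e−9 relative.
- **Coefficient of variation** uses the n−1 sample standard deviation.
- **Normative check** = Student-t confidence interval *of the mean* of the
  reference group (not a prediction interval), strict exclusion; this is
  the literal reading of "mean and 95% CI" screening and is the documented
  default rather than a hidden choice.
- **Lobule standardization**: the 17 enumerated cerebellar labels (I–X,
  SIM, Par, Cop, Fl, PFl, Crus I, Crus II) merge I+II and IV+V to give 15
  subregions, expanded ×2 hemispheres to 30 partitions (L block first,
  canonical order within block). Merging conserves totals exactly.
- Coordinates are millimeters throughout; no unit inference.

## Problem sizes in the default suites

The shipped tests and the acceptance script run at desk scale, chosen so
every claim is still sharply testable: icospheres at subdivision 3–4
(642 / 2,562 vertices), 20 eigenmodes on folded meshes, 200-node
connectomes over 20 seeds, 200 calibration replicates at 500 permutations,
and 20,000 rotation draws. Production parameters (100 modes, K = 400
nodes, 10,000 permutations) are the package defaults and are exercised for
interface correctness; the statistical suites use the smaller sizes.

## Known limitations

- Single-mode couplings are basis-dependent inside degenerate eigenvalue
  groups (e.g., perfect spheres); use subspace criteria there.
- The radial spherical projection assumes a star-shaped surface; deeply
  folded or sheet-like structures (e.g., hippocampal surfaces) require an
  external spherical registration, supplied as coordinates.
- Surface smoothing of mapped gradients belongs to the volume-to-surface
  tool chain and is not implemented; maps are compared unsmoothed.
- Explained-variance fractions depend on the chosen normalization
  (positive nontrivial eigenvalue share); other toolkits may normalize
  over only the requested components, so compare conventions before
  comparing numbers.
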