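# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `molstruct`, and what the test suite does and does
not establish.

## Coordinates, units, particle systems

Atomic units throughout: Bohr, Hartree, electron masses; charges in units of
e. A `ParticleSystem` carries per-particle (mass, charge, kind) with kinds
`nucleus`/`electron`; identical-particle groups are particles sharing all
three. Internal coordinates are the 3(N−1) Cartesian positions of particles
2..N relative to particle 1, which is a nucleus by convention; the
wave-function file format records the reference particle explicitly, since
deposited parameter sets may use either a nucleus or the nuclear center of
mass as origin and the reader must not guess.

`N_perm`, the number of label permutations interchanging positions of
identical nuclei, is the product of group-size factorials over *nuclear*
groups only. Electrons are excluded deliberately: structure is a statement
about nuclear positions, and electron antisymmetry is handled inside the
wave function, not in the structural analysis. Permutation enumeration is
guarded (default limit 10⁵ permutations) and fails loudly beyond it.

## Wave functions

The ECG model evaluates Ψ(x) = Σₛ wₛ Σₖ cₖ exp(−(Tₛx)ᵀ(Aₖ⊗I₃)(Tₛx)).
Choices:

- **Cholesky storage.** Exponent matrices are stored as Aₖ = LₖLₖᵀ with
  positive diagonal, so positive definiteness is structural rather than
  checked numerically.
- **Spin integrated out.** The projector (Tₛ, wₛ) carries the net *spatial*
  symmetrization weights; no spin coordinates are sampled. For a D3⁺-like
  ground state this means symmetric deuteron permutations and a spatially
  symmetric electron pair.
- **Signed log-sum-exp.** Amplitudes are accumulated in the log domain with
  signs, so ρ = |Ψ|² underflows to exactly −∞ (a node) rather than NaN, and
  large-|x| tails stay finite.

The native parameter file is versioned plain text (header with particle
table and reference particle; one line per projector term and per basis
term). A converter for ATOM-MOL-nonBO dumps is a documented extension point
only: that program's dump layout and ansatz conventions (possible
pre-exponential factors, shifted Gaussians) are not reimplemented here, and
fidelity to any particular deposit must be established against its own
documentation.

## Synthetic model densities

The generator exists so every downstream stage is testable without external
data. It emulates exactly the statistical structure the method assumes:

- **Exact rotation invariance** — the density depends only on interparticle
  distances, mirroring a J = 0 state. This is why the nuclear factor is a
  conformer- and permutation-symmetrized mixture of Gaussians in the
  *internuclear distances* (width σ_nuc), not a Cartesian mixture.
- **Exact permutation invariance** — explicit symmetrization over the
  enumerated nuclear permutations.
- **Vibrational fluctuation** about one or more planted conformers, and
  per-nucleus Gaussian electron clouds (width σ_e).

The direct sampler perturbs conformer *vertices* (then applies a uniform
random rotation, a uniform label permutation, and attaches electrons),
whereas the density oracle perturbs *distances*. The two are intentionally
not distributionally identical; they agree to first order in σ_nuc, and
tests needing both use small σ_nuc. The generator makes no attempt to mimic
electron–electron correlation or wave-function nodes.

Default study conditions: equilateral triangle of side 1.65 Bohr (the
equilibrium side of the D3⁺-like system the package is built around),
σ_nuc = 0.05 Bohr (a typical zero-point internuclear spread for light
nuclei), σ_e = 0.6 Bohr (electron clouds delocalized over the bond scale),
uniform electron site weights.

## MCMC sampler

Random-walk Metropolis over internal coordinates. Each step updates the
coordinates of one particle *kind* (cycling deterministically through the
kinds present), which keeps per-kind acceptance rates well defined; nuclei
and electrons have separate step sizes because their density scales differ
by orders of magnitude. During burn-in each kind's step size is adapted
multiplicatively (×0.8 / ×1.25) in windows of 1000 steps until its
acceptance enters the target window (0.2–0.5), with a bounded number of
rounds; sizes are frozen at the burn-in boundary so the recorded chain is a
valid Markov chain, and the adaptation history is kept in the sample set's
provenance. Defaults: 3·10⁶ total steps, 10⁵ burn-in, thinning 100 — a
production-scale single chain; tests and the acceptance script use
2·10⁴–2·10⁵ steps, which the synthetic densities (12 internal coordinates)
mix well within.

A chain started at ρ = 0 is rejected; a NaN from the oracle aborts with the
step index. Identical seeds give bit-identical sample sets.

**Expectation values.** Class-pair distances average over all particle pairs
in the class pair and all snapshots. ⟨V⟩ is the mean Coulomb energy; the
total energy is reported through the virial theorem for Coulomb eigenstates,
E_tot = ⟨V⟩/2 — an exact identity of the report, not an estimate (the ratio
is asserted, not measured). Standard errors come from block averaging with
50 contiguous blocks (fewer when the sample is shorter; zero when fewer than
two blocks exist). Block averaging absorbs autocorrelation at the tens-of-
steps scale; no further autocorrelation analysis is attempted.

## Alignment metric

d(a, b) = nuclear RMSD after (i) mass-weighted nuclear center-of-mass
translation and (ii) optimal proper rotation (Kabsch: SVD of the
cross-covariance with determinant sign correction). Decisions:

- **Proper rotations only.** Space inversion is excluded so chiral
  configurations remain distinct from their mirror images.
- **Labeled configurations.** No minimization over permutations — distinct
  permutational images must remain distinguishable for the symmetry analysis
  to read off feasibility.
- **Weights.** Centering is mass-weighted; the RMSD sum is unweighted over
  nuclei. For systems of identical nuclei the two conventions coincide; a
  `mass_weighted_rmsd` switch exposes the alternative.
- **Electrons** are carried through the alignment (rotated by the nuclear
  optimal rotation) but never enter the metric.
- **Degenerate optima.** For collinear nuclei the optimum is unique only up
  to spin about the line; the smallest-angle rotation is selected
  deterministically and the result flagged.

The pairwise distance matrix uses a batched closed form (singular values of
3×3 cross-covariances): RMSD² = (‖P‖² + ‖Q‖² − 2(s₁+s₂±s₃))/m. The trace
subtraction has a √ε ≈ 10⁻⁸ cancellation floor near zero distance; the
single-pair path and ensemble alignment therefore compute RMSD from the
explicitly rotated residuals, which is exact at the minimum. A configurable
pair-count guard (default 2·10⁸ pairs) fails fast on quadratically oversized
requests.

## Clustering and symmetry

k-medoids is PAM: greedy BUILD initialization, then best-improvement swaps
to a local optimum. Because the swap phase is a local search, a small number
of additional swap passes from seeded random initial medoid sets (default
10) guard against local optima; only strict cost improvements are accepted,
so results are deterministic for a given seed, with ties broken toward the
lowest index. On small instances (n ≤ 12, k ≤ 3) this matches exhaustive
search over all medoid subsets in every tested trial.

k is suggested by the mean silhouette on the precomputed metric for
k = 2..k_max, downgraded to k = 1 when the best silhouette falls below 0.25
— unstructured unimodal ensembles on this metric score well below that;
planted well-separated conformers score near 1.

**Symmetry analysis.** For each nuclear permutation P the report records
d(P·medoid, medoid) and flags P feasible below a tolerance τ. The default τ
is the ensemble's median snapshot-to-medoid distance: the vibrational spread
sets the natural scale of "essentially unchanged". g = #flagged, versions =
N_perm/g. The report warns when g fails to divide N_perm or the flagged set
is not closed under composition (both symptoms of a τ cutting through the
distance spectrum). MS-group labels are a lookup for small standard patterns
(three identical nuclei with g = 6 → D3h(M); an identical pair with g = 2 →
C2v(M)); otherwise only g and versions are reported.

A clustering subset (default 30000 snapshots, stride-thinned) bounds the
quadratic distance-matrix cost.

## Density maps

Snapshots are aligned to the medoid, whose principal nuclear axes are mapped
to x, y, z (best-fit plane → x–y, a proper rotation), so planar structures
lie flat and the 2D nuclear map is taken in their plane. KDE kernels are
isotropic Gaussians with an explicit bandwidth in Bohr; the default is
Scott's rule on the pooled positions. 2D maps pool *all* nuclear positions
(one map of the whole structure, not per-nucleus maps); densities are
normalized to the pooled particle count per snapshot (nucleus count in 2D,
electron count in 3D). Grids extend 5 bandwidths beyond the data by default,
which keeps the trapezoidal integral within 1% of the declared
normalization. Evaluation is an exact chunked Gaussian sum — scipy's KDE
only supports covariance-scaled bandwidths, and an explicit isotropic
bandwidth is needed for the convolution identities the tests rely on
(planted σ and bandwidth h combine to peak variance σ² + h²). Cost scales as
(grid points × samples); the tests use grids ≤ 41³.

Cube export follows the Gaussian cube standard (Bohr, z-fastest voxel order,
atomic numbers from nuclear charges) and is byte-stable; 2D maps export as
delimited text. Both carry bandwidth and snapshot-count metadata.

## Pipeline

A versioned YAML config drives sample → expectations → cluster → symmetry →
density; every stage persists its artifact (HDF5 sample sets and distance
matrices with provenance attributes, JSON reports, XYZ medoids — the XYZ
dialect is Bohr with log-density in the comment line) and later stages
consume persisted artifacts, so stages re-run individually and byte-identical
reruns follow from fixed seeds. Stage failures propagate with the stage name;
partial outputs are retained. The CLI is a thin click wrapper; exit code 2
marks validation errors, 1 runtime failures.

## What the tests show — and what they do not

The synthetic generator has, by construction, exact rotation and permutation
invariance, Gaussian fluctuations, and no nodes. Passing tests therefore
demonstrate that the machinery (sampling, metric, clustering, symmetry
accounting, density estimation) is correct under the method's stated
assumptions; they do not establish behaviour on real wave functions with
nodes, heavy-tailed densities, or J ≠ 0 states (the method assumes a
rotation-invariant density throughout; nonzero total angular momentum is out
of scope). Published-scale validation against the deposited D3⁺ wave
function is wired into the acceptance tests but requires obtaining that
deposit and converting it to the native parameter format.

Problem sizes in tests and the acceptance script (5000-sample recoveries,
10⁵-step chains, 10⁶-point rotation grids, ≤ 41³ KDE grids) are the
package's chosen desk-scale study conditions; all defaults remain overridable
for production runs.

## Known limitations

- Single-chain sampling only; no parallel tempering or gradient-based
  proposals, so strongly multimodal densities (well-separated conformers
  with high barriers) may mix poorly in MCMC — the direct synthetic sampler
  sidesteps this for testing.
- The distance matrix is dense; memory grows quadratically in the subset
  size (the 30000-snapshot default needs ~3.6 GB).
- MS-group labeling covers only small standard patterns.
- The 3D KDE's exact-sum evaluation is O(grid × samples); very large grids
  call for coarser sampling or larger bandwidths.
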