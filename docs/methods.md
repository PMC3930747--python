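# Methods

This note documents the models and numerical choices behind `mhcplast`, in
the order the pipeline runs.

## Units, numbering, formats

Coordinates are stored in nanometres internally and converted from/to
Ångström at the PDB boundary (multi-model PDB is the mandatory trajectory
dialect; a binary reader can be plugged in behind `read_trajectory`).
Residue numbering is 1-based lumenal-domain numbering — position 1 is the
first residue after the signal peptide, so a full MHC I heavy chain spans
positions 1–274.  Alignment symbols outside the canonical 20-letter
alphabet (B, Z, X, unknowns) are normalized to gaps on input, keeping the
frequency model strictly 20-state.  Frame times are in picoseconds;
equilibration discard operates per replica label before re-concatenation,
so three replicas of 150 ns sampled at 5 ps with the first 10 ns discarded
leave 3 × 28,000 = 84,000 frames.

## Synthetic generators

The generators are first-class, tested code: they define the statistical
structure every downstream stage assumes.

- **Trajectories** are drawn as `x_t = ref + Σ_i z_{t,i} s_i µ_i + ε_t` with
  orthonormal modes µ_i (checked to 1e-8), amplitudes s_i (nm), and
  isotropic noise ε.  The sample covariance converges to
  `Σ s_i² µ_i µ_iᵀ + σ² I`, which is exactly what the essential-dynamics
  stage inverts; the tests verify recovery at signal-to-noise ≥ 10 with
  10⁴ frames.
- **Dihedral series** are wrapped normal.  For a wrapped normal the mean
  resultant length is `R̄ = exp(−σ²/2)`, so the circular SD `√(−2 ln R̄)`
  equals the generator's σ exactly — the generator parameter is the
  statistic being estimated, with no calibration constant in between.
- **Backbone geometry** is built from internal coordinates (standard bond
  lengths/angles, ω = 180°), so trajectories with planted per-residue φ
  spreads can be produced in Cartesian form and re-measured.
- **Alignments** mix i.i.d. background columns (default background: the
  standard database amino-acid composition), conserved columns emitting a
  dominant symbol with stated probability, and one coevolving group driven
  by a shared latent binary state: with probability `sector_coupling` a
  sequence carries the designated joint state at *all* group positions,
  otherwise those columns revert to background.  This is the simplest
  mechanism that guarantees a rank-1 dominant coupling mode.  The
  `heavy_chain_msa_recipe` preset emulates a curated heavy-chain alignment:
  141 sequences, a gap-free 274-position query, five conserved anchor
  columns (disulfide cysteines and aromatics at 0.90–0.98), and a
  26-position planted group containing positions 22 and 220 at coupling
  0.9 — strong enough to be cleanly detectable at this alignment depth, as
  a real sector would be.

What the generators do **not** emulate: phylogenetic correlation between
sequences (every sequence is an independent draw), gap structure in the
alignment body, force-field physics, anharmonicity or kinetics in the
trajectories.  Passing tests therefore demonstrate correctness of the
estimators under their own model assumptions, not robustness to tree
structure or to non-Gaussian dynamics.

## φ flexibility

φ is measured per residue per frame from C(i−1)–N(i)–Cα(i)–C(i) with the
IUPAC sign convention; the first residue, and any residue with a missing
backbone atom, is marked missing (NaN) and propagates as missing, never as
zero.  The spread is the **circular** standard deviation by default: the
naive linear SD is wrong at the ±180° wrap — an alternating ±179° series
has a true spread of ≈1°, not ≈179° — and the wrap region is precisely
where highly flexible sites live.  A linear estimator is available for
comparison (`estimator="linear"`); for angles confined to a narrow arc the
two agree within 1%.  Flexible sites are those with SD strictly above the
threshold (default 25°), and the bound/free comparison reports per-residue
ΔSD plus the two site counts.  Glycines are flagged in reports but kept in
the statistics.

## Essential dynamics

Rigid-body motion is removed by weighted least-squares (Kabsch)
superposition computed over the analysis selection and applied to all
atoms.  When no reference is supplied, frames are fitted to the ensemble
mean and the fit is iterated until the mean stops moving (tolerance 1e-12,
max 20 iterations) — a fixed small number of passes leaves ~1e-7 nm of
residual motion, visible in the idempotence check.  A collinear reference
leaves the rotation undetermined and is rejected.

The covariance uses the population average over frames, so eigenvalues are
exactly mean-square fluctuations and the variance of each projection equals
its eigenvalue to machine precision.  Mass weighting enters as
`√(m_a m_b)` in C and is inverted on reconstruction; unit masses reduce all
formulas to the unweighted case (tested).  Eigenvector signs are fixed by
making each mode's largest-magnitude component positive, so exported mode
vectors and porcupine data are reproducible.  Mode extremes export both the
Cartesian displacement (weighting inverted) and the raw mass-weighted
vector, since either convention is found in visualisation pipelines.
Projections from two ensembles are comparable only on an identical atom
selection; the mode set records its selection and enforces identity.

Block RMSF splits the trajectory into consecutive fixed-duration blocks
(trailing partial block dropped; a block longer than the trajectory means
one whole-trajectory block) and reports per-atom RMSF about each block
mean — the stationarity diagnostic for production runs.

## Free-energy landscapes

The joint (PC1, PC2) histogram uses 64×64 bins by default spanning the data
range plus a 5% margin per axis.  Free energy is `G_b = −ln(P_b/P_max)` in
kT (invariant under count rescaling; occupied minimum exactly 0), with kT
referenced to 300 K and a kJ/mol conversion available.  Empty bins are
masked, never pseudo-counted: inventing an energy for unexplored regions
would fabricate barriers, and barrier paths may not cross masked bins.

Minima are occupied bins below all occupied 8-neighbours (plateau ties keep
one representative), merged within a Chebyshev `min_separation` (deeper one
kept).  The barrier between two bins is the lowest level at which they
become connected on the occupied-bin graph (computed by union-find flooding
in order of increasing G) minus the higher of the two bin energies; it is
symmetric and non-negative, and the tests check it against an exhaustive
threshold-connectivity oracle.  Each minimum's *persistence* is its barrier
to any deeper minimum (for a minimum disconnected from all deeper ones, the
depth of its own occupied island); minima with persistence below
`depth_threshold` (default 1.0 kT) are discarded.  With raw counts,
rim bins of a well-sampled basin can form spurious wells of up to ~1.5 kT
persistence at 2×10⁴ samples, so minima *counting* in the tests uses a
1.5 kT depth threshold; smoothing is deliberately not applied by default
because it changes minima counts (an optional σ = 1 bin Gaussian filter
would be the alternative).

## Statistical coupling analysis

Frequencies `f_i^a` are computed over non-gap symbols per mapped column
(columns where the query has a residue).  Conservation is
`D_i = Σ_a f_i^a ln(f_i^a/q^a)`; the background q defaults to the standard
database composition and is swappable.  The coupling matrix weights raw
pair correlations `C_ij^ab = f_ij^ab − f_i^a f_j^b` by the conservation
gradient `w_i^a = |ln(f(1−q)/(q(1−f)))|`, evaluated at frequencies
regularized by a pseudo-count λ = 0.03 mixed toward the background (the
weight diverges at f ∈ {0,1}), and reduces over amino-acid pairs with the
Frobenius norm.  No sequence weighting by identity clustering is applied by
default — every sequence counts once — keeping the documented procedure
reproducible; a weighting hook would be the first extension for
phylogenetically biased alignments.

Significance: each randomization permutes every column independently across
sequences (preserving composition, destroying coupling), the matrix is
rebuilt, and eigenvalues are pooled over 100 randomizations; true
eigenvalues strictly above the pooled maximum are significant.  The first
eigenmode of an SCA matrix reflects overall conservation; it is retained by
default (`include_first_mode=False` to drop it).  In the planted-sector
model the coupling signal *is* carried by the first mode, since the latent
state both conserves and couples the group.

ICA is a symmetric fixed-point iteration with the tanh contrast (tolerance
1e-6, max 10⁴ iterations, seeded), applied to the mode coordinates of the
retained eigenvectors **without re-centering**, so the components are exact
linear combinations of the retained modes and the spanned subspace is
preserved to machine precision.  (A generic ICA implementation that centers
its input leaves the subspace and was rejected for that reason.)
Components are sign-fixed to put the heavy tail positive and ordered by
excess kurtosis — the heaviest-tailed component is the sector-bearing axis
and is selected by default, overridable by index.

Sector membership fits a location-scale Student's t to the chosen
component's weights by maximum likelihood and keeps positions above the
fitted quantile at `cdf_cutoff`.  The cutoff controls the expected selection
fraction: at 0.85 (the conventional documented value) the quantile sits
near the bulk's upper edge and the sector approaches the top ~15% of
positions; at 0.95 the heavy-tail-depressed quantile clears a tight bulk
and selects only clear outliers.  Recovery experiments against planted
groups therefore use 0.95, chosen so the expected tail fraction (5%) does
not exceed the planted sparsity (10%); with that setting, full-pipeline
precision and recall against a 10-position group planted among 100
(coupling 0.8, 500 sequences) are 1.0.  Membership is monotone
non-increasing in the cutoff.

Contiguity builds a graph on sector members with edges where any
inter-residue heavy-atom distance is below 4.5 Å (the standard contact
convention, configurable) and reports connected components.  The
polymorphism overlay compares two ungapped allele sequences position by
position and intersects the differences with the sector.

## Pipeline, seeds, problem sizes

Configuration is a plain-text `key = value` file with full defaulting
(φ threshold 25°, discard 10 ns, 64 bins at 300 K, 100 randomizations,
cutoff 0.85, contacts 4.5 Å).  Every report carries a provenance header
with the analysis-parameter hash and seed; identical configs and seeds
reproduce all numeric outputs byte for byte.  Stage dependencies are
validated before execution, and every stage runs standalone.

The test suite and `scripts/acceptance.py` run on deliberately modest
problem sizes chosen to exercise the estimators' stated tolerances:
10⁴-frame trajectories for mode recovery, 10⁵ samples for circular-SD
consistency, 2×10⁴ points for landscape minima, 141×274 and 500×100
alignments for sector recovery, with 20–100 column randomizations.

## Known limitations

- SCA here has no phylogenetic correction; closely related sequence sets
  will inflate apparent coupling.
- The landscape estimator is a raw histogram; minima/barrier values carry
  sampling noise of order 1/√(bin count) and the depth threshold is the
  only guard.
- The rank-1 planted-coupling model makes conservation and coupling
  coincide in one eigenmode; real alignments distribute sectors over
  several significant modes, which the significance and ICA machinery
  supports but the generator does not exercise beyond two groups.
- ω and ψ torsions, side-chain rotamer coupling, and kinetic (time-lagged)
  analyses are out of scope.
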