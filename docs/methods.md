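# Methods

`mdnetics` implements the post-simulation inference stack used to
rationalise affinity differences between two variants of a protein–protein
complex (the motivating case is a parental versus an affinity-engineered
T-cell receptor bound to the same peptide–MHC): flexibility profiling,
end-state (MM/PBSA-style) energy decomposition with residue-pairwise
detail, generalized-correlation networks with shortest allosteric
pathways, Schlitter configurational entropy, and relative binding free
energies from nonequilibrium work ensembles. This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Units and conventions

Internal units are nm, ps, kJ/mol, elementary charges and amu; PDB
Ångström coordinates are converted at the I/O boundary. kB =
0.008314462618 kJ/mol/K, Coulomb factor f = 138.935458 kJ·mol⁻¹·nm·e⁻²,
default temperature 310 K. Residues are indexed 0-based contiguously in
memory; the original PDB author numbering is retained as a reporting label
(mutation sites and CDR-loop residues are conventionally quoted in author
numbering). All distance and occupancy thresholds are inclusive (≤, ≥).

Every time-averaged quantity excludes an initial equilibration window,
measured from each replica's first frame (default 200 ns). Replica
aggregation is uniform across stages: means are computed per replica, the
reported value is the mean of replica means, and the spread is the
standard deviation of that mean, σ_μ = sd(replica means)/√R.

## Flexibility

RMSD uses least-squares rigid superposition (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) with separate fit and
measure selections. RMSF is block-averaged: the post-discard span is cut
into `floor(span/block)` windows (default block 100 ns), each window's
frames are iteratively superposed (2 iterations) onto the window-mean
structure, and RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩ is averaged over windows, then
replicas. Whether the fit reference should be per-block or global is a
genuinely open choice; per-block is implemented because it removes slow
rigid-body drift the same way per-window averaging does.

The per-block fit is optional (`superpose=False`). A least-squares rigid
fit necessarily absorbs some fluctuation variance into the removed rigid
modes — preferentially from high-amplitude atoms far from the centroid —
so on ensembles sampled in a fixed laboratory frame (the synthetic
harmonic wells below) fitting biases peripheral soft-well RMSF low by up
to ~18%. Validation against the closed form therefore runs without the
fit; real trajectories, which do drift, use the default.

Hydrogen bonds use the geometric criterion D···A ≤ 0.35 nm and H–D···A
angle ≤ 30° (donor hydrogens must be recorded explicitly); both
parameters are exposed. Residue-pair distances support minimum-heavy-atom
and named-atom modes, with occupancy defined as the fraction of analysis
frames at or below a threshold.

## End-state energetics

Binding terms follow ΔE = E(complex) − (E(receptor) + E(ligand)) term by
term under the single-trajectory convention: component frames are the
complex frames restricted to each group, so bonded terms cancel
identically and the short-range term reduces to the inter-group pair sum.

- **E_SR** — inter-group Coulomb (f·q_iq_j/r) plus Lennard-Jones
  (4ε[(σ/r)¹²−(σ/r)⁶], Lorentz–Berthelot combination) within a 1.2 nm
  cutoff, on the dense snapshot set.
- **E_Coul/LJ** — the same sum without a cutoff (minimum image when a box
  is present). At the scale this package targets, direct summation is
  exact; it stands in semantically for the reciprocal-space and
  dispersion-correction contributions a mesh-Ewald engine would add.
- **E_solv−apolar** — γ·SAS + b with γ = 0.00542·4.184·100 = 2.267728
  kJ/(mol·nm²) and b = 0.92·4.184 = 3.84928 kJ/mol, from Shrake–Rupley
  SASA (probe 0.14 nm, 960 sphere points by default). The intercept b
  cancels once in the three-term binding difference. The test-point grid
  is oriented in the molecule's principal-axes frame (axis signs fixed by
  third coordinate moments), which makes the discretised area exactly
  invariant under rigid motions rather than invariant only to O(1/n_points).
- **E_solv−polar** — reaction-field energy from a finite-difference
  **linearized** Poisson–Boltzmann solve: 7-point stencil, face
  dielectrics from midpoint inside/outside tests, trilinear charge
  spreading, Dirichlet boundaries from the (Debye-screened) Coulomb
  potential, conjugate-gradient solution (Jacobi preconditioner, relative
  tolerance 1e-8). The energy is ½Σq_i[φ_het − φ_hom] with the reference
  solve using the solute dielectric everywhere on the same grid, so the
  grid self-energy cancels. Defaults: spacing 0.0325 nm, ε_in = 4,
  ε_out = 78.5, padding 1.0 nm, ionic strength 0 (a configuration knob
  exists; reports should note the value used). Atomic radii default to
  the LJ energy-minimum radius σ·2^{1/6}/2. Against the Born ion the
  solver is within ~1.5% at 0.025 nm spacing with error decreasing
  roughly linearly in spacing; it is a validation-scale solver, not a
  replacement for a production nonlinear-PB engine, and polar values are
  flagged accordingly.

Snapshot cadence follows the dense/sparse convention (defaults reproduce
800 SR/apolar and 80 polar snapshots per replica for a 1 μs trajectory
with 200 ns discard). Residue-pairwise energies are computed only for
pairs gated by the any-frame contact rule: any interatomic distance
≤ 0.6 nm in at least one analysis frame.

## Correlation networks and allosteric paths

Node motions are the 3-D displacement vectors of one atom per residue
(Cα by convention) about their mean, after global superposition onto the
ensemble mean (skippable for synthetic ensembles with no rigid-body
motion, for the same variance-absorption reason as in the RMSF section).
Mutual information between node pairs uses the Kraskov kNN estimator
(algorithm 1, Chebyshev metric, k = 6; the method's literature does not
pin estimator settings, so they are configuration). Frames may be strided
(default 10) because the estimator assumes weakly dependent samples. MI
is mapped to the generalized correlation coefficient
r_MI = √(1 − e^(−2I/d)) with d = 3 (MI is computed on the 3-D vectors
jointly, the standard form of the method). For a 3-D Gaussian pair with
per-dimension correlation ρ, I = −(3/2)ln(1−ρ²) and r_MI = |ρ| exactly,
which is the recovery oracle.

The correlation matrix is filtered by an occupancy contact map — any
heavy-atom pair within 0.5 nm in ≥ 70% of pooled analysis frames — and
the surviving pairs become edges weighted −log10(r_MI) (r clipped at 1;
r ≤ 0 omits the edge). Since the filtered graph never consults
correlations of non-contacting pairs, MI can be restricted to the contact
edges; the full matrix remains available. Sequence-adjacent residues are
retained as edges (a flag can exclude them). Shortest paths are Dijkstra;
among equal-weight optima the lexicographically smallest node sequence is
returned (built greedily from distance maps), making reported
"preferential" paths deterministic. Replica handling mirrors the global
convention: r_MI matrices are averaged element-wise across replicas, and
system comparisons are differences of replica means.

## Entropy and work-based free energies

Schlitter's bound S = (kB/2) ln det[𝟙 + (kB·T·e²/ħ²) M^{1/2} C M^{1/2}]
is evaluated via the eigenvalues of the mass-weighted covariance of the
superposed analysis frames (Cα selection by default; configurable). The
prefactor is assembled in SI units (amu→kg, nm²→m²) because the argument
must be dimensionless and unit slips are the dominant failure mode; the
spectrum is also used for the quantum harmonic-oscillator entropy
S_QHO = kB Σ[α/(e^α−1) − ln(1−e^{−α})], α = ħ/√(kB·T·m·λ), which
Schlitter upper-bounds mode by mode. Covariances are accumulated per
replica and entropies averaged (pooling is available). Binding-entropy
double differences use −TΔΔS_b = −T[(S_c1 − ΣS_p1) − (S_c2 − ΣS_p2)].

Relative binding free energies come from forward/backward work ensembles:
BAR solves the Bennett self-consistency equation by bracketed root
finding; CGI intersects the forward and negated-backward Gaussians
(quadratic roots, the intersection between the two means). Uncertainties
are seeded bootstrap standard deviations (100 resamples by default).
Non-overlapping work distributions attach a warning rather than failing.
The thermodynamic cycle is ΔΔG_b = ΔG_mut(complex) − ΔG_mut(isolated),
uncertainties in quadrature.

## Synthetic study systems

The generators are pure functions of spec + seed and guarantee exactly
the statistical/geometric properties the analyses measure — they make no
attempt at protein-like geometry or force-field realism:

- **Gaussian ensembles**: bead chains with planted per-dimension
  correlations; i.i.d. frames by default, optional AR(1) colouring to
  stress block averaging.
- **Harmonic wells**: per-dimension variance kB·T/k_i with the analytic
  covariance attached — the RMSF and entropy oracle.
- **Toy complex**: a 3+2-bead charged interface (net +0.5/−0.5 groups)
  with Gaussian jitter (sd 0.02 nm); the mutant moves one charged ligand
  bead 0.1 nm closer to its oppositely charged partner — a planted
  tighter salt bridge, the minimal analogue of an affinity-enhancing
  interface mutation. Parent and mutant share the random stream so they
  differ only by the declared mutation.
- **Planted path**: path nodes laid at 0.4 nm spacing form a Markov chain
  with adjacent correlation exactly ρ_on (0.9); off-path beads bridge
  consecutive path nodes in contact range with correlation exactly ρ_off
  (0.1) to each anchor, providing decoy routes. Built from an explicit
  linear-Gaussian model, so the covariance is positive definite by
  construction; a naive correlation matrix with 0.9 only on chain edges
  is not.
- **Work sets**: W_f ~ N(ΔG + βσ²/2, σ²), W_b ~ N(−ΔG + βσ²/2, σ²) —
  the Gaussian family satisfying the Crooks relation exactly in
  distribution.

Passing the recovery suite shows the estimators are correctly implemented
and unbiased under their own assumptions (i.i.d. or weakly dependent
frames, Gaussian fluctuations, planted truth). It does not show that
microsecond trajectories of a 3·10⁵-atom complex are converged, that the
single-trajectory MM/PBSA approximation is accurate for flexible
interfaces, or that a linearized desk-scale PB solve matches a production
nonlinear solver — those depend on sampling and physics outside the scope
of this package.

## Problem sizes and determinism

The bundled study conditions are sized for a desk run: toy complexes use
300 frames × 2 replicas (pipeline default), recovery checks use 5000
frames (MI, RMSF), 2·10⁴ frames (entropy), 10⁴ works per direction (BAR),
and a 97³ grid for the Born validation. One master seed drives everything:
per-stage seeds derive from SHA-256 of `"{seed}:{stage}"`, so stages stay
independent while the full run (pipeline report, analysis scripts,
acceptance script) is bit-reproducible for a given seed.

## Known limitations

- The PB solver is linearized with binary (midpoint) dielectric faces;
  no molecular-surface construction, no nonlinear term, first-order
  convergence in spacing.
- The full-range Coulomb/LJ term is direct summation, adequate at bead
  scale but not a periodic-lattice treatment.
- KSG MI needs hundreds of effective samples per pair; on strongly
  autocorrelated trajectories the stride must rise accordingly.
- Schlitter entropy is an upper bound and converges slowly; the per-dof
  sampling diagnostic warns below 3N frames, and differences between
  similar systems are more trustworthy than absolute values.
- H-bond detection requires explicit donor-hydrogen pairs; no topology
  perception is attempted.
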