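# Methods

This note documents the models implemented in `bindfe`, their assumptions,
the numerical choices behind them, and what the synthetic validation does
and does not demonstrate about real molecular systems.

## Units and thermodynamic context

All quantities use Å, kcal/mol, elementary charges, amu and kelvin.
GROMACS-style inputs (XVG, nm) are converted at the I/O boundary so a
single unit system reaches the estimators.  `ThermoContext` pins
R = 1.9872036×10⁻³ kcal/(mol·K), the 1 M standard-state volume
V° = 1660.5392 Å³ and the Coulomb constant 332.0637 kcal·Å/(mol·e²);
pinning makes test expectations bit-stable.  Defaults: T = 300 K.

## Alchemical leg (EXP and MBAR)

Work values and reduced potentials are dimensionless (units of k_BT).
The Zwanzig estimator is evaluated as −log-mean-exp(−Δu), so samples with
|Δu| up to ~700 cannot overflow.  MBAR is solved by self-consistent
iteration of its fixed-point equation with log-sum-exp accumulation,
gauge f̂₀ = 0, tolerance 10⁻⁸ on the largest per-state change, cap 10 000
iterations; non-convergence raises with the last residual rather than
returning a silent partial answer.  States with zero samples are legal
perturbation targets and are flagged in the output.  The overlap matrix
O_ij = Σ_n N_j W_ni W_nj is row-stochastic at self-consistency; the
smallest nearest-neighbour off-diagonal entry is reported as the
schedule's bottleneck.

Decoupling bookkeeping follows the two-stage convention: electrostatics
are removed at full van der Waals coupling, then van der Waals at zero
charge; `LambdaSchedule` enforces this ordering and per-stage
monotonicity.  The cycle estimate is
ΔG_bind = −(ΔG_complex − ΔG_solvent) + ΔG_restraint with uncertainties in
quadrature.

**Restraint correction.** The release of an isotropic 3D harmonic
restraint with force constant k to the 1 M standard state has the closed
form ΔG = −k_BT ln[V°/(2π k_BT/k)^{3/2}].  A production protocol restrains
one ligand heavy atom plus protein residues, whose exact correction
depends on that geometry; the isotropic formula is this package's own
analytic, quadrature-testable choice, with k exposed in the interface.

**Uncertainty.** Block bootstrap with five contiguous sub-blocks by
default: the sub-blocks of a long equilibrium series act as
quasi-independent replicas, which handles residual autocorrelation that
an i.i.d. bootstrap would ignore.  An autocorrelation-based statistical
inefficiency subsampler is available but off by default — inputs are
assumed pre-subsampled, and the block scheme covers what remains.  With
few blocks the bootstrap SD is itself noisy (χ²-distributed with
n_blocks−1 degrees of freedom); tests that compare it against closed
forms use more blocks for that reason.

## Umbrella-sampling leg (WHAM)

Per-window unbiasing histograms the biased samples into
A′(s) = −k_BT ln p(s), subtracts the bias w(s) and the window constant
−k_BT ln⟨e^{−w/k_BT}⟩ taken over the window's own samples.  Empty bins
are masked (NaN), never zero-filled.  The multi-window profile comes from
the standard WHAM self-consistent equations iterated in log space to
10⁻⁷ k_BT on the window constants (cap 100 000 iterations).  The grid
defaults to 200 uniform half-open bins spanning the pooled sample range
padded by one bin.  Windows are sorted by centre before processing, so
input order cannot affect the result.  Adjacent windows whose sample
ranges do not touch raise a coverage error; adjacent windows without a
shared occupied bin only warn, because sparse tails can legitimately
leave single-bin holes.

**PMF depth → ΔG_bind.**
ΔG = −k_BT ln[(A/V°) ∫_bound e^{−β(W−W_unbound)} dz], with W_unbound the
mean over the flat tail (last 15% of covered grid; a non-flat tail
warns).  The bound region defaults to everything up to the first point
past the global minimum where W rises 2 k_BT above it — the basin edge is
a convention, so it is configurable and stamped into outputs.  The
lateral cross-section A defaults to 1 Å² with a logged note when no
lateral restraint constant is available, and to 2π k_BT/k_lat when one
is.

## End-point MM/PB(GB)SA

Single-trajectory protocol: protein and ligand frames are sub-selections
of the complex frames, so bonded terms cancel and ΔE_MM reduces to the
protein–ligand Coulomb + Lennard-Jones interaction (Lorentz–Berthelot
combination, no cutoff, no periodic images — appropriate at desk scale
only).

**PB solver.** The linearised Poisson–Boltzmann equation
∇·(ε∇φ) − ε_out κ² φ = −4πCρ is discretised on a uniform grid with the
7-point flux stencil.  Face dielectrics use harmonic averaging with
fractional boundary smoothing: the van der Waals envelope is located on
each grid edge by linear interpolation of the signed distance, and the
edge dielectric is the series-harmonic average of the inside/outside
fractions.  This keeps the Born-ion error smooth in h (2.1% at h = 0.8 Å,
0.4% at h = 0.4 Å for a = 2 Å), so Richardson extrapolation (order 2 by
default) is meaningful; a node-classified staircase boundary, by
contrast, oscillates with grid offset and does not extrapolate.  Charges
are spread trilinearly (conservation to machine precision, checked to
10⁻⁶ e); boundary conditions are Debye–Hückel superpositions; the SPD
system is solved by Jacobi-preconditioned conjugate gradients to 10⁻⁸
relative residual.  ΔG_Polar = ½Σ q_i[φ_solv(r_i) − φ_ref(r_i)] against a
uniform-ε_in, κ=0 reference on the identical grid, which cancels the grid
self-energy exactly.  The ionic term acts only outside the solute
envelope; κ is derived from the ionic strength (κ⁻¹ ≈ 7.95 Å at 0.15 M,
the physiological Debye length).  The dielectric boundary is the bare
van der Waals surface (no solvent-excluded-surface construction) — a
documented simplification relative to molecular-surface PB codes.

**GB model.** OBC-II-lineage: pairwise HCT descreening integrals,
Ψ-rescaling with (α, β, γ) = (1.0, 0.8, 4.85), and
f_GB = √(r² + R_iR_j e^{−r²/4R_iR_j}).  The Amber dielectric-radius
offset is a parameter with default 0, so an isolated atom's effective
radius equals its intrinsic radius and the single-sphere energy reduces
to the Born formula exactly — the model's cleanest analytic anchor.
Against the PB solver on a 3-atom toy the GB energy agrees to ~13%,
consistent with the approximation's reputation on compact charged
systems.

**SASA and nonpolar term.** Shrake–Rupley with a golden-spiral point set
(default 960 points, probe 1.4 Å); fewer than 32 points is rejected as
meaningless.  Nonpolar energy is γ·SASA + b with the classical
γ = 0.00542 kcal/mol/Å², b = 0.92 kcal/mol; both configurable.

**Entropy.** Quasi-harmonic only: eigenvalues of the mass-weighted
coordinate covariance give ω_i = √(k_BT/λ_i) and the quantum
harmonic-oscillator entropy is summed over modes.  Frames are
mass-weighted least-squares superposed onto an iteratively refined mean
(3 passes) when the solute has ≥3 atoms; smaller systems skip
superposition, since translating a one-particle cloud onto its mean would
erase the fluctuations being measured.  Near-zero eigenvalues (rigid-body
modes, frozen coordinates) are infinitely stiff oscillators contributing
zero entropy; their count is recorded, and an all-degenerate (identical
frames) ensemble returns S = 0.  At least 3N+1 frames are required.
Normal-mode entropy is out of scope.

**Decomposition bookkeeping.** Per-frame ΔE_MM, ΔG_Polar and ΔG_NonPolar
are averaged; −TΔS is added once; the identity
total = ΔE_MM + ΔG_Polar + ΔG_NonPolar + (−TΔS) holds exactly by
construction.  More than 5% failed frames aborts the run with the
per-frame error log.

## Selectivity statistics

ΔG = RT ln(IC50 [M]) with natural log; σ_ΔG = RT σ/IC50 to first order
(absent σ propagates as absent, never as zero).  ΔΔG is the difference of
a ligand's two per-target ΔG values under one method, uncertainties in
quadrature, negative meaning selective for the first target.  Method
agreement uses unweighted ordinary least squares of y on x (σ values are
carried for display, not as weights, and the fit orientation is a
documented choice); R² from that fit; D is the root mean squared residual
about the fitted line, in kcal/mol.  Ligand exclusions are applied by
label and logged in the report.  Ligand/method combinations missing one
target appear in the ΔΔG table with NaN rather than being dropped.

## Contact analysis

A residue contacts the ligand in a frame when the minimum distance from
any ligand heavy atom (heavy = non-hydrogen, hydrogens ignored even when
present) to the residue's side-chain centre of mass is within the cutoff.
Backbone is N/CA/C/O; glycine falls back to CA.  Cutoff 5.0 Å and
frequency threshold 0.5 are conventions, config-exposed and stamped into
every output.  Paralogue correspondences are user-supplied tables (e.g.
HIS862↔HIS428, TYR907↔TYR473 for the PARP1/PARP2 catalytic domains);
sequence alignment is out of scope.  Classification partitions mapped
pairs into shared / exclusive-to-A / exclusive-to-B; contacting residues
absent from the mapping are reported separately.  The per-residue
Coulomb+LJ decomposition sums exactly to the total protein–ligand
interaction energy.

## Synthetic data

All 1D target densities are sampled by inverse-CDF inversion on a
10⁴-point grid — exact to grid resolution with no burn-in ambiguity.
Generators take explicit seeds, are bit-reproducible, and stamp seed and
parameters into a `GroundTruth` record.  The study conditions used by the
validation suite: Gaussian work (m, s) = (2, 1) at n = 10⁵ (truth
βΔG = 1.5); oscillator ladder K = (1, 2, 4, 8) at 2000 samples/state
(truth ½ln2 per step); tilted double well U = 2(z²−1)² + 0.25z tiled by
12 windows of k = 15 kcal/mol/Å² at 5000 samples each (the tilt makes the
basin-ΔG check non-trivial); 8-ligand affinity panels with true ΔΔG
drawn from the clearly-selective / non-selective pattern of the clinical
inhibitor set and per-method noise of 0.5–2 kcal/mol.

**What the synthetic validation shows — and does not.** Passing tests
demonstrate that each estimator implements its defining equations
correctly: closed forms are recovered at quoted tolerances, invariances
(gauge, duplication, order, translation) hold, and error propagation
behaves.  The generators do not emulate the hard parts of real MD data —
long autocorrelation (beyond what the block bootstrap absorbs),
metastability, force-field error, conformational heterogeneity of real
binding pockets, or structured water.  Agreement with analytic truth
here therefore bounds implementation error, not the physical accuracy of
any estimator on a real protein–ligand system.

## Known limitations

- PB: linearised response only; vdW dielectric boundary; no
  solvent-excluded surface; dense-grid memory grows as (L/h)³.
- GB: no salt screening term; accuracy degrades for deeply buried or
  highly charged geometries (by design of the model class).
- Entropy: QHA assumes a unimodal quasi-Gaussian ensemble; multimodal
  ensembles overestimate S.
- US: 1D reaction coordinate, no periodic or 2D PMFs; the bound-region
  and cross-section conventions materially affect absolute ΔG_bind and
  must be reported alongside results.
- Toy complexes are pseudo-residue shells, not protein structures; they
  exercise bookkeeping and estimators, not chemistry.
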