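# Methods

This note records the models implemented in `flipmsm`, the conventions and
numerical choices behind them, what the synthetic generators do and do not
emulate, and the known limitations.

## Scope and shape

The package is a library: the importable API plus `examples/` scripts are
the interface, and one config-driven orchestrator (`pipeline.run_pipeline`)
executes the full analysis graph (features → TICA → microstates → MSM →
implied timescales → Chapman–Kolmogorov → PCCA+ → ΔG → TPT), persisting
every intermediate as delimited text or JSON. All core math works in
frames; a `ns_per_frame` factor converts reported rates and timescales to
physical units when the caller knows the frame spacing.

## Collective variables

* **Centers of mass** are mass-weighted means; masses come from a small
  element table (H, C, N, O, P, S), overridable per selection.
* **Torsions** (atomic and COM-based pseudodihedral) use the signed-atan2
  IUPAC convention, wrapped to (−180°, 180°]; colinear or coincident
  defining points raise rather than returning garbage. The flip
  pseudodihedral takes p1 = flanking base pairs (heavy atoms of the pairs
  immediately 5′ and 3′ of the flipping base, both strands — the precise
  membership is configurable because conventions differ), p2/p3 = flanking
  phosphate groups on the lesion strand, p4 = the six-membered ring of the
  flipping pyrimidine.
* **Hydrogen bonds** use geometric criteria: donor–acceptor distance
  ≤ 3.5 Å and donor–H–acceptor angle ≥ 120° by default. These are
  field-standard values, not fitted; both are parameters.
* **RMSD** is computed after optimal rigid-body superposition (Kabsch, via
  quaternion alignment); **RMSF** superposes all frames onto the
  self-consistent time-mean structure (three fixed-point iterations, which
  converges to machine precision for equilibrium-like data) and can be
  aggregated per residue by mass-weighted averaging.

## Featurization and TICA

Pairwise lesion–partner atom distances form the feature matrix; the atom
subsets are fully configurable and the pipeline never assumes a particular
dimension count. Multiple independent trajectories are concatenated with
recorded segment starts; **no lagged pair ever crosses a segment
boundary** — this invariant is enforced in covariance estimation and
transition counting alike.

TICA uses the symmetrized (reversible) estimator: lagged pairs contribute
in both time directions, C(0) averages the second moment over both pair
ends, and C(τ) is symmetrized. This guarantees real eigenvalues in [−1, 1]
(up to sampling noise) and makes the decomposition invariant under time
reversal — appropriate for equilibrium MD. Covariances are normalized by
the number of lagged pairs (N − τ per segment, summed). Whitening truncates
C(0) eigenvalues below 1e−10 × trace (pairwise distances are strongly
collinear; dropped directions are counted on the model). Eigenvectors are
C(0)-orthonormal with a deterministic sign (largest-magnitude component
positive). "Kinetic variance" for dimension selection is the cumulative
squared-eigenvalue fraction; eigenvalue scaling of outputs (kinetic map) is
available but off by default.

## MSM estimation and validation

* Counting is sliding-window at lag τ, restricted to the largest strongly
  connected component of the count graph (scipy's strongly connected
  components; frames outside the active set are dropped from macrostate
  statistics with a logged count).
* The reversible MLE maximizes Π T_ij^C_ij under detailed balance by the
  standard self-consistent iteration on symmetric pair weights
  x_ij = (C_ij + C_ji)/(C_i/x_i + C_j/x_j); convergence is declared when
  the stationary distribution changes by < 1e−10 relative (1e−7 inside
  bootstrap replicates, where speed matters and band widths dominate).
* Spectral analysis symmetrizes T with √π similarity, giving real sorted
  eigenvalues and left/right eigenvectors.
* Implied timescales t_i = −τ/ln λ_i(τ) are reported across a lag list
  with non-positive eigenvalues excluded (counted) and a plateau flag when
  the slowest timescale changes by < 20% between consecutive lags.
  Eigenvalues pinned at 1 are clipped to 1 − 1e−15, giving a huge finite
  timescale instead of an exception.
* **Lag selection**: analyses in the tests and acceptance script use the
  implied-timescale plateau (lag 100 frames for the five-basin system,
  where ITS are flat to a few percent) — the same procedure used to pick
  lag times for MSMs of MD data.

### Chapman–Kolmogorov test

Predicted curves propagate the tested model, T(τ)^k, coarse-grained onto
macrostate sets (start distribution = π restricted to the set); estimated
curves re-estimate the MSM at lag kτ with the same reversible estimator.
The pass criterion is a **joint test at 95% family-wise confidence**:
trajectory blocks (≥ 10 lags long) are bootstrap-resampled, predicted and
estimated curves are recomputed per resample *from the same resample* so
their difference carries both statistical errors, and each observed
difference must lie within a Gaussian band of width z·std where z carries a
Bonferroni adjustment over the compared points. A naive per-point 95%
criterion would reject a perfectly Markovian model with probability
≈ 1 − 0.95^m (observed in practice on exactly-Markov synthetic data); the
joint test is the faithful reading of "validated at 95% confidence". The
uncertainty model is a trajectory-block bootstrap (default 100 replicates;
50 in the acceptance run, where band widths are already stable) rather than
a conjugate-posterior sampler: it reproduces both the point estimates and
the confidence bands with one estimator.

### PCCA+ and free energies

Memberships come from the top-M right eigenvectors: a deterministic
furthest-point search on the eigenvector rows finds M vertex microstates
spanning the simplex, the linear transform mapping those vertices to the
unit-simplex corners gives the memberships, which are clipped to [0, 1] and
row-renormalized. There is no stochastic refinement step, so the
decomposition is seed-free and reproducible; on well-separated metastable
systems it coincides with the optimized variant. M must not exceed the
number of positive eigenvalues.

Free energies use ΔG(S_I) = −k_B T ln Σ_{j∈S_I} π_j with
k_B = 0.0019872041 kcal mol⁻¹ K⁻¹, default T = 298 K, min-shifted to zero;
empty macrostates get +∞ rather than an exception. The result is invariant
under uniform rescaling of the weights.

## Transition path theory

Committors are linear solves of the boundary-value problem (backward
committor via the time-reversed chain; for reversible models q⁻ = 1 − q⁺
to 1e−10, which is tested). Gross flux f_ij = π_i q⁻_i T_ij q⁺_j, net flux
f⁺ = max(0, f − fᵀ); the total flux is cut-independent and conserved at
every intermediate node to 1e−10. Pathways come from iterative bottleneck
(widest-path) decomposition with deterministic tie-breaks — fewer edges
first, then lexicographic state order — so the decomposition is exhaustive
(fractions sum to 1) and reproducible. Pathway analysis between macrostates
projects the flux network onto the partition first (block-summed, netted
fluxes; committors block-averaged with π weights): decomposing at the
microstate level instead fragments the flux into hundreds of
interchangeable micro-routes with individually meaningless fractions.
Rates are reported per lag time, and per nanosecond when the frame spacing
is supplied.

## meta-eABF and CZAR

The 1-D engine couples an extended variable λ to the CV by ½k_u(ξ − λ)²
and integrates both by overdamped (Euler–Maruyama) Langevin steps. Per
step, the instantaneous spring force on λ is accumulated in λ's bin; the
ABF bias applies the negative running mean, ramped linearly until a bin has
`n_full` samples. Metadynamics Gaussians are deposited on λ every
`deposit_stride` steps and tabulated as forces on the bin grid.
Defaults follow Colvars-style conventions: bin width 0.1 CV-units (5° for
angle CVs), n_full = 200, Gaussian height 0.1 kcal/mol, width 2 bins,
stride 1000, extended kT equal to the physical kT, and
k_u = kT / bin_width² so the coupling fluctuation is about one bin. All are
parameters, since published meta-eABF hyperparameters are rarely complete.

Because the metadynamics Gaussians perturb the λ marginal, the PMF is
recovered with the CZAR estimator — dA/dξ = −kT ∂ln ρ̃(ξ)/∂ξ +
k_u(⟨λ⟩_ξ − ξ) — using central finite differences of the log histogram,
trapezoid integration and min-shifting. Reporting requires ≥ n_full
samples per bin; interior gaps raise instead of being interpolated. On
non-periodic grids the two outermost visited bins are trimmed: λ is
reflected at the grid edges and the reflection distorts the biased marginal
in the boundary bins (visible as an edge artifact on an exactly flat
landscape). Errors are block-averaged standard errors over five contiguous
time blocks. Periodic CVs wrap consistently; the profile-closure error is
reported rather than silently redistributed.

Barrier extraction scans the profile for local minima with a prominence
filter (default 0.2 kcal/mol, so estimator wiggles do not create spurious
states; profile endpoints count as minima), then reports forward/reverse
barriers between the reactant and product minima; monotone profiles return
zero ("barrier-free"). Short runs bias barriers slightly low because the
barrier top converges last — at 2×10⁶ steps the 5.0 kcal/mol double-well
barrier is recovered at 4.8 ± 0.1.

## Synthetic data: what it emulates, and what it does not

* **Markov chains** with a known matrix stand in for discretized MD as the
  data-generating process for estimator-recovery tests.
* **Overdamped Langevin** on analytic potentials (harmonic, symmetric
  double well, five-basin 2-D) emulates metastable dynamics with fast
  orthogonal noise (stiff OU dimensions). The five-basin landscape is a
  sum of inverted Gaussians plus a quartic confinement; default depths
  (4.6, 3.9, 4.2, 3.8, 3.6 kcal/mol), centers spaced ~2 length units,
  σ = 0.72, kT = 0.596 kcal/mol were chosen once so inter-basin barriers
  are a few kT: a 10⁶-step walker then recrosses every basin many times
  (good statistics) while remaining clearly metastable (five slow states).
  Relative basin populations are free parameters — no experimental
  populations are encoded. Ground-truth labels are nearest-basin-center
  assignments, deterministic by construction.
* **The toy duplex** is an idealized geometry fixture — planar hexagonal
  rings and one P atom per residue on two antiparallel strands — not a
  physical B-DNA model. Its one honest property is that the flip is a
  rigid rotation of the lesion ring about the flanking-phosphate axis, so
  the flip pseudodihedral tracks the flip angle exactly and the
  lesion–partner COM distance grows monotonically to 180°.

Passing tests on these generators demonstrate estimator correctness and
pipeline integrity, not force-field accuracy: real MD features are higher
dimensional, non-Markovian at short lags, and carry correlated noise that
no generator here reproduces. In particular the meta-eABF engine works on
analytic 1-D landscapes only; free-energy profiles of solvated DNA require
all-atom simulations outside this package's scope.

## Problem sizes

The default test and acceptance runs use 10⁶ Langevin/Markov-chain steps,
300 microstates, 5 macrostates, TICA/MSM lag 100 frames, 50 bootstrap
replicates for CK bands, 2×10⁶ meta-eABF steps for the double well and
10⁶ for the flat landscape, and 4000 Monte-Carlo trials per committor
check. These sizes give sampling errors comfortably below the tested
tolerances while keeping a full run in the minutes range on one core.

## Known limitations

* Linear TICA only — no VAMP/Koopman variants, no kinetic-map scaling by
  default.
* Reversible point-estimate MSM with bootstrap uncertainty — no Bayesian
  transition-matrix sampler, no hidden Markov models, no multi-ensemble
  estimators.
* PCCA+ without the inner-point optimization step; memberships can be
  slightly suboptimal for poorly separated spectra.
* meta-eABF is strictly 1-D with reflective or periodic grids; no
  multi-walker sharing.
* PDB is the only coordinate format (binary trajectory readers are a
  documented extension point); delimited text is the only feature format.
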