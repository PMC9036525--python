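# Methods

## Model

The toy system replaces a molecule by 1–3 reduced coordinates: one periodic
"dihedral" χ ∈ (−180°, 180°] and optional auxiliary harmonic bath
coordinates. A level of theory is a `PotentialSurface`

    U(χ, q) = Σ_j A_j (1 + cos(n_j χ − φ_j)) + Σ_i ½ k_i q_i² + c_i χ q_i + U_0

with amplitudes in kcal/mol, χ and phases in degrees, and k_B =
0.0019872041 kcal/(mol·K). The constant U_0 plays the role of the absolute
energy gap between levels of theory. A nonzero bilinear coupling c_i breaks
strict 360° periodicity; the quadrature then treats χ on the (−180°, 180°]
box (the default surfaces use no coupling).

The two levels are mixed linearly, U(λ) = (1−λ)U_low + λU_high, so every
slow-growth work increment reduces to (λ_{k+1} − λ_k)(U_high − U_low)
evaluated at the current configuration.

**Default parameterisation.** The low level is a single broad trans well,
U_low = 8(1 + cos χ) (thermal width ≈ 16° at 300 K). The high level,
U_high = 6(1 + cos(2χ − 70°)) + (1 + cos(χ + 55°)), is bistable: a
trans-like global minimum at 125°, a cis-like local minimum at −55°
(+2 kcal/mol), and ≈13 kcal/mol barriers between them — far too high to
cross dynamically at 300 K. Two features of this choice matter:

- the high level's trans minimum is *displaced* 55° from the low level's,
  so the two levels disagree about the preferred geometry. Fast switches
  are then dissipative and the lowest work values come from rarely-sampled
  starting configurations, which is exactly the regime in which the
  one-sided estimator converges slowly and the budget question (many short
  vs few long switches) has a non-trivial answer. A purely concentric
  narrowing of the same well was explored first and rejected: its dominant
  low works coincide with the *most probable* starts, so Jarzynski
  converges even for near-sudden switches and nothing interesting happens.
- a switch that starts near the cis basin ends trapped there (the barrier
  grows in as λ → 1) with work ≈ −10 kcal/mol and χ^post ≈ −55°, producing
  the rare-negative-outlier phenomenology that the diagnostics and PCA
  stages are built to detect.

The exact ΔA of the default pair is +0.3168 kcal/mol at 300 K (and is
independent of the displacement, which merely translates the high surface).

## Exact free-energy oracle

`exact_delta_a` returns −k_BT ln(Z_high/Z_low). Bath coordinates are
Gaussian after completing the square against the coupling and integrate in
closed form; the remaining χ marginal is a midpoint quadrature over one
period whose resolution is doubled until two successive estimates differ by
< 1e-4 kcal/mol (error if 12 doublings do not converge). Antisymmetry
(swap of the two surfaces negates the result) holds by construction because
both partition functions share a grid. The same effective χ marginal drives
`chi_marginal` / `sample_boltzmann` (inverse-CDF sampling with uniform
within-cell jitter, conditional Gaussian bath) and `scan_surface` (bath
minimised analytically, scan shifted so its minimum is zero).

## Dynamics

Langevin dynamics uses the BAOAB splitting (half-kick, half-drift, exact
Ornstein–Uhlenbeck velocity refresh, half-drift, half-kick), chosen for its
configurational accuracy at the 1 fs default step; friction = 0 reduces it
to velocity Verlet. Defaults: T = 300 K, friction 5 ps⁻¹, timestep 1 fs,
and one inertial parameter per coordinate of 1 kcal·fs²/(mol·deg²), which
gives a ≈100 fs oscillation period in the default high-level trans well —
comfortably resolved at 1 fs, and a position relaxation time 2/γ ≈ 400 fs
at the default friction. The integrator core is vectorised over an
ensemble axis; a protocol's switches are integrated as one batch driven by
a single seeded RNG stream, and all stochastic operations are
bit-reproducible given their seed. Energies above 1e8 kcal/mol abort with
a suggestion to reduce the timestep.

Work is accumulated in slow-growth mode with λ_k = k/n: the dynamics step k
runs at λ_k, and the increment U(λ_{k+1}; x_k) − U(λ_k; x_k) is evaluated
at the configuration that step produced. The endpoint convention is stated
so runs are exactly reproducible; for a linear mix any such convention adds
a constant offset U_high − U_low sum that converges to the same work
distribution as n grows, and a constant shift of U_high moves every forward
work by exactly that constant at any n. Work is potential-energy work only
(the kinetic term is untouched by the λ schedule).

## Restart pools

A pool is 8 independent blocks of snapshots in save order, each block with
its own RNG stream spawned from the pool seed. Two qualities are provided:

- `start_distribution="uniform"`: each block is one *sequential* Langevin
  run started from a uniformly random χ with Maxwell–Boltzmann velocities
  after `burn_in` unsaved steps. This is the deliberately fragile,
  randomised-conformer analog: with little or no burn-in, blocks that
  start in (or relax through) unrepresentative regions carry that into
  their early snapshots, which is precisely how early-block work outliers
  arise.
- `start_distribution="boltzmann"`: the idealised well-equilibrated pool.
  Every snapshot's coordinates are drawn independently from the exact
  Boltzmann law and then relaxed for `save_stride` Langevin steps (batched)
  to stay consistent with the integrator's sampled ensemble. This is what
  an unaffordably long equilibrium simulation would deliver for a system
  whose basins are separated by many-k_BT barriers; a sequential
  desk-scale run cannot provide it, because its ≈400 fs position
  correlation time spans a sizeable fraction of any affordable block and
  pool autocorrelation noise would then dominate every downstream
  comparison.

## Estimators and uncertainties

`jarzynski` evaluates the exponential average via log-sum-exp (safe to
|W| ≈ 1e4 kcal/mol). "Crooks reference" means the maximum-likelihood
solution of the Crooks fluctuation relation — the Bennett acceptance-ratio
self-consistency equation — solved by bracketed Brent root finding to a
1e-12 kcal/mol residual by default, with automatic bracket expansion.
Backward work values enter as generated (high→low); exchanging the roles of
the two directions negates the estimate. Uncertainties are bootstrap
standard deviations (default 1000 resamples, fixed internal seed;
independent resampling of each direction for BAR). The bootstrap
understates the true error of a far-from-converged Jarzynski average —
the usual caveat, and one reason the bidirectional reference exists.

Work densities use a Gaussian kernel with the nrd0 rule-of-thumb bandwidth
0.9·min(sd, IQR/1.34)·n^{−1/5} and a grid extended 3 bandwidths past the
sample range — the long-standing default of the reference statistical
software for this analysis. The overlap diagnostic negates backward works,
evaluates both densities on a common grid and integrates their pointwise
minimum.

## Diagnostics

The quasi time series orders work values by (block, save index) with
continuous global numbering (blocksize 100 → block 4, switch 41 is
global 341). Outliers are W < W̄ − kσ with k = 3 by default and σ the
pooled sample SD (n−1 denominator) over all 8 blocks; the criterion is
one-sided because only strongly negative works carry outsized Boltzmann
weight. Positive-tail values are reported separately and never removed.
Note an arithmetic consequence of the criterion: the largest standardised
deviation among n values is (n−1)/√n, so a single extreme value cannot
trigger k = 3 for n ≤ 10 — the criterion is meant for pools of hundreds of
switches. With σ = 0 (all works equal) the criterion is vacuous and
nothing is flagged. `outlier_impact` re-runs Jarzynski without the flagged
records; removal can only raise the estimate.

## PCA

Features are the work value and each tracked dihedral before and after the
switch, angles as raw degrees in (−180°, 180°] (a sin/cos circular
embedding is available behind a flag but off by default, since the
|χ^post| outlier criterion operates on raw angles). Scaled PCA divides
centred columns by their sample SD and is used when mixing W with angles;
unscaled PCA is for angle-only or degenerate inputs. Components come from
SVD; the sign ambiguity is fixed by making the largest-magnitude entry of
each loading column positive. The |χ^post| criterion flags rows with
|χ| < mean(|χ|) − k·SD(|χ|), catching switches that ended near 0-ish cis
values when the bulk sits near ±180°; on basin-hopping switches it flags
the same rows as the work criterion, which is the attribution argument.
Biplot arrows scale loadings by singular values (correlation-biplot
convention; cosmetic only).

## Protocol study

The default grid holds the total switching budget at 64 000 steps:
40/100/200/400-step switches × 1600/640/320/160 replicates (the same
1 : 2.5 : 5 : 10 length ratios as the full-scale 200–2000 fs grids, which
remain expressible via `make_protocol` and are verified exactly in the
tests). Pools are 8 × 400 snapshots. An optional "reduced" set keeps every
4th switch per block of a chosen protocol (`subsample_reduced`; `"first"`
mode selectable). Master seed → stage sub-seeds via `SeedSequence`
(`stage_seeds`), so any stage is independently reproducible; all sub-seeds
stay below 2³¹. `run_experiment` writes work sets, quasi-time-series
tables, the δΔA grid, MAD/RMSE summaries, PCA loadings and an echo of the
configuration under the run directory, aborting with the stage name on
failure. For a single toy system MAD(protocol) = |δΔA|; the MAD/RMSE
machinery generalises to many systems.

**Problem sizes.** Default test and acceptance runs use the 64 000-step
budget, 3 200-snapshot pools, 300–1600 switches per estimate, 200–1000
bootstrap resamples, and 10 seeds for the convergence-ordering comparison;
these sizes were chosen as the smallest at which the studied effects are
comfortably resolved on a single CPU.

## What the generator does and does not emulate

The synthetic system reproduces: two levels with shifted conformational
preferences, metastability that switching cannot cross, rare negative work
outliers caused by basin-trapped switches, block-structured restart pools
with controllable equilibration quality, and fixed-budget protocol
arithmetic. It does not emulate: many coupled degrees of freedom (work
distributions here are smoother than molecular ones), force-field or
electronic-structure specifics, solvent, kinetic-energy contributions to
work, or sampling problems that equilibrium reweighting cannot describe.
Passing tests therefore validate the estimators, diagnostics and study
design — not the behaviour of any particular molecule.

## Known limitations

- The Boltzmann pool mode requires the exact marginal and hence a plain
  `PotentialSurface`; it is the toy's privilege and has no direct analog
  in molecular practice (there, only longer equilibration helps).
- BAR bootstrap resamples directions independently; correlated
  forward/backward launches (shared pool) would need a block bootstrap.
- Angles enter PCA unwrapped; systems whose relevant states straddle the
  ±180° branch cut should use the circular embedding flag and forgo the
  |χ^post| criterion.
- The bilinear χ–bath coupling breaks periodicity and is excluded from the
  default surfaces; it exists for experiments with displaced-bath
  dissipation.
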