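# Methods

`mepkit` re-implements, at desk scale, the statistical workflow used to map
the energetics of large conformational transitions in proteins: a
discretized transition pathway is optimized by the mean-forces string
method, free energies are accumulated along the path from umbrella sampling
via MBAR, absolute binding free energies come from a double-decoupling
alchemical cycle, and allosteric coupling between structural groups is
detected by resampling reactive trajectories and estimating mutual
information with a k-nearest-neighbor estimator.  All components run on
analytic toy systems with known ground truth, so every stage can be
validated against an independent oracle.

## Synthetic dynamics (toy_systems)

The molecular-dynamics engine is replaced by overdamped Langevin dynamics on
analytic potentials (Müller–Brown, 1-D double well `h((x/a)^2-1)^2`,
isotropic harmonic, linear).  One walker is propagated per restrained window
with the Euler–Maruyama discretization

    x' = x + (dt/γ) F(x) + sqrt(2 kT dt/γ) ξ,

and each move is accepted or rejected by the Metropolis criterion with the
asymmetric-proposal correction (MALA).  The Metropolis step is the package's
own design choice: the pipeline needs a correct *stationary* distribution,
not kinetics, and the plain discretization carries an O(dt) stationary bias
(measured as an ≈2% effective-temperature inflation at the stability-bound
timestep) that is large enough to contaminate free-energy profiles at the
0.1 kT level.  With the correction the sampled law is exactly Boltzmann at
any stable timestep; rejection rates in the studies below are under a few
percent.  Plain Euler–Maruyama remains available (`ToySystem(metropolis=
False)`) for integrator-bias experiments.

A timestep guard refuses dt above `0.5·γ/k_max` (Metropolis mode; `0.1·γ/
k_max` for plain EM, where accuracy, not only stability, is at stake).
`k_max` is a conservative curvature bound per potential: the spring constant
for harmonic systems, `44 h` for the double well on |x| ≤ 2, and 4200 for
Müller–Brown from a fine-grid Hessian scan of the U < 200 basin region.

Two unit modes exist: `physical` (kcal/mol, Å, kB = 0.0019872041, default
300 K) and `reduced` (kT given directly).  All studies below use reduced
units.  Random numbers derive from a master `SeedSequence`; every window,
λ-stage and slice draws from its own spawned substream, so enlarging a study
never perturbs existing streams, and all outputs are bitwise reproducible
for a fixed seed.

Alchemical toy models attach their closed-form free-energy difference:
Gaussian ΔU (ΔF = μ − βσ²/2, with Crooks-consistent reverse draws), a
λ-interpolated spring constant (ΔF = kT ln(k1/k0)/2), and a constant offset.
The coupled-domain generator emits two sets of 3-D Gaussian "center-of-mass"
time series with unit marginals in which selected (A,B) pairs share a
per-axis correlation ρ, giving a planted ground-truth mutual information of
−3/2·ln(1−ρ²) nats per pair.

## Path geometry

A pathway is an ordered set of M images in CV space (reported 1-based,
image 1 = initial state).  Reparameterization redistributes images to equal
consecutive gaps by iterating the equal-arc-length pass to a fixed point;
this makes the operation idempotent to round-off and the gap spread < 1e-12
relative.  Because chords of a curved polyline are shorter than its arcs,
iterated redistribution shortens the path by O(gap²·curvature) — exactly
zero for collinear paths, ~0.05% for a smooth well-resolved curve, and up to
~2% for deliberately jagged test paths.  Smoothing replaces interior image i
by `(1−κ)x_i + κ(x_{i−1}+x_{i+1})/2` with endpoints fixed; κ ∈ [0,1),
default 0.1 ("weak" smoothing), and any κ > 0 strictly reduces the discrete
curvature sum.

Samples project onto the path by nearest-segment orthogonal projection:
progress = segment index plus the clamped fractional foot position (ties to
the lower segment), orthogonal distance = squared distance to the foot.
Both an interpolable image coordinate and a [0,1]-normalized progress are
reported, since either convention appears in practice.  The reactive tube
keeps samples with squared orthogonal distance below a cutoff (default 2000
squared position units, mirroring the Å² cutoff used for membrane-protein
CVs; 1500/3000 are the standard sensitivity settings).

Structure fitting is restricted to rotation about z plus xy-translation
(closed-form 2-D Procrustes); z-coordinates pass through unchanged, because
a membrane system's free energy is symmetric only in the xy-plane.  The
3-fold symmetric reference averages the three cyclic assembly states mapped
into a common frame and then symmetrizes over the rotation-plus-relabeling
operator T (σ³ = id), so T(ref) = ref holds by construction.

## Mean-forces string method

Each cycle samples one harmonically restrained window per image (all
windows propagated as one vectorized batch), estimates the mean force from
the restraint-force average `F = k_r(⟨x⟩ − c)` — unbiased for a harmonic
restraint and equal to minus the free-energy gradient at the window — and
moves every interior image by `step_size · F`.  Displacements are capped
per image at 20% of the mean image spacing (a per-image trust region; a
global rescale lets one stiff image stall the whole string).  Terminal
images stay fixed for the first `fixed_terminal_cycles` cycles (default 9)
and afterwards move only by the force component perpendicular to the local
path tangent, so they cannot drift along the pathway.  The order of
operations per cycle is: step, smooth, reparameterize.  Convergence is
declared when the RMSD-to-initial-path series varies by less than
`convergence_tol` over five cycles.

Two practical constraints matter on rugged landscapes:

* the restraint must be stiffer than the most negative Hessian eigenvalue
  anywhere the path visits (Müller–Brown ridges reach ≈ −2000), otherwise a
  window's biased potential is non-confining and its walker escapes to a
  neighboring basin, corrupting the mean force;
* `step_size` should map typical converged-force magnitudes to displacements
  near (but below) the trust cap, so that statistical force noise produces
  proportionally small moves rather than cap-sized random walks of the
  terminals.

A deterministic zero-temperature string (exact gradients, steepest descent
with reparameterization, fine discretization) is provided as both a feature
and the reference: on an analytic potential it converges to the
minimum-energy path, which the sampled string must approach as kT → 0 and
k_r → ∞.

### Müller–Brown study conditions

kT = 0.25, dt = 4e-5, k_r = 8000, 2000 sampling steps + 400 burn-in per
window per cycle, step_size = 2e-4, κ = 0.05, 150 cycles, 30 images; the
initial path is a steered run (restraint center moving linearly between the
two outer minima over 40 000 steps at pull k = 2000) resampled to 30
equidistant images.  These conditions keep the known finite-temperature,
finite-restraint and smoothing biases each below ~0.02–0.03 reduced units
so the converged string tracks the zero-temperature oracle to better than
0.05 everywhere; at kT = 0.5 with k_r = 500 the residual bias at the
hairpin reaches ~0.4 and the restraint fails to confine windows near the
ridge, which is the instructive failure mode documented above.

## Umbrella sampling and MBAR (free_energy)

All windows share the unbiased Hamiltonian, so the reduced energy of frame
n in window k is just β·bias_k(x_n).  The MBAR free energies minimize the
convex MBAR objective (quasi-Newton) and are polished by self-consistent
iteration to a residual of 1e-8 in f (kT units, gauge f_1 = 0); the
unbiased per-frame weights follow from the same log-denominators via
log-sum-exp throughout.  A warning reports the minimum adjacent-window
overlap mass when windows barely overlap.

The free-energy profile accumulates unbiased weights in bins along the
progress coordinate (default: one bin per image, assignment by nearest
image), after discarding frames outside the reactive tube and renormalizing
over the retained frames; `F_bin = −kT ln Σw`, referenced to the profile
minimum.  Empty bins are flagged (NaN), never interpolated.  Standard
errors are block averages: block b pools the b-th contiguous slice of every
window (5 blocks by default), each block profile is referenced at the
global minimum bin, and the SE is the spread of block values over √B.
`block_average_error` applies the same rule to any scalar series.

Study conditions for the double-well profile: h = 4 kT, wells at ±1,
20 windows spanning [−1.25, 1.25] at k_r = 50, 2·10⁴ recorded samples per
window with a recording stride of 15 at dt = 2e-3 (so recorded frames are
nearly uncorrelated).  The quadrature oracle integrates exp(−βU) over each
bin's progress interval, with the end bins receiving the clamped tails.
At these conditions the profile reproduces the quadrature to ≲ 0.05 kT per
bin; the accuracy is statistics-limited, so halving the stride roughly
doubles the worst-bin error.

## Alchemical estimators (alchemy)

EXP (Zwanzig) evaluates `ΔF = −kT ln⟨exp(−βΔU)⟩` per adjacent λ-pair with
log-sum-exp stabilization; its SE is a block average of the per-block
exponential estimates (degenerate all-equal samples give SE 0).  BAR solves
the Bennett self-consistency equation — equal Fermi-weighted acceptance
sums in both directions, with M = ln(N_F/N_R) — by bracketed root finding
(bracket built from the two one-sided EXP estimates, expanded if needed),
and its SE is Bennett's analytic asymptotic variance, following the usual
practice of analytic BAR errors versus block-averaged EXP errors.  Stage
estimates add, and stage variances add in quadrature.

A stratified schedule (`staged_decoupling`) splits the transformation into
uniform λ-stages (a 25-stratification run has 26 states).  The binding
cycle is `ΔG_bind = ΔG_decouple(site) − ΔG_decouple(solvent)` with the
convention "decoupling = ligand → non-interacting" recorded in the output,
and quadrature error propagation.  No standard-state volume correction is
applied — no restraint acts on the ligand analogue — and the output carries
an explicit `standard_state_correction: none` flag so the omission is
visible.

## Reactive-trajectory resampling and mutual information (coupling)

The distribution of reactive trajectories equals the equilibrium
distribution restricted to isocommittor surfaces, which are orthogonal to a
converged pathway.  The pipeline therefore discretizes the path into
n_slices = 29 orthogonal slices, assigns every tube-retained frame to a
slice by progress, renormalizes the MBAR weights within each slice, and
draws (with replacement, per slice, weight-proportional) n_trajectories =
100 frames that are concatenated slice-by-slice into pseudo-reactive
trajectories.  Draws are independent across slices — consistent with the
isocommittor-restricted equilibrium picture, under which slices are
conditionally independent for pooled MI estimation; this chaining choice is
a documented assumption, as the linking of per-slice draws is genuinely
open.  Per-slice effective sample sizes are reported, with a warning when a
draw exceeds them.

Mutual information uses the Kraskov k-NN estimator (variant 1):

    MI = ψ(k) + ψ(n) − ⟨ψ(n_x + 1) + ψ(n_y + 1)⟩,

with max-norm distances in the joint space and strict-inequality marginal
neighbor counts within the joint k-th-neighbor radius.  k defaults to 3;
values are in nats.  Duplicate points (inevitable after resampling with
replacement) are broken by a deterministic jitter of 1e-10 × coordinate
scale keyed to the run seed.  MI(A,B) = MI(B,A) exactly.  The estimator's
known negative bias in six dimensions (3-D vs 3-D groups) is ≈ −0.12 nats
at n = 2900 and ≈ −0.05 at n = 2·10⁴ for strongly coupled pairs; it
affects planted and null pairs far from equally (planted ≈ 2.5 nats versus
null ≈ 0.0–0.4 after resampling duplicates), so recovery by thresholding is
unaffected, but absolute MI values at pipeline sample sizes should be read
with this bias in mind.  Thresholds are user-chosen (strict inequality,
descending sort); a permutation-null helper estimates the no-coupling
distribution instead of guessing a value.  Pooling over slices is the
default; a per-slice mode averages per-slice estimates.

## What the synthetic data do and do not show

The toy systems exercise every statistical property the pipeline relies on:
Boltzmann sampling under harmonic biases, window overlap, reweighting
consistency, estimator bias/variance trade-offs, and planted dependence
recovery.  They do not emulate high-dimensional CV spaces (the string runs
in 2-D, not ~5000-D), rugged all-atom energy landscapes with entropic
barriers, correlated noise across windows, anisotropic diffusion, or the
slice-to-slice kinetic correlations of genuine reactive trajectories.
Passing tests therefore demonstrate correctness of the estimators and
drivers, not that desk-scale resources could reproduce cluster-scale
membrane-protein results.

## Numerical choices

- MBAR: residual tolerance 1e-8 in f; L-BFGS on the convex objective, then
  self-consistent polish; weights normalized to 1 within 1e-10.
- Tie-breaks: path projection to the lower segment index; profile binning by
  nearest image (round-half-even at bin boundaries).
- Degenerate inputs: duplicate consecutive images are merged (warning);
  image collisions during a string step halve the displacement (warning);
  zero-length sample arrays, non-monotone λ-schedules, empty slices and
  non-confining timesteps raise typed errors.
- Block counts default to 5 (free energies) — a compromise between bias of
  the SE (few blocks) and block-length shortness.
- Trust region: per-image displacement cap at 20% of mean spacing.
- Convergence flags: RMSD plateau (spread < tol over 5 cycles); the
  zero-temperature string stops when the largest per-iteration image move
  falls below 1e-7 (1e-8 in the studies).

## Problem sizes

The default study sizes — 30 images × 2000 steps × 150 cycles for the
string, 20 windows × 2·10⁴ samples for the profile, 10⁴ samples per
alchemical stage pair, 25 stages × 10³ for stratification, 100 × 29
resampled frames for MI over ten replicates — were chosen so the complete
validation (test suite plus acceptance script) runs in a few minutes on one
CPU while keeping every statistical comparison's error at least three times
smaller than its tolerance.

## Known limitations

- Iterated reparameterization shortens strongly curved, coarsely resolved
  paths (corner cutting); resolve hairpins with enough images.
- The restraint-average mean force is only meaningful where k_r exceeds the
  most negative local curvature; the guard cannot detect this automatically
  because it depends on where the path wanders.
- EXP's block SE is itself noisy at 5–10 blocks; BAR's analytic SE is more
  stable and preferred when both directions exist.
- The k-NN MI bias in 6-D is material at n ≲ 10⁴ (see above).
- The PDB reader handles fixed-column ATOM/HETATM records only — enough for
  the optional ingestion path, not a general structure parser.
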