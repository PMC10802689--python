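# Methods

This note documents the models behind `poremap`, the choices made where the
design was genuinely open, and what the synthetic-data generators do and do
not emulate. Units are nanometres and milliseconds throughout unless noted;
diffusion coefficients are reported both as nm²/ms and μm²/s
(1 nm²/ms = 10⁻³ μm²/s).

## Coordinate and data conventions

The transport axis of the pore is X (negative = cytoplasmic side); Y is the
transverse coordinate the microscope records; Z is lost to projection. All
data move through one table schema (`x_nm, y_nm, t_ms, frame, traj_id,
photons, precision_nm`), exchanged as tab-delimited text. Frames within a
trajectory are strictly increasing; precisions are positive where present.

## Localization precision of moving emitters

For an emitter moving during the acquisition time Δt, the localization
variance is

σ² = F · [ 16(s² + a²/12)/(9N) + 8πb²(s² + a²/12)²/(a²N²) ],
s² = s₀² + DΔt/3,

with N photons, a the effective pixel size (default 120 nm), b the
background SD (photons/pixel, default 2), s₀ the in-focus PSF SD (default
150 nm), D the diffusion coefficient, and F the excess-noise factor of
EM-gain cameras (default 2, multiplying the variance — the published form
of this equation is typographically ambiguous, and the standard EMCCD
convention is adopted). The first term is shot noise (∝ 1/N), the second
background noise (∝ 1/N²); σ is strictly decreasing in N and the motion
term vanishes for immobile emitters. Independent errors combine in
quadrature: δ² = δ₁² + δ₂².

## Residence-time filtering

At the pore three populations coexist: free dye that clears the observation
volume within ~3 ms, unbound labeled protein dwelling ~9–12 ms, and
anchored molecules persisting 0.2–2 s until photobleaching. Dwell time
(frames × frame time) classifies trajectories with configurable boundaries
at 5 ms and 100 ms — values chosen between the observed ranges, since no
exact thresholds are standard. Retained data are anchored trajectories in
which every localization has precision ≤ 10 nm and which form a continuous
run (no missing frame indices; no gap closing is attempted) of 4–40 frames
at the 50 ms rate. Filters apply in a fixed order (class → precision →
length) so every trajectory has exactly one disposition; filtering is
idempotent.

## Registration

The nuclear envelope is traced by fitting a 1D Gaussian to each pixel line
perpendicular to it and passing a 2nd-degree polynomial through the
per-line peaks; the RMS residual of that polynomial is the midline
precision (~10 nm on real images; bounded by pixel quantization on clean
synthetic ridges). Pooled clouds are centered by fitting the Y histogram
with a single and a double symmetric Gaussian (equal amplitudes and widths
at c ± d) and keeping the AIC-preferred model — with two guards: ties go to
the single model, and a "double" whose peak separation is below one
histogram bin is treated as unresolved and discarded. The X histogram's
envelope gap is located with an inverted-Gaussian dip fit restricted to the
interior between the data lobes. The total centering error is the
quadrature sum of the two center standard errors. Per-pore tables are
merged by translating each to its reference centroid; recordings with
drift > 10 nm are rejected, and the centroid's localization error is folded
into every merged point in quadrature.

## MSD and extension lengths

Per-trajectory MSD is time-averaged over all frame pairs at each lag (the
all-pairs estimator; overlapping pairs are correlated but the estimator has
the lowest variance at these trajectory lengths). Pooling weights each
trajectory by its length; lags with fewer than 4 contributing pairs are
dropped. The power law MSD(t) = 4Dt^α is fitted by OLS on
(log₁₀ t, log₁₀ MSD): α is the slope, D = 10^intercept/4. α ≤ 0.3 is
labelled strong subdiffusion (the published threshold), α < 1 subdiffusive,
otherwise free/superdiffusive.

For confined motion the MSD plateaus; the average extension is √MSD at the
lag nearest 1 s, with a warning when the local log-log slope there exceeds
0.3 (no plateau reached). The max extension is the largest pairwise
distance between positions in a trajectory — the explored span, not the net
displacement. Both per-trajectory distributions are summarized by Gaussian
histogram fits. The closed-form check: a particle uniform in a reflecting
disk of radius R has stationary E|ΔX|² = R², so the average extension of a
long confined simulation converges to R.

## 2D→3D transformation

Under cylindrical symmetry, the |y| histogram of an axial bin mixes annulus
densities linearly: strip j (|y| ∈ [jΔ, (j+1)Δ)) receives area
contributions only from annuli i ≥ j, so h_j = Σ_{i≥j} ρ_i A_ji with A
upper triangular. A is closed-form from slab-disk intersection areas
S(r, y) = 2(y√(r² − y²) + r² asin(y/r)):

A_ji = [S(r_{i+1}, y_{j+1}) − S(r_{i+1}, y_j)] − [S(r_i, y_{j+1}) − S(r_i, y_j)].

Column sums reproduce annulus areas exactly (the strips partition each
annulus), and the matrix is validated against Monte Carlo area estimates.
Back-substitution from the outermost annulus inward solves the system
exactly; forward-projection → inversion is the identity to machine
precision.

Numerical choices:

- **Folding.** The +y and −y sides are pooled into one |y| histogram before
  inversion (A is built double-sided), enforcing the symmetry assumption
  and halving noise.
- **Axial binning.** X bins grow greedily from the most-negative X until
  each holds ≥ 200 localizations (the reproducibility floor, see below);
  the trailing remainder merges into the last bin.
- **Density convention.** ρ is probability density per unit cross-section
  area, so a uniform disk is flat; Σ ρ_i · (annulus area)_i over a bin
  equals its count fraction (mass conservation, exact before clamping).
- **Clamping.** Negative densities — pure noise artifacts of the
  subtraction — are clamped to zero, not redistributed (densities are
  physical); the clamped mass is recorded per bin and a warning is raised
  only when it exceeds 5% of the bin's counts.
- **Uncertainties.** Poisson counting errors propagate through the
  triangular solve: cov(ρ) = A⁻¹ diag(h) A⁻ᵀ.
- **Peak fitting.** Radial peaks are located by a Gaussian fit to ρ(r) at
  annulus mid-radii, inverse-variance weighted by the propagated
  uncertainties. Weighting matters: per-area densities are strongly
  heteroscedastic (inner annuli have tiny areas, hence noisy densities),
  and an unweighted fit is systematically dragged inward by inner-bin
  noise. The fitted center is confined to the mid-radius range (beyond the
  last annulus, center and amplitude are no longer jointly identified).
  Degenerate profiles fall back to the single-occupied-bin center
  or, when the Gaussian is ill-conditioned (few bins, clamped zeros), to
  three-point parabolic interpolation around the heaviest bin; flat
  profiles raise a no-peak error, and fits wider than the whole radial
  range are flagged low-curvature.
- **Bin width.** The radial width Δr (default 10 nm, candidates
  {5, 10, 15} nm, matching the 5–10 nm scale of radial averaging) is chosen
  as the smallest candidate whose fitted peak agrees with the next-larger
  candidate's within half the smaller width and whose inversion chi-square
  (forward-projected ρ vs observed h) is acceptable; otherwise the largest
  candidate is returned with a warning.

Exposure averaging and localization noise both bias the recovered radius
inward (the mean of points on an arc lies inside the ring); this is
verified on the simulator rather than corrected for.

## Monte Carlo reproducibility

Route localization precision — how precisely the *route*, not a single
molecule, is placed — is the SD of fitted radial peaks over repeated
simulated datasets (default 100 fittings). The reproducibility rate at a
condition (n points, precision σ, radius R) is the fraction of replicates
whose fitted peak lies within an acceptance window of R; the window
defaults to one radial bin (10 nm), since a peak off by more than a bin is
a different route. Replicates sample uniform-angle rings of radius R over a
40 nm axial span with Gaussian noise of SD σ, mirroring the experimental
10 nm single-molecule precision. The rate is reported with a Wilson 95%
interval; the minimal sample size for a target rate takes the smallest grid
value whose interval lower bound clears the target. At the design point
(n = 200, σ = 10 nm, R = 25 nm) the measured rate is ≈ 95%, the basis of
the ≥ 200-per-axial-bin rule. Default 10,000 iterations with a fast mode
(1,000) for desk-scale runs; rates are monotone in n and window and
antitone in σ.

## Open/closed state bootstrap

State percentages are estimated by repeatedly drawing n_sub = 300
localizations, reconstructing, and classifying. The subsample is drawn
without replacement as a contiguous-in-time block by default: state
transitions happen over time, so a time window sees predominantly one
state, making the closed fraction an estimate of the closed-state time
share. (I.i.d. row subsampling is also available, but on a time-mixed table
every replicate sees the same mixture and carries no state signal.) The
classifier is an explicit reconstruction, since no operational definition
of the engaged/disengaged states is standard: a map is *closed* when the
mass fraction inside a 10 nm core exceeds an occupancy threshold. The
default threshold is the uniform-disk expectation (core/r_max)²; for
two-state data a better discriminant is the midpoint of the two pure
states' core fractions (`calibrate_occupancy_threshold`), which is
symmetric between the states. Opening radii of open replicates (first
annulus where density rises above half the profile maximum) are pooled and
summarized by a 1- or 2-component Gaussian mixture chosen by BIC, since the
open state can show more than one characteristic opening. Fractions carry
Wilson intervals and always sum to one. Planted epoch mixtures
(60/40, 50/50, 30/70) are recovered within binomial error plus a small
epoch-boundary mixing floor (windows straddling a transition).

## Overlap statistics

Two maps' overlap is reported as Pearson and Spearman coefficients of their
binned marginal mass profiles. Axial (X) overlap is evaluated first; the
radial (R) dimension is evaluated only when the X Pearson coefficient is
positive — the stated gating rule operationalized with zero as the
criterion. R marginals are restricted to the shared axial support.
Mismatched grids are rebinned mass-preservingly onto the coarser grid.
Disjoint axial supports yield a gated report, not an error. No significance
tests are attached — the coefficients are descriptive.

## Synthetic generators

- **Ring routes.** x ~ U(x_interval), θ ~ U(0, 2π), r ~ N(R, jitter)
  clipped at 0; observable (x, r cos θ). The ring (surface) sampler is the
  default because transport routes are radially peaked; a uniform-volume
  cylinder sampler exists for oracle tests (its inversion must be flat).
  E|y| = 2R/π for the pure ring — used as an analytic check.
- **Tethered chain.** A ball-and-stick analog of a disordered nucleoporin:
  beads (FG-motif regions) joined by links whose length is capped by the
  intervening disordered segment, the root anchored on the wall of an
  open-ended 40 nm × 25 nm-radius cylindrical channel, 8 copies with root
  positions uniform along the wall's axial span. Per 0.5 ms step each
  non-root bead takes an isotropic Gaussian step; constraints apply in a
  fixed, documented order — (1) links clipped root-outward by projecting
  the outer bead toward its inner neighbour, (2) beads axially inside the
  channel reflected off the wall (r → 2R − r) — root re-pinned. The first
  10 s are discarded (burn-in from the collapsed start), then 10 s recorded.
  The per-step SD is a user parameter: its published calibration (≈ 10%
  above the fastest measured terminus) depends on measured data. The
  terminus-anchor distance never exceeds Σ linker_max; this and wall
  containment are asserted in tests on every frame. Bead count and linker
  lengths are user-set (no published values exist); defaults of 8 beads ×
  10 nm links give a 70 nm maximum reach, the scale of the longest measured
  FG-domain extensions.
- **Exposure averaging.** Non-overlapping blocks of k positions average to
  one localization (k = 100 maps 0.5 ms → 50 ms); trailing partial blocks
  are dropped (an incomplete camera frame is discarded); timestamps are
  block midpoints. Averaging is variance-reducing for stationary series and
  biases shell radii inward.
- **Localization noise.** Independent N(0, σ) on x and y; the precision
  column records σ.
- **Auxiliary.** An angular Brownian walk on a transverse ring (shell
  diffusion, for the exposure-bias demonstration) and 2D Brownian motion in
  a reflecting disk (for the confined-MSD closed form).

What the generators do **not** emulate: photophysics (blinking, bleaching
kinetics), EM-gain noise and rendered images, imperfect cylindrical
symmetry, pore orientation scatter at the envelope, and labeling
efficiency. Tests passing on these generators therefore validate the
algorithms' correctness and statistical behaviour, not the full error
budget of real recordings.

## Problem sizes

The test suite and the acceptance script run reduced but statistically
adequate problem sizes, chosen as desk-scale defaults: 1,000–2,000 Monte
Carlo replicates (vs 10,000 in production), 200-iteration monotonicity
grids, 20 × 4,000-step disk simulations, and 10⁵-point area oracles.
Production-scale parameters are plain function arguments.

## Known limitations

- The inversion assumes perfect cylindrical symmetry and a centered cloud;
  residual centering error propagates into the radial profile and is not
  modelled.
- Localization noise enters the reconstruction in the 2D projection, so
  the recovered radial profile is the true profile under an
  inward-skewed effective kernel; peak positions are accurate to about one
  radial bin at the design conditions, no deconvolution is attempted.
- The open/closed classifier is a declared reconstruction; its threshold
  should be calibrated per dataset (pure-state exemplars or the
  uniform-disk default), and reported fractions are conditional on that
  choice.
- The all-pairs MSD estimator correlates neighbouring lags; standard
  errors from the log-log OLS understate the true uncertainty at long
  lags.
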