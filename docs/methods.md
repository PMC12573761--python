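# Methods

This note records the model assumptions, the parameter choices that
matter, the numerical decisions taken where the design was genuinely
open, and the known limitations of the package. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Dynamics model and the toy test bed

The package assumes reversible, overdamped dynamics in a confining
potential V, with equilibrium density π(x) ∝ exp(−βV(x)). Under these
assumptions the Koopman operator K_τ is self-adjoint in L²(π), its
spectrum is real, the leading eigenfunction is constant, and the first
nontrivial eigenfunction ψ₁ encodes the slowest relaxation. The
membership function χ is ψ₁ affinely rescaled to [0, 1].

The built-in test bed integrates the 2D four-well potential
V(x, y) = 10(x²−1)² + 5xy + 10(y²−1)² + 2.2x with the Euler–Maruyama
scheme, x' = x − βD∇V Δt + √(2DΔt) ξ. Defaults: T = 300 K with molar
k_B = 8.314×10⁻³ kJ/(K·mol) (so k_BT = 2.49 kJ/mol), m = 1 amu,
γ = 1 ps⁻¹, hence D = k_BT/(mγ) = 2.49 nm²/ps, and Δt = 0.001 ps. The
four minima near the corners of [−1, 1]² have energies −7.2, −2.8, 2.8
and 7.2 kJ/mol at (−1,1), (1,−1), (−1,−1) and (1,1) respectively, all
separated by barriers well above k_BT.

Numerical choices for the integrator:

* The long-trajectory driver is JIT-compiled (numba) for the built-in
  potential; arbitrary user potentials fall back to a NumPy loop.
  Bursts are integrated vectorized over all N×M replicas at once.
* Noise is drawn from a `numpy` Generator seeded outside the compiled
  kernel, so results are bit-reproducible per platform and independent
  of the execution path.
* The trajectory stream and the burst stream derive from separate child
  seeds of the master seed: changing the number of bursts never
  perturbs X0.
* A divergence guard aborts integration when any coordinate exceeds
  10⁶ in magnitude — unreachable under confining dynamics, so it fires
  only on unstable timestep choices.
* The long trajectory starts at the deepest minimum (−1, 1) by default
  and a burn-in fraction (default 0) is available; starting in a
  minimum makes equilibration fast for the toy landscape.

## Membership-function learning

The iteration f_{k+1} = S K̂_τ f_k uses the Monte-Carlo Koopman
estimate K̂_τ f(x₀ₙ) = (1/M) Σ_m f(x_τ,n,m) and the strict shift–scale
S(v) = (v − min v)/(max v − min v). Strict extremes (not robust
quantiles) are used in S; a constant Koopman image raises a
degenerate-spectrum error with the remedy (longer lag, more states)
named. The initial function f₀ is the shift-scaled first feature
coordinate; any non-constant choice works, and the iteration forgets it
geometrically.

Regression choices:

* **Feedforward network (default).** One hidden layer of 128 sigmoid
  units for inputs with d < 32; a rectifier pyramid (F/2, F/4) above
  that. Training is warm-started: the same parameters continue across
  iterations, 15 epochs per iteration, minibatches of 100, learning
  rate 10⁻³, plain SGD. SGD rather than an adaptive optimizer is a
  deliberate choice: its implicit smoothing keeps the learned surface
  gently varying between sparsely sampled basins, which makes the outer
  fixed point reproducible across seeds, whereas adaptive optimizers
  sharpen χ and can pin a basin represented by only a handful of states
  to an arbitrary extreme. The cost is a slightly smoothed χ: in the
  four-well system the transition corners come out near 0.5 rather
  than at their sharp-limit values closer to 1/3.
* **RBF interpolant** (thin-plate spline, optional k-nearest-neighbor
  locality) for inputs with d ≤ 3. It interpolates its targets exactly,
  including their Monte-Carlo noise, so with small M its iteration
  plateaus at the noise floor instead of converging; it is preferable
  only when M is large or the targets are exact.

Validation and stopping: a random 20% of states (fixed split per run)
is held out; training and validation mean-squared errors are recorded
each iteration and a divergence of more than 10× between them raises an
overfitting warning. The iteration stops when the maximum absolute
change of χ on X0 falls below 10⁻³ (or at the iteration cap, flagged in
the report, not raised). Predictions are clamped to [0, 1] only at
read-out; training targets are already bounded by S. The χ vs 1−χ gauge
is fixed deterministically by requiring the minimum-energy state of X0
to have χ < 0.5 when energies are available; otherwise the trained
orientation is kept and recorded.

Because the regression at each iteration is itself approximate, the
converged χ satisfies the fixed-point identity χ ≈ S K̂_τ χ up to the
regression bias plus the Monte-Carlo noise of a single Koopman
application — not to the stopping tolerance itself. The test suite
checks the residual statistically (per-state standard errors) rather
than at the raw tolerance.

## Map construction

* χ-intervals are uniform on [0, 1], half-open with the last closed, so
  χ = 1 belongs to the last interval.
* CNN clustering: neighbors are pairs at distance < ε (a point is never
  its own neighbor); a density link requires both the direct neighbor
  relation and ≥ θ shared neighbors (the pair itself excluded from the
  count). The text-literal variant — shared neighbors alone, no direct
  neighbor requirement — is available as a switch. Clusters are the
  connected components of the link relation; unlinked states are noise.
* Cluster neighborhoods are **member-anchored** by default: a state of
  X0 (noise included) belongs to a cluster's neighborhood when it lies
  within r_n of *some* member. The mean-anchored alternative (within
  r_n of the cluster's average structure) is available, but for maps
  whose consecutive-interval clusters sit in different basins the
  centroids are typically several r_n apart while the member clouds
  interdigitate along the transition channels, and the mean-anchored
  rule then finds no edges at all; the member-anchored rule detects
  exactly the channel overlap an edge is meant to represent.
* An edge joins clusters of consecutive intervals when their
  neighborhoods share at least one state (threshold configurable); the
  edge weight is the intersection size. For the RMSD metric, candidate
  states are aligned to the anchor before the distance is taken.
* Node weights π are member counts normalized over all clustered
  states; noise carries no weight. Source and sink are the nodes of
  extreme mean χ (ties broken by larger π), and pathways are all simple
  source-to-sink paths with strictly increasing interval index,
  enumerated depth-first in ascending node id, capped at 1000 with a
  truncation warning.

## Kinetics

Free energies E_i = −β⁻¹ ln π_i are reported in k_BT units by default
(β = 1). SqRA edge rates use a unit prefactor: the geometric flux
factor of the full square-root approximation is not identifiable from
cluster weights alone, so all rates are *relative* — comparable within
one map, not absolute inverse times. A prefactor hook is exposed.
Detailed balance π_i k_ij = π_j k_ji = √(π_i π_j) holds algebraically.
The rate matrix spectrum is computed directly; if complex residues
beyond 10⁻⁸ appear, the π-weighted symmetrization D^{1/2} Q D^{-1/2}
(exact under detailed balance) is used instead and the event logged.

A consequence of the unit prefactor worth stating explicitly: the
spectrum of Q is *not* invariant under refining the χ-cover. Splitting
a basin across more intervals changes all √(π_j/π_i) magnitudes, so
eigenvalues drift systematically with N_I rather than reaching a
plateau; only a discretization-aware prefactor (flux area over cell
volume and spacing) would make spectra comparable across N_I. The
sensitivity scan therefore reports the spectrum as a diagnostic of
(ε, θ) granularity — where cluster counts and eigenvalues do stabilize
— rather than as an N_I-convergence check.

## The four-well study conditions and what they show

The reference experiment uses 10⁷ integrator steps, 4000 states at
stride 1000, 10 bursts of 10 steps (τ = 0.01 ps), N_I = 3, ε = 1.0,
θ = 5, r_n = 0.6 — all fixed as the study conditions of the built-in
benchmark. Under these conditions the map resolves the two macro-states
and the two transition corners (4 clusters), and the pathway through
the lower-energy transition corner (−1, −1) is faster in both
directions than the pathway through (1, 1): the (−1, −1) basin is
~e^{β·4.4} ≈ 6× more populated, and SqRA rates inherit that ordering
through √(π_mid/π_source). This ordering is forced by the Boltzmann
weights regardless of the learned χ.

Two fragilities are intrinsic to these conditions rather than to the
implementation. First, the transition corners sit close to the 1/3
χ-boundary, so the middle interval holds only a few tens of states and
its cluster sizes fluctuate across seeds. Second, the (1, 1) channel
crosses the tallest saddle (12.2 kJ/mol ≈ 5 k_BT) and is visited in
roughly 0.1% of samples; at N = 4000 the edge bridging it is
occasionally missed by the r_n criterion, and the map then contains a
single pathway. The package reports these outcomes as they occur.

## What the synthetic test bed does and does not emulate

The four-well system exercises every stage of the method — metastable
basins of unequal depth, a genuine spectral gap, transition regions
sampled only rarely, Monte-Carlo Koopman noise — in a setting where
exact references (quadrature Boltzmann weights, grid discretizations of
the generator) are available. It does not emulate high-dimensional
molecular features, rotational/translational invariance requirements,
RMSD-metric clustering on conformations, or enhanced-sampling state
generation; the feature and metric code paths for those cases are
exercised on small synthetic conformations instead. Passing tests on
the toy system therefore validate the algorithms and their couplings,
not force-field realism.

## Problem sizes in the test suite

The unit suite uses a 2×10⁶-step trajectory fixture and
hundreds-of-states ensembles; the end-to-end acceptance tests run the
full 10⁷-step, 4000-state protocol for three fixed seeds (about a
minute in total). Solvable-system checks use a 1D Ornstein–Uhlenbeck
ensemble built from the exact propagator (N = 400, M = 100) and a
3-state jump process with an explicit transition matrix (N = 300,
M = 400), both with eigendecomposition oracles.

## Known limitations

* Rates are relative (unit SqRA prefactor); no mean-first-passage
  times, committor probabilities, or reactive-flux decompositions.
* χ captures the single dominant slow mode; systems whose interesting
  kinetics live in κ₂ and beyond need a different filter (the map
  accepts any user-supplied ordering parameter in [0, 1]).
* The empirical π assumes X0 is drawn from the canonical equilibrium
  distribution; ensembles from enhanced sampling must be reweighted or
  re-equilibrated upstream.
* Internal coordinates are defined for a declared simple chain; other
  topologies require an explicitly ordered atom selection.
* The CNN distance matrix is computed densely per interval (fine up to
  a few thousand states per interval).
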