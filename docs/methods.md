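# Methods

## Model

A motion is represented by a centralized network: a small bank of
oscillator *centers* drives a large layer of *satellite* units whose
weighted outputs reproduce marker coordinates.  For output channel
`k` (one coordinate axis of one marker),

    x_k(t) = Σ_j  W_kj  Φ_j(q(t)),

where `q(t) = (q_1, …, q_n)` are the center states and `Φ_j` are the
satellite basis functions.  Centers are harmonic oscillators
`q_i'' + ω_i² q_i = 0` for fitting, and optionally nonlinear oscillators
`q_i'' + z_c f(q_i) = 0` (pendulum `f = sin q` or Duffing
`f = a q − b q³`) when a single scalar control `z_c` should select the
frequency; the nonlinear orbit frequency `ω(z_c, p0) = 2π/T` is computed
from the first return of the integrated orbit to `q = 0` with `p > 0`, and
its conserved energy `E = p²/2 + z_c F(q)` (with `F' = f`, `F(0) = 0`) is
exposed as an integration diagnostic.

Three basis families are implemented: Gaussian radial basis functions
`Φ_j(q) = exp(−b²|q − q̄_j|²/2)` (the default and the one used in all
acceptance experiments), a cosine series `Φ_j(q) = cos(j π ⟨q,u⟩ / x0)`
on a scalar projection of the center state, and scalar monomials
`Φ_j(q) = q^{j−1}`.

## Conventions and defaults

- **Units.** Angular frequencies are rad/s internally; every user-facing
  frequency is in Hz (factor 2π).  Marker coordinates carry an opaque unit
  label (typically mm) and all absolute errors are reported in it.
- **Oscillator phase and amplitude.** `q_i(0) = 0`, `q_i'(0) = p0_i`.
  For harmonic banks the default `p0_i = ω_i` gives unit amplitude
  `q_i(t) = sin(ω_i t)`; any output amplitude is absorbed by `W`, so this is
  pure normalization.  The phase is anchored at the first frame of the
  fitted segment.  Consequences: relabeling the time axis leaves every fit
  unchanged (tested), but a genuine phase shift of the *data* is only
  partly absorbed by the weights — where the center curve `q(t)`
  self-intersects, the shifted target becomes a multivalued function of `q`
  and the attainable error grows.  We therefore do not claim phase
  invariance of the objective; the tests assert exact invariance under
  relabeling and under shifts by a common full period only.
- **RBF geometry.** Centers `q̄_j` default to the center states at `N_m`
  equally spaced sample indices of the fitted segment (endpoints included):
  every satellite is then active somewhere on the data.  The sharpness
  defaults to `b = 1 / median(nearest-neighbour distance among centers)`,
  where neighbours closer than 1e−8 of the center-cloud diameter are
  treated as duplicates and skipped — trajectory-placed centers revisit
  states (to rounding) whenever the candidate frequencies are commensurate
  with the window, and a duplicate carries no length scale.  A lone
  satellite defaults to `b = 1`, matching the unit amplitude convention.
  Both placement and sharpness can be overridden in `BasisConfig`.
- **Intercept.** A constant design column is appended for the RBF family
  only (the cosine family contains near-constant columns and the
  polynomial family an exact one), so fits can absorb channel offsets.
  Switchable via `BasisConfig.intercept`.
- **Least squares.** `fit_weights` returns the minimum-norm solution at
  ridge 0 (LAPACK gelsd) and solves the regularized normal equations
  otherwise.  Higher-level fits default to a numerical-stability ridge of
  1e−10 times the mean Gram diagonal; pass `ridge=0.0` for exact least
  squares (the nestedness tests do).

## Accuracy functionals

Per marker and axis, the squared error `ε²_X = Σ_m (X(t_m) − x̂(t_m))²`
and its relative form `ε²_{r,X} = ε²_X / Σ_m X(t_m)²` with the **raw
(uncentered)** second moment in the denominator — deliberately so, which
makes relative accuracy offset-dependent; channels with zero second moment
raise a degenerate-channel error naming the axis.  The integral relative
accuracy is the mean of the three squared relative errors,

    ε²_{r,k} = (ε²_{r,X} + ε²_{r,Y} + ε²_{r,Z}) / 3,

exposed both in squared form (`integral_rel2`, the quantity minimized) and
as its square root (`integral_rel`, the scalar quoted in reports).  The
absolute error is the mean per-frame Euclidean distance between observed
and predicted 3-D position.

## Frequency search

`ω* = argmin ε²_{r,k}(ω)` over candidate frequency vectors: an exhaustive
grid (default 0.05–5 Hz, step 0.01 Hz; unordered pairs for n = 2) for one
or two centers, and a seeded uniform random search (default 2000 draws)
for n ≥ 3.  Frequency vectors are sorted ascending (centers are
exchangeable); candidates within 1e−12 of the minimum objective are ties,
broken to the lexicographically smallest vector — the tolerance matters
because the batched objective computes residuals through normal-equation
quadratic forms with ~1e−16·‖Y‖² cancellation noise, so exact ties (e.g. a
constant channel, which every candidate fits through the intercept) are
ties only up to that noise.

The search engine evaluates candidates in vectorized chunks: per-frequency
distance fields are precomputed once (the squared distance in `q`-space
separates across centers for trajectory-placed RBF centers), and the
ridge-regularized normal equations are solved in batch.  The scalar
single-fit path is the reference; tests assert the two agree to ~1e−9.
The reported model and accuracies always come from a final scalar refit at
`ω*` with directly computed residuals.

Frequencies learned on one marker transfer to the others by weight-only
refits (`transfer_fit`); `average_marker_search` instead minimizes the sum
of the per-marker objectives (slower, all-marker evidence).

A practical caveat measured during development: with trajectory-placed
RBF centers the objective is *steep* in ω — a frequency error of a few
thousandths of a Hz over a 10 s window already degrades the fit visibly,
so when the generating frequency falls mid-cell of the 0.01 Hz grid an
alias pair occasionally wins under observation noise.  The recovery tests
therefore assert ≥ 18/20 seeded successes, not 20/20.

## Segmented motions

Segment boundaries are 1-based frame indices `T_1 < … < T_{S+1}`; segment
`i` covers `[T_i, T_{i+1})` except the last, which is closed (a trailing
boundary of `K+1` is accepted and clipped, matching the common habit of
writing overlapping endpoints).  Each segment is searched and fit
independently with the oscillator phase re-anchored at the segment start;
no continuity constraint is imposed across seams — the assembled piecewise
prediction reports the jump magnitude at every boundary instead, so
smoothness is measured, not enforced.

## Model-size selection

`AICc = n ln(rss/n) + 2k + 2k(k+1)/(n − k − 1)` with `n = 3·K·M` scalar
observations and `k = (#weight entries) + (#searched frequencies)`; both
counts are configurable.  `model_scan` evaluates the (centers × satellites)
lattice — grid search for n ≤ 2, seeded random search (seed offset by n)
above — refits all markers at each `ω*`, pools the residual, and returns
the AICc-minimizing pair.

## Switching module

A distar network (hub `z`, satellites `w̃_1..w̃_m`, no satellite–satellite
edges) switches the generator between stored motions:

    w̃_i' = σ(b̃_i z − h̃_i) − w̃_i/κ,
    z'   = σ(κ⁻¹ Σ_j ã_j w̃_j − h) − ξ λ̄ z,

with logistic σ by default.  Equilibria satisfy `w̃_i = κ σ(b̃_i z − h̃_i)`
exactly, so rest points are roots of the reduced scalar equation
`σ(S(z) − h) = ξ λ̄ z` with the staircase `S(z) = Σ ã_j σ(b̃_j z − h̃_j)`;
`find_rest_points` brackets sign changes on a dense grid (default 4000
points on (−0.5, m+1.5)), refines by bisection, lifts each root to the full
state and classifies stability from the forward-difference Jacobian
(step 1e−7 of the state scale, hyperbolicity margin 1e−6).

`construct_switch(m, β, κ)` realizes m-stability constructively: satellite
sigmoids of gain 50 step the staircase up at `z = j − 1 + β/2`; the hub
gains and threshold are solved in closed form so that on the j-th plateau
the hub output equals `ξ0 λ̄ t_j` with `t_j = j − 1/2 + 3β/4`, which places
the j-th stable crossing inside `(j − 1 + β, j + β)` while keeping the
decaying line below the staircase elsewhere (the feasibility interval for
the hub threshold `h` is non-empty for every m ≥ 1, 0 < β < 1).  A numeric
scan then certifies an open ξ-interval with exactly m stable rest points in
those intervals and finds a larger ξ with a single stable rest point near
zero (geometric search, factor 1.5, 40 steps budget; failure raises a
construction error with the scanned range).  The hub decay is applied
*outside* the sigmoid — the reading under which the rest-point intervals
scale with ξ as required.

Stored motions are `(z-anchor, model)` pairs; a settled hub value selects
the nearest anchor (ties toward smaller z).  `run_global_model` plays a
piecewise-constant ξ schedule: each piece integrates the switch from the
current state, settles (a warning is issued and the nearest anchor used if
the vector-field norm still exceeds 1e−6), and emits that motion's outputs
with the oscillator phase restarting at the piece start; transitions are
instantaneous re-parameterizations, and nothing feeds back from the
generator onto the switch.  Note the hub relaxes at rate ξλ̄ (≈ 0.1/s for
a calibrated 3-motion module), so schedules need tens of seconds per piece
to settle.

## Synthetic data

The generator draws exactly the model the method assumes: harmonic centers
at stated or uniformly drawn frequencies (default range 0.3–1.6 Hz),
RBF centers placed on the actual trajectory, i.i.d. standard-normal weights
rescaled so every channel has unit half peak-to-peak amplitude, sampled at
120 Hz for 10 s (K = 1200) by default — the sampling rate and clip scale of
typical optical mocap.  Observation noise is i.i.d. Gaussian per sample and
channel with SD expressed as a fraction of the channel amplitude; this is
the minimal observation model for recovery experiments.  Segmented
generation concatenates independent per-segment models on a continuous time
axis and returns the true boundaries.

What the generator does **not** emulate: skeleton constraints and rigid-body
correlations between markers, soft-tissue artifacts, marker occlusions/gaps,
non-stationary amplitudes, and transients between segments.  Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not performance on real
captures.

## Problem sizes in tests and the acceptance script

Acceptance experiments use the defaults above (K = 1200, 25 satellites,
grid 0.05–2.0 Hz step 0.01 Hz); recovery and AICc-selection experiments use
20 seeded replicates at 1% noise with per-replicate frequencies drawn from
0.3–1.6 Hz, and the random search for three centers uses a 1000-draw
budget.  The nestedness check uses nested center subsets
{10, 20, 40, 80, 160} of one 160-point placement with shared sharpness and
ridge 0 — nestedness of the design columns is what guarantees monotone
residuals, so the sharpness must not be re-inferred per subset.

## Known limitations

- Exhaustive grid search is limited to two centers; beyond that the seeded
  random search gives no optimality guarantee (the AICc scan inherits
  this).
- The cosine (harmonic) basis spans only functions even in the projected
  center state; a pure off-phase sinusoid is not representable at its own
  frequency, so frequency identification with that family alone is
  unreliable.  It is retained for completeness; the RBF family is the
  recommended default.
- Relative accuracies are offset-dependent by construction (raw second
  moments); compare them only between fits of the same channel.
- Segment boundaries are inputs; no automatic segmentation is provided.
- Oscillator centers are uncoupled; synchronization phenomena are out of
  scope.
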