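# Methods

## Model and procedure

The forecaster treats a monthly count series x(t) as a superposition of
oscillatory modes on different time scales plus a slow trend, and models
each mode separately with a small autoregressive neural network.

**Empirical mode decomposition.** Sifting extracts one intrinsic mode
function (IMF) at a time: find the strict interior local maxima and
minima (a plateau of equal values contributes one extremum at its
midpoint, rounded down — any deterministic convention works, this one is
fixed); interpolate natural cubic splines through each set (second
derivative zero at the end knots); subtract the envelope mean from the
candidate; repeat until the normalized squared change between successive
candidates, SD = Σ(h_prev − h)² / Σ h_prev², falls below 0.2 *and* the
candidate satisfies both IMF conditions — extrema and zero-crossing
counts within one of each other, and an envelope mean within 5% of the
amplitude half-range of zero.  The SD criterion with threshold 0.2 is
the classical choice; the explicit IMF check guards against premature
acceptance.  Decomposition stops when the running remainder is monotone
or has fewer than two maxima or two minima.  Reconstruction (ΣIMFs +
residue = input) is exact to round-off because every component is
obtained by subtraction.

Boundary handling: before spline fitting, two extrema are reflected
across each end of the index range (mirror policy; a clamp policy that
pins the envelope to the nearest extremum value is available).  Without
extension, cubic envelopes diverge at the ends and leak spurious energy
into the fast modes.  Edge samples within roughly two extrema of a
boundary remain the least trustworthy part of any component.

**Component networks.** Each component is min-max scaled onto [−1, 1]
and embedded with 3 lags: inputs (x(t−3), x(t−2), x(t−1)), target x(t).
The network is three-layer, 3–14–1: hidden units tanh(Σωx − b), linear
output Σv·H − b₀ (thresholds subtracted, an equivalent reparameterization
of the usual +bias convention).  The hidden size follows the empirical
rule n₂ = n₁ + n₃ + m with m = 10.  The scaling is fitted on the whole
component path because the pipeline order is decompose → normalize →
split; under the leakage-free option (below) the path itself ends at the
split, so nothing from the test period enters either way.

**PSO initialization.** All 71 weights and thresholds form one particle
(layout: input→hidden weights row-major, hidden thresholds,
hidden→output weights, output threshold).  The swarm (40 particles, 200
iterations) minimizes the training MSE on the normalized pairs.
Velocity update V ← ωV + c₁r₁(P_i − X) + c₂r₂(P_g − X) with fresh
uniforms per particle *and* per dimension (standard practice; a scalar
per particle correlates the dimensions and slows convergence); inertia ω
decreases linearly 0.9 → 0.3, the cognitive factor c₁ falls 2.5 → 0.5
while the social factor c₂ rises 0.5 → 2.5, shifting the swarm from
exploration to consensus.  Velocities are clamped to [−1, 1]; positions
are unbounded.  Initial positions are uniform on [−1, 1] (matching the
velocity scale), initial velocities uniform on one tenth of the velocity
box.  The schedule index runs t = 0..t_max so both endpoints are
attained.  A best fitness of 1e-30 stops the run early.

**Refinement.** The swarm's global best seeds resilient backpropagation
(Rprop): per-parameter steps start at 0.07, grow ×1.2 while the gradient
keeps its sign, shrink ×0.5 when it flips (the flipped step is skipped),
bounded to [1e-6, 50].  Stopping: epoch MSE ≤ 0.01 (normalized scale),
gradient max-norm ≤ 1e-6, or 1000 epochs.  The best parameters seen are
returned, so refinement can never leave the network worse than its PSO
seed.  Plain gradient descent with momentum (rate 0.15, momentum 0.9) is
available as `TrainConfig(algorithm="gdm")`; Rprop is the default
trainer, momentum descent the documented alternative, since the two are
complementary conventions for the same refinement stage.

**Forecasting.** Default scheme is one-step-ahead: each horizon month is
predicted from the *observed* previous three component values
(teacher forcing); `recursive` feeds the model's own predictions instead
and degrades gracefully with horizon length.  Per-component predictions
are denormalized and summed; the superposition identity (total = column
sum of components) is asserted to 1e-9.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `sd_threshold` | 0.2 | — | classical sifting stop; smaller splits modes more finely |
| `n_lags` | 3 | months | input width of every component network |
| `n_hidden` | 14 | nodes | n₁ + n₃ + m with m = 10 |
| `goal_mse` | 0.01 | normalized² | training stop on the [−1,1] scale |
| `max_epochs` | 1000 | epochs | refinement budget |
| `population` / `iterations` | 40 / 200 | — | swarm budget per component |
| inertia / factors | 0.9→0.3, 2.5↔0.5 | — | exploration→exploitation schedules |
| `decompose_scope` | `"full"` | — | see leakage note below |

One master seed deterministically derives per-component PSO, training
and initialization seeds, so an entire pipeline run is reproducible
bit-for-bit.

**Leakage note.** The default decomposes the *whole* series before
splitting, the natural procedure when a completed historical record is
decomposed once and then studied — but the test months then influence
the IMF shapes.  `decompose_scope="train"` restricts decomposition (and
scaling) to the training span; the test suite verifies that altering
test-period values leaves a train-scoped fit bit-identical.  Prefer
`"train"` when the evaluation must simulate genuine out-of-sample
forecasting.

## Synthetic study conditions

The generator emulates nine years of monthly outpatient counts:
value(t) = (30000 + 50t)·profile[month] + N(0, 1000²).  The profile is
multiplicative — January 1.25, February 1.20, July 0.80, the remaining
nine months on a gentle ramp chosen so the twelve factors average to
exactly 1 (hence the trend component is the deseasonalized level and
calendar months with factor 1 have zero seasonal index in the noiseless
limit).  Multiplicative seasonality on an additive trend keeps the
seasonal swing growing mildly with the level while the ground-truth
additive split (seasonal + trend + noise) stays exact and testable.
Gaussian noise is the simplest null; at counts of ~3·10⁴ discreteness is
negligible.

What passing tests on these series do **not** show: robustness to
epidemic shocks, calendar-day composition, holiday effects, policy
breaks, or overdispersed count noise — none of which the generator
produces.  Results on real registries can be materially worse.

## Evaluation

R is the Pearson correlation between forecasts and observations.  MAPE
is the mean of |x̂ − x|/|x|, reported as a fraction (0.077 = 7.7%); the
sum-of-absolute-errors variant without the denominator is dimensionally
inconsistent for count series and is not used.  SSE = n·RMSE² by
identity, asserted in tests.  SFI1 uses every calendar month with at
least two observations across years; SFI2 and the relative error are
per-step and scale-invariant.

## Numerical choices and degenerate inputs

- Signals with fewer than two maxima or two minima are "not siftable";
  decomposition terminates there (and refuses inputs under 8 samples
  outright, where envelopes are meaningless).
- Constant components cannot be min-max scaled and raise a degenerate-
  input error naming the component.
- Duplicate spline knots created by boundary mirroring are deduplicated
  (first occurrence wins); two remaining knots degrade to linear
  interpolation.
- Fitness and loss values are checked for finiteness every iteration;
  a non-finite value aborts with the iteration number rather than
  propagating NaNs.
- Sub-seeds are drawn from a seed sequence keyed by (master seed,
  component index, purpose) and reduced below 2³¹.

## Known limitations

- Three lags cannot disambiguate every phase of a 12-month pattern: in
  the zero-noise limit the fastest IMF becomes a sharp near-alternating
  seasonal mode whose 3-gram → next-value map is ambiguous, leaving a
  MAPE floor around 0.12 on the noiseless synthetic series regardless of
  training depth.  With realistic noise the decomposition spreads the
  structure across more IMFs and the hybrid clearly beats the plain
  network (10/10 default seeds in the acceptance run).
- The IMF count of a real series is sensitive to the sifting stop and
  boundary policy; reported counts should always be read alongside the
  `SiftConfig` used.
- No prediction intervals; metrics describe point forecasts only.
- One architecture and one hyperparameter set are shared by all
  components; very slow residues might profit from a simpler model.
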