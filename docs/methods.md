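# Methods

This note documents the models, defaults and design choices behind
`enosekit`, including the points where the underlying method is
ambiguous and the package had to commit to one reading.

## Sensor-event model (simulator)

Channel *c* of a synthetic event is

    v_c(t) = b_c + A_c · (1 − exp(−t/τ_c)) + δ·t + ε(t),   ε ~ N(0, σ²),

clipped to [0, s_c], sampled at 1 Hz for 1,000 s. This is the simplest
model with the observed qualitative features of MOS arrays exposed to a
volatile source: a saturating rise toward a class-dependent plateau, a
slow positive drift of the semiconductor baseline, and additive read
noise. Clipping at the saturation voltage guarantees that dividing by
s_c always lands in [0, 1].

Defaults (built-in class library): s_c = 5 V on every channel,
baseline b_c = 0.3 V, drift δ = 2 mV/s, noise σ = 2 mV, amplitudes
0.3–2.5 V, time constants 110–320 s. The amplitude ceiling keeps
b + A + 1000·δ below 5 V, so events never clip and the response stays
informative over the whole recording. The 2 mV noise corresponds to a
clean bench amplifier on a volts-scale signal (signal-to-noise of order
10³) — the *high-SNR* regime in which the every-epoch matching rule
below is meaningful. The six built-in classes (fresh/day-1/day-2 fish
and meat) are hand-chosen illustrations of a decay series — response
amplitude growing with decay day, fish and meat exciting different
channel subsets — not fits to any real sensor.

The drift floor matters more than it looks: at the plateau the true
normalized gradient is δ/s ≈ 4·10⁻⁴ s⁻¹, roughly 20× the standard
deviation of the gradient noise after smoothing (σ/s per sample,
reduced by √K by the mean filter and divided by K by the gradient).
Keeping every epoch's true gradient that far above the noise is what
makes a rule demanding ≥ 80% similarity *at every epoch* satisfiable;
with zero drift the late-time gradients decay into the noise floor and
the per-channel match becomes a coin flip.

What the simulator does **not** model: sensor-specific response
kinetics and cross-sensitivities, temperature/humidity covariates,
correlated or 1/f noise, sensor aging between events, and concentration
dynamics of the odor source. Passing tests on these events therefore
demonstrates the correctness and internal consistency of the pipeline,
not field performance on real arrays.

Every event, split and stage is seeded through `numpy`'s
`SeedSequence` spawning, so a study is bitwise reproducible from one
integer.

## Preprocessing

The smoothed moving average is the plain causal windowed mean
(`out[t] = mean(x[max(0, t−K+1) .. t])`), with partial windows at the
start so the output has the source length and no future samples are
used. An alternative reading — a recursively weighted (Wilder-type)
moving average — exists, but the plain mean is what "returns the mean
value while dropping the oldest sample" describes; the filter is
isolated behind `preprocess.smma` should anyone want to swap it.
The window defaults to K = 10 samples: long enough to suppress 2 mV
sample noise by ~3×, short enough to leave ~100 gradient epochs in a
1,000 s event. K is a logged configuration value, not a constant.

Normalization divides by a *configured* per-channel saturation rather
than the observed maximum (both are supportable; the observed maximum
makes signatures scale-invariant but couples them to the event).
A reading above the configured saturation raises — it signals a mis-set
ceiling rather than data to be silently clipped.

## Gradient features

The two-branch gradient (see README) is evaluated at t = K, 2K, …; the
t ≤ K branch fires exactly once (at t = K, where both branches agree),
and t = 0 is excluded since the first branch divides by t. Gradients
are computed on the smoothed **normalized** series, so their units are
fraction-of-saturation per second and channels are comparable. The
telescoping identity S(mK) − S(K) = K·Σ T over epochs 2K..mK is kept as
a conservation check in the tests. Profiles carry a query/reference
role flag; the formula is identical for both roles and the flag is
bookkeeping.

## GA stage

Ambiguities resolved, as the package's own choices:

* **Fitness argument.** f(x) = x + K·|sin(32x)| takes a scalar, but a
  chromosome has 8 genes. Chromosome fitness is defined as the mean
  per-gene f, which preserves the formula and is invariant to
  chromosome length. Genes live in [0, 1] ⊂ [0, π), so the domain
  constraint holds by construction; radians throughout.
* **Selection operator** (unspecified): roulette wheel, the canonical
  choice for this style of GA, with a uniform fallback when the total
  fitness mass is zero.
* **Elite count** (unspecified): 1 — "the strongest individual is
  passed to the next generation unchanged" — which makes the best
  fitness provably non-decreasing.
* **Crossover probability** applies per selected pair; non-crossing
  pairs are cloned before mutation.
* **Threshold scope**: the 0.5 stopping threshold applies to the best
  individual (stopping when *every* individual passes is the stricter
  alternative reading; with threshold 0.5 and K ≥ 1 it would rarely
  differ by more than a few generations).
* **Population seeding.** When the GA is used to denoise a measured
  feature vector, the population is seeded entirely
  (`seed_fraction = 1.0`) with jittered copies of the observation
  (Gaussian jitter, sd 0.01, clipped to [0, 1]). This is deliberate:
  if uniform-random individuals are admitted, the fitness-maximizing
  elite decouples from the measurement entirely and the "denoised"
  vector carries no class information. With pure seeding the elite is
  a local, fitness-guided refinement that stays within a few jitter
  sd of the data. The fraction is a config knob, so the exploratory
  variant remains available.

With K = 10, typical feature vectors score well above the 0.5
threshold already in the seeded initial population, so denoising runs
usually terminate at generation 0 — the GA's role collapses to "pick
the fittest local perturbation", and the expensive generational loop
only engages for low-level signals.

## ANN stage

One output unit cannot encode several classes, so the pipeline trains
one one-vs-rest network per reference class (targets 0.9/0.1, strictly
inside the sigmoid's range). Choices:

* logistic sigmoid activation everywhere (outputs in (0, 1) match the
  normalized targets);
* full-batch updates per epoch, making training independent of sample
  order;
* weights initialized uniform on [−0.5, 0.5], seeded;
* stopping metric: epoch MSE against the 2·10⁻⁴ learning goal, with
  the normalized deviation d logged alongside (d is a reporting
  statistic here; descending on MSE is the standard, well-posed
  choice);
* epoch budget 20,000 by default: at learning rate 0.01 full
  convergence to the goal takes ≈ 30,000 epochs on a 20-point toy
  problem, and 20,000 gives one-vs-rest scores comfortably separated
  around the 0.5 output threshold at acceptable runtime. The budget is
  a patience cap, not a tuning parameter — training stops early the
  moment the goal is reached.

The trained network acts as a *confirmation gate* in the full
pipeline: the database-matching verdict (below) stands only if the
matched class's network scores the GA-denoised features at or above
the output threshold (default 0.5); otherwise the event is declared
unidentified. The gate cannot overturn the matching rule in favor of
another class.

## Database matching

Per class, the reference record stores the gradient signature of the
*averaged* training events (averaging n events shrinks noise by √n)
plus the GA-denoised class feature vector. Matching a query:

* **similarity** of two gradients: 0 if their signs differ, else
  1 − |g_q − g_r| / max(|g_q|, |g_r|); magnitudes below ε = 10⁻⁶
  (normalized units) count as sign 0 and match only other near-zeros,
  with similarity 1. "Same pattern" is thus read as sign agreement and
  "more than 80%" as this relative score with threshold 0.80 —
  implemented inclusively (≥), with a `strict_inequality` flag to flip
  the boundary, since the source description does not resolve it.
* a **channel matches** when similarity ≥ 0.80 at *every* shared epoch
  (the strictest of the possible readings of "in all epoch"; the
  similarity threshold and channel quorum are both config keys so the
  looser readings are testable);
* **identification succeeds** when ≥ 6 of 8 channels match; records
  are ranked by matched-channel count then mean similarity, ties kept
  in database order.

## Ablations (benchmark)

"ANN-only" = skip the GA: networks trained on raw feature vectors,
verdict by arg-max score. "GA-only" = skip the ANN: verdict by nearest
(L2) stored class elite vector after GA denoising. These are this
package's definitions, stated here because the corresponding
stage-wise comparisons are not standardized anywhere; the benchmark
asserts only the qualitative ordering (full pipeline at least as good
as ANN-only on average), not any absolute rate.

## PCA diagnostics

Covariance-mode PCA (correlation mode available) of the per-event
feature matrix, computed by eigendecomposition of the sample
covariance; components sign-fixed so the largest-magnitude loading is
positive; a dominance ratio λ₁/λ₂ summarizes the scree (∞ for
numerically rank-1 data, detected at relative tolerance 10⁻¹²). PCA is
a visualization aid only; the classifier never consumes it.

## Problem sizes and numerical notes

The acceptance script and the end-to-end tests use the study design as
specified — 2 classes × 50 events × 1,000 samples, 30/20 split —
across 20 seeds; unit tests use shorter events (150–400 samples) and
smaller populations where only correctness, not operating-point
behavior, is at stake. Feature extraction is O(n) per channel via
cumulative sums; the per-event feature vector handed to the GA/ANN is
the smoothed normalized end-of-event (plateau) level per channel — the
only reading of "the sensor values as chromosome inputs" that keeps
genes in [0, 1]. Degenerate inputs fail loudly: empty series, windows
below 1, saturations ≤ 0, readings above saturation, untrained
networks, empty databases and mismatched windows all raise
`ValueError` rather than degrading silently.

## Known limitations

* The every-epoch matching rule is intrinsically brittle at low SNR —
  one noisy epoch fails a channel. That is a faithful property of the
  rule, not of the implementation; the config exposes the threshold,
  quorum and ε for more forgiving variants.
* Success rates reported on synthetic events say nothing quantitative
  about real sensor data; only the pipeline's internal contracts and
  qualitative orderings transfer.
* The GA fitness rewards large feature values as such; its denoising
  benefit is limited to the seeded local-refinement regime described
  above.
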