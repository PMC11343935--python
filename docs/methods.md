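# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `stresscast`, and what the synthetic benchmark does and
does not establish about real data.

## Data model

A stress sequence is one value per calendar day in `{0..5}`; 0 is the
*unknown* sentinel for unreported days. Unknown days are kept positionally
(phase-space indexing assumes contiguous days) and are fed **literally as 0**
into embedding and forecasting — the same convention the missing-data
robustness protocol uses when it corrupts inputs — but are always excluded
from metric computation. Imputing instead of feeding 0 is a plausible
alternative we deliberately do not take, to keep the analysis and the
robustness protocol consistent.

Label schemes map raw levels 1–5 to ordinal classes. The cut points are not
canonical; the defaults ({1,2} vs {3,4,5}, and {1,2}/{3,4}/{5}) were chosen
so that on data with the benchmark's marginals the class balances are ≈1:2
and ≈5:10:1 respectively. Both are user-configurable, and any configured
mapping must be monotone in the raw level.

## Phase-space reconstruction

* **Delay τ** — first interior local minimum of the plug-in mutual
  information over the discrete 6-letter alphabet (continuous test series
  fall back to a fixed-width 16-bin histogram). `M(0)` is taken as the
  series' self-information when testing whether τ=1 is a local minimum. If
  no interior minimum exists by `tau_max` (default 10) the argmin is used
  with a warning.
* **Dimension d** — Cao-style statistic: `r(k,d)` is the distance ratio of
  the dimension-d nearest-neighbor pair re-measured in d+1 dimensions, with
  the neighbor found in dimension d and *not* re-searched; `E(d)` averages
  over the indices valid in both embeddings (the naive index bound
  `n−(d−1)τ` overshoots for d+1 and would be ill-defined). `d` is the
  smallest value with `|EV(d)−1| ≤ ε` for two consecutive d (ε default 0.05;
  "stops changing" has no canonical numeric threshold, so ε is exposed).
  No saturation by `d_max` returns `d_max` with a warning — the signature of
  a stochastic series.
* **Neighbor searches** use a k-d tree with a Theiler exclusion window
  (default 1) so temporally adjacent points cannot be neighbors. On
  discrete-valued series exact duplicates are common; a duplicate carries no
  information about local expansion, so searches prefer the nearest
  *distinct* point and fall back to duplicates only when nothing else
  exists. Remaining zero-distance denominators are skipped (count reported).

## Lyapunov exponent and horizon

`D(q)` averages the log separation of each retained pair `q` steps
downstream, over the pairs that stay inside the embedding for every
`q ≤ q_max` (default 15) and never hit an exactly zero separation. `l_max`
is the least-squares slope of the **longest initial segment (≥3 points)
whose linear fit keeps R² ≥ 0.95** — a reproducible stand-in for "fit before
the plateau", with a manual `fit_range` override. The horizon is
`m = ⌊1/l_max⌋` days, floored at 1; exponents are in natural log per day, so
the reciprocal is directly in days. Non-positive slope ⇒ not chaotic,
horizon unbounded. A zero-variance series short-circuits to the fixed-point
profile (l_max = 0).

The R²-prefix rule has a known mild bias: on the r=4 logistic map the fitted
window extends one or two points into the plateau bend, giving ≈0.60 against
the analytic ln 2 ≈ 0.693 (−13%), stable across seeds. We accept this bias
rather than hand-pick fit windows per series.

## Forecasters

**Analog predictor.** Gaussian-kernel vote of the q (default 3 — small
neighbor counts suit ~35-point trajectories) nearest predecessors of the
last embedded vector; the continuous estimate is a convex combination of
neighbor successors, rounded half-up into 1..5 before re-embedding.
τ and d stay fixed across recursive steps: re-estimating them on a
36-point series is unstable and the per-user profile is meant to be a single
object.

**Attention LSTM.** Implemented from scratch in float64 numpy with
analytically derived gradients (verified against central finite differences
in the test suite) and Adam (β₁=0.9, β₂=0.999, ε=1e−8). Defaults follow the
study conditions: hidden size 8, learning rate 0.001, batch 64, cross-entropy
loss, `max_len` 44. Choices the architecture description leaves open, fixed
here:

* Dimension attention as printed (`X′ = X·DA`) is shape-inconsistent with a
  per-step d-vector recurrence; we read it as **columnwise reweighting**
  `X′ = X ⊙ DA`, the only shape-consistent interpretation. `W_DA` is tied to
  the padded length so one parameter set serves all input lengths.
* Each training prefix is zero-padded to `max_len` both in front and in
  back, and **both variants enter the batch as separate rows**; at inference
  the two variants' probability vectors are averaged.
* Epochs are governed by early stopping: 10% validation split, patience 20,
  cap 500.
* Recursive feedback needs a raw level from a class prediction: we append
  the **midpoint of the class's raw-level set** (half-up), e.g. class
  "stressed" = {3,4,5} → 4. Configurable via the label scheme.
* When recursion grows the sequence past `max_len`, the most recent
  `max_len` days are kept (sliding window).
* Initialisation is Glorot-uniform from the config seed, forget-gate bias 1;
  the whole pipeline is a pure function of (seed, data), so forecasts are
  bit-reproducible.

The DL-only ablation feeds the raw padded sequence as scalar steps with no
embedding and no dimension attention; `no_DA`/`no_TA` flags remove either
attention independently (no_TA ⇒ uniform mean pooling).

## Evaluation

One-vs-rest TP/FP/TN/FN per class; accuracy, precision, recall, F1 are
macro-averaged (per-class accuracy is otherwise undefined for 3 labels;
micro variants are exposed too, and for 2 classes macro accuracy equals
plain accuracy). Pairs with unknown truth are dropped and counted, never
scored. Range prediction pools every user × horizon-day into one confusion
computation and also reports per-day-offset curves. Cross-validation
partitions **users**, not rows, so no user appears in both train and test;
the fold assignment is a pure function of the seed. The protocol horizons
default to the consensus (median) chaos profile of the fold's training pool
and can be pinned (the sweep grids pin 19/17/12 days for 35/30/25-day
inputs).

## Synthetic benchmark

Defaults: 50 users × 56 days, logistic map r=4 latent dynamics with
observation noise σ=0.05, quantile discretization to levels 1–5 (cumulative
targets 1/6, 1/3, 2/3, 15/16 of a 50k-point reference orbit, yielding the
≈1:2 and ≈5:10:1 class balances), and exactly `round(0.076·n)` days blanked
per user. Chaotic maps were chosen over surrogate shuffles because they have
analytic exponents, enabling recovery tests (logistic ln 2, Hénon vs a
Jacobian-QR oracle).

What the benchmark does **not** emulate: real EMA sequences have slower
divergence (horizons of ~2–3 weeks), autocorrelated missingness, and
between-user heterogeneity. In particular, r=4 logistic dynamics have a
~1–2-day horizon, so over a 19-day recursive forecast most days are beyond
predictability and the best achievable pooled accuracy approaches the
class-marginal ceiling (~66% for the 2-label scheme). The learned
forecasters converge to near-marginal behaviour there — which is
near-optimal under these dynamics — while the analog predictor keeps
tracking (and mis-tracking) the dynamics and lands below that ceiling.
Passing the direction-of-effect check (DL+Chaos ≥ Chaos) on this benchmark
therefore shows correct mechanics and ordering, not the absolute accuracy
levels reachable on slower real-world stress dynamics.

Problem sizes used by the tests and the acceptance script (5000-point map
orbits, 2000-point embedding scans, 50-user benchmarks, ≤200 training
epochs) were chosen to make every estimate stable at desk scale.

## Known limitations

* The first-local-minimum delay rule is estimator-noise sensitive on short
  discrete series; the consensus (median-over-users) profile mitigates this.
* `E(d)`/`EV(d)` on 35-point discrete sequences rests on very few distinct
  neighbor pairs; the EV tolerance ε=0.05 is a convention, not a theorem.
* The horizon rule `m = ⌊1/l_max⌋` treats one e-folding of initial error as
  the usability limit; other multiples are defensible and change `m`
  proportionally.
* Ordinal structure of the classes is ignored by the cross-entropy head
  (classes are treated as categorical).
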