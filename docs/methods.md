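# Methods

## Task and data model

`affectcast` forecasts one-step-ahead *changes* in per-user affect scores
derived from text. Scores are computed per message as the fraction of
tokens carrying each emotion category in a word–emotion lexicon (a word
carrying several categories counts once per category), averaged over the
messages of an ordinal time bin (weekly: 7-day blocks from the user's
first message; daily: single days). Differencing neighboring bins
detrends each user's series — the change series is treated as (weakly)
stationary, which the raw level series typically is not. A series over
`n` bins yields `n−1` change steps, indexed 1-based; 20 weekly bins give
19 change points.

Assumptions inherited by every model in the ladder:

* the affect score at a time is a deterministic function of the language
  at that time (self-supervision: targets are scores of future text);
* one user-bin is one observation; users are exchangeable; all learning
  pools across users;
* predictability lives in the recent history of changes (order `p`
  lags), possibly helped by language covariates.

### Missingness conventions (daily resolution)

A change is observed only when both endpoint bins are observed. Masked
changes are stored as 0 ("no change") so models without missing-data
machinery can consume them; decay-aware models receive the mask and
ignore the filled value. The per-dimension time-gap vector `delta`
follows the time-since-last-observation recursion: 1 after an observed
step, previous delta + 1 across a missing run, 1 at the first step.
Unobserved changes are never used as training or evaluation targets.
The zero-rule baselines predict 0 when their whole history window is
masked — the same no-change reading.

## Splits

Per fold: training users contribute change steps 1–14 as training
targets; steps 15–19 of the same users form the OOS-Time test set; steps
15–19 of held-out users form the OOS-User test set; a third disjoint
held-out group's steps 15–19 are the validation set used for tuning and
early stopping (their steps 1–14 are discarded). Users are shuffled once
by seed and the fold rotates the shuffled list by n/k, taking 70% train /
10% validation / 20% OOS-user blocks, so across k=5 folds every user is
held out at least once. Test-time forecasting is one-step-ahead with
*observed* rolling history (never the model's own fed-back predictions);
test histories may reach back into the training weeks, which leaks no
targets.

The source convention for the train/test boundary contains an off-by-one
(a 19-step series "split into 14 training and 4 test steps" vs. "steps
15–19" as test); this package fixes training targets = 1–14 and test
targets = 15–19. One consequence: a fixed order-14 window has no
in-range training target, so order-14 trainable models are run with
dynamic order (below) or a smaller `p`.

## Example generation

`build_examples` takes a contiguous span of change indices covering both
histories and targets. Fixed mode slides a length-`p` window: one
example per in-span target with a full in-span history. Dynamic mode
anchors at the span start and emits one example per history length from
`min_order` to the span maximum (steps 1..3 → 4, 1..4 → 5, …, 1..14 →
15: twelve examples at `min_order` 3). Counts are property-tested
against a brute-force enumerator; increasing fixed `p` by one removes
exactly one example per user. For GRU-D under dynamic order, shorter
histories are left-padded to the maximum length with mask-0 cells
(`delta` counting up through the pad) so the input decay imputes them
toward the training mean.

## Models

* **last(1)** / **mean(14)**: repeat the most recent observed change;
  mean of observed changes over a 14-step window. No parameters.
* **AR-Ridge / SVR / GBR**: scikit-learn regressors on flattened,
  z-scored lag vectors (masked cells zero after standardization).
  Regularization strength (ridge alpha ∈ {0.01…100}, SVR C ∈ {0.01…10})
  is chosen on validation examples by Pearson r; GBR runs with library
  defaults and a fixed seed. These are comparators, not the
  contribution.
* **DAN**: two dense layers with a sigmoid between, on the per-dimension
  mean of observed history changes — deliberately the same information
  as mean(14). Hidden width 2 (univariate) or 35 (multivariate).
* **GRU with attention**: update
  `z = σ(xWz + hUz + bz)`, `r = σ(xWr + hUr + br)`,
  `n = tanh(xWn + r·(hUn) + bn)`, `h' = z·h + (1−z)·n`, unrolled over
  the lag window from a learned shared initial hidden state. Attention
  scores each step's tanh-squashed hidden state to a scalar
  (`W ∈ R^H, B ∈ R`), softmaxes over time, and pools the raw hidden
  states; a single affine head maps the pooled vector to the predicted
  change.
* **GRU-DS / GRU-D**: decay `gamma = exp(−max(0, W delta + b))`.
  DS applies `h ← gamma_h ⊙ h` before each update (hidden decay only);
  GRU-D additionally replaces unobserved inputs by
  `gamma_x·x_last + (1−gamma_x)·x_mean` with `x_last` the last observed
  value and `x_mean` the training mean. Input decay is per input
  dimension (elementwise weights); hidden decay maps the gap vector to
  hidden size. The two decays use separate parameters, and dual-sequence
  branches do not share them. On complete weekly data `delta ≡ 1`, so
  GRU-DS learns a constant per-step retention factor — retained because
  it remains a distinct, useful inductive bias there.
* **Dual-sequence**: one branch consumes only past target changes (pure
  autoregression), the other only covariates; separate attention and
  heads; the final prediction is `w·ŷ1 + (1−w)·ŷ2` with a single learned
  scalar `w` initialized at 0.6.

### Numerical choices

* Weights uniform ±1/√H; reset-gate biases −1 (favoring retention);
  `h0 = 0`. Decay parameters initialize uniform in (0.01, 0.1), i.e.
  gamma ≈ 0.9 at unit gaps: `max(0, ·)` has a dead gradient at exactly
  zero, so a zero start could never learn to decay, while a small
  positive start stays close to the plain-GRU limit and is trainable.
  The zero-decay limit (gamma = 1 exactly) is a tested identity with the
  plain GRU.
* Loss: mean squared error on the standardized one-step-ahead change.
  Optimizer: Adam, default learning rate 0.01, batch 32 (64 in the
  larger benchmarks), at most 200 epochs. Model selection: early
  stopping on validation Pearson r (the task metric), patience 15,
  restoring the best-epoch parameters; a non-finite loss aborts and
  restores the last finite-loss parameters. Runs are deterministic given
  the spec seed.
* Features and targets are z-scored per dimension with training-fold
  statistics only; predictions are mapped back before evaluation.
  Pearson r is invariant to this affine map, so reported correlations do
  not depend on the scaling.
* The recurrent stack runs on a small reverse-mode autodiff engine over
  numpy float64 (`affectcast._autodiff`), verified against central
  finite differences in the test suite; examples are batched by unrolled
  length for vectorized steps.
* Attention implements per-step scalar scores (the score-shape choice is
  otherwise open); softmax uses a detached max shift.
* NMF covariate reduction: embeddings may be negative, so each column is
  shifted by its minimum over the fitting subset (stored in the reducer;
  residual negatives on unseen rows are clipped), then scikit-learn NMF
  with `nndsvda` initialization, fitted once on an evenly strided row
  subset and applied everywhere.

## Evaluation

Pearson r is pooled over all (user, step) prediction pairs of a split;
multi-fold summaries report the mean over folds with per-fold values
retained. Model pairs are compared with a two-sided paired t-test on
per-prediction squared errors over identical (user, step) keys;
identical error vectors return p = 1.0 (a zero mean difference carries
no evidence). Seasonal robustness groups squared errors by calendar
month across years with standard errors and user counts; the order sweep
retrains one model per (p, order mode) and reports OOS-Time r. No
multiple-comparison correction is applied across the model grid.

## Synthetic data

The generator produces the statistical structure the task assumes, at
desk scale, so every stage is testable without any external corpus.

* **Series**: per user, per affect dimension, a stationary AR process on
  the *changes* (coefficients checked via the companion matrix; burn-in
  discarded). Covariates are a loading matrix times the latent changes
  plus independent noise. Daily mode drops raw bins independently at a
  configured rate and derives masks and gap vectors exactly as the real
  differencing does. Calendar labels come from per-user start weeks
  spread over a five-year window. Identical seeds give identical bytes.
* **Corpus**: weekly latent affect rendered as token streams. Affect
  dimension *i* drives lexicon category *i*: a token belongs to that
  category with probability `clip(base + g·z, 0.02, cap)` where `z` is
  the user's mean-centered latent level over a *cohort-median* scale and
  `g = 0.2` is the largest slope that keeps a ±2.25 sd excursion inside
  the feasible frequency band. Two deliberate design choices keep the
  measurement channel faithful enough for recovery analyses:
  per-message category token counts are *stochastically rounded* rather
  than binomially drawn (same expectation, sub-binomial dispersion —
  binomial noise at tweet-scale token counts acts as errors-in-variables
  after differencing and attenuates AR estimates by ~0.2), and the
  level→rate scale is shared across the cohort (a per-user realized
  scale down-weights exactly the users with strongly autocorrelated
  realizations and biases pooled estimates low). Message volume defaults
  to 3 + Poisson(19) messages per user-week of 8 + Poisson(7) tokens,
  matching the order of magnitude of large public Twitter cohorts
  (~20 messages per user-week over 20 weeks).
* **What it does not emulate**: real language (fillers are synthetic
  words), user-behavioral missingness (drops are independent per day;
  real silence is bursty and state-dependent), topic drift, lexicon
  polysemy in context, or covariates with their own dynamics. Passing
  tests therefore certify the machinery — scoring, differencing,
  masking, training, evaluation — not performance claims about any real
  population.

## Problem sizes

The benchmarks are sized for quick, repeatable runs on one CPU: 200
users for the weekly model-ladder comparison (AR(2) signal, one fold),
120 users at 140 daily bins with 30% missingness for the daily
benchmark, ~5,000 pooled examples for coefficient-recovery checks, and
60 users for the corpus-to-coefficient pipeline. At these sizes the
model-ordering comparisons (recurrent ≥ ridge ≥ mean) hold up to
paired-t noise; larger cohorts tighten them.

## Known limitations

* The attention layer attends over padded (masked) steps in GRU-D's
  fixed-shape dynamic batches; the decay imputation makes those steps
  near-neutral but they are not excluded from pooling.
* Hidden-size and learning-rate defaults (32, 0.01) are serviceable
  rather than tuned; sweeps belong in configs.
* `delta` is bin-valued (integer gaps), not wall-clock time.
* The paired t-test on squared errors is the only significance
  machinery; it ignores within-user error correlation.
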