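# Methods

`fedtab` simulates a cross-institution federated learning study for binary
breast-tumour diagnosis on cytology tables: each simulated clinic trains a
neural classifier on its own shard of the data, and a coordinating server
combines the clients into a single global classifier without pooling raw
records. This note documents the statistical procedure, the default
parameters and why they hold their values, the numerical choices, and what
the synthetic data does and does not establish.

## Data model

The working currency is a labelled feature table: opaque record IDs, an
`n × d` real matrix (d = 30 for the Wisconsin Diagnostic cytology features:
ten nucleus morphology measurements × mean / standard-error / worst), and a
binary diagnosis label, fixed as benign = 0 and malignant = 1. The label
orientation is deliberately not configurable so that sensitivity and
specificity are unambiguous everywhere downstream: *positive always means
malignant*.

`load_wdbc()` returns the bundled 569-record Wisconsin Diagnostic table
(357 benign / 212 malignant), sourced from scikit-learn's packaged copy of
the UCI data and relabelled to this convention. The UCI headerless
`wdbc.data` dialect and a headed-CSV dialect are both supported for external
files.

## Preprocessing

Stages run in a fixed order on the full table: outlier removal → noise
augmentation → SMOTE.

**Outlier removal.** Per-feature Tukey fences `[Q1 − k·IQR, Q3 + k·IQR]`
with multiplier k = 1.5; quartiles use linear interpolation between order
statistics (the numpy/pandas default), making every fence reproducible to
the digit. A record is removed when it breaches the fences of at least
`min_violations` features. The textbook any-feature rule
(`min_violations = 1`) removes 171 of the 569 records — on 30 correlated,
heavy-tailed morphology features nearly every malignant case is extreme in
*something* — which would gut the malignant class. The reference
configuration for this dataset therefore sets `min_violations = 6`, which
retains 536 records, and the violation count is exposed as an explicit
policy knob rather than hidden inside the stage.

**Noise augmentation.** Each class is grown to an explicit per-class target
(defaults 3212 benign / 2530 malignant, i.e. 5742 records from the cleaned
table) by appending copies of randomly chosen originals with elementwise
`Uniform(noise_low, noise_high)` noise added on the raw feature scale.
Originals are never modified and copies inherit their source's label. The
default interval is symmetric, `[−0.01, 0.01]`: post-augmentation summary
minima of several nonnegative features (e.g. `smoothness_se`) drop slightly
below zero, which only subtractive noise can produce; the one-sided
`[0, 0.01]` variant is available through configuration.

**SMOTE.** The minority class is grown to parity using the canonical rule:
synthetic point = `x + u·(nn − x)` with `u ~ Uniform(0,1)` and `nn` one of
the k = 5 nearest minority neighbours (Euclidean distance, via
scikit-learn's `NearestNeighbors`). 3212/2530 in, 3212/3212 (6424 records)
out. Synthetic points therefore lie on segments between minority records —
inside the minority convex hull — which the tests verify geometrically.

## Feature selection

An L1-penalised logistic model is fit to the preprocessed table:

    J(θ, b) = −(1/m) Σᵢ [ yᵢ log h(θᵀxᵢ + b) + (1 − yᵢ) log(1 − h(θᵀxᵢ + b)) ]
              + λ‖θ‖₁

with `h` the sigmoid. The intercept is unpenalised (standard lasso-logistic
practice). Features are z-scored from the data being fit — raw scales span
four orders of magnitude (`area_worst` vs `fractal_dimension_se`) — and
weights are reported on the standardised scale. Features with
`|θⱼ| > zero_tol` (default 1e-8) survive; the table is then projected onto
the surviving columns.

**Solver.** Proximal gradient descent (ISTA): gradient step on the smooth
term, soft-threshold of θ, with backtracking line search so the objective
never increases. Convergence is declared when the proximal-gradient
residual — the step-normalised change of the iterate, which at λ = 0
reduces to the plain gradient — has sup-norm below `tol` (default 1e-6).
Non-convergence at `max_iter` flags the result rather than raising.

**Choosing λ.** No regularisation strength is prescribed, so the default is
data-driven: an 80:20 validation split, a 15-point logarithmic grid
(1e-4 … 10^-0.5), and the **one-standard-error rule** — the largest
(sparsest) λ whose validation negative log-likelihood is within one standard
error of the minimum. Plain loss minimisation on this augmented dataset
always picks the weakest penalty and keeps all 30 features; the 1-SE rule is
the standard parsimony correction and typically keeps 15–25 features here,
seed-depending.

## Local model

A dense feed-forward network: input layer sized to the selected features,
three ReLU hidden layers (64, 32, 16), one ReLU fully-connected layer (8),
and a 2-unit output head. The head uses softmax by default: the training
loss is sparse categorical cross-entropy on integer labels, which pairs with
a normalised 2-unit output, not independent per-unit sigmoids. A per-unit
sigmoid head (row-normalised into probabilities) is available as a
configuration switch. Hidden widths, the learning rate and the
initialisation are not externally prescribed; the defaults are the canonical
choices (He fan-in initialisation, Adam at 1e-3 with moment decays
0.9/0.999, batch size 32, up to 70 epochs).

Each model stores z-scoring statistics of its own training split and applies
them inside `predict_proba` — effectively a frozen first layer. This keeps
scaling out of the preprocessing contract, travels with the model archive,
and gives weight averaging something coherent to average (the statistics are
averaged along with the weights; shards are IID so they are close).

**Early stopping** monitors validation loss with patience 10 (training halts
after 10 consecutive epochs without improvement) and restores the weights of
the best validation epoch — restoration is this package's stability choice.
Models serialise to versioned JSON archives (spec, weights, scaling
statistics), one file per client.

## Federation

Per round: the table is sharded IID across `n_clients` (seeded shuffle,
contiguous near-equal blocks), each client makes its own seeded 70:15:15
train/validation/test split and trains locally; the server then aggregates.
Global metrics are computed on the union of client *test* splits, which is
disjoint from all client training data by construction (asserted by record
IDs).

Two aggregation rules are provided because they answer different design
philosophies, and the choice is surfaced rather than silently resolved:

* `prediction_sum` (default): per record, sum the clients' probability rows
  and take the argmax — soft voting. Exact probability ties resolve to
  benign (the conservative label; a tie is no evidence of malignancy).
  Clients retrain fresh each round, so rounds are independent replicates.
* `weight_average`: FedAvg — every parameter array of the global model is
  the equal-weighted mean of the client arrays (equal weighting because
  shards differ in size by at most one record). In subsequent rounds clients
  warm-start from the global model. An optional server-side fine-tune of the
  average on the pooled training data is off by default, since pooling
  training data weakens the privacy story that motivates federation.

**Leakage.** By default, augmentation and SMOTE run once on the full table
*before* sharding and splitting. Noisy copies of a source record can then
land in one client's training split while the source (or another copy) lands
in a test split, so global test metrics are optimistic — they measure the
protocol, not generalisation to unseen patients. This is deliberate: the
default reproduces the common augment-then-split protocol this pipeline
models. `leak_safe=True` instead applies augmentation and SMOTE to each
client's training split only (targets rescaled proportionally to shard class
counts), leaving validation and test data untouched; expect visibly lower,
more honest test metrics in that mode.

## Metrics

Confusion counts with malignant positive, and the derived rates: accuracy,
precision, recall/sensitivity (TPR), F1 (harmonic mean of precision and
recall), FPR, specificity (TNR), FNR. Zero-denominator ratios are reported
as NaN ("undefined"), never silently 0 — a model that predicts no positives
has *undefined* precision, not perfect or zero precision. The identities
`TPR + FNR = 1` and `TNR + FPR = 1` hold exactly whenever defined, as does
the prevalence-weighted decomposition of accuracy; all are enforced by
property tests. Percentages render at two decimals with round-half-even.

## Synthetic data generator

`generate()` draws each feature from a truncated normal on the profiled
`[min, max]` with the profiled standard deviation, per class. Truncation
biases a naive truncated normal's mean, so the generator solves (Brent root
finding) for the location parameter that makes the *post-truncation* mean
hit the configured target exactly; targets are clamped 2% of the range away
from the bounds to keep the root bracketed. Profiled features with zero
printed standard deviation degenerate to constants. The malignant class
targets `mean + separation·std` per informative feature (default: all
features, separation 1.0 — on the order of the class separation real
morphology features show, where a linear classifier reaches the mid-90s).

Only marginals are emulated. The packaged profile publishes per-feature
summaries, not a covariance, and the pipeline's correctness tests need
marginal realism plus controllable separability — not the real cytology
correlation structure. Consequences worth keeping in mind: synthetic
features are conditionally independent given the class, which makes the
class separation *easier* to exploit than in correlated real data, and
L1 selection on synthetic data faces no collinearity. Passing tests on
synthetic data therefore establish pipeline correctness and recovery under
known ground truth, not clinical performance.

`generate_toy()` produces plain two-Gaussian blobs (centroids `separation`
standard deviations apart) for unit tests.

## Problem sizes and determinism

The bundled study runs at its natural scale (569 → 536 → 5742 → 6424
records, 2 clients, 3 rounds); unit and property tests use tables of
50–2000 records. A single master seed fans out to stage seeds by fixed
offsets, so any stage can be rerun in isolation; fixed seeds give
bit-identical training histories and round metrics on the same platform.

## Known limitations

* The default protocol's global test metrics are inflated by design (see
  Leakage above); use `leak_safe` for honest generalisation estimates.
* IID sharding only; no client sampling, stragglers, secure aggregation or
  differential privacy.
* The outlier stage's `min_violations = 6` is a calibration to this
  dataset's cleaning profile, not a universal rule; other tables should
  revisit it.
* `weight_average` averages nonlinear networks trained from different
  initialisations; without warm-starting it can average to a poor model in
  round 1 — warm starts across rounds mitigate this.
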