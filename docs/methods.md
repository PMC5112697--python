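# Methods

## Problem setting

The package targets binary screening from subject-structured tabular
features, modelled on dysphonia-based Parkinson's-disease classification:
each subject (healthy control or patient) contributes many short speech
recordings, each summarised as a fixed-length acoustic feature vector
(26 dimensions in the reference corpus — sustained vowels, numbers, words
and short sentences).  Two properties of such data drive the design:

1. **Uneven sample quality.** Not every recording of a patient carries the
   dysphonic signature; some samples of either class fall inside the other
   class's feature region and mislead a classifier trained on them.
2. **Within-subject correlation.** All samples of one subject share a
   subject effect, so evaluation that lets same-subject samples appear in
   both training and test folds is optimistically biased.

The method is a two-stage composite: instance selection by multi-edit
nearest-neighbor (MENN) on the training samples, followed by an ensemble
classifier — either the closed-form decorrelated RVFL ensemble (DNNE) or a
standard backend (random forest, SVM, k-NN) — trained on the retained
samples.  A subject decision is the majority vote over that subject's
per-sample predictions.

## Multi-edit nearest-neighbor editing

Given N training samples, one editing round:

1. randomly partitions the samples into s disjoint subsets X_1..X_s of
   near-equal size (s = 4 by default, with the classical constraint s > 3
   enforced unless explicitly relaxed);
2. classifies each subset X_i with a k-NN (k = 1 by default) trained on
   the *next* subset X_{i+1}, circularly (X_1 trains the pass over X_s);
3. deletes every misclassified sample.

Rounds repeat — with a *fresh* random partition each time, the partition
seed advancing by the iteration index — until a full round deletes nothing
(converged), an iteration cap is hit (default 20), or the viability guard
fires: a round whose deletions would leave a class empty is withheld, the
trace flagged, and the run returns unconverged.  The guard matters on
heavily overlapped data, where the literal stopping rule ("repeat until no
misclassifications") can annihilate a class.

Editing distances are Euclidean on z-scored features (acoustic features
span orders of magnitude).  Determinism is total: distance ties resolve to
the lowest training index (stable argsort), vote ties for even k resolve
toward the patient class, and the whole trace is a function of
(data, s, k, seed, max_iter).  The editing k-NN is implemented directly on
a distance matrix rather than through a library classifier precisely to
pin these tie rules.

The supporting theory is the asymptotic conditional error of the edited
nearest-neighbor rule at a point with class posteriors p_i.  With no
editing it is the classical 1 − Σ p_i²; after M edits the package evaluates

    P_M(e|x) = 1 − Σ_i p_i^(2^M + 1) / Σ_i p_i^(2^M),

which is monotone non-increasing in M and converges to the Bayes floor
min_i p_i.  A variant seen in print with numerator exponent 2^(M+1) is
exposed as `form="printed"` for reference; it contradicts the min-posterior
limit (the ratio collapses and the error tends to 1) and is not the
default.  Both coincide at M = 0.  Evaluation is done in a scaled form
(dividing through by p_max^(2^M)) because the raw powers underflow long
before M = 30.

## The decorrelated RVFL ensemble

The ensemble holds M single-hidden-layer networks with L sigmoid neurons
each.  Hidden weights w_mn ∈ R^d and biases b_mn are drawn once from
Uniform(−1, 1) — independently per (network, neuron) pair, which is what
makes cross-network decorrelation meaningful — and never trained.  With
hidden outputs g_mn(x) = sigmoid(w_mn·x + b_mn) collected into the
N × (M·L) matrix G (network-major column order), the joint output-weight
vector B_ens solves

    H_corr B_ens = T_h,
    H_corr[p, q] = C1·φ(p, q) if p, q index the same network, else C2·φ(p, q),
    φ(p, q) = Σ_n G[n, p]·G[n, q],      T_h[p] = Σ_n G[n, p]·y_n,

with flat-index decoding m = ⌈p/L⌉, n = ((p−1) mod L) + 1 and penalty
constants

    C2 = 2λ(M−1)/M²,    C1 = 1 − (M−1)·C2  (≡ 1 − 2λ(M−1)²/M²).

C1 is computed through the conservation identity C1 + (M−1)C2 = 1, which
is algebraically identical to its closed form and keeps the identity exact
in floating point.  λ ∈ [0, 1] trades individual fit against inter-network
correlation; λ = 0 block-diagonalizes H_corr, so the joint solve must equal
M independent per-network least-squares fits — an identity used as a
standing cross-check.  Note C1 < 0 is reachable (λ large, M moderate), so
H_corr need not be positive definite.

**Solver.** A direct dense solve is used while the condition estimate is
below 1e10; otherwise ridge jitter ε·mean(diag(H))·I is added with ε
escalating 1e−8 → 1e−2 in decades, each step recorded in a solver note,
with a pseudo-inverse least-squares solve as the final fallback.  On
well-conditioned systems the residual satisfies
‖H B − T‖∞ ≤ 1e−8·max(1, ‖T‖∞).

**Targets and prediction.** Labels {0 = healthy, 1 = patient} are used
directly as regression targets; the ensemble score of x is the mean of the
M base-network outputs, (1/M)·Σ_mn β_mn g_mn(x), thresholded at 0.5.
Features are z-scored with a scaler fitted on the training rows (sigmoid
saturation control).  No direct input–output links are included: the
normal system above contains hidden-neuron terms only, so the networks are
plain random-feature maps rather than full RVFL with skip connections.

An optional per-network subsampling mode (`bagging_fraction`) lets each
network's φ sums run over a random row subset (cross-network terms over
the intersection of the two networks' subsets); the default is the shared
closed form, since the joint system sums over a single training set.
Hyperparameter search (`dnne_grid_search`) is exhaustive over
M ∈ [2, 15], L ∈ [5, 50], λ ∈ {0, 0.1, …, 1}, scored by subject-grouped
5-fold inner CV, ties broken toward the smaller model.  A
`boosting_threshold` argument is accepted for config compatibility and
ignored with a warning — it has no referent in the closed-form fit.

## Pipeline and backends

`train_pipeline` optionally edits (MENN always operates on z-scored
features, even when a scale-invariant tree backend consumes raw ones),
optionally fits a z-score scaler on the retained set, then fits the
backend.  Backends other than DNNE are library classifiers behind a common
contract: random forest (500 trees, √d features per split, unpruned),
linear/RBF SVM, and k-NN.  A single pipeline seed fans out to component
seeds (MENN, backend, subsampling, per-fold) via `SeedSequence([seed,
counter])` reduced below 2^31, so end-to-end runs are exactly repeatable.

Subject decisions are majority votes over sample predictions.  With an
even per-subject sample count ties are possible; the default tie rule is
"patient" (favoring sensitivity in a screening context), with "healthy"
and mean-score alternatives.

## Evaluation protocols

* **LOO** — leave one *sample* out; same-subject samples remain in
  training.  The pipeline, including editing, is re-run inside every fold;
  editing never sees the held-out sample (no selection leakage).
* **LOSO** — the LOO per-sample predictions voted per subject.
* **Independent ("inDe")** — one fold per subject; a fold's training set
  excludes every sample of the predicted subject.  Reported at sample
  level or voted per subject.

The LOO-minus-independent accuracy difference measures within-subject
leakage.  Every CV result stores per-fold training indices, so coverage
(each sample predicted exactly once), fold exclusion, and the metric
identity accuracy·(P+N) = sensitivity·P + specificity·N are auditable
after the fact (`check_fold_hygiene`).

Metrics follow the standard confusion-matrix definitions with patient as
the positive class; zero-denominator ratios (e.g. specificity on an
all-patient test set) propagate as NaN and are excluded from
mean/std/best summaries with an explicit count, never coerced to 0.

Repeated runs use seeds base+1..base+n, re-randomizing both editing
partitions and backend randomness per run.  Between-algorithm comparison
is Welch's unequal-variance two-sided t-test per metric on run-level
values; two constant, equal run lists return p = 1 flagged as degenerate.

## Synthetic data generator

The generator emulates the reference corpus structure: 2 classes ×
20 subjects × 26 samples × 26 features by default.  Class c has subject
centers μ_u = c·δ·e1 + η_u with η_u ~ N(0, σ_subj² I); samples are
μ_u + ε, ε ~ N(0, σ_noise² I).  A per-subject fraction ρ of samples
(⌊ρ·m⌋ of m, so 3 of 26 at the default ρ = 0.15) is instead drawn from the
*opposite* class's marginal sample distribution — fresh subject offset
included — while keeping the subject's label.  These contaminated samples
model recordings that do not carry the subject's class signature, and they
are flagged so editing behaviour can be scored against ground truth.

Defaults: σ_subj = 1.0, σ_noise = 0.5, and δ = 1.5086 chosen so the
single-sample Bayes error of the uncontaminated mixture is 0.25
(δ = 2·z₀.₇₅·σ with σ² = σ_subj² + σ_noise²).  The closed-form achievable
error including contamination is (1−ρ_eff)·Φ(−δ/2σ) + ρ_eff·(1−Φ(−δ/2σ))
with ρ_eff = ⌊ρm⌋/m, used as the analytic anchor in tests.

What the generator does *not* emulate: real acoustic features are
non-Gaussian, heteroscedastic across features, and correlated; sample
kinds (vowel vs sentence) differ systematically; class separation is not
confined to one direction.  Passing tests therefore demonstrate the
algorithmic properties (editing removes the planted non-discriminative
population, protocols measure what they claim), not clinical performance.

## Problem sizes used in the checked experiments

The shipped experiments run at these sizes, chosen to make the measured
quantities stable while keeping a full run comfortably interactive:
closed-form checks on 50 random instances (N = 50, M = 3, L = 5);
editing-contraction on 2 × 400 one-dimensional Gaussian samples × 20
seeds with 2000-sample held-out sets; the contamination-benefit experiment
at the full corpus shape (1040 samples) × 10 paired seeds; the leakage
experiment at 100 subjects-smaller shape (20 subjects/class × 5 samples,
d = 5) × 10 seeds per condition, where the independent protocol excludes
only 2.5 % of training rows per fold so the zero-subject-effect control
isolates leakage rather than training-set shrinkage; significance-test
calibration over 200 null repetitions of 10-vs-10 runs.

## Known limitations and behaviour worth knowing

* Editing benefits neighborhood-based backends most: contaminated samples
  dominate 1-NN errors, and removing them demonstrably moves held-out 1-NN
  error toward the Bayes floor.  A random forest is already robust to
  label-style noise, and on small, strongly subject-confounded datasets
  editing can *reduce* its accuracy by discarding informative boundary
  samples; the comparison example shows such a case.  The composite is a
  method to evaluate per dataset, not a uniform improvement.
* The editing stopping rule is stochastic (fresh partitions); on
  overlapped data the retained set varies across seeds, which is why
  repeated-run summaries re-randomize it deliberately.
* DNNE with M·L approaching or exceeding N produces rank-deficient
  systems; the ridge/pseudo-inverse path handles them, but the fit is then
  regularized least-norm rather than the pure closed form, and the solver
  note says so.
* No probability calibration, multiclass support, ROC analysis, or
  feature selection/transformation stages are provided; inputs are
  precomputed feature vectors (no audio processing).
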