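# Methods

`t2dmeta` re-implements, as a tested library, a microarray-based pipeline
for detecting Type II diabetes mellitus: block-wise feature extraction from
per-patient gene-expression vectors, wrapper feature selection with two
nature-inspired meta-heuristics, and target-coded classification with seven
classifier families evaluated under stratified tenfold cross-validation.
This note records the model choices, the defaults and why, what the
synthetic data do and do not emulate, and the numerical conventions.

## Data model and preprocessing

The reference cohort shape is 22,960 genes for 70 pancreatic-islet donors
(20 diabetic, 50 non-diabetic). Preprocessing is: keep the
highest-peak-intensity record per duplicated gene id, log10-transform the
intensities, and standardize each gene to mean 0 / variance 1 across
patients (unbiased, n−1 denominator). Zero-variance genes cannot be
standardized and are dropped with a warning. The transform is idempotent:
the log step is skipped on data already flagged as log-scale.

Standardization is per gene **across patients** (row-wise). The alternative
(per patient across genes) would leave gene scales incomparable and make
the block statistics meaningless.

## Synthetic cohorts

`syndata.generate_dataset` draws log10 intensities i.i.d. Gaussian per gene
around a gene-specific baseline b_g ~ U(6, 12), with noise SD
`noise_sd` (default 1.0, a log10-intensity scale typical of microarray
dynamic range). A configurable subset of `n_informative` genes (default
200, a plausible disease-signature size) receives an additive class-mean
shift of `effect_size · noise_sd` (random sign per gene) in the diabetic
class. Values are exponentiated back to the linear scale, so the generator
feeds the same preprocessing path as real data.

What this emulates: the dimensions, class imbalance, log-normal intensity
scale, and a sparse differential-expression signal with known ground truth.
What it does not emulate: gene–gene correlation structure, batch effects,
probe-level artifacts, or any real islet biology. Passing tests therefore
demonstrate that the pipeline recovers a planted signal of the stated
strength under idealized noise — not that it reproduces the published
accuracies on the proprietary cohort, which would require the original
data.

## Feature extraction (22,960 → 2,870)

All three extractors share one layout: the standardized gene vector is cut
into 2,870 consecutive non-overlapping blocks of 8 (the only partition
consistent with the published dimensions), and each block yields one
scalar:

- **STFT** — the block's discrete Fourier magnitude at one frequency bin.
  The windowed transform X(m, ω) = Σ_n x_n w(n−m) e^{−iωn} is implemented
  with an absolute-sample phase reference; the default kept coefficient is
  the largest-magnitude non-DC bin ("dominant frequency"), configurable to
  any bin. The window taper is rectangular by default (none was specified
  for the original analysis).
- **Ridge regression** — the ridge slope of the block on a fixed design
  (intercept + standardized linear index), i.e. the local estimator
  β̂_i = (XᵢᵀXᵢ + nᵢλᵢI)⁻¹XᵢᵀYᵢ with λ default 0.1. The weighted one-shot
  distributed combination β̂ = Σ ωᵢβ̂ᵢ is exposed with uniform weights; the
  SNR-based weighting mentioned for the original analysis is underspecified
  and not implemented.
- **Pearson correlation** — the correlation of the block with a per-block
  template. The template is the mean block over the **non-diabetic
  training patients** (a healthy reference profile), computed inside each
  training fold only. The across-everyone mean was considered and
  rejected: after per-gene standardization every row has mean 0, so the
  pooled mean template is numerically ~0 and carries no signal (measured
  class separation ~0.33 vs ~1.16 correlation units on planted-signal
  cohorts).

Descriptive statistics for extracted features: moments (unbiased variance,
standardized 3rd/4th moments with excess kurtosis), Shannon entropy in bits
over a 16-bin histogram, sample entropy with embedding m = 2 and tolerance
r = 0.2·SD, Higuchi fractal dimension with kmax = 8, and the first
canonical correlation (generalized-eigenvalue form with ridge 1e−6 on the
covariance blocks). Entropy/FD defaults are standard literature values; all
are configurable. A constant series reports zero entropies and FD 1 (the
smooth-curve limit).

## Feature selection (2,870 → 287)

Both optimizers are bounded continuous minimizers on [0, 1]^d with greedy
(improvement-only) acceptance of every move and elitist best tracking, so
best-fitness traces are non-increasing by construction. A position is
decoded as the subset of its k largest coordinates (ties to the lowest
index); k is fixed (287 at full scale) because the published output
dimension is fixed — threshold rules cannot guarantee an exact subset size.

**Bald Eagle Search (BESO)** iterates three stages: select
(P_new = P_best + a·r·(P_mean − P_i), a = 2.0 in [1.5, 2]), spiral search
(θ = a_polar·π·rand with a_polar = 7.5 in (5, 10), r = θ + R + rand with
R = 1.5 in [0.5, 2], sin/cos coordinates normalized by the population
maxima), and a swoop with hyperbolic coordinates (r = θ; C1, C2 ~ U(1, 2)).
The search-stage radius uses the additive R form and the swoop stage uses
r = θ, exactly as the two stages are defined.

**Red Deer (RDO)** keeps a herd of 100 (15 males) by default and iterates
roaring (a random fraction 0.25 of males step by ±a₁((UB−LB)a₂ + LB);
improvers become commanders), commander–stag fights (midpoint ± random
step; the best contender leads, the runner-up takes the stag slot), harem
formation proportional to commander power (round-half-up with residual
repair so hind counts are conserved), and three mating modes (fraction
α = 0.85 of the own harem, β = 0.4 of one random other harem, and stag ×
nearest hind), with the offspring pool capped at 0.77·population. The next
generation keeps the elite males and fills up by roulette wheel on inverse
cost. γ = 0.7 is carried in the parameter set but unused — its role is
not defined in the source description. The 10 s wall-clock stop is off by
default so seeded runs are exactly reproducible.

**Wrapper fitness.** Cost = mean stratified 5-fold nearest-centroid
misclassification error + 0.01·k/d + 1e−3·(soft margin loss). The third
term is the mean of (1 + m)/2 with the relative margin
m = (d²_true − d²_other)/(d²_true + d²_other) ∈ [−1, 1]. It is bounded by
its weight (1e−3), far below the cost of a single misclassification
(≈1.4e−2 at n = 70), and exists because the hard error saturates at zero
on separable cohorts: without it, every candidate subset on the zero-error
plateau ties, greedy acceptance rejects all moves, and selection freezes at
whatever the initial population contained. `select_features` also supports
multi-start (`restarts`), the standard remedy for this flat, multimodal
landscape; the bundled recovery study uses three seeded restarts.

## Classifiers and target coding

Classifiers regress onto fixed class targets — 0.1 (non-diabetic) and 0.85
(diabetic), separation 0.75 ≥ 0.5 — and emit one continuous output per
patient; a patient is called diabetic when the output is at or above the
midpoint 0.475 (ties diabetic; the decision rule on continuous outputs was
left open and the midpoint is the natural choice for symmetric targets).
Class-conditional models (GMM, EM, SDC) are mapped to the same scale
through their diabetic posterior. Mean squared error against the coded
targets is the common training criterion.

- **NLR**: y = θ₁ + θ₂/(1 + e^{−(w·a + θ₃)}) with the fixed uniform
  projection weight w_j = 0.4, fit by iterative least squares. The
  expectation function is the simplest curve meeting the nonlinearity
  requirement with the stated uniform weight.
- **LR**: ordinary least squares on coded targets (ridge 1e−8 fallback).
- **GMM / EM**: one mixture per class, diagonal covariances (necessary for
  d ≫ n), classified by class-conditional likelihood with empirical
  priors. GMM uses a single component (closed form in one EM step); EM
  uses two components fit by expectation–maximization with a 1e−6 variance
  floor. Log-likelihood is non-decreasing per iteration up to that floor.
- **LoR**: ridge-penalized logistic regression, penalty ‖υ‖²/(2τ²) with
  τ = 1 (intercept unpenalized), L-BFGS on the analytic gradient.
- **SDC**: score_i(v) = log Σ_j exp(−λ‖v − υ_ji‖²) with λ = Γ = 0.5;
  class = argmax. As λ → 0 the scores tend to log class sizes.
- **SVM-RBF**: soft margin with kernel exp(−‖xi − xj‖²/(2σ)²)
  (equivalently gamma = 1/(2σ)²); defaults C = 1, gamma = 100, diabetic
  class weight 0.86, following the reference parameterization. On the
  scaled-down synthetic runs (correlation-scale features, d ≈ 10–25) a
  fixed gamma = 100 shrinks every off-diagonal kernel entry to ~0 and the
  classifier degenerates to the majority class, so the bundled small
  configuration uses the variance-adaptive "scale" convention
  (1/(d·Var X)); kernel width must track feature scale.

## Evaluation

Stratified tenfold cross-validation (seeded); with 20/50 classes every test
fold holds exactly 2 diabetic and 5 non-diabetic patients. Test-fold
confusion matrices are **pooled** (summed) into one 70-patient matrix —
the convention under which the reported reference rows are mutually
consistent — and six metrics are computed: accuracy, F1, MCC, Jaccard
(TP/(TP+FP+FN)), error rate (exactly 1 − accuracy) and Cohen's kappa.
MCC and kappa return 0 with a warning when their denominators vanish.
Training MSE is averaged over folds; test MSE is reported both pooled and
as the per-fold mean (the original convention is unstated).

Feature selection and PCC templates are re-fit inside each training fold to
prevent leakage; a `pooled_selection` switch instead selects once on all data,
mimicking the likely original protocol.

`evalkit.recover_confusion` enumerates all integer confusion matrices with
the given class sizes and returns the unique one matching a printed
accuracy/F1 pair — the device used to verify metric-suite agreement with
the reference rows without access to the original data.

## Problem sizes in the bundled studies

The acceptance studies run at reduced scale, chosen so a full pass stays
comfortable on one CPU: optimizer benchmarks in 5-D (20 paired replicates
against budget-matched random search, one-sided sign test); selection
recovery with 20 informative among 200 dimensions, effect 2 SD, 35 + 35
patients, k = 40, three restarts; and a 200-gene, 70-patient end-to-end
grid (25 extracted features, 10 selected) covering all 63 FE × FS ×
classifier cells. The full 22,960-gene configuration runs through the same
code paths and is the library default.

## Known limitations

- The synthetic generator's independence assumption makes selection easier
  than on correlated real expression data; recovery rates here are upper
  bounds on what the same budget would achieve on real cohorts.
- The published accuracies for the original islet cohort are not
  reproducible without that data; the package verifies the metric algebra
  of those results, not the results themselves.
- RDO's roar/fight/mating rates are interpreted as per-generation fractions
  (of males roaring, of stags fought per commander, and of the offspring
  cap); other readings are possible since the source description is loose.
- Sample entropy is O(n²) and intended for feature-length series, not raw
  gene vectors.
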