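# Methods

`diabsgan` implements an end-to-end classification pipeline for tabular
clinical diabetes data in the PIMA schema (Pregnancies, Glucose,
BloodPressure, SkinThickness, Insulin, BMI, DiabetesPedigreeFunction, Age,
binary Outcome). This note records the models, the assumptions behind them,
the parameters that matter, and the design choices made where the design was
genuinely open.

## Zero-as-missing imputation

In the PIMA convention a zero in Glucose, BloodPressure, SkinThickness,
Insulin or BMI is physiologically impossible and encodes a missing
measurement. `detect_missing` flags those cells in a boolean mask (the raw
value is kept; nothing is overwritten at detection time). Pregnancies is
deliberately excluded: zero pregnancies is a legitimate value, so its zeros
are counted but retained.

Filling uses a per-feature **mean/median joint rule** driven by the shape of
the observed distribution: compute the adjusted Fisher–Pearson sample
skewness of the non-missing values and fill with the **mean** when
|skewness| ≤ `skew_threshold` (default 0.5), otherwise with the **median**.
The rationale is distributional: for a roughly symmetric feature the mean
preserves the centre, while for a skewed feature (Insulin is the canonical
case) the median avoids dragging the fill value into the tail, keeping the
post-imputation distribution closer to normal. The threshold 0.5 is the
conventional boundary between "fairly symmetric" and "moderately skewed"
sample skewness; it is a config knob, and the fitted plan records the
observed skewness per feature so the decision is auditable. Fill values are
computed from observed values only, so imputation is idempotent by
construction.

## Outlier capping

Per feature we compute the quartiles Q1, Q2, Q3 with **linear interpolation
between order statistics** (position (n−1)·p, NumPy's default). The choice
of quantile convention is recorded explicitly because the fence values
depend on it. With IQR = Q3 − Q1, values are clamped into the Tukey fences

    upper = Q3 + 1.5·IQR,    lower = Q1 − 1.5·IQR.

Capping (winsorization) keeps every row; `remove_outliers` implements
outright deletion as a non-default alternative for protocol comparison. Q2
is stored for reporting although the clamp does not use it. Inside
cross-validation, fences are fitted on the training fold only and applied
to the held-out fold, avoiding test-information leakage.

## Glucose relabeling

The binary outcome can be replaced by a three-class label from fasting
plasma glucose: ≤ 99 mg/dL normal (code 0), 100–125 prediabetes (code 1),
≥ 126 diabetes (code 2). Both boundaries are inclusive on the stated side
(99 → normal, 125 → prediabetes, 126 → diabetes). Relabeling reads only the
Glucose column and is intended to run after imputation, since a zero-coded
missing glucose would otherwise land in the "normal" class.

## SMOTE + ENN rebalancing

SMOTE generates minority samples by interpolation: for minority point x_i,
draw one of its `k_smote` (default 5) nearest minority neighbours x_nn and
emit x_i + u·(x_nn − x_i) with u ~ U[0,1]. Every non-majority class is
oversampled toward `target_ratio` (default 1.0) times the majority count;
originals are preserved verbatim. ENN then deletes any sample — of any
class, original or synthetic — whose label loses the majority vote of its
`k_enn` (default 3) nearest neighbours, with ties broken toward keeping the
sample (conservative deletion).

Distances for both steps are Euclidean on **internally standardized**
features (zero mean, unit variance, fit on the input), with synthetics
mapped back to the original scale. PIMA-like features span two orders of
magnitude (Insulin vs. DiabetesPedigreeFunction) and unscaled distances
would be dominated by the widest column. Standardization is affine, so the
convex-combination property of SMOTE outputs holds in either scale.

Resampling placement is a protocol choice with real consequences: the
default applies SMOTE+ENN **inside training folds only**; a
`resample_before_split` flag resamples the whole dataset before the CV
split. The latter leaks synthetic neighbours of test points into training
and inflates metrics, and is provided only so the two protocols can be
compared; no claim is made about which protocol external results use.

## The semi-supervised GAN classifier

The classifier couples a GAN with an auxiliary classification head. A
generator G maps latent noise z (dimension 64 by default) to a feature
vector; a discriminator with a shared trunk carries two heads, a sigmoid
adversarial head D(x) ∈ (0,1) and a softmax classification head C(x). The
contested value function is

    V(D, G, C) = E[log D(x)] + E[log(1 − D(G(z)))] + λ·L_C(C(x), y),

with L_C the mean categorical cross-entropy −1/N Σ Σ y log p and λ
(`lambda_c`, default 1.0) weighting the supervised term. The classifier is
trained on **real labeled samples only**; generated samples influence C
only through the shared trunk. The shared-trunk-two-heads realization was
chosen over a single (K+1)-way softmax because it keeps D and C as the
separate maximizations the objective describes while still sharing
representations, which is where the semi-supervised benefit arises: the
adversarial game forces the trunk to model the data manifold, and the
classification head rides on that representation.

Training alternates per minibatch: (1) a discriminator/classifier step
minimizing −E[log D(x)] − E[log(1 − D(G(z)))] + λ·CE; (2) a generator step
minimizing −E[log D(G(z))] — the **non-saturating** form rather than the
minimax term, the standard remedy for vanishing generator gradients early
in training.

Numerical choices: multilayer perceptrons with leaky-ReLU hidden units
(slope 0.2); generator hidden widths (128, 128), discriminator trunk
(128, 64); He-style initialization; Adam with β1 = 0.5 (the usual GAN
setting), β2 = 0.999, learning rate 2·10⁻⁴; probabilities clamped at
ε = 10⁻⁷ inside logs so a saturated head yields a large finite loss;
non-finite losses abort with a diagnostic. Features are standardized (fit
on training data) before either network; the generator emits standardized
values, de-standardized on sampling. All of this is implemented in NumPy
with hand-written backpropagation — the networks are small enough that a
deep-learning framework would add nothing but a dependency. Training is
bit-reproducible given the seed: all randomness (initialization, shuffling,
latent draws) flows from one `numpy` generator.

Defaults of 300 epochs and batch size 64 train the 600-sample reference
fixture in well under a minute on one CPU core. Prediction standardizes
with the stored scaler, evaluates the classification head, and breaks
probability ties toward the lowest class code.

## Logistic-regression feature analysis

`fit_logistic` fits a standard multivariate binary logistic regression by
iteratively reweighted least squares (Newton's method), converging when the
maximum absolute score < 10⁻⁸ or the maximum coefficient change < 10⁻¹⁰,
capped at 100 iterations. Standard errors come from the inverse observed
information; each predictor gets a Wald statistic (β/SE)² referred to χ²₁,
a two-sided p-value, the odds ratio e^β and the 95% CI e^(β ± 1.96·SE).
Perfect separation (all fitted probabilities saturated at 0/1, diverging
coefficients) is detected and returned as a flagged non-converged fit, not
an exception.

The **modeled event level is explicit** (default: Outcome = 0, so that odds
ratios below 1 read as "risk factors for diabetes reduce the probability of
being healthy"); flipping the event level negates all coefficients and
inverts all odds ratios, which is tested. Significance markers follow the
three-level star convention: *** for p < 0.01, ** for p < 0.05, * for
p < 0.10, strict inequalities. No multiple-testing correction is applied;
p-values are reported raw.

Pearson correlations use sample moments; zero-variance columns yield NaN
entries and are flagged by name rather than silently zeroed.

## Evaluation

`run_cv` performs stratified k-fold cross-validation (default k = 10;
stratified because with ~35% prevalence unstratified folds can distort
per-fold class balance). Per fold, the imputation plan, cap fences and
optional resampling are fitted on the training indices only; the GAN is
trained on the processed training fold and scored on the untouched test
fold. Index bookkeeping asserts train/test disjointness. Metrics: accuracy;
precision, recall, F1 for the positive class in binary tasks and
macro-averaged for three classes (the averaging choice is recorded in the
protocol descriptor); ROC AUC as a rank statistic with ties counted ½
(one-vs-rest macro for multiclass); and the confusion matrix. Standard
metric computations are delegated to scikit-learn and cross-checked in the
test suite against brute-force oracles (pairwise rank counting for AUC,
hand-evaluated confusion matrices).

## Synthetic data

`generate_pima_like` emulates the *structure* of the PIMA cohort: exact
class counts (default 500 non-diabetic : 268 diabetic), class-conditional
feature distributions with real signal in Glucose, BMI, Age, Pregnancies
and DiabetesPedigreeFunction, lognormal Insulin and pedigree (exercising
the median branch of the imputation rule; near-symmetric features exercise
the mean branch), multiplicative outliers (rate 0.01, factor 4), and
zero-coded missingness at roughly the rates seen in the public data (zeros
are injected after outliers so detection sees a realistic mixture). What it
does **not** emulate: the real PIMA marginals and their correlation
structure, measurement rounding, or cohort-specific confounding — so tests
passing on synthetic data demonstrate correctness of the machinery and
qualitative behaviour (imbalance correction, preprocessing effects,
classifier learning), not clinical performance on the real cohort.

`generate_separable_gaussians` is the known-truth fixture: balanced
unit-variance Gaussian classes with class c centred at separation·e_c. At
separation 8 the Bayes error is negligible (the pairwise class-mean
distance is 8√2·σ), so any competent classifier must score ≥ 0.95 held-out
accuracy — this calibrates the GAN classifier's training loop end to end.

## Problem sizes and limitations

The reference checks run at n = 768 (synthetic PIMA-like) with 5-fold CV
and 60 training epochs per fold, and n = 600 for the Gaussian fixture with
the default 300 epochs — sizes chosen so the full verification completes in
minutes on a single core while leaving the learning dynamics comfortably
converged. Known limitations: the GAN's headline metrics depend on
architecture, λ, epochs and resampling placement, none of which have
field-standard values for this problem — results are therefore always
reported together with the protocol descriptor; Wald inference is
first-order asymptotic and degrades near separation; SMOTE assumes minority
interpolation is meaningful, which fails for discrete features (synthetic
Pregnancies values need not be integers); ENN with very small classes can
delete aggressively.
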