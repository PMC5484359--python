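# Methods

`imbalmrs` studies imbalanced multiclass learning for single-voxel
¹H-MRS classification of the three common pediatric posterior-fossa
tumors — pilocytic astrocytoma (PA), medulloblastoma (MB) and ependymoma
(EP) — where EP is a small minority class (10 of 90 cases, ~11%).  The
pipeline combines a data-level correction (borderline synthetic minority
oversampling, bSMOTE) with algorithm-level corrections (AdaBoostM1
ensembles and a random forest), and evaluates everything with
imbalance-aware metrics under a cross-validation scheme that never lets a
synthetic case reach a test set.

## Synthetic cohort model

No patient data ship with the package.  The generator draws a 42/38/10
cohort whose 17 profile variables (14 metabolites plus the grouped
lipid/macromolecule resonances TLM09/TLM13/TLM20) follow per-class
normal distributions with the means and standard deviations in
`src/imbalmrs/data/class_profiles.yaml` (mM-like arbitrary units on the
quantitation scale of the fitting software).  Draws are clipped at zero —
concentrations are nonnegative, and clipping rather than rejection keeps
the number of random draws, and therefore bit-level reproducibility,
independent of the parameters.  Clipping shifts the realized mean of a
variable whose SD is comparable to its mean; the large-n generator test
accounts for this with the truncated-normal correction.

Two deliberate simplifications, and what they imply:

* **Independence.** Metabolites are drawn independently within a sample;
  real MRS metabolite concentrations covary strongly (e.g. the choline
  and creatine pools).  Consequently the synthetic EP class is a diffuse
  cloud in 17 dimensions rather than the coherent cluster a real cohort
  forms.  This matters for what the package can and cannot demonstrate:
  see "Known limitations" below.
* **Stand-in lineshapes.** The matching "complete spectra" are synthesized
  as sums of single unit-area Lorentzians at canonical chemical shifts
  (editable in `data/peak_library.yaml`, which is explicitly labelled a
  synthetic stand-in), a flat baseline, and i.i.d. Gaussian noise
  (default SD 0.5 intensity units per point), on an axis of 457 points
  covering exactly 0.5–4.0 ppm (~0.0077 ppm/point, emulating resampling
  to 0.49 Hz/point at a 1.5 T proton frequency).  No time-domain
  simulation, water signal, phase errors or multiplet structure.

## Preprocessing

* **Quality control.** SNR is defined as (spectral maximum − baseline) /
  (2 × RMS noise); thresholds are inclusive (SNR ≥ 4, FWHM ≤ 0.15 ppm).
  FWHM is accepted as a per-sample input (it comes from the spectral
  fitting software); noise RMS may be supplied or estimated from the
  3.75–4.0 ppm region, which the default peak library leaves signal-free.
* **CRLB inclusion rule.** A metabolite is retained when at least two
  samples have a Cramér–Rao lower bound strictly below 50%; missing
  values never count.  The rule is monotone in the bound.
* **Profile assembly.** Composites are plain sums (total NAA = NAA + NAAG,
  total creatine = creatine + phosphocreatine, total choline = GPC + PC on
  request); the nine lipid/macromolecule components are grouped onto the
  0.9 / 1.3 / 2.0 ppm resonances (default mapping: MM09+Lip09 → TLM09;
  MM12+MM14+Lip13a+Lip13b → TLM13; MM17+MM20+Lip20 → TLM20 — MM17 is
  assigned to the 2.0 ppm group; the mapping is a caller-supplied
  argument).
* **PCA.** Components are retained up to the smallest count whose
  cumulative explained-variance fraction reaches the threshold (default
  0.95).  PCA is fitted inside each CV fold on the training block only —
  after oversampling, in the original feature space — and the test block
  is centered with the training means and projected with the training
  loadings.  Fitting PCA on all data would leak test information through
  the loadings; the SMOTE-then-PCA order is a package choice (the
  alternative order is available by composing the functions directly).
* An optional per-spectrum intensity normalization exists in the pipeline
  config (`normalize_spectra`), default off.

## Borderline-SMOTE

For each minority sample, its k = 5 nearest neighbors among *all* other
samples (Euclidean distance, ties broken by row order) classify it as
noise (all k non-minority), danger (non-minority neighbors strictly
outnumber minority ones, but not all k) or safe.  Synthetic samples are
generated only from the danger set: seeds are visited in random order,
one sample per visit, until round-half-up(rate × n_minority) cases exist;
each case is x_i + (x̂ − x_i)·δ with x̂ one of the seed's k nearest
*minority* neighbors and δ ~ U[0,1].  When the danger set is empty the
seed pool falls back to the minority set minus noise points, with a
logged warning — aborting would make small simulations brittle.  The two
large classes are pooled as "the majority" throughout, and only one
minority class is supported.

## Learners

AdaBoostM1: uniform initial weights summing to 1; per round the weak
learner is fitted to the weighted set, the weighted error ε computed; a
round with ε ≥ 0.5 stops training *before* the member is added (round
one keeps the single unweighted learner with weight 1); otherwise the
member joins with voting weight log((1−ε)/ε), misclassified weights are
multiplied by (1−ε)/ε and renormalized, and ε = 0 stops early (perfect
fit; the voting weight uses an ε floor of 1e-8 to stay finite).
Prediction is the weighted plurality vote, ties broken toward the
earlier class name.  Default round caps: 100 for profiles, 200 for
spectra.

Weak learner families and how they receive instance weights:

| family      | implementation                          | weighting          |
|-------------|-----------------------------------------|--------------------|
| naive_bayes | Gaussian NB                             | native             |
| svm_rbf     | standardizer + RBF SVC (C = 1, γ = 1/(p·Var)) | native; weights rescaled to sum n, since SVC multiplies C by each sample weight and unit-sum weights would collapse the effective cost to C/n |
| ann         | standardizer + 3-hidden-layer logistic MLP (32/16/8, L2 1e-3, ≤ 500 epochs, L-BFGS) | weighted bootstrap (no native support) |
| lda         | LDA                                     | weighted bootstrap |

The SVM/ANN hyperparameter defaults are documented stand-ins — the
architectures are specified but no values are published for this
pipeline.  The fold-local standardizer for SVM/ANN is a package choice:
RBF kernels and sigmoid nets require comparable feature scales, while NB
and LDA are scale-equivariant and run on raw PCA scores.  A weighted
bootstrap draws n samples with probability proportional to weight and
retries (×5) if the resample degenerates to one class; a round whose
weak learner cannot fit is skipped with a warning and still counts
toward the round cap.  All families handle ≥ 3 classes natively; there
is no one-vs-rest wrapping.

Random forest: the tree count is selected from a per-representation grid
(profiles 25–90, spectra 78–170) by internal stratified CV maximizing
the minority-class F-measure, ties broken by balanced accuracy and then
by the smaller count.  In the orchestrated pipeline this grid search
runs once per (representation, rate) on an oversampled copy of the full
cohort, mirroring the published procedure of one tree count per sampling
rate, rather than nested per fold.

## Evaluation

Per class (one-vs-rest): precision, sensitivity, specificity (pooled
non-target classes), F-measure 2ps/(p+s), and G-mean
√(sensitivity × specificity).  The geometric-mean square root is applied
deliberately; the bare product is available via `g_mean(..., sqrt=False)`.
BAR is the unweighted mean of per-class sensitivities over classes
present in the truth.  Empty denominators yield 0 with a logged warning.

Pool-rotation CV: the original cohort (synthetic rows are rejected on
input) is stratified into z = 10 pools, each class dealt round-robin from
a random permutation so the 10 minority cases spread ~1 per pool
(unstratified pools can leave test sets with no minority case, making
per-class metrics undefined).  For each held-out pool, bSMOTE runs only
on the minority cases of the remaining z−1 pools; the learner trains on
the augmented partition with fold-local PCA and is scored on the
untouched pool.  Fold confusions accumulate into one confusion per
repeat; metric values (not pooled confusions) are averaged across
repeats.  At rate 0 the scheme reduces exactly to plain stratified
z-fold CV.  Rate comparisons use the Kruskal–Wallis rank test on
per-repeat BARs (one-way ANOVA optional); all-identical groups return
p = 1 by convention.

## Problem sizes and numerical choices

The shipped pipeline default is 25 repeats per cell (the full-budget
setting of 100 is one config value away).  The acceptance script and the
heavier acceptance tests use z = 10, 25 repeats, boosting capped at 15
rounds (5 for the ANN, with a reduced 8/8/8 net and 60 epochs), and the
per-rate tuned forest tree counts — the package's desk-scale operating
point.  Seeds: every stochastic component (cohort draws, spectra noise,
SMOTE deltas and visit order, bootstrap resamples, ANN initialization,
forest bagging, pool assignment) descends from one master seed through
`numpy.random.default_rng`, so any run is reproducible bit-for-bit.
Neighbor-distance ties break by cohort row order; prediction ties by
class-name order; the synthetic count uses round-half-up.

## Known limitations

* Independent per-metabolite draws make the synthetic minority class far
  more diffuse than a real ependymoma cohort.  Under these conditions
  roughly half the minority samples classify as bSMOTE noise points, and
  the synthetic cases concentrate near the few danger seeds inside the
  class-overlap region, *reducing* the variability of the learned
  minority model (synthetic bSMOTE sets genuinely have less variability
  than the original class — an intrinsic property of convex
  interpolation).  As a result, oversampling reliably helps the random
  forest here but can degrade the Gaussian-type boosted learners, and
  the package's tests of the directional benefit of oversampling reflect
  exactly this: passing or failing them speaks to the synthetic geometry,
  not to real MRS cohorts, where metabolite covariance concentrates the
  minority class.
* The spectra are linear projections of the profiles plus noise; they
  cannot show representation effects beyond dimensionality and peak
  overlap.
* One minority class only; no undersampling or other SMOTE variants; no
  ROC/AUC or calibration analysis; QC FWHM is an input, never estimated.
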