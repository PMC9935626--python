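# Methods

`jdr` decomposes two gene-expression cohorts that share a gene axis into
variation that is *joint* (structurally shared between the cohorts),
*individual* (cohort-specific) and *residual* (noise), and builds the
downstream analyses — per-sample variation profiles, a per-gene joint
statistic with permutation FDR, and translation-aware elastic-net response
models — on top of that decomposition. This note records the model, the
defaults and the design decisions a maintainer would want to know about.

## The decomposition model

Each cohort is a mean-centered matrix `X_k` (samples x genes; genes are
the shared feature axis, so right singular vectors are metagenes). The
working model is additive low-rank-plus-noise:

    X_k = J_k + I_k + E_k

with the gene-space (row-space) structure of `J_A` and `J_B` lying in a
common joint subspace, `I_k` lying in cohort-specific subspaces, and
`E_k` isotropic noise. The fit is the angle-based two-stage SVD:

1. **Initial SVD.** `X_k ~ U_k D_k V_k'` truncated at the initial signal
   rank `r_k`. This strips residual noise; everything downstream sees only
   the retained metagenes.
2. **Principal angle analysis.** Stack `M = [V_A'; V_B']` and take its SVD
   `M = U_M D_M V_M'`. The principal angles between the two metagene
   subspaces follow from the singular values as
   `phi_i = arccos(sigma_i^2 - 1)`, `i = 1..min(r_A, r_B)`; arccos
   arguments are clamped to [-1, 1] and angles to [0, 90] degrees.
3. **Joint rank.** An angle counts as joint when it is smaller than a
   cutoff calibrated on chance: the 5th percentile (default) of the
   smallest principal angle between independently drawn random `r_A`- and
   `r_B`-dimensional subspaces of gene space (1000 draws by default,
   seeded). The cutoff is injectable (`AjiveConfig.angle_cutoff`) for
   users who prefer an analytic bound computed externally. The joint
   gene-space basis `W` is the corresponding top right singular vectors of
   `M`, re-orthonormalised.
4. **Reprojection.** The original data are projected through mutually
   orthogonal gene-space projectors: `J_k = X_k P_W`; `I_k = X_k P_I`,
   where `P_I` projects onto the part of the retained row space
   `span(V_k)` orthogonal to `W`; and `E_k = X_k - J_k - I_k`. Because
   the projector ranges are pairwise orthogonal, every sample's row
   decomposes exactly — `||x||^2 = ||j||^2 + ||i||^2 + ||e||^2` — and the
   matrices are pairwise Frobenius-orthogonal. (An alternative seen in
   JIVE variants, `I_k = Xhat_k (Id - P_W)`, conserves sums of squares
   only in aggregate; the per-sample decomposition then fails by ~1%,
   which would contaminate the sample-level profiles below. The projector
   construction was chosen for that reason.)

Only the two-block case is implemented: every pairing the method targets
(cell lines vs tumors, mouse models vs tumors) is pairwise, and the
chance-angle calibration for more than two blocks would need a different
null.

## Initial signal rank selection

`r_k` is chosen per block by a half-split bootstrap: samples are split
into two random equal halves (one sample dropped at random when odd),
both halves are re-centered and integrated against each other at each
candidate rank (the same rank for both halves), and the percent of total
sum of squares (pooled over both halves) landing in joint, individual and
residual structure is recorded; the split is repeated (default 10 times).
True signal directions reproduce in both halves and appear joint; noise
directions do not and appear individual. The selected rank maximises
mean(% joint) - mean(% individual), ties toward the smaller rank. The
full curve is always returned so an elbow can be read off directly
instead. Percentages are pooled across halves by total sum of squares
rather than averaged per half; with equal halves the two choices are
nearly identical, and pooling keeps the triple summing to 100 exactly.

## Sample- and gene-level variation partition

Because the row-wise split is exact, a sample's percent joint variation
is simply `100 ||j||^2 / ||x||^2` (similarly individual/residual), and
the three percentages sum to 100 by construction. The per-sample
joint/individual ratio summarises how well a sample is represented by
shared structure; group summaries (e.g. by tissue) are reported as
distributions of this ratio, with no parametric form imposed. An
equivalent route via the SVD scores of the reprojected matrices is
exercised as a cross-check in the test suite. Gene-set partitions sum
per-gene variances within the original, joint and individual matrices
over the set and report joint/individual fractions of the original.

## Per-gene joint statistic and permutation FDR

For gene `g` with variance `var_J` in the joint matrix and `var_I` in the
individual matrix (population variances, denominator n — both matrices
share the sample count, so the convention cancels except in the floored
regime):

    T_g = ln( max(var_J, s) / max(var_I, s) ),   s = 0.5 by default

implemented as a difference of logs, which is exactly antisymmetric under
swapping J and I. The floor `s` suppresses artefacts from genes with
negligible variance in both matrices; with the printed-formula reading the
statistic is zero only when *both* variances are at or below the floor. A
stricter mode (`strict_prose=True`) zeroes the statistic whenever either
variance is floored; it is off by default because the max-floored form is
the one defined by the formula, and the two differ only for genes with
one-sided low variance.

The null is built by permutation: per gene, the joint-row and
individual-row entries are pooled, shuffled, and re-split into pseudo-rows
of the original sizes (an exchangeable per-gene null giving
approximately uniform p-values under the null; verified by a
Kolmogorov–Smirnov check in the tests). A whole-row label-swap variant is
available behind `scheme="label_swap"`. Two-tailed p-values use the +1
smoothing `(1 + #{|null| >= |obs|}) / (1 + n_perm)`.

FDR cutoffs follow the significance-analysis-of-microarrays permutation
estimator: for candidate cutoff `c > 0`, the estimated FDR is the median
over permutations of the count of null statistics >= c, divided by the
count of observed statistics >= c (capped at 1); the cutoff is the
smallest observed statistic attaining the target. The negative tail is
mirrored independently, since per-cohort thresholds are applied to a
signed statistic. The median-count form was chosen over the mean-count
variant for robustness to the occasional permutation with a heavy tail.

Genes significant in both integrated cohorts are *fully joint*
(translatable); in exactly one, *unidirectional*; in neither, *not
joint*.

## Translation models

Elastic-net response models are trained on the original, joint or
individual matrix with a fixed selection protocol: alphas are taken from
the regularisation path (100 per l1_ratio, at l1_ratio in {0.1, 0.5,
0.7, 0.9, 0.95, 1}); every (alpha, l1_ratio) pair is scored over 20
random 67/33 train/test splits (stratified when a grouping such as tissue
is supplied; rare classes are merged into the modal class with a
warning); the pair with the best mean held-out R² wins, ties toward the
larger alpha (sparser model); the winner is refit on all samples. Paths
are computed per l1_ratio on the training fold, so one path call scores
all alphas of that ratio at once. The binary-outcome variant uses
logistic regression with elastic-net penalty (SGD) under the same split
protocol, scored by held-out ROC-AUC since R² is undefined for
classification; its alpha grid is taken from the regression path on the
0/1 labels, as the protocol defines no classification-specific grid rule.

Models are evaluated out of sample by applying the linear predictor to an
external cohort (genes aligned by label; absent genes imputed as zero
with a warning) and computing ROC-AUC against a binary clinical outcome.
The trapezoid AUC equals the Mann–Whitney pair-counting statistic, with
ties contributing 1/2. Two models on the same samples are compared by
bootstrap: resample samples with replacement (redrawing single-class
resamples), compute the AUC difference per resample, and report the
fraction of resamples with difference <= 0 as a one-sided p-value.

Signature scores are per-sample medians over a gene set; group contrasts
use a pooled-variance two-sample t-test (Welch behind a flag). Per-gene
drug-response association uses exact tie-corrected Spearman correlation;
when several response measurements exist per sample they are collapsed by
the median (mean available — both conventions appear in practice, and
the choice is surfaced rather than hidden).

## Synthetic data generator

The generator emulates the regime the decomposition assumes, on the
post-normalisation log scale:

    X_k = S_J_k W_J' + S_I_k W_k' + noise_sd * N_k

Scores are i.i.d. `N(0, signal_sd^2)`; noise is i.i.d.
`N(0, noise_sd^2)`. Genes are partitioned into disjoint classes (defaults:
10% joint, 10% per-block individual, remainder null) and each basis is
supported only on its class's genes, so `W_J`, `W_A`, `W_B` are mutually
orthogonal by construction and the classes are exact ground truth.

Bases are built as disjoint random-sign columns rotated by a random
orthogonal matrix, giving (near-)equal row norms on the support. This is
deliberate: orthonormalised Gaussian bases have chi-square row norms, and
at ranks 2–3 roughly 10–17% of "planted" genes would carry negligible
loading — gene classes would then not mean what they say, and no method
could recover them. With equalised loadings, a planted gene's variance
contribution is `signal_sd^2 * rank / support_size` up to rotation.

Signal strength is parameterised in tests via
`snr_to_signal_sd(snr, n, p, noise_sd)`, which defines SNR as the
expected smallest planted singular value `signal_sd * sqrt(n)` over the
expected noise operator norm `noise_sd * (sqrt(n) + sqrt(p))`. Random
matrix theory puts the detectability transition near SNR = 1, so SNR = 4
is a strong-signal regime in any dimensions.

The response generator produces either a continuous response linear in
the joint metagene scores plus Gaussian noise, or binary labels through
the logistic transform of the same predictor. The adversarial
`simulate_translation_scenario` additionally ties the training cohort's
first individual component to the response and reverses that association
in the external test cohort — the situation in which training on the
joint matrix should beat training on the original matrix.

What the generator does **not** emulate: count-level RNA-seq artefacts
(library-size variation, overdispersion, dropout), gene–gene correlation
beyond the planted low-rank structure, batch effects within a cohort, and
non-linear response surfaces. Passing tests therefore demonstrate
correctness of the algorithms under the model's own assumptions, not
robustness to violations of them on real data.

## Numerical conventions and degenerate inputs

- SVD sign convention: each right singular vector's largest-magnitude
  entry is made positive (bit-reproducible decompositions).
- arccos arguments clamped to [-1, 1]; angles to [0, 90] degrees.
- A requested initial rank above the numerical rank is truncated with a
  warning; rank 0 joint structure yields all-zero `J` and `I = Xhat`.
- The individual basis is extracted from `(Id - P_W) V_k` by SVD with a
  relative singular-value threshold of 1e-8, so joint directions inside
  the retained row space are removed exactly once.
- Upper-quartile normalisation uses the linearly interpolated 75th
  percentile of each sample's nonzero values; the default target is the
  geometric mean of per-sample upper quartiles (scale-equivariant and
  keeps a typical sample near its original scale), pseudo-count 1 before
  log2. All-zero samples and negative entries are rejected.
- Gene filtering at intersection: by default a gene is dropped when it is
  zero in every sample of at least one block (strict reading); the
  lenient reading (zero everywhere in every block) and no filtering are
  available behind a flag.
- Homolog mapping: mouse symbols are upper-cased and translated via the
  Jackson Laboratory homology-class report; classes with several human
  symbols keep the first in file order, and several source genes mapping
  to one human symbol keep the highest-variance source gene (both logged).
- Zero-variance samples get NaN variation percentages with a warning; the
  joint/individual ratio is NaN/inf when the individual percent is zero.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` exercise the pipeline at
desk-scale study conditions chosen to finish in minutes while keeping
every regime distinguishable: cohorts of 60–200 samples, 200–2000 genes,
planted joint ranks 0–5, individual ranks 2, SNR 4–5, 300–1000
permutations, 500 Monte-Carlo draws for angle cutoffs, and 20–50
replicates per recovery rate. Reported quantities (recovery rates,
recalls, win rates, oracle errors) are computed fresh at run time from
these simulations.

## Known limitations

- Two blocks only; no K > 2 integration and no nonlinear (kernel) variant.
- The random-subspace angle cutoff is a chance calibration, not the
  Wedin-bound perturbation analysis; for data near the detectability
  threshold the joint rank can be under- or over-counted.
- The permutation null treats samples as exchangeable within a gene;
  strong sample substructure (e.g. unmodelled batches) violates this.
- Elastic-net selection optimises mean held-out performance; no
  one-standard-error rule is applied.
- The half-split rank curve assumes splitting halves the sample size but
  not the structure; very small cohorts (n < ~40) give noisy curves.
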