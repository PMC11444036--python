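# Methods

This note documents the models and procedures implemented in `mvcotrain`,
the parameters that matter, the numerical and design choices made where the
problem left them open, and what the bundled synthetic data can and cannot
show.

## Problem setting

The package targets binary prediction of a rare clinical event — severe
hypoglycemia (SH) in type 2 diabetes is the motivating case — from tabular
subject-level data in which (i) the positive class is heavily outnumbered
(the reference cohort has 151 positives to 1,025 negatives, 1:6.79) and
(ii) the majority of subjects cannot be labeled at all because the event
information is missing (≈9,000 of ≈10,200 subjects). Both properties defeat
conventional supervised fits, which motivates the semi-supervised design.

## Outcome derivation

An SH event is called from three coded fields: glucose-below-50 mg/dl
(1 = below, 2 = at/above, 3 = unknown), medical assistance (1 = required,
0 = not), and hospital admission (1 = required, 2 = not, 3 = unknown).

- **SH**: glucose code 1 AND (assistance 1 OR admission 1).
- **non-SH**: glucose code 2 AND assistance 0 AND admission 2.
- **Unknown**: everything else.

The SH/non-SH predicates cover 4 + 1 of the 18 valid combinations; the
remaining 13 include combinations the source definitions leave implicit
(e.g. glucose at/above 50 with assistance required). These are deliberately
mapped to Unknown rather than guessed: a conservative rule keeps the
labeled classes clean at the cost of a larger unlabeled pool, which the
co-training machinery exploits anyway. Subjects with no event record join
the Unknown pool. The source coding also contains one internal ambiguity
(prose mentions a 0 value for hospital admission that the explicit code
definition does not include); the explicit code set {1, 2, 3} is enforced
and out-of-range codes raise a validation error rather than being coerced.

## Imputation and longitudinal summarization

Longitudinal raw variables are imputed per subject with
last-observation-carried-forward (LOCF), ordered by visit. Two cases LOCF
does not define are resolved as follows: leading missing values (no prior
observation) take the subject's observed median for that variable, and a
subject with no observation at all takes the cohort median. Median-of-
observed imputation is used for non-longitudinal columns. Both operations
are idempotent and never alter an observed value.

Each continuous clinical variable (HbA1c, fasting plasma glucose, health
check, diabetes education, nutrition education) is summarized per subject
as mean and sample standard deviation (n−1 denominator); each of the seven
medication indicators as the mean of its 0/1 visit values, i.e. a
use-fraction in [0, 1]. A single visit yields std = 0 rather than a missing
value so downstream models never see gaps. The 12-variable expert schema
therefore produces exactly 17 model columns.

## Feature selection

- **LASSO**: L1-penalized logistic regression on internally standardized
  features over a 50-point log-spaced penalty path; the penalty is chosen
  by 5-fold cross-validated deviance with the one-standard-error rule
  (strongest penalty within one SE of the minimum), and nonzero
  coefficients at that penalty are the selection. The one-SE rule is the
  package's choice of tie-breaker along the path; note that on (nearly)
  separable data the deviance path decreases monotonically and the rule
  loses its protective effect — a known property of penalized logistic
  deviance, visible in the test design, which uses probabilistic labels.
- **Boruta**: candidates compete against per-column permuted shadow copies
  under random-forest impurity importance. A feature scores a hit when its
  importance exceeds the *maximum* shadow importance; accumulated hits are
  tested against Binomial(t, ½), two-sided at α = 0.05 with a Bonferroni
  correction over candidates (as in reference implementations), confirming
  or rejecting features as evidence accumulates; features still tentative
  after `max_iter` (default 100) count as not selected. The Binomial(½)
  null is conservative for confirmation because the true null hit rate
  against the max of m shadows is ≈ 1/(m+1).
- **MRMR**: greedy forward selection under the *difference* criterion,
  relevance − mean redundancy, with both terms estimated by discrete mutual
  information after quartile binning of continuous features (binary
  features and the label enter as-is). The difference form is the common
  default; the variant was not pinned by the source. Selection is fully
  deterministic with ties resolved to the earliest feature in source-column
  order.
- **MRMR k sweep**: because MRMR needs k in advance, the sweep evaluates
  k = 1..k_max by stratified cross-validated AUROC with a chosen base
  learner and returns the smallest k attaining the maximum.
- **Consensus / majority vote**: consensus keeps features selected by every
  base method (set intersection); majority keeps those selected by more
  than half. The expert (MD) list is an input, not a computed selector, and
  participates only if the caller includes it.

## Co-training

Self-training (single view): fit, pseudo-label every unlabeled row whose
maximum class probability **strictly** exceeds Θ (default 0.90), refit,
repeat until no row qualifies. Θ = 1.0 therefore absorbs nothing.

Two-view co-training follows the classical pool-based scheme. Parameters
and defaults:

| parameter | default | meaning |
|---|---|---|
| `k` | 30 | iterations (the classical experimental choice) |
| `p` | 1 | confident positives harvested per view per iteration |
| `n` | 5 | confident negatives harvested per view per iteration |
| `u` | 75 | unlabeled working-pool size per view (classical choice; not stated by the source) |
| `undersample_ratio` | 1.0 | majority-per-minority ratio of the one-time balancing of L (None disables) |
| Θ | 0.90 | self-training probability threshold |

Design choices that were genuinely open, and their rationale:

- **One shared labeled set.** Pseudo-labels harvested by either view join a
  single L used by both learners at the next fit. This realizes
  cross-teaching ("h1 labels rows that h2 learns from") without maintaining
  two per-view labeled sets; whether the original experiments kept one or
  two sets is not stated.
- **Under-sampling once, before the first fit.** Re-balancing L to the
  target ratio at every iteration would exactly cancel the class-ratio
  drift produced by an asymmetric (n > p) harvest, and with it the
  characteristic specificity gain of the method: measured on the bundled
  preset, per-iteration re-balancing leaves last-iteration specificity
  statistically indistinguishable from the first iteration, while one-time
  balancing reproduces the expected monotone specificity rise (and
  sensitivity fall) in every tested seed. The accumulated confident
  negatives shifting the fit is the mechanism, so the balancing is applied
  once and the drift is allowed to happen.
- **Disjoint pools.** The two views' pools are drawn disjointly from U and
  refilled disjointly, so a row is pseudo-labeled at most once.
- **Ranking and ties.** Harvesting ranks by predicted positive-class
  probability (top p positives, bottom n negatives, positives take
  precedence in tiny pools); ties break to the earlier row in source order,
  which together with the column-order convention makes every run
  reproducible from its seed.
- **Hard labels at 0.5.** View predictions are thresholded at probability
  0.5 before AND/OR combination. AND is positive only when both views
  agree, OR when either fires; consequently positives(AND) ⊆ positives(OR)
  and specificity(AND) ≥ specificity(OR), sensitivity(AND) ≤
  sensitivity(OR) on any fixed test set — an exact identity, tested as
  such.
- **Positive class = the rare event** throughout all metrics.
- **Base learners** (LR, XGBoost, naive Bayes, SVM with Platt scaling,
  random forest) use their library defaults; no tuning grids were
  specified, and the learners are deliberately treated as exchangeable
  plug-ins behind one probability-emitting contract.

## Evaluation

Confusion-matrix metrics use the standard definitions; any 0/0 is carried
as an explicit undefined marker (`None` in memory, `"undef"` in CSV), never
silently zero, because near-degenerate classifiers on imbalanced data are a
reportable outcome. Reports print at 3 decimals; full precision is kept in
memory and JSON. Percentage improvement between the first and last
co-training iterations is `(last − first) × 100 / first`, computed from
full-precision values — applying it to already-rounded 3-decimal table
cells reproduces published percentages only approximately (e.g. a printed
144.732% recomputes as 144.53% from the printed cells), which is why full
precision is persisted.

## Synthetic data

The generator emulates the cohort's statistical shape, not its content:

- exact class quotas (default: 151 positives, 1,025 negatives, 9,068
  unlabeled at the same prevalence), so count assertions are exact;
- view 1 = four continuous glycemic summaries with per-class mean shift
  δ₁ = 1.0·σ; view 2 = six continuous management summaries with δ₂ = 0.8·σ
  plus seven 0/1 medication indicators with a 0.25 class rate gap (base
  rate 0.30). These are moderate, individually-predictive effect sizes —
  each view alone reaches AUROC ≈ 0.75–0.85, in the range where
  semi-supervised augmentation plausibly helps; a view-AUROC near 1 would
  make co-training pointless and near 0.5 would make it impossible;
- an optional shared latent Gaussian (weight ρ) added to both views'
  continuous features provides a single redundancy knob; ρ = 0 gives
  conditional independence of the views given the class, the classical
  co-training assumption;
- longitudinal panels with per-cell missingness for exercising LOCF and
  summarization, with the hidden complete panel retained.

It does **not** reproduce real units, clinical ranges, inter-feature
covariance within a view, non-Gaussian tails, informative missingness, or
label noise. Passing tests on this generator demonstrate that the machinery
is correct and that the qualitative specificity-gain mechanism operates
when two informative views exist; they do not certify performance on any
real cohort.

## Problem sizes and determinism

Tests and the acceptance script run the full pipeline at the cohort's
labeled-set scale (1,176 labeled / 9,068 unlabeled, 30 iterations, 5
seeds); selector behavior is checked on planted-signal instances of
200–800 rows, sizes at which the planted effects are statistically
resolvable. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global state is used, and every operation is
a pure function of (data, parameters, seed).

## Known limitations

- Exactly two views; no soft (probabilistic) view combination.
- Pseudo-labels are immutable — there is no mechanism to revisit an early
  wrong pseudo-label, which is the classical failure mode of co-training
  when a view is weak.
- The MRMR variant (difference criterion, quartile binning) and the Boruta
  settings are sensible defaults, not certified matches to the original
  experiments' unavailable configuration details.
- The LASSO one-SE rule degrades on separable data (see above).
- No model-based or multiple imputation; LOCF is known to bias variance
  estimates when missingness is informative.
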