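# Methods

This note documents the models, algorithms and design choices behind
gaitmod: what each stage assumes, which tunable parameters matter, what
the synthetic cohort does and does not emulate, and where the known
limitations are.

## Outcome

Gait speed reserve (GSR) is defined as maximum minus usual gait speed,
in cm/s — the headroom a person has above their comfortable pace.
Usual gait speed is the secondary outcome. Non-positive speeds are
invalid input; rows with missing gait data are excluded by the QC stage
rather than silently dropped downstream. A negative computed reserve is
flagged for review, never removed automatically.

## Free-text annotation

**Model.** Medication and comorbidity histories are free text. A
lexicon maps terms to classes: generic and brand drug names to one of
22 drug classes, and English/German condition phrases to one of 12
conditions. Matching is a two-level comparator per token:

1. exact match of the case-folded token against a lexicon term;
2. otherwise, if both token and term have ≥ 4 characters, the best
   approximate match under the normalized Damerau–Levenshtein
   similarity `sim(a,b) = 1 − DL(a,b) / max(|a|,|b|)`, accepted when
   `sim ≥ threshold` (default 0.85).

DL is the *optimal string alignment* variant: insertions, deletions,
substitutions and adjacent transpositions, with no substring edited
twice. The normalization makes the threshold length-aware: one edit is
tolerated from length 7 upward (6/7 ≈ 0.857), two edits from length 14.
Strings under four characters match exactly or not at all — at that
length a single edit rewrites a third of the string, so approximate
matching would be noise. Tokens containing digits ("40mg") or shorter
than three characters never match. Ties among equal-similarity
candidates resolve deterministically: longer matched term, then
lexicographically smaller class code.

**Negation.** A match is discarded when a negation cue (configurable;
defaults cover English and German: no/not/without/stopped/kein/keine/
nicht/ohne/…) appears within a 3-token look-behind window, without
crossing a clause boundary (comma, semicolon, period). The clause rule
prevents "no aspirin, metformin" from suppressing the metformin
mention. The window and cue list are parameters of every annotation
entry point.

**Multi-token conditions.** Condition descriptions of k tokens are
matched with a moving window of k + 2 text tokens (tolerating missing
or extra words). Within a window, each description token takes the best
per-token similarity under the same two-level rule; the window score is
the mean of these, thresholded at 0.85. Alignment order within the
window is not enforced — a deliberate simplification that tolerates
word reordering ("disease, coronary heart") at the cost of occasional
cross-phrase false positives when two condition mentions abut (e.g.
"… heart failure, … pulmonary disease" partially scoring against
"coronary heart disease"). This mirrors the reality that condition
annotation from free text is noisier than drug annotation; flag-level
accuracy on rendered text is ≈ 99% in the test suite.

**Exclusion semantics.** An absent or empty medication history marks
the record for exclusion (unknown exposure); an absent comorbidity
history yields an empty condition report (conditions are covariates).

## Synthetic cohort generator

The generator produces the data structure the analysis assumes, at the
scale of the motivating study's analyzed cohort (defaults: n = 5519,
age ~ truncated Normal(76.4, 7.4²) on [60, 100], 54% female, BMI ~
Normal(25.7, 4.4²), statin prevalence 31%, aspirin 28%, mean usual
speed 105 cm/s, mean GSR 41.3 cm/s).

**Comorbidity and exposure.** Twelve conditions are Bernoulli draws
whose log-odds load on age and a shared latent burden factor, inducing
realistic co-occurrence. Twenty-one non-statin drug classes depend on
their indication conditions (biguanides on diabetes, loop diuretics on
heart failure, …); the 5α-reductase-inhibitor class is male-only, which
exercises the overlap-screening path. Statin assignment is logistic in
conditions, concomitant drugs and demographics; its coefficients were
calibrated once against the published baseline table so that the
pre-weighting imbalance is realistic (aspirin SMD ≈ 0.65,
hyperlipidemia ≈ 0.85, statin prevalence 0.31) and then frozen as
defaults. A single `confounding` scalar rescales all assignment
coefficients (0 = randomized exposure). Each logistic intercept is
solved by bisection so the realized marginal prevalence matches its
target regardless of confounding strength.

**Outcomes.** Usual speed and GSR are linear in centered covariates
with Gaussian residuals (Student-t(5) behind a `heavy_tails` flag for
robustness checks). GSR carries the moderation structure
`β₁·X + β₂·M + β₃·X·M` with defaults from the published aspirin row
(β₁ = −3.43, β₃ = 5.76 cm/s) and residual SD 12 cm/s; intercepts are
set so the population means hit their targets. Negative GSR draws are
resampled (truncation at zero); at the default means this affects well
under 1% of rows and has no measurable effect on interaction recovery
(verified by the unbiasedness test).

**Text rendering.** Each held drug emits a generic term (or a brand
synonym with probability `brand_rate`), optionally a dose token; a
fraction `negation_rate` of non-held drugs emits a negated mention
("does not take X", "kein X"), placed after the active medications so a
cue's look-behind scope cannot swallow a held drug. Single-character
typos (substitution/deletion/insertion/transposition) are injected at
`typo_rate`, but only on tokens of length ≥ `typo_min_len` (default 8):
one edit at that length keeps similarity ≥ 0.875, i.e. above the 0.85
acceptance threshold, so the typo channel models recoverable
misspellings. Conditions render in English or German (`german_rate`).

**Missingness.** `inject_missingness` blanks fields completely at
random at per-field rates; a `mar_by`/`mar_ratio` option multiplies the
rate in one arm (missing-at-random by treatment), which is what the
missingness-balancing property of the weights is tested against.
Defaults in the generator are zero; the pipeline's example
configuration uses study-like rates (gait 5.8%, medication history
25%, BMI 3%).

**What passing tests do and do not show.** The generator matches the
analysis model's assumptions by construction (linearity, logistic
exposure, MCAR/MAR missingness, noise within single free-text fields).
Real clinical text is messier (abbreviations, multi-drug lines, OCR
noise), real confounding need not be logistic-linear, and real
missingness can be informative. Green simulation tests therefore
validate the machinery and its calibration under the stated conditions,
not performance on any particular hospital's records.

## Five-step moderation analysis

For each candidate moderator M (each drug class except the treatment):

1. **Overlap screen.** Within the four X × M cells, any level of a
   binary covariate absent from a cell is excluded (rows dropped and
   listed — e.g. females when M is a male-only drug class); numeric
   covariates with disjoint interquartile ranges across cells are
   flagged. An empty cell marks the moderator non-analyzable; such
   moderators are reported, never silently dropped.
2. **Propensity estimation, separately per moderator level.** Numeric
   missings are imputed with a constant outside the observed range and
   a per-covariate missingness indicator joins the covariate set, so
   weights also balance missingness rates. Two estimators:
   - `gbm`: stagewise gradient-boosted trees (depth ≤ 3, shrinkage
     0.05, up to 300 trees by default) with the iteration chosen to
     minimize a balance criterion (mean weighted SMD by default; max
     SMD and mean KS available) — balance-tuned boosting in the twang
     tradition, with a logistic fallback on failure;
   - `logistic`: standardized logistic regression with a negligible
     ridge penalty (separation guard only; stronger shrinkage was found
     to leave residual imbalance on strong confounders in small
     moderator-level subsets) — fast, always converges, and used
     throughout the simulation-heavy tests.
   Probabilities are clipped to [1e−4, 1 − 1e−4] (clipping count
   reported).
3. **Balance check.** Weighted SMD and weighted KS for every covariate
   and missingness indicator, pass iff both < 0.20.
4. **Weighted interaction fit.** WLS of the outcome on X, M, X·M plus
   the same covariates as the propensity model (doubly-robust spirit),
   using the concatenated per-level ATE weights. Sandwich standard
   errors are used because the weights are estimated; the HC3 variant
   is the default since per-level subsets of a few hundred rows with
   ~40 adjustment covariates make HC1 anticonservative (null rejection
   ≈ 0.07–0.08 vs 0.055 for HC3 in the calibration tests). Aliased adjustment
   covariates are dropped with a warning; a moderator identical or
   complementary to the treatment is refused.
5. **Tabulation.** β₃ with CI and p-value, M-ATE₀ = β₁ and
   M-ATE₁ = β₁ + β₃ (CI from the coefficient covariance), average
   marginal effects, per-cell n, balance and overlap reports. No
   multiple-testing correction is applied across moderators — the
   design is explicitly exploratory, and per-moderator p-values are
   reported as-is.

**Weights.** ATE weights (treated 1/e, control 1/(1−e)) are stabilized
to mean 1 per arm (leaves weighted mean differences unchanged) and, by
default, truncated at the within-arm 99th percentile. Truncation was
added because in moderator-level subsets of a few hundred rows a single
extreme weight occasionally left a strong confounder's weighted SMD in
the 0.2–0.3 range; capping at the 99th percentile is the standard
remedy, and the covariate-adjusted outcome model keeps the effect
estimates unbiased (verified by the recovery and type-I tests). The
quantile is configurable (`weight_truncate=None` disables).

**Stratified runs** repeat the full per-moderator analysis within each
level of a binary stratum flag (the generator provides
atherosclerotic-cardiovascular-disease and cognition flags).

## Omitted-variable sensitivity analysis

Within one moderator level, for each grid cell (SMD s, correlation r)
a synthetic confounder U is drawn: a mix of the treatment-residualized,
standardized outcome and orthogonalized Gaussian noise, then
mean-shifted between arms. The construction is exact in-sample — the
noise is centered per arm and orthogonalized against the residual, the
mixing weight is rescaled by sd(Y)/sd(resid) — so the achieved between-
arm SMD equals s and corr(U, Y) equals r up to floating error when one
target is varied at a time (jointly, the arm shift perturbs the
correlation slightly; cells are scenario labels, not estimands). The
propensity model is re-fit with U included, the outcome model re-fit,
and the adjusted effect and p-value averaged over replicates (default
25) per cell. Observed covariates' own (SMD, |corr|) coordinates are
attached as markers. This is a transparent re-implementation of the
simulate-augment-refit idea behind published omitted-variable tooling,
not a port of any package's internals; per-cell failures are recorded
and the grid always completes.

## QC and exclusions

Inclusion filters run in a fixed order — age ≥ 60, complete gait,
complete medication history — with each excluded row attributed to the
first criterion it trips. Because the criteria overlap, the ledger also
reports the full joint-trigger matrix. Exclusion is idempotent.
Outlier screening builds Sturges-binned histograms (⌈log₂ n⌉ + 1 bins)
and flags values outside configurable plausibility bounds (BMI
[10, 70], usual speed [5, 250] cm/s, …); removal is a separate,
explicit caller action.

## Numerical choices and problem sizes

- Propensity clipping 1e−4; weight truncation quantile 0.99;
  balance threshold 0.20; significance 0.05 two-sided.
- WLS uses a pseudo-inverse-free design with explicit rank checking;
  collinear adjustment columns are dropped greedily, protected columns
  (intercept, X, M, X·M) never.
- Simulation-based tests run the logistic propensity path at
  n = 2000–5000 with 200–500 replicates — sizes chosen so Monte-Carlo
  error is small relative to the tolerances being asserted while the
  suite stays fast; the boosting path is exercised at smaller n in its
  own tests.
- Seeded `numpy.random.Generator` instances are passed explicitly
  everywhere; identical spec + seed reproduces cohorts and pipeline
  outputs byte-for-byte.

## Known limitations

- Cross-sectional design: the pipeline estimates associations and
  effect moderation under ignorability given the measured covariates;
  it cannot establish temporal ordering.
- Propensity weighting balances statin arms *within* moderator levels,
  not across them: moderation findings are not causal statements about
  the moderator itself.
- The condition matcher's unordered window scoring trades precision for
  recall on reordered phrases; drug annotation is near-exact, condition
  annotation is not.
- The sensitivity grid treats the unmeasured confounder as independent
  of observed covariates given treatment; correlated unmeasured
  confounding is outside its scope.
- Dose, duration and within-class drug subtype are not modelled.
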