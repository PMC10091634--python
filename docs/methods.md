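# Methods

## The task and its two metrics

The rapid serial visual presentation (RSVP) task shows a fast stream of
characters — digit distractors drawn from {3, 4, 6, 7, 8, 9} and two letter
targets (T1, T2) drawn from the 17-letter Latin alphabet that remains after
removing I, O, Q, S, U, V, W, X, Z — at 150 ms per character (9 frames at
60 Hz). A trial's *separation* is the number of digits strictly between T1
and T2; the seven conditions are {0, 1, 2, 4, 5, 6, 8} and a session holds
70 trials, 10 per separation, in randomised order. Only schedules and
scoring are implemented here; nothing is rendered.

Two conditional accuracies summarise performance at each separation *s*:

* attentional blink, AB(s) = P(T2 correct | T1 correct) — failing the second
  target after getting the first;
* attentional masking, AM(s) = P(T1 correct | T2 correct) — failing the
  first target after getting the second, an effect reported in cognitively
  impaired but not healthy older adults.

The *global* AB and AM are the means over separations 0–2 (where both
effects are strongest), expressed as percentages. The classifier feature
vector is the 14 per-separation values in fixed order (AB at all seven
separations, then AM; column names `ab_sep0 … am_sep8`).

**Degenerate cells.** A conditional with a zero denominator (e.g. no
T1-correct trial at a separation) is `None`, never 0. Two consumers need a
number anyway and both impute 0 — the worst possible performance — with a
warning: the feature matrix (`feature_vector`) and the per-participant
global metrics used by the cohort analysis (`compute_global_imputed`). The
strict `compute_global` raises instead, naming the separation. At 10 trials
per separation and the default model the imputation fires for roughly 1 in
700 impaired participants; choosing 0 treats an unmeasurable blink in a
participant who never reports T1 as maximal impairment, which is the
conservative direction for screening.

## Trial generation choices

The total stream length is not a property the metrics depend on, so it is
configurable: by default 5–10 leading distractors precede T1 (drawn
uniformly per trial) and exactly 3 trailing distractors follow T2, so T2 is
never the final character and remains maskable. No two consecutive
distractors are identical (at 150 ms identical neighbours perceptually
fuse). T1 ≠ T2 is enforced because duplicate targets would make a single
reported letter ambiguous. Report matching is case-insensitive; a missing
report scores as incorrect.

## Synthetic cohort model

The real cohort (13 CI = mild AD + MCI-non-AD, 9 age-matched HC) is not
deposited, so the pipeline runs on a generative stand-in. Published group
summaries give only the conditionals and their global means, which do not
identify a sampling model, so the generator is parameterised by the *joint*
distribution (p11, p10, p01, p00) of (T1 correct, T2 correct) per group and
separation.

* At separations 0–2 the conditionals are flat at the published global
  means: AB 0.5588 / AM 0.4732 for CI, AB 0.8861 / AM 0.6989 for HC, so the
  model-implied global metrics equal those means exactly.
* The conditionals leave one free parameter, the scale p11, bounded by
  p11 · (1/AB + 1/AM − 1) ≤ 1. The default sets p11 at 0.9 of that bound —
  high enough that T1/T2 marginal accuracies are realistic for a
  suprathreshold letter task (CI ≈ 0.54/0.64, HC ≈ 0.65/0.83) while keeping
  all four joint cells strictly positive.
* Separations 4–8 carry a qualitative recovery shape only (CI conditionals
  rise monotonically toward ceiling, HC stay above 0.9); no published
  per-separation value exists in numeric form, and none is asserted.

CDT and Phototest scores are rounded normals clamped to their supports
([0, 7] and [0, ∞)), with means 5.69/6.56 (CDT) and 33.08/41.56 (Phototest)
and standard deviations recovered from the published standard errors via
sd = SEM·√n (1.77/0.96 and 5.88/3.21). Clamping (rather than resampling)
slightly compresses the CDT tail near the ceiling; the calibration property
below deliberately covers only the RSVP metrics, which clamping does not
touch.

**What the generator does not emulate:** age, sex and education structure;
within-participant fatigue or learning across the 70 trials (outcomes are
exchangeable given separation); any correlation between the cognitive-test
scores and the RSVP outcomes within a participant beyond what the shared
group label induces. Real data are likely noisier and more correlated, so a
classifier's accuracy on the synthetic cohort overstates what the same
procedure achieves clinically — the synthetic results validate the
machinery and the qualitative ordering of the methods, not the absolute
accuracy.

Verified generator properties (all in the test suite): per-separation AB/AM
recover the generating conditionals within ±0.02 at 10,000 trials per
separation; over 200 default cohorts the mean group means of global AB/AM
sit within 2 published SEMs of the published values; scores respect their
integer supports.

## Group statistics

Groups are compared with the Mann–Whitney U test using midranks for ties.
With n_ci + n_hc ≤ 25 (the study is 22) the two-sided p-value is exact:
a subset-sum dynamic programme over doubled midranks counts, across all
C(N, n_ci) assignments of the observed ranks, the outcomes at least as
extreme as the observed minimum U in either direction —
p = P(U ≤ u_min) + P(U ≥ n₁n₂ − u_min), capped at 1. This conditions on the
observed tie pattern and needs no symmetry assumption. Beyond 25 the
tie- and continuity-corrected normal approximation (scipy) is used; the
result records which method ran. The reported U follows the
minimum-of-the-two convention, so the common-language effect size — the
probability a random HC score exceeds a random CI score, ties counted half —
is recoverable as 1 − U/(n₁n₂). Significance is declared at 5% with no
multiple-testing correction, matching the original analysis.

## Classifiers

CI is always the positive class and every threshold rule is strict:
score **below** the cutoff ⇒ CI, so a score exactly at the cutoff
classifies HC.

1. **Fixed thresholds** — literature screening cutoffs: CDT < 6,
   Phototest < 29.
2. **Sequential** — CDT gate first; CDT passers are gated on the Phototest.
   Its CI set therefore contains the CDT rule's CI set.
3. **Learned global-AM threshold (LOOCV)** — per fold, the cutoff
   maximising training accuracy is chosen among midpoints of consecutive
   distinct scores plus one sentinel below the minimum and one above the
   maximum (finite stand-ins for "classify none"/"classify all"); ties
   break toward the smallest cutoff. The held-out participant is predicted
   with that fold's cutoff.
4. **Logistic regression (LOOCV, grid search)** — penalised logistic
   regression on the 14 AB/AM features, grid l1/l2 × C = 10⁻⁷ … 10⁷
   (30 points). Features are z-scored with training-fold statistics
   (penalised fits are scale-sensitive; per-fold scaling avoids leakage).
   Solvers leave the intercept unpenalised (lbfgs for l2, saga for l1),
   tolerance 1e-8, 10,000-iteration budget. The grid point with the highest
   LOOCV accuracy is selected and that accuracy reported — whole-grid
   selection, not nested CV, which matches reporting a single best
   hyperparameter pair and is optimistic by construction; a nested scheme
   would cost 22× more fits for a quantity the analysis does not report.

At extreme C the maximum-likelihood problem on a separable 21-point fold
has no finite optimum, so tolerance cannot be reached; `fit_logistic`
raises a `ConvergenceError` carrying the iteration count by default, and
the grid search opts out (`strict=False`) and uses the iteration-capped
solution, whose predictions are stable. Tie-breaks in the grid (stronger
penalty first, then l2) and in the threshold learner are deliberate
conventions, stated here because any choice is defensible.

## Evaluation

Confusion matrices count CI-positive outcomes; precision and recall are
macro averages (mean of the per-class values, classes weighted equally); a
per-class metric with an empty denominator contributes 0 with a warning.
The 95% interval around an accuracy treats the n predictions as Bernoulli
trials and inverts the score test — the Wilson interval — which reproduces
all four published intervals at 2-decimal rounding (a regression test keeps
this identification pinned; Wald and Clopper–Pearson do not reproduce
them). Display tables round to 2 decimals; the JSON report keeps full
precision. The full report (`report.build_report`) is deterministic given
the cohort: rerunning on the same cohort is byte-identical.

## Problem sizes

Default analyses use the study-sized cohort (22 participants × 70 trials).
The statistical property checks use: 10,000 trials per separation for
parameter recovery; 200 cohorts for calibration; 2,000 null simulations for
type-I control of the exact test (rejection rate ≤ 0.055 at α = 0.05);
5,000 Bernoulli simulations for Wilson coverage (≥ 93% at p = 0.7, n = 22);
and 50 seeded cohorts for the classifier-ordering check (grid-searched
logistic LOOCV accuracy ≥ fixed-threshold CDT accuracy in ≥ 90% of
replicates).

## Known limitations

* The synthetic cohort is cleaner than real data (see above), so
  end-to-end synthetic accuracies run high; only their ordering across
  methods is meaningful.
* Exact published p-values and U statistics are not reproducible without
  the raw per-participant scores; the pipeline reproduces the published
  quantities that are functions of published inputs (confusion-matrix
  metrics, Wilson intervals, effect sizes from U) and validates the rest by
  statistical properties.
* The whole-grid LOOCV selection reports an optimistically biased accuracy;
  this mirrors the reported analysis rather than best current practice.
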