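# Methods

This note documents the models, algorithms and design choices behind
`qcascreen`, in the order the pipeline runs them: synthetic cohort →
scale scoring → logistic regression → calibration → fsQCA.

## Synthetic cohort generator

The generator emulates a cross-sectional women's mental-health screening
survey. Covariates are drawn independently from configured marginal
distributions; the defaults reproduce the frequency table of the survey
the package models (e.g. 61.2% urban, 63.8% married, 44.6% with a
bachelor's degree, 96.8% non-smokers). Age follows a skew-normal
(shape 4, location 19.625, scale 18.298) left-truncated at 18 by
inverse-CDF sampling; the truncated distribution has mean 34.7, SD 11.1
and 15/50/85 percentiles near 23/33/47, matching a younger-skewed adult
cohort. Sleep is normal (7.3 ± 1.0 h) rounded to half hours and clipped
to 4–11 h.

Mental health is generated from two correlated standard-normal latent
distress factors (depressive, anxious). Each is a linear combination of
standardized covariates — protective loadings on self-rated health
(−0.30/−0.26), social support (−0.28/−0.22), sleep, marriage, education,
exercise and age; risk loadings on occupational stress (+0.22/+0.24),
smoking, drinking, chronic disease and recent illness — plus a noise pair
with correlation ρ (default 0.68). Scale items arise by
cumulative-threshold discretization: item j of case i is the count of
thresholds exceeded by `a·L_i + √(1−a²)·ε_ij` with loading a = 0.70
(CESD-10), 0.74 (GAD-7), 0.63 (SSRS components). The thresholds
(CESD 0.47/1.31/2.11; GAD 0.49/1.40/2.28; SSRS −1.48/−0.84/−0.10 with
two binomial source-count items) were calibrated once, by simulation at
n = 120,000, so the default cohort reproduces the survey's screening
structure: ≈ 16.7% depression-positive, ≈ 26.0% anxiety-positive,
≈ 67% of depression-positives also anxiety-positive, SSRS total
≈ 41 ± 7 with 10/50/90 percentiles near 31/43/49, and a moderate positive
rank correlation (ρ_S ≈ 0.6) between the two distress scores.

**Planted recipes.** For engine-validation experiments a cohort can be
built from an explicit condition-combination → outcome-propensity rule. A
respondent *matches* the recipe when every named condition lies on the
stated side of its calibration crossover (membership ≥ 0.5 — exactly the
rule that later assigns cases to truth-table rows); matching respondents
screen healthy with probability 0.99, others with baseline 0.70, and the
targeted latent factor is replaced by a well-separated two-level value so
the screening classification is essentially deterministic given the
Bernoulli draw. The crisp-match form was chosen deliberately: with a
crisp screening outcome, the fuzzy membership mass of non-matching cases
bounds any row's attainable consistency, and smoother propensity ramps
leave the planted row's consistency hovering at its detection threshold.
The reference recipe used in tests (married × educated × supported →
no depression) avoids conditions that heap a large probability mass
exactly at their crossover — self-rated health puts ≈ 40% of respondents
at Likert 3, which contaminates adjacent truth-table rows.

**What the generator does not emulate.** Covariates are mutually
independent (no age–marriage or education–income dependence); there is no
multi-stage geographic clustering, so the design effect of 2 used in the
sample-size arithmetic has no counterpart in the generated data; item
responses are exchangeable within a scale (no item-specific difficulty or
reverse-keyed wording effects); and missingness only appears when planted
explicitly. Passing tests therefore demonstrate the correctness of the
pipeline's computations and the recoverability of planted structure, not
the field validity of any substantive configuration.

## Scale scoring

CESD-10: sum of ten 0–3 items (0–30), screening positive at ≥ 10.
GAD-7: sum of seven 0–3 items (0–21), banded 0–4 normal / 5–9 mild /
10–14 moderate / 15–21 severe; mild or worse screens positive. SSRS: sum
of seven 1–4 Likert items, five 1–4 sub-parts of item 5, and items 6–7;
banded ≤ 22 low / 23–44 medium / ≥ 45 high. Items 6–7 are scored 0/1
(any source of support counts one point) by default, with a
`source_count` variant (0–9 per item, under which the scale spans 12–66)
because the instrument is scored both ways in the survey literature and
the two conventions are not mutually consistent with every published
range. CESD-10 items are scored as given; reverse-keying of items 5 and
8 is not applied by default since the emulated survey scores raw
frequencies.

## Logistic regression

Outcomes are the binary screening indicators. Categorical predictors use
declared reference levels (lowest category; "no"; low support);
continuous predictors (age, sleep) enter linearly. Fits are
maximum-likelihood (statsmodels `Logit`); odds ratios carry Wald 95%
intervals exp(β ± 1.96·SE), matching the OR (low–high) presentation
convention. Backward elimination removes, per step, the predictor whose
likelihood-ratio test (all its levels jointly) has the largest p-value
above 0.10, refitting until all survive; the order is logged and an empty
final model is reported as intercept-only. The LR-based removal stands in
for the "conditional" statistic of commercial packages; for models of
this size the two are practically indistinguishable. Perfect separation
and empty factor levels raise explicit errors naming the predictor.

## Calibration

Direct method: anchors (full membership, crossover, full non-membership)
map to log-odds +3/0/−3; between and beyond anchors the log-odds are
piecewise linear with per-segment slope 3/(anchor gap), then passed
through the logistic. This keeps memberships at the anchors fixed
(≈ 0.953 / 0.5 / 0.047) while handling asymmetric spacing such as sleep
6/7/8 versus age 23/33/47. Anchor selection follows the survey protocol:
90/50/10 percentiles for roughly symmetric continuous conditions (social
support), 85/50/15 for right-skewed ones (age, sleep), Likert 5/3/1 for
exercise and self-rated health (oriented so better health ⇒ higher
membership), the sample mean as the stress crossover (the low-stress
tail is too thin for the median convention), an equal-spaced six-value
set {0, 0.2, …, 1} for education, and pass-through for marital status.
Percentiles use linear interpolation between order statistics (numpy
default, "type 7"), fixed for reproducibility. After calibration a
constant 0.001 is added to any membership equal to 0.5 (conditions only;
the binary outcome never hits 0.5), guaranteeing each case a unique
truth-table row. The sufficiency outcome is membership in the
screen-negative set (1 = no symptoms); both polarities of every condition
are examined in the necessity analysis.

## fsQCA engine

Truth table: each case belongs to the corner where all its memberships
exceed 0.5; corner counts sum to n. A corner with fewer than the
frequency threshold (default 10, appropriate to n ≈ 3,000) is a
remainder; otherwise it is positive when its raw consistency
Σ min(m, y)/Σ m (over all cases, using fuzzy corner membership) reaches
the consistency threshold, else negative. Contradictory corners are kept
as negative, never dropped. PRI consistency is computed and reported but
does not drive assignment.

Minimization is Quine–McCluskey over the positive corners with don't-care
sets depending on the solution type (complex: none; parsimonious: all
remainders; intermediate: easy counterfactuals). The empty conjunction is
inadmissible — a configurational solution must name at least one
condition — so single-literal implicants do not merge away even when
every corner is positive or don't-care; primality is judged against
admissible generalizations. The prime-implicant chart takes essential
implicants first and completes them by exact branch-and-bound set cover;
when several minimum-cardinality covers exist, all are reported and the
lexicographically smallest (by condition order, present < absent <
don't-care) is canonical, making an ambiguity explicit that desktop QCA
tools resolve silently.

Easy counterfactuals: a remainder is admitted when it can be reached from
some observed positive corner by moving conditions only toward their
expected direction ("either" permits both). Default expectations are
theory-guided — self-rated health, social support, sleep, education and
marriage expected present, occupational stress absent, age and exercise
open — and overridable per run. A literal in an intermediate
configuration is core iff the same condition with the same polarity
occurs in a parsimonious implicant subsuming that configuration.

Metrics: per-configuration consistency Σ min(m, y)/Σ m and raw coverage
Σ min(m, y)/Σ y with m the configuration membership; unique coverage is
the drop in union coverage (union = elementwise max) when the
configuration is removed; solution consistency/coverage are computed on
the union membership.

## Thresholds and problem sizes

Survey-scale runs use frequency 10 and consistency 0.80, raised to 0.85
for the depression outcome, which sharpens its configuration set; the
necessity flag is strict (> 0.9). The default analysis cohort is
n = 3,063 (the survey's size); marginal-fidelity checks use n = 100,000
(±0.01 on categorical frequencies, ±0.2 years on mean age);
engine-recovery experiments use n = 3,000; the minimizer oracle runs 500
random truth tables with ≤ 5 conditions; regression coverage uses 500
replicates of n = 600 at a planted odds ratio of 2. These sizes make the
full suite run in well under a minute while keeping Monte-Carlo noise far
from every asserted margin.

## Known limitations

Solution-configuration counts after minimization are not mathematically
monotone in the consistency threshold (only the positive-corner set is);
the threshold-sweep check therefore holds by design of the planted
scenario, not as a theorem. The intermediate solution uses the
easy-counterfactual remainder filter described above, which is one of
several formulations of directional counterfactual analysis in the QCA
literature. Survey-weighted estimation, csQCA/mvQCA variants, and
robustness automation beyond threshold sweeps are out of scope.
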