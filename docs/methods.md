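# Methods

`tedclaims` re-implements, as a tested pipeline over synthetic data, the
validation of claims-based case-identification algorithms for thyroid eye
disease (TED): six rule-based phenotyping algorithms, a diagnostic-
performance framework, and a recursive-feature-elimination (RFE) consensus
feature-selection procedure for a gradient-boosted classifier. The linked
registry/claims dataset such validations run on is proprietary, so the
package ships a synthetic-data generator that emulates its statistical
structure, and every downstream stage is exercised against it.

## Synthetic linked cohort

The generator emulates a case-enriched validation cohort linking an
ophthalmology registry (which supplies a note-derived reference label) to
longitudinal claims:

* **Cohort composition.** Ground-truth TED status is Bernoulli with
  prevalence 0.72 (the enriched-cohort prevalence such linkages exhibit,
  not a population prevalence). Age at index is N(60.4, 14.5) years,
  clipped to [1, 100]; 76% of patients are female. Index dates are uniform
  over 2017–2023. Dates are integer day offsets from a fixed epoch
  (2016-01-01) internally; calendar rendering happens only at I/O.
* **Imperfect reference standard.** The registry label emulates an NLP
  note classifier with recall 0.91 and precision 0.90. True cases are
  labelled positive with probability equal to the recall; the
  false-positive probability for controls is solved analytically from
  precision = r·π / (r·π + q·(1−π)), so expected precision is exact at the
  cohort prevalence (empirical by default). Infeasible combinations (q
  outside [0, 1]) raise an error that reports the implied rate. At the
  default settings q ≈ 0.26, i.e. reference specificity ≈ 0.74 —
  consistent with a note-classifier false-positive rate in the low-20%
  range.
* **Per-code claim frequencies.** Each billing code has an occurrence
  profile: the probability of at least one claim within ±90, ±180 and
  ±365 days of the index date, separately for TED and non-TED patients.
  The shipped profile (`data/code_profile.yaml`) uses the published
  frequencies among confirmed TED patients for the top-20 codes per
  window (e.g. E05.00 at 32.3%/37.1%/42.4%). Codes that reach the
  published top-20 list in only some windows get the missing values by a
  0.85 nested-window ratio (the observed ratio for E05.00 is 0.87/0.875),
  keeping window probabilities monotone. Non-TED probabilities default to
  0.6× the TED values, except TED-specific signs (e.g. exophthalmos
  H05.20) which are explicitly near zero. A small set of TED eye-sign
  codes (diplopia, lid retraction, bilateral exophthalmos, orbital
  disorders, …) is added at package-chosen frequencies so the rule
  algorithms have realistic inputs; these are simulator defaults, not
  published values. Configurable noise codes (default 25) occur with
  identical probability in both classes and carry no signal.
* **Sampling mechanism.** For each patient × code, one uniform draw
  selects a nested band (±90; 91–180; 181–365 days; or absent), and claims
  are placed uniformly inside the band, with Poisson-distributed repeat
  claims in the same band. Because bands partition the windows, the
  configured window probabilities are exactly recoverable and window
  nesting (codes within ±90 ⊆ ±180 ⊆ ±365) holds by construction.
* **Enrollment.** Each patient receives one coverage span containing the
  index lookback and every claim (a claims database observes only covered
  periods, so claims are generated only inside spans). Pre/post-index
  coverage lengths are 365 + Exp and 30 + Exp days with mean set by
  `enrollment_mean_span_days` (default 1095). A configurable fraction
  (default 8%) has the span start moved to 30–330 days before index —
  these patients fail the continuous-enrollment criterion, and any claims
  before the shortened start are dropped to preserve the observability
  guarantee. Consequence: configured window frequencies are recoverable
  exactly only among *fully observed* patients (enrollment covering
  ±365 days of index); `fully_observed_mask` identifies them and the
  recovery tests condition on it.
* **Proxy index dates.** Controls have no TED diagnosis to anchor an index
  date, so each non-TED patient's index is re-anchored to first record
  plus a gap resampled from the TED patients' empirical (index − first
  record) gap distribution, clipped into the patient's observed record
  range. The empirical-resampling default is overridable by any interval
  sample. Patients with no claims cannot receive a proxy and are flagged
  for downstream exclusion.

What the generator does **not** emulate: payer adjudication and costs,
pharmacy fills beyond code occurrence, record linkage/tokenization,
regional or clinician coding variation, and comorbidity correlation
structure (codes occur independently given class). Passing tests therefore
demonstrate that the machinery is correct under the stated statistical
structure, not that any algorithm achieves particular operating
characteristics on real claims.

## Cohort construction

Inclusion mirrors the standard design: age ≥ 18 at index; ≥ 365 days of
continuous enrollment before the index date ("12 months" is interpreted as
365 days; the lookback excludes the index day itself); an evaluated
reference label. Gap tolerance defaults to 0 days (the design says
"continuous") but is configurable. Exclusion reasons are evaluated in a
fixed order (age → enrollment → reference evaluated) so each excluded
patient carries exactly one first-failing reason and the attrition log is
deterministic; the per-criterion layout of the log is this package's
convention. Coding-pattern windows (±90/±180/±365 days) include the index
day.

The minimum number of reference-positive patients for estimating a
sensitivity p to margin E at confidence 1−α is the smallest n with
z·√(p(1−p)/n) ≤ E, i.e. ⌈z²p(1−p)/E²⌉; at p = 0.70, 95% confidence,
E = 0.025 this gives n = 1291. Train/test splitting is a seeded
permutation, optionally stratified on the reference label.

## Rule-based phenotyping

Six declarative algorithms over diagnosis claims (code lists are editable
YAML data, not code; entries support trailing-`*` prefix wildcards and are
compared dot-insensitively after uppercasing):

1. any claim in the broad eye-sign list (13 concepts), no hyperthyroidism
   requirement;
2. ≥1 hyperthyroidism claim and ≥1 claim in the core sign list
   (exophthalmos, diplopia, lid retraction, strabismus, orbital
   inflammation) within 12 months;
3. algorithm 2 plus ocular pain and keratoconjunctivitis;
4. algorithm 2 with the full broad list;
5. hyperthyroidism plus a narrow list (exophthalmos, lid retraction,
   periorbital edema, eyelid erythema) within 12 months;
6. algorithm 2 without the timing restriction.

"Within 12 months" is |Δ| ≤ 365 days, inclusive, in either temporal order;
same-day claims qualify. The co-occurrence test is a sorted two-pointer
sweep, property-tested against an all-pairs brute-force oracle. By
construction the positive sets nest (alg2 ⊆ alg3 ⊆ alg4 ⊆ alg1 and
alg2 ⊆ alg6), mirroring the sensitivity ordering such relaxations must
produce. Algorithms see the patient's entire claims history by default
(algorithm 6 is defined without a lookback bound); an index-anchored
observation window is available. The shipped code lists are plausible
ICD-10-CM/ICD-9 families per concept and are expected to be revised
against any authoritative list; every test is parameterized by the
code-list file so lists are data.

## Diagnostic metrics

Standard 2×2 metrics with explicit conventions:

* PLR = sens/(1−spec), NLR = (1−sens)/spec; F1 = 2TP/(2TP+FP+FN).
* PPV/NPV transport to an arbitrary prevalence π by Bayes' rule:
  PPV = sens·π / (sens·π + (1−spec)(1−π)), NPV = spec(1−π) /
  ((1−sens)π + spec(1−π)); at the empirical prevalence these coincide
  with the raw-table values.
* Confidence intervals (stated in output metadata): Wilson score for
  proportions; log method for likelihood ratios, with
  SE(ln PLR) = √((1−sens)/(sens·n₁) + spec/((1−spec)·n₀)) and the NLR
  analogue; a normal approximation for AUC. These are standard closed-form
  choices; they are conventions of this package, not reproductions of any
  published interval method.
* AUC equals the tie-corrected Mann–Whitney statistic (checked against
  exhaustive pair counting).
* Threshold sweep: predicted positive iff probability ≥ threshold (ties
  positive — fixed for determinism), default grid 0.60–0.85 in steps of
  0.05; sensitivity is nonincreasing and specificity nondecreasing in the
  threshold.
* Undefined metrics (zero denominators) surface as explicit markers naming
  the empty cell, never as silent zeros; a zero false-positive cell with
  positive TP yields PLR = +∞.
* Report rounding: percentages to 1 decimal, ratios to 2.

### Internal consistency of the published validation tables

Every derived metric in the published per-algorithm and per-threshold
tables is a deterministic function of that row's sensitivity, specificity
and the cohort composition (66,396 reference-positive / 25,754
reference-negative, prevalence 66,396/92,150 ≈ 0.7205). The package stores
the published rows as data (`data/reported_operating_points.csv`) and
recomputes PLR, NLR, PPV, NPV and F1 from each row; all 90 derived values
agree within one unit in the last printed digit (absorbing the source
table's own rounding, e.g. a recomputed PLR of 2.46 against a printed
2.47). Where the running text and the table disagree for one threshold
(86.6/29.9 vs 86.8/29.4 at 0.60), the table values are used.

## ML feature pipeline

* **Features**: binary indicators of ≥1 occurrence per diagnosis/procedure
  code (NDC drug codes excluded) in the baseline window
  [index − 730, index], index day included (on-index claims are
  observable). Columns are deduplicated after normalization.
* **Screening**: a code is retained iff its prevalence is ≥ 0.1% in the
  TED class *and* in the non-TED class, computed on training rows only.
  An expert-curated code list can be merged by set union (the bookkeeping
  reports data-driven / expert-only / overlap counts). ICD-10 chapters
  X/Y/Z (external causes; factors influencing health status) are removed
  as utilization rather than disease signal.
* **RFE**: each iteration measures the current set's stratified 5-fold CV
  AUC, refits for importances (recomputed every iteration), and drops the
  lowest-importance 20% of features (≥1). The unstated details are fixed
  as: stop after 2 consecutive iterations without an AUC gain > 1e-4; the
  selected subset is the argmax-AUC iterate, hard-capped at 201 features
  by importance.
* **Grid and consensus**: the default tuning grid is 3 values on each of
  learning rate, tree depth, boosting rounds and L2 strength (3⁴ = 81
  configurations), each RFE run seeded deterministically from the base
  seed and configuration index. Consensus ranks codes by selection
  frequency across runs, then mean importance, then the code string as a
  deterministic tie-break (the ranking key beyond frequency is this
  package's convention); the top 29 form the simplified feature set.
* **Simplified model**: a 10-tree gradient-boosted model over the
  consensus codes only; boosting rounds equal the tree count.
* **Learner**: a pluggable contract (fit / predict-probability / feature
  importance); the default backend is LightGBM configured single-threaded
  and deterministic. Tests also drive the pipeline with a cheap
  correlation-scoring stub, so pipeline logic is checked independently of
  any particular booster.
* **Hygiene**: screening and selection never see test rows; the evaluation
  entry point raises on any train/test patient overlap; the whole pipeline
  is bit-reproducible under one base seed (per-stage seeds derive from a
  stable hash of the stage name).

## Problem sizes and statistical checks

Module tests run at n = 500–10,000 patients; generator parameter recovery
uses n = 50,000; the planted-signal study uses 2 informative features
(class-conditional rates 0.6 vs 0.1) among 48 noise features at n = 2,000
over 20 seeded runs with a compact 2-configuration grid per run; the
analysis drivers use n = 20,000 with a compact grid. These sizes make the
binomial error bars tight enough for 3-standard-error checks while keeping
the full suite fast.

Two statistical conventions worth noting. First, single pre-specified
recovery checks (prevalence, reference precision/recall, the named E05.00
frequency) use a 3-standard-error band. The blanket sweep over every
profile code × window is ~100 simultaneous binomial comparisons, for which
a per-comparison 3-SE band would be exceeded by chance alone in roughly a
quarter of runs; that sweep therefore uses the Bonferroni-adjusted
critical value at the same family-wise error rate (≈4.2 SE per
comparison). Second, frequency recovery conditions on fully observed
patients, because enrollment truncation censors claims by design.

## Known limitations

* The shipped eye-sign code lists are package defaults, not an
  authoritative clinical appendix; results with other lists will differ
  (the engine is list-agnostic).
* Codes occur independently given disease class, so the synthetic ML task
  is easier than real claims, where correlated utilization codes can
  shadow disease signal; consensus-selection behaviour on real data is
  not established by these tests.
* The simulated reference standard flips labels independently per patient;
  real note-classifier errors correlate with disease severity and
  documentation practices, which biases validated sensitivity in ways the
  simulation does not reproduce.
* Accuracy estimates are *not* corrected for reference-standard
  misclassification; the generator makes the phenomenon simulatable, but
  no correction method is implemented.
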