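# Methods

## Problem and model

Two registries describe overlapping patients at one hospital: a surgical
registry with full identifiers (names, medical record number, date of
birth) and an ICU registry whose direct identifiers are removed before
central collation, leaving the SLK-581 statistical linkage key plus
non-identifying variables (episode dates, age, sex). The linkage target
is each surgical procedure's *subsequent* ICU admission: an admission
more than two days from the procedure date is not an acceptable partner
even when it belongs to the same person, because ICU registries capture
mostly first-24-hour physiology that is only meaningful temporally
adjacent to the procedure.

Four strategies are implemented.

### Probabilistic scoring (strategies 1 and 3)

Each candidate pair receives the sum of per-field weights: agreement
adds the positive weight, disagreement the negative, a missing value on
either side adds nothing. The shipped weights are surname 7/−3,
forename 5/−2, MRN 15/−5, SLK-581 10/−2 and the procedure-vs-ICU
admission date 2/−40 with a ±2-day caliper; the acceptance cutoff is a
total score of 1. A single total-score cutoff across all configured
fields is used; treating the key in a separate pass with its own cutoff
would be an alternative reading of the source material, but the single
cutoff is the simplest consistent one and is what the config file
expresses. Because the positive weights sum to 39 < 40, a pair outside
the caliper can never reach the cutoff, so candidate generation
restricted to the caliper window is an exact optimization, not a
blocking approximation. Text fields compare equal after the same
normalization the key builder uses (uppercase, non-alphanumerics
stripped); string-distance weights are deliberately absent — near-misses
are the clerical-review problem this package does not model.

Accepted pairs are resolved one-to-one by exact optimal assignment:
maximize the number of accepted pairs, then total score (a per-pair
bonus larger than any attainable score spread reduces this to one
`linear_sum_assignment` solve). A greedy descending-score pass was
considered and rejected: greedy can be cardinality-suboptimal (scores
a–1: 10, a–2: 8, b–1: 9 with b having no other candidate leave b
unmatched under greedy), and the optimal assignment is what the
brute-force oracle in the test suite enumerates. The solve is
deterministic for the sorted input order used; among equal-total-score
optima the solver's internal order decides, which is reproducible
run-to-run.

Strategy 3 is the same machinery restricted to `{slk, date}`; an
equivalent single-stage deterministic plan ({SLK, admission ±2}) is
shipped and tested for pair-set equality.

### Staged deterministic matching (strategies 2 and 4)

An ordered list of passes, each naming required fields from {SLK,
ICUAdmDt, ICUDisDt, HospAdmDt, HospDisDt, Age, Sex}, where ICUAdmDt
compares the surgery registry's procedure date with the ICU registry's
admission date. Stage 1 demands exact agreement; every later stage
applies ±2 days (dates) / ±2 years (age). The source hierarchy states
that stage 1 is tight and criteria "loosen" afterwards without printing
a per-stage tolerance schedule, so the tolerance is a per-stage flag
with this default. Within a stage, over not-yet-matched records only,
a pair is accepted iff each of its two records has exactly one agreeing
counterpart; ambiguous records are deferred to later stages rather than
dropped or guessed, so a stage can only err when a *unique wrong*
candidate appears while the true one is corrupted. A field missing on
either side fails any stage requiring it. The 9-stage (key-free) and
12-stage (keyed) hierarchies are shipped verbatim as `strategy2_plan()`
/ `strategy4_plan()`.

One structural consequence, visible in the targeted-error tests: in the
12-stage plan several late keyed stages (8–11) are field-supersets of
earlier keyed stages (2–4), so an error pattern compatible with stage 9
is in fact caught at stage 2 — those late stages act as fallbacks
reachable only when the key or admission date degrade in particular
combinations. In the 9-stage plan every stage is the first compatible
one for its own complement, and errors confined to the fields a stage
omits are recovered exactly there.

The surgical registry must carry the ICU discharge date for ICUDisDt to
be comparable at all; `SurgeryRecord.icu_dis_date` holds it (optional —
records without an ICU episode leave it empty and fail any stage that
needs it).

### Evaluation

A result pair is a true match iff it equals a gold pair; accepted pairs
whose surgery record has a different or no gold partner are false
positives; gold pairs absent from the result are missed links. The
match-rate denominator is the gold-eligible count (procedures with a
matchable episode), not the registry size; both appear in reports.
Percentages round half away from zero to one decimal. Between-strategy
match rates are compared by Pearson chi-square on the 2×2 table without
continuity correction (correction available as an option); cohort
characteristics use Student's t (two groups) or one-way ANOVA, Pearson
chi-square for categorical variables, and Wilcoxon rank-sum or
Kruskal–Wallis for the skewed mortality-risk score. Degenerate
comparisons (zero variance, empty category margins) report no p-value
rather than a fabricated one.

## Synthetic registry generator

The generator emulates a 21-month single-centre cohort: 1283 surgical
procedures and enough emergency-style non-surgical ICU admissions to
total ≈5179 ICU rows. Per-patient quantities:

* **Stratum.** Patients planted with a pathology that makes them
  unmatchable — no ICU episode (rate 10/1283) or an ICU admission 3–10
  days *before* the procedure (rate 31/1273) — form the hard-to-match
  stratum; everyone else is clean. Gold pairs exist only for clean
  patients, whose episode starts 0–2 days after the procedure
  (delay distribution 0.80/0.15/0.05 — the within-caliper delay split is
  a modelling choice, configurable, as the source reports none).
* **Covariates by stratum** (clean / hard): age normal 63.5 (12.7) /
  53.6 (15.1) years; male 77.3% / 80.5%; urgent procedure 22.0% /
  58.5%; procedure-type mix from the reported matched / unmatched
  counts; 30-day mortality risk log-normal with median 1.08% / 7.50%
  and log-sd fitted from the reported IQRs (0.847 / 1.771).
* **Stays.** Hospital admission 0–14 days before an elective procedure
  (0–2 urgent); ICU length of stay 1–5 days; ward tail 2–14 days; with
  probability 0.05 a second ICU episode 2–7 days after the first, inside
  the same hospital stay. Non-surgical admissions are emergency-shaped:
  ICU entry ~Exp(1.5) days after hospital admission, ICU stay
  1+Exp(3) days, ward tail Exp(7) days. These forms are artifact
  choices — the source reports no stay distributions — picked to make
  the hospital-date fields informative.
* **Identity.** Names from a packaged synthetic pool (disjoint halves
  for surgical vs non-surgical patients), unique 7-digit MRNs, date of
  birth consistent with age at procedure.

Error processes, applied to the ICU table only (the identified registry
is treated as the cleaner source): single-character name typos (rate
0.012 per name field), single-digit MRN typos (0.010), single-digit
date typos that keep the date valid (0.010 per date field, including
date of birth), hospital admission *and* discharge shifted 3–30 days as
if recorded from a transfer episode (0.07), and complete blanking of
surname/forename/MRN (47/5179). The ICU-side key is rebuilt from the
*corrupted* identity and never perturbed directly, so key errors arise
only from upstream name/birth-date errors — the mechanism by which
duplicate keys arise in practice. Date typos that would break record
validity (discharge before admission) are dropped rather than clamped.

The transfer-shift process is the one component not reducible to
independent single-digit typos: every stage of the key-free hierarchy
requires at least one hospital-date field, so with independent typos
alone the key-free strategy could never lose more pairs than the
key-based one, contradicting the phenomenon under study (errors
concentrated in multiple hospital-date fields). Its 0.07 rate is what
calibrates the key-free strategy's ≈7% miss rate.

**Identifiability by construction.** Clean (pre-corruption) stays are
rejection-sampled so that no ICU episode lies within the ±2-day
matching tolerance of another patient's surgery profile on all four
date fields simultaneously (and vice versa). Without this, ±2-day
windows over ~5200 admissions in 640 days occasionally produce twin
stays, and the deferral rule then starves genuinely clean pairs — an
identification failure caused by the generator rather than by any error
process. With it, an error-free run is recovered exactly, by every
strategy, for every seed, and misses under the calibrated error model
are attributable to the injected errors alone.

What the generator does **not** emulate: real name frequency
distributions (keys collide less often than in practice), casemix beyond
the reported summary profile, multi-site structure, admission *times*
(dates only), and correlated data-entry error bursts beyond the
transfer-shift process. Passing tests therefore show the strategies'
relative behaviour under a controlled, plausibly calibrated error
model — not their absolute performance on any real registry pair.

## Behaviour under the calibrated defaults

Across seeds the mean recovery ordering is stable: full identifiers
(≈99.9%) ≥ staged+key (≈99.7%) ≥ key+date (≈98%) ≥ staged key-free
(≈92.5%), with the key-free strategy's misses dominated by the
transfer-shifted hospital dates and the key strategies' misses by
name/birth-date typos corrupting the key. The probabilistic strategies
accept essentially no false pairs (the caliper plus negative weights
reject strangers). The staged key-free strategy, by contrast, accepts a
few dozen false pairs per cohort at its loosest stages: when a record's
true episode is corrupted and exactly one coincidental stranger fits a
three- or four-date window, the uniqueness rule is satisfied by the
wrong pair. This is a real failure mode of loose deterministic passes
on imperfect data; the clean single-centre data the design originates
from did not exhibit it, and the error-free configuration here
reproduces that zero-false-positive behaviour by design.

## Numerical and interface choices

* Dates are ISO-8601 in files; all arithmetic is whole days. Ages are
  integer years. Sex serializes as M/F/U; the key maps it to 1/2/9.
* Registry files are flat CSV with fixed headers; strategy config is a
  flat `key = value` text file whose omitted keys keep the published
  weights; experiment configs are YAML.
* Assignment ties (equal total score) resolve by solver order over
  lexicographically sorted ids; stage candidates are processed in
  sorted id order — both make reruns byte-identical.
* The relaxed per-character key comparison (fraction of the 14
  positions agreeing) is exposed as `slk_partial_agreement` only; no
  shipped strategy uses it.
* Multi-part surnames are concatenated before indexing ("DE LA CRUZ" →
  "ELACRUZ" positions 2,3,5 → "EL?"): a documented artifact convention,
  not a claim about any registry's practice.
* Generator validity rules (episode within hospital stay, discharge
  after admission) are enforced after every perturbation by dropping
  offending typos, so emitted files always parse back.

## Known limitations

* Weights are fixed inputs; no EM estimation of match probabilities and
  no clerical-review loop.
* The false-positive rate of the key-free staged strategy under the
  default error model has no external calibration target.
* Key privacy machinery (hashing, encryption) is out of scope.
* The 0.07 transfer-shift rate and the typo rates are calibrated to
  reproduce one cohort's miss pattern; other registry pairs will need
  their own `ErrorModel`.
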