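# regilink

Linking episodes between two hospital registries when one of them no
longer carries names: `regilink` implements and compares four
record-linkage strategies between a fully identified cardiac-surgery
registry and a deidentified intensive-care registry that carries the
Australian **SLK-581** statistical linkage key, together with a synthetic
dual-registry generator that provides a known gold standard and
configurable data pathologies.

It is written for registry custodians, data-linkage units and
health-services researchers who need to quantify what a linkage key buys
over non-identifying variables — and what both lose against full
identifiers — on data whose error processes they control.

## The linkage strategies

**SLK-581** is the 14-character key defined by the Australian Institute
of Health and Welfare: characters 2, 3, 5 of the family name, characters
2, 3 of the given name, the date of birth as `DDMMYYYY`, and a sex code
(1 male, 2 female, 9 unknown). Short names pad with the digit `2`;
wholly missing names code as `999`/`99`. Names are uppercased and
stripped of punctuation before indexing, so `O'Brien-Smith` and
`obrien smith` yield the same key.

**Strategy 1 — probabilistic, full identifiers.** Candidate pairs within
a ±2-day caliper of procedure vs ICU-admission date are scored by
additive field weights:

| field     | agree | disagree |
|-----------|------:|---------:|
| surname   |   +7  |   −3     |
| forename  |   +5  |   −2     |
| MRN       |  +15  |   −5     |
| SLK-581   |  +10  |   −2     |
| date (±2) |   +2  |  −40     |

Missing fields contribute 0; pairs scoring ≥ 1 enter an exact one-to-one
assignment (maximum accepted pairs, then maximum total score). The −40
date weight guarantees no out-of-caliper admission is ever accepted.

**Strategy 2 — staged deterministic, non-identifying variables.** Nine
sequential passes over {procedure/ICU admission date, ICU discharge,
hospital admission, hospital discharge, age, sex}: pass 1 exact, later
passes ±2 days/years on progressively smaller field subsets. Matched
records leave the pool; a record agreeing with more than one candidate at
a pass is deferred, never guessed.

**Strategy 3 — SLK-581 + admission date.** The probabilistic scorer
restricted to the key and the date caliper.

**Strategy 4 — staged deterministic + SLK-581.** Twelve passes mixing
the key into the stage hierarchy of strategy 2.

The synthetic generator emulates a single-centre linkage problem
(~1283 procedures, ~5179 ICU admissions over 21 months) with blanked
identities, planted never-matchable records (no ICU episode, or a
pre-operative ICU admission outside the caliper), single-character name
typos, single-digit date typos, transfer-shifted hospital dates and
repeat ICU episodes — and emits the true pairing for evaluation
(match rate, false positives, missed links, matched-vs-unmatched cohort
tables with t/ANOVA, chi-square and rank tests).

## Worked example

```python
from regilink import ExperimentConfig, run_experiment

summary = run_experiment(ExperimentConfig(seeds=(0, 1, 2)))
print(summary.groupby("strategy")["match_rate_pct"].mean().round(1))
```

prints

```
strategy
strategy1    100.0
strategy2     92.1
strategy3     97.9
strategy4     99.7
```

— the mean percentage of gold-standard pairs each strategy recovers over
three synthetic cohorts at the calibrated error rates. Full identifiers
recover essentially everything; dates/age/sex alone lose the ~7% of
records whose hospital dates were recorded from a transfer episode; the
SLK-581 key recovers most of those, alone (strategy 3) or combined with
the staged match (strategy 4). Per-seed detail, accepted pairs with
their score or accepting stage, and the registries themselves are
written to `out_dir` when one is set.

The same pipeline is scriptable from a shell:

```sh
regilink simulate --seed 7 --out data/
regilink link --method strategy4 --surgery data/surgery.csv --icu data/icu.csv --out pairs.csv
regilink evaluate --pairs pairs.csv --gold data/gold.csv --surgery data/surgery.csv
```

and `examples/` holds one narrative script per capability.

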