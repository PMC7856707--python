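"""Simulate → link with all four strategies → evaluate, over several seeds.

Reproduces the four-way comparison on synthetic registries at the
calibrated study conditions (~1283 procedures, ~5179 ICU admissions,
blanked identities, planted no-ICU and pre-operative admissions, typos,
transfer-shifted hospital dates).  Expected ordering of mean recovery:
full identifiers ≥ staged+SLK ≥ SLK+date ≥ staged deidentified-only.
"""

from regilink import ExperimentConfig, run_experiment

cfg = ExperimentConfig(seeds=(0, 1, 2))
summary = run_experiment(cfg)

print(summary.to_string(index=False))
print()
means = summary.groupby("strategy")["match_rate_pct"].mean().round(1)
print("mean match rate (% of gold-eligible procedures):")
print(means.to_string())
# strategy1 uses full identifiers and recovers essentially everything;
# strategy2 (dates/age/sex only) loses the records whose hospital dates
# were recorded from a transfer episode; the SLK-581 key recovers most
# of those (strategies 3 and 4).
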