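"""End-to-end experiment: simulate → link (four strategies) → evaluate.

Strategy names:

* ``strategy1`` — probabilistic on surname/forename/MRN/SLK plus the
  admission-date caliper (the full-identifier, gold-standard-recovery run;
  the generator always knows the identifiers, exactly as the identified
  hospital extract did);
* ``strategy2`` — 9-stage deterministic on non-identifying variables;
* ``strategy3`` — probabilistic restricted to SLK + admission date;
* ``strategy4`` — 12-stage deterministic with SLK-581 added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .deterministic import run_stages, strategy2_plan, strategy4_plan
from .evaluation import EvalReport, evaluate
from .probabilistic import LinkageResult, link_probabilistic
from .records import IcuRecord, LinkConfig, SurgeryRecord, write_pairs, write_registry
from .synthetic import CohortParams, ErrorModel, generate, write_gold

log = logging.getLogger("regilink")

STRATEGIES = ("strategy1", "strategy2", "strategy3", "strategy4")


@dataclass(frozen=True)
class ExperimentConfig:
    cohort: CohortParams = field(default_factory=CohortParams)
    errors: ErrorModel = field(default_factory=ErrorModel)
    link: LinkConfig = field(default_factory=LinkConfig)
    strategies: tuple[str, ...] = STRATEGIES
    seeds: tuple[int, ...] = (0,)
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if not self.strategies:
            raise ValueError("at least one strategy is required")
        if not self.seeds:
            raise ValueError("at least one seed is required")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        """Build a config from a YAML mapping with optional ``cohort``,
        ``errors``, ``link``, ``strategies``, ``seeds`` and ``out_dir``
        sections; omitted keys keep the calibrated defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "cohort" in raw:
            kwargs["cohort"] = CohortParams(**raw["cohort"])
        if "errors" in raw:
            kwargs["errors"] = ErrorModel(**raw["errors"])
        if "link" in raw:
            link_raw = dict(raw["link"])
            if "fields" in link_raw:
                link_raw["fields"] = tuple(link_raw["fields"])
            kwargs["link"] = LinkConfig(**link_raw)
        if "strategies" in raw:
            kwargs["strategies"] = tuple(raw["strategies"])
        if "seeds" in raw:
            kwargs["seeds"] = tuple(int(s) for s in raw["seeds"])
        if "out_dir" in raw:
            kwargs["out_dir"] = Path(raw["out_dir"])
        return cls(**kwargs)


def link_strategy(
    name: str,
    surgery: list[SurgeryRecord],
    icu: list[IcuRecord],
    cfg: LinkConfig | None = None,
) -> LinkageResult:
    """Run one named strategy over in-memory registries."""
    cfg = cfg or LinkConfig()
    if name == "strategy1":
        return link_probabilistic(surgery, icu, cfg)
    if name == "strategy3":
        return link_probabilistic(surgery, icu, cfg.restricted(("slk", "date")))
    if name == "strategy2":
        return run_stages(surgery, icu, strategy2_plan(), cfg)
    if name == "strategy4":
        return run_stages(surgery, icu, strategy4_plan(), cfg)
    raise ValueError(f"unknown strategy {name!r}")


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Simulate, link and evaluate for every seed × strategy.

    Returns the summary (one row per seed × strategy: matched, false
    positives, missed links, match rate).  When ``cfg.out_dir`` is set,
    per-seed registries, gold standard, accepted pairs and the combined
    ``summary.csv`` are written beneath it.
    """
    rows = []
    for seed in cfg.seeds:
        surgery, icu, gold = generate(cfg.cohort, cfg.errors, seed=seed)
        log.info("seed %d: %d surgery records, %d ICU records, %d gold pairs",
                 seed, len(surgery), len(icu), gold.n_eligible)
        seed_dir = None
        if cfg.out_dir is not None:
            seed_dir = Path(cfg.out_dir) / f"seed_{seed}"
            seed_dir.mkdir(parents=True, exist_ok=True)
            write_registry(surgery, seed_dir / "surgery.csv")
            write_registry(icu, seed_dir / "icu.csv")
            write_gold(gold, seed_dir / "gold.csv")
        for strategy in cfg.strategies:
            result = link_strategy(strategy, surgery, icu, cfg.link)
            report: EvalReport = evaluate(result, gold, strategy=strategy)
            log.info("seed %d %s: matched %d/%d (%.1f%%), FP %d, FN %d",
                     seed, strategy, report.n_matched_true, report.n_eligible,
                     report.match_rate_pct, report.n_false_positive,
                     report.n_false_negative)
            if seed_dir is not None:
                write_pairs(
                    ((s, i, strategy, prov) for s, i, prov in result.pairs),
                    seed_dir / f"pairs_{strategy}.csv",
                )
            rows.append({
                "seed": seed,
                "strategy": strategy,
                "n_eligible": report.n_eligible,
                "n_matched_true": report.n_matched_true,
                "n_false_positive": report.n_false_positive,
                "n_false_negative": report.n_false_negative,
                "match_rate_pct": report.match_rate_pct,
            })
    summary = pd.DataFrame(rows)
    if cfg.out_dir is not None:
        Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
        summary.to_csv(Path(cfg.out_dir) / "summary.csv", index=False)
    return summary
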