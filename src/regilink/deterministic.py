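"""Sequential multi-stage deterministic matching.

Each stage names a subset of comparison fields; over the records still
unmatched, every (surgery, ICU) pair agreeing on all of the stage's fields
is formed, and a pair is accepted only when both of its records have
exactly one agreeing counterpart at that stage.  Ambiguous records are
deferred — they remain available to later, usually looser, stages — so a
stage can never create a false positive by arbitrary choice.  Records
accepted at stage *k* are excluded from every later stage.

Field semantics (surgery side vs ICU side):

====  =======================================================
SLK        key built from the surgery registry's identifiers vs the
           ICU registry's stored key (exact comparison)
ICUAdmDt   procedure date vs ICU admission date
ICUDisDt   ICU discharge date (recorded by both registries)
HospAdmDt  hospital admission dates
HospDisDt  hospital discharge dates
Age        integer ages
Sex        sex codes (unknown counts as missing)
====  =======================================================

Stage 1 of each shipped plan demands exact agreement; later stages allow
±2 days on dates and ±2 years on age (sex and SLK are always exact).
Two plans are shipped: a 9-stage plan over the six non-identifying
variables, and a 12-stage plan that adds the SLK-581 key.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from datetime import date, timedelta
from itertools import product

from .probabilistic import LinkageResult, surgery_slk
from .records import IcuRecord, LinkConfig, Sex, SurgeryRecord
from .slk581 import slk_agree

STAGE_FIELDS = ("SLK", "ICUAdmDt", "ICUDisDt", "HospAdmDt", "HospDisDt", "Age", "Sex")
DATE_FIELDS = ("ICUAdmDt", "ICUDisDt", "HospAdmDt", "HospDisDt")


@dataclass(frozen=True)
class StageSpec:
    """One matching pass: the fields that must all agree, and whether the
    ±2 day/year tolerance applies to its date and age comparisons."""

    stage_number: int
    required_fields: tuple[str, ...]
    tolerant: bool = True

    def __post_init__(self) -> None:
        if self.stage_number < 1:
            raise ValueError("stage_number must be >= 1")
        if not self.required_fields:
            raise ValueError("a stage needs at least one required field")
        unknown = set(self.required_fields) - set(STAGE_FIELDS)
        if unknown:
            raise ValueError(f"unknown stage fields: {sorted(unknown)}")


@dataclass(frozen=True)
class StagePlan:
    name: str
    stages: tuple[StageSpec, ...]

    def __post_init__(self) -> None:
        numbers = [st.stage_number for st in self.stages]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError("stage numbers must be strictly increasing")


def _plan(name: str, field_lists: list[str]) -> StagePlan:
    stages = tuple(
        StageSpec(k, tuple(fields.split()), tolerant=(k > 1))
        for k, fields in enumerate(field_lists, start=1)
    )
    return StagePlan(name, stages)


def strategy2_plan() -> StagePlan:
    """Nine passes over the six non-identifying variables, loosening from
    full agreement down to the three most discriminating dates."""
    return _plan("strategy2", [
        "ICUAdmDt ICUDisDt HospAdmDt HospDisDt Age Sex",
        "ICUAdmDt ICUDisDt HospAdmDt HospDisDt Age",
        "ICUAdmDt ICUDisDt HospAdmDt HospDisDt Sex",
        "ICUAdmDt ICUDisDt HospAdmDt Age Sex",
        "ICUAdmDt ICUDisDt HospDisDt Age Sex",
        "ICUAdmDt HospAdmDt HospDisDt Age Sex",
        "ICUDisDt HospAdmDt HospDisDt Age Sex",
        "ICUAdmDt ICUDisDt HospAdmDt HospDisDt",
        "ICUAdmDt ICUDisDt HospAdmDt",
    ])


def strategy4_plan() -> StagePlan:
    """Twelve passes combining the SLK-581 key with the non-identifying
    variables; stages 5-7 repeat the strongest key-free combinations so
    records whose key is corrupted can still match."""
    return _plan("strategy4", [
        "SLK ICUAdmDt ICUDisDt HospAdmDt HospDisDt Age Sex",
        "SLK ICUAdmDt ICUDisDt HospAdmDt",
        "SLK ICUAdmDt ICUDisDt",
        "SLK ICUAdmDt",
        "ICUAdmDt ICUDisDt HospAdmDt HospDisDt Age Sex",
        "ICUAdmDt ICUDisDt HospAdmDt HospDisDt Age",
        "ICUAdmDt ICUDisDt HospAdmDt HospDisDt Sex",
        "SLK ICUAdmDt ICUDisDt HospAdmDt HospDisDt Sex",
        "SLK ICUAdmDt ICUDisDt HospAdmDt Age Sex",
        "SLK ICUAdmDt ICUDisDt HospDisDt Age Sex",
        "SLK ICUAdmDt HospAdmDt HospDisDt Age Sex",
        "SLK ICUDisDt HospAdmDt HospDisDt Age Sex",
    ])


def strategy3_plan() -> StagePlan:
    """Single-pass deterministic equivalent of the key-plus-date strategy:
    SLK exact and admission date within the 2-day window."""
    return StagePlan("strategy3", (StageSpec(1, ("SLK", "ICUAdmDt"), tolerant=True),))


def _surgery_value(s: SurgeryRecord, fname: str, s_slk: str):
    if fname == "SLK":
        return s_slk or None
    if fname == "ICUAdmDt":
        return s.procedure_date
    if fname == "ICUDisDt":
        return s.icu_dis_date
    if fname == "HospAdmDt":
        return s.hosp_adm_date
    if fname == "HospDisDt":
        return s.hosp_dis_date
    if fname == "Age":
        return s.age
    if fname == "Sex":
        return None if s.sex is Sex.UNKNOWN else s.sex
    raise ValueError(fname)


def _icu_value(i: IcuRecord, fname: str):
    if fname == "SLK":
        return i.slk or None
    if fname == "ICUAdmDt":
        return i.icu_adm_date
    if fname == "ICUDisDt":
        return i.icu_dis_date
    if fname == "HospAdmDt":
        return i.hosp_adm_date
    if fname == "HospDisDt":
        return i.hosp_dis_date
    if fname == "Age":
        return i.age
    if fname == "Sex":
        return None if i.sex is Sex.UNKNOWN else i.sex
    raise ValueError(fname)


def stage_agree(s: SurgeryRecord, i: IcuRecord, stage: StageSpec,
                cfg: LinkConfig, _s_slk: str | None = None) -> bool:
    """True iff every field the stage requires agrees; a field missing on
    either side fails the stage for this pair."""
    s_slk = surgery_slk(s) if _s_slk is None else _s_slk
    date_tol = cfg.date_tolerance_days if stage.tolerant else 0
    age_tol = cfg.age_tolerance_years if stage.tolerant else 0
    for fname in stage.required_fields:
        sv = _surgery_value(s, fname, s_slk)
        iv = _icu_value(i, fname)
        if sv is None or iv is None:
            return False
        if fname == "SLK":
            if slk_agree(sv, iv) != "agree":
                return False
        elif fname in DATE_FIELDS:
            if abs((sv - iv).days) > date_tol:
                return False
        elif fname == "Age":
            if abs(sv - iv) > age_tol:
                return False
        elif sv != iv:
            return False
    return True


def _stage_candidates(
    surgery: list[SurgeryRecord],
    icu: list[IcuRecord],
    stage: StageSpec,
    cfg: LinkConfig,
    slk_cache: dict[str, str],
) -> list[tuple[str, str]]:
    """All agreeing pairs at one stage.

    Blocks on the stage's first date field (probing the ±tolerance window)
    when one exists, which enumerates exactly the agreeing pairs; custom
    date-free stages fall back to the full cross product.
    """
    block = next((f for f in stage.required_fields if f in DATE_FIELDS), None)
    pairs: list[tuple[str, str]] = []
    if block is None:
        for s, i in product(surgery, icu):
            if stage_agree(s, i, stage, cfg, _s_slk=slk_cache[s.record_id]):
                pairs.append((s.record_id, i.record_id))
        return pairs
    tol = cfg.date_tolerance_days if stage.tolerant else 0
    index: dict[date, list[IcuRecord]] = defaultdict(list)
    for i in icu:
        index[_icu_value(i, block)].append(i)
    for s in surgery:
        sv = _surgery_value(s, block, slk_cache[s.record_id])
        if sv is None:
            continue
        for d in range(-tol, tol + 1):
            for i in index.get(sv + timedelta(days=d), ()):
                if stage_agree(s, i, stage, cfg, _s_slk=slk_cache[s.record_id]):
                    pairs.append((s.record_id, i.record_id))
    return pairs


def run_stages(
    surgery: list[SurgeryRecord],
    icu: list[IcuRecord],
    plan: StagePlan,
    cfg: LinkConfig,
) -> LinkageResult:
    """Run the plan's stages sequentially and return the one-to-one linkage.

    At each stage a pair is accepted only when it is the unique agreeing
    candidate for both of its records among the still-unmatched pool;
    provenance is the accepting stage number.
    """
    if len({s.record_id for s in surgery}) != len(surgery):
        raise ValueError("duplicate record_id in surgery registry")
    if len({i.record_id for i in icu}) != len(icu):
        raise ValueError("duplicate record_id in ICU registry")

    slk_cache = {s.record_id: surgery_slk(s) for s in surgery}
    remaining_s = sorted(surgery, key=lambda r: r.record_id)
    remaining_i = sorted(icu, key=lambda r: r.record_id)
    accepted: list[tuple[str, str, int]] = []

    for stage in plan.stages:
        pairs = _stage_candidates(remaining_s, remaining_i, stage, cfg, slk_cache)
        deg_s: dict[str, int] = defaultdict(int)
        deg_i: dict[str, int] = defaultdict(int)
        for sid, iid in pairs:
            deg_s[sid] += 1
            deg_i[iid] += 1
        taken_s: set[str] = set()
        taken_i: set[str] = set()
        for sid, iid in sorted(pairs):
            if deg_s[sid] == 1 and deg_i[iid] == 1:
                accepted.append((sid, iid, stage.stage_number))
                taken_s.add(sid)
                taken_i.add(iid)
        if taken_s:
            remaining_s = [s for s in remaining_s if s.record_id not in taken_s]
            remaining_i = [i for i in remaining_i if i.record_id not in taken_i]

    return LinkageResult(
        pairs=accepted,
        unmatched_surgery=sorted(s.record_id for s in remaining_s),
        unmatched_icu=sorted(i.record_id for i in remaining_i),
    )
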