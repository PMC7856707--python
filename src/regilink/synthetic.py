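"""Synthetic dual-registry generator with a known gold standard.

Emulates the structure of a single-centre linkage problem: a fully
identified cardiac-surgery registry (~1283 procedures over 21 months) and
a deidentified ICU registry (~5179 admissions, mostly non-surgical) that
carries the SLK-581 key.  Each surgical patient receives a consistent
identity, a hospital stay bracketing the procedure and (usually) a
post-operative ICU episode starting 0-2 days after the procedure; the
generator then corrupts the ICU table the way registry data degrades in
practice:

* a small fraction of ICU rows lose surname/forename/MRN entirely
  (deidentification error) while keeping their SLK;
* a small fraction of surgical patients have no ICU episode at all;
* a further fraction were admitted to ICU more than two days *before*
  the procedure, so no post-procedure admission exists to match;
* single-character name typos and single-digit date/MRN typos;
* hospital admission/discharge dates occasionally recorded from a
  transfer episode, shifting both well outside tolerance;
* extra ICU readmissions within the same hospital stay.

The ICU-side SLK is built from the *corrupted* identity, never perturbed
directly: key errors arise only from upstream name/birth-date errors,
mirroring how duplicate keys arise from alternate spellings in real data.
Patients carrying the planted no-ICU / pre-operative pathologies form the
hard-to-match stratum and draw their covariates (younger, more urgent,
higher predicted mortality, more non-standard procedures) from the
unmatched-patient profile; everyone else draws from the matched profile.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from ._names import FORENAMES, SURNAMES
from .records import (
    IcuRecord,
    PersonIdentity,
    ProcedureType,
    Sex,
    SurgeryRecord,
    Urgency,
)
from .slk581 import SlkError, build_slk

_PROC_TYPES = (ProcedureType.CABG, ProcedureType.VALVE,
               ProcedureType.CABG_VALVE, ProcedureType.OTHER)


def _normalized(probs: tuple[float, ...]) -> tuple[float, ...]:
    total = sum(probs)
    return tuple(p / total for p in probs)


@dataclass(frozen=True)
class CohortParams:
    """Cohort sizes and covariate distributions, per stratum.

    Defaults reproduce the matched / unmatched covariate profiles of the
    emulated study: matchable patients mean age 63.5 (sd 12.7), 77.3% male,
    22.0% urgent, predicted-mortality median 1.08%; hard-to-match patients
    mean age 53.6 (sd 15.1), 80.5% male, 58.5% urgent, median risk 7.50%.
    Risk of death is log-normal (median/log-sd parametrized from the
    reported median and IQR).  ``n_icu_nonsurgical`` defaults so the ICU
    table totals ≈5179 rows once surgical episodes are added.
    """

    n_surgery: int = 1283
    n_icu_nonsurgical: int = 3842
    study_start: date = date(2017, 4, 1)
    study_end: date = date(2018, 12, 31)
    age_mean_clean: float = 63.5
    age_sd_clean: float = 12.7
    age_mean_hard: float = 53.6
    age_sd_hard: float = 15.1
    p_male_clean: float = 0.773
    p_male_hard: float = 0.805
    p_urgent_clean: float = 0.220
    p_urgent_hard: float = 0.585
    # CABG, valve, CABG+valve, other — from the reported counts
    procedure_probs_clean: tuple[float, ...] = _normalized((703, 187, 93, 259))
    procedure_probs_hard: tuple[float, ...] = _normalized((11, 7, 2, 21))
    risk_median_clean: float = 0.0108
    risk_log_sd_clean: float = 0.847   # from IQR 0.67-2.10%
    risk_median_hard: float = 0.0750
    risk_log_sd_hard: float = 1.771    # from IQR 1.33-14.5%
    nonsurg_age_mean: float = 61.0
    nonsurg_age_sd: float = 18.0
    nonsurg_p_male: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surgery < 1 or self.n_icu_nonsurgical < 0:
            raise ValueError("cohort sizes must be positive")
        if self.study_end <= self.study_start:
            raise ValueError("study_end must follow study_start")
        for p in (self.p_male_clean, self.p_male_hard,
                  self.p_urgent_clean, self.p_urgent_hard, self.nonsurg_p_male):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for probs in (self.procedure_probs_clean, self.procedure_probs_hard):
            if len(probs) != 4 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError("procedure-type probabilities must be 4 values summing to 1")


@dataclass(frozen=True)
class ErrorModel:
    """Rates of the data pathologies injected into the registries.

    With every rate zero the registries are error-free and every strategy
    recovers the gold standard exactly.  Defaults are calibrated to the
    emulated study's observed frequencies: 47/5179 ICU rows with blanked
    identity, 10/1283 procedures with no ICU episode, 31/1273 with a
    pre-operative ICU admission beyond the 2-day window, plus modest typo
    rates and a hospital-date transfer artefact (see docs/methods.md).
    """

    p_missing_identity: float = 47 / 5179
    p_no_icu: float = 10 / 1283
    p_preop_icu: float = 31 / 1273
    p_name_typo: float = 0.012
    p_date_typo: float = 0.010
    p_mrn_typo: float = 0.010
    p_hosp_shift: float = 0.07
    p_extra_icu: float = 0.05
    # distribution of procedure -> ICU-admission delay, days 0/1/2
    icu_delay_probs: tuple[float, float, float] = (0.80, 0.15, 0.05)

    def __post_init__(self) -> None:
        for name in ("p_missing_identity", "p_no_icu", "p_preop_icu",
                     "p_name_typo", "p_date_typo", "p_mrn_typo",
                     "p_hosp_shift", "p_extra_icu"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if len(self.icu_delay_probs) != 3 or abs(sum(self.icu_delay_probs) - 1.0) > 1e-9 \
                or min(self.icu_delay_probs) < 0:
            raise ValueError("icu_delay_probs must be 3 values summing to 1")

    @classmethod
    def zero(cls) -> "ErrorModel":
        """Error-free registries (the delay distribution is kept)."""
        return cls(p_missing_identity=0, p_no_icu=0, p_preop_icu=0,
                   p_name_typo=0, p_date_typo=0, p_mrn_typo=0,
                   p_hosp_shift=0, p_extra_icu=0)


@dataclass(frozen=True)
class GoldStandard:
    """The generator's true pairing: surgery id -> ICU id for every
    procedure with a matchable (post-operative, within-caliper) ICU
    episode, plus the clean/hard stratum label per surgery record."""

    true_pairs: dict[str, str]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.true_pairs.values())) != len(self.true_pairs):
            raise ValueError("gold pairing must be injective")

    @property
    def n_eligible(self) -> int:
        return len(self.true_pairs)


def write_gold(gold: GoldStandard, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["surgery_id", "icu_id", "label"])
        for sid in sorted(gold.labels):
            writer.writerow([sid, gold.true_pairs.get(sid, ""), gold.labels[sid]])


def read_gold(path: str | Path) -> GoldStandard:
    pairs: dict[str, str] = {}
    labels: dict[str, str] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            labels[row["surgery_id"]] = row["label"]
            if row["icu_id"]:
                pairs[row["surgery_id"]] = row["icu_id"]
    return GoldStandard(true_pairs=pairs, labels=labels)


# ---------------------------------------------------------------------------
# perturbation helpers

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _uniform_days(rng: np.random.Generator, lo: int, hi: int) -> timedelta:
    return timedelta(days=int(rng.integers(lo, hi + 1)))


def _typo_name(rng: np.random.Generator, name: str) -> str:
    """Substitute one character (the classic single-keystroke error)."""
    if not name:
        return name
    pos = int(rng.integers(0, len(name)))
    old = name[pos]
    new = old
    while new == old:
        new = _LETTERS[int(rng.integers(0, 26))]
    return name[:pos] + new + name[pos + 1:]


def _typo_digits(rng: np.random.Generator, text: str) -> str:
    pos = int(rng.integers(0, len(text)))
    old = text[pos]
    new = old
    while new == old:
        new = str(int(rng.integers(0, 10)))
    return text[:pos] + new + text[pos + 1:]


def _typo_date(rng: np.random.Generator, d: date) -> date:
    """Single-digit error in the DDMMYYYY representation, kept a valid
    calendar date (invalid outcomes are redrawn; the original is returned
    if 20 draws fail)."""
    text = f"{d.day:02d}{d.month:02d}{d.year:04d}"
    for _ in range(20):
        cand = _typo_digits(rng, text)
        try:
            out = date(int(cand[4:8]), int(cand[2:4]), int(cand[0:2]))
        except ValueError:
            continue
        if out != d and 1900 <= out.year <= 2100:
            return out
    return d


# ---------------------------------------------------------------------------

@dataclass
class _IcuDraft:
    """ICU row before ids are assigned (order is shuffled first)."""
    identity: PersonIdentity
    slk: str
    icu_adm: date
    icu_dis: date
    hosp_adm: date
    hosp_dis: date
    age: int
    gold_surgery: str | None  # surgery record_id if this is its true episode


def _dob_for(rng: np.random.Generator, ref: date, age: int) -> date:
    return ref - timedelta(days=round(age * 365.25) + int(rng.integers(0, 365)))


#: matching tolerance (days) the linkage stages apply; clean stays are kept
#: at least this far apart so identification failures can only come from
#: the injected error processes, never from generator-made twin stays
_SEPARATION_DAYS = 2


class _StayIndex:
    """Date-bucketed index of clean stay profiles.

    A profile is ``(anchor, icu_dis, hosp_adm, hosp_dis)`` where the anchor
    is the procedure date (surgery side) or ICU admission date (ICU side).
    Two profiles collide when every component present on both sides lies
    within the matching tolerance; colliding draws are redrawn.
    """

    def __init__(self) -> None:
        self._by_anchor: dict[date, list[tuple]] = {}

    def add(self, profile: tuple) -> None:
        self._by_anchor.setdefault(profile[0], []).append(profile)

    def collides(self, profile: tuple) -> bool:
        anchor = profile[0]
        for d in range(-_SEPARATION_DAYS, _SEPARATION_DAYS + 1):
            for other in self._by_anchor.get(anchor + timedelta(days=d), ()):
                if all(
                    a is None or b is None or abs((a - b).days) <= _SEPARATION_DAYS
                    for a, b in zip(profile[1:], other[1:])
                ):
                    return True
        return False


def _corrupt_icu(rng: np.random.Generator, draft: _IcuDraft, errs: ErrorModel) -> _IcuDraft:
    """Apply the error model to one ICU row and rebuild its SLK from the
    corrupted identity.  Date typos that would break record validity
    (discharge before admission, ICU before hospital admission) are
    dropped rather than clamped, so every emitted row is well-formed."""
    ident = draft.identity
    surname, forename, mrn, dob = ident.surname, ident.forename, ident.mrn, ident.dob
    if rng.random() < errs.p_name_typo:
        surname = _typo_name(rng, surname)
    if rng.random() < errs.p_name_typo:
        forename = _typo_name(rng, forename)
    if rng.random() < errs.p_mrn_typo and mrn:
        mrn = _typo_digits(rng, mrn)
    if rng.random() < errs.p_date_typo and dob is not None:
        dob = _typo_date(rng, dob)

    icu_adm, icu_dis = draft.icu_adm, draft.icu_dis
    hosp_adm, hosp_dis = draft.hosp_adm, draft.hosp_dis
    if rng.random() < errs.p_date_typo:
        cand = _typo_date(rng, icu_adm)
        if cand <= icu_dis and cand >= hosp_adm:
            icu_adm = cand
    if rng.random() < errs.p_date_typo:
        cand = _typo_date(rng, icu_dis)
        if cand >= icu_adm:
            icu_dis = cand
    if rng.random() < errs.p_date_typo:
        cand = _typo_date(rng, hosp_adm)
        if cand <= icu_adm:
            hosp_adm = cand
    if rng.random() < errs.p_date_typo:
        hosp_dis = _typo_date(rng, hosp_dis)
    if rng.random() < errs.p_hosp_shift:
        # stay recorded from a transfer episode: both ends move > tolerance
        hosp_adm = hosp_adm - _uniform_days(rng, 3, 30)
        hosp_dis = hosp_dis + _uniform_days(rng, 3, 30)

    corrupted = PersonIdentity(surname=surname, forename=forename, mrn=mrn,
                               dob=dob, sex=ident.sex)
    try:
        slk = build_slk(corrupted).value
    except SlkError:
        slk = ""
    if rng.random() < errs.p_missing_identity:
        corrupted = replace(corrupted, surname="", forename="", mrn="")
    return _IcuDraft(identity=corrupted, slk=slk, icu_adm=icu_adm, icu_dis=icu_dis,
                     hosp_adm=hosp_adm, hosp_dis=hosp_dis, age=draft.age,
                     gold_surgery=draft.gold_surgery)


def generate(
    params: CohortParams, errs: ErrorModel, seed: int | None = None
) -> tuple[list[SurgeryRecord], list[IcuRecord], GoldStandard]:
    """Generate paired registries and the true linkage.

    Deterministic for fixed ``(params, errs, seed)``; ``seed=None`` falls
    back to ``params.seed``.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    span = (params.study_end - params.study_start).days

    half_s, half_f = len(SURNAMES) // 2, len(FORENAMES) // 2
    n_total = params.n_surgery + params.n_icu_nonsurgical
    mrns = rng.choice(9_000_000, size=n_total, replace=False) + 1_000_000

    surgery: list[SurgeryRecord] = []
    drafts: list[_IcuDraft] = []
    labels: dict[str, str] = {}
    surgery_index = _StayIndex()   # clean surgery-side stay profiles
    episode_index = _StayIndex()   # clean ICU-episode stay profiles

    for k in range(params.n_surgery):
        sid = f"S{k + 1:05d}"
        no_icu = rng.random() < errs.p_no_icu
        preop = (not no_icu) and rng.random() < errs.p_preop_icu
        hard = no_icu or preop
        labels[sid] = "hard" if hard else "clean"

        age_mu, age_sd = ((params.age_mean_hard, params.age_sd_hard) if hard
                          else (params.age_mean_clean, params.age_sd_clean))
        age = int(np.clip(round(rng.normal(age_mu, age_sd)), 18, 95))
        p_male = params.p_male_hard if hard else params.p_male_clean
        sex = Sex.MALE if rng.random() < p_male else Sex.FEMALE
        p_urg = params.p_urgent_hard if hard else params.p_urgent_clean
        urgency = Urgency.URGENT if rng.random() < p_urg else Urgency.ELECTIVE
        probs = params.procedure_probs_hard if hard else params.procedure_probs_clean
        ptype = _PROC_TYPES[int(rng.choice(4, p=probs))]
        median, log_sd = ((params.risk_median_hard, params.risk_log_sd_hard) if hard
                          else (params.risk_median_clean, params.risk_log_sd_clean))
        risk = float(min(np.exp(rng.normal(np.log(median), log_sd)), 0.99))

        surname = SURNAMES[int(rng.integers(0, half_s))]
        forename = FORENAMES[int(rng.integers(0, half_f))]
        identity = PersonIdentity(surname=surname, forename=forename,
                                  mrn=str(mrns[k]), dob=None, sex=sex)

        for _attempt in range(200):
            proc = params.study_start + _uniform_days(rng, 0, span)
            hosp_adm = proc - (_uniform_days(rng, 0, 14) if urgency is Urgency.ELECTIVE
                               else _uniform_days(rng, 0, 2))
            episodes: list[tuple[date, date]] = []
            gold_icu_episode: int | None = None
            if no_icu:
                surg_icu_dis = None
                hosp_dis = proc + _uniform_days(rng, 5, 15)
            elif preop:
                # stabilised in ICU days before theatre; no post-op episode
                # in the extract, so nothing can match the procedure date
                icu_adm = proc - _uniform_days(rng, 3, 10)
                icu_dis = icu_adm + _uniform_days(rng, 1, 2)
                hosp_adm = min(hosp_adm, icu_adm - _uniform_days(rng, 0, 2))
                episodes.append((icu_adm, icu_dis))
                surg_icu_dis = proc + _uniform_days(rng, 1, 5)
                hosp_dis = surg_icu_dis + _uniform_days(rng, 2, 14)
            else:
                delay = timedelta(days=int(rng.choice(3, p=errs.icu_delay_probs)))
                icu_adm = proc + delay
                icu_dis = icu_adm + _uniform_days(rng, 1, 5)
                episodes.append((icu_adm, icu_dis))
                gold_icu_episode = 0
                surg_icu_dis = icu_dis
                hosp_dis = icu_dis + _uniform_days(rng, 2, 14)
                if rng.random() < errs.p_extra_icu:
                    adm2 = icu_dis + _uniform_days(rng, 2, 7)
                    dis2 = adm2 + _uniform_days(rng, 1, 4)
                    episodes.append((adm2, dis2))
                    hosp_dis = max(hosp_dis, dis2 + _uniform_days(rng, 2, 14))
            surg_profile = (proc, surg_icu_dis, hosp_adm, hosp_dis)
            ep_profiles = [(adm, dis, hosp_adm, hosp_dis) for adm, dis in episodes]
            if not episode_index.collides(surg_profile) and \
                    not any(surgery_index.collides(p) for p in ep_profiles):
                break
        surgery_index.add(surg_profile)
        for p in ep_profiles:
            episode_index.add(p)
        identity = replace(identity, dob=_dob_for(rng, proc, age))

        surgery.append(SurgeryRecord(
            record_id=sid, identity=identity, procedure_date=proc,
            icu_dis_date=surg_icu_dis, hosp_adm_date=hosp_adm,
            hosp_dis_date=hosp_dis, age=age, urgency=urgency,
            procedure_type=ptype, risk_of_death=risk,
        ))
        for ep_idx, (adm, dis) in enumerate(episodes):
            drafts.append(_corrupt_icu(rng, _IcuDraft(
                identity=identity, slk="", icu_adm=adm, icu_dis=dis,
                hosp_adm=hosp_adm, hosp_dis=hosp_dis, age=age,
                gold_surgery=sid if ep_idx == gold_icu_episode else None,
            ), errs))

    for j in range(params.n_icu_nonsurgical):
        age = int(np.clip(round(rng.normal(params.nonsurg_age_mean, params.nonsurg_age_sd)),
                          18, 95))
        sex = Sex.MALE if rng.random() < params.nonsurg_p_male else Sex.FEMALE
        surname = SURNAMES[half_s + int(rng.integers(0, len(SURNAMES) - half_s))]
        forename = FORENAMES[half_f + int(rng.integers(0, len(FORENAMES) - half_f))]
        # emergency-style stays: ICU entry at or shortly after hospital
        # admission, with right-skewed ICU and ward lengths of stay
        for _attempt in range(200):
            hosp_adm = params.study_start + _uniform_days(rng, 0, span)
            icu_adm = hosp_adm + timedelta(days=int(min(rng.exponential(1.5), 25)))
            icu_dis = icu_adm + timedelta(days=1 + int(min(rng.exponential(3.0), 40)))
            hosp_dis = icu_dis + timedelta(days=int(min(rng.exponential(7.0), 60)))
            if not surgery_index.collides((icu_adm, icu_dis, hosp_adm, hosp_dis)):
                break
        identity = PersonIdentity(surname=surname, forename=forename,
                                  mrn=str(mrns[params.n_surgery + j]),
                                  dob=_dob_for(rng, hosp_adm, age), sex=sex)
        drafts.append(_corrupt_icu(rng, _IcuDraft(
            identity=identity, slk="", icu_adm=icu_adm, icu_dis=icu_dis,
            hosp_adm=hosp_adm, hosp_dis=hosp_dis, age=age, gold_surgery=None,
        ), errs))

    # shuffle before assigning ids so row order carries no linkage signal
    order = rng.permutation(len(drafts))
    icu: list[IcuRecord] = []
    true_pairs: dict[str, str] = {}
    for rank, idx in enumerate(order):
        draft = drafts[idx]
        iid = f"I{rank + 1:05d}"
        icu.append(IcuRecord(
            record_id=iid, identity=draft.identity, slk=draft.slk,
            icu_adm_date=draft.icu_adm, icu_dis_date=draft.icu_dis,
            hosp_adm_date=draft.hosp_adm, hosp_dis_date=draft.hosp_dis,
            age=draft.age,
        ))
        if draft.gold_surgery is not None:
            true_pairs[draft.gold_surgery] = iid

    return surgery, icu, GoldStandard(true_pairs=true_pairs, labels=labels)
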