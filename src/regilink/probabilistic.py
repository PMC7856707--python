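"""Probabilistic pair scoring and one-to-one linkage.

Candidate (surgery, ICU) pairs are scored additively: each compared field
contributes its agreement weight, its disagreement weight, or nothing when
either side is missing.  The date field compares the procedure date with
the ICU admission date under a caliper (default |Δ| ≤ 2 days); outside the
caliper its strongly negative weight (−40) sinks the pair below any
attainable cutoff, so candidate generation restricts to the caliper window
— an exact optimization, not an approximation, for the shipped weights.

Pairs at or above the cutoff (default 1) are resolved to a one-to-one
linkage by exact optimal assignment: maximize the number of accepted pairs
first, then the total score.  The solve is deterministic for a fixed input
order (records are processed in sorted id order).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .records import IcuRecord, LinkConfig, SurgeryRecord
from .slk581 import SlkError, build_slk, normalize_name, slk_agree

Outcome = str  # "agree" | "disagree" | "missing"


@dataclass(frozen=True)
class PairScore:
    """Score breakdown for one candidate pair."""

    surgery_id: str
    icu_id: str
    score: float
    field_outcomes: dict[str, Outcome] = field(default_factory=dict)
    date_delta_days: int = 0


@dataclass(frozen=True)
class LinkageResult:
    """One-to-one linkage: accepted pairs with provenance plus the leftovers.

    ``provenance`` is the accepted score (probabilistic strategies) or the
    accepting stage number (staged deterministic strategies).
    """

    pairs: list[tuple[str, str, float | int]]
    unmatched_surgery: list[str]
    unmatched_icu: list[str]

    def pair_map(self) -> dict[str, str]:
        return {s: i for s, i, _ in self.pairs}

    def __post_init__(self) -> None:
        s_ids = [s for s, _, _ in self.pairs]
        i_ids = [i for _, i, _ in self.pairs]
        if len(set(s_ids)) != len(s_ids) or len(set(i_ids)) != len(i_ids):
            raise ValueError("linkage is not one-to-one")


def _norm_mrn(mrn: str) -> str:
    # MRNs are alphanumeric; strip separators/whitespace but keep digits
    return "".join(ch for ch in mrn.upper() if ch.isalnum())


def _text_outcome(a: str, b: str, norm) -> Outcome:
    na, nb = norm(a), norm(b)
    if not na or not nb:
        return "missing"
    return "agree" if na == nb else "disagree"


def surgery_slk(record: SurgeryRecord) -> str:
    """SLK-581 derived from the surgical registry's own identifiers
    (mirrors adding the key to an identified registry); empty when the
    date of birth is absent."""
    try:
        return build_slk(record.identity).value
    except SlkError:
        return ""


def score_pair(s: SurgeryRecord, i: IcuRecord, cfg: LinkConfig,
               _s_slk: str | None = None) -> PairScore:
    """Additive field-agreement score for one candidate pair.

    Only the fields named in ``cfg.fields`` contribute.  Name fields are
    compared after the same normalization the SLK builder applies; a field
    missing on either side contributes 0.
    """
    outcomes: dict[str, Outcome] = {}
    delta = (i.icu_adm_date - s.procedure_date).days
    for fname in cfg.fields:
        if fname == "surname":
            outcomes[fname] = _text_outcome(s.identity.surname, i.identity.surname, normalize_name)
        elif fname == "forename":
            outcomes[fname] = _text_outcome(s.identity.forename, i.identity.forename, normalize_name)
        elif fname == "mrn":
            outcomes[fname] = _text_outcome(s.identity.mrn, i.identity.mrn, _norm_mrn)
        elif fname == "slk":
            outcomes[fname] = slk_agree(_s_slk if _s_slk is not None else surgery_slk(s), i.slk)
        elif fname == "date":
            outcomes[fname] = "agree" if abs(delta) <= cfg.date_caliper_days else "disagree"
    score = 0.0
    for fname, outcome in outcomes.items():
        if outcome == "agree":
            score += cfg.field_weights[fname][0]
        elif outcome == "disagree":
            score += cfg.field_weights[fname][1]
    return PairScore(s.record_id, i.record_id, score, outcomes, delta)


def assign_one_to_one(
    scored: list[PairScore], cutoff: float
) -> list[tuple[str, str, float]]:
    """Optimal one-to-one assignment over pairs with score ≥ cutoff.

    Maximizes the number of accepted pairs, breaking ties by maximum total
    score (a large per-pair bonus makes one extra accepted pair always worth
    more than any score rearrangement).  Ids are ordered lexicographically
    before solving, so the result is reproducible.
    """
    eligible = sorted(
        (p for p in scored if p.score >= cutoff),
        key=lambda p: (p.surgery_id, p.icu_id),
    )
    if not eligible:
        return []
    s_ids = sorted({p.surgery_id for p in eligible})
    i_ids = sorted({p.icu_id for p in eligible})
    s_index = {sid: k for k, sid in enumerate(s_ids)}
    i_index = {iid: k for k, iid in enumerate(i_ids)}
    scores = np.array([p.score for p in eligible])
    span = float(scores.max() - scores.min()) + 1.0
    bonus = (min(len(s_ids), len(i_ids)) + 1) * span
    weights = np.zeros((len(s_ids), len(i_ids)))
    best: dict[tuple[int, int], PairScore] = {}
    for p in eligible:
        key = (s_index[p.surgery_id], i_index[p.icu_id])
        # duplicate (surgery, icu) entries keep the best-scoring one
        if key not in best or p.score > best[key].score:
            best[key] = p
            weights[key] = bonus + (p.score - scores.min()) + 1.0
    rows, cols = linear_sum_assignment(weights, maximize=True)
    accepted = [
        (s_ids[r], i_ids[c], best[(r, c)].score)
        for r, c in zip(rows, cols)
        if weights[r, c] > 0
    ]
    accepted.sort()
    return accepted


def link_probabilistic(
    surgery: list[SurgeryRecord], icu: list[IcuRecord], cfg: LinkConfig
) -> LinkageResult:
    """Score all caliper-window candidates and assign one-to-one.

    Blocking: only ICU admissions within ``cfg.date_caliper_days`` of the
    procedure date are scored.  With the shipped weights no pair outside
    the caliper can reach the cutoff (total positive weight 39 < 40), so
    the block loses nothing.
    """
    if len({s.record_id for s in surgery}) != len(surgery):
        raise ValueError("duplicate record_id in surgery registry")
    if len({i.record_id for i in icu}) != len(icu):
        raise ValueError("duplicate record_id in ICU registry")

    icu_sorted = sorted(icu, key=lambda r: r.icu_adm_date)
    adm_dates = [r.icu_adm_date for r in icu_sorted]
    from datetime import timedelta

    window = timedelta(days=cfg.date_caliper_days)
    scored: list[PairScore] = []
    for s in surgery:
        s_slk = surgery_slk(s) if "slk" in cfg.fields else ""
        lo = bisect_left(adm_dates, s.procedure_date - window)
        hi = bisect_right(adm_dates, s.procedure_date + window)
        for i in icu_sorted[lo:hi]:
            scored.append(score_pair(s, i, cfg, _s_slk=s_slk))

    accepted = assign_one_to_one(scored, cfg.cutoff_score)
    matched_s = {s for s, _, _ in accepted}
    matched_i = {i for _, i, _ in accepted}
    return LinkageResult(
        pairs=accepted,
        unmatched_surgery=sorted(s.record_id for s in surgery if s.record_id not in matched_s),
        unmatched_icu=sorted(i.record_id for i in icu if i.record_id not in matched_i),
    )
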