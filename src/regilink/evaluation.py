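"""Scoring a linkage against the gold standard and cohort comparisons.

A pair is a *true match* iff it coincides with a gold pair; an accepted
pair whose surgery record has a different gold partner — or none — is a
*false positive*; a gold pair absent from the result is a *false negative*
(missed link).  The match-rate denominator is the number of gold-eligible
procedures (those with a matchable ICU episode), not the registry size;
both are reported.

Cohort comparisons reproduce the standard matched-vs-unmatched table:
age by Student's t-test (two groups) or one-way ANOVA (more), binary and
categorical variables by Pearson chi-square, predicted mortality by
Wilcoxon rank-sum (two groups) or Kruskal–Wallis (more).  Percentages are
printed to one decimal, half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .probabilistic import LinkageResult
from .records import Sex, SurgeryRecord, Urgency
from .synthetic import GoldStandard


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (``round()`` is banker's rounding)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_pct_n(count: int, total: int, ndigits: int = 1) -> str:
    """``24 of 41 -> "58.5 (24)"`` — the percentage (n) cell format."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = round_half_up(100.0 * count / total, ndigits)
    return f"{pct:.{ndigits}f} ({count})"


@dataclass(frozen=True)
class EvalReport:
    strategy: str
    n_eligible: int
    n_matched_true: int
    n_false_positive: int
    n_false_negative: int
    match_rate_pct: float
    n_pairs: int
    false_negative_ids: tuple[str, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        assert self.n_matched_true + self.n_false_negative == self.n_eligible
        assert self.n_matched_true + self.n_false_positive == self.n_pairs


def evaluate(result: LinkageResult, gold: GoldStandard, strategy: str = "") -> EvalReport:
    """Count true matches, false positives and missed links.

    The match rate is ``100 × true matches / gold-eligible``, to one
    decimal (half away from zero).
    """
    matched_true = 0
    false_pos = 0
    found: set[str] = set()
    for sid, iid, _ in result.pairs:
        if gold.true_pairs.get(sid) == iid:
            matched_true += 1
            found.add(sid)
        else:
            false_pos += 1
    missed = tuple(sorted(set(gold.true_pairs) - found))
    n_eligible = gold.n_eligible
    rate = round_half_up(100.0 * matched_true / n_eligible, 1) if n_eligible else 0.0
    return EvalReport(
        strategy=strategy,
        n_eligible=n_eligible,
        n_matched_true=matched_true,
        n_false_positive=false_pos,
        n_false_negative=len(missed),
        match_rate_pct=rate,
        n_pairs=len(result.pairs),
        false_negative_ids=missed,
    )


def compare_match_rates(k1: int, n1: int, k2: int, n2: int,
                        correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square (df 1) on the 2×2 table [[k1, n1−k1], [k2, n2−k2]].

    No continuity correction by default.  Returns ``(statistic, p_value)``;
    an empty margin (all successes or all failures) is undefined and raises.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: empty row or column margin")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Table-2-shaped cohort characteristics


def _safe_p(callable_, *args, **kwargs) -> float | None:
    try:
        p = float(callable_(*args, **kwargs).pvalue)
    except (ValueError, ZeroDivisionError):
        return None
    return None if np.isnan(p) else p


def _median_iqr_pct(risks: list[float]) -> str:
    pct = np.asarray(risks) * 100.0
    med = round_half_up(float(np.median(pct)), 2)
    lo = round_half_up(float(np.percentile(pct, 25)), 2)
    hi = round_half_up(float(np.percentile(pct, 75)), 2)
    return f"{med:.2f} ({lo:.2f}-{hi:.2f})"


def compare_cohorts(
    *groups: list[SurgeryRecord], labels: list[str] | None = None
) -> list[dict]:
    """Characteristics table over two or more cohorts of surgery records.

    Returns one row per characteristic: ``{"characteristic", "cells":
    {label: formatted}, "test", "p_value"}``.  Two groups use t-test /
    rank-sum; more use ANOVA / Kruskal–Wallis.  A degenerate comparison
    (zero variance, empty group) reports ``p_value=None``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two records")
    labels = labels or [f"group{k + 1}" for k in range(len(groups))]
    two = len(groups) == 2
    rows: list[dict] = []

    ages = [[r.age for r in g] for g in groups]
    rows.append({
        "characteristic": "Age (mean, sd)",
        "cells": {lab: f"{np.mean(a):.1f} ({np.std(a, ddof=1):.1f})"
                  for lab, a in zip(labels, ages)},
        "test": "t-test" if two else "ANOVA",
        "p_value": (_safe_p(stats.ttest_ind, *ages) if two
                    else _safe_p(stats.f_oneway, *ages)),
    })

    males = [sum(r.sex is Sex.MALE for r in g) for g in groups]
    sex_table = [[m, len(g) - m] for m, g in zip(males, groups)]
    rows.append({
        "characteristic": "Male sex (%, n)",
        "cells": {lab: format_pct_n(m, len(g))
                  for lab, m, g in zip(labels, males, groups)},
        "test": "chi-square",
        "p_value": _safe_p(stats.chi2_contingency, sex_table, correction=False),
    })

    risks = [[r.risk_of_death for r in g] for g in groups]
    rows.append({
        "characteristic": "Risk of death % (median, IQR)",
        "cells": {lab: _median_iqr_pct(rk) for lab, rk in zip(labels, risks)},
        "test": "rank-sum" if two else "Kruskal-Wallis",
        "p_value": (_safe_p(stats.mannwhitneyu, *risks, alternative="two-sided") if two
                    else _safe_p(stats.kruskal, *risks)),
    })

    urgent = [sum(r.urgency is Urgency.URGENT for r in g) for g in groups]
    urg_table = [[u, len(g) - u] for u, g in zip(urgent, groups)]
    rows.append({
        "characteristic": "Urgent/emergent procedure (%, n)",
        "cells": {lab: format_pct_n(u, len(g))
                  for lab, u, g in zip(labels, urgent, groups)},
        "test": "chi-square",
        "p_value": _safe_p(stats.chi2_contingency, urg_table, correction=False),
    })

    from .records import ProcedureType
    ptypes = list(ProcedureType)
    counts = [[sum(r.procedure_type is t for r in g) for t in ptypes] for g in groups]
    type_p = _safe_p(stats.chi2_contingency, counts, correction=False)
    for t_idx, ptype in enumerate(ptypes):
        rows.append({
            "characteristic": f"Procedure type: {ptype.value} (%, n)",
            "cells": {lab: format_pct_n(c[t_idx], len(g))
                      for lab, c, g in zip(labels, counts, groups)},
            "test": "chi-square",
            "p_value": type_p if t_idx == 0 else None,
        })
    return rows


def cohort_table_markdown(rows: list[dict]) -> str:
    """Render the characteristics rows as a GitHub-style markdown table."""
    labels = list(rows[0]["cells"])
    header = ["Characteristic", *labels, "Test", "p"]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "---|" * len(header)]
    for row in rows:
        p = row["p_value"]
        p_txt = "" if p is None else ("<0.001" if p < 0.001 else f"{p:.2f}")
        lines.append("| " + " | ".join(
            [row["characteristic"], *(row["cells"][lab] for lab in labels),
             row["test"], p_txt]) + " |")
    return "\n".join(lines)
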