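"""Staged deterministic matching: stage agreement, plans, sequential runs."""

from dataclasses import replace
from datetime import date, timedelta

import pytest

from regilink.deterministic import (
    StagePlan,
    StageSpec,
    run_stages,
    stage_agree,
    strategy2_plan,
    strategy3_plan,
    strategy4_plan,
)
from regilink.pipeline import link_strategy
from regilink.records import Sex

from conftest import make_icu, make_surgery

ALL_SIX = ("ICUAdmDt", "ICUDisDt", "HospAdmDt", "HospDisDt", "Age", "Sex")


class TestStageAgree:
    def test_identical_records_agree_tight(self, cfg, matched_pair):
        s, i = matched_pair
        stage = StageSpec(1, ALL_SIX, tolerant=False)
        assert stage_agree(s, i, stage, cfg)

    def test_one_day_discrepancy_needs_tolerance(self, cfg, matched_pair):
        s, i = matched_pair
        i = replace(i, hosp_dis_date=i.hosp_dis_date + timedelta(days=1))
        assert not stage_agree(s, i, StageSpec(1, ALL_SIX, tolerant=False), cfg)
        assert stage_agree(s, i, StageSpec(1, ALL_SIX, tolerant=True), cfg)

    def test_admission_three_days_after_procedure_fails(self, cfg, matched_pair):
        s, i = matched_pair
        i = replace(i, icu_adm_date=s.procedure_date + timedelta(days=3))
        stage = StageSpec(1, ("ICUAdmDt",), tolerant=True)
        assert not stage_agree(s, i, stage, cfg)

    def test_missing_field_fails_stage(self, cfg, matched_pair):
        s, i = matched_pair
        s = replace(s, icu_dis_date=None)
        assert not stage_agree(s, i, StageSpec(1, ("ICUDisDt",), tolerant=True), cfg)
        i = replace(i, slk="")
        assert not stage_agree(s, i, StageSpec(1, ("SLK",), tolerant=True), cfg)

    def test_age_tolerance_is_two_years(self, cfg, matched_pair):
        s, i = matched_pair
        stage = StageSpec(1, ("Age",), tolerant=True)
        assert stage_agree(s, replace(i, age=s.age + 2), stage, cfg)
        assert not stage_agree(s, replace(i, age=s.age + 3), stage, cfg)


class TestShippedPlans:
    def test_nine_and_twelve_stages(self):
        p2, p4 = strategy2_plan(), strategy4_plan()
        assert len(p2.stages) == 9 and len(p4.stages) == 12
        assert all("SLK" not in st.required_fields for st in p2.stages)
        assert sum("SLK" in st.required_fields for st in p4.stages) == 9
        # stage 1 is tight, later stages tolerant
        for plan in (p2, p4):
            assert not plan.stages[0].tolerant
            assert all(st.tolerant for st in plan.stages[1:])
        assert p2.stages[0].required_fields == ALL_SIX
        assert p2.stages[3].required_fields == ("ICUAdmDt", "ICUDisDt",
                                                "HospAdmDt", "Age", "Sex")
        assert p4.stages[3].required_fields == ("SLK", "ICUAdmDt")

    def test_stage_numbers_strictly_increase(self):
        with pytest.raises(ValueError):
            StagePlan("bad", (StageSpec(2, ("Age",)), StageSpec(2, ("Sex",))))


def _pair_set(result):
    return {(s, i) for s, i, _ in result.pairs}


class TestRunStages:
    def test_clean_pair_accepted_at_stage_one(self, cfg, matched_pair):
        s, i = matched_pair
        result = run_stages([s], [i], strategy2_plan(), cfg)
        assert result.pairs == [("S1", "I1", 1)]

    def test_five_day_discharge_typo_recovered_at_first_omitting_stage(self, cfg, matched_pair):
        """A gross HospDisDt error fails stages 1-3 and is caught by the
        first pass that drops the field."""
        s, i = matched_pair
        i = replace(i, hosp_dis_date=i.hosp_dis_date + timedelta(days=5))
        result = run_stages([s], [i], strategy2_plan(), cfg)
        assert result.pairs == [("S1", "I1", 4)]

    def test_ambiguous_candidates_deferred(self, cfg):
        """Two surgery records identical in all six variables against one
        ICU record: neither may claim it at that stage."""
        s1 = make_surgery("S1")
        s2 = make_surgery("S2", surname="NG", mrn="7654321")  # same stay pattern
        i1 = make_icu("I1")
        result = run_stages([s1, s2], [i1], strategy2_plan(), cfg)
        assert result.pairs == []
        assert result.unmatched_surgery == ["S1", "S2"]

    def test_sequential_exclusion_and_provenance(self, cfg):
        """Records accepted early never reappear; every accepted pair
        satisfies its recorded stage (auditability)."""
        plan = strategy2_plan()
        s1, i1 = make_surgery("S1"), make_icu("I1")
        s2 = make_surgery("S2", surname="NG", mrn="7654321",
                          proc=date(2018, 8, 1), icu_dis=date(2018, 8, 4),
                          hosp_adm=date(2018, 7, 28), hosp_dis=date(2018, 8, 12))
        i2 = make_icu("I2", surname="NG", mrn="7654321",
                      icu_adm=date(2018, 8, 1), icu_dis=date(2018, 8, 4),
                      hosp_adm=date(2018, 7, 28),
                      hosp_dis=date(2018, 8, 13))  # 1-day slip -> stage 2
        result = run_stages([s1, s2], [i1, i2], plan, cfg)
        stages = {sid: prov for sid, _, prov in result.pairs}
        assert stages == {"S1": 1, "S2": 2}
        smap = {"S1": s1, "S2": s2}
        imap = {"I1": i1, "I2": i2}
        for sid, iid, prov in result.pairs:
            spec = plan.stages[prov - 1]
            assert spec.stage_number == prov
            assert stage_agree(smap[sid], imap[iid], spec, cfg)

    def test_strategy3_plan_equals_probabilistic_restriction(self, cfg):
        """The single-stage {SLK, ICUAdmDt ±2} plan accepts the same pair
        set as the key-plus-caliper probabilistic strategy."""
        surgery, icu = [], []
        for k, (delay, slk_ok) in enumerate([(0, True), (2, True), (1, False), (3, True)]):
            proc = date(2018, 3, 1) + timedelta(days=10 * k)
            s = make_surgery(f"S{k}", surname=f"NAME{k}", mrn=str(1000 + k),
                             dob=date(1950 + k, 5, 6), proc=proc,
                             icu_dis=proc + timedelta(days=4),
                             hosp_adm=proc - timedelta(days=2),
                             hosp_dis=proc + timedelta(days=9))
            adm = proc + timedelta(days=delay)
            i = make_icu(f"I{k}", surname=f"NAME{k}" if slk_ok else f"NXME{k}",
                         mrn=str(1000 + k), dob=date(1950 + k, 5, 6),
                         icu_adm=adm, icu_dis=proc + timedelta(days=4),
                         hosp_adm=proc - timedelta(days=2),
                         hosp_dis=proc + timedelta(days=9))
            surgery.append(s)
            icu.append(i)
        det = run_stages(surgery, icu, strategy3_plan(), cfg)
        prob = link_strategy("strategy3", surgery, icu, cfg)
        assert _pair_set(det) == _pair_set(prob) == {("S0", "I0"), ("S1", "I1")}


def _universe(plan):
    fields = []
    for st in plan.stages:
        for f in st.required_fields:
            if f not in fields:
                fields.append(f)
    return tuple(fields)


def _inject(s, i, fields):
    """Corrupt exactly *fields* beyond every tolerance, keeping records valid."""
    for f in fields:
        if f == "SLK":
            i = replace(i, slk=i.slk[:13] + ("1" if i.slk[13] != "1" else "2"))
        elif f == "ICUAdmDt":
            i = replace(i, icu_adm_date=i.icu_adm_date - timedelta(days=5))
        elif f == "ICUDisDt":
            i = replace(i, icu_dis_date=i.icu_dis_date + timedelta(days=5))
        elif f == "HospAdmDt":
            i = replace(i, hosp_adm_date=i.hosp_adm_date - timedelta(days=5))
        elif f == "HospDisDt":
            i = replace(i, hosp_dis_date=i.hosp_dis_date + timedelta(days=5))
        elif f == "Age":
            i = replace(i, age=i.age + 5)
        elif f == "Sex":
            flipped = Sex.FEMALE if i.sex is Sex.MALE else Sex.MALE
            i = replace(i, identity=replace(i.identity, sex=flipped))
    return s, i


@pytest.mark.parametrize("plan_fn", [strategy2_plan, strategy4_plan],
                         ids=["9-stage", "12-stage"])
def test_targeted_errors_recovered_at_first_compatible_stage(cfg, plan_fn):
    """Errors confined to the fields a stage omits are recovered at the
    first stage whose required fields are all intact — which, for every
    stage of the 9-stage plan and the non-redundant stages of the 12-stage
    plan, is that stage itself."""
    plan = plan_fn()
    universe = _universe(plan)
    # wide gap between hospital and ICU admission leaves room to shift the
    # ICU admission date without breaking record validity
    base_s = make_surgery(hosp_adm=date(2018, 6, 2))
    base_i = make_icu(hosp_adm=date(2018, 6, 2))
    for stage in plan.stages:
        errored = tuple(f for f in universe if f not in stage.required_fields)
        s, i = _inject(base_s, base_i, errored)
        expected = next(st.stage_number for st in plan.stages
                        if not set(st.required_fields) & set(errored))
        result = run_stages([s], [i], plan, cfg)
        assert result.pairs == [("S1", "I1", expected)], (
            f"stage {stage.stage_number}: errors in {errored}")
        if plan.name == "strategy2" or stage.stage_number in (1, 2, 3, 4, 5, 6, 7, 12):
            assert expected == stage.stage_number
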