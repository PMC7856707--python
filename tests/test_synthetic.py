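"""Synthetic dual-registry generator: determinism, calibration, pathologies."""

import numpy as np
import pytest

from regilink.deterministic import stage_agree
from regilink.records import LinkConfig, Sex, write_registry
from regilink.synthetic import (
    CohortParams,
    ErrorModel,
    GoldStandard,
    generate,
    read_gold,
    write_gold,
)

SMALL = CohortParams(n_surgery=150, n_icu_nonsurgical=300)


def test_same_seed_byte_identical(tmp_path):
    paths = []
    for run in ("a", "b"):
        s, i, g = generate(SMALL, ErrorModel(), seed=11)
        d = tmp_path / run
        d.mkdir()
        write_registry(s, d / "surgery.csv")
        write_registry(i, d / "icu.csv")
        write_gold(g, d / "gold.csv")
        paths.append(d)
    for name in ("surgery.csv", "icu.csv", "gold.csv"):
        assert (paths[0] / name).read_bytes() == (paths[1] / name).read_bytes()


def test_different_seeds_differ():
    s1, _, _ = generate(SMALL, ErrorModel(), seed=1)
    s2, _, _ = generate(SMALL, ErrorModel(), seed=2)
    assert s1 != s2


def test_error_free_run_structure():
    """Without errors every procedure has exactly one gold episode whose
    admission trails the procedure by 0-2 days, and every true pair agrees
    exactly on every staged matching field."""
    cfg = LinkConfig()
    s, i, g = generate(SMALL, ErrorModel.zero(), seed=3)
    assert len(s) == 150
    assert g.n_eligible == 150
    smap = {r.record_id: r for r in s}
    imap = {r.record_id: r for r in i}
    from regilink.deterministic import StageSpec
    from regilink.probabilistic import surgery_slk

    all_fields = StageSpec(1, ("SLK", "ICUAdmDt", "ICUDisDt", "HospAdmDt",
                               "HospDisDt", "Age", "Sex"), tolerant=True)
    for sid, iid in g.true_pairs.items():
        sr, ir = smap[sid], imap[iid]
        delta = (ir.icu_adm_date - sr.procedure_date).days
        assert 0 <= delta <= 2  # admission within the caliper of the procedure
        assert stage_agree(sr, ir, all_fields, cfg)
        # all shared fields are exactly equal; only the procedure/ICU
        # admission offset (the planted transfer delay) can differ
        assert sr.icu_dis_date == ir.icu_dis_date
        assert sr.hosp_adm_date == ir.hosp_adm_date
        assert sr.hosp_dis_date == ir.hosp_dis_date
        assert sr.age == ir.age and sr.sex == ir.sex
        assert surgery_slk(sr) == ir.slk


def test_gold_injective_and_labels_cover_cohort():
    s, i, g = generate(SMALL, ErrorModel(), seed=4)
    assert len(set(g.true_pairs.values())) == len(g.true_pairs)
    assert set(g.labels) == {r.record_id for r in s}
    assert set(g.labels.values()) <= {"clean", "hard"}
    with pytest.raises(ValueError):
        GoldStandard(true_pairs={"S1": "I1", "S2": "I1"})


def test_gold_round_trip(tmp_path):
    _, _, g = generate(SMALL, ErrorModel(), seed=5)
    write_gold(g, tmp_path / "gold.csv")
    back = read_gold(tmp_path / "gold.csv")
    assert back.true_pairs == g.true_pairs and back.labels == g.labels


def test_planted_pathology_rates_match_binomial_expectation():
    """Across seeds the planted pathology counts track their binomial
    means: blanked identities ≈ n·p, no-ICU records ≈ n·p."""
    errs = ErrorModel()
    blanked, no_icu, n_icu = [], [], []
    for seed in range(12):
        s, i, g = generate(SMALL, errs, seed=seed)
        blanked.append(sum(1 for r in i if not r.identity.surname and not r.identity.mrn))
        no_icu.append(sum(1 for r in s if r.record_id not in g.true_pairs
                          and g.labels[r.record_id] == "hard"))
        n_icu.append(len(i))
    exp_blank = np.mean(n_icu) * errs.p_missing_identity
    assert abs(np.mean(blanked) - exp_blank) < 3 * np.sqrt(exp_blank / 12) + 1
    # hard records = planted no-ICU + pre-op admissions
    exp_hard = 150 * (errs.p_no_icu + errs.p_preop_icu)
    assert abs(np.mean(no_icu) - exp_hard) < 3 * np.sqrt(exp_hard / 12) + 1


def test_blanked_rows_keep_their_key():
    s, i, g = generate(CohortParams(), ErrorModel(), seed=6)
    blanked = [r for r in i if not r.identity.surname and not r.identity.forename
               and not r.identity.mrn]
    assert blanked, "expected some deidentified rows at study scale"
    assert all(len(r.slk) == 14 for r in blanked)


def test_covariate_calibration_matched_stratum():
    """Matchable patients reproduce the target profile: mean age 63.5,
    77.3% male, risk-of-death median near 1.08%."""
    ages, males, risks = [], [], []
    for seed in range(3):
        s, _, g = generate(CohortParams(), ErrorModel(), seed=seed)
        clean = [r for r in s if g.labels[r.record_id] == "clean"]
        ages += [r.age for r in clean]
        males += [r.sex is Sex.MALE for r in clean]
        risks += [r.risk_of_death for r in clean]
    assert abs(np.mean(ages) - 63.5) < 1.0
    assert abs(np.mean(males) - 0.773) < 0.03
    assert 0.8 < 100 * np.median(risks) < 1.4


def test_hard_stratum_shifted_as_in_unmatched_profile():
    """Hard-to-match patients are younger, more urgent and higher-risk."""
    ages_c, ages_h, risk_c, risk_h, urg_c, urg_h = [], [], [], [], [], []
    for seed in range(8):
        s, _, g = generate(CohortParams(), ErrorModel(), seed=seed)
        for r in s:
            hard = g.labels[r.record_id] == "hard"
            (ages_h if hard else ages_c).append(r.age)
            (risk_h if hard else risk_c).append(r.risk_of_death)
            from regilink.records import Urgency
            (urg_h if hard else urg_c).append(r.urgency is Urgency.URGENT)
    assert np.mean(ages_h) < np.mean(ages_c)
    assert np.median(risk_h) > np.median(risk_c)
    assert np.mean(urg_h) > np.mean(urg_c)


def test_invalid_rates_rejected():
    with pytest.raises(ValueError):
        ErrorModel(p_no_icu=1.5)
    with pytest.raises(ValueError):
        ErrorModel(icu_delay_probs=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        CohortParams(p_male_clean=-0.1)
    with pytest.raises(ValueError):
        CohortParams(procedure_probs_clean=(0.5, 0.5, 0.5, 0.5))


def test_slk_errors_only_from_perturbed_sources():
    """Keys are rebuilt from the corrupted identity: whenever the stored
    key differs from the key of the stored identity the row was blanked,
    otherwise they coincide."""
    from regilink.slk581 import build_slk
    s, i, g = generate(SMALL, ErrorModel(p_name_typo=0.3, p_date_typo=0.3), seed=7)
    for r in i:
        if r.identity.surname and r.identity.dob:
            assert r.slk == build_slk(r.identity).value
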