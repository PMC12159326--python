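"""Symptom coding, outcomes, quintiles, cascade and agreement."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import rankdata

from deprisk.phenotypes import (
    AgreementTable,
    DiagnosisStatus,
    PhenotypeError,
    SymptomRecord,
    apply_exclusion_cascade,
    code_mdd_diagnosis,
    cohen_kappa,
    derive_incident_outcomes,
    derive_predictors,
    grade_ds,
    quintile_split,
)


def record(cm=False, ca=False, sec=0, sui=False) -> SymptomRecord:
    return SymptomRecord(
        participant_id="x",
        wave="baseline",
        reporter="youth",
        core_depressed_or_irritable=cm,
        core_anhedonia=ca,
        secondary_count=sec,
        suicidality=sui,
    )


# --- independent truth-table oracle, written from the clinical rule ---------


def oracle_mdd(cm: bool, ca: bool, sec: int) -> bool:
    # case iff at least one core symptom and five or more symptoms in total
    return (cm or ca) and (int(cm) + int(ca) + sec) >= 5


def oracle_grade(cm: bool, ca: bool, sec: int, sui: bool) -> int:
    cores = int(cm) + int(ca)
    total = cores + sec
    if (cores == 2 and sec >= 3) or sui:
        return 3
    if total in (7, 8) or (cores >= 1 and sec >= 2):
        return 2
    if total in (5, 6) or (cores >= 1 and sec >= 1):
        return 1
    return 0


ALL_COMBOS = list(itertools.product([False, True], [False, True], range(8), [False, True]))


def test_mdd_and_grade_match_exhaustive_truth_table():
    for cm, ca, sec, sui in ALL_COMBOS:
        r = record(cm, ca, sec, sui)
        assert code_mdd_diagnosis(r) == oracle_mdd(cm, ca, sec)
        assert grade_ds(r) == oracle_grade(cm, ca, sec, sui)


@pytest.mark.parametrize(
    "cm, ca, sec, expected",
    [
        (True, True, 3, True),  # both cores, total 5: threshold boundary
        (False, False, 7, False),  # no core symptom: never a case
        (True, False, 4, True),  # one core, total 5
        (True, False, 3, False),  # one core, total 4: below threshold
    ],
)
def test_mdd_threshold_examples(cm, ca, sec, expected):
    assert code_mdd_diagnosis(record(cm, ca, sec)) is expected


@pytest.mark.parametrize(
    "cm, ca, sec, sui, expected",
    [
        (True, False, 1, False, 1),  # one core + one secondary: mild
        (True, False, 2, False, 2),  # one core + two secondary: moderate
        (True, True, 3, False, 3),  # both cores + 3 secondary: severe
        (False, False, 0, True, 3),  # suicidality alone: severe
        (False, False, 0, False, 0),
        (False, False, 5, False, 1),  # five total without a core: mild
    ],
)
def test_ds_grade_examples(cm, ca, sec, sui, expected):
    assert grade_ds(record(cm, ca, sec, sui)) == expected


def test_grade_monotone_in_every_symptom():
    """Adding any single symptom never lowers the severity grade."""
    for cm, ca, sec, sui in ALL_COMBOS:
        g = grade_ds(record(cm, ca, sec, sui))
        if not cm:
            assert grade_ds(record(True, ca, sec, sui)) >= g
        if not ca:
            assert grade_ds(record(cm, True, sec, sui)) >= g
        if sec < 7:
            assert grade_ds(record(cm, ca, sec + 1, sui)) >= g
        if not sui:
            assert grade_ds(record(cm, ca, sec, True)) >= g


def test_mdd_implies_at_least_mild():
    for cm, ca, sec, sui in ALL_COMBOS:
        if code_mdd_diagnosis(record(cm, ca, sec, sui)):
            assert grade_ds(record(cm, ca, sec, sui)) >= 1


# --- incident outcomes ------------------------------------------------------


def status(mdd, grade, pid="x", reporter="youth", wave="baseline"):
    return DiagnosisStatus(pid, wave, reporter, mdd, grade)


def test_incident_outcomes():
    inc, up = derive_incident_outcomes(status(False, 0), status(True, 2, wave="followup"))
    assert inc and up  # control to case: incident, and grade stepped up
    inc, up = derive_incident_outcomes(status(False, 0), status(False, 1, wave="followup"))
    assert not inc and up  # none -> mild is a one-step increase
    inc, up = derive_incident_outcomes(status(False, 3), status(False, 3, wave="followup"))
    assert not inc and not up  # severe -> severe: no step up
    inc, up = derive_incident_outcomes(status(True, 2), status(True, 2, wave="followup"))
    assert not inc  # prevalent at baseline is not incident


def test_incident_outcomes_mismatch_errors():
    with pytest.raises(PhenotypeError):
        derive_incident_outcomes(status(False, 0), status(True, 2, pid="other"))
    with pytest.raises(PhenotypeError):
        derive_incident_outcomes(status(False, 0), status(True, 2, reporter="parent"))


# --- quintile split ---------------------------------------------------------


def oracle_quintiles(scores: np.ndarray) -> np.ndarray:
    """Brute-force percentile-rank assignment: category k iff the min-rank
    percentile falls in ((k-1)/5, k/5]."""
    n = len(scores)
    ranks = rankdata(scores, method="min")
    cats = np.empty(n, dtype=int)
    for i, r in enumerate(ranks):
        pr = r / n
        for k in range(1, 6):
            if pr <= k / 5 or k == 5:
                cats[i] = k
                break
    return cats


def test_quintile_balanced_split():
    cats = quintile_split(np.arange(1, 11), "higher_is_worse")
    assert cats.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]


def test_quintile_acceptance_orientation():
    # caregiver acceptance: higher score = better relationship = category 1
    cats = quintile_split(np.arange(10, 0, -1), "higher_is_better")
    assert cats.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]


def test_quintile_ties_share_lower_category_vs_oracle(rng):
    for _ in range(20):
        scores = rng.integers(0, 6, 37).astype(float)  # heavy ties
        cats = quintile_split(scores, "higher_is_worse")
        assert cats.tolist() == oracle_quintiles(scores).tolist()
        # tied values always share one category
        for v in np.unique(scores):
            assert len(set(cats[scores == v])) == 1


def test_quintile_degenerate_and_short_inputs():
    with pytest.raises(PhenotypeError):
        quintile_split(np.ones(20))
    with pytest.raises(PhenotypeError):
        quintile_split([1.0, 2.0, 3.0])


@given(st.lists(st.floats(-1e6, 1e6), min_size=10, max_size=200, unique=True))
def test_quintile_counts_balanced_without_ties(scores):
    counts = np.bincount(quintile_split(scores), minlength=6)[1:]
    assert counts.max() - counts.min() <= 1


# --- raw predictor derivation ----------------------------------------------


def raw_row(**overrides):
    row = {
        "sex": "M",
        "ethnicity_white": 1,
        "trauma_count": 0,
        "school_bores": 0,
        "grades_unimportant": 0,
        "lonely_item": 0,
        "fights_item": 0,
        "ran_away_item": 0,
        "alcohol_ever": 0,
        "tobacco_ever": 0,
        "cannabis_ever": 0,
        "other_drug_ever": 0,
        "caregiver1_q": 1,
        "caregiver2_q": 1,
        "family_conflict_q": 1,
    }
    row.update(overrides)
    return row


def test_derive_predictors_rules():
    p = derive_predictors(raw_row(school_bores=1, grades_unimportant=1))
    assert p["school_disengaged"] == 1
    p = derive_predictors(raw_row(school_bores=1))  # one item is not enough
    assert p["school_disengaged"] == 0
    assert derive_predictors(raw_row(trauma_count=3))["trauma"] == 2
    assert derive_predictors(raw_row(trauma_count=1))["trauma"] == 1
    assert derive_predictors(raw_row())["substance_ever"] == 0
    assert derive_predictors(raw_row(tobacco_ever=1))["substance_ever"] == 1
    assert derive_predictors(raw_row(sex="F"))["sex_female"] == 1
    assert derive_predictors(raw_row(ethnicity_white=0))["nonwhite"] == 1


def test_derive_predictors_missing_marker():
    p = derive_predictors(raw_row(lonely_item=np.nan))
    assert np.isnan(p["loneliness"])
    p = derive_predictors(raw_row(alcohol_ever=np.nan))
    assert np.isnan(p["substance_ever"])


# --- exclusion cascade ------------------------------------------------------


def analytic_frame(n, families=None, baseline_cases=(), missing=()):
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "family_id": families if families is not None else [f"F{i}" for i in range(n)],
            "site_id": ["S0"] * n,
            "attended_both": [True] * n,
            "youth_mdd_baseline": [i in baseline_cases for i in range(n)],
        }
    )
    from deprisk.predictors import PREDICTOR_NAMES

    for name in PREDICTOR_NAMES:
        ref = 1 if name.endswith("_q") else 0
        df[name] = float(ref)
    for i in missing:
        df.loc[i, "trauma"] = np.nan
    return df


def test_cascade_no_exclusions():
    df = analytic_frame(6)
    out, report = apply_exclusion_cascade(df, seed=0)
    assert len(out) == 6
    assert all(s.n_excluded == 0 for s in report.stages)


def test_cascade_family_sampling():
    df = analytic_frame(10, families=[f"F{i // 2}" for i in range(10)])
    out, report = apply_exclusion_cascade(df, seed=0)
    assert len(out) == 5
    assert out["family_id"].is_unique


def test_cascade_hand_enumerated_toy():
    # 8 participants, 2 baseline cases, 1 disjoint missing-predictor row -> 5
    df = analytic_frame(8, baseline_cases={0, 1}, missing={2})
    out, report = apply_exclusion_cascade(df, seed=3)
    assert len(out) == 5
    assert [s.n_excluded for s in report.stages] == [0, 0, 2, 1]


def test_cascade_counts_reconcile_and_idempotent(small_analytic):
    out, report = apply_exclusion_cascade(small_analytic, seed=11)
    for s in report.stages:
        assert s.n_after == s.n_before - s.n_excluded
    assert len(out) == len(small_analytic)  # second pass excludes nothing
    stages = [s.label for s in report.stages]
    assert stages == [
        "did not attend both waves",
        "sibling in sampled family",
        "MDD case at baseline",
        "missing predictor data",
    ]


def test_cascade_empty_stage_errors():
    df = analytic_frame(3, baseline_cases={0, 1, 2})
    with pytest.raises(PhenotypeError, match="baseline"):
        apply_exclusion_cascade(df, seed=0)


# --- Cohen's kappa ----------------------------------------------------------


def test_kappa_perfect_agreement():
    assert cohen_kappa(AgreementTable(10, 0, 0, 90)) == 1.0


def test_kappa_published_2x2():
    """The worked 2×2 from the analytic sample: 3 cases flagged by both
    reporters, 58 youth-reported and 52 parent-reported in N=7709."""
    k = cohen_kappa(AgreementTable(3, 55, 49, 7602))
    assert round(k, 3) == 0.048


def test_kappa_chance_level():
    # cells exactly proportional to marginal products: kappa = 0
    assert cohen_kappa(AgreementTable(10, 40, 10, 40)) == pytest.approx(0.0, abs=1e-12)


@given(
    st.tuples(
        st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(1, 500)
    )
)
def test_kappa_symmetries(cells):
    a, b, c, d = cells
    t = AgreementTable(a, b, c, d)
    swapped = AgreementTable(a, c, b, d)  # transpose: swap the raters
    relabeled = AgreementTable(d, c, b, a)  # swap positive/negative labels
    try:
        k = cohen_kappa(t)
    except PhenotypeError:
        return  # degenerate marginals
    assert cohen_kappa(swapped) == pytest.approx(k, abs=1e-12)
    assert cohen_kappa(relabeled) == pytest.approx(k, abs=1e-12)


def test_kappa_degenerate_marginals_error():
    with pytest.raises(PhenotypeError):
        cohen_kappa(AgreementTable(5, 0, 0, 0))
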