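"""MetS classification rules, counting logic, and the continuous score."""
import itertools

import numpy as np
import pandas as pd
import pytest

from metscreen.errors import (
    ClassificationError,
    CriteriaConstructionError,
    DegenerateCohortError,
)
from metscreen.mets import (
    COMPONENTS,
    ContinuousScoreSpec,
    PediatricPercentileTables,
    PercentileTable,
    build_default_criteria,
    classify_cohort,
    classify_mets,
    continuous_mets_score,
    idf_adult_criteria,
    pediatric_criteria,
)
from metscreen.cohort import CHILDREN, YOUNG_ADULTS


def _adult_row(sex="female", **overrides):
    row = dict(
        id="s0", sex=sex, age=22.0, waist=70.0, triglycerides=90.0,
        hdl=55.0, sbp=115.0, dbp=70.0, glucose=90.0,
    )
    row.update(overrides)
    return row


def test_idf_woman_three_abnormalities_is_mets():
    row = _adult_row(waist=85.0, triglycerides=160.0, hdl=45.0)
    res = classify_mets(row, idf_adult_criteria())
    assert res.component_flags == {
        "abdominal_obesity": True,
        "triglycerides": True,
        "hdl": True,
        "blood_pressure": False,
        "glucose": False,
    }
    assert res.n_abnormal == 3
    assert res.mets


def test_idf_man_same_values_is_clear():
    # male thresholds are WC >= 90 and HDL < 40, so this man is unflagged
    row = _adult_row(sex="male", waist=85.0, triglycerides=100.0, hdl=45.0)
    res = classify_mets(row, idf_adult_criteria())
    assert res.n_abnormal == 0
    assert not res.mets


@pytest.mark.parametrize(
    "field,value,component",
    [
        ("glucose", 100.0, "glucose"),          # inclusive >= boundary
        ("triglycerides", 150.0, "triglycerides"),
        ("sbp", 130.0, "blood_pressure"),
        ("dbp", 85.0, "blood_pressure"),
        ("waist", 80.0, "abdominal_obesity"),   # woman threshold
    ],
)
def test_idf_thresholds_are_inclusive_as_printed(field, value, component):
    row = _adult_row(**{field: value})
    res = classify_mets(row, idf_adult_criteria())
    assert res.component_flags[component]


def test_hdl_threshold_is_strict_less_than():
    assert not classify_mets(
        _adult_row(hdl=50.0), idf_adult_criteria()
    ).component_flags["hdl"]
    assert classify_mets(
        _adult_row(hdl=49.99), idf_adult_criteria()
    ).component_flags["hdl"]


def test_counting_rule_matches_truth_table_oracle():
    """All 2^5 flag patterns against exhaustive enumeration (>=3 rule)."""
    crit = idf_adult_criteria()
    makers = {
        "abdominal_obesity": lambda on: {"waist": 85.0 if on else 70.0},
        "triglycerides": lambda on: {"triglycerides": 160.0 if on else 90.0},
        "hdl": lambda on: {"hdl": 45.0 if on else 55.0},
        "blood_pressure": lambda on: {"sbp": 135.0 if on else 115.0},
        "glucose": lambda on: {"glucose": 105.0 if on else 90.0},
    }
    for pattern in itertools.product([False, True], repeat=5):
        row = _adult_row()
        for comp, on in zip(COMPONENTS, pattern):
            row.update(makers[comp](on))
        res = classify_mets(row, crit)
        assert tuple(res.component_flags[c] for c in COMPONENTS) == pattern
        assert res.n_abnormal == sum(pattern)
        assert res.mets == (sum(pattern) >= 3)


def test_worsening_any_component_never_lowers_count():
    worse = {
        "waist": 30.0, "triglycerides": 200.0, "sbp": 40.0,
        "glucose": 60.0, "hdl": -20.0,
    }
    base = _adult_row(waist=78.0, triglycerides=140.0, hdl=51.0,
                      sbp=125.0, glucose=95.0)
    n0 = classify_mets(base, idf_adult_criteria()).n_abnormal
    for field, delta in worse.items():
        row = dict(base)
        row[field] = row[field] + delta
        assert classify_mets(row, idf_adult_criteria()).n_abnormal >= n0


def test_missing_field_names_the_component():
    row = _adult_row()
    row["glucose"] = float("nan")
    with pytest.raises(ClassificationError, match="glucose"):
        classify_mets(row, idf_adult_criteria())


def test_mandatory_component_gate():
    crit = idf_adult_criteria(mandatory="abdominal_obesity")
    row = _adult_row(triglycerides=160.0, hdl=45.0, glucose=105.0)  # 3 flags
    res = classify_mets(row, crit)
    assert res.n_abnormal == 3 and not res.mets  # lacks central obesity


def test_default_criteria_by_age_group():
    adult = build_default_criteria(YOUNG_ADULTS)
    assert adult.name == "IDF-adult"
    with pytest.raises(CriteriaConstructionError, match="percentile"):
        build_default_criteria(CHILDREN, percentile_tables=None)


def _synthetic_pediatric_tables():
    """Synthetic percentile tables for tests (not a real reference)."""
    rows_wc, rows_sbp, rows_dbp = [], [], []
    for sex in ("female", "male"):
        for age in range(9, 18):
            rows_wc.append({"sex": sex, "age": age, "value": 60.0 + age})
            rows_sbp.append({"sex": sex, "age": age, "value": 115.0 + age / 2})
            rows_dbp.append({"sex": sex, "age": age, "value": 75.0})
    return PediatricPercentileTables(
        wc_p75=PercentileTable(pd.DataFrame(rows_wc)),
        sbp_p90=PercentileTable(pd.DataFrame(rows_sbp)),
        dbp_p90=PercentileTable(pd.DataFrame(rows_dbp)),
    )


def test_pediatric_hdl_threshold_depends_on_sex_and_age():
    crit = pediatric_criteria(_synthetic_pediatric_tables())
    base = dict(id="p", age=14.0, waist=60.0, triglycerides=80.0,
                sbp=100.0, dbp=60.0, glucose=90.0)
    girl = classify_mets({**base, "sex": "female", "hdl": 47.0}, crit)
    assert girl.component_flags["hdl"]  # < 50 flags girls at any age
    boy14 = classify_mets({**base, "sex": "male", "hdl": 47.0}, crit)
    assert boy14.component_flags["hdl"]  # boys under 15 still use < 50
    boy15 = classify_mets(
        {**base, "age": 15.0, "sex": "male", "hdl": 47.0}, crit
    )
    assert not boy15.component_flags["hdl"]  # threshold drops to 45


def test_pediatric_bp_uses_either_pressure_percentile():
    crit = pediatric_criteria(_synthetic_pediatric_tables())
    base = dict(id="p", sex="female", age=10.0, waist=60.0,
                triglycerides=80.0, hdl=55.0, glucose=90.0)
    assert classify_mets(
        {**base, "sbp": 125.0, "dbp": 60.0}, crit
    ).component_flags["blood_pressure"]
    assert classify_mets(
        {**base, "sbp": 110.0, "dbp": 80.0}, crit
    ).component_flags["blood_pressure"]
    assert not classify_mets(
        {**base, "sbp": 110.0, "dbp": 60.0}, crit
    ).component_flags["blood_pressure"]


def test_classify_cohort_appends_flags_and_count(analysis_df):
    assert {"n_abnormal", "mets"} <= set(analysis_df.columns)
    flag_cols = [f"flag_{c}" for c in COMPONENTS]
    counted = analysis_df[flag_cols].sum(axis=1)
    np.testing.assert_array_equal(counted, analysis_df["n_abnormal"])
    np.testing.assert_array_equal(
        analysis_df["mets"], analysis_df["n_abnormal"] >= 3
    )


# --- continuous score -----------------------------------------------------

def test_score_mean_is_zero_on_generated_cohort(analysis_df):
    score = continuous_mets_score(analysis_df)
    assert abs(score.mean()) < 1e-10


def test_identical_subjects_raise_degenerate_error():
    df = pd.DataFrame([_adult_row()] * 5)
    df["map"] = 85.0
    with pytest.raises(DegenerateCohortError):
        continuous_mets_score(df)


def test_two_subject_single_component_scores_are_symmetric():
    df = pd.DataFrame([
        {"waist": 70.0}, {"waist": 80.0},
    ])
    spec = ContinuousScoreSpec(components=(("waist", 1),))
    score = continuous_mets_score(df, spec)
    # z-score of two points with sample SD is +-1/sqrt(2)
    np.testing.assert_allclose(
        np.sort(score.to_numpy()),
        [-1 / np.sqrt(2), 1 / np.sqrt(2)],
        atol=1e-12,
    )


def test_score_invariant_under_affine_component_rescaling(analysis_df):
    df = analysis_df.copy()
    base = continuous_mets_score(df)
    df["triglycerides"] = df["triglycerides"] * 0.0113 + 3.0  # mg/dL -> mmol/L-ish
    rescaled = continuous_mets_score(df)
    np.testing.assert_allclose(base, rescaled, atol=1e-10)


def test_score_invariant_under_row_permutation(analysis_df, rng):
    base = continuous_mets_score(analysis_df)
    perm = rng.permutation(len(analysis_df))
    shuffled = analysis_df.iloc[perm]
    score_perm = continuous_mets_score(shuffled)
    np.testing.assert_allclose(
        score_perm.to_numpy(), base.iloc[perm].to_numpy(), atol=1e-12
    )


def test_sum_aggregation_is_five_times_mean(analysis_df):
    mean_s = continuous_mets_score(analysis_df, ContinuousScoreSpec())
    sum_s = continuous_mets_score(
        analysis_df, ContinuousScoreSpec(aggregation="sum")
    )
    np.testing.assert_allclose(sum_s, 5.0 * mean_s, atol=1e-10)


def test_hdl_enters_with_negative_sign(analysis_df):
    df = analysis_df.copy()
    base = continuous_mets_score(df)
    df.loc[df.index[0], "hdl"] += 40.0  # raising HDL must lower the score
    assert continuous_mets_score(df).iloc[0] < base.iloc[0]
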