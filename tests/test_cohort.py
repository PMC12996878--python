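"""Eligibility logic, index dates, Charlson scoring, BMI selection."""
import numpy as np
import pandas as pd
import pytest

from nsburden.cohort import (
    ATTRITION_REASONS,
    bmi_at_index,
    compute_cci,
    derive_index_date,
    is_schizophrenia_code,
    select_ehr_cohort,
    select_linked_cohort,
)


# ---------------------------------------------------------------------------
# index date


@pytest.mark.parametrize(
    "code,expected",
    [("295.30", True), ("F20.9", True), ("f209", True), ("29590", True),
     ("F21", False), ("E11.9", False), ("2950", True)],
)
def test_schizophrenia_code_prefix_match(code, expected):
    assert is_schizophrenia_code(code) == expected


def test_index_date_is_earliest_in_window():
    dx = [("2017-05-01", "F20.0"), ("2016-03-02", "295.30")]
    assert derive_index_date(dx) == pd.Timestamp("2016-03-02")


def test_index_date_none_without_schizophrenia_codes():
    assert derive_index_date([("2018-01-01", "E11.9")]) is None


def test_index_date_none_outside_window():
    assert derive_index_date([("2015-12-31", "F20.9")]) is None


# ---------------------------------------------------------------------------
# EHR cohort selection


def _base_tables():
    patients = pd.DataFrame(
        {
            "patient_id": ["ok", "young", "single", "short_lb", "excl"],
            "birth_date": ["1980-01-01", "2001-01-01", "1975-05-05", "1990-03-03", "1960-10-10"],
            "gender": ["male"] * 5,
            "race": ["White"] * 5,
            "ethnicity": ["Unknown"] * 5,
            "region": ["South"] * 5,
            "payer": ["Medicaid"] * 5,
        }
    )
    dx_rows = []
    for pid in ["ok", "young", "single", "short_lb", "excl"]:
        dx_rows.append((pid, "2018-06-01", "F20.9", "outpatient"))
        if pid != "single":
            dx_rows.append((pid, "2018-09-01", "F20.9", "outpatient"))
    dx_rows.append(("excl", "2012-04-01", "G40.909", "outpatient"))  # epilepsy, lifetime
    diagnoses = pd.DataFrame(dx_rows, columns=["patient_id", "date", "code", "setting"])
    enc_rows = [
        ("ok", "2016-01-15", "visit"),
        ("young", "2016-01-15", "visit"),
        ("single", "2016-01-15", "visit"),
        ("short_lb", "2017-09-05", "visit"),  # 270 days before index
        ("excl", "2016-01-15", "visit"),
    ]
    encounters = pd.DataFrame(enc_rows, columns=["patient_id", "date", "kind"])
    return patients, diagnoses, encounters


def test_eligibility_reasons_and_partition():
    patients, dx, enc = _base_tables()
    cohort, attrition = select_ehr_cohort(patients, dx, enc)
    assert list(cohort["patient_id"]) == ["ok"]
    counts = attrition.set_index("reason")["n"]
    assert counts["age"] == 1  # 17 at index
    assert counts["encounters"] == 1
    assert counts["lookback"] == 1
    assert counts["excl_dx"] == 1
    assert counts.sum() == len(patients)  # partition property


def test_cohort_is_order_independent():
    patients, dx, enc = _base_tables()
    rng = np.random.default_rng(8)
    shuffled_dx = dx.sample(frac=1.0, random_state=3).reset_index(drop=True)
    shuffled_enc = enc.sample(frac=1.0, random_state=4).reset_index(drop=True)
    a, _ = select_ehr_cohort(patients, dx, enc)
    b, _ = select_ehr_cohort(patients, shuffled_dx, shuffled_enc)
    assert sorted(a["patient_id"]) == sorted(b["patient_id"])


def test_unknown_patient_in_events_is_error():
    patients, dx, enc = _base_tables()
    dx = pd.concat(
        [dx, pd.DataFrame([("ghost", "2018-01-01", "F20.9", "outpatient")], columns=dx.columns)]
    )
    with pytest.raises(ValueError, match="ghost"):
        select_ehr_cohort(patients, dx, enc)


# ---------------------------------------------------------------------------
# linked cohort / continuous enrollment


def _cohort_row():
    return pd.DataFrame(
        {"patient_id": ["p1"], "index_date": [pd.Timestamp("2018-06-01")]}
    )


def _spans(rows):
    return pd.DataFrame(rows, columns=["patient_id", "start", "end", "benefit"])


def test_full_coverage_included():
    enr = _spans([("p1", "2018-05-01", "2019-08-01", "both")])
    out = select_linked_cohort(_cohort_row(), enr)
    assert out["in_linked_cohort"].all()


def test_45_day_gap_excluded_but_small_gap_bridged():
    gap45 = _spans(
        [
            ("p1", "2018-05-01", "2018-11-28", "both"),
            ("p1", "2019-01-13", "2019-08-01", "both"),  # 45-day gap
        ]
    )
    assert not select_linked_cohort(_cohort_row(), gap45)["in_linked_cohort"].any()
    gap20 = _spans(
        [
            ("p1", "2018-05-01", "2018-11-28", "both"),
            ("p1", "2018-12-19", "2019-08-01", "both"),  # 20-day gap, bridged
        ]
    )
    assert select_linked_cohort(_cohort_row(), gap20)["in_linked_cohort"].all()


def test_missing_pharmacy_benefit_excluded():
    enr = _spans([("p1", "2018-05-01", "2019-08-01", "medical")])
    assert not select_linked_cohort(_cohort_row(), enr)["in_linked_cohort"].any()


# ---------------------------------------------------------------------------
# Charlson comorbidity index


def test_cci_empty_is_zero():
    score, flags = compute_cci([])
    assert score == 0
    assert not any(flags.values())


#: hand-scored with the original Charlson weight table
CCI_GOLDEN = [
    ([], 0),
    (["E119", "I509"], 2),  # diabetes (1) + CHF (1)
    (["C782"], 6),  # metastatic solid tumor
    (["B20"], 6),  # HIV/AIDS
    (["K700", "K704"], 3),  # severe liver supersedes mild
    (["E119", "E112"], 2),  # complicated diabetes supersedes plain
    (["I219", "I702", "J449"], 3),  # MI + PVD + COPD
    (["N189", "G819"], 4),  # renal (2) + hemiplegia (2)
    (["M059", "K259", "F039"], 3),  # rheumatic + PUD + dementia
    (["C349", "C509"], 2),  # two malignancy codes count once
    (["I652", "I10"], 1),  # cerebrovascular 1; hypertension tracked at weight 0
    # every tier at once: 8x1 + 3 + 2 + 2 + 2 + 6 = 23
    (["I219", "I509", "I702", "I652", "F039", "J449", "M060", "K269",
      "K700", "K721", "E112", "G819", "N189", "C349", "C772"], 23),
]


@pytest.mark.parametrize("codes,expected", CCI_GOLDEN)
def test_cci_golden_fixture(codes, expected):
    score, flags = compute_cci(codes)
    assert score == expected
    # score equals the weighted sum over the reported flags
    from nsburden.cohort import default_charlson_map

    weights, _ = default_charlson_map()
    assert score == sum(w for c, w in weights.items() if flags[c])


def test_cci_icd9_codes_score():
    score, flags = compute_cci(["41090", "4280"])  # ICD-9 MI + CHF
    assert score == 2
    assert flags["myocardial_infarction"] and flags["congestive_heart_failure"]


# ---------------------------------------------------------------------------
# BMI


def test_bmi_nearest_wins():
    obs = [("2018-05-02", 31.0), ("2017-11-13", 28.0)]  # -30d vs -200d
    assert bmi_at_index(obs, "2018-06-01") == 31.0


def test_bmi_missing_outside_window():
    assert bmi_at_index([("2016-01-01", 30.0)], "2018-06-01") is None


def test_bmi_tie_breaks_to_pre_index():
    obs = [("2018-05-22", 27.0), ("2018-06-11", 33.0)]  # -10d vs +10d
    assert bmi_at_index(obs, "2018-06-01") == 27.0


def test_bmi_nonpositive_dropped():
    obs = [("2018-05-30", -1.0), ("2018-05-01", 29.0)]
    assert bmi_at_index(obs, "2018-06-01") == 29.0


def test_attrition_reason_order_is_stable():
    assert ATTRITION_REASONS == ("no_index", "age", "encounters", "lookback", "excl_dx")
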