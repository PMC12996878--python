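"""PPPY utilization/cost summaries and unadjusted group comparisons."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nsburden.outcomes import (
    compare_groups,
    costs_frame,
    summarize_costs,
    summarize_utilization,
    utilization_frame,
)

IDX = "2018-01-01"


def _claims(rows):
    cols = ["patient_id", "date", "setting", "category", "psychosocial_type",
            "paid_cost", "schizophrenia_related", "admission_id", "los_days"]
    return pd.DataFrame(rows, columns=cols)


def _line(date, setting, category="medical", cost=0.0, sz=False, adm=None, los=None, ptype=None):
    return ("p1", date, setting, category, ptype, cost, sz, adm, los)


def test_three_admissions_ten_days():
    claims = _claims(
        [
            _line("2018-02-01", "inpatient", cost=100, adm="a1", los=3),
            _line("2018-05-01", "inpatient", cost=100, adm="a2", los=5),
            _line("2018-08-01", "inpatient", cost=100, adm="a3", los=2),
        ]
    )
    s = summarize_utilization(claims, IDX, "p1")
    assert s.hospitalizations == 3
    assert s.hospitalized_days == 10


def test_zero_claims_all_zero():
    s = summarize_utilization(_claims([]), IDX, "p1")
    assert s.all_cause_claims == 0 and s.hospitalizations == 0
    assert not s.any_psychiatric_rx and not s.any_psychosocial


def test_all_cause_claims_is_line_count():
    rows = (
        [_line(f"2018-01-{d+1:02d}", "outpatient") for d in range(28)]
        + [_line(f"2018-02-{d+1:02d}", "outpatient") for d in range(12)]
        + [_line("2018-03-01", "emergency"), _line("2018-03-02", "emergency")]
        + [_line(f"2018-04-{d+1:02d}", "pharmacy", category="pharmacy") for d in range(28)]
        + [_line(f"2018-05-{d+1:02d}", "pharmacy", category="pharmacy") for d in range(2)]
    )
    s = summarize_utilization(_claims(rows), IDX, "p1")
    assert s.outpatient_visits == 40
    assert s.ed_visits == 2
    assert s.pharmacy_claims == 30
    assert s.all_cause_claims == 72


def test_claims_outside_window_ignored():
    claims = _claims(
        [
            _line("2017-12-31", "outpatient"),  # pre-index
            _line("2019-01-05", "outpatient"),  # past index+364
            _line("2018-06-01", "outpatient"),
        ]
    )
    assert summarize_utilization(claims, IDX, "p1").all_cause_claims == 1


def test_admission_days_truncated_at_window_end():
    claims = _claims([_line("2018-12-25", "inpatient", adm="a1", los=30)])
    s = summarize_utilization(claims, IDX, "p1")
    # 2018-12-25 .. 2018-12-31 inclusive (index+364 = 2018-12-31)
    assert s.hospitalized_days == 7


def test_single_inpatient_cost_line():
    claims = _claims([_line("2018-03-01", "inpatient", cost=1000.0, adm="a1", los=2)])
    c = summarize_costs(claims, IDX, "p1")
    assert c.inpatient_cost == 1000.0
    assert c.all_cause_cost == 1000.0
    assert c.outpatient_cost == 0.0


def test_no_claims_zero_costs():
    c = summarize_costs(_claims([]), IDX, "p1")
    assert c.all_cause_cost == 0.0 and c.schizophrenia_related_cost == 0.0


def test_mixed_cost_fixture_hand_summed():
    claims = _claims(
        [
            _line("2018-01-10", "inpatient", cost=1000.0, sz=True, adm="a1", los=2),
            _line("2018-02-10", "inpatient", cost=2500.0, adm="a2", los=4),
            _line("2018-03-10", "outpatient", cost=300.0, sz=True),
            _line("2018-04-10", "outpatient", cost=200.0),
            _line("2018-05-10", "emergency", cost=450.0),
            _line("2018-06-10", "pharmacy", category="pharmacy", cost=75.0, sz=True),
            _line("2018-07-10", "pharmacy", category="pharmacy", cost=25.0),
            _line("2018-08-10", "outpatient", cost=500.0),
        ]
    )
    c = summarize_costs(claims, IDX, "p1")
    assert c.inpatient_cost == 3500.0
    assert c.outpatient_cost == 1000.0
    assert c.all_cause_cost == 5050.0
    assert c.schizophrenia_related_cost == 1375.0


def test_negative_cost_is_error():
    claims = _claims([_line("2018-03-01", "outpatient", cost=-5.0)])
    with pytest.raises(ValueError, match="negative"):
        summarize_costs(claims, IDX, "p1")


def test_frame_versions_match_per_patient(smoke_bundle):
    """Vectorized cohort summaries equal the per-patient implementation."""
    cohort = smoke_bundle.claims["patient_id"].drop_duplicates().head(25).to_frame()
    # anchor each patient's window at their first claim; both code paths see
    # the same anchor, so the equality check is exact
    truth_idx = smoke_bundle.claims.groupby("patient_id")["date"].min()
    cohort["index_date"] = cohort["patient_id"].map(truth_idx)
    util = utilization_frame(smoke_bundle.claims, cohort).set_index("patient_id")
    costs = costs_frame(smoke_bundle.claims, cohort).set_index("patient_id")
    for row in cohort.itertuples():
        mine = smoke_bundle.claims[smoke_bundle.claims.patient_id == row.patient_id]
        s = summarize_utilization(mine, row.index_date, row.patient_id)
        c = summarize_costs(mine, row.index_date, row.patient_id)
        assert util.at[row.patient_id, "hospitalizations"] == s.hospitalizations
        assert util.at[row.patient_id, "hospitalized_days"] == s.hospitalized_days
        assert util.at[row.patient_id, "all_cause_claims"] == s.all_cause_claims
        assert util.at[row.patient_id, "outpatient_visits"] == s.outpatient_visits
        assert costs.at[row.patient_id, "all_cause_cost"] == pytest.approx(c.all_cause_cost)
        assert costs.at[row.patient_id, "inpatient_cost"] == pytest.approx(c.inpatient_cost)


def test_group_mean_is_mean_of_patient_values(smoke_bundle):
    cohort = smoke_bundle.claims["patient_id"].drop_duplicates().to_frame()
    truth_idx = smoke_bundle.claims.groupby("patient_id")["date"].min()
    cohort["index_date"] = cohort["patient_id"].map(truth_idx)
    util = utilization_frame(smoke_bundle.claims, cohort)
    assert util["outpatient_visits"].mean() == pytest.approx(
        np.mean(util["outpatient_visits"].to_numpy())
    )
    # psychosocial per-type share never exceeds the any-psychosocial share
    any_share = util["any_psychosocial"].mean()
    for t in ("psychotherapy", "cbt", "group_therapy"):
        assert util[f"psychosocial_{t}"].mean() <= any_share + 1e-12


# ---------------------------------------------------------------------------
# group comparisons


def test_identical_samples_t_zero_p_one():
    data = pd.DataFrame({"ns": [1] * 4 + [0] * 4, "y": [1.0, 2.0, 3.0, 4.0] * 2})
    c = compare_groups(data, "y", "continuous")
    assert c.statistic == pytest.approx(0.0)
    assert c.p_value == pytest.approx(1.0)


def test_constant_outcome_flagged_degenerate():
    data = pd.DataFrame({"ns": [1, 1, 0, 0], "y": [2.0, 2.0, 2.0, 2.0]})
    c = compare_groups(data, "y", "continuous")
    assert c.degenerate and c.statistic is None


def test_balanced_table_chi_square_zero():
    data = pd.DataFrame({"ns": [1] * 20 + [0] * 20, "y": ([True] * 10 + [False] * 10) * 2})
    c = compare_groups(data, "y", "categorical")
    assert c.statistic == pytest.approx(0.0)
    assert c.p_value == pytest.approx(1.0)


def test_chi_square_matches_hand_computation():
    """2x2 table (30,10;10,30): X^2 = N(ad-bc)^2 / (row/col products) = 20."""
    data = pd.DataFrame(
        {"ns": [1] * 40 + [0] * 40, "y": [True] * 30 + [False] * 10 + [True] * 10 + [False] * 30}
    )
    c = compare_groups(data, "y", "categorical")
    assert c.statistic == pytest.approx(20.0)
    assert c.p_value == pytest.approx(float(stats.chi2.sf(20.0, 1)))


def test_welch_t_test_on_unequal_variances():
    rng = np.random.default_rng(5)
    data = pd.DataFrame(
        {
            "ns": [1] * 50 + [0] * 50,
            "y": np.concatenate([rng.normal(5, 3, 50), rng.normal(4, 1, 50)]),
        }
    )
    c = compare_groups(data, "y", "continuous")
    a, b = data.loc[data.ns == 1, "y"], data.loc[data.ns == 0, "y"]
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    assert c.statistic == pytest.approx(float(stat))
    assert c.p_value == pytest.approx(float(p))
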