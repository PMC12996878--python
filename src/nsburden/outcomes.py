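"""Post-index treatment patterns, utilization, and cost summaries (PPPY).

All measures are restricted to the 12 months following the index date,
[index, index + 364]; with a fixed one-year window the per-patient-per-year
(PPPY) value equals the raw annual value.  Group contrasts use Welch t-tests
for continuous measures and chi-square tests for proportions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import POST_INDEX_DAYS

logger = logging.getLogger(__name__)

CLAIM_SETTINGS = ("outpatient", "inpatient", "emergency", "pharmacy")
DRUG_CLASSES = ("antipsychotic_fga", "antipsychotic_sga", "mood_stabilizer", "antidepressant")
PSYCHOSOCIAL_TYPES = ("cbt", "psychotherapy", "family_therapy", "psychosocial_rehab", "group_therapy")


@dataclass(frozen=True)
class UtilizationSummary:
    patient_id: str
    outpatient_visits: int
    hospitalizations: int
    hospitalized_days: int
    ed_visits: int
    all_cause_claims: int
    pharmacy_claims: int
    psychosocial_visits: int
    any_psychiatric_rx: bool
    fga: bool
    sga: bool
    mood_stabilizer: bool
    antidepressant: bool
    any_psychosocial: bool
    psychosocial_types: Mapping[str, bool]


@dataclass(frozen=True)
class CostSummary:
    patient_id: str
    inpatient_cost: float
    outpatient_cost: float
    all_cause_cost: float
    schizophrenia_related_cost: float


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    group_values: Mapping[str, float]
    test: str  # "t_test" | "chi_square"
    statistic: Optional[float]
    p_value: Optional[float]
    degenerate: bool = False


def _window_claims(claims: pd.DataFrame, index_date, followup_days: int) -> pd.DataFrame:
    c = claims.copy()
    c["date"] = pd.to_datetime(c["date"])
    idx = pd.Timestamp(index_date)
    hi = idx + pd.Timedelta(days=followup_days - 1)
    return c.loc[c["date"].between(idx, hi)]


def summarize_utilization(
    claims: pd.DataFrame,
    index_date,
    patient_id: str = "",
    followup_days: int = POST_INDEX_DAYS,
    enrollment: pd.DataFrame | None = None,
) -> UtilizationSummary:
    """Annual utilization counts and treatment flags for one patient.

    Hospitalizations count unique admission ids; hospitalized days sum each
    admission's length of stay, truncated at the follow-up window end.  A
    claim outside the patient's enrollment (when spans are supplied) is
    logged but still counted.
    """
    c = _window_claims(claims, index_date, followup_days)
    if enrollment is not None and len(c):
        covered = np.zeros(len(c), dtype=bool)
        for span in enrollment.itertuples():
            covered |= c["date"].between(
                pd.Timestamp(span.start), pd.Timestamp(span.end)
            ).to_numpy()
        if not covered.all():
            logger.warning(
                "%d claim(s) for patient %s fall outside enrollment; counted anyway",
                int((~covered).sum()), patient_id,
            )
    idx = pd.Timestamp(index_date)
    window_end = idx + pd.Timedelta(days=followup_days - 1)

    inpat = c.loc[c["setting"] == "inpatient"]
    admissions = inpat.drop_duplicates(subset="admission_id")
    days = 0
    for adm in admissions.itertuples():
        los = int(adm.los_days)
        last_covered = min(adm.date + pd.Timedelta(days=los - 1), window_end)
        days += max((last_covered - adm.date).days + 1, 0)

    categories = set(c["category"])
    psychosocial = c.loc[c["category"] == "psychosocial"]
    types_present = set(psychosocial["psychosocial_type"].dropna())
    return UtilizationSummary(
        patient_id=patient_id,
        outpatient_visits=int((c["setting"] == "outpatient").sum()),
        hospitalizations=int(len(admissions)),
        hospitalized_days=int(days),
        ed_visits=int((c["setting"] == "emergency").sum()),
        all_cause_claims=int(len(c)),
        pharmacy_claims=int((c["setting"] == "pharmacy").sum()),
        psychosocial_visits=int(len(psychosocial)),
        any_psychiatric_rx=bool(categories & set(DRUG_CLASSES)),
        fga="antipsychotic_fga" in categories,
        sga="antipsychotic_sga" in categories,
        mood_stabilizer="mood_stabilizer" in categories,
        antidepressant="antidepressant" in categories,
        any_psychosocial=len(psychosocial) > 0,
        psychosocial_types={t: t in types_present for t in PSYCHOSOCIAL_TYPES},
    )


def summarize_costs(
    claims: pd.DataFrame,
    index_date,
    patient_id: str = "",
    followup_days: int = POST_INDEX_DAYS,
) -> CostSummary:
    """Annual paid costs by setting for one patient; negative costs are an error."""
    c = _window_claims(claims, index_date, followup_days)
    if (c["paid_cost"] < 0).any():
        raise ValueError(f"negative paid_cost for patient {patient_id!r}")
    return CostSummary(
        patient_id=patient_id,
        inpatient_cost=float(c.loc[c["setting"] == "inpatient", "paid_cost"].sum()),
        outpatient_cost=float(c.loc[c["setting"] == "outpatient", "paid_cost"].sum()),
        all_cause_cost=float(c["paid_cost"].sum()),
        schizophrenia_related_cost=float(
            c.loc[c["schizophrenia_related"].astype(bool), "paid_cost"].sum()
        ),
    )


# ---------------------------------------------------------------------------
# vectorized per-cohort versions (identical definitions, one row per patient)


def utilization_frame(
    claims: pd.DataFrame, cohort: pd.DataFrame, followup_days: int = POST_INDEX_DAYS
) -> pd.DataFrame:
    c = claims.merge(cohort[["patient_id", "index_date"]], on="patient_id", how="inner")
    c["date"] = pd.to_datetime(c["date"])
    c["index_date"] = pd.to_datetime(c["index_date"])
    delta = (c["date"] - c["index_date"]).dt.days
    c = c.loc[(delta >= 0) & (delta < followup_days)].copy()
    c["_win_end"] = c["index_date"] + pd.Timedelta(days=followup_days - 1)

    out = pd.DataFrame(index=cohort["patient_id"].astype(str))
    for setting, col in (
        ("outpatient", "outpatient_visits"),
        ("emergency", "ed_visits"),
        ("pharmacy", "pharmacy_claims"),
    ):
        out[col] = c.loc[c["setting"] == setting].groupby("patient_id").size()
    out["all_cause_claims"] = c.groupby("patient_id").size()

    inpat = c.loc[c["setting"] == "inpatient"].drop_duplicates(
        subset=["patient_id", "admission_id"]
    ).copy()
    if len(inpat):
        end = inpat["date"] + pd.to_timedelta(
            inpat["los_days"].astype(int) - 1, unit="D"
        )
        capped = np.minimum(end, inpat["_win_end"])
        inpat["_days"] = ((capped - inpat["date"]).dt.days + 1).clip(lower=0)
        gi = inpat.groupby("patient_id")
        out["hospitalizations"] = gi.size()
        out["hospitalized_days"] = gi["_days"].sum()
    else:
        out["hospitalizations"] = 0
        out["hospitalized_days"] = 0

    psycho = c.loc[c["category"] == "psychosocial"]
    out["psychosocial_visits"] = psycho.groupby("patient_id").size()
    out["any_psychosocial"] = out["psychosocial_visits"].fillna(0) > 0
    for t in PSYCHOSOCIAL_TYPES:
        out[f"psychosocial_{t}"] = (
            psycho.loc[psycho["psychosocial_type"] == t].groupby("patient_id").size() > 0
        )
    for cls, col in zip(DRUG_CLASSES, ("fga", "sga", "mood_stabilizer", "antidepressant")):
        out[col] = c.loc[c["category"] == cls].groupby("patient_id").size() > 0
    count_cols = [
        "outpatient_visits", "ed_visits", "pharmacy_claims", "all_cause_claims",
        "hospitalizations", "hospitalized_days", "psychosocial_visits",
    ]
    out[count_cols] = out[count_cols].fillna(0).astype(int)
    bool_cols = [col for col in out.columns if col not in count_cols]
    for col in bool_cols:
        out[col] = out[col].astype("boolean").fillna(False).astype(bool)
    out["any_psychiatric_rx"] = (
        out[["fga", "sga", "mood_stabilizer", "antidepressant"]].any(axis=1)
    )
    return out.reset_index()


def costs_frame(
    claims: pd.DataFrame, cohort: pd.DataFrame, followup_days: int = POST_INDEX_DAYS
) -> pd.DataFrame:
    if (claims["paid_cost"] < 0).any():
        raise ValueError("negative paid_cost in claims")
    c = claims.merge(cohort[["patient_id", "index_date"]], on="patient_id", how="inner")
    c["date"] = pd.to_datetime(c["date"])
    c["index_date"] = pd.to_datetime(c["index_date"])
    delta = (c["date"] - c["index_date"]).dt.days
    c = c.loc[(delta >= 0) & (delta < followup_days)]
    g = c.groupby("patient_id")["paid_cost"]
    out = pd.DataFrame(index=cohort["patient_id"].astype(str))
    out["all_cause_cost"] = g.sum()
    for setting, col in (("inpatient", "inpatient_cost"), ("outpatient", "outpatient_cost")):
        out[col] = (
            c.loc[c["setting"] == setting].groupby("patient_id")["paid_cost"].sum()
        )
    out["schizophrenia_related_cost"] = (
        c.loc[c["schizophrenia_related"].astype(bool)]
        .groupby("patient_id")["paid_cost"]
        .sum()
    )
    return out.fillna(0.0).reset_index()


# ---------------------------------------------------------------------------
# unadjusted group comparisons


def compare_groups(
    data: pd.DataFrame,
    variable: str,
    kind: str,
    group_col: str = "ns",
    welch: bool = True,
) -> GroupComparison:
    """Two-group contrast: Welch t-test (continuous) or chi-square (categorical).

    The chi-square uses no continuity correction when every expected cell
    count is >= 5, and Yates' correction otherwise.  Zero variance in both
    groups leaves the t statistic undefined (flagged, not raised).
    """
    groups = sorted(data[group_col].unique(), reverse=True)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups in {group_col!r}, got {groups}")
    a = data.loc[data[group_col] == groups[0], variable]
    b = data.loc[data[group_col] == groups[1], variable]
    if a.empty or b.empty:
        raise ValueError("both groups must be non-empty")
    if kind == "continuous":
        values = {str(groups[0]): float(a.mean()), str(groups[1]): float(b.mean())}
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            return GroupComparison(variable, values, "t_test", None, None, degenerate=True)
        stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        return GroupComparison(variable, values, "t_test", float(stat), float(p))
    if kind == "categorical":
        table = np.array(
            [
                [int(a.astype(bool).sum()), int(len(a) - a.astype(bool).sum())],
                [int(b.astype(bool).sum()), int(len(b) - b.astype(bool).sum())],
            ]
        )
        values = {
            str(groups[0]): float(table[0, 0] / table[0].sum()),
            str(groups[1]): float(table[1, 0] / table[1].sum()),
        }
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return GroupComparison(variable, values, "chi_square", None, None, degenerate=True)
        expected = stats.contingency.expected_freq(table)
        correction = bool((expected < 5).any())
        stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
        return GroupComparison(variable, values, "chi_square", float(stat), float(p))
    raise ValueError(f"unknown kind {kind!r}")


def comparison_table(
    data: pd.DataFrame,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
    group_col: str = "ns",
) -> pd.DataFrame:
    """Utilization/cost report: group means (or %) and test results per variable."""
    rows = []
    for var in continuous:
        c = compare_groups(data, var, "continuous", group_col)
        rows.append(_row(c))
    for var in categorical:
        c = compare_groups(data, var, "categorical", group_col)
        rows.append(_row(c))
    return pd.DataFrame(rows)


def _row(c: GroupComparison) -> dict:
    keys = list(c.group_values)
    return {
        "variable": c.variable,
        f"group_{keys[0]}": c.group_values[keys[0]],
        f"group_{keys[1]}": c.group_values[keys[1]],
        "test": c.test,
        "statistic": c.statistic,
        "p_value": c.p_value,
        "degenerate": c.degenerate,
    }
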