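"""Cohort eligibility, index dates, and baseline covariates.

Eligibility for the EHR cohort follows the study design of a retrospective
schizophrenia cohort drawn from ambulatory EHR data:

* a schizophrenia diagnosis (ICD-9 295.xx / ICD-10-CM F20.x) inside the study
  window (default 2016-01-01 .. 2023-02-28); the index date is the first such
  diagnosis;
* age >= 18 at index;
* >= 2 outpatient schizophrenia encounters on or after 2016-01-01;
* >= 12 months of EHR activity (any recorded event) before index;
* no lifetime diagnosis from an exclusion list of dementia/cognitive-impairment
  conditions (dementia, frontotemporal lobe disease, prion disease, autism
  spectrum disorder, epilepsy, intellectual disability, multiple sclerosis,
  Parkinson's disease, stroke, traumatic brain injury).

The linked-claims subcohort additionally requires continuous medical and
pharmacy enrollment for the year after index (gaps of <= 30 days bridged, the
usual claims convention).

Baseline covariates are assessed over the 12-month pre-index window
[index-365, index-1]: Charlson Comorbidity Index (original weights, Quan ICD
mappings), psychiatric comorbidity flags, and the BMI value closest to the
index date.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

STUDY_START = pd.Timestamp("2016-01-01")
STUDY_END = pd.Timestamp("2023-02-28")

PRE_INDEX_DAYS = 365
POST_INDEX_DAYS = 365
ENROLLMENT_MAX_GAP_DAYS = 30

#: attrition reasons, in the precedence order they are assigned
ATTRITION_REASONS = ("no_index", "age", "encounters", "lookback", "excl_dx")

PSYCHIATRIC_FLAGS = ("anxiety", "bipolar", "depression", "panic", "ptsd", "substance_use")

#: Charlson component hierarchies: the severe form supersedes the mild one
CCI_HIERARCHY = (
    ("diabetes_with_complications", "diabetes_without_complications"),
    ("metastatic_solid_tumor", "any_malignancy"),
    ("moderate_severe_liver_disease", "mild_liver_disease"),
)


def _norm_code(code: str) -> str:
    return str(code).strip().upper().replace(".", "")


def is_schizophrenia_code(code: str) -> bool:
    """Prefix test after dot-stripping: ICD-9 295.xx or ICD-10-CM F20.x."""
    c = _norm_code(code)
    return c.startswith("295") or c.startswith("F20")


# ---------------------------------------------------------------------------
# code mappings (packaged editable CSVs)


def _data_path(name: str) -> Path:
    return Path(resources.files("nsburden").joinpath(f"data/{name}"))  # type: ignore[arg-type]


def load_condition_map(path: str | Path) -> dict[str, list[str]]:
    """condition -> list of normalized code prefixes (ICD-9 and ICD-10 pooled)."""
    out: dict[str, list[str]] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["condition"], []).append(_norm_code(row["code_prefix"]))
    return out


def load_charlson_map(path: str | Path | None = None) -> tuple[dict[str, int], dict[str, list[str]]]:
    """Returns ({condition: weight}, {condition: prefixes})."""
    path = Path(path) if path is not None else _data_path("charlson_icd.csv")
    weights: dict[str, int] = {}
    prefixes: dict[str, list[str]] = {}
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            cond = row["condition"]
            weights[cond] = int(row["weight"])
            prefixes.setdefault(cond, []).append(_norm_code(row["code_prefix"]))
    return weights, prefixes


@lru_cache(maxsize=1)
def default_charlson_map() -> tuple[Mapping[str, int], Mapping[str, tuple[str, ...]]]:
    weights, prefixes = load_charlson_map()
    return weights, {c: tuple(p) for c, p in prefixes.items()}


@lru_cache(maxsize=1)
def default_exclusion_map() -> Mapping[str, tuple[str, ...]]:
    m = load_condition_map(_data_path("exclusion_codes.csv"))
    return {c: tuple(p) for c, p in m.items()}


@lru_cache(maxsize=1)
def default_psychiatric_map() -> Mapping[str, tuple[str, ...]]:
    m = load_condition_map(_data_path("psychiatric_codes.csv"))
    return {c: tuple(p) for c, p in m.items()}


def match_conditions(
    codes: Iterable[str], condition_prefixes: Mapping[str, Sequence[str]]
) -> set[str]:
    """Set of conditions whose prefix list matches any of the given codes."""
    normed = {_norm_code(c) for c in codes}
    hit = set()
    for cond, prefixes in condition_prefixes.items():
        for code in normed:
            if any(code.startswith(p) for p in prefixes):
                hit.add(cond)
                break
    return hit


# ---------------------------------------------------------------------------
# index date


def derive_index_date(
    dx: pd.DataFrame | Sequence[tuple],
    window: tuple[pd.Timestamp, pd.Timestamp] = (STUDY_START, STUDY_END),
) -> Optional[pd.Timestamp]:
    """Earliest schizophrenia-coded diagnosis date within the window, else None.

    ``dx`` is a single patient's diagnosis table with columns (date, code), or
    an iterable of (date, code) pairs.
    """
    if isinstance(dx, pd.DataFrame):
        pairs = zip(pd.to_datetime(dx["date"]), dx["code"])
    else:
        pairs = ((pd.Timestamp(d), c) for d, c in dx)
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    dates = [d for d, c in pairs if is_schizophrenia_code(c) and lo <= d <= hi]
    return min(dates) if dates else None


# ---------------------------------------------------------------------------
# CCI


def compute_cci(
    dx_in_window: pd.DataFrame | Sequence[str],
    charlson: tuple[Mapping[str, int], Mapping[str, Sequence[str]]] | None = None,
) -> tuple[int, dict[str, bool]]:
    """Charlson score and per-condition flags from pre-index diagnoses.

    ``dx_in_window`` is a diagnosis table (column ``code``) or an iterable of
    codes, already restricted to the assessment window by the caller.  Flags
    are reported after the severity hierarchy (e.g. diabetes-with-complications
    supersedes diabetes-without), so the score equals the weighted sum of the
    flags; every condition counts once.
    """
    weights, prefixes = charlson if charlson is not None else default_charlson_map()
    codes = dx_in_window["code"] if isinstance(dx_in_window, pd.DataFrame) else dx_in_window
    present = match_conditions(codes, prefixes)
    for severe, mild in CCI_HIERARCHY:
        if severe in present:
            present.discard(mild)
    flags = {cond: cond in present for cond in weights}
    score = sum(weights[c] for c in present)
    return score, flags


# ---------------------------------------------------------------------------
# BMI


def bmi_at_index(
    observations: pd.DataFrame | Sequence[tuple],
    index_date,
    window_days: int = PRE_INDEX_DAYS,
) -> Optional[float]:
    """BMI value recorded closest to the index date within the pre-index year.

    Non-positive values are dropped.  Ties in distance break toward the
    earlier date.  Returns None when no eligible observation exists.
    """
    if isinstance(observations, pd.DataFrame):
        pairs = list(zip(pd.to_datetime(observations["date"]), observations["bmi"]))
    else:
        pairs = [(pd.Timestamp(d), v) for d, v in observations]
    index_date = pd.Timestamp(index_date)
    lo = index_date - pd.Timedelta(days=window_days)
    eligible = [
        (abs((d - index_date).days), d, float(v))
        for d, v in pairs
        if v is not None and not pd.isna(v) and float(v) > 0 and lo <= d <= index_date
    ]
    if not eligible:
        return None
    eligible.sort(key=lambda t: (t[0], t[1]))
    return eligible[0][2]


# ---------------------------------------------------------------------------
# EHR cohort selection


def _require_known_patients(frame: pd.DataFrame, known: set, what: str) -> None:
    unknown = set(frame["patient_id"]) - known
    if unknown:
        raise ValueError(f"{what} reference unknown patient ids: {sorted(unknown)[:5]}")


def select_ehr_cohort(
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    encounters: pd.DataFrame,
    window: tuple = (STUDY_START, STUDY_END),
    exclusion_map: Mapping[str, Sequence[str]] | None = None,
    min_encounters: int = 2,
    lookback_days: int = PRE_INDEX_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the EHR-cohort eligibility rules; returns (cohort, attrition).

    The cohort frame carries patient_id, index_date, age_at_index, the
    demographic columns of ``patients``, and in_ehr_cohort=True.  Every
    dropped patient appears in the attrition table under exactly one reason
    (precedence: no index diagnosis, age, encounter count, lookback,
    exclusion diagnosis), so reasons plus retained partition the input.
    """
    if exclusion_map is None:
        exclusion_map = default_exclusion_map()
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])

    patients = patients.copy()
    known = set(patients["patient_id"])
    _require_known_patients(diagnoses, known, "diagnoses")
    _require_known_patients(encounters, known, "encounters")

    dx = diagnoses.copy()
    dx["date"] = pd.to_datetime(dx["date"])
    enc = encounters.copy()
    enc["date"] = pd.to_datetime(enc["date"])

    codes = dx["code"].astype(str).str.upper().str.replace(".", "", regex=False)
    dx["_sz"] = codes.str.startswith("295") | codes.str.startswith("F20")

    # index date: first schizophrenia dx in window
    in_win = dx["_sz"] & dx["date"].between(lo, hi)
    index_dates = dx.loc[in_win].groupby("patient_id")["date"].min()

    # outpatient schizophrenia encounters on/after the window start
    outp = dx.loc[
        dx["_sz"] & (dx["setting"] == "outpatient") & (dx["date"] >= lo)
    ].groupby("patient_id").size()

    # earliest EHR activity of any kind
    earliest = (
        pd.concat(
            [enc.groupby("patient_id")["date"].min(), dx.groupby("patient_id")["date"].min()]
        )
        .groupby(level=0)
        .min()
    )

    # lifetime exclusion diagnoses
    all_prefixes = tuple(p for plist in exclusion_map.values() for p in plist)
    excluded_pts: set = set(
        dx.loc[codes.str.startswith(all_prefixes), "patient_id"]
    ) if all_prefixes else set()

    patients["index_date"] = patients["patient_id"].map(index_dates)
    birth = pd.to_datetime(patients["birth_date"])
    patients["age_at_index"] = np.floor(
        (patients["index_date"] - birth).dt.days / 365.25
    )

    reasons = pd.Series(pd.NA, index=patients.index, dtype="object")
    no_index = patients["index_date"].isna()
    reasons[no_index] = "no_index"
    young = reasons.isna() & (patients["age_at_index"] < 18)
    reasons[young] = "age"
    n_outp = patients["patient_id"].map(outp).fillna(0)
    few = reasons.isna() & (n_outp < min_encounters)
    reasons[few] = "encounters"
    first_activity = patients["patient_id"].map(earliest)
    short_lb = reasons.isna() & ~(
        (patients["index_date"] - first_activity).dt.days >= lookback_days
    )
    reasons[short_lb] = "lookback"
    excl = reasons.isna() & patients["patient_id"].isin(excluded_pts)
    reasons[excl] = "excl_dx"

    retained = patients.loc[reasons.isna()].copy()
    retained["age_at_index"] = retained["age_at_index"].astype(int)
    retained["age"] = retained["age_at_index"]  # modelling alias
    retained["in_ehr_cohort"] = True

    counts = reasons.value_counts()
    attrition = pd.DataFrame(
        [{"reason": r, "n": int(counts.get(r, 0))} for r in ATTRITION_REASONS]
        + [{"reason": "retained", "n": int(len(retained))}]
    )
    return retained.reset_index(drop=True), attrition


# ---------------------------------------------------------------------------
# linked-claims subcohort


def _merged_spans(spans: list[tuple[pd.Timestamp, pd.Timestamp]], max_gap_days: int):
    spans = sorted(spans)
    merged: list[list[pd.Timestamp]] = []
    for start, end in spans:
        if merged and (start - merged[-1][1]).days - 1 <= max_gap_days:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return merged


def _covers(
    spans: list[tuple[pd.Timestamp, pd.Timestamp]],
    start: pd.Timestamp,
    end: pd.Timestamp,
    max_gap_days: int,
) -> bool:
    return any(s <= start and end <= e for s, e in _merged_spans(spans, max_gap_days))


def select_linked_cohort(
    cohort: pd.DataFrame,
    enrollment: pd.DataFrame,
    followup_days: int = POST_INDEX_DAYS,
    max_gap_days: int = ENROLLMENT_MAX_GAP_DAYS,
) -> pd.DataFrame:
    """Flag patients continuously enrolled in both benefits for a year post-index.

    Coverage must span [index, index + followup_days - 1] for the medical and
    the pharmacy benefit separately (a span with benefit "both" counts toward
    each); gaps of at most ``max_gap_days`` days are bridged.
    """
    enr = enrollment.copy()
    enr["start"] = pd.to_datetime(enr["start"])
    enr["end"] = pd.to_datetime(enr["end"])
    if (enr["start"] > enr["end"]).any():
        raise ValueError("enrollment span with start > end")
    by_patient: dict = {pid: grp for pid, grp in enr.groupby("patient_id")}

    out = cohort.copy()
    flags = []
    for row in out.itertuples():
        idx = pd.Timestamp(row.index_date)
        hi = idx + pd.Timedelta(days=followup_days - 1)
        grp = by_patient.get(row.patient_id)
        ok = False
        if grp is not None:
            ok = all(
                _covers(
                    list(
                        zip(
                            grp.loc[grp["benefit"].isin([benefit, "both"]), "start"],
                            grp.loc[grp["benefit"].isin([benefit, "both"]), "end"],
                        )
                    ),
                    idx,
                    hi,
                    max_gap_days,
                )
                for benefit in ("medical", "pharmacy")
            )
        flags.append(ok)
    out["in_linked_cohort"] = flags
    return out


# ---------------------------------------------------------------------------
# baseline covariates


def build_baseline(
    cohort: pd.DataFrame,
    diagnoses: pd.DataFrame,
    bmi_obs: pd.DataFrame | None = None,
    charlson: tuple | None = None,
    psychiatric_map: Mapping[str, Sequence[str]] | None = None,
    pre_index_days: int = PRE_INDEX_DAYS,
) -> pd.DataFrame:
    """Attach CCI score/flags, psychiatric flags, and BMI to a cohort frame.

    All clinical covariates are assessed over [index - pre_index_days,
    index - 1] (dates inclusive).
    """
    weights, cci_prefixes = charlson if charlson is not None else default_charlson_map()
    if psychiatric_map is None:
        psychiatric_map = default_psychiatric_map()

    dx = diagnoses.copy()
    dx["date"] = pd.to_datetime(dx["date"])
    merged = dx.merge(cohort[["patient_id", "index_date"]], on="patient_id", how="inner")
    delta = (merged["index_date"] - merged["date"]).dt.days
    window = merged.loc[(delta >= 1) & (delta <= pre_index_days)]
    codes_by_patient = window.groupby("patient_id")["code"].apply(list)

    out = cohort.copy()
    cci_scores, cci_flag_rows, psych_rows = [], [], []
    for pid in out["patient_id"]:
        codes = codes_by_patient.get(pid, [])
        score, flags = compute_cci(codes, (weights, cci_prefixes))
        cci_scores.append(score)
        cci_flag_rows.append(flags)
        present = match_conditions(codes, psychiatric_map)
        psych_rows.append({f: f in present for f in PSYCHIATRIC_FLAGS})
    out["cci"] = cci_scores
    for cond in weights:
        out[f"cci_{cond}"] = [r[cond] for r in cci_flag_rows]
    for f in PSYCHIATRIC_FLAGS:
        out[f] = [r[f] for r in psych_rows]

    if bmi_obs is not None and len(bmi_obs):
        obs = bmi_obs.copy()
        obs["date"] = pd.to_datetime(obs["date"])
        obs_by_patient: dict = {pid: grp for pid, grp in obs.groupby("patient_id")}
        out["bmi"] = [
            bmi_at_index(obs_by_patient[pid], idx, pre_index_days)
            if pid in obs_by_patient
            else None
            for pid, idx in zip(out["patient_id"], out["index_date"])
        ]
    else:
        out["bmi"] = None
    return out


def attach_symptom_profiles(cohort: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Join the annotator's patient-level flag table onto the cohort.

    Patients without any notes get negative_symptom_flag = False.
    """
    out = cohort.merge(
        profiles[["patient_id", "any_negative_symptom", "experiential", "expressive"]],
        on="patient_id",
        how="left",
    )
    for col in ("any_negative_symptom", "experiential", "expressive"):
        out[col] = out[col].fillna(False).astype(bool)
    return out.rename(columns={"any_negative_symptom": "negative_symptom_flag"})
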