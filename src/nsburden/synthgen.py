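"""Synthetic linked EHR + claims bundles with planted ground truth.

Every pipeline stage in this package is testable without any external data:
this module generates

* clinical notes assembled from neutral filler sentences, planted
  negative-symptom phrases (optionally misspelled within a small edit
  distance), and decoy sentences that wrap a symptom phrase in a negation /
  question / goal / family-history frame;
* structured EHR tables (patients, diagnoses, encounters, enrollment, BMI)
  in which each eligibility rule is violated at a configured rate, so every
  attrition path is exercised;
* a claims table whose per-patient annual cost is drawn from the same
  two-part (Bernoulli x gamma) structure the cost model assumes, and whose
  admission counts are negative binomial — both with named-coefficient
  linear predictors over the adjusted-model covariate set plus the
  negative-symptom flag.

The generator's default outcome parameters are calibrated so that the
planted marginal group means equal the published benchmark values this
package is tested against (documented in docs/methods.md); ``smoke``,
``benchmark``, ``paper_calibration``, and ``recovery`` named configurations
scale the same machinery to different uses.  One seed governs everything;
per-table substreams are derived deterministically so regenerating one table
does not perturb the others.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._design import PSYCHIATRIC_FLAGS, linear_predictor
from .annotator import EXCLUSION_REASONS
from .cohort import compute_cci
from .lexicon import MIN_FUZZY_TOKEN_LEN, SymptomDomain, default_lexicon


class ConfigError(ValueError):
    """A generator configuration violates its invariants."""


# conditional probability that an NS-positive patient documents each domain,
# matching the published domain mix (avolition and blunted affect dominate)
DEFAULT_DOMAIN_RATES: Mapping[str, float] = {
    "blunted_affect": 0.42,
    "avolition": 0.44,
    "alogia": 0.25,
    "asociality": 0.054,
    "anhedonia": 0.22,
}

DEFAULT_GENDER_PROBS = {"male": 0.62, "female": 0.38}
DEFAULT_RACE_PROBS = {"White": 0.43, "Black": 0.25, "Asian": 0.055, "Other": 0.17, "Unknown": 0.095}
DEFAULT_REGION_PROBS = {"Northeast": 0.13, "Midwest": 0.16, "South": 0.25, "West": 0.44, "Other": 0.02}
DEFAULT_ETHNICITY_PROBS = {"Hispanic": 0.06, "Non-Hispanic": 0.56, "Unknown": 0.38}
DEFAULT_PAYER_PROBS = {
    "Commercial": 0.05, "Dual": 0.085, "Medicaid": 0.705, "Medicare": 0.075,
    "Self-insured": 0.005, "Other": 0.01, "Unknown": 0.07,
}

# baseline comorbidity prevalences (linked-cohort scale); conditions that are
# also cohort-exclusion diagnoses (dementia etc.) are never planted here
DEFAULT_COMORBIDITY_PREVALENCE: Mapping[str, float] = {
    "hypertension": 0.41,
    "diabetes_without_complications": 0.23,
    "diabetes_with_complications": 0.09,
    "chronic_pulmonary_disease": 0.215,
    "congestive_heart_failure": 0.045,
    "renal_disease": 0.055,
    "mild_liver_disease": 0.08,
    "any_malignancy": 0.027,
    "peripheral_vascular_disease": 0.066,
    "myocardial_infarction": 0.019,
    "rheumatic_disease": 0.016,
    "cerebrovascular_disease": 0.016,
}

# representative planted code per condition (matches the packaged mappings and
# avoids every cohort-exclusion prefix)
REPRESENTATIVE_CODES: Mapping[str, str] = {
    "hypertension": "I10",
    "diabetes_without_complications": "E119",
    "diabetes_with_complications": "E112",
    "chronic_pulmonary_disease": "J449",
    "congestive_heart_failure": "I509",
    "renal_disease": "N189",
    "mild_liver_disease": "K709",
    "any_malignancy": "C509",
    "peripheral_vascular_disease": "I702",
    "myocardial_infarction": "I219",
    "rheumatic_disease": "M059",
    "cerebrovascular_disease": "I652",
}

PSYCH_CODES: Mapping[str, str] = {
    "anxiety": "F411",
    "bipolar": "F319",
    "depression": "F329",
    "panic": "F410",
    "ptsd": "F4310",
    "substance_use": "F1020",
}

EXCLUSION_PLANT_CODE = "G40909"  # epilepsy

# psychiatric prevalence by group (no-NS, NS), linked-claims scale
DEFAULT_PSYCH_PREVALENCE: Mapping[str, tuple[float, float]] = {
    "anxiety": (0.294, 0.385),
    "bipolar": (0.213, 0.242),
    "depression": (0.313, 0.364),
    "panic": (0.028, 0.041),
    "ptsd": (0.082, 0.114),
    "substance_use": (0.307, 0.344),
}

POSITIVE_TEMPLATES = (
    "Patient exhibits {p} during the visit.",
    "Exam notable for {p}.",
    "Continues to demonstrate {p} at follow up.",
    "Clinician observed {p} throughout the session.",
    "Chart documents persistent {p}.",
)

DECOY_TEMPLATES: Mapping[str, tuple[str, ...]] = {
    "negation": (
        "No {p} noted on exam.",
        "Denies {p}.",
        "Without {p} at this time.",
        "Negative for {p} today.",
    ),
    "question": (
        "Any {p} recently?",
        "Does the patient report {p}?",
    ),
    "goal": (
        "Goal: address {p} with patient.",
        "Goals of therapy include reducing {p}.",
    ),
    "family_history": (
        "Mother has history of {p}.",
        "Family history of {p} reported.",
    ),
}

FILLER_SENTENCES = (
    "Vital signs reviewed and stable.",
    "Medication list reconciled with patient.",
    "Labs ordered for next visit.",
    "Blood pressure within normal limits.",
    "Continue current treatment regimen.",
    "Sleep reported as adequate.",
    "Appetite unchanged since last visit.",
    "Patient arrived on time for appointment.",
    "Reviewed side effects of current medication.",
    "Follow up scheduled in four weeks.",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All planted-truth parameters for one synthetic bundle."""

    n_patients: int = 400
    seed: int = 11
    ns_prevalence: float = 0.2
    domain_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_RATES)
    )
    #: assign exactly one uniformly chosen domain per NS patient (benchmark mode)
    single_domain_per_patient: bool = False

    # notes
    notes_per_patient_mean: float = 3.0
    plant_rate_per_note: float = 0.6
    decoy_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "negation": 0.15, "question": 0.10, "goal": 0.08, "family_history": 0.08
        }
    )
    misspelling_rate: float = 0.15
    misspelling_max_distance: int = 1
    html_rate: float = 0.3

    # demographics
    age_mean: float = 47.5
    age_sd: float = 14.0
    gender_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GENDER_PROBS))
    race_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RACE_PROBS))
    region_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_REGION_PROBS))
    ethnicity_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ETHNICITY_PROBS))
    payer_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PAYER_PROBS))
    comorbidity_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCE)
    )
    psych_prevalence: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PSYCH_PREVALENCE)
    )

    # eligibility violations
    violation_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.0, "encounters": 0.0, "lookback": 0.0, "exclusion_dx": 0.0
        }
    )
    enrollment_gap_rate: float = 0.0
    enrollment_gap_days: int = 45
    index_start: str = "2016-06-01"
    index_end: str = "2021-06-30"

    # two-part cost model (logit / log scale); defaults calibrated so that
    # E[cost] is $26,291 without and $32,187 with documented negative symptoms
    cost_part1_coefs: Mapping[str, float] = field(
        default_factory=lambda: {"const": 3.1781, "ns": 0.0}
    )
    cost_part2_coefs: Mapping[str, float] = field(
        default_factory=lambda: {"const": 10.21778, "ns": 0.20236}
    )
    cost_gamma_shape: float = 2.0

    # admissions model (log scale); defaults give mean 0.3 vs 0.4 per year
    admit_coefs: Mapping[str, float] = field(
        default_factory=lambda: {"const": math.log(0.3), "ns": math.log(4.0 / 3.0)}
    )
    admit_dispersion: float = 0.8
    #: mean length of stay per admission = 1 + (los_mean - 1); 13 days yields
    #: planted hospitalized-day means of 3.9 and 5.2 per year
    los_mean: float = 13.0

    # utilization count means and treatment probabilities, (no-NS, NS)
    outpatient_mean: tuple[float, float] = (40.2, 46.9)
    ed_mean: tuple[float, float] = (1.3, 1.6)
    pharmacy_mean: tuple[float, float] = (36.0, 37.2)
    psychosocial_any_prob: tuple[float, float] = (0.283, 0.346)
    psychosocial_visits_mean: tuple[float, float] = (9.3, 8.9)
    treatment_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "antipsychotic_fga": (0.192, 0.204),
            "antipsychotic_sga": (0.721, 0.769),
            "mood_stabilizer": (0.187, 0.221),
            "antidepressant": (0.518, 0.543),
        }
    )
    psychosocial_type_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "psychotherapy": 0.82, "group_therapy": 0.10,
            "psychosocial_rehab": 0.05, "family_therapy": 0.02, "cbt": 0.01,
        }
    )
    sz_related_cost_frac: tuple[float, float] = (0.42, 0.73)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be > 0")
        proportions = (
            [self.ns_prevalence, self.misspelling_rate, self.html_rate,
             self.plant_rate_per_note, self.enrollment_gap_rate]
            + list(self.domain_rates.values())
            + list(self.decoy_rates.values())
            + list(self.violation_rates.values())
            + [p for pair in self.psych_prevalence.values() for p in pair]
            + list(self.comorbidity_prevalence.values())
        )
        if any(not (0.0 <= p <= 1.0) for p in proportions):
            raise ConfigError("all rates and prevalences must lie in [0, 1]")
        if self.cost_gamma_shape <= 0:
            raise ConfigError("gamma shape must be > 0")
        if self.admit_dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if self.misspelling_max_distance < 0:
            raise ConfigError("misspelling_max_distance must be >= 0")
        unknown = set(self.decoy_rates) - set(EXCLUSION_REASONS)
        if unknown:
            raise ConfigError(f"unknown decoy reasons {sorted(unknown)}")


@dataclass
class SyntheticBundle:
    notes: Optional[pd.DataFrame]
    gold_labels: Optional[pd.DataFrame]
    gold_spans: Optional[pd.DataFrame]
    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    encounters: pd.DataFrame
    enrollment: pd.DataFrame
    bmi: pd.DataFrame
    claims: pd.DataFrame
    truth: dict


_STREAMS = {"truth": 0, "notes": 1, "structured": 2, "claims": 3}


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _STREAMS[stream]])
    )


def _choice(rng, probs: Mapping[str, float], size: int) -> np.ndarray:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(keys, size=size, p=p)


# ---------------------------------------------------------------------------
# truth assignment (patients, NS flags, domains) — shared by all tables


def assign_truth(config: GeneratorConfig) -> pd.DataFrame:
    """Patient ids, NS status, and per-domain documentation truth."""
    config.validate()
    rng = _rng(config, "truth")
    n = config.n_patients
    frame = pd.DataFrame({"patient_id": [f"P{i:06d}" for i in range(1, n + 1)]})
    frame["ns"] = rng.random(n) < config.ns_prevalence
    domains = [d.value for d in SymptomDomain]
    if config.single_domain_per_patient:
        pick = rng.integers(0, len(domains), n)
        for j, d in enumerate(domains):
            frame[d] = frame["ns"] & (pick == j)
    else:
        rates = np.array([config.domain_rates.get(d, 0.0) for d in domains])
        draws = rng.random((n, len(domains))) < rates
        none = ~draws.any(axis=1)
        if none.any():
            # an NS patient must document at least one domain
            forced = rng.choice(len(domains), size=int(none.sum()), p=rates / rates.sum())
            draws[np.flatnonzero(none), forced] = True
        for j, d in enumerate(domains):
            frame[d] = frame["ns"] & draws[:, j]
    return frame


# ---------------------------------------------------------------------------
# notes


def _misspell(token: str, rng: np.random.Generator) -> str:
    """One random unit edit (substitution, deletion, or insertion)."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    i = int(rng.integers(0, len(token)))
    op = rng.choice(["sub", "del", "ins"])
    if op == "sub":
        alternatives = [c for c in letters if c != token[i]]
        return token[:i] + str(rng.choice(alternatives)) + token[i + 1 :]
    if op == "del":
        return token[:i] + token[i + 1 :]
    return token[:i] + str(rng.choice(list(letters))) + token[i:]


def _lexicon_phrases() -> dict[str, list[tuple[str, bool]]]:
    """canonical phrases per domain, with their fuzzy-eligibility flag."""
    lex = default_lexicon()
    phrases: dict[str, list[tuple[str, bool]]] = {d.value: [] for d in SymptomDomain}
    for entry in lex.entries:
        phrases[entry.domain.value].append((entry.canonical_term, entry.fuzzy_eligible))
    for d in phrases:
        phrases[d].sort()
    return phrases


def _all_lexicon_tokens() -> set[str]:
    lex = default_lexicon()
    toks: set[str] = set()
    for entry in lex.entries:
        for v in entry.variants:
            toks.update(v.split())
    return toks


def _maybe_misspell_phrase(
    phrase: str, rng: np.random.Generator, config: GeneratorConfig, forbidden: set[str]
) -> tuple[str, bool]:
    """Misspell at most one sufficiently long token of a phrase.

    The corrupted token must stay recoverable by fuzzy matching (source token
    length >= MIN_FUZZY_TOKEN_LEN + 1) and must not collide with another
    lexicon token or an exclusion cue.
    """
    if config.misspelling_max_distance < 1:
        return phrase, False
    tokens = phrase.split()
    eligible = [i for i, t in enumerate(tokens) if len(t) >= MIN_FUZZY_TOKEN_LEN + 1]
    if not eligible:
        return phrase, False
    i = int(rng.choice(eligible))
    for _ in range(10):
        bad = _misspell(tokens[i], rng)
        if bad not in forbidden and bad != tokens[i]:
            out = tokens.copy()
            out[i] = bad
            return " ".join(out), True
    return phrase, False


_CUE_TOKENS = {
    "no", "not", "denies", "denied", "without", "absent", "negative",
    "mother", "father", "brother", "sister", "parent", "parents", "fh",
    "goal", "goals", "plan", "any", "does", "is", "are", "do", "have",
}


def generate_notes(
    config: GeneratorConfig, truth: Optional[pd.DataFrame] = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Notes plus gold labels and planted-span records.

    Returns (notes, gold_labels, gold_spans): gold_labels is one row per
    (patient, domain) with the intended documentation label; gold_spans is
    one row per planted phrase with its intended retention status.  With the
    decoy and misspelling rates at zero, running the annotator on the notes
    reproduces gold_labels exactly.
    """
    config.validate()
    if truth is None:
        truth = assign_truth(config)
    rng = _rng(config, "notes")
    phrases = _lexicon_phrases()
    forbidden = _all_lexicon_tokens() | _CUE_TOKENS
    domains = [d.value for d in SymptomDomain]

    note_rows: list[dict] = []
    span_rows: list[dict] = []
    note_counter = 0
    for patient in truth.itertuples():
        n_notes = 1 + int(rng.poisson(max(config.notes_per_patient_mean - 1, 0)))
        patient_domains = [d for d in domains if getattr(patient, d)]
        planted_any = {d: False for d in patient_domains}
        note_ids = []
        sentences_by_note: list[list[str]] = []
        for k in range(n_notes):
            note_counter += 1
            note_id = f"N{note_counter:07d}"
            note_ids.append(note_id)
            sents = [str(rng.choice(FILLER_SENTENCES)) for _ in range(int(rng.integers(1, 4)))]
            for d in patient_domains:
                if rng.random() < config.plant_rate_per_note:
                    sents.append(_plant_positive(d, phrases, rng, config, forbidden, span_rows, note_id, patient.patient_id))
                    planted_any[d] = True
            for reason in EXCLUSION_REASONS:
                if rng.random() < config.decoy_rates.get(reason, 0.0):
                    d = str(rng.choice(domains))
                    template = str(rng.choice(DECOY_TEMPLATES[reason]))
                    phrase = phrases[d][int(rng.integers(0, len(phrases[d])))][0]
                    sents.append(template.format(p=phrase))
                    span_rows.append(
                        {
                            "note_id": note_id, "patient_id": patient.patient_id,
                            "domain": d, "phrase": phrase, "misspelled": False,
                            "intended_retained": False, "reason": reason,
                        }
                    )
            sentences_by_note.append(sents)
        # every documented domain must be planted at least once
        for d in patient_domains:
            if not planted_any[d]:
                k = int(rng.integers(0, n_notes))
                sentences_by_note[k].append(
                    _plant_positive(d, phrases, rng, config, forbidden, span_rows, note_ids[k], patient.patient_id)
                )
        base_date = pd.Timestamp("2018-01-01") + pd.Timedelta(days=int(rng.integers(0, 1000)))
        for k, (note_id, sents) in enumerate(zip(note_ids, sentences_by_note)):
            order = rng.permutation(len(sents))
            text = " ".join(sents[i] for i in order)
            if rng.random() < config.html_rate:
                text = "".join(f"<p>{sents[i]}</p>" for i in order)
            note_rows.append(
                {
                    "note_id": note_id,
                    "patient_id": patient.patient_id,
                    "note_date": (base_date + pd.Timedelta(days=30 * k)).date().isoformat(),
                    "text": text,
                }
            )

    labels = truth.melt(
        id_vars=["patient_id"], value_vars=domains, var_name="domain", value_name="label"
    ).sort_values(["patient_id", "domain"], ignore_index=True)
    notes = pd.DataFrame(note_rows, columns=["note_id", "patient_id", "note_date", "text"])
    spans = pd.DataFrame(
        span_rows,
        columns=["note_id", "patient_id", "domain", "phrase", "misspelled",
                 "intended_retained", "reason"],
    )
    return notes, labels, spans


def _plant_positive(domain, phrases, rng, config, forbidden, span_rows, note_id, patient_id) -> str:
    k = int(rng.integers(0, len(phrases[domain])))
    phrase, fuzzable = phrases[domain][k]
    planted = phrase
    misspelled = False
    # only phrases the fuzzy matcher is allowed to recover get misspelled
    if fuzzable and rng.random() < config.misspelling_rate:
        planted, misspelled = _maybe_misspell_phrase(phrase, rng, config, forbidden)
    template = str(rng.choice(POSITIVE_TEMPLATES))
    span_rows.append(
        {
            "note_id": note_id, "patient_id": patient_id, "domain": domain,
            "phrase": planted, "misspelled": misspelled,
            "intended_retained": True, "reason": "none",
        }
    )
    return template.format(p=planted)


# ---------------------------------------------------------------------------
# structured EHR tables


def generate_structured(
    config: GeneratorConfig, truth: Optional[pd.DataFrame] = None
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Structured tables plus the per-patient violation echo.

    Each eligibility rule (age, encounter count, lookback, exclusion
    diagnosis) is violated independently at its configured rate; a patient
    may violate several, but the cohort builder attributes the drop to the
    first reason in its fixed precedence.
    """
    config.validate()
    if truth is None:
        truth = assign_truth(config)
    rng = _rng(config, "structured")
    n = config.n_patients
    pids = truth["patient_id"].to_numpy()
    ns = truth["ns"].to_numpy()

    index_lo = pd.Timestamp(config.index_start)
    index_hi = pd.Timestamp(config.index_end)
    span_days = (index_hi - index_lo).days
    index_dates = index_lo + pd.to_timedelta(rng.integers(0, span_days + 1, n), unit="D")

    viol = pd.DataFrame({"patient_id": pids})
    for rule in ("age", "encounters", "lookback", "exclusion_dx"):
        viol[rule] = rng.random(n) < config.violation_rates.get(rule, 0.0)
    viol["enrollment_gap"] = rng.random(n) < config.enrollment_gap_rate

    ages = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.5, 90.0)
    ages = np.where(viol["age"], rng.uniform(14.0, 17.5, n), ages)
    birth_dates = index_dates - pd.to_timedelta((ages * 365.25).astype(int), unit="D")

    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "birth_date": [d.date().isoformat() for d in birth_dates],
            "gender": _choice(rng, config.gender_probs, n),
            "race": _choice(rng, config.race_probs, n),
            "ethnicity": _choice(rng, config.ethnicity_probs, n),
            "region": _choice(rng, config.region_probs, n),
            "payer": _choice(rng, config.payer_probs, n),
        }
    )

    dx_rows: list[tuple] = []
    enc_rows: list[tuple] = []
    enr_rows: list[tuple] = []
    bmi_rows: list[tuple] = []
    for i in range(n):
        pid, idx = pids[i], index_dates[i]
        # schizophrenia history: first dx at index (outpatient)
        n_sz = 1 if viol.at[i, "encounters"] else int(rng.integers(2, 6))
        offsets = np.sort(rng.integers(0, 330, n_sz - 1)) if n_sz > 1 else []
        dx_rows.append((pid, idx.date().isoformat(), "F209", "outpatient"))
        for off in offsets:
            dx_rows.append((pid, (idx + pd.Timedelta(days=int(off) + 7)).date().isoformat(), "F209", "outpatient"))
        # EHR activity establishing (or violating) the 12-month lookback
        first_activity = (
            int(rng.integers(30, 300)) if viol.at[i, "lookback"] else int(rng.integers(400, 1200))
        )
        enc_rows.append((pid, (idx - pd.Timedelta(days=first_activity)).date().isoformat(), "office_visit"))
        enc_rows.append((pid, (idx + pd.Timedelta(days=int(rng.integers(10, 300)))).date().isoformat(), "office_visit"))
        if viol.at[i, "exclusion_dx"]:
            dx_rows.append((pid, (idx - pd.Timedelta(days=int(rng.integers(0, 700)))).date().isoformat(), EXCLUSION_PLANT_CODE, "outpatient"))
        # baseline comorbidities + psychiatric history in the pre-index year
        for cond, prev in config.comorbidity_prevalence.items():
            if rng.random() < prev:
                dx_rows.append((pid, (idx - pd.Timedelta(days=int(rng.integers(30, 300)))).date().isoformat(), REPRESENTATIVE_CODES[cond], "outpatient"))
        for flag, (p_no, p_yes) in config.psych_prevalence.items():
            if rng.random() < (p_yes if ns[i] else p_no):
                dx_rows.append((pid, (idx - pd.Timedelta(days=int(rng.integers(30, 300)))).date().isoformat(), PSYCH_CODES[flag], "outpatient"))
        # enrollment: both benefits around the follow-up year, optional gap
        start = (idx - pd.Timedelta(days=30)).date().isoformat()
        if viol.at[i, "enrollment_gap"]:
            gap_at = idx + pd.Timedelta(days=180)
            enr_rows.append((pid, start, gap_at.date().isoformat(), "both"))
            enr_rows.append(
                (pid, (gap_at + pd.Timedelta(days=config.enrollment_gap_days + 1)).date().isoformat(),
                 (idx + pd.Timedelta(days=430)).date().isoformat(), "both")
            )
        else:
            enr_rows.append((pid, start, (idx + pd.Timedelta(days=400)).date().isoformat(), "both"))
        for _ in range(int(rng.integers(1, 4))):
            bmi_rows.append(
                (pid, (idx - pd.Timedelta(days=int(rng.integers(10, 300)))).date().isoformat(),
                 round(float(np.clip(rng.normal(30.0, 6.3), 15, 60)), 1))
            )

    tables = {
        "patients": patients,
        "diagnoses": pd.DataFrame(dx_rows, columns=["patient_id", "date", "code", "setting"]),
        "encounters": pd.DataFrame(enc_rows, columns=["patient_id", "date", "kind"]),
        "enrollment": pd.DataFrame(enr_rows, columns=["patient_id", "start", "end", "benefit"]),
        "bmi": pd.DataFrame(bmi_rows, columns=["patient_id", "date", "bmi"]),
    }
    tables["index_dates"] = pd.DataFrame(
        {"patient_id": pids, "index_date": [d.date().isoformat() for d in index_dates]}
    )
    return tables, viol


# ---------------------------------------------------------------------------
# claims


def draw_model_data(
    config: GeneratorConfig, seed: Optional[int] = None, n: Optional[int] = None
) -> pd.DataFrame:
    """Covariates plus per-patient annual cost and admission count draws.

    The direct inverse of the modelling assumptions: cost is Bernoulli(p) x
    Gamma(shape, mean exp(lp)), admissions are gamma-Poisson (NB2) with
    dispersion alpha.  Used both for the claims table and for fast
    parameter-recovery simulations.
    """
    config.validate()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    n = n if n is not None else config.n_patients
    data = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(1, n + 1)],
            "ns": (rng.random(n) < config.ns_prevalence).astype(int),
            "age": np.clip(rng.normal(config.age_mean, config.age_sd, n), 18, 90),
            "gender": _choice(rng, config.gender_probs, n),
            "race": _choice(rng, config.race_probs, n),
            "region": _choice(rng, config.region_probs, n),
        }
    )
    # CCI score distribution approximated by a small overdispersed count
    data["cci"] = rng.poisson(0.8, n)
    for flag, (p_no, p_yes) in config.psych_prevalence.items():
        p = np.where(data["ns"] == 1, p_yes, p_no)
        data[flag] = (rng.random(n) < p).astype(int)
    for flag in PSYCHIATRIC_FLAGS:
        if flag not in data.columns:
            data[flag] = 0
    _draw_outcomes(data, config, rng)
    return data


def _draw_outcomes(data: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator) -> None:
    n = len(data)
    lp1 = linear_predictor(data, config.cost_part1_coefs)
    lp2 = linear_predictor(data, config.cost_part2_coefs)
    any_cost = rng.random(n) < 1.0 / (1.0 + np.exp(-lp1))
    shape = config.cost_gamma_shape
    cost = np.where(any_cost, rng.gamma(shape, np.exp(lp2) / shape, n), 0.0)
    data["all_cause_cost"] = np.round(cost, 2)

    lp_admit = linear_predictor(data, config.admit_coefs)
    alpha = config.admit_dispersion
    lam = rng.gamma(1.0 / alpha, alpha * np.exp(lp_admit), n)
    data["hospitalizations"] = rng.poisson(lam)


def generate_claims(
    config: GeneratorConfig,
    cohort: pd.DataFrame,
    ns_flags: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Claim lines for the patients of ``cohort`` over their follow-up year.

    ``cohort`` must carry patient_id, index_date, and the adjusted-model
    covariates (age, gender, race, region, cci, psychiatric flags);
    ``ns_flags`` (indexed like ``cohort``) overrides/provides the
    negative-symptom exposure.  Per-patient totals are drawn from the planted
    outcome models, then decomposed into claim lines per setting.
    """
    config.validate()
    rng = _rng(config, "claims")
    data = cohort.copy().reset_index(drop=True)
    if ns_flags is not None:
        data["ns"] = np.asarray(ns_flags, dtype=float)
    if "ns" not in data.columns:
        raise ConfigError("cohort must carry an 'ns' column or ns_flags must be given")
    data["ns"] = data["ns"].astype(float)
    for flag in PSYCHIATRIC_FLAGS:
        if flag not in data.columns:
            data[flag] = 0
    n = len(data)
    ns = data["ns"].to_numpy() > 0

    _draw_outcomes(data, config, rng)
    total_cost = data["all_cause_cost"].to_numpy()
    admits = data["hospitalizations"].to_numpy()

    def per_group(pair: tuple[float, float]) -> np.ndarray:
        return np.where(ns, pair[1], pair[0])

    n_outp = 1 + rng.poisson(np.maximum(per_group(config.outpatient_mean) - 1, 0))
    n_ed = rng.poisson(per_group(config.ed_mean))
    n_rx = rng.poisson(per_group(config.pharmacy_mean))
    any_psycho = rng.random(n) < per_group(config.psychosocial_any_prob)
    n_psycho = np.where(
        any_psycho, 1 + rng.poisson(np.maximum(per_group(config.psychosocial_visits_mean) - 1, 0)), 0
    )
    sz_frac = per_group(config.sz_related_cost_frac)

    index_dates = pd.to_datetime(data["index_date"]).to_numpy()
    rows: list[dict] = []

    # cost allocation weights by setting, renormalized over present settings
    w_ip = np.where(admits > 0, 0.30, 0.0)
    w_ed = np.where(n_ed > 0, 0.05, 0.0)
    w_rx = np.where(n_rx > 0, 0.25, 0.0)
    w_op = 1.0 - w_ip - w_ed - w_rx  # outpatient lines always exist

    for i in range(n):
        pid = data.at[i, "patient_id"]
        idx = pd.Timestamp(index_dates[i])
        total = total_cost[i]
        sz_p = sz_frac[i]

        def add(setting, category, date, cost, admission_id=None, los=None, ptype=None):
            rows.append(
                {
                    "patient_id": pid, "date": date.date().isoformat(),
                    "setting": setting, "category": category,
                    "psychosocial_type": ptype, "paid_cost": round(float(cost), 2),
                    "schizophrenia_related": bool(rng.random() < sz_p),
                    "admission_id": admission_id,
                    "los_days": los,
                }
            )

        for j in range(int(admits[i])):
            los = 1 + int(rng.poisson(max(config.los_mean - 1, 0)))
            los = min(los, 365)
            start_off = int(rng.integers(0, 365 - los + 1))
            add(
                "inpatient", "medical", idx + pd.Timedelta(days=start_off),
                total * w_ip[i] / max(int(admits[i]), 1),
                admission_id=f"{pid}-A{j+1}", los=los,
            )
        for _ in range(int(n_ed[i])):
            add("emergency", "medical", idx + pd.Timedelta(days=int(rng.integers(0, 365))),
                total * w_ed[i] / max(int(n_ed[i]), 1))
        share_op = total * w_op[i] / (int(n_outp[i]) + int(n_psycho[i]))
        for _ in range(int(n_outp[i])):
            add("outpatient", "medical", idx + pd.Timedelta(days=int(rng.integers(0, 365))), share_op)
        if n_psycho[i]:
            ptype = str(rng.choice(
                list(config.psychosocial_type_probs),
                p=np.array(list(config.psychosocial_type_probs.values()))
                / sum(config.psychosocial_type_probs.values()),
            ))
            for _ in range(int(n_psycho[i])):
                add("outpatient", "psychosocial", idx + pd.Timedelta(days=int(rng.integers(0, 365))), share_op, ptype=ptype)
        classes = [cls for cls, pair in config.treatment_probs.items() if rng.random() < per_group(pair)[i]]
        n_plain_rx = max(int(n_rx[i]) - len(classes), 0)
        n_rx_lines = n_plain_rx + len(classes)
        share_rx = total * w_rx[i] / n_rx_lines if n_rx_lines else 0.0
        for cls in classes:
            add("pharmacy", cls, idx + pd.Timedelta(days=int(rng.integers(0, 365))), share_rx)
        for _ in range(n_plain_rx):
            add("pharmacy", "pharmacy", idx + pd.Timedelta(days=int(rng.integers(0, 365))), share_rx)

    claims = pd.DataFrame(
        rows,
        columns=["patient_id", "date", "setting", "category", "psychosocial_type",
                 "paid_cost", "schizophrenia_related", "admission_id", "los_days"],
    )
    return claims


# ---------------------------------------------------------------------------
# bundle + named configurations


def generate_bundle(config: GeneratorConfig, include_notes: bool = True) -> SyntheticBundle:
    """Generate every table of one referentially consistent synthetic study."""
    config.validate()
    truth = assign_truth(config)
    if include_notes:
        notes, labels, spans = generate_notes(config, truth)
    else:
        notes = labels = spans = None
        labels = truth.melt(
            id_vars=["patient_id"],
            value_vars=[d.value for d in SymptomDomain],
            var_name="domain", value_name="label",
        ).sort_values(["patient_id", "domain"], ignore_index=True)
    tables, viol = generate_structured(config, truth)

    # claims need baseline covariates; assemble them from planted truth
    base = tables["patients"].merge(tables["index_dates"], on="patient_id")
    base = base.merge(truth[["patient_id", "ns"]], on="patient_id")
    dx = tables["diagnoses"]
    idx_map = base.set_index("patient_id")["index_date"]
    dxx = dx.assign(
        _idx=pd.to_datetime(dx["patient_id"].map(idx_map)),
        _date=pd.to_datetime(dx["date"]),
    )
    delta = (dxx["_idx"] - dxx["_date"]).dt.days
    pre = dxx.loc[(delta >= 1) & (delta <= 365)]
    codes_by_pt = pre.groupby("patient_id")["code"].apply(list)
    cci, psych_flags = [], {f: [] for f in PSYCHIATRIC_FLAGS}
    for pid in base["patient_id"]:
        codes = codes_by_pt.get(pid, [])
        score, _flags = compute_cci(codes)
        cci.append(score)
        for f in PSYCHIATRIC_FLAGS:
            # planted codes are exactly the representative codes
            psych_flags[f].append(PSYCH_CODES[f] in codes)
    base["cci"] = cci
    for f in PSYCHIATRIC_FLAGS:
        base[f] = np.array(psych_flags[f], dtype=int)
    birth = pd.to_datetime(base["birth_date"])
    base["age"] = (
        (pd.to_datetime(base["index_date"]) - birth).dt.days / 365.25
    ).astype(int)
    claims = generate_claims(config, base)

    truth_echo = {
        "config": _config_echo(config),
        "violations": {
            rule: int(viol[rule].sum())
            for rule in ("age", "encounters", "lookback", "exclusion_dx", "enrollment_gap")
        },
        "n_ns": int(truth["ns"].sum()),
    }
    return SyntheticBundle(
        notes=notes,
        gold_labels=labels,
        gold_spans=spans,
        patients=tables["patients"],
        diagnoses=tables["diagnoses"],
        encounters=tables["encounters"],
        enrollment=tables["enrollment"],
        bmi=tables["bmi"],
        claims=claims,
        truth=truth_echo,
    )


def _config_echo(config: GeneratorConfig) -> dict:
    echo = asdict(config)
    return {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in echo.items()}


def smoke_config(seed: int = 11) -> GeneratorConfig:
    """Small, fast bundle with every attrition path exercised."""
    return GeneratorConfig(
        n_patients=400,
        seed=seed,
        violation_rates={"age": 0.06, "encounters": 0.07, "lookback": 0.06, "exclusion_dx": 0.05},
        enrollment_gap_rate=0.08,
    )


def benchmark_config(seed: int = 42) -> GeneratorConfig:
    """NLP benchmark: ~500 notes per domain, default decoy/misspelling rates."""
    return GeneratorConfig(
        n_patients=2500,
        seed=seed,
        ns_prevalence=0.5,
        single_domain_per_patient=True,
        notes_per_patient_mean=2.0,
    )


def paper_calibration_config(seed: int = 7) -> GeneratorConfig:
    """Cohort calibrated to the published linked-claims benchmark values."""
    return GeneratorConfig(n_patients=12000, seed=seed, ns_prevalence=0.175)


def recovery_config(seed: int = 5) -> GeneratorConfig:
    """Non-trivial covariate effects for parameter-recovery simulations."""
    return GeneratorConfig(
        n_patients=5000,
        seed=seed,
        ns_prevalence=0.3,
        cost_part1_coefs={"const": 1.0, "ns": 0.5, "cci": 0.15, "anxiety": 0.3},
        cost_part2_coefs={"const": 8.0, "ns": 0.3, "cci": 0.1, "depression": 0.2, "gender_female": -0.1},
        admit_coefs={"const": -1.2, "ns": 0.3, "cci": 0.15, "substance_use": 0.25},
        admit_dispersion=0.7,
    )


NAMED_CONFIGS = {
    "smoke": smoke_config,
    "benchmark": benchmark_config,
    "paper_calibration": paper_calibration_config,
    "recovery": recovery_config,
}


def get_config(name: str, seed: Optional[int] = None) -> GeneratorConfig:
    try:
        factory = NAMED_CONFIGS[name]
    except KeyError as exc:
        raise ConfigError(
            f"unknown config {name!r}; available: {sorted(NAMED_CONFIGS)}"
        ) from exc
    return factory() if seed is None else factory(seed=seed)
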