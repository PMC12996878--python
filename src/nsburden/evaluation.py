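"""Quality-control harness: annotator output vs gold chart-review labels.

The evaluation unit is the (patient, domain) pair — the same unit a manual
chart review labels.  For each domain a confusion matrix is tallied over the
gold-labelled patients and summarized as precision, recall, and F1
(the harmonic mean of precision and recall).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotator import PatientSymptomProfile
from .lexicon import SymptomDomain

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GoldAnnotation:
    patient_id: str
    domain: SymptomDomain
    label: bool  # documented / not documented


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    f1: float
    #: names of metrics whose denominator was zero (reported as 0 by convention)
    undefined: frozenset[str] = frozenset()


def confusion(
    pred: Sequence[PatientSymptomProfile],
    gold: Sequence[GoldAnnotation],
    domain: SymptomDomain,
) -> ConfusionMatrix:
    """Patient-level confusion counts for one domain.

    A gold patient without a prediction is scored as predicted-negative (and
    logged): an annotator that never saw the chart cannot have flagged it.
    Duplicate (patient, domain) gold labels are an input error.
    """
    seen: set[tuple[str, SymptomDomain]] = set()
    for g in gold:
        key = (g.patient_id, g.domain)
        if key in seen:
            raise ValueError(f"duplicate gold label for {key}")
        seen.add(key)
    predicted = {p.patient_id: bool(p.domain_flags[domain]) for p in pred}
    tp = fp = fn = tn = 0
    for g in gold:
        if g.domain != domain:
            continue
        if g.patient_id not in predicted:
            logger.info("no prediction for patient %s; scoring as negative", g.patient_id)
        p = predicted.get(g.patient_id, False)
        if p and g.label:
            tp += 1
        elif p and not g.label:
            fp += 1
        elif not p and g.label:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


def precision_recall_f1(cm: ConfusionMatrix) -> MetricSet:
    """precision = tp/(tp+fp); recall = tp/(tp+fn); F1 = 2PR/(P+R).

    Zero denominators yield 0 and are flagged in ``undefined`` (the usual
    information-retrieval convention, avoiding NaN propagation).
    """
    undefined = set()
    if cm.tp + cm.fp == 0:
        precision, recall = 0.0, None
        undefined.add("precision")
    else:
        precision = cm.tp / (cm.tp + cm.fp)
    if cm.tp + cm.fn == 0:
        recall = 0.0
        undefined.add("recall")
    else:
        recall = cm.tp / (cm.tp + cm.fn)
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        undefined.add("f1")
    return MetricSet(
        precision=precision if precision is not None else 0.0,
        recall=recall,
        f1=f1,
        undefined=frozenset(undefined),
    )


def evaluate_domains(
    pred: Sequence[PatientSymptomProfile], gold: Sequence[GoldAnnotation]
) -> pd.DataFrame:
    """Per-domain metrics table: tp, fp, fn, tn, precision, recall, f1."""
    rows = []
    for domain in SymptomDomain:
        cm = confusion(pred, gold, domain)
        ms = precision_recall_f1(cm)
        rows.append(
            {
                "domain": domain.value,
                "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
                "precision": ms.precision, "recall": ms.recall, "f1": ms.f1,
                "undefined": ";".join(sorted(ms.undefined)),
            }
        )
    return pd.DataFrame(rows)


_TRUTHY = {"1", "true", "yes", "y", "t", "documented"}


def read_gold(path: str | Path) -> list[GoldAnnotation]:
    frame = pd.read_csv(path)
    required = {"patient_id", "domain", "label"}
    if not required <= set(frame.columns):
        raise ValueError(f"gold file needs columns {sorted(required)}")
    return gold_from_frame(frame)


def gold_from_frame(frame: pd.DataFrame) -> list[GoldAnnotation]:
    return [
        GoldAnnotation(
            patient_id=str(r.patient_id),
            domain=SymptomDomain(str(r.domain)),
            label=str(r.label).strip().lower() in _TRUTHY,
        )
        for r in frame.itertuples()
    ]
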