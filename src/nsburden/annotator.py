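"""Rule-based annotation of clinical notes for documented negative symptoms.

The pipeline mirrors charting-oriented clinical NLP practice:

1. strip HTML markup from raw note text (notes exported from ambulatory EHRs
   frequently embed markup), decoding entities and collapsing whitespace;
2. segment the plain text into sentences on punctuation, guarding decimals
   and common clinical abbreviations;
3. match the compiled symptom lexicon inside each sentence (optionally after
   fuzzy expansion against the corpus vocabulary, to catch misspellings at
   small edit distance);
4. apply sentence-scoped exclusion rules — negation, question, goal, and
   family-history framing — in that fixed precedence order.  A sentence on
   which any rule fires contributes no retained mentions: "No flat affect
   noted" documents the absence of a symptom, not its presence.

Retained mentions are aggregated to patient-level domain flags: a patient is
positive for a domain iff at least one retained mention of that domain occurs
anywhere in their notes.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from html.parser import HTMLParser
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .lexicon import (
    DEFAULT_MAX_DISTANCE,
    EXPERIENTIAL_DOMAINS,
    EXPRESSIVE_DOMAINS,
    CompiledLexicon,
    SymptomDomain,
)

EXCLUSION_REASONS = ("negation", "question", "goal", "family_history")


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    patient_id: str
    note_date: str
    raw_text: str


@dataclass(frozen=True)
class Sentence:
    """A sentence with its half-open character span in the cleaned note."""

    note_id: str
    index: int
    text: str
    start: int
    end: int


@dataclass
class SymptomMention:
    patient_id: str
    note_id: str
    sentence_index: int
    domain: SymptomDomain
    matched_variant: str
    canonical_term: str
    start: int  # char offsets within the sentence text, half-open
    end: int
    retained: Optional[bool] = None
    exclusion_reason: Optional[str] = None


@dataclass(frozen=True)
class PatientSymptomProfile:
    patient_id: str
    domain_flags: Mapping[SymptomDomain, bool]
    any_negative_symptom: bool
    experiential_flag: bool
    expressive_flag: bool
    n_notes: int
    n_retained_mentions: int


# ---------------------------------------------------------------------------
# step 1: markup removal


class _TextExtractor(HTMLParser):
    _BLOCK = {
        "p", "div", "br", "li", "ul", "ol", "tr", "table", "section", "article",
        "h1", "h2", "h3", "h4", "h5", "h6",
    }
    _SKIP = {"script", "style"}

    def __init__(self) -> None:
        super().__init__(convert_charrefs=True)
        self.parts: list[str] = []
        self._skip_depth = 0

    def handle_starttag(self, tag, attrs):
        if tag in self._SKIP:
            self._skip_depth += 1
        elif tag in self._BLOCK:
            self.parts.append("\n")

    def handle_endtag(self, tag):
        if tag in self._SKIP:
            self._skip_depth = max(0, self._skip_depth - 1)
        elif tag in self._BLOCK:
            self.parts.append("\n")

    def handle_data(self, data):
        if not self._skip_depth:
            self.parts.append(data)


def _collapse(text: str) -> str:
    lines = [" ".join(line.split()) for line in text.split("\n")]
    return "\n".join(line for line in lines if line)


def strip_html(raw_text: str) -> str:
    """Remove markup, decode entities, collapse whitespace.  Never raises.

    Block-level tags become newlines so that adjacent paragraphs cannot fuse
    into one sentence; plain text passes through (modulo whitespace
    collapsing) unchanged.
    """
    if not raw_text:
        return ""
    if "<" not in raw_text and "&" not in raw_text:
        return _collapse(raw_text)
    parser = _TextExtractor()
    try:
        parser.feed(raw_text)
        parser.close()
    except Exception:
        # malformed markup: fall back to a crude tag strip
        return _collapse(re.sub(r"<[^>]*>", " ", raw_text))
    return _collapse("".join(parser.parts))


# ---------------------------------------------------------------------------
# step 2: sentence segmentation

#: tokens before a period that do not end a sentence
ABBREVIATION_GUARDS = {
    "dr", "mr", "mrs", "ms", "pt", "pts", "vs", "etc", "eg", "ie", "st",
    "appt", "approx", "hx", "dx", "rx", "tx", "wt", "ht", "neg", "pos",
}


def segment_sentences(clean_text: str, note_id: str = "") -> list[Sentence]:
    """Split plain text into sentences on {., !, ?, newline}.

    A period is not a boundary inside a decimal number, after a guarded
    abbreviation or single-letter initial, or when not followed by whitespace.
    Spans are 0-based half-open offsets into ``clean_text``; concatenating the
    sentence texts (modulo inter-sentence whitespace) recovers the input.
    """
    sentences: list[Sentence] = []
    n = len(clean_text)

    def emit(s: int, e: int) -> None:
        while s < e and clean_text[s].isspace():
            s += 1
        while e > s and clean_text[e - 1].isspace():
            e -= 1
        if e > s:
            sentences.append(
                Sentence(note_id, len(sentences), clean_text[s:e], s, e)
            )

    start = 0
    for i, ch in enumerate(clean_text):
        if ch == "\n":
            emit(start, i)
            start = i + 1
            continue
        if ch not in ".!?":
            continue
        boundary = True
        if i + 1 < n and not clean_text[i + 1].isspace():
            boundary = False  # mid-token, e.g. "e.g" or "80.5"
        elif ch == ".":
            if 0 < i < n - 1 and clean_text[i - 1].isdigit() and clean_text[i + 1].isdigit():
                boundary = False
            else:
                j = i - 1
                while j >= 0 and (clean_text[j].isalpha() or clean_text[j] == "."):
                    j -= 1
                token = clean_text[j + 1 : i].lower().replace(".", "")
                if len(token) == 1 or token in ABBREVIATION_GUARDS:
                    boundary = False
        if boundary:
            emit(start, i + 1)
            start = i + 1
    emit(start, n)
    return sentences


# ---------------------------------------------------------------------------
# step 3a: lexicon matching


def match_lexicon(
    sentence: Sentence,
    lexicon: CompiledLexicon,
    patient_id: str = "",
) -> list[SymptomMention]:
    """All maximal non-overlapping lexicon matches in one sentence.

    Overlaps are resolved longest-match-first, ties to the leftmost match
    (then lexicographically by pattern id, for determinism).  Retention is
    left undetermined; see :func:`apply_exclusion_rules`.
    """
    text = sentence.text.lower()
    candidates = []
    for pat in lexicon.patterns.values():
        for m in pat.regex.finditer(text):
            candidates.append((m.end() - m.start(), m.start(), m.end(), pat))
    candidates.sort(key=lambda c: (-c[0], c[1], c[3].pattern_id))
    occupied: list[tuple[int, int]] = []
    chosen = []
    for length, s, e, pat in candidates:
        if any(s < oe and os < e for os, oe in occupied):
            continue
        occupied.append((s, e))
        chosen.append((s, e, pat))
    chosen.sort(key=lambda c: c[0])
    return [
        SymptomMention(
            patient_id=patient_id,
            note_id=sentence.note_id,
            sentence_index=sentence.index,
            domain=pat.domain,
            matched_variant=pat.variant,
            canonical_term=pat.canonical_term,
            start=s,
            end=e,
        )
        for s, e, pat in chosen
    ]


# ---------------------------------------------------------------------------
# step 3b: sentence-scoped exclusion rules

_B_L, _B_R = r"(?<![a-z0-9])", r"(?![a-z0-9])"

#: pre-trigger negation cues, in the spirit of NegEx
NEGATION_CUES = ("no", "not", "denies", "denied", "without", "absent", "negative for", "w/o")
_NEG_RE = re.compile(_B_L + "(" + "|".join(re.escape(c) for c in NEGATION_CUES) + ")" + _B_R)

#: leading interrogative tokens typical of screening-questionnaire text
QUESTION_LEADS = frozenset({"any", "does", "is", "are", "do", "have"})

_GOAL_RE = re.compile(
    r"^(goals?|plan)\s*[:\-]"
    + "|"
    + _B_L + r"(goals? of|working towards?)" + _B_R
)

FAMILY_CUES = (
    "mother", "father", "brother", "sister", "parent", "parents",
    "grandmother", "grandfather", "aunt", "uncle", "family history", "fh",
)
_FAMILY_RE = re.compile(_B_L + "(" + "|".join(re.escape(c) for c in FAMILY_CUES) + ")" + _B_R)


def apply_exclusion_rules(
    sentence: Sentence, mentions: Sequence[SymptomMention]
) -> list[SymptomMention]:
    """Resolve retention for every mention of one sentence.

    Exclusion is sentence-scoped: the first firing rule in the precedence
    order negation > question > goal > family_history excludes all of the
    sentence's mentions with that reason.  A negation cue that lies inside a
    matched span (the "no" of "no response") does not negate; to fire it must
    occur outside every mention and before at least one mention's start.
    """
    mentions = list(mentions)
    if not mentions:
        return []
    text = sentence.text.lower()
    spans = [(m.start, m.end) for m in mentions]

    def inside_mention(pos: int) -> bool:
        return any(s <= pos < e for s, e in spans)

    reason: Optional[str] = None
    for m in _NEG_RE.finditer(text):
        if inside_mention(m.start()):
            continue
        if any(m.start() < s for s, _ in spans):
            reason = "negation"
            break
    if reason is None:
        if text.rstrip().endswith("?"):
            reason = "question"
        else:
            lead = re.match(r"\s*([a-z]+)", text)
            if (
                lead
                and lead.group(1) in QUESTION_LEADS
                and any(s >= lead.end(1) for s, _ in spans)
            ):
                reason = "question"
    if reason is None and _GOAL_RE.search(text):
        reason = "goal"
    if reason is None and _FAMILY_RE.search(text):
        reason = "family_history"

    for m in mentions:
        m.retained = reason is None
        m.exclusion_reason = "none" if reason is None else reason
    return mentions


# ---------------------------------------------------------------------------
# corpus-level driver


def _profile(
    patient_id: str, mentions: Sequence[SymptomMention], n_notes: int
) -> PatientSymptomProfile:
    retained = [m for m in mentions if m.retained]
    flags = {d: any(m.domain == d for m in retained) for d in SymptomDomain}
    return PatientSymptomProfile(
        patient_id=patient_id,
        domain_flags=flags,
        any_negative_symptom=any(flags.values()),
        experiential_flag=any(flags[d] for d in EXPERIENTIAL_DOMAINS),
        expressive_flag=any(flags[d] for d in EXPRESSIVE_DOMAINS),
        n_notes=n_notes,
        n_retained_mentions=len(retained),
    )


def annotate_corpus(
    notes: Sequence[ClinicalNote],
    lexicon: CompiledLexicon,
    *,
    fuzzy: bool = True,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    date_from: Optional[str] = None,
    date_to: Optional[str] = None,
) -> tuple[list[SymptomMention], list[PatientSymptomProfile]]:
    """Annotate a note corpus; returns (mention table, patient profiles).

    With ``fuzzy=True`` the lexicon is expanded against the corpus vocabulary
    before matching, so misspellings within ``max_distance`` edits of an
    eligible variant token are still caught.  The optional date window filters
    notes by ``note_date`` (inclusive bounds) for sensitivity analyses.
    Duplicate note ids are an input error.
    """
    seen: set[str] = set()
    for note in notes:
        if note.note_id in seen:
            raise ValueError(f"duplicate note_id {note.note_id!r}")
        seen.add(note.note_id)

    if date_from is not None or date_to is not None:
        lo = pd.Timestamp(date_from) if date_from is not None else pd.Timestamp.min
        hi = pd.Timestamp(date_to) if date_to is not None else pd.Timestamp.max
        notes = [n for n in notes if lo <= pd.Timestamp(n.note_date) <= hi]

    cleaned = [(note, strip_html(note.raw_text)) for note in notes]

    if fuzzy:
        vocab: set[str] = set()
        for _, text in cleaned:
            vocab.update(re.findall(r"[a-z]+", text.lower()))
        lexicon = lexicon.expand(vocab, max_distance)

    mentions: list[SymptomMention] = []
    per_patient: dict[str, list[SymptomMention]] = {}
    notes_per_patient: dict[str, int] = {}
    for note, text in cleaned:
        notes_per_patient[note.patient_id] = notes_per_patient.get(note.patient_id, 0) + 1
        for sentence in segment_sentences(text, note.note_id):
            found = match_lexicon(sentence, lexicon, patient_id=note.patient_id)
            if not found:
                continue
            resolved = apply_exclusion_rules(sentence, found)
            mentions.extend(resolved)
            per_patient.setdefault(note.patient_id, []).extend(resolved)

    profiles = [
        _profile(pid, per_patient.get(pid, []), n_notes)
        for pid, n_notes in notes_per_patient.items()
    ]
    return mentions, profiles


# ---------------------------------------------------------------------------
# tabular interchange


def notes_from_frame(frame: pd.DataFrame) -> list[ClinicalNote]:
    required = {"note_id", "patient_id", "note_date", "text"}
    if not required <= set(frame.columns):
        raise ValueError(f"notes table needs columns {sorted(required)}")
    return [
        ClinicalNote(str(r.note_id), str(r.patient_id), str(r.note_date), str(r.text))
        for r in frame.itertuples()
    ]


def mentions_to_frame(mentions: Sequence[SymptomMention]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "note_id": m.note_id,
                "sentence_index": m.sentence_index,
                "domain": m.domain.value,
                "matched_variant": m.matched_variant,
                "canonical_term": m.canonical_term,
                "start": m.start,
                "end": m.end,
                "retained": bool(m.retained),
                "exclusion_reason": m.exclusion_reason,
            }
            for m in mentions
        ],
        columns=[
            "patient_id", "note_id", "sentence_index", "domain", "matched_variant",
            "canonical_term", "start", "end", "retained", "exclusion_reason",
        ],
    )


def profiles_to_frame(profiles: Sequence[PatientSymptomProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"patient_id": p.patient_id}
        for d in SymptomDomain:
            row[d.value] = bool(p.domain_flags[d])
        row.update(
            any_negative_symptom=p.any_negative_symptom,
            experiential=p.experiential_flag,
            expressive=p.expressive_flag,
            n_notes=p.n_notes,
            n_retained_mentions=p.n_retained_mentions,
        )
        rows.append(row)
    cols = ["patient_id"] + [d.value for d in SymptomDomain] + [
        "any_negative_symptom", "experiential", "expressive", "n_notes",
        "n_retained_mentions",
    ]
    return pd.DataFrame(rows, columns=cols)
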