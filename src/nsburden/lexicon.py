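"""Five-domain negative-symptom term inventory.

Negative symptoms of schizophrenia fall into five domains — blunted (flat)
affect, alogia, avolition, asociality, and anhedonia — conventionally grouped
into an experiential dimension (avolition, asociality, anhedonia) and an
expressive dimension (alogia, blunted affect).  This module holds the term
inventory for those domains, expands it with fuzzy (edit-distance) variants
observed in a corpus vocabulary, and compiles it into word-boundary-anchored
regular-expression patterns for the annotator.

The packaged default inventory (``data/negative_symptoms_lexicon.csv``) is a
clinician-editable delimited file; additional synonyms are configuration, not
code.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class SymptomDomain(str, Enum):
    """The five negative-symptom domains."""

    BLUNTED_AFFECT = "blunted_affect"
    ALOGIA = "alogia"
    AVOLITION = "avolition"
    ASOCIALITY = "asociality"
    ANHEDONIA = "anhedonia"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: experiential dimension: motivation- and pleasure-related domains
EXPERIENTIAL_DOMAINS = frozenset(
    {SymptomDomain.AVOLITION, SymptomDomain.ASOCIALITY, SymptomDomain.ANHEDONIA}
)
#: expressive dimension: outwardly observable expression domains
EXPRESSIVE_DOMAINS = frozenset({SymptomDomain.ALOGIA, SymptomDomain.BLUNTED_AFFECT})

#: fuzzy matching is restricted to tokens at least this long; short clinical
#: tokens ("flat", "no") have too many spurious unit-distance neighbours
MIN_FUZZY_TOKEN_LEN = 5
#: default maximum Levenshtein distance for variant expansion
DEFAULT_MAX_DISTANCE = 1


class LexiconError(ValueError):
    """A lexicon file or entry set violates the schema."""


def normalize_phrase(phrase: str) -> str:
    """Lowercase and collapse internal whitespace."""
    return " ".join(phrase.lower().split())


def levenshtein(a: str, b: str) -> int:
    """Levenshtein edit distance (unit-cost insert/delete/substitute).

    Iterative two-row dynamic programme; O(len(a) * len(b)) time,
    O(min(len(a), len(b))) memory.
    """
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@dataclass(frozen=True)
class LexiconEntry:
    """One canonical term with its variant set under a single domain.

    ``derived_variants`` tracks variants added by fuzzy expansion so that
    repeated expansion never chains fuzz-of-fuzz (idempotence).
    """

    domain: SymptomDomain
    canonical_term: str
    variants: frozenset[str] = frozenset()
    fuzzy_eligible: bool = True
    derived_variants: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        canonical = normalize_phrase(self.canonical_term)
        if not canonical:
            raise LexiconError("canonical_term must be non-empty")
        variants = frozenset(normalize_phrase(v) for v in self.variants) | {canonical}
        derived = frozenset(normalize_phrase(v) for v in self.derived_variants)
        object.__setattr__(self, "canonical_term", canonical)
        object.__setattr__(self, "variants", variants)
        object.__setattr__(self, "derived_variants", derived & variants)

    @property
    def base_variants(self) -> frozenset[str]:
        """Variants that were curated rather than derived by fuzzy expansion."""
        return self.variants - self.derived_variants


def expand_variants(
    entry: LexiconEntry,
    corpus_vocabulary: Iterable[str],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> LexiconEntry:
    """Add corpus tokens within ``max_distance`` edits of a variant token.

    Multi-token phrases expand per token, substituting at most one fuzzy token
    per phrase.  Only tokens of length >= ``MIN_FUZZY_TOKEN_LEN`` are eligible,
    and only when the entry is flagged ``fuzzy_eligible``.  Expansion always
    starts from the curated (non-derived) variants, which makes it idempotent.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    if not entry.fuzzy_eligible or max_distance == 0:
        return entry
    vocab = set(corpus_vocabulary)
    new: set[str] = set()
    for phrase in entry.base_variants:
        tokens = phrase.split()
        for i, tok in enumerate(tokens):
            if len(tok) < MIN_FUZZY_TOKEN_LEN:
                continue
            for word in vocab:
                if word == tok or abs(len(word) - len(tok)) > max_distance:
                    continue
                if levenshtein(word, tok) <= max_distance:
                    candidate = " ".join(tokens[:i] + [word] + tokens[i + 1 :])
                    if candidate not in entry.variants:
                        new.add(candidate)
    if not new:
        return entry
    return replace(
        entry,
        variants=entry.variants | new,
        derived_variants=entry.derived_variants | new,
    )


# token boundaries: a match may not be flanked by letters or digits, so
# "apathy" never fires inside "apathyxyz"
_BOUNDARY_L = r"(?<![a-z0-9])"
_BOUNDARY_R = r"(?![a-z0-9])"


def _variant_regex(variant: str) -> re.Pattern[str]:
    body = r"\s+".join(re.escape(tok) for tok in variant.split())
    return re.compile(_BOUNDARY_L + body + _BOUNDARY_R)


@dataclass(frozen=True)
class CompiledPattern:
    pattern_id: str
    domain: SymptomDomain
    canonical_term: str
    variant: str
    regex: re.Pattern[str]


@dataclass(frozen=True)
class CompiledLexicon:
    """Entries plus one compiled, boundary-anchored matcher per variant."""

    entries: tuple[LexiconEntry, ...]
    patterns: Mapping[str, CompiledPattern]

    @classmethod
    def from_entries(cls, entries: Sequence[LexiconEntry]) -> "CompiledLexicon":
        if not entries:
            raise LexiconError("lexicon is empty")
        owner: dict[str, LexiconEntry] = {}
        for entry in entries:
            for variant in entry.variants:
                other = owner.get(variant)
                if other is not None and other is not entry:
                    kind = (
                        "two different domains"
                        if other.domain != entry.domain
                        else "two entries"
                    )
                    raise LexiconError(
                        f"variant {variant!r} appears under {kind} "
                        f"({other.domain.value}/{other.canonical_term} and "
                        f"{entry.domain.value}/{entry.canonical_term})"
                    )
                owner[variant] = entry
        patterns: dict[str, CompiledPattern] = {}
        for entry in entries:
            for variant in sorted(entry.variants):
                pid = f"{entry.domain.value}|{entry.canonical_term}|{variant}"
                patterns[pid] = CompiledPattern(
                    pattern_id=pid,
                    domain=entry.domain,
                    canonical_term=entry.canonical_term,
                    variant=variant,
                    regex=_variant_regex(variant),
                )
        return cls(entries=tuple(entries), patterns=patterns)

    def entry(self, domain: SymptomDomain, canonical_term: str) -> LexiconEntry:
        term = normalize_phrase(canonical_term)
        for e in self.entries:
            if e.domain == domain and e.canonical_term == term:
                return e
        raise KeyError((domain, canonical_term))

    def expand(
        self,
        corpus_vocabulary: Iterable[str],
        max_distance: int = DEFAULT_MAX_DISTANCE,
    ) -> "CompiledLexicon":
        """Fuzzy-expand every eligible entry against a corpus vocabulary.

        Derived variants that collide with another entry's curated variant, or
        that are derived by entries of more than one domain, are dropped: an
        ambiguous fuzzy token is evidence of nothing.
        """
        vocab = set(corpus_vocabulary)
        expanded = [expand_variants(e, vocab, max_distance) for e in self.entries]
        base_owner: dict[str, int] = {}
        derived_owner: dict[str, set[int]] = {}
        for i, entry in enumerate(expanded):
            for v in entry.base_variants:
                base_owner[v] = i
            for v in entry.derived_variants:
                derived_owner.setdefault(v, set()).add(i)
        cleaned = []
        for i, entry in enumerate(expanded):
            drop = {
                v
                for v in entry.derived_variants
                if v in base_owner or len(derived_owner[v]) > 1
            }
            if drop:
                entry = replace(
                    entry,
                    variants=entry.variants - drop,
                    derived_variants=entry.derived_variants - drop,
                )
            cleaned.append(entry)
        return CompiledLexicon.from_entries(cleaned)


_REQUIRED_COLUMNS = {"domain", "canonical_term", "variant", "fuzzy_eligible"}
_TRUTHY = {"1", "true", "yes", "y", "t"}


def load_lexicon(path: str | Path) -> CompiledLexicon:
    """Load a lexicon file (columns: domain, canonical_term, variant, fuzzy_eligible).

    One row per variant; the canonical term is added to its own variant set
    automatically.  Raises :class:`LexiconError` on unknown domains, duplicate
    variants across entries, missing columns, or an empty file.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not _REQUIRED_COLUMNS <= set(reader.fieldnames):
            raise LexiconError(
                f"lexicon file {path} must have columns {sorted(_REQUIRED_COLUMNS)}"
            )
        rows = list(reader)
    if not rows:
        raise LexiconError(f"lexicon file {path} contains no entries")
    grouped: dict[tuple[SymptomDomain, str], dict] = {}
    for row in rows:
        try:
            domain = SymptomDomain(row["domain"].strip().lower())
        except ValueError as exc:
            raise LexiconError(f"unknown domain {row['domain']!r}") from exc
        canonical = normalize_phrase(row["canonical_term"])
        key = (domain, canonical)
        slot = grouped.setdefault(
            key, {"variants": set(), "fuzzy": False}
        )
        variant = normalize_phrase(row["variant"] or canonical)
        if variant:
            slot["variants"].add(variant)
        slot["fuzzy"] = slot["fuzzy"] or (
            row["fuzzy_eligible"].strip().lower() in _TRUTHY
        )
    entries = [
        LexiconEntry(
            domain=domain,
            canonical_term=canonical,
            variants=frozenset(slot["variants"]),
            fuzzy_eligible=slot["fuzzy"],
        )
        for (domain, canonical), slot in grouped.items()
    ]
    return CompiledLexicon.from_entries(entries)


def default_lexicon_path() -> Path:
    return Path(
        resources.files("nsburden").joinpath("data/negative_symptoms_lexicon.csv")  # type: ignore[arg-type]
    )


@lru_cache(maxsize=1)
def default_lexicon() -> CompiledLexicon:
    """The packaged default term inventory."""
    return load_lexicon(default_lexicon_path())
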