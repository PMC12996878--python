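"""HTML stripping, segmentation, matching, exclusion rules, aggregation."""
import numpy as np
import pytest

from nsburden.annotator import (
    ClinicalNote,
    annotate_corpus,
    apply_exclusion_rules,
    match_lexicon,
    mentions_to_frame,
    notes_from_frame,
    segment_sentences,
    strip_html,
)
from nsburden.lexicon import SymptomDomain
from nsburden.synthgen import GeneratorConfig, generate_notes
from oracles import brute_force_matches


# ---------------------------------------------------------------------------
# strip_html


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("<p>flat affect</p>", "flat affect"),
        ("", ""),
        ("no&nbsp;motivation", "no motivation"),
        ("plain text stays", "plain text stays"),
        ("<div>Pt seen.</div><div>Denies SI.</div>", "Pt seen.\nDenies SI."),
        ("a &amp; b", "a & b"),
        ("<b>bold</b> move", "bold move"),
        ("<script>var x=1;</script>note text", "note text"),
        ("<p class='x' malformed", ""),  # lenient, never raises
    ],
)
def test_strip_html(raw, expected):
    assert strip_html(raw) == expected


def test_strip_html_collapses_runs_of_whitespace():
    assert strip_html("flat   affect\t noted") == "flat affect noted"


# ---------------------------------------------------------------------------
# segmentation


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Pt withdrawn. Denies SI.", ["Pt withdrawn.", "Denies SI."]),
        ("", []),
        ("Wt 80.5 kg. Mood flat.", ["Wt 80.5 kg.", "Mood flat."]),
        ("Seen by Dr. Smith today. Stable.", ["Seen by Dr. Smith today.", "Stable."]),
        ("Any concerns? None reported.", ["Any concerns?", "None reported."]),
        ("One sentence without terminator", ["One sentence without terminator"]),
        ("Line one\nLine two", ["Line one", "Line two"]),
        ("Improved vs. last visit. Continue.", ["Improved vs. last visit.", "Continue."]),
    ],
)
def test_segment_sentences(text, expected):
    assert [s.text for s in segment_sentences(text)] == expected


def test_segment_spans_partition_the_text():
    text = "First thought. Second one! Third?\nFourth line."
    sentences = segment_sentences(text)
    assert [s.index for s in sentences] == list(range(len(sentences)))
    for s in sentences:
        assert text[s.start : s.end] == s.text
    for a, b in zip(sentences, sentences[1:]):
        assert a.end <= b.start
        assert text[a.end : b.start].strip() == ""


# ---------------------------------------------------------------------------
# matching


def _sentence(text):
    return segment_sentences(text)[0]


def test_match_exact_phrase(lexicon):
    m = match_lexicon(_sentence("Patient has flat affect today"), lexicon)
    assert [(x.domain, x.matched_variant) for x in m] == [
        (SymptomDomain.BLUNTED_AFFECT, "flat affect")
    ]
    s = _sentence("Patient has flat affect today")
    assert s.text[m[0].start : m[0].end].lower() == "flat affect"


def test_no_match_in_neutral_sentence(lexicon):
    assert match_lexicon(_sentence("Patient is cheerful and engaged"), lexicon) == []


def test_longest_match_wins(lexicon):
    # "loss of interest in activities" (avolition) over "loss of interest" (anhedonia)
    m = match_lexicon(_sentence("Notes loss of interest in activities lately."), lexicon)
    assert [x.domain for x in m] == [SymptomDomain.AVOLITION]
    m2 = match_lexicon(_sentence("Notes loss of interest lately."), lexicon)
    assert [x.domain for x in m2] == [SymptomDomain.ANHEDONIA]


def test_fuzzy_match_of_misspelling(lexicon):
    expanded = lexicon.expand({"noted", "pverty", "of", "speech"}, 1)
    m = match_lexicon(_sentence("noted pverty of speech"), expanded)
    assert [x.domain for x in m] == [SymptomDomain.ALOGIA]
    assert m[0].canonical_term == "poverty of speech"


def _random_sentences(rng, n):
    pool = [
        "flat affect", "apathy", "apathyxyz", "empathy", "poor hygiene",
        "no response", "loss of interest", "loss of interest in activities",
        "social withdrawal", "poverty of speech", "stable", "mood", "flat",
        "affect", "pleasant", "short answers", "withdrawn", "alert", "80.5",
    ]
    out = []
    for _ in range(n):
        k = rng.integers(1, 8)
        words = [pool[rng.integers(0, len(pool))] for _ in range(k)]
        text = " ".join(words) + rng.choice([".", "?", "!", ""])
        out.append(text)
    return out


def test_matcher_equals_brute_force_scan(lexicon):
    """Regex matcher agrees with a variant-by-token-window brute force."""
    rng = np.random.default_rng(202)
    for text in _random_sentences(rng, 300):
        sent = segment_sentences(text)
        if not sent:
            continue
        got = [
            (m.start, m.end, f"{m.domain.value}|{m.canonical_term}|{m.matched_variant}")
            for m in match_lexicon(sent[0], lexicon)
        ]
        assert sorted(got) == brute_force_matches(sent[0].text, lexicon), text


# ---------------------------------------------------------------------------
# exclusion rules


@pytest.mark.parametrize(
    "text,reason",
    [
        ("No flat affect noted.", "negation"),
        ("Patient denies poor hygiene.", "negation"),
        ("Any loss of interest in activities?", "question"),
        ("Does she report apathy", "question"),  # leading interrogative
        ("Goal: improve poor hygiene.", "goal"),
        ("Goals of therapy include reducing social withdrawal.", "goal"),
        ("Mother had flat affect.", "family_history"),
        ("FH of anhedonia reported.", "family_history"),
        ("Patient exhibits flat affect.", None),
        ("Patient shows no motivation daily.", None),  # cue inside the span
        ("Affect flat but denies nothing unusual afterwards.", None),  # cue after span
    ],
)
def test_exclusion_rules(text, reason, lexicon):
    sent = _sentence(text)
    mentions = apply_exclusion_rules(sent, match_lexicon(sent, lexicon))
    assert mentions, text
    for m in mentions:
        if reason is None:
            assert m.retained and m.exclusion_reason == "none"
        else:
            assert not m.retained and m.exclusion_reason == reason


def test_negation_takes_precedence_over_question(lexicon):
    sent = _sentence("Denies flat affect today?")
    mentions = apply_exclusion_rules(sent, match_lexicon(sent, lexicon))
    assert mentions[0].exclusion_reason == "negation"


def test_exclusion_is_sentence_scoped(lexicon):
    sent = _sentence("No flat affect and denies apathy.")
    mentions = apply_exclusion_rules(sent, match_lexicon(sent, lexicon))
    assert len(mentions) == 2
    assert all(not m.retained and m.exclusion_reason == "negation" for m in mentions)


# ---------------------------------------------------------------------------
# corpus aggregation


def _note(nid, pid, text):
    return ClinicalNote(note_id=nid, patient_id=pid, note_date="2020-01-01", raw_text=text)


def test_profiles_aggregate_retained_mentions(lexicon):
    notes = [
        _note("n1", "p1", "Patient exhibits flat affect."),
        _note("n2", "p2", "No flat affect noted."),
        _note("n3", "p3", "Shows avolition. Alogia documented."),
    ]
    _, profiles = annotate_corpus(notes, lexicon, fuzzy=False)
    by_id = {p.patient_id: p for p in profiles}
    p1 = by_id["p1"]
    assert p1.domain_flags[SymptomDomain.BLUNTED_AFFECT]
    assert p1.any_negative_symptom and p1.expressive_flag and not p1.experiential_flag
    p2 = by_id["p2"]
    assert not p2.any_negative_symptom
    p3 = by_id["p3"]
    flagged = {d for d, v in p3.domain_flags.items() if v}
    assert flagged == {SymptomDomain.AVOLITION, SymptomDomain.ALOGIA}


def test_duplicate_note_id_rejected(lexicon):
    notes = [_note("n1", "p1", "ok."), _note("n1", "p2", "ok.")]
    with pytest.raises(ValueError, match="duplicate note_id"):
        annotate_corpus(notes, lexicon)


def test_date_window_filter(lexicon):
    notes = [
        ClinicalNote("n1", "p1", "2019-01-01", "Patient exhibits flat affect."),
        ClinicalNote("n2", "p1", "2021-01-01", "Shows avolition."),
    ]
    _, profiles = annotate_corpus(notes, lexicon, fuzzy=False, date_from="2020-01-01")
    assert profiles[0].domain_flags[SymptomDomain.AVOLITION]
    assert not profiles[0].domain_flags[SymptomDomain.BLUNTED_AFFECT]


def test_pipeline_is_deterministic(lexicon, clean_notes_bundle):
    notes, _, _ = clean_notes_bundle
    corpus = notes_from_frame(notes)
    a, _ = annotate_corpus(corpus, lexicon, fuzzy=True)
    b, _ = annotate_corpus(corpus, lexicon, fuzzy=True)
    assert mentions_to_frame(a).equals(mentions_to_frame(b))


def test_adding_notes_never_clears_a_domain_flag(lexicon, clean_notes_bundle):
    """Domain flags are monotone in the note set (retained mentions only add)."""
    notes, _, _ = clean_notes_bundle
    corpus = notes_from_frame(notes)
    pid = corpus[0].patient_id
    mine = [n for n in corpus if n.patient_id == pid]
    extra = ClinicalNote("extra", pid, "2021-06-01", "Routine visit. Stable.")
    _, before = annotate_corpus(mine, lexicon, fuzzy=False)
    _, after = annotate_corpus(mine + [extra], lexicon, fuzzy=False)
    flags_before = {d: v for d, v in before[0].domain_flags.items()}
    flags_after = {d: v for d, v in after[0].domain_flags.items()}
    for d, v in flags_before.items():
        if v:
            assert flags_after[d]


def test_planted_corpus_recovered_exactly(lexicon, clean_notes_bundle):
    """On a decoy-free corpus every planted mention is retained and nothing else fires."""
    notes, labels, spans = clean_notes_bundle
    mentions, _ = annotate_corpus(notes_from_frame(notes), lexicon, fuzzy=True)
    retained = {(m.note_id, m.domain.value) for m in mentions if m.retained}
    planted = {
        (r.note_id, r.domain) for r in spans.itertuples() if r.intended_retained
    }
    assert retained == planted
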