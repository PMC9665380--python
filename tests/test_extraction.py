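"""Contact and name extraction: normalisation, grouping, lexicon."""

from collections import Counter
from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adpop import (
    AdRecord,
    Context,
    Gender,
    NameLexicon,
    assign_gender,
    build_name_lexicon,
    canonicalize_emails,
    canonicalize_name,
    detect_collective,
    extract_names,
    load_area_codes,
    load_seed_names,
    normalize_phone,
    obfuscate_phone,
    PhoneStyle,
)


def ad(text, category=Gender.CIS_FEMALE):
    return AdRecord(
        ad_id="x", site="s", timestamp=datetime(2015, 1, 1, tzinfo=timezone.utc),
        category=category, text=text,
    )


# ---------------------------------------------------------------------------
# Phones
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        ("call sevenseveneight 5five5 5421", {"778 555 5421"}),
        ("416-555-1234 anytime", {"416 555 1234"}),
        ("(604) 555-0000 or 416.555.9999", {"604 555 0000", "416 555 9999"}),
        ("1-416-555-1234 toll", {"416 555 1234"}),
        ("no numbers here, just words", set()),
        ("short 12345", set()),
    ],
)
def test_normalize_phone(text, expected):
    assert normalize_phone(text) == expected


def test_invalid_area_code_goes_to_review_queue():
    queue = []
    assert normalize_phone("999-555-1234", review_queue=queue) == set()
    assert len(queue) == 1
    assert queue[0]["kind"] == "phone" and queue[0]["value"] == "9995551234"


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.sampled_from(sorted(load_area_codes())),
    st.integers(200, 999),
    st.integers(0, 9999),
    st.sampled_from(list(PhoneStyle)),
    st.integers(0, 2**31 - 1),
)
def test_obfuscation_round_trip(area, mid, last, style, seed):
    """normalize_phone recovers the canonical number for every style."""
    digits = f"{area}{mid:03d}{last:04d}"
    rng = np.random.default_rng(seed)
    rendered = obfuscate_phone(digits, style, rng)
    assert normalize_phone(f"contact: {rendered} ok") == {
        f"{digits[:3]} {digits[3:6]} {digits[6:]}"
    }


# ---------------------------------------------------------------------------
# Emails
# ---------------------------------------------------------------------------


def dp_levenshtein(a, b):
    """Independent dynamic-programming edit-distance oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@pytest.mark.parametrize(
    "emails,same",
    [
        (["a@x.com", "a@x.com"], True),
        (["jane@mail.com", "jnae@mail.com"], True),   # distance 2
        (["jane@mail.com", "john@mail.com"], False),  # distance > 2
    ],
)
def test_email_grouping_matches_distance_rule(emails, same):
    assert dp_levenshtein(emails[0], emails[1]) <= 2 if same else dp_levenshtein(
        emails[0], emails[1]
    ) > 2
    mapping = canonicalize_emails(emails)
    assert (mapping[emails[0]] == mapping[emails[1]]) == same


def test_email_canonical_is_majority_spelling():
    mapping = canonicalize_emails(["real@mail.com", "real@mail.com", "reall@mail.com"])
    assert mapping["reall@mail.com"] == "real@mail.com"


def test_malformed_email_reviewed_not_grouped():
    queue = []
    mapping = canonicalize_emails(["ok@mail.com", "bad@nodomain"], review_queue=queue)
    assert "bad@nodomain" not in mapping
    assert queue and queue[0]["kind"] == "email"


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.text("abcdef", min_size=1, max_size=8), st.text("abcdef", min_size=1, max_size=8))
def test_levenshtein_agrees_with_dp_oracle(a, b):
    from adpop.extraction import _levenshtein

    assert _levenshtein(a, b) == dp_levenshtein(a, b)


# ---------------------------------------------------------------------------
# Names
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "raw,canon",
    [
        ("Angellaaaaaa", "angela"),
        ("angela", "angela"),
        ("ANNA!!", "ana"),
        ("  Mi-Mi  ", "mimi"),
        ("J'adore", "j'adore"),
    ],
)
def test_canonicalize_name(raw, canon):
    assert canonicalize_name(raw) == canon
    assert canonicalize_name(canon) == canon  # idempotent


def test_canonicalize_name_rejects_empty():
    with pytest.raises(ValueError):
        canonicalize_name("!!! 123")


def test_lexicon_accepts_planted_novel_name_and_excludes_filler():
    texts = (
        ["My name is Mia. Available now."] * 3
        + ["My name is Lana."] * 2
        + ["Je m'appelle Mia."] * 2
        + ["Je m'appelle Lana, sweet and discreet."] * 2
        + ["Je m'appelle Zarelle! Sweet and discreet."] * 3
        + ["Sweet deals all week, very sweet."] * 3
    )
    lex = build_name_lexicon(texts, ["mia", "lana"], threshold=0.5)
    assert "mia" in lex.accepted
    assert "zarele" in lex.accepted  # canonical form of the novel name
    assert "sweet" not in lex.accepted  # never follows a context word often enough
    assert "is" in lex.context_words and "m'appelle" in lex.context_words


def test_lexicon_seed_below_threshold_dropped():
    # "mia" appears mostly mid-sentence -> not name-like; "anna" establishes
    # the context words
    texts = (
        ["My name is Anna."] * 4
        + ["Call me Anna."] * 2
        + ["the mia special offer"] * 6
        + ["My name is Mia."] * 2
    )
    lex = build_name_lexicon(texts, ["anna", "mia"], threshold=0.5)
    assert "ana" in lex.accepted
    assert "mia" not in lex.accepted


def test_lexicon_no_seeds_found_falls_back():
    lex = build_name_lexicon(["nothing here"], ["mia"], threshold=0.5)
    assert lex.accepted == {"mia"}


def test_extract_names_uses_lexicon():
    lex = NameLexicon(seeds={"angela"}, context_words=["is"], accepted={"angela"})
    assert extract_names(ad("Hi I'm Angellaaaaaa"), lex) == Counter({"angela": 1})
    assert extract_names(ad("no names at all"), lex) == Counter()


def test_lexicon_round_trip_dict():
    lex = NameLexicon(seeds={"a"}, context_words=["is"], accepted={"a", "b"})
    assert NameLexicon.from_dict(lex.to_dict()) == lex


def test_generated_corpus_names_are_recovered(small_corpus, small_extracted):
    """Planted names are found by the corpus-built lexicon."""
    cfg, records, truth = small_corpus
    extracted, lexicon = small_extracted
    planted = set()
    for p in truth.persons:
        if p.names_visible:
            planted |= set(p.names)
    missing = planted - lexicon.accepted
    assert len(missing) <= max(2, 0.02 * len(planted))


# ---------------------------------------------------------------------------
# Context and gender
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,n_names,expected",
    [
        ("our agency has availability", 0, Context.COLLECTIVE),
        ("independent, no agency", 1, Context.COLLECTIVE),  # no negation handling
        ("quiet and classy", 3, Context.COLLECTIVE),  # name-count branch
        ("quiet and classy", 1, Context.INDIVIDUAL),
        ("four hands massage available", 1, Context.COLLECTIVE),  # phrase keyword
        ("clubbing outfit pics", 1, Context.INDIVIDUAL),  # 'club' must be whole word
    ],
)
def test_detect_collective(text, n_names, expected):
    assert detect_collective(text, n_names) is expected


def test_assign_gender_passthrough_and_partition(small_corpus):
    assert assign_gender(ad("x", Gender.CIS_FEMALE)) is Gender.CIS_FEMALE
    assert assign_gender(ad("x", Gender.OTHER)) is Gender.OTHER
    _, records, _ = small_corpus
    counts = Counter(assign_gender(r) for r in records)
    assert sum(counts.values()) == len(records)  # strata partition the corpus
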