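"""Turn raw ad text into canonical contacts, names, social context and gender.

Phone numbers may be written plainly ("416-555-1234") or obscured with number
words ("sevenseveneight 5five5 5421"); both are normalised to the canonical
"NNN NNN NNNN" form and validated against the packaged North American
area-code table.  Emails are grouped by Levenshtein distance <= 2 so that
simple misspellings map to one canonical address.  First names are detected
with a corpus-built lexicon: seed names identify the context words that
typically precede names ("name is ...", "je m'appelle ..."), and tokens that
follow those context words are accepted as additional names.

Items that the rules cannot accept automatically (phones with invalid area
codes, emails with malformed domains) are routed to a review queue instead of
being silently accepted or dropped.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources

import edlib

from .corpus_model import AdRecord, Contact, ContactKind, Context, Gender

logger = logging.getLogger("adpop")

# ---------------------------------------------------------------------------
# Packaged reference data
# ---------------------------------------------------------------------------


def load_area_codes() -> frozenset:
    """Valid North American area codes shipped with the package."""
    text = resources.files("adpop").joinpath("data/area_codes.csv").read_text()
    codes = set()
    for line in text.splitlines()[1:]:
        if line.strip():
            codes.add(line.split(",")[0].strip())
    return frozenset(codes)


def load_seed_names() -> list:
    """Packaged list of common first names, canonicalised."""
    text = resources.files("adpop").joinpath("data/first_names.txt").read_text()
    out = []
    seen = set()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        name = canonicalize_name(line)
        if name not in seen:
            seen.add(name)
            out.append(name)
    return out


_AREA_CODES = None


def _area_codes() -> frozenset:
    global _AREA_CODES
    if _AREA_CODES is None:
        _AREA_CODES = load_area_codes()
    return _AREA_CODES


# ---------------------------------------------------------------------------
# Phones
# ---------------------------------------------------------------------------

# Digit words, longest first so concatenations like "sevenseveneight" resolve
# greedily; "oh" is the spoken homophone of zero.
_WORD_DIGITS = [
    ("seven", "7"), ("eight", "8"), ("three", "3"), ("zero", "0"),
    ("four", "4"), ("five", "5"), ("nine", "9"), ("six", "6"),
    ("one", "1"), ("two", "2"), ("oh", "0"),
]
_WORD_RE = re.compile("|".join(w for w, _ in _WORD_DIGITS))
_WORD_MAP = dict(_WORD_DIGITS)
_DIGIT_RUN_RE = re.compile(r"\d(?:[\s\-.()]*\d)*")


def _candidate_numbers(text: str) -> set:
    """Maximal digit runs (allowing common separators) with 10 significant
    digits, or 11 with a leading country code 1."""
    out = set()
    for m in _DIGIT_RUN_RE.finditer(text):
        digits = re.sub(r"\D", "", m.group(0))
        if len(digits) == 11 and digits.startswith("1"):
            digits = digits[1:]
        if len(digits) == 10:
            out.add(digits)
    return out


def normalize_phone(text: str, review_queue=None) -> set:
    """Extract canonical phone numbers ("NNN NNN NNNN") from ad text.

    Candidates with an invalid area code are not accepted; they are appended
    to ``review_queue`` (when given) for manual inspection.
    """
    low = text.lower()
    plain = _candidate_numbers(low)
    deobscured = _candidate_numbers(_WORD_RE.sub(lambda m: _WORD_MAP[m.group(0)], low))
    accepted = set()
    for digits in plain | deobscured:
        if digits[:3] in _area_codes():
            accepted.add(f"{digits[:3]} {digits[3:6]} {digits[6:]}")
        elif review_queue is not None:
            review_queue.append(
                {"kind": "phone", "value": digits, "reason": "invalid area code"}
            )
    return accepted


# ---------------------------------------------------------------------------
# Emails
# ---------------------------------------------------------------------------

_EMAIL_RE = re.compile(r"[a-z0-9._%+\-']+@[a-z0-9\-]+(?:\.[a-z0-9\-]+)*\.[a-z]{2,}")
_EMAILISH_RE = re.compile(r"[^\s@]+@[^\s@]+")


def extract_emails(text: str, review_queue=None) -> set:
    """Syntactically plausible emails in the text; malformed-domain lookalikes
    go to the review queue."""
    low = text.lower()
    good = set(_EMAIL_RE.findall(low))
    if review_queue is not None:
        for cand in _EMAILISH_RE.findall(low):
            cand = cand.strip(".,;:!?")
            if cand not in good and not _EMAIL_RE.fullmatch(cand):
                review_queue.append(
                    {"kind": "email", "value": cand, "reason": "malformed domain"}
                )
    return good


def _levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def canonicalize_emails(emails, review_queue=None, max_distance: int = 2) -> dict:
    """Map each email to one canonical representative.

    Pairs at Levenshtein distance <= ``max_distance`` are flagged as likely
    misspellings of each other; flagged groups (single-linkage connected
    components) collapse onto their most frequent member (ties broken
    lexicographically).  Malformed entries are excluded and reviewed.
    """
    counts = Counter(emails)
    valid = []
    for e in counts:
        if _EMAIL_RE.fullmatch(e):
            valid.append(e)
        elif review_queue is not None:
            review_queue.append({"kind": "email", "value": e, "reason": "malformed"})
    parent = {e: e for e in valid}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_len = defaultdict(list)
    for e in valid:
        by_len[len(e)].append(e)
    for e in valid:
        for ln in range(len(e) - max_distance, len(e) + max_distance + 1):
            for other in by_len.get(ln, ()):
                if other <= e:
                    continue
                if _levenshtein(e, other) <= max_distance:
                    ra, rb = find(e), find(other)
                    if ra != rb:
                        parent[rb] = ra
    groups = defaultdict(list)
    for e in valid:
        groups[find(e)].append(e)
    mapping = {}
    for members in groups.values():
        canonical = min(members, key=lambda e: (-counts[e], e))
        for e in members:
            mapping[e] = canonical
    return mapping


# ---------------------------------------------------------------------------
# Names
# ---------------------------------------------------------------------------

_NAME_STRIP_RE = re.compile(r"[^a-z']+")
_RUN_RE = re.compile(r"(.)\1+")


def canonicalize_name(raw: str) -> str:
    """Canonical name form: lowercase, punctuation stripped except single
    quotes, maximal runs of a repeated letter collapsed ("Angellaaaaaa" ->
    "angela").  Idempotent; empty results are rejected."""
    s = _NAME_STRIP_RE.sub("", raw.lower())
    s = _RUN_RE.sub(r"\1", s).strip("'")
    if not s:
        raise ValueError(f"no name content in {raw!r}")
    return s


def _tokenize(text: str) -> list:
    """Lowercase tokens with punctuation stripped except single quotes."""
    return re.findall(r"[a-z0-9']+", text.lower())


@dataclass
class NameLexicon:
    """Corpus-derived lexicon of accepted first names."""

    seeds: set
    context_words: list
    accepted: set
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "seeds": sorted(self.seeds),
            "context_words": list(self.context_words),
            "accepted": sorted(self.accepted),
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NameLexicon":
        return cls(
            seeds=set(d["seeds"]),
            context_words=list(d["context_words"]),
            accepted=set(d["accepted"]),
            threshold=d.get("threshold", 0.5),
        )


def build_name_lexicon(
    texts,
    seeds,
    threshold: float = 0.5,
    min_context_count: int = 2,
    min_new_count: int = 2,
) -> NameLexicon:
    """Build a name lexicon from ad texts.

    Steps: (i) locate seed-name occurrences; (ii) rank the tokens immediately
    preceding them as candidate context words; (iii) retain seeds for which at
    least ``threshold`` of occurrences are name-like (preceded by a context
    word); (iv) accept new tokens that follow context words, canonicalised,
    provided they behave name-like themselves.
    """
    seed_canon = set()
    for s in seeds:
        try:
            seed_canon.add(canonicalize_name(s))
        except ValueError:
            continue

    token_lists = [_tokenize(t) for t in texts]

    prev_counts = Counter()
    prev_seeds = defaultdict(set)  # prev token -> distinct seeds it precedes
    seed_occurrences = Counter()
    seed_with_prev = defaultdict(Counter)  # seed -> Counter(prev token)
    for toks in token_lists:
        canon = [_safe_canon(t) for t in toks]
        for i, c in enumerate(canon):
            if c in seed_canon:
                seed_occurrences[c] += 1
                if i > 0:
                    prev = toks[i - 1]
                    prev_counts[prev] += 1
                    prev_seeds[prev].add(c)
                    seed_with_prev[c][prev] += 1

    if not seed_occurrences:
        logger.warning("no seed names found in corpus; lexicon falls back to seeds")
        return NameLexicon(seeds=seed_canon, context_words=[], accepted=set(seed_canon),
                           threshold=threshold)

    # a context word typically precedes names in general, not one specific
    # name: require it before several distinct seeds when several were seen
    need_seeds = min(2, len(seed_occurrences))
    context_candidates = {
        w for w, c in prev_counts.items()
        if c >= min_context_count and len(prev_seeds[w]) >= need_seeds
    }

    retained = set()
    for seed, total in seed_occurrences.items():
        namelike = sum(c for w, c in seed_with_prev[seed].items() if w in context_candidates)
        if total and namelike / total >= threshold:
            retained.add(seed)

    ctx_counter = Counter()
    for seed in retained:
        ctx_counter.update({w: c for w, c in seed_with_prev[seed].items()
                            if w in context_candidates})
    context_words = [w for w, _ in ctx_counter.most_common()]
    context_set = set(context_words)

    follows_ctx = Counter()
    occurs = Counter()
    for toks in token_lists:
        for i, tok in enumerate(toks):
            c = _safe_canon(tok)
            if c is None or c in context_set or len(c) < 2 or c.isdigit():
                continue
            occurs[c] += 1
            if i > 0 and toks[i - 1] in context_set:
                follows_ctx[c] += 1

    accepted = set(retained)
    for tok, n_follow in follows_ctx.items():
        if n_follow >= min_new_count and n_follow / occurs[tok] >= threshold:
            accepted.add(tok)

    return NameLexicon(seeds=seed_canon, context_words=context_words,
                       accepted=accepted, threshold=threshold)


def _safe_canon(tok: str):
    try:
        return canonicalize_name(tok)
    except ValueError:
        return None


def extract_names(ad: AdRecord, lexicon: NameLexicon) -> Counter:
    """Canonical names from one ad, as a multiset restricted to the lexicon's
    accepted set."""
    out = Counter()
    for tok in _tokenize(ad.text):
        c = _safe_canon(tok)
        if c is not None and c in lexicon.accepted:
            out[c] += 1
    return out


# ---------------------------------------------------------------------------
# Social context and gender
# ---------------------------------------------------------------------------

COLLECTIVE_KEYWORDS = (
    "models", "girls", "we", "our", "us", "spa", "agency", "club",
    "nous", "filles", "agence", "four hands", "duo", "trio", "roommate", "couple",
)


def detect_collective(ad_text: str, distinct_names: int) -> Context:
    """Collective iff more than one distinct name, or any group keyword matches
    as a whole word (case-insensitive, punctuation-stripped; no negation
    handling)."""
    if distinct_names > 1:
        return Context.COLLECTIVE
    haystack = " ".join(_tokenize(ad_text))
    for kw in COLLECTIVE_KEYWORDS:
        if re.search(rf"(?<![a-z0-9']){re.escape(kw)}(?![a-z0-9'])", haystack):
            return Context.COLLECTIVE
    return Context.INDIVIDUAL


def assign_gender(ad: AdRecord) -> Gender:
    """Gender comes from the ad's placement category; anything unknown is
    'other'."""
    return ad.category if isinstance(ad.category, Gender) else Gender.OTHER


# ---------------------------------------------------------------------------
# Per-ad extraction used by the pipeline
# ---------------------------------------------------------------------------


@dataclass
class ExtractedAd:
    """Extraction output for one ad."""

    ad: AdRecord
    contacts: frozenset  # of Contact
    names: Counter = field(default_factory=Counter)


def extract_contacts(records, review_queue=None) -> list:
    """Phones and emails for every record, with emails canonicalised
    corpus-wide. Returns a list of ExtractedAd (names not yet filled)."""
    raw_emails = []
    per_ad = []
    for rec in records:
        phones = normalize_phone(rec.text, review_queue)
        emails = extract_emails(rec.text, review_queue)
        raw_emails.extend(emails)
        per_ad.append((rec, phones, emails))
    email_map = canonicalize_emails(raw_emails, review_queue)
    out = []
    for rec, phones, emails in per_ad:
        contacts = {Contact(ContactKind.PHONE, p) for p in phones}
        contacts |= {
            Contact(ContactKind.EMAIL, email_map[e]) for e in emails if e in email_map
        }
        out.append(ExtractedAd(ad=rec, contacts=frozenset(contacts)))
    return out
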