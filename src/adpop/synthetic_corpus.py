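"""Synthetic ad corpora with known ground truth.

The generator emulates the statistical structure the estimation pipeline
assumes.  Each underlying advertising entity (an individual worker or a
small collective) is intermittently active over the study period: it has a
characteristic appearance span D drawn from a heavy-tailed mixture (a point
mass at one day plus a log-normal tail, giving a days-online distribution
with median near two weeks, a mean several times larger and an interquartile
range starting at one day), and roughly Period/D appearance slots of which
one is always realised.  At each unobserved slot the entity may re-appear
under fresh contact details, so the expected number of observed advertiser
fragments per entity is 1 + (P/D - 1) * (R_contact + R_chat): exactly the
overcounting process the uniqueness correction inverts.

Chat-account churn has two equal-rate flavours, realising the identifying
assumption behind the additive rate correction: an account change that keeps
the contact (measurable by counting chat ids per contact) and an account
reset that also replaces the contact (invisible to both direct
measurements).  Name churn, irrelevant advertisers, spurious extracted
names, missing contacts and names, collectives with co-occurring contacts,
obfuscated phones, misspelled emails and reused image tokens are all planted
at configurable rates with per-event ground truth.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Optional

import numpy as np
import yaml

from .corpus_model import AdRecord, Context, Gender, GroundTruth, TruePerson
from .extraction import load_area_codes, load_seed_names

# Canonical-form novel names absent from the packaged seed list; they let
# tests verify that the lexicon accepts genuinely new names from context.
NOVEL_NAMES = (
    "zarele", "kyrela", "maelise", "taviene", "solara", "vexandra",
    "amarine", "quinela", "calisandre", "rosavel", "marovia", "selvane",
    "lunaris", "tirenza", "ophalie", "zephyra",
)

_FILLERS = (
    "Available today and tomorrow, downtown location.",
    "Sweet and discreet, see you soon.",
    "New in town, limited availability this week.",
    "Incall and outcall, serious inquiries only.",
    "Back in the city, ask about specials.",
    "Genuine photos, no rush sessions.",
)

_IRRELEVANT_FILLERS = (
    "Best detailing deals in town, winter tires on special.",
    "Casting agency recruiting for promo modeling gigs.",
    "Massage therapy clinic accepting new patients.",
    "Nightclub promo team hiring hosts, apply now.",
)

_COLLECTIVE_PHRASES = (
    "Our duo welcomes you.",
    "The girls at our spa welcome you.",
    "Visit our agency lounge.",
    "Two of us available for duo bookings.",
)

_NAME_TEMPLATES = (
    "My name is {name}.",
    "I'm {name}.",
    "Je m'appelle {name}.",
    "Meet {name}.",
    "Call me {name}.",
)

_EMAIL_DOMAINS = ("mail.com", "hotmail.com", "gmail.com", "yahoo.ca", "live.ca")


class PhoneStyle(str, enum.Enum):
    PLAIN = "plain"
    SPACES = "spaces"
    DOTS = "dots"
    PARENS = "parens"
    WORDMIX = "wordmix"
    WORDS = "words"


_DIGIT_WORDS = ("zero", "one", "two", "three", "four", "five", "six", "seven", "eight", "nine")


def obfuscate_phone(digits: str, style: PhoneStyle, rng: np.random.Generator) -> str:
    """Render a 10-digit phone number in one of the styles seen in ads; every
    style is recoverable by extraction.normalize_phone."""
    if len(digits) != 10 or not digits.isdigit():
        raise ValueError("digits must be a 10-digit string")
    a, b, c = digits[:3], digits[3:6], digits[6:]
    style = PhoneStyle(style)
    if style is PhoneStyle.PLAIN:
        return f"{a}-{b}-{c}"
    if style is PhoneStyle.SPACES:
        return f"{a} {b} {c}"
    if style is PhoneStyle.DOTS:
        return f"{a}.{b}.{c}"
    if style is PhoneStyle.PARENS:
        return f"({a}) {b}-{c}"

    def wordify(group: str, prob: float) -> str:
        return "".join(
            _DIGIT_WORDS[int(d)] if rng.random() < prob else d for d in group
        )

    prob = 1.0 if style is PhoneStyle.WORDS else 0.5
    return " ".join(wordify(g, prob) for g in (a, b, c))


@dataclass
class CorpusConfig:
    """Study conditions for a synthetic corpus.

    Defaults follow the magnitudes the analysis design assumes: 1000 workers
    over a two-year window, contact churn 0.0223/day, chat-id churn
    0.0024/day, 95% relevant advertisers, 11% of ads without contacts, and a
    gender mix matching observed ad-category shares.
    """

    n_workers: int = 1000
    start: date = date(2014, 11, 1)
    end: date = date(2016, 10, 31)  # exclusive
    # appearance-span mixture: point mass at one day + log-normal tail
    duration_point_mass: float = 0.25
    duration_lognorm_mu: float = 3.322
    duration_lognorm_sigma: float = 1.585
    ads_per_active_day: float = 0.3
    contact_change_rate: float = 0.0223
    chatid_change_rate: float = 0.0024
    name_change_rate: float = 1.0e-4
    name_validity: float = 0.9612
    fraction_irrelevant: float = 0.05
    missing_contact_rate: float = 0.11
    missing_name_rate: float = 0.10
    collective_fraction: float = 0.45
    collective_extra_names_mean: float = 0.4
    collective_multi_contact_prob: float = 0.5
    gender_mix: dict = field(
        default_factory=lambda: {
            "cis_female": 0.847, "cis_male": 0.051, "transgender": 0.017, "other": 0.085,
        }
    )
    site_weights: dict = field(
        default_factory=lambda: {"site1": 0.20, "site2": 0.50, "site3": 0.30}
    )
    chat_sites: tuple = ("site3",)
    email_fraction: float = 0.15
    phone_obfuscation_prob: float = 0.10
    email_misspell_prob: float = 0.05
    images_per_advertiser: float = 16.0
    image_reuse_factor: float = 1.4
    tokens_per_ad_max: int = 3
    novel_name_fraction: float = 0.05
    seed: int = 0

    @property
    def period_days(self) -> int:
        return (self.end - self.start).days

    def validate(self) -> None:
        probs = {
            "duration_point_mass": self.duration_point_mass,
            "fraction_irrelevant": self.fraction_irrelevant,
            "missing_contact_rate": self.missing_contact_rate,
            "missing_name_rate": self.missing_name_rate,
            "collective_fraction": self.collective_fraction,
            "collective_multi_contact_prob": self.collective_multi_contact_prob,
            "email_fraction": self.email_fraction,
            "phone_obfuscation_prob": self.phone_obfuscation_prob,
            "email_misspell_prob": self.email_misspell_prob,
            "name_validity": self.name_validity,
            "novel_name_fraction": self.novel_name_fraction,
        }
        for k, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{k} must be a probability, got {v}")
        for k in ("contact_change_rate", "chatid_change_rate", "name_change_rate",
                  "ads_per_active_day"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be >= 0")
        if self.n_workers < 0:
            raise ValueError("n_workers must be >= 0")
        if self.period_days < 1:
            raise ValueError("date range must span at least one day")
        for mix in (self.gender_mix, self.site_weights):
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError("mixture weights must sum to 1")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["start"] = self.start.isoformat()
        d["end"] = self.end.isoformat()
        d["chat_sites"] = list(self.chat_sites)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CorpusConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "start" in d:
            d["start"] = date.fromisoformat(d["start"])
        if "end" in d:
            d["end"] = date.fromisoformat(d["end"])
        if "chat_sites" in d:
            d["chat_sites"] = tuple(d["chat_sites"])
        return cls(**d)


class _TokenFactory:
    def __init__(self, rng, reuse_factor):
        self.rng = rng
        self.pool = []
        self.borrow_prob = 0.0 if reuse_factor <= 1 else 1.0 - 1.0 / reuse_factor
        self.counter = 0

    def person_tokens(self, n):
        out = []
        for _ in range(n):
            if self.pool and self.rng.random() < self.borrow_prob:
                out.append(self.pool[int(self.rng.integers(0, len(self.pool)))])
            else:
                tok = f"img{self.counter:08x}"
                self.counter += 1
                self.pool.append(tok)
                out.append(tok)
        return out


def _draw_duration(cfg: CorpusConfig, rng) -> int:
    """Appearance span for one entity.

    The configured mixture describes the span distribution of *observed*
    advertisers (the published days-online shape: IQR starting at one day,
    median near two weeks, heavy tail).  An entity with span D is observed as
    about 1 + (P/D - 1) * R advertiser fragments, so entity spans are drawn
    by rejection with weight 1/(expected fragments) to make the
    fragment-weighted span distribution match the target mixture."""
    period = cfg.period_days
    r_total = cfg.contact_change_rate + cfg.chatid_change_rate
    while True:
        if rng.random() < cfg.duration_point_mass:
            d = 1
        else:
            d = int(round(rng.lognormal(cfg.duration_lognorm_mu, cfg.duration_lognorm_sigma)))
            d = max(1, min(d, period))
        if r_total <= 0:
            return d
        if rng.random() < 1.0 / (1.0 + (period / d - 1.0) * r_total):
            return d


def generate(config: CorpusConfig, seed: Optional[int] = None):
    """Generate (corpus records, ground truth); deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    seed_names = load_seed_names()
    area_codes = sorted(load_area_codes())
    period = config.period_days
    r_c = config.contact_change_rate
    r_chat = config.chatid_change_rate
    tokens = _TokenFactory(rng, config.image_reuse_factor)

    genders = list(config.gender_mix)
    gender_p = np.array([config.gender_mix[g] for g in genders])
    sites = list(config.site_weights)
    site_p = np.array([config.site_weights[s] for s in sites])

    used_phones: set = set()
    used_emails: set = set()
    records: list = []
    persons: list = []
    ad_to_person: dict = {}
    ad_counter = 0
    chat_counter = 0
    person_id = 0
    workers = 0

    def fresh_phone() -> str:
        while True:
            area = area_codes[int(rng.integers(0, len(area_codes)))]
            rest = f"{rng.integers(200, 1000):03d}{rng.integers(0, 10000):04d}"
            digits = area + rest
            if digits not in used_phones:
                used_phones.add(digits)
                return digits

    def fresh_email() -> str:
        alphabet = "abcdefghijklmnopqrstuvwxyz0123456789"
        while True:
            local = "".join(alphabet[i] for i in rng.integers(0, 36, size=10))
            dom = _EMAIL_DOMAINS[int(rng.integers(0, len(_EMAIL_DOMAINS)))]
            email = f"{local}@{dom}"
            if email not in used_emails:
                used_emails.add(email)
                return email

    def misspell(email: str) -> str:
        local, dom = email.split("@")
        chars = list(local)
        n_edits = 1 + int(rng.random() < 0.3)
        for _ in range(n_edits):
            i = int(rng.integers(0, len(chars)))
            chars[i] = "abcdefghijklmnopqrstuvwxyz"[int(rng.integers(0, 26))]
        return "".join(chars) + "@" + dom

    def pick_names(k: int, exclude=()) -> list:
        out = []
        tries = 0
        while len(out) < k and tries < 200:
            tries += 1
            if rng.random() < config.novel_name_fraction:
                cand = NOVEL_NAMES[int(rng.integers(0, len(NOVEL_NAMES)))]
            else:
                cand = seed_names[int(rng.integers(0, len(seed_names)))]
            if cand not in out and cand not in exclude:
                out.append(cand)
        return out

    def render_contacts(phones, emails) -> str:
        parts = []
        for digits in phones:
            if rng.random() < config.phone_obfuscation_prob:
                style = PhoneStyle.WORDMIX if rng.random() < 0.7 else PhoneStyle.WORDS
            else:
                style = list(PhoneStyle)[int(rng.integers(0, 4))]
            parts.append("call " + obfuscate_phone(digits, style, rng))
        for email in emails:
            shown = misspell(email) if rng.random() < config.email_misspell_prob else email
            parts.append("email " + shown)
        return " ".join(parts)

    while workers < config.n_workers:
        relevant = rng.random() >= config.fraction_irrelevant
        gender = Gender(genders[rng.choice(len(genders), p=gender_p)])
        site = sites[rng.choice(len(sites), p=site_p)]
        chat_enabled = site in config.chat_sites
        collective = rng.random() < config.collective_fraction
        if collective:
            n_names = 2 + int(rng.poisson(config.collective_extra_names_mean))
        else:
            n_names = 1
        names = pick_names(n_names)
        names_visible = rng.random() >= config.missing_name_rate
        duration = _draw_duration(config, rng)
        slots_minus1 = period / duration - 1.0

        n_extra = int(rng.poisson(slots_minus1 * (r_c + r_chat)))
        n_extra = min(n_extra, max(10, int(3 * period / duration)))
        n_frag = 1 + n_extra
        if r_c + r_chat > 0:
            boundary_is_reset = rng.random(n_frag - 1) < r_chat / (r_c + r_chat)
        else:
            boundary_is_reset = np.zeros(0, dtype=bool)

        multi_contact = collective and rng.random() < config.collective_multi_contact_prob
        n_contacts = 2 if multi_contact else 1
        pool = tokens.person_tokens(max(1, int(rng.poisson(config.images_per_advertiser))))

        chat_id = f"chat{chat_counter:07d}" if chat_enabled else None
        chat_counter += chat_enabled
        fragments = []
        contact_change_events = 0
        chatid_reset_events = 0
        chatid_extra_events = 0
        name_change_events = 0
        extra_valid_names: list = []
        person_ads: list = []

        for f_idx in range(n_frag):
            if f_idx > 0:
                contact_change_events += 1
                if boundary_is_reset[f_idx - 1] and chat_enabled:
                    chatid_reset_events += 1
                    chat_id = f"chat{chat_counter:07d}"
                    chat_counter += 1

            frag_contacts = []
            for _ in range(n_contacts):
                if rng.random() < config.email_fraction:
                    frag_contacts.append(("email", fresh_email()))
                else:
                    frag_contacts.append(("phone", fresh_phone()))

            start_off = int(rng.integers(0, period - duration + 1))
            f_start = config.start + timedelta(days=start_off)
            f_end = f_start + timedelta(days=duration - 1)

            day_offsets = {0, duration - 1}
            if duration > 2:
                interior = np.nonzero(rng.random(duration - 2) < config.ads_per_active_day)[0]
                day_offsets |= {int(i) + 1 for i in interior}
            day_offsets = sorted(day_offsets)
            n_ads = len(day_offsets)

            # chat-account additions that keep the contact (measurable churn,
            # at the configured rate per observed day)
            frag_chats = [chat_id]
            if chat_enabled:
                n_b1 = min(int(rng.poisson(r_chat * duration)), n_ads - 1)
                chatid_extra_events += n_b1
                for _ in range(n_b1):
                    frag_chats.append(f"chat{chat_counter:07d}")
                    chat_counter += 1
            cuts = sorted(rng.choice(np.arange(1, n_ads), size=len(frag_chats) - 1,
                                     replace=False)) if len(frag_chats) > 1 else []
            chat_of_ad = []
            ci = 0
            for i in range(n_ads):
                if ci < len(cuts) and i >= cuts[ci]:
                    ci += 1
                chat_of_ad.append(frag_chats[ci])

            # mid-fragment name change for named individuals
            frag_names = [list(names)] * n_ads
            if (not collective) and names_visible and n_ads >= 2 and slots_minus1 > 0:
                if rng.random() < min(slots_minus1 * config.name_change_rate, 0.9):
                    new_name = pick_names(1, exclude=names + extra_valid_names)
                    if new_name:
                        name_change_events += 1
                        extra_valid_names.append(new_name[0])
                        cut = int(rng.integers(1, n_ads))
                        frag_names = [list(names)] * cut + [new_name] * (n_ads - cut)

            # one spurious (wrongly extracted) name on average per
            # (1 - validity)/validity true pairs
            spurious_ad = None
            spurious_name = None
            if names_visible and config.name_validity < 1.0:
                lam = len(names) * (1.0 - config.name_validity) / config.name_validity
                if rng.random() < min(lam, 1.0):
                    cand = pick_names(1, exclude=names + extra_valid_names)
                    if cand:
                        spurious_name = cand[0]
                        # prefer interior ads so endpoint filtering cannot
                        # shorten the fragment's observable span
                        if n_ads >= 3:
                            spurious_ad = int(rng.integers(1, n_ads - 1))
                        else:
                            spurious_ad = int(rng.integers(0, n_ads))

            phones = [v for k, v in frag_contacts if k == "phone"]
            emails = [v for k, v in frag_contacts if k == "email"]

            for i, off in enumerate(day_offsets):
                day = f_start + timedelta(days=off)
                ts = datetime(day.year, day.month, day.day, tzinfo=timezone.utc) + timedelta(
                    seconds=int(rng.integers(0, 86400))
                )
                pieces = []
                if names_visible:
                    ad_names = frag_names[i]
                    if collective:
                        pieces.append(" ".join(f"Meet {n.capitalize()}." for n in ad_names))
                    else:
                        tmpl = _NAME_TEMPLATES[int(rng.integers(0, len(_NAME_TEMPLATES)))]
                        pieces.append(tmpl.format(name=ad_names[0].capitalize()))
                if spurious_ad == i and spurious_name:
                    pieces.append(f"Meet {spurious_name.capitalize()}.")
                if collective:
                    pieces.append(_COLLECTIVE_PHRASES[int(rng.integers(0, len(_COLLECTIVE_PHRASES)))])
                fillers = _FILLERS if relevant else _IRRELEVANT_FILLERS
                pieces.append(fillers[int(rng.integers(0, len(fillers)))])
                if multi_contact and i == 0:
                    pieces.append(render_contacts(phones, emails))
                elif multi_contact:
                    j = int(rng.integers(0, len(frag_contacts)))
                    k, v = frag_contacts[j]
                    if rng.random() < 0.5:
                        pieces.append(render_contacts(phones, emails))
                    else:
                        pieces.append(render_contacts([v] if k == "phone" else [],
                                                      [v] if k == "email" else []))
                else:
                    pieces.append(render_contacts(phones, emails))

                ad_tokens = rng.choice(
                    pool, size=min(len(pool), 1 + int(rng.integers(0, config.tokens_per_ad_max))),
                    replace=False,
                )
                ad_id = f"ad{ad_counter:07d}"
                ad_counter += 1
                records.append(
                    AdRecord(
                        ad_id=ad_id,
                        site=site,
                        timestamp=ts,
                        category=gender,
                        text=" ".join(pieces),
                        image_tokens=frozenset(str(t) for t in ad_tokens),
                        chat_id=chat_of_ad[i],
                    )
                )
                ad_to_person[ad_id] = person_id
                person_ads.append(ad_id)

            canon = tuple(
                f"{v[:3]} {v[3:6]} {v[6:]}" if k == "phone" else v for k, v in frag_contacts
            )
            fragments.append((canon, f_start, f_end))

        # contact-less extra ads (ads whose advertiser cannot be resolved)
        n_missing = int(rng.binomial(
            len(person_ads), config.missing_contact_rate / (1 - config.missing_contact_rate)
        )) if config.missing_contact_rate > 0 else 0
        for _ in range(n_missing):
            _, f_start, f_end = fragments[int(rng.integers(0, len(fragments)))]
            day = f_start + timedelta(
                days=int(rng.integers(0, (f_end - f_start).days + 1))
            )
            ts = datetime(day.year, day.month, day.day, tzinfo=timezone.utc) + timedelta(
                seconds=int(rng.integers(0, 86400))
            )
            ad_tokens = rng.choice(pool, size=min(len(pool), 2), replace=False)
            ad_id = f"ad{ad_counter:07d}"
            ad_counter += 1
            fillers = _FILLERS if relevant else _IRRELEVANT_FILLERS
            records.append(
                AdRecord(
                    ad_id=ad_id, site=site, timestamp=ts, category=gender,
                    text="Ask for details in person. " + fillers[int(rng.integers(0, len(fillers)))],
                    image_tokens=frozenset(str(t) for t in ad_tokens),
                    chat_id=None,
                )
            )
            ad_to_person[ad_id] = person_id

        persons.append(
            TruePerson(
                person_id=person_id,
                relevant=relevant,
                gender=gender,
                context=Context.COLLECTIVE if collective else Context.INDIVIDUAL,
                names=tuple(names),
                site=site,
                duration_days=duration,
                fragments=fragments,
                contact_change_events=contact_change_events,
                chatid_reset_events=chatid_reset_events,
                chatid_extra_events=chatid_extra_events,
                name_change_events=name_change_events,
                names_visible=names_visible,
                extra_valid_names=tuple(extra_valid_names),
            )
        )
        if relevant:
            workers += len(names)
        person_id += 1

    records.sort(key=lambda r: (r.timestamp, r.ad_id))
    truth = GroundTruth(
        persons=persons,
        ad_to_person=ad_to_person,
        config=config,
        period_start=config.start,
        period_end=config.end,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Truth-derived labels for the measurement stage
# ---------------------------------------------------------------------------


def person_of_advertiser(advertiser, truth: GroundTruth) -> Optional[int]:
    """Majority underlying person for a resolved advertiser."""
    votes: dict = {}
    for ad_id in advertiser.ad_ids:
        pid = truth.ad_to_person.get(ad_id)
        if pid is not None:
            votes[pid] = votes.get(pid, 0) + 1
    if not votes:
        return None
    return max(votes, key=lambda k: (votes[k], -k))


def relevance_labels(advertisers, truth: GroundTruth) -> list:
    """Truth relevance label per resolved advertiser (stands in for the
    manual review of a random advertiser sample)."""
    by_id = {p.person_id: p for p in truth.persons}
    out = []
    for a in advertisers:
        pid = person_of_advertiser(a, truth)
        out.append(by_id[pid].relevant if pid is not None else False)
    return out


def name_validity_labels(advertisers, truth: GroundTruth) -> list:
    """Truth validity label per (advertiser, name) pair: a name is valid when
    the underlying person really advertised under it."""
    by_id = {p.person_id: p for p in truth.persons}
    valid_names = {
        p.person_id: set(p.names) | set(p.extra_valid_names) for p in truth.persons
    }
    out = []
    for a in advertisers:
        pid = person_of_advertiser(a, truth)
        if pid is None:
            continue
        for name in a.names:
            out.append(name in valid_names[pid])
    return out
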