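"""Error/churn parameter measurement and scaled population estimates.

Raw advertiser counts overcount people: some advertisers are irrelevant, and
advertisers periodically change contact details, names and chat accounts, so
one person reappears as several advertisers.  The corrections are
multiplicative:

    N_advertisers = P(a relevant) * sum_a P(a unique)
    N_workers     = P(n valid) * P(n unique) * P(a relevant)
                    * sum_a Names(a) * P(a unique)

with the per-advertiser uniqueness probability

    P(a unique) = 1 / (1 + (Period / Days(a) - 1) * R_idchange)

where Days(a) is the advertiser's inclusive observed span within the window
and Period the window length in days.  The model treats an advertiser
observed for Days(a) of a Period as one appearance of an intermittently
active entity with roughly Period/Days(a) appearance slots, at risk of
re-appearing under fresh contact details once per unobserved slot.
R_idchange combines the directly measured contact-change rate with the
chat-id change rate, on the assumption that an account change accompanies an
unobservable contact change as often as it happens alone.

Confidence intervals for probabilities use the Wald interval
CI = P +/- z*sqrt(P(1-P)/N); the combined rate uses a root-sum-of-squares
interval; scaled estimates are bracketed by rerunning the scaling with all
parameters moved to their lower (resp. upper) interval bounds.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional, Sequence

from scipy.optimize import brentq

from .corpus_model import (
    DEFAULT_Z,
    Advertiser,
    Context,
    ErrorParams,
    Gender,
    ImageStats,
    ParamEstimate,
)

# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


def confidence_interval_p(p: float, n: int, z: float = DEFAULT_Z) -> tuple:
    """Wald interval for a proportion, clipped to [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    half = z * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def rate_ci_rss(r1: float, n1: int, r2: float, n2: int, z: float = DEFAULT_Z) -> tuple:
    """Root-sum-of-squares interval for the sum of two measured rates."""
    if r1 < 0 or r2 < 0:
        raise ValueError("rates must be >= 0")
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    total = r1 + r2
    half = z * math.sqrt(r1 * r1 / n1 + r2 * r2 / n2)
    return (max(0.0, total - half), total + half)


def p_unique(days_active: int, period_days: int, r_idchange: float) -> float:
    """Probability that an advertiser did not change identity in the window."""
    if not 1 <= days_active <= period_days:
        raise ValueError(
            f"days_active must satisfy 1 <= {days_active} <= {period_days}"
        )
    if r_idchange < 0:
        raise ValueError("r_idchange must be >= 0")
    return 1.0 / (1.0 + (period_days / days_active - 1.0) * r_idchange)


# ---------------------------------------------------------------------------
# Direct proportion measurements
# ---------------------------------------------------------------------------


def estimate_relevance(labels: Sequence[bool], z: float = DEFAULT_Z) -> ParamEstimate:
    """P(a relevant) from a labelled sample of advertisers."""
    n = len(labels)
    if n < 1:
        raise ValueError("need at least one labelled advertiser")
    p = sum(1 for x in labels if x) / n
    lo, hi = confidence_interval_p(p, n, z)
    return ParamEstimate(p, n, lo, hi)


def estimate_proportion(labels: Sequence[bool], z: float = DEFAULT_Z) -> ParamEstimate:
    """Generic labelled-sample proportion (used for P(n valid))."""
    return estimate_relevance(labels, z)


# ---------------------------------------------------------------------------
# Churn samples and rates
# ---------------------------------------------------------------------------


@dataclass
class ChurnSample:
    """Eligible ad sequences for a churn measurement.

    ``events`` counts observed changes; ``exposure_days`` is the at-risk
    exposure on the same clock the uniqueness correction uses: one at-risk
    day per unobserved appearance slot of a tracked entity, where an entity
    observed with typical span D in a period P has P/D - 1 such slots.
    """

    events: int
    exposure_days: float
    n_units: int  # tracked entities (or contacts / name pairs) in the sample
    pairs: int = 0  # advertiser-name pairs, for the name-change sample
    # delta-method effective event count when the exposure itself depends on
    # the estimated rate (smaller than `events`: the solve amplifies noise)
    effective_events: Optional[float] = None

    def __post_init__(self):
        if self.events > 0 and self.exposure_days <= 0:
            raise ValueError("events counted with zero exposure")


def _span_days(days: Iterable[date]) -> int:
    days = list(days)
    return (max(days) - min(days)).days + 1


def _eligible_single(extracted_ads, require_chat: bool, require_single_name: bool = False):
    """Ads usable for churn measurement: one contact, face imagery, and (for
    name-change sequences) exactly one name."""
    out = []
    for ex in extracted_ads:
        if len(ex.contacts) != 1:
            continue
        if require_single_name and len(ex.names) != 1:
            continue
        if not ex.ad.image_tokens:
            continue
        if require_chat and not ex.ad.chat_id:
            continue
        out.append(ex)
    return out


def collect_contact_churn_sample(
    extracted_ads,
    period_days: int,
    r_chatid: float = 0.0,
) -> ChurnSample:
    """Contact-change sample from chat-id-tracked advertisers.

    Ads with a single contact, a single name and face imagery are grouped
    into tracked entities by linking contacts and chat ids (an entity is a
    connected component of the contact/chat-id co-occurrence graph).  Within
    an entity every additional contact is one change event.  The at-risk
    exposure credited to an observed contact with span D is
    (P/D - 1) / (1 + (P/D - 1) * (r + r_chatid)), because an entity changing
    identity at total rate r + r_chatid per unobserved slot is observed as
    1 + (P/D - 1)(r + r_chatid) contacts on average; the rate r solving
    events = r * exposure(r) is found numerically and the sample stores the
    implied exposure so that rate = events / exposure_days.
    """
    eligible = _eligible_single(extracted_ads, require_chat=True)
    # entities must be trackable through a single contact at a time: any
    # contact that ever co-appears with another contact belongs to a
    # multi-contact advertiser whose per-contact spans are fragmentary
    co_contacts = set()
    for ex in extracted_ads:
        if len(ex.contacts) > 1 and ex.ad.chat_id:
            co_contacts |= set(ex.contacts)
    # union contacts <-> chat ids
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    contact_days = defaultdict(list)
    for ex in eligible:
        contact = next(iter(ex.contacts))
        union(("c", contact), ("chat", ex.ad.chat_id))
        contact_days[contact].append(ex.ad.day)

    components = defaultdict(set)
    for key in list(parent):
        if key[0] == "c":
            components[find(key)].add(key[1])

    events = 0
    spans = []
    for members in components.values():
        if members & co_contacts:
            continue
        events += len(members) - 1
        spans.extend(_span_days(contact_days[c]) for c in members)

    if not spans:
        return ChurnSample(events=0, exposure_days=0.0, n_units=0)

    slot_terms = [period_days / d - 1.0 for d in spans]

    def implied_exposure(r: float) -> float:
        return sum(s / (1.0 + s * (r + r_chatid)) for s in slot_terms)

    if events == 0:
        exposure = implied_exposure(0.0)
        return ChurnSample(events=0, exposure_days=exposure, n_units=len(components))

    def f(r):
        return events - r * implied_exposure(r)

    hi = 10.0
    while f(hi) > 0 and hi < 1e6:
        hi *= 10
    r_hat = brentq(f, 0.0, hi, xtol=1e-12)
    exposure = implied_exposure(r_hat)
    # delta method: N = r * E(r) with E' < 0, so dr/dN = 1/(E + r E') and the
    # sampling error exceeds the naive Poisson error by E/(E + r E')
    e_prime = -sum(
        s * s / (1.0 + s * (r_hat + r_chatid)) ** 2 for s in slot_terms
    )
    denom = exposure + r_hat * e_prime
    n_eff = events * (denom / exposure) ** 2 if denom > 0 else 1.0
    return ChurnSample(
        events=events,
        exposure_days=exposure,
        n_units=len(components),
        effective_events=max(n_eff, 1.0),
    )


def collect_chatid_churn_sample(
    extracted_ads,
    period_days: int = 0,
) -> ChurnSample:
    """Chat-id change sample: single contacts on chat-id sites.

    For each contact the extra chat ids it accumulated over its ad sequence
    are change events; exposure is the contact's inclusive observed span in
    days, so the rate is new chat ids per observed day."""
    eligible = _eligible_single(extracted_ads, require_chat=True)
    co_contacts = set()
    for ex in extracted_ads:
        if len(ex.contacts) > 1 and ex.ad.chat_id:
            co_contacts |= set(ex.contacts)
    chat_ids = defaultdict(set)
    days = defaultdict(list)
    for ex in eligible:
        contact = next(iter(ex.contacts))
        if contact in co_contacts:
            continue
        chat_ids[contact].add(ex.ad.chat_id)
        days[contact].append(ex.ad.day)
    events = 0
    exposure = 0.0
    for contact, ids in chat_ids.items():
        events += len(ids) - 1
        exposure += _span_days(days[contact])
    return ChurnSample(events=events, exposure_days=exposure, n_units=len(chat_ids))


def collect_name_churn_sample(extracted_ads) -> ChurnSample:
    """Name-change sample: single-contact, single-name, image-bearing ads.

    A change is the same contact reappearing with shared imagery under a
    different canonical name; observations are advertiser-name pairs."""
    eligible = _eligible_single(extracted_ads, require_chat=False, require_single_name=True)
    names = defaultdict(set)
    tokens = defaultdict(set)
    for ex in eligible:
        contact = next(iter(ex.contacts))
        if tokens[contact] and not (tokens[contact] & ex.ad.image_tokens):
            continue  # no shared imagery: identity not established
        tokens[contact] |= ex.ad.image_tokens
        names[contact].add(next(iter(ex.names)))
    pairs = sum(len(v) for v in names.values())
    changes = sum(len(v) - 1 for v in names.values())
    return ChurnSample(
        events=changes,
        exposure_days=float(pairs),
        n_units=len(names),
        pairs=pairs,
    )


def estimate_contact_change_rate(sample: ChurnSample, z: float = DEFAULT_Z) -> ParamEstimate:
    """Contact-change rate per at-risk day: events / exposure, with a Poisson
    (root-sum-of-squares-compatible) interval using the event count as N."""
    if sample.exposure_days <= 0:
        return ParamEstimate(0.0, 1, 0.0, 0.0)
    r = sample.events / sample.exposure_days
    n = sample.effective_events if sample.effective_events is not None else sample.events
    n = max(int(round(n)), 1)
    half = z * r / math.sqrt(n)
    return ParamEstimate(r, n, max(0.0, r - half), r + half)


def estimate_chatid_rate(sample: ChurnSample, z: float = DEFAULT_Z) -> ParamEstimate:
    """Chat-id change rate per at-risk day."""
    return estimate_contact_change_rate(sample, z)


def estimate_name_unchanged(sample: ChurnSample, z: float = DEFAULT_Z) -> ParamEstimate:
    """P(n unique) = 1 - changed names / name observations."""
    pairs = sample.pairs or int(sample.exposure_days)
    if pairs < 1:
        return ParamEstimate(1.0, 1, 1.0, 1.0)
    p = 1.0 - sample.events / pairs
    lo, hi = confidence_interval_p(p, pairs, z)
    return ParamEstimate(p, pairs, lo, hi)


def measure_error_params(
    extracted_ads,
    relevance_labels: Sequence[bool],
    name_validity_labels: Sequence[bool],
    period_days: int,
    z: float = DEFAULT_Z,
) -> ErrorParams:
    """Measure every scaling parameter from a corpus plus labelled samples."""
    chat_sample = collect_chatid_churn_sample(extracted_ads, period_days)
    r_chat = estimate_chatid_rate(chat_sample, z)
    contact_sample = collect_contact_churn_sample(
        extracted_ads, period_days, r_chatid=r_chat.value
    )
    r_contact = estimate_contact_change_rate(contact_sample, z)
    name_sample = collect_name_churn_sample(extracted_ads)
    return ErrorParams(
        p_relevant=estimate_relevance(relevance_labels, z),
        p_name_valid=estimate_proportion(name_validity_labels, z),
        p_name_unique=estimate_name_unchanged(name_sample, z),
        r_idchange_perday=r_contact,
        r_chatid_perday=r_chat,
        z=z,
    )


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------


def _r_total_bounds(params: ErrorParams) -> tuple:
    return rate_ci_rss(
        params.r_idchange_perday.value,
        params.r_idchange_perday.n,
        params.r_chatid_perday.value,
        params.r_chatid_perday.n,
        params.z,
    )


def _sum_p_unique(advertisers, period_days, r, weights=None) -> float:
    total = 0.0
    for i, a in enumerate(advertisers):
        w = 1.0 if weights is None else weights[i]
        total += w * p_unique(min(a.days_active, period_days), period_days, r)
    return total


def scaled_advertisers(
    advertisers: Sequence[Advertiser],
    period_days: int,
    params: ErrorParams,
) -> tuple:
    """Corrected advertiser count with CI: point and bound reruns."""
    r = params.r_total
    r_lo, r_hi = _r_total_bounds(params)
    point = params.p_relevant.value * _sum_p_unique(advertisers, period_days, r)
    lower = params.p_relevant.lower * _sum_p_unique(advertisers, period_days, r_hi)
    upper = params.p_relevant.upper * _sum_p_unique(advertisers, period_days, r_lo)
    return point, (lower, upper)


def interpolate_names(
    advertisers: Sequence[Advertiser],
    default_individual: int = 1,
    default_collective: int = 2,
) -> dict:
    """Name count per advertiser with medians imputed for nameless ones.

    Advertisers with at least one observed name keep their distinct-name
    count; nameless advertisers receive the window's median distinct-name
    count for their social context (falling back to the defaults when the
    window has no named advertiser of that context)."""
    observed = {Context.INDIVIDUAL: [], Context.COLLECTIVE: []}
    for a in advertisers:
        if a.distinct_names > 0:
            observed[a.context].append(a.distinct_names)
    medians = {}
    for ctx, default in (
        (Context.INDIVIDUAL, default_individual),
        (Context.COLLECTIVE, default_collective),
    ):
        values = sorted(observed[ctx])
        if values:
            k = len(values)
            mid = (values[(k - 1) // 2] + values[k // 2]) / 2
            medians[ctx] = mid
        else:
            medians[ctx] = float(default)
    return {
        id(a): (a.distinct_names if a.distinct_names > 0 else medians[a.context])
        for a in advertisers
    }


def scaled_workers(
    advertisers: Sequence[Advertiser],
    period_days: int,
    params: ErrorParams,
    name_counts: Optional[dict] = None,
) -> dict:
    """Corrected worker count with CI, stratified by advertiser gender.

    Returns ``{"total": (point, (lo, hi)), Gender.X: (point, (lo, hi)), ...}``;
    gender strata sum exactly to the total."""
    if name_counts is None:
        name_counts = interpolate_names(advertisers)
    r = params.r_total
    r_lo, r_hi = _r_total_bounds(params)

    def scale_factor(which: str) -> float:
        ps = (params.p_name_valid, params.p_name_unique, params.p_relevant)
        if which == "point":
            return math.prod(p.value for p in ps)
        if which == "lower":
            return math.prod(p.lower for p in ps)
        return math.prod(p.upper for p in ps)

    sums = {"point": defaultdict(float), "lower": defaultdict(float), "upper": defaultdict(float)}
    for a in advertisers:
        w = name_counts[id(a)]
        days = min(a.days_active, period_days)
        sums["point"][a.category] += w * p_unique(days, period_days, r)
        sums["lower"][a.category] += w * p_unique(days, period_days, r_hi)
        sums["upper"][a.category] += w * p_unique(days, period_days, r_lo)

    out = {}
    total = [0.0, 0.0, 0.0]
    for g in Gender:
        point = scale_factor("point") * sums["point"].get(g, 0.0)
        lo = scale_factor("lower") * sums["lower"].get(g, 0.0)
        hi = scale_factor("upper") * sums["upper"].get(g, 0.0)
        out[g] = (point, (lo, hi))
        total[0] += point
        total[1] += lo
        total[2] += hi
    out["total"] = (total[0], (total[1], total[2]))
    return out


# ---------------------------------------------------------------------------
# Side estimators
# ---------------------------------------------------------------------------


def image_based_advertisers(stats: ImageStats, p_relevant: float) -> int:
    """Advertiser count implied by image reuse:
    Unique / (Av per advertiser * R reused) * P(a relevant), as an integer."""
    est = stats.unique_images / (stats.avg_images_per_advertiser * stats.reuse_factor)
    return int(round(est * p_relevant))


def missed_advertisers(
    n_ads_without_contacts: int,
    mean_ads_per_advertiser: float,
    p_relevant: float,
) -> int:
    """Unscaled advertisers likely missed among contact-less ads."""
    if n_ads_without_contacts < 0 or mean_ads_per_advertiser <= 0:
        raise ValueError("inputs must be positive")
    return int(round(n_ads_without_contacts / mean_ads_per_advertiser * p_relevant))


def chatid_adjusted_advertisers(
    raw_count: int,
    mean_chat_ids: float,
    p_relevant: float,
) -> float:
    """Advertiser count from raw chat-id counts, deflated by the mean number
    of chat ids per advertiser and the relevance proportion; one decimal."""
    if raw_count < 0 or mean_chat_ids <= 0:
        raise ValueError("inputs must be positive")
    return round(raw_count / mean_chat_ids * p_relevant, 1)


def compute_image_stats(extracted_ads, advertiser_of: Optional[dict] = None) -> ImageStats:
    """Image-token statistics over a corpus.

    ``advertiser_of`` maps ad_id -> advertiser key; without it each contact
    set is its own advertiser key."""
    token_users = defaultdict(set)
    per_adv = defaultdict(set)
    for ex in extracted_ads:
        if advertiser_of is not None:
            key = advertiser_of.get(ex.ad.ad_id)
        else:
            key = ex.contacts or None
        if key is None:
            continue
        for tok in ex.ad.image_tokens:
            token_users[tok].add(key)
            per_adv[key].add(tok)
    if not token_users:
        raise ValueError("no image tokens in corpus")
    reuse = sum(len(v) for v in token_users.values()) / len(token_users)
    avg = sum(len(v) for v in per_adv.values()) / len(per_adv)
    return ImageStats(
        unique_images=len(token_users),
        avg_images_per_advertiser=avg,
        reuse_factor=reuse,
    )
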