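"""Group co-occurring contacts into advertisers for an analysis window.

Two contacts are related when they appear together in at least one ad inside
the window; advertisers are the connected components of that co-occurrence
graph.  A density-based clustering with a minimum neighbourhood of one over
co-occurrence adjacency yields exactly these components, so they are computed
directly with a union-find for determinism.  Components of two or more
contacts receive a content-addressed virtual contact identifier, stable
across reruns.  Any contact is stand-alone or in exactly one cluster for a
given window.
"""

from __future__ import annotations

import hashlib
from collections import Counter, defaultdict
from datetime import date
from typing import Iterable, Optional

import numpy as np

from .corpus_model import Advertiser, Contact, ContactKind, Context, Gender
from .extraction import detect_collective


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def add(self, x):
        if x not in self.parent:
            self.parent[x] = x

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_clusters(ad_contact_sets: Iterable[frozenset], window_key: str = "") -> dict:
    """Partition window contacts into advertisers.

    Parameters
    ----------
    ad_contact_sets
        One frozenset of `Contact` per ad in the window.
    window_key
        Disambiguates virtual ids between windows (clusters are only
        meaningful for a specific time period).

    Returns a mapping ``Contact -> advertiser id Contact``: the contact itself
    for singletons, a shared ``cluster_virtual`` contact for components of
    two or more.
    """
    uf = _UnionFind()
    for contacts in ad_contact_sets:
        contacts = sorted(contacts)
        for c in contacts:
            uf.add(c)
        for other in contacts[1:]:
            uf.union(contacts[0], other)

    components = defaultdict(list)
    for c in uf.parent:
        components[uf.find(c)].append(c)

    assignment = {}
    for members in components.values():
        if len(members) == 1:
            assignment[members[0]] = members[0]
        else:
            digest = hashlib.sha1(
                ("|".join(sorted(f"{m.kind.value}:{m.value}" for m in members))
                 + "@" + window_key).encode()
            ).hexdigest()[:12]
            virtual = Contact(ContactKind.CLUSTER_VIRTUAL, f"cluster_{digest}")
            for m in members:
                assignment[m] = virtual
    return assignment


def cluster_size_stats(assignment: dict) -> dict:
    """Descriptive statistics of contacts per cluster (parts of size >= 2
    only; singletons are not clusters).  Empty sentinel when no clusters."""
    sizes = Counter()
    for contact, owner in assignment.items():
        if owner.kind is ContactKind.CLUSTER_VIRTUAL:
            sizes[owner] += 1
    values = np.array(sorted(sizes.values()), dtype=float)
    if values.size == 0:
        return {"n_clusters": 0, "median": None, "iqr": (None, None),
                "mean": None, "sd": None}
    q1, q3 = np.percentile(values, [25, 75])
    return {
        "n_clusters": int(values.size),
        "median": float(np.median(values)),
        "iqr": (float(q1), float(q3)),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
    }


def resolve_advertisers(
    extracted_ads,
    window_start: Optional[date] = None,
    window_end: Optional[date] = None,
) -> list:
    """Assemble `Advertiser` entities for a window from extracted ads.

    Ads outside the half-open ``[window_start, window_end)`` date window or
    without contacts are ignored.  An advertiser's activity span is the
    inclusive range of its ad dates within the window; its gender is the modal
    ad category (ties -> other); its context is collective if it shows more
    than one distinct name or any of its ads uses a group keyword.
    """
    in_window = []
    for ex in extracted_ads:
        d = ex.ad.day
        if window_start is not None and d < window_start:
            continue
        if window_end is not None and d >= window_end:
            continue
        if ex.contacts:
            in_window.append(ex)

    key = f"{window_start}..{window_end}"
    assignment = build_clusters([ex.contacts for ex in in_window], window_key=key)

    by_owner = defaultdict(list)
    for ex in in_window:
        owners = {assignment[c] for c in ex.contacts}
        for owner in owners:
            by_owner[owner].append(ex)

    advertisers = []
    for owner, ads in by_owner.items():
        days = [ex.ad.day for ex in ads]
        names = Counter()
        cats = Counter()
        texts = []
        members = set()
        for ex in ads:
            names.update(ex.names)
            cats[ex.ad.category] += 1
            texts.append(ex.ad.text)
            members |= set(ex.contacts)
        top = cats.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            category = Gender.OTHER
        else:
            category = top[0][0]
        context = Context.INDIVIDUAL
        if len(names) > 1:
            context = Context.COLLECTIVE
        else:
            for t in texts:
                if detect_collective(t, len(names)) is Context.COLLECTIVE:
                    context = Context.COLLECTIVE
                    break
        advertisers.append(
            Advertiser(
                id=owner,
                ad_ids={ex.ad.ad_id for ex in ads},
                names=names,
                first_seen=min(days),
                last_seen=max(days),
                context=context,
                category=category,
                member_contacts=frozenset(
                    members if owner.kind is ContactKind.CLUSTER_VIRTUAL else {owner}
                ),
            )
        )
    advertisers.sort(key=lambda a: (a.first_seen, a.id.value))
    return advertisers
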