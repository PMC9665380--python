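"""Core data types and corpus interchange I/O.

The corpus interchange format is line-delimited: one ad record per line,
either JSON-lines (``*.jsonl``) or an equivalent CSV dialect (``*.csv``).
All timestamps are ISO-8601 UTC; windows throughout the package are
half-open ``[start, end)`` intervals of UTC dates.
"""

from __future__ import annotations

import csv
import enum
import io
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from typing import Iterable, Optional, Sequence

logger = logging.getLogger("adpop")

SCHEMA_VERSION = "1"

#: z quantile for two-sided 95% confidence intervals.
DEFAULT_Z = 1.959964


class Gender(str, enum.Enum):
    """Gender category of an ad, taken from the ad's placement category."""

    CIS_FEMALE = "cis_female"
    CIS_MALE = "cis_male"
    TRANSGENDER = "transgender"
    OTHER = "other"


class ContactKind(str, enum.Enum):
    PHONE = "phone"
    EMAIL = "email"
    CLUSTER_VIRTUAL = "cluster_virtual"


class Context(str, enum.Enum):
    INDIVIDUAL = "individual"
    COLLECTIVE = "collective"


@dataclass(frozen=True, order=True)
class Contact:
    """A canonicalised contact: phone ("NNN NNN NNNN"), lowercase email, or a
    virtual cluster identifier that never occurs in raw ad text."""

    kind: ContactKind
    value: str


class CorpusError(ValueError):
    """Unrecoverable corpus-level problem (e.g. duplicate ad id)."""


@dataclass
class AdRecord:
    """One observed ad page."""

    ad_id: str
    site: str
    timestamp: datetime
    category: Gender
    text: str
    image_tokens: frozenset = frozenset()
    chat_id: Optional[str] = None

    def __post_init__(self):
        if not self.ad_id:
            raise CorpusError("ad_id must be non-empty")
        if not isinstance(self.timestamp, datetime):
            raise CorpusError(f"ad {self.ad_id}: timestamp must be a datetime")
        if self.timestamp.tzinfo is None:
            self.timestamp = self.timestamp.replace(tzinfo=timezone.utc)
        if not isinstance(self.category, Gender):
            self.category = Gender(self.category) if self.category in set(
                g.value for g in Gender
            ) else Gender.OTHER
        self.image_tokens = frozenset(self.image_tokens)

    @property
    def day(self) -> date:
        return self.timestamp.date()


@dataclass
class Advertiser:
    """A resolved advertising entity: a single contact, or a cluster of
    co-occurring contacts, with everything observed under it in a window."""

    id: Contact
    ad_ids: set
    names: Counter
    first_seen: date
    last_seen: date
    context: Context
    category: Gender
    member_contacts: frozenset = frozenset()

    def __post_init__(self):
        if not self.ad_ids:
            raise CorpusError("advertiser must own at least one ad")
        if self.last_seen < self.first_seen:
            raise CorpusError("last_seen precedes first_seen")

    @property
    def days_active(self) -> int:
        """Inclusive span in days between first and last observed ad."""
        return (self.last_seen - self.first_seen).days + 1

    @property
    def distinct_names(self) -> int:
        return len(self.names)


@dataclass
class ParamEstimate:
    """A measured probability or rate together with the sample size that
    determined it and its 95% interval."""

    value: float
    n: int
    lower: float
    upper: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("sample size must be >= 1")


@dataclass
class ErrorParams:
    """Measured error and churn parameters feeding the scaling formulas."""

    p_relevant: ParamEstimate
    p_name_valid: ParamEstimate
    p_name_unique: ParamEstimate
    r_idchange_perday: ParamEstimate
    r_chatid_perday: ParamEstimate
    z: float = DEFAULT_Z

    def __post_init__(self):
        for name in ("p_relevant", "p_name_valid", "p_name_unique"):
            p = getattr(self, name).value
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("r_idchange_perday", "r_chatid_perday"):
            r = getattr(self, name).value
            if r < 0:
                raise ValueError(f"{name} must be >= 0, got {r}")

    @property
    def r_total(self) -> float:
        """Combined per-day identity-change rate (contact + chat id)."""
        return self.r_idchange_perday.value + self.r_chatid_perday.value

    def to_dict(self) -> dict:
        def pe(e):
            return {"value": e.value, "n": e.n, "lower": e.lower, "upper": e.upper}

        return {
            "p_relevant": pe(self.p_relevant),
            "p_name_valid": pe(self.p_name_valid),
            "p_name_unique": pe(self.p_name_unique),
            "r_idchange_perday": pe(self.r_idchange_perday),
            "r_chatid_perday": pe(self.r_chatid_perday),
            "z": self.z,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorParams":
        def pe(x):
            return ParamEstimate(x["value"], x["n"], x["lower"], x["upper"])

        return cls(
            p_relevant=pe(d["p_relevant"]),
            p_name_valid=pe(d["p_name_valid"]),
            p_name_unique=pe(d["p_name_unique"]),
            r_idchange_perday=pe(d["r_idchange_perday"]),
            r_chatid_perday=pe(d["r_chatid_perday"]),
            z=d.get("z", DEFAULT_Z),
        )


@dataclass
class ImageStats:
    """Corpus-level image-token statistics for the image-reuse estimator."""

    unique_images: int
    avg_images_per_advertiser: float
    reuse_factor: float

    def __post_init__(self):
        if min(self.unique_images, self.avg_images_per_advertiser, self.reuse_factor) <= 0:
            raise ValueError("image statistics must be strictly positive")


@dataclass
class WindowEstimate:
    """Raw, interpolated and scaled counts for one analysis window."""

    window_start: date
    window_end: date  # exclusive
    period_days: int
    raw_advertisers: int
    raw_names: int
    interpolated_names: float
    scaled_advertisers: float
    scaled_advertisers_ci: tuple
    scaled_workers: float
    scaled_workers_ci: tuple
    names_by_gender: dict = field(default_factory=dict)
    interpolated_by_gender: dict = field(default_factory=dict)
    scaled_workers_by_gender: dict = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = self.scaled_workers_ci
        if not (lo <= self.scaled_workers + 1e-9 and self.scaled_workers <= hi + 1e-9):
            raise ValueError("worker CI does not bracket the point estimate")
        lo, hi = self.scaled_advertisers_ci
        if not (lo <= self.scaled_advertisers + 1e-9 and self.scaled_advertisers <= hi + 1e-9):
            raise ValueError("advertiser CI does not bracket the point estimate")


# ---------------------------------------------------------------------------
# Ground truth emitted by the synthetic generator
# ---------------------------------------------------------------------------


@dataclass
class TruePerson:
    """Generator-side record of one advertising entity (one or more workers)."""

    person_id: int
    relevant: bool
    gender: Gender
    context: Context
    names: tuple  # canonical true worker names
    site: str
    duration_days: int
    fragments: list  # list of (contact_values: tuple, start: date, end: date)
    contact_change_events: int = 0
    chatid_reset_events: int = 0
    chatid_extra_events: int = 0
    name_change_events: int = 0
    names_visible: bool = True
    extra_valid_names: tuple = ()  # names adopted through mid-stream changes

    @property
    def n_workers(self) -> int:
        return len(self.names)


@dataclass
class GroundTruth:
    """Everything the generator knows, for recovery tests."""

    persons: list
    ad_to_person: dict  # ad_id -> person_id, contact-bearing ads only
    config: object
    period_start: date
    period_end: date  # exclusive

    def _active(self, person: TruePerson, start: date, end: date) -> bool:
        return any(f_start < end and f_end >= start for _, f_start, f_end in person.fragments)

    def true_worker_count(self, start: Optional[date] = None, end: Optional[date] = None) -> int:
        """Workers of relevant entities with >=1 contact-bearing ad in window."""
        start = start or self.period_start
        end = end or self.period_end
        return sum(
            p.n_workers for p in self.persons if p.relevant and self._active(p, start, end)
        )

    def true_advertiser_count(self, start: Optional[date] = None, end: Optional[date] = None) -> int:
        start = start or self.period_start
        end = end or self.period_end
        return sum(1 for p in self.persons if p.relevant and self._active(p, start, end))

    def to_dict(self) -> dict:
        return {
            "period_start": self.period_start.isoformat(),
            "period_end": self.period_end.isoformat(),
            "persons": [
                {
                    "person_id": p.person_id,
                    "relevant": p.relevant,
                    "gender": p.gender.value,
                    "context": p.context.value,
                    "names": list(p.names),
                    "site": p.site,
                    "duration_days": p.duration_days,
                    "fragments": [
                        [list(c), s.isoformat(), e.isoformat()] for c, s, e in p.fragments
                    ],
                    "contact_change_events": p.contact_change_events,
                    "chatid_reset_events": p.chatid_reset_events,
                    "chatid_extra_events": p.chatid_extra_events,
                    "name_change_events": p.name_change_events,
                    "names_visible": p.names_visible,
                    "extra_valid_names": list(p.extra_valid_names),
                }
                for p in self.persons
            ],
            "ad_to_person": self.ad_to_person,
        }


# ---------------------------------------------------------------------------
# Interchange I/O
# ---------------------------------------------------------------------------

_FIELDS = ("ad_id", "site", "timestamp", "category", "text", "image_tokens", "chat_id")


def _record_to_row(rec: AdRecord) -> dict:
    return {
        "ad_id": rec.ad_id,
        "site": rec.site,
        "timestamp": rec.timestamp.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ"),
        "category": rec.category.value,
        "text": rec.text,
        "image_tokens": sorted(rec.image_tokens),
        "chat_id": rec.chat_id,
    }


def _row_to_record(row: dict) -> AdRecord:
    ts = row["timestamp"]
    if isinstance(ts, str):
        ts = datetime.strptime(ts, "%Y-%m-%dT%H:%M:%SZ").replace(tzinfo=timezone.utc)
    toks = row.get("image_tokens") or []
    if isinstance(toks, str):
        toks = [t for t in toks.split("|") if t]
    cat = row.get("category") or "other"
    if cat not in set(g.value for g in Gender):
        cat = "other"
    return AdRecord(
        ad_id=row["ad_id"],
        site=row["site"],
        timestamp=ts,
        category=Gender(cat),
        text=row.get("text", ""),
        image_tokens=frozenset(toks),
        chat_id=row.get("chat_id") or None,
    )


def read_corpus(
    path,
    schema_version: str = SCHEMA_VERSION,
    rejects: Optional[list] = None,
) -> list:
    """Read an ad corpus from a JSON-lines or CSV file.

    Records failing validation (e.g. unparseable timestamps) are rejected and
    logged, and appended to ``rejects`` when a list is supplied; a duplicate
    ``ad_id`` is a hard error. Record order is preserved.
    """
    if schema_version != SCHEMA_VERSION:
        raise CorpusError(f"unsupported schema version {schema_version!r}")
    path = str(path)
    records = []
    seen = set()

    def handle(lineno, row):
        try:
            rec = _row_to_record(row)
        except (KeyError, ValueError, CorpusError) as exc:
            logger.warning("rejected record at line %d: %s", lineno, exc)
            if rejects is not None:
                rejects.append((lineno, str(exc)))
            return
        if rec.ad_id in seen:
            raise CorpusError(f"duplicate ad_id {rec.ad_id!r} at line {lineno}")
        seen.add(rec.ad_id)
        records.append(rec)

    with open(path, "r", encoding="utf-8", newline="") as fh:
        if path.endswith(".csv"):
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                handle(lineno, row)
        else:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    logger.warning("rejected line %d: %s", lineno, exc)
                    if rejects is not None:
                        rejects.append((lineno, str(exc)))
                    continue
                handle(lineno, row)
    return records


def write_corpus(records: Sequence[AdRecord], path) -> None:
    """Write records in the canonical interchange encoding (deterministic
    field order; UTF-8; sorted image tokens). Re-readable by `read_corpus`."""
    path = str(path)
    if path.endswith(".csv"):
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_FIELDS)
            writer.writeheader()
            for rec in records:
                row = _record_to_row(rec)
                row["image_tokens"] = "|".join(row["image_tokens"])
                row["chat_id"] = row["chat_id"] or ""
                writer.writerow(row)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(_record_to_row(rec), ensure_ascii=False, sort_keys=True))
                fh.write("\n")


def corpus_date_range(records: Iterable[AdRecord]):
    """(first day, day after last day) over a corpus; None for an empty one."""
    days = [r.day for r in records]
    if not days:
        return None
    from datetime import timedelta

    return min(days), max(days) + timedelta(days=1)
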