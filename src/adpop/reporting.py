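"""Windowed population series, descriptive statistics, trends and the
end-to-end pipeline.

Estimates are produced for the whole study period and for blocked weekly
(consecutive 7-day blocks from the corpus start) and calendar-month windows;
clustering, name interpolation and scaling are recomputed inside each
window.  Trends are ordinary least-squares fits of monthly counts against
the month index.  Per-capita figures express an estimate against a census
reference population per 100,000, as a percentage, or as one person in N.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

from .clustering import cluster_size_stats, build_clusters, resolve_advertisers
from .corpus_model import (
    DEFAULT_Z,
    ContactKind,
    ErrorParams,
    Gender,
    WindowEstimate,
    corpus_date_range,
    read_corpus,
)
from .estimation import (
    confidence_interval_p,
    interpolate_names,
    measure_error_params,
    scaled_advertisers,
    scaled_workers,
)
from .extraction import build_name_lexicon, extract_contacts, extract_names, load_seed_names

logger = logging.getLogger("adpop")


# ---------------------------------------------------------------------------
# Window grids
# ---------------------------------------------------------------------------


def weekly_windows(start: date, end: date) -> list:
    """Consecutive 7-day blocks from the corpus start; half-open."""
    out = []
    s = start
    while s < end:
        e = min(s + timedelta(days=7), end)
        out.append((s, e))
        s = e
    return out


def monthly_windows(start: date, end: date) -> list:
    """Calendar months intersected with [start, end); half-open."""
    out = []
    s = start
    while s < end:
        if s.month == 12:
            nxt = date(s.year + 1, 1, 1)
        else:
            nxt = date(s.year, s.month + 1, 1)
        e = min(nxt, end)
        out.append((s, e))
        s = e
    return out


def windows_for(granularity: str, start: date, end: date) -> list:
    if granularity == "weekly":
        return weekly_windows(start, end)
    if granularity == "monthly":
        return monthly_windows(start, end)
    if granularity == "whole":
        return [(start, end)]
    raise ValueError(f"unknown granularity {granularity!r}")


# ---------------------------------------------------------------------------
# Window estimates
# ---------------------------------------------------------------------------


def estimate_window(extracted_ads, start: date, end: date, params: ErrorParams) -> WindowEstimate:
    advertisers = resolve_advertisers(extracted_ads, start, end)
    period_days = (end - start).days
    raw_names = {g: 0 for g in Gender}
    for a in advertisers:
        raw_names[a.category] += a.distinct_names
    name_counts = interpolate_names(advertisers)
    interp = {g: 0.0 for g in Gender}
    for a in advertisers:
        interp[a.category] += name_counts[id(a)]
    adv_point, adv_ci = scaled_advertisers(advertisers, period_days, params)
    workers = scaled_workers(advertisers, period_days, params, name_counts)
    return WindowEstimate(
        window_start=start,
        window_end=end,
        period_days=period_days,
        raw_advertisers=len(advertisers),
        raw_names=sum(raw_names.values()),
        interpolated_names=sum(interp.values()),
        scaled_advertisers=adv_point,
        scaled_advertisers_ci=adv_ci,
        scaled_workers=workers["total"][0],
        scaled_workers_ci=workers["total"][1],
        names_by_gender={g.value: raw_names[g] for g in Gender},
        interpolated_by_gender={g.value: interp[g] for g in Gender},
        scaled_workers_by_gender={g.value: workers[g][0] for g in Gender},
    )


def window_series(
    extracted_ads,
    params: ErrorParams,
    granularity: str,
    period_start: date,
    period_end: date,
) -> list:
    """One WindowEstimate per window of the requested granularity."""
    return [
        estimate_window(extracted_ads, s, e, params)
        for s, e in windows_for(granularity, period_start, period_end)
    ]


def descriptive_stats(values: Sequence[float]) -> dict:
    """Mean, SD, median and IQR of a series (SD with n-1 denominator)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return {"n": 0, "mean": None, "sd": None, "median": None, "iqr": (None, None)}
    q1, q3 = np.percentile(arr, [25, 75])
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "median": float(np.median(arr)),
        "iqr": (float(q1), float(q3)),
    }


def days_online_stats(advertisers) -> dict:
    """Descriptive statistics of advertisers' inclusive activity spans."""
    return descriptive_stats([a.days_active for a in advertisers])


# ---------------------------------------------------------------------------
# Comparisons
# ---------------------------------------------------------------------------


def per_capita(estimate: float, reference_population: float, mode: str):
    """Express an estimate against a reference population."""
    if estimate <= 0 or reference_population <= 0:
        raise ValueError("inputs must be positive")
    if mode == "per_100k":
        return int(round(estimate / reference_population * 1e5))
    if mode == "one_in_n":
        return int(round(reference_population / estimate))
    if mode == "percent":
        return round(estimate / reference_population * 100.0, 1)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class TrendFit:
    """OLS slope of a monthly series against month index 0..K."""

    beta: float
    stderr: float
    pvalue: float
    intercept: float

    def __post_init__(self):
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p-value out of range")


def trend_fit(monthly_values: Sequence[float]) -> TrendFit:
    y = np.asarray(list(monthly_values), dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 monthly values")
    x = sm.add_constant(np.arange(y.size, dtype=float))
    fit = sm.OLS(y, x).fit()
    pvalue = float(fit.pvalues[1])
    if math.isnan(pvalue):  # perfectly constant series: no evidence of trend
        pvalue = 1.0
    return TrendFit(
        beta=float(fit.params[1]),
        stderr=float(fit.bse[1]),
        pvalue=pvalue,
        intercept=float(fit.params[0]),
    )


def proportion_compare(
    x1: int,
    n1: int,
    x2: Optional[int] = None,
    n2: Optional[int] = None,
    z: float = DEFAULT_Z,
    continuity: bool = False,
) -> dict:
    """Single-sample proportion with Wald CI, or a two-sample z comparison.

    Two-sample mode tests p1 == p2 with the pooled-proportion z statistic
    (continuity correction optional, off by default)."""
    if not 0 <= x1 <= n1:
        raise ValueError("need 0 <= x1 <= n1")
    p1 = x1 / n1
    out = {"proportion": p1, "ci": confidence_interval_p(p1, n1, z)}
    if x2 is not None:
        if n2 is None or not 0 <= x2 <= n2:
            raise ValueError("need 0 <= x2 <= n2")
        p2 = x2 / n2
        pooled = (x1 + x2) / (n1 + n2)
        se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        diff = abs(p1 - p2)
        if continuity:
            diff = max(0.0, diff - 0.5 * (1 / n1 + 1 / n2))
        zstat = diff / se if se > 0 else 0.0
        out.update(
            {
                "proportion2": p2,
                "z": zstat,
                "p_value": float(2 * norm.sf(zstat)),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def prepare_corpus(records, lexicon_threshold: float = 0.5, review_queue=None):
    """Extraction stage: contacts, the corpus name lexicon, and per-ad names."""
    extracted = extract_contacts(records, review_queue)
    lexicon = build_name_lexicon(
        [r.text for r in records], load_seed_names(), threshold=lexicon_threshold
    )
    for ex in extracted:
        ex.names = extract_names(ex.ad, lexicon)
    return extracted, lexicon


def run_pipeline(
    records=None,
    corpus_path=None,
    truth=None,
    params: Optional[ErrorParams] = None,
    out_dir=None,
    granularities: Sequence[str] = ("whole", "monthly", "weekly"),
    z: float = DEFAULT_Z,
    lexicon_threshold: float = 0.5,
) -> dict:
    """Execute extract -> cluster -> measure -> scale -> report.

    Error parameters are measured from the corpus; the relevance and
    name-validity labels come from the supplied ground truth (standing in for
    manual review) unless ready-made ``params`` are given.  Fully
    deterministic for a fixed corpus and configuration.
    """
    if records is None:
        if corpus_path is None:
            raise ValueError("need records or corpus_path")
        records = read_corpus(corpus_path)
    log_lines = []

    def log(msg):
        logger.info(msg)
        log_lines.append(msg)

    log(f"corpus: {len(records)} ads")
    review_queue: list = []
    extracted, lexicon = prepare_corpus(records, lexicon_threshold, review_queue)
    log(f"extraction: lexicon of {len(lexicon.accepted)} accepted names, "
        f"{len(review_queue)} review items")

    if truth is not None:
        period_start, period_end = truth.period_start, truth.period_end
    else:
        rng = corpus_date_range(records)
        if rng is None:
            period_start = period_end = None
        else:
            period_start, period_end = rng

    if period_start is None:
        return {
            "params": params,
            "series": {g: [] for g in granularities},
            "advertisers": [],
            "lexicon": lexicon,
            "review_queue": review_queue,
            "cluster_stats": cluster_size_stats({}),
            "trends": {},
            "log": log_lines,
        }

    period_days = (period_end - period_start).days
    advertisers = resolve_advertisers(extracted, period_start, period_end)
    log(f"clustering: {len(advertisers)} advertisers over {period_days} days")

    if params is None:
        if truth is None:
            raise ValueError("measuring parameters requires ground-truth labels; "
                             "otherwise pass params explicitly")
        from .synthetic_corpus import name_validity_labels, relevance_labels

        rel = relevance_labels(advertisers, truth)
        val = name_validity_labels(advertisers, truth)
        params = measure_error_params(extracted, rel, val, period_days, z)
        log(
            "measured params: "
            f"p_relevant={params.p_relevant.value:.4f} (n={params.p_relevant.n}), "
            f"p_name_valid={params.p_name_valid.value:.4f}, "
            f"p_name_unique={params.p_name_unique.value:.4f}, "
            f"r_idchange={params.r_idchange_perday.value:.5f}/day, "
            f"r_chatid={params.r_chatid_perday.value:.5f}/day"
        )

    series = {}
    for gran in granularities:
        series[gran] = window_series(extracted, params, gran, period_start, period_end)
        log(f"{gran}: {len(series[gran])} windows")

    assignment = build_clusters(
        [ex.contacts for ex in extracted if ex.contacts],
        window_key=f"{period_start}..{period_end}",
    )
    cstats = cluster_size_stats(assignment)

    trends = {}
    if "monthly" in series and len(series["monthly"]) >= 3:
        monthly = series["monthly"]
        trends = {
            "scaled_advertisers": trend_fit([w.scaled_advertisers for w in monthly]),
            "scaled_workers": trend_fit([w.scaled_workers for w in monthly]),
            "ad_volume": trend_fit(
                [len([1 for ex in extracted
                      if w.window_start <= ex.ad.day < w.window_end])
                 for w in monthly]
            ),
        }

    bundle = {
        "params": params,
        "series": series,
        "advertisers": advertisers,
        "lexicon": lexicon,
        "review_queue": review_queue,
        "cluster_stats": cstats,
        "trends": trends,
        "days_online": days_online_stats(advertisers),
        "log": log_lines,
    }
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle, out_dir) -> None:
    import os

    os.makedirs(out_dir, exist_ok=True)

    with open(os.path.join(out_dir, "params.json"), "w") as fh:
        json.dump(bundle["params"].to_dict(), fh, indent=2)

    with open(os.path.join(out_dir, "estimates.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        header = [
            "granularity", "window_start", "window_end", "period_days",
            "raw_advertisers", "scaled_advertisers", "scaled_advertisers_lo",
            "scaled_advertisers_hi", "raw_names", "interpolated_names",
            "scaled_workers", "scaled_workers_lo", "scaled_workers_hi",
        ] + [f"names_{g.value}" for g in Gender] + [f"workers_{g.value}" for g in Gender]
        writer.writerow(header)
        for gran, wins in bundle["series"].items():
            for w in wins:
                writer.writerow(
                    [
                        gran, w.window_start, w.window_end, w.period_days,
                        w.raw_advertisers, f"{w.scaled_advertisers:.1f}",
                        f"{w.scaled_advertisers_ci[0]:.1f}", f"{w.scaled_advertisers_ci[1]:.1f}",
                        w.raw_names, f"{w.interpolated_names:.1f}",
                        f"{w.scaled_workers:.1f}",
                        f"{w.scaled_workers_ci[0]:.1f}", f"{w.scaled_workers_ci[1]:.1f}",
                    ]
                    + [w.names_by_gender[g.value] for g in Gender]
                    + [f"{w.scaled_workers_by_gender[g.value]:.1f}" for g in Gender]
                )

    with open(os.path.join(out_dir, "clusters.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cluster_id", "size", "members", "ad_count"])
        for a in bundle["advertisers"]:
            if a.id.kind is ContactKind.CLUSTER_VIRTUAL:
                writer.writerow(
                    [a.id.value, len(a.member_contacts),
                     "|".join(sorted(c.value for c in a.member_contacts)),
                     len(a.ad_ids)]
                )

    with open(os.path.join(out_dir, "trend.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["variable", "beta", "stderr", "p_value"])
        for name, fit in bundle["trends"].items():
            writer.writerow([name, f"{fit.beta:.2f}", f"{fit.stderr:.2f}", f"{fit.pvalue:.3g}"])

    with open(os.path.join(out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(bundle["log"]) + "\n")
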