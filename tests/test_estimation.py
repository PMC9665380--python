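"""Scaling estimators, confidence intervals and churn measurement."""

import math
from collections import Counter
from datetime import date, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from adpop import (
    Advertiser,
    ChurnSample,
    Contact,
    ContactKind,
    Context,
    ErrorParams,
    Gender,
    ImageStats,
    ParamEstimate,
    chatid_adjusted_advertisers,
    confidence_interval_p,
    estimate_chatid_rate,
    estimate_contact_change_rate,
    estimate_name_unchanged,
    estimate_relevance,
    image_based_advertisers,
    interpolate_names,
    missed_advertisers,
    p_unique,
    rate_ci_rss,
    scaled_advertisers,
    scaled_workers,
)

Z = 1.959964


def pe(value, n, z=Z):
    half = z * math.sqrt(value * (1 - value) / n)
    return ParamEstimate(value, n, max(0.0, value - half), min(1.0, value + half))


def rate_pe(value, n, z=Z):
    half = z * value / math.sqrt(n)
    return ParamEstimate(value, n, max(0.0, value - half), value + half)


def make_params(p_rel=1.0, p_nv=1.0, p_nu=1.0, r_id=0.0, r_chat=0.0, n=1000):
    return ErrorParams(
        p_relevant=pe(p_rel, n),
        p_name_valid=pe(p_nv, n),
        p_name_unique=pe(p_nu, n),
        r_idchange_perday=rate_pe(r_id, n),
        r_chatid_perday=rate_pe(r_chat, n),
    )


def adv(days, names=("mia",), context=Context.INDIVIDUAL, gender=Gender.CIS_FEMALE, idx=0):
    first = date(2015, 1, 1)
    return Advertiser(
        id=Contact(ContactKind.PHONE, f"p{idx}"),
        ad_ids={f"a{idx}"},
        names=Counter(names),
        first_seen=first,
        last_seen=first + timedelta(days=days - 1),
        context=context,
        category=gender,
    )


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------


def test_wald_interval_relevance_sample():
    lo, hi = confidence_interval_p(0.764, 6955, Z)
    assert lo == pytest.approx(0.754, abs=5e-4)
    assert hi == pytest.approx(0.774, abs=5e-4)


def test_wald_interval_degenerate_and_halfwidth():
    assert confidence_interval_p(0.0, 50) == (0.0, 0.0)
    assert confidence_interval_p(1.0, 50) == (1.0, 1.0)
    lo, hi = confidence_interval_p(0.5, 100, 1.96)
    assert (hi - lo) / 2 == pytest.approx(0.098, abs=1e-4)


def test_rate_ci_rss():
    # degenerate second term
    lo, hi = rate_ci_rss(0.02, 100, 0.0, 1, z=2.0)
    assert (hi - lo) / 2 == pytest.approx(2.0 * 0.02 / 10, rel=1e-12)
    assert rate_ci_rss(0.0, 5, 0.0, 5) == (0.0, 0.0)
    # independently recomputed from the formula
    lo, hi = rate_ci_rss(0.0223, 8454, 0.0024, 4761, Z)
    assert (hi - lo) / 2 == pytest.approx(4.8022e-4, rel=1e-3)


# ---------------------------------------------------------------------------
# Uniqueness probability
# ---------------------------------------------------------------------------


def test_p_unique_values():
    assert p_unique(30, 30, 0.5) == 1.0
    assert p_unique(3, 30, 0.0) == 1.0
    assert p_unique(1, 30, 0.0223) == pytest.approx(1 / (1 + 29 * 0.0223), rel=1e-12)
    assert p_unique(1, 30, 0.0223) == pytest.approx(0.6073, abs=1e-4)


def test_p_unique_domain():
    with pytest.raises(ValueError):
        p_unique(0, 30, 0.1)
    with pytest.raises(ValueError):
        p_unique(31, 30, 0.1)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    st.integers(1, 364),
    st.integers(1, 365),
    st.floats(0.0, 1.0),
    st.floats(1e-4, 0.5),
)
def test_p_unique_monotonicity(days, period, r, dr):
    """Nondecreasing in days active; nonincreasing in rate and period."""
    days = min(days, period)
    base = p_unique(days, period, r)
    assert 0.0 < base <= 1.0
    if days + 1 <= period:
        assert p_unique(days + 1, period, r) >= base
    assert p_unique(days, period + 1, r) <= base
    assert p_unique(days, period, r + dr) <= base


# ---------------------------------------------------------------------------
# Measured proportions and rates
# ---------------------------------------------------------------------------


def test_estimate_relevance():
    est = estimate_relevance([True] * 2707 + [False] * (4000 - 2707))
    assert est.value == pytest.approx(0.67675, rel=1e-12)
    assert estimate_relevance([True, True]).value == 1.0


def test_churn_rates_are_direct_ratios():
    assert estimate_contact_change_rate(ChurnSample(10, 500.0, 5)).value == pytest.approx(0.02)
    assert estimate_contact_change_rate(ChurnSample(0, 100.0, 5)).value == 0.0
    assert estimate_chatid_rate(ChurnSample(1, 100.0, 1)).value == pytest.approx(0.01)


def test_name_unchanged():
    assert estimate_name_unchanged(ChurnSample(0, 50.0, 50, pairs=50)).value == 1.0
    est = estimate_name_unchanged(ChurnSample(1, 200.0, 199, pairs=200))
    assert est.value == pytest.approx(0.995)
    assert est.n == 200


# ---------------------------------------------------------------------------
# Scaling sums vs brute force
# ---------------------------------------------------------------------------


def test_scaled_advertisers_trivial_cases():
    period = 30
    two = [adv(period, idx=0), adv(period, idx=1)]
    point, _ = scaled_advertisers(two, period, make_params())
    assert point == pytest.approx(2.0)
    point, _ = scaled_advertisers([adv(period)], period, make_params(p_rel=0.95))
    assert point == pytest.approx(0.95)


def test_scaled_workers_trivial():
    period = 30
    res = scaled_workers([adv(period)], period, make_params())
    assert res["total"][0] == pytest.approx(1.0)
    assert res[Gender.CIS_FEMALE][0] == pytest.approx(1.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(1, 60),                      # days active
            st.integers(0, 4),                       # distinct names
            st.sampled_from(list(Gender)),
            st.sampled_from(list(Context)),
        ),
        min_size=1,
        max_size=50,
    ),
    st.floats(0.3, 1.0),
    st.floats(0.3, 1.0),
    st.floats(0.3, 1.0),
    st.floats(0.0, 0.2),
)
def test_scaling_sums_match_brute_force_oracle(rows, p_rel, p_nv, p_nu, r):
    """Both scaling formulas equal an independent per-advertiser summation,
    the gender strata sum to the total, CIs bracket the point, and scaled
    counts never exceed raw/interpolated counts."""
    period = 60
    advertisers = [
        adv(days, names=tuple(f"n{i}_{j}" for j in range(k)), context=ctx,
            gender=g, idx=i)
        for i, (days, k, g, ctx) in enumerate(rows)
    ]
    params = make_params(p_rel, p_nv, p_nu, r_id=r, r_chat=0.0)
    point, (lo, hi) = scaled_advertisers(advertisers, period, params)

    oracle_adv = p_rel * sum(
        1.0 / (1.0 + (period / a.days_active - 1.0) * r) for a in advertisers
    )
    assert point == pytest.approx(oracle_adv, rel=1e-9)
    assert lo <= point + 1e-9 and point <= hi + 1e-9
    assert point <= len(advertisers) + 1e-9  # shrinkage

    counts = interpolate_names(advertisers)
    workers = scaled_workers(advertisers, period, params, counts)
    oracle_w = (
        p_nv * p_nu * p_rel
        * sum(counts[id(a)] / (1.0 + (period / a.days_active - 1.0) * r)
              for a in advertisers)
    )
    assert workers["total"][0] == pytest.approx(oracle_w, rel=1e-9)
    strata = sum(workers[g][0] for g in Gender)
    assert strata == pytest.approx(workers["total"][0], rel=1e-9)
    assert workers["total"][0] <= sum(counts.values()) + 1e-9  # shrinkage
    wlo, whi = workers["total"][1]
    assert wlo <= workers["total"][0] + 1e-9 <= whi + 2e-9


# ---------------------------------------------------------------------------
# Name interpolation
# ---------------------------------------------------------------------------


def test_interpolate_names_medians_by_context():
    advertisers = [
        adv(5, names=("a",), idx=0),
        adv(5, names=("b",), idx=1),
        adv(5, names=(), idx=2),  # nameless individual -> median 1
        adv(5, names=("c", "d"), context=Context.COLLECTIVE, idx=3),
        adv(5, names=(), context=Context.COLLECTIVE, idx=4),  # -> median 2
    ]
    counts = interpolate_names(advertisers)
    assert counts[id(advertisers[2])] == 1
    assert counts[id(advertisers[4])] == 2


def test_interpolate_names_no_nameless_is_identity():
    advertisers = [adv(5, names=("a", "b"), idx=0), adv(5, names=("c",), idx=1)]
    counts = interpolate_names(advertisers)
    assert counts[id(advertisers[0])] == 2
    assert counts[id(advertisers[1])] == 1


# ---------------------------------------------------------------------------
# Side estimators
# ---------------------------------------------------------------------------


def test_image_based_advertisers():
    stats = ImageStats(1640209, 16.0, 1.4)
    assert image_based_advertisers(stats, 0.95) == 69562
    assert image_based_advertisers(ImageStats(1234, 1.0, 1.0), 1.0) == 1234
    # doubling reuse halves the estimate
    half = image_based_advertisers(ImageStats(1640209, 16.0, 2.8), 0.95)
    assert half == pytest.approx(69562 / 2, abs=1.0)


def test_missed_advertisers():
    assert missed_advertisers(399318, 17.8, 0.764) == 17139
    assert missed_advertisers(0, 17.8, 0.764) == 0
    assert missed_advertisers(1234, 1.0, 1.0) == 1234


def test_chatid_adjusted_advertisers():
    assert chatid_adjusted_advertisers(48832, 1.1, 2707 / 4000) == 30042.8
    with pytest.raises(ValueError):
        chatid_adjusted_advertisers(10, 0.0, 0.5)
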