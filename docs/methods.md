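# Methods

`adpop` estimates how many people advertise — and how many workers they
represent — from a corpus of time-stamped classified ads. This note
describes the model, the measurement procedures, the synthetic-data
generator that validates them, and the numerical choices made where the
design was genuinely open.

## The estimation model

**Ads → advertisers.** Ads are linked by canonical contacts (phones
normalised to `NNN NNN NNNN`, emails lowercased and grouped across
misspellings at Levenshtein distance ≤ 2). Contacts that co-appear in at
least one ad within an analysis window are merged into one *advertiser*
(connected components of the co-occurrence graph; a density clustering with
a minimum neighbourhood of one over this adjacency yields the same
partition, so components are computed directly for determinism). Clusters
get content-addressed virtual ids so reruns are stable. Clustering is
recomputed per window: clusters are only meaningful for a time period.

**Advertisers → workers.** First names are detected with a corpus-built
lexicon. Seed names locate the context words that typically precede names
("name is …", "je m'appelle …"); a context word must precede at least two
distinct seed names (when two were seen at all) so that generic high-
frequency tokens do not qualify. A seed is retained when at least a
threshold fraction (default 0.5) of its occurrences is name-like, and new
tokens following context words are accepted under the same threshold.
Names are canonicalised (lowercase, punctuation stripped except single
quotes, repeated-letter runs collapsed: "Angellaaaaaa" → "angela"). An
advertiser with several distinct names, or group keywords ("duo", "agency",
"our", …, matched as whole words with no negation handling), is a
*collective*; each distinct canonical name counts as one worker. Nameless
advertisers receive the window's median name count for their social context
(individual/collective), falling back to 1 and 2.

**Scaling.** Raw counts overcount: some advertisers are irrelevant, and one
person reappears under fresh contact details. For a window of `Period`
days, an advertiser observed over an inclusive span of `Days(a)` is treated
as one appearance of an intermittently active entity with about
`Period/Days(a)` appearance slots, at risk of re-appearing under new
contact details once per unobserved slot at rate `R`:

    P(a unique) = 1 / (1 + (Period/Days(a) − 1) · R)
    N̂_advertisers = P(a relevant) · Σ_a P(a unique)
    N̂_workers = P(n valid) · P(n unique) · P(a relevant) · Σ_a Names(a) · P(a unique)

`R` adds the directly measured contact-change rate and the chat-account
change rate, on the identifying assumption that an account reset hides a
contact change as often as an account change occurs alone.

**Intervals.** Probabilities get Wald intervals `P ± z·sqrt(P(1−P)/N)`
(z = 1.959964, clipped to [0, 1], no continuity correction). The combined
rate gets a root-sum-of-squares interval. Scaled estimates are bracketed by
rerunning the scaling with every parameter at its lower (upper) bound —
with the rate at its *upper* (lower) bound, since the estimate is
monotonically decreasing in `R`. This simultaneous-extreme rerun is the
most conservative reading of interval propagation for these monotone
formulas.

## Measuring the parameters

* **P(a relevant)**, **P(n valid)** — labelled samples of advertisers and
  advertiser–name pairs. In synthetic runs the labels come from ground
  truth, standing in for the manual review a real study performs.
* **Contact-change rate** — advertisers tracked independently of their
  contacts through site-internal chat ids. Eligible ads carry one contact,
  imagery and a chat id; entities are connected components of the
  contact/chat-id graph; entities with co-occurring contacts are excluded
  (their per-contact spans are fragmentary). Every extra contact within an
  entity is one change event. Exposure is counted on the same at-risk clock
  the uniqueness correction assumes: an entity observed with span `D` in a
  period `P` has `P/D − 1` unobserved slots, and because an entity changing
  identity at total rate `R` is observed as `1 + (P/D − 1)·R` fragments on
  average, each observed fragment is credited `(P/D−1)/(1+(P/D−1)R)`
  at-risk days. The rate solving `events = r · exposure(r)` is found by
  bisection. A span-based (advertiser-day) denominator would measure a
  different quantity than the one the uniqueness formula consumes and makes
  joint recovery of the rate and the counts impossible. The reported
  sample size is a delta-method *effective* event count: the exposure
  shrinks as the rate grows, so the solve amplifies event noise by
  `E/(E + r·E′)` and the effective count is correspondingly smaller.
* **Chat-id change rate** — extra chat ids accumulated by single contacts,
  per observed span-day (the clock on which "new chat ids per day" is
  actually observable).
* **P(n unique)** — single-contact, single-name, image-bearing sequences;
  a change is the same contact with shared imagery under a different
  canonical name; observations are advertiser–name pairs.

## The synthetic corpus

The generator emulates the statistical structure the analysis assumes, with
known ground truth, so every stage is testable without any scraped data.
Default conditions: 1000 workers over a two-year window; contact churn
0.0223/day and chat-id churn 0.0024/day; 95% relevant advertisers; name
validity 0.9612; 11% of ads without contacts; 45% collectives (collective
name counts 2 + Poisson(0.4): median 2, mean ≈ 2.4); 10% of advertisers
nameless; gender mix 84.7 / 5.1 / 1.7 / 8.5% (cis-female / cis-male /
transgender / other) following observed ad-category shares.

* **Entities and fragments.** Each entity draws an appearance span `D` from
  a heavy-tailed mixture (point mass at 1 day + log-normal μ=3.322,
  σ=1.585) and manifests as `1 + Poisson((P/D−1)·R)` advertiser fragments
  of span exactly `D`, placed uniformly — the exact overcounting process
  the correction inverts, making the whole-period estimator unbiased by
  construction. Spans are drawn by rejection with weight 1/(expected
  fragments) so that the *observed* days-online distribution matches the
  published shape (median ≈ 14–16 days, IQR starting at 1, mean ≈ 65);
  the configured mixture describes observed advertisers, while entity-level
  draws must be down-weighted by their fragment multiplicity.
* **Churn flavours.** Fragment boundaries keep the chat id (measurable
  contact change) or reset both contact and chat id, the reset flavour at
  the chat-id change rate — realising the additive-rate assumption exactly.
  Contact-keeping chat-id additions are planted per observed day so the
  ids-per-contact measurement recovers the configured 0.0024/day.
* **Noise channels.** Phones are rendered in plain, dashed, dotted,
  parenthesised or word-mixed styles ("sevenseveneight 5five5 5421"), all
  recoverable by extraction; emails are misspelled at 1–2 edits on 5% of
  ads; spurious names are planted at a rate giving the configured pair
  validity, on interior ads so they cannot shorten observable spans; ~5% of
  names are novel (absent from the seed list) to exercise lexicon growth;
  image tokens are drawn from per-entity pools with a global reuse factor.
* **Missing contacts** are extra contact-less ads, so no fragment loses
  visibility; ground truth counts a worker active in a window only when a
  contact-bearing ad falls there — the estimand is workers represented in
  contact-bearing advertising.
* **Site structure.** Three sites; only one carries chat ids. That site's
  default ad share (0.30) is larger than any single real site's share: at
  the 1000-worker scale of the validation corpus it gives the churn
  measurement roughly the precision the full-size analysis had (SE ≈ 4–10%
  on 0.0223/day); a 6% share would leave a few dozen tracked entities and
  make the measurement, not the estimator, the binding error source.

**What the generator does not emulate:** natural ad prose (text is
templated with controllable slots), multiple simultaneous identities,
advertisers borrowing face images from unrelated people, cross-site
advertising by one entity, seasonal or trending activity. Passing recovery
tests therefore show that the estimators invert the assumed observation
process correctly — not that the assumptions hold for any real market.

## Windows, trends, comparisons

Windows are half-open UTC date intervals: "weekly" means consecutive 7-day
blocks from the corpus start, "monthly" means calendar months (the
convention is fixed here; week/time-zone boundaries are not claimed to
match any external analysis). `Days(a)` is clamped to the window. Trends
are OLS fits of monthly values on month index (a perfectly constant series
reports p = 1). Proportion comparisons use the pooled two-sample z test
without continuity correction by default (a flag enables it). Per-capita
conventions: per-100k and one-in-N round to integers, percent to one
decimal.

## Numerical and edge-case choices

* `days_active` is the inclusive span (last − first + 1), so
  `1 ≤ Days(a) ≤ Period` always holds and a days-online IQR lower bound of
  1 is attainable.
* Duplicate ad ids are a hard error; unparseable timestamps reject the
  record with a logged diagnostic, never silently.
* Email canonical representatives: most frequent spelling, ties broken
  lexicographically; grouping is single-linkage over the distance-≤2 graph.
  Unmatchable phones (invalid area code) and malformed emails go to a
  review-queue sidecar instead of the estimates.
* Advertiser gender is the modal ad category, ties → other.
* Cluster statistics cover parts of size ≥ 2 only; an empty-stats sentinel
  is returned when a window has no clusters.
* The relevance-recovery check uses the effective sample size
  `(Σf)²/Σf²` over entity fragment counts: advertiser-level counts are
  clustered within entities and the naive binomial SD overstates precision.

## Validation problem sizes

The validation suite runs five independent 1000-worker corpora
(~30k ads each) through the full pipeline — the scale at which the
recovery properties are stated — plus a 200-worker corpus for golden-file
and structural tests; the whole suite completes in about a minute on one
CPU.

## Known limitations

* The uniqueness correction is a heuristic inversion of an intermittency
  model; when real activity is continuous rather than intermittent it
  over-deflates long-lived advertisers and under-deflates short-lived ones.
* The self-consistent churn-rate solve is ill-conditioned when exposure is
  dominated by a few very short-span entities (the delta-method effective
  event count makes this visible rather than hiding it).
* Median name interpolation slightly undercounts collectives whose true
  mean exceeds the window median.
* Image-based estimation takes image tokens as perfect equivalence keys;
  perceptual-hash collisions and reuse across unrelated advertisers are out
  of scope.
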