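# Methods

This note records the modelling assumptions, estimation schemes, numerical
choices and limitations behind `adlseq`, in the order the pipeline runs.

## Day construction

Raw logs arrive either as interval records (start, end, identifier) or as
point events (date, time, sensor, binary value, optional activity
begin/end tag). Timestamps are rounded to the nearest whole second, halves
rounding up — the rounding direction is a convention; what matters is that
it is deterministic. All intervals are half-open `[start, end)`: a sensor
or activity covers a one-second slot iff it covers the slot's start
second. Point-event streams are normalised first (known token typos such
as `OF` → `OFF`, optional impossible-year corrections), non-binary
readings (temperature, power) are dropped, and begin/end activity tags are
paired per resident; a `begin` that never closes is closed at the log end
with a warning (or rejected, by policy).

An experiment day spans 04:00 → 04:00 so that sleep brackets both ends;
the day length is exactly 86 400 one-second slots. Data before the first
04:00 boundary are disregarded. A trailing partial day is completed by
holding the last observed state (`edge_policy="extend"`, the default) or
dropped (`"drop"`). An explicit `origin` can pin the day grid when
ground-truth day labels must stay aligned (the synthetic pipeline does
this). Activity annotations may overlap; concurrency is capped at two
activities per slot — a third is an error by default, or the two
longest-running intervals are kept under `concurrency_policy=
"keep_two_longest"`. Slots with no annotation hold the reserved label
`"no activity"`. Multi-resident logs keep one activity stream per
resident; sensors are shared.

Daily vectors are stored as run-length-shared arrays of frozensets
(identical consecutive slots point at one set object), which keeps a
30-day dataset at a few megabytes and makes run detection cheap. The wide
interchange format is a tab-separated 0/1 matrix, one line per second:
day index, one column per sensor, one column per (resident, activity);
write → read is lossless.

## Distances

Per-slot differences:

- sensor sets match when `2·|s ∩ q| > ε·(|s| + |q|)` (partial matching
  under noise). Two empty sets match, and equal sets always match — the
  latter matters only at ε = 1, where the strict inequality would
  otherwise make a slot mismatch itself and break `d(a, a) = 0`.
- activity sets: 0 on equality; a reduced cost when any cross pair of
  members is adjacent (observed consecutively somewhere in the data); 1
  otherwise. Unequal sets that share a member get no special treatment by
  default (they score through the adjacency cases); the
  `overlap_is_match` flag maps them to 0 for sensitivity analyses.

Transition statistics are estimated on compressed sequences (consecutive
equal sets merged). For set-valued slots, each member of the predecessor
set transitions to each member of the successor set *not already present*
— unchanged members contribute no transition, capturing only what
changed. Counts are pooled over days; p(b|a) is a's outgoing fraction to
b, zero when a has no outgoing transitions (which drives the symmetric
cost `1 − ½p(a|b) − ½p(b|a)` to its maximum of 1 absent evidence). When
several adjacent member pairs hold between two concurrent sets, the
cheapest holding pair is charged — the most favourable match, consistent
with a single-cost outcome per slot.

Hamming-family distances factorise the slot sets of all days into integer
codes and evaluate the difference function once per distinct set pair;
a full 30-day, 86 400-slot distance matrix then costs well under a second.
Sums involve at most 86 400 terms in [0, 1], so double precision needs no
special care, and H1 is exactly integer-valued.

The Levenshtein distance runs the classic two-row dynamic program on
compressed sequences with configurable insert/delete/substitute costs
(defaults 1/1/2); element equality is set equality. The derived
similarity `1 − L/max(|x|, |y|)` is clamped at 0: with a substitution
cost above the insert cost the raw expression can dip below 0 (two
unequal one-element sequences give L = 2 over a maximum length of 1),
and the similarity is defined as a 0-to-1 scale. Two empty sequences
have similarity 1. The clamp never affects clustering, which operates on
distances.

## Entropy

Entropy is computed by default on half-minute slots (a 30× resize; an
activity is present in a coarse slot if present in at least one covered
second, and the idle label is dropped from a union that contains a real
activity). Per-slot probabilities count each activity present in a day's
slot once and normalise by the total number of presences — with
concurrency, normalising by days instead would not sum to 1.

The first-order conditional entropy pools joint (previous-member,
current-member) pair counts across days, weighting each pair by
1/|previous set|. This weighting makes the joint's current-slot marginal
coincide exactly with the presence distribution above, so
`h*ᵢ ≤ hᵢ` is a theorem (conditioning never increases entropy) rather
than an empirical tendency; an unweighted pooling would double-count
successors of concurrent slots and could violate the ordering. Slot 0 has
no predecessor within the day and carries its unconditional entropy.
`0·log 0 := 0` throughout; base 2, values in bits.

## Clustering

PAM runs the classic two phases: k initial medoids, nearest-medoid
assignment (ties to the lowest partition id), then repeated evaluation of
all k·(m−k) medoid/non-medoid swaps, applying only the single best
strictly-improving swap per iteration. Strict improvement is required to
continue, which rules out cycling on ties; every tie (swap choice,
restart choice, assignment) breaks toward the lowest index, so the result
is a pure function of (matrix, seed). The default runs 10 restarts from
seeds `seed..seed+9`; `restarts="all"` enumerates every C(m, k) initial
set, which is exact for small m (verified against a brute-force optimum
over all medoid sets in the tests). k defaults to 4 but is user-chosen;
no internal model-selection criterion is imposed.

The Rand index is the plain pair-agreement fraction (Ns + Nd)/C(m, 2) —
deliberately not the adjusted index, so values should be read
comparatively (even unrelated partitionings score close to 1). Partition
summaries report the average distance over all day pairs, over
within-partition pairs (undefined for singletons), and the mean of the
defined per-partition averages.

## Synthetic data

The generator emulates single- or few-resident homes: each day type is an
ordered schedule of activity blocks with truncated-normal start/duration
jitter (truncation keeps the day valid; sampled blocks are forced into
order and clipped at the day end), optional concurrent overlays placed
inside a host block (so concurrency never exceeds two), and per-second
Bernoulli sensor emissions per activity, plus an optional spurious-event
noise rate. The default study conditions are 30 days drawn uniformly from
three day types loosely shaped like a real single-resident apartment
study — a full-home routine, an evening-away routine and a night-away
routine over seven activities — with 10-minute jitter SD. The away
windows differ by more than six hours between types, so the types are
well separated by construction; day-type recovery (PAM k = 3 on H3
against the ground-truth labels) is the pipeline-level check.

What the generator does *not* emulate: annotation errors and boundary
slop around true activity switches, sensor cross-talk between activities,
long-range dependencies (weekday/weekend structure, trends), or
multi-resident interaction (streams would be independent). Passing the
recovery test therefore shows the pipeline recovers cleanly separated
routines, not that real annotated datasets are this separable — on real
data the partitions are expected to be noisier and the choice of k a
judgement call.

## Numerical and interface conventions

- Rounding: half-up to seconds on parse; heatmap annotations are in
  thousands with round-half-even.
- Distance matrices serialise as TSV with day labels, plus a small
  key-value `.meta` sidecar carrying the metric name and parameters.
- Plots use a red (low) → green (high) colormap for distance matrices
  with black frames around within-partition blocks, and a fixed
  activity-to-colour mapping by sorted label order; concurrency in the
  raster is shown as a split band per day row.
- All stochastic components (generator, PAM restarts) take explicit
  integer seeds; reruns are byte-identical.

## Problem sizes

Tests and the acceptance script run on full-resolution 86 400-slot days
where a dimension itself is the claim, and on shorter vectors (tens to
hundreds of slots) for property suites, which exercise identical code
paths. Day-type recovery uses 30-day datasets over 20 generator seeds;
PAM-versus-brute-force uses 50 random instances with m ≤ 8, k ≤ 3, where
exhaustive enumeration is exact.

## Known limitations

- Annotations are taken as given: no ADL recognition is performed, and
  non-binary sensor channels are excluded rather than modelled.
- Scoring an unseen day against discovered partitions (anomaly detection)
  is out of scope; the partitions and distances here are its inputs.
- The H2 fixed cost defaults to 0.5 and is a free parameter; H3 removes
  the choice but inherits estimation noise from small datasets.
- Entropy estimates carry no smoothing; with few days, rare activities
  make the profiles jumpy.
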