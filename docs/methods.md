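# Methods

## Scoring model

An item's relevance to a user is a weighted blend of two soft Dice
similarities: against the learned profile tag set P_u (union of tags of
positively rated content) and against the onboarding biography tag set
B_u:

    sim(T_i, P_u, B_u) = w_p · sim_dice(T_i, P_u) + (1 − w_p) · sim_dice(T_i, B_u)

The blend is linear in w_p and bounded in [0, 1].  "Rated positively"
means a positive smiley only; neutral ratings are excluded from P_u (the
three-level smiley maps to {0, 0.5, 1} and only the top level signals the
kind of enthusiasm worth generalising from; this is configurable through
the rating predicate).  An activation abort is recorded as an implicit
score of 0 on the rating event and counts as non-positive regardless of
the smiley.

### History weight

The hand-off schedule is w_p = min(w_max, n/(n+k)) with defaults k = 10,
w_max = 0.9.  It is 0 with no history (pure biography cold start), reaches
0.5 at n = k, and saturates at w_max so the biography is never fully
discarded.  The functional form is a design choice: any bounded,
monotone schedule with w_p(0) = 0 would serve; the hyperbolic form has a
single interpretable half-saturation constant.

### Soft Dice

Pairwise concept similarity is derived from the unweighted shortest-path
distance d in an undirected concept network: 1 for identity, 1/(d+1) for
d ≥ 1, and 0 for disconnected pairs or d > d_max (default 4).  The raw
"inverse distance" 1/d is undefined at d = 0 and would give adjacency the
same score as identity; 1/(d+1) is bounded, monotone, and makes identity
strictly dominate adjacency.

Set similarity generalises the Dice coefficient: soft_dice(A, B) =
2·M/(|A|+|B|), where M is the mass of a greedy one-to-one matching —
repeatedly pair the remaining cross pair of highest positive similarity
(ties broken lexicographically, so the result is deterministic), remove
both concepts, and sum.  On a network without edges only identity pairs
have positive similarity, so soft_dice reduces *exactly* to the classical
Dice coefficient; on any network soft_dice ≥ dice, because the matching
can only add mass.  The greedy matching is O(|A|·|B|·min(|A|,|B|)) on a
dense similarity submatrix; an optimal-assignment variant would differ
only in rare tie structures and is not implemented.  Both sets empty is
defined as similarity 0.

### Tagging pipeline

Descriptions are lowercased, tokenised at Unicode word boundaries
(punctuation stripped), filtered against a stop-word list, stemmed with an
in-package implementation of the classic Porter (1980) algorithm, and the
stems resolved through the network's surface-form index.  Unresolved
stems are dropped with a warning rather than kept as ad-hoc concepts, so
all similarity arithmetic stays inside one graph.  Tagging is
deterministic and idempotent for a fixed network and stop-word list.  A
small packaged toy network (45 everyday-life concepts in 7 themed
clusters, TSV format) serves tests and examples; any node/edge TSV pair
can be plugged in instead.

### Seasonal term, filtering, selection

Content tagged with a calendar event receives an additive bonus w_s
(default 1.0 — deliberately as large as the maximum similarity so seasonal
content clears any threshold) when today falls in the event's window:
Christmas Dec 1–26, birthday ±3 days around the anniversary of the user's
birth date; windows are configurable.  Thresholding applies to the final
score (similarity + bonus) with an *inclusive* boundary (score ≥ θ,
default θ = 0.1), after removing content used within the last 24 h
(keyed on content start) and content excluded by the biography (by item id
or by tag; exclusions dominate unconditionally).

Remaining candidates are ordered by average liking — the Laplace-smoothed
mean normalized rating over all users and sessions (prior 0.5, prior
weight 1, so unrated items sit at 0.5) — with ties broken by final score,
then item id.  The slate (default size 6) is drawn by
fitness-proportionate selection over content types: each draw picks a
type with probability proportional to its remaining candidate count, then
pops that type's top-ranked item.  This preserves the type mix of the
candidate pool in expectation while still ranking within type by liking.
A deterministic largest-remainder mode exists for testing.  If no
candidate clears the threshold (e.g. empty biography and no history), the
slate falls back to the globally top-liked eligible items; the comparison
baseline draws items at random with probability proportional to average
liking among recency-eligible content.

## Session logs and analytics

Events are JSON Lines with a version header: session start/end, daily
condition (ordinal), recommendation slates, reloads, selection (with
source recommendation vs search), content start/end, ratings.  Malformed
lines are collected as error records, never silently dropped; reading is
the exact inverse of writing.  Timestamps are ISO-8601; event ordering
within a session is validated by the summariser (unpaired content starts
are counted to session end with a warning).

Type entropy S = −Σ P_i log(P_i) is computed over relative *duration*
shares by default (a count-based mode is available by passing counts as
the duration mapping); the log base is configurable and defaults to the
natural log.  S is 0 for a single present type, maximal (log k) under
uniformity, and unaffected by zero-duration types.  Study-level tables
aggregate per-type totals, per-user entropy series, duration-weighted
personal-content share per study week, and smiley histograms by type and
provenance.

## A-B evaluation

Sessions are assigned 50/50 at session start (assignment drawn once per
session id and cached, reproducible under a seed).  Metrics per session:
selection rate = recommendation-sourced selections / all selections;
reloads per activation = reload events / content starts; mean rating =
mean normalized rating over items selected from recommendations (an
all-items variant can be derived from the session tables).  The paired
unit is the participant: per-participant values are unweighted means over
that participant's sessions in each condition (sessions where a metric is
undefined — e.g. no selections — are skipped for that metric).
Participants lacking both conditions are excluded from the pairing and
reported.  The one-sided paired t-test (scipy) is directed at the
personalized condition being better (higher selection, fewer reloads,
higher rating); no multiple-testing correction is applied across the three
metrics.  Degenerate all-zero differences are reported as t = 0, p = 0.5.
Fewer than two paired participants marks the test not computable rather
than raising.

## Simulator

The simulator emulates the statistical structure of tandem-session data,
not its behavioural richness:

* **Activation counts** per session are 1 + NB(r, p) with r ≈ 0.69,
  p ≈ 0.123, chosen so the shifted variate has mean 5.9 and SD 6.3 — the
  field-observed per-session moments.  Overdispersion (SD > mean) rules
  out a Poisson model; the unit shift implements the ≥ 1 support without
  inflating the calibrated mean, which a rejection-style truncation would
  (zero-truncating the same NB raises the mean to ≈ 6.9).
* **Users** carry a latent affinity concentrated on one topic cluster of
  the generated concept graph (12 clusters × 7 concepts; star-shaped
  clusters whose hubs form a ring, so same-cluster concepts are ≤ 2 edges
  apart and remote clusters fall beyond the similarity horizon).  The
  internal liking of an item is soft_dice(T_i, affinity support) weighted
  by a per-type preference drawn from U(0.4, 1.0) — the wide spread
  mirrors the strong individual differences in activation-type selection
  observed in field data, and gives the A-B harness the within-arm
  variance the prescribed power analysis (power > 0.8 at 25 participants
  on all three metrics) assumes.  The biography exposes half of the
  affinity support (biography_fidelity = 0.5).
* **Choice model**: the user accepts the best slate item whose liking
  clears an acceptance threshold (0.25 — tolerant enough that a mediocre
  match is accepted, which is what produces mid-scale ratings for
  baseline recommendations), otherwise reloads (cap 2) and finally
  searches directly for their best not-recently-used item.  Smileys are
  positive above liking 0.5, negative below 0.2, neutral between, and
  flip to a random other level with probability 0.1 (rating noise); noise
  enters *only* at this layer, never in the latent liking.
* **Durations** are lognormal (median 120 s, σ = 0.6), giving ≈ 15-minute
  sessions at the calibrated activation count.
* **Catalog**: 120 items, seven types in equal proportions via
  largest-remainder apportionment, descriptions synthesised from sampled
  concept surface forms and tagged through the ordinary pipeline; 10%
  personal provenance, 5% seasonal-tagged.

Default study size is 25 users × 16 sessions (~2 s on one CPU), matching
the scale at which the A-B protocol is evaluated.  All randomness flows
through one seeded numpy generator; a study is bit-reproducible from its
seed.  What the simulator does **not** model: facial or biosignal affect,
dyadic conversation, caregiver influence, drifting preferences, or any
claim of behavioural realism beyond the calibrated moments — passing
tests demonstrate that the *pipeline* behaves as specified under the
assumed statistical structure, not that the recommender would achieve the
same effect sizes with real tandems.

## Numerical and degenerate-input conventions

* Dice of two empty sets is 0; entropy of an all-zero duration vector is
  an error, but a session with no activations reports entropy 0 by
  convention.
* Threshold filtering is inclusive at θ; ranking ties break by final
  score then item id, so every ordering is deterministic.
* Result JSONs serialise floats at 10 significant digits; two runs with
  identical seeds produce byte-identical outputs.
* The recency rule keys on content start; profile updates stamp last use
  at rating time as well, so whichever event occurs is honoured.

## Known limitations

* The greedy soft-Dice matching is not an optimal assignment (a
  deliberately cheaper choice; exact reduction to classical Dice and the
  soft ≥ classical dominance hold regardless).
* Average liking is global, not cohort-stratified; with few raters it is
  dominated by the 0.5 prior.
* The simulator's search fallback is oracle-like (the user always finds
  their best item), which makes the baseline arm stronger than a
  realistic search and thus the measured A-B contrasts conservative.
* No cross-user collaborative filtering, clustering of user groups, or
  learning-to-rank; these are outside the engine's scope.
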