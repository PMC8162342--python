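# tandemrec

Content-based recommendation engine for *tandem activation sessions* —
joint sessions in which a person with dementia and a caregiver use a
tablet library of activation content (videos, quizzes, games, stories,
images, audio, phrases) together.  The package covers the full
personalization stack: semantic tagging of content descriptions, user
modeling from biography and rated history, Dice-coefficient scoring with
diversity-preserving slate selection, session-log analytics, an A-B
evaluation protocol, and a synthetic session simulator that makes the
whole pipeline testable without any study data.

## The model

Each content item *i* carries a tag set *T<sub>i</sub>* derived from its
free-text description (tokenise → stop-word filter → Porter stem → map to
concepts of a semantic network).  Each user *u* has a biography tag set
*B<sub>u</sub>* entered at onboarding and a learned profile
*P<sub>u</sub>* = the union of tags of all content rated positively.  An
item is scored by the weighted Dice similarity

```
sim(T_i, P_u, B_u) = w_p · sim_dice(T_i, P_u) + (1 − w_p) · sim_dice(T_i, B_u)
```

where the history weight *w<sub>p</sub>* = min(w_max, n/(n+k)) grows with
the number *n* of rated items, handing scoring over from biography to
learned preferences.  `sim_dice` is a *soft* Dice coefficient
2·M/(|A|+|B|): instead of the exact intersection, M is a greedy one-to-one
matching over pairwise concept similarities 1/(d+1) (d = shortest-path
distance in the concept network, zero beyond a cutoff), so near-synonymous
tags still contribute.  A seasonal term with high weight boosts content
matching calendar events (Christmas, the user's birthday).  Candidates
with score ≥ θ that were not used in the past 24 h are sorted by average
liking and drawn into the slate by fitness-proportionate selection over
content types, preserving type diversity.

Session analytics summarise event logs into per-type durations, the type
diversity entropy *S* = −Σ *P<sub>i</sub>* log *P<sub>i</sub>*, personal-content
shares and rating histograms.  The A-B harness assigns each session 50/50
to a personalized or popularity-baseline condition and compares three
metrics across participants with one-sided paired t-tests: selection rate
from recommendations, reloads per activation, and mean rating of
recommended content.

## Worked example

```python
from tandemrec import compute_metrics
from tandemrec.simulator import SimConfig, run_ab_study

res = run_ab_study(SimConfig(rng_seed=1))   # 25 users x 16 sessions
ab = compute_metrics(res.log, res.assignment)
for name, t in ab.tests.items():
    print(f"{name}: baseline={t.mean_baseline:.3f} "
          f"personalized={t.mean_personalized:.3f} p={t.p_value:.2g}")
```

prints

```
selection_rate: baseline=0.526 personalized=0.677 p=0.0004
reloads_per_activation: baseline=1.326 personalized=1.020 p=0.0012
mean_rating: baseline=0.728 personalized=0.786 p=0.013
```

i.e. in the simulated study users take 68% of their content from the
personalized recommendations versus 53% under the popularity baseline,
trigger fewer slate reloads per started activation, and rate the
recommended content higher; all three one-sided paired t-tests across the
25 simulated participants are significant.  The `examples/` directory
walks through each capability (tagging, cold start, profile learning,
analytics, A-B evaluation) as short narrative scripts; the `tandemrec`
console script exposes the same pipeline as `tag-content`, `recommend`,
`simulate`, `evaluate` and `report` subcommands.

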