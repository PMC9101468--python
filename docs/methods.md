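# Methods

## The measurement problem

Direct continuous observation is the de-facto criterion for time-use
measurement in low-literacy rural settings, but it is too costly to scale.
Recall-based instruments — the 24-hour recall (24HR) and, more recently,
image-assisted recall (IAR) cued by automated wearable-camera photos — are
the practical alternatives, and their validity must be established against
observation. The distinctive difficulty in this population is
*simultaneity*: passive childcare and chatting happen alongside almost
everything else, so any crediting rule that divides each timeslot equally
among activities (implicitly treating them as sequential) mechanically
shrinks the time attributed to exactly the activities women perform most.

This package implements the full validation pipeline: slot-level
crediting, ICATUS-2016 aggregation, population descriptives, and the
inter-method agreement suite, plus a synthetic-cohort generator so every
stage is testable end to end without field data.

## Crediting model

The analysis window (default 08:00–20:00) is discretised into half-open
slots `[t, t + T)` with `T = 15` min (48 slots). Slot intervals being
half-open means an episode ending exactly at a slot's start does not
occupy it, so boundaries are never double-marked.

Per slot, with simultaneous activities `S` and non-simultaneous
activities `N` present:

- **simultaneous-aware** (default): every `a ∈ S` is credited `T`; every
  `a ∈ N` is credited `T/|N|`. Total credited = `T·(|S| + [|N|>0])`.
- **sequential**: every activity is credited `T/(|S|+|N|)`. Total = `T`.

A slot with a single activity of either kind credits it the full `T` in
both modes. When a slot contains only simultaneous activities there is no
splitting pool and each receives full credit; the rule is deterministic
and needs no tie-breaking.

Activities excluded from aggregation (resting/sleeping, study-related
interactions) are removed *before* crediting: they neither receive credit
nor shrink the splitting pool. The alternative (post-split removal, which
leaks credit out of the slot) is available via `drop_excluded=False` on
`credit_timeslot`. They still count toward concurrency profiles by
default, switchable with `include_excluded=False`.

Credits are exact rationals (`fractions.Fraction`), so k-way splits incur
no floating-point error; conversion to float happens only when summing
into division totals. Tests compare credits exactly where the divisor
divides `T` and at 1e-9 otherwise.

### Catalog

The default catalog has 44 activities, exactly four flagged simultaneous,
mapped onto the nine ICATUS-2016 major divisions; MD5 (volunteer work) and
MD6 (learning) are representable but intentionally empty, matching the
population this vocabulary describes. The full activity-to-division
mapping is a documented reconstruction shipped as data (export with
`timeuse-validate catalog`) and overridable from CSV; notable choices:
post-harvest processing maps to domestic chores (MD3) to keep
variably-coded food-processing work in one division, and "care of the
index child" includes feeding. Exactly one division per activity.

## Agreement statistics

Sign convention, fixed project-wide: differences are **criterion minus
test**, so positive bias means the recall method underestimates.

- **Bland–Altman**: bias `mean(d)`, `sd(d)` with n−1 denominator, limits
  of agreement `bias ± m·sd`. The multiplier `m` defaults to **2.0**, not
  1.96 — the implemented formula is "mean difference ± 2 SD" — and is
  configurable for users preferring the normal-quantile convention.
- **Shape diagnostics** replace visual plot reading with two regressions:
  difference on mean (trend) and |OLS residual| on mean (spread), each
  tested at a configurable level (default 0.05). Neither significant →
  cloud; spread only → fan; slope only → sloped; both → fan+sloped.
  Constant means leave the slopes undefined and the result flagged. This
  operationalisation is a design choice of this package; the underlying
  visual categories are standard.
- **Cronbach's alpha** uses the k = 2 item form
  `2·(1 − (V_a + V_b)/V_{a+b})` with sample variances. Zero total variance
  (e.g. mirrored inputs) flags the result undefined rather than raising,
  so report tables can carry the flag. Benchmark labels: ≤0.70
  unacceptable, >0.70 acceptable, >0.80 moderate, 0.90–0.95 high, >0.95
  suspect.
- **Weighted κ** builds the shared ordered category range from the
  observed min..max of both raters. Half-integer ratings (possible for a
  median over 48 slots) are doubled to integers first — this preserves
  order without inventing bins. Disagreement weights are `|i−j|/(R−1)`
  (linear, default — the scheme is recorded in every result) or its
  square; with two categories the schemes coincide. Fewer than two
  observed categories flags the result undefined.
- **Wilcoxon signed-rank**: midranks for tied |d|; zero differences
  dropped by default (classic Wilcoxon), Pratt handling available. The
  exact null distribution is built by dynamic programming over doubled
  midranks when the effective n ≤ 12 (at most 4096 sign assignments);
  beyond that a normal approximation with tie correction
  (−Σ(t³−t)/48) and a 0.5 continuity correction is used. All-zero
  differences are flagged "not testable". No multiple-testing correction
  is applied by default (raw p at 0.05), matching common practice in
  validation tables.

### Descriptives

Percentiles use linear interpolation between order statistics (the most
common convention; stated because published tables rarely say).
Non-participation (zero credited minutes) is judged on the criterion
method's credits by default — validation tables typically print one
non-participation column — switchable to per-method. Partaker medians are
computed over participants with positive criterion minutes. The
complete-case rule applies throughout: any record with a missing slot is
excluded, and the pipeline keeps only participants complete on every
method being compared.

## Synthetic cohort generator

The generator emulates the *structure* of an observed rural-Ugandan
women's day, not any particular dataset:

- per slot, each simultaneous activity is present independently with its
  configured probability — defaults 0.5625 (care of index child), 0.3542
  (care of others), 0.50 (chatting), 0.05 (TV/radio), chosen once so that
  a single omnipresent care activity accrues about 405 expected min/day
  (0.5625 × 720, before reactivity; full-credit simultaneous activities in
  the same division stack, so the MD4 division median is higher) and
  roughly 88% of slots hold more than one activity (the preset's own
  multitasking target, checked in tests at (0.80, 0.95));
- exactly one non-simultaneous "foreground" activity per slot, drawn from
  division prevalence weights (MD3-dominated: 0.55, then MD9 0.20, MD2
  0.12, MD1 0.05, MD7 0.08) with Markov persistence 0.6, uniformly among
  the division's activities; a second foreground joins with probability
  0.1;
- method degradation operates on **episodes** (maximal consecutive runs),
  because recall omission plausibly affects whole activity bouts: each
  simultaneous episode is dropped with `q_sim(method)`, each
  non-simultaneous episode with `q_act(method)`, optionally shifted by ±1
  slot or merged across one-slot gaps. A per-slot omission mode exists for
  the analytic oracle. Default rates (q_sim, q_act, shift): 24HR (0.45,
  0.05, 0.05), IAR (0.12, 0.03, 0.02), EII (0.30, 0.10, 0.02) — assumed,
  not estimated: no quantitative recall-error rates exist to calibrate
  against. The presets encode only the qualitative ordering the field
  comparison found (24HR misses passive/background activities far more
  than IAR; EII worse than IAR on every rate);
- observation-day reactivity: caregiving presence multiplied by 1.2 and
  own-production weight by 0.75 on observation days, reproducing the
  observed more-care/less-field-work shift while observed;
- random streams are keyed per participant (and per day/method), so
  cohorts are bit-reproducible and a participant's data are unchanged when
  `n_participants` grows.

What the generator does **not** emulate: between-participant
heterogeneity in activity repertoires, seasonal and day-of-week structure,
correlated omission across related activities, systematic mis-coding
between divisions, and interviewer effects. Passing recovery tests
therefore demonstrates that the pipeline measures what the error model
injects — not that real recall error follows this model.

### Analytic expected bias

In the omission-only regime (`q_act = 0`, no shifts, merges, or missing
slots), non-simultaneous credits cancel exactly between truth and degraded
records, and simultaneous credits never interact with the splitting pool,
so the expected credited-minute bias for a division is

```
E[bias_D] = Σ_{a ∈ D, simultaneous} q_sim · n_slots · p_a · T
```

independent of episode structure, because dropping whole episodes with
probability q retains each presence-slot with probability 1 − q in
expectation. `expected_bias` rejects configurations outside this regime,
naming the offending features. Tests verify the formula against a
brute-force enumeration of all presence patterns and drop decisions on a
4-slot grid, and against Monte-Carlo pipeline estimates within 3 standard
errors.

### Camera-frame model

A fixed-interval wearable camera over a wear window yields
`floor(wear_seconds / interval_seconds)` frames — 1800 for a 06:00–21:00
day at one frame per 30 s.

## Problem sizes and numerical choices

Recovery and ordering tests run at 500 participants — large enough that
3-Monte-Carlo-SE bands are tight relative to the injected effects and that
the qualitative bias ordering (24HR > IAR > 0 for caregiving and
socializing) is stable across seeds; unit tests use 2–175. The alpha→0
independence check uses n = 10,000 with a ±0.05 band. Exhaustive
conservation checks enumerate all 64 subsets of a 6-activity toy catalog.
Report CSVs round minutes to one decimal and statistics to four, making
pipeline output byte-deterministic for a given config.

## Known limitations

- The default catalog's 44-activity division mapping is a reconstruction;
  studies with their own instruments should supply a catalog CSV.
- Shape classification inherits the size/power of its component
  regression tests: with ~175 participants, mild heteroscedasticity is
  often classified fan even when a reader would call the plot a cloud, and
  the two tests are not independent.
- The exact Wilcoxon enumerates sign assignments only; it does not
  implement the permutation distribution conditional on observed zeros
  beyond the drop/Pratt rules.
- `expected_bias` covers only divisions' simultaneous components in the
  omission-only regime; biases under shifts/merges are available by
  simulation only.
- Alpha/κ benchmark labels are conventions, not inferences; no confidence
  intervals are attached to alpha or κ.
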