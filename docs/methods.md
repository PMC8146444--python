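# Methods

This note documents the models and procedures implemented in
`herdaffinity`, the assumptions behind them, and the choices made where the
design was genuinely open.

## The measurement problem

A guided-flow AMS pen produces a single behavioural stream: the timestamped
sequence of cows passing the sorting gate. The working hypothesis is that a
social bond between two cows shows up as repeated close succession in that
stream, and that breaking such a bond (one cow leaves the pen) perturbs the
remaining cow's milk production — less in its mean than in its day-to-day
variability. The pipeline therefore needs four models: an association score
over the event stream, a pairing rule, a per-cow production baseline, and a
paired contrast between bond-intact and bond-broken periods.

## Affinity scoring

Three interchangeable schemes (`ScoringSpec.method`):

* **window15** — time is cut into fixed `window_minutes` bins aligned to
  midnight; every unordered pair of distinct cows present in a bin gains one
  unit per bin. Presence, not event count: a pair passing twice in one bin
  scores once. Fixed bins (not sliding windows) keep the score a sum of
  independent bin contributions.
* **inverse_interval** — every pair of passages by distinct cows within
  `window_minutes` contributes `1 / max(Δt, ε)` with `ε = 1 s` guarding
  simultaneous stamps at second resolution.
* **lag_sequence** (default) — purely order-based: the event at position
  `i` credits the cows at positions `i-1 … i-max_lag` with
  `decay_base^-(k-1)`. A cow's own events occupy lag slots but score
  nothing. The sequence crosses days and arbitrary gaps by design, which
  makes the score free of any time-scale parameter. The decay base is 2
  (lag weights 1, ½, ¼, ⅛) — the simplest exponential over four lags — and
  is configurable.

Two normalisations make scores comparable:

* **Month weights** `w(m) = C_min / C_m`, where `C_m` is the pen's gate
  count in *calendar month of the year* `m` (pooled across years, so a
  February-to-February study window still covers each month fully) and
  `C_min` the smallest nonzero count. Heavily logged months are
  down-weighted by exactly the busiest-to-quietest traffic ratio. Weights
  multiply each event contribution, not the final matrix, so a pair's score
  remains a weighted sum over its events.
* **Residency normalisation** divides the pair score by `sqrt(T_a T_b)`
  (total days each cow spent in the pen). The geometric mean keeps the
  matrix symmetric, as an undirected network requires; a co-residency
  overlap denominator is available as an option.

All three schemes produce a symmetric non-negative matrix with zero
diagonal; zero entries mean "no relationship" and never form network edges.

## Network metrics

Density is `2E / (N(N-1))` over strictly positive edges; degree counts
incident positive edges. Diameter and betweenness treat edge weights as
path *lengths* — the convention of the classical SNA toolchain for weighted
graphs, under which a stronger tie is a longer step. This is semantically
odd, but it is the convention under which dense pen networks report large
diameters, so it is the default, documented rather than silently
corrected; `distance="inverse"`
gives the strong-tie-is-close alternative. Disconnected graphs report the
diameter of the largest component and are flagged.

## Pair matching

Preference lists order each cow's partners by descending score with ties
broken by ascending cow id (determinism everywhere); zero-score partners
are omitted, and cows with no positive score are excluded.

* *Greedy* (non-exclusive): every cow gets its top partner; mutual choices
  are symmetric pairs.
* *Stable roommates*: Irving's two-phase algorithm, extended to incomplete
  lists. A blocking pair is defined only over expressed (mutually listed)
  preferences; unmatched cows are allowed. Two conservative guards: a list
  exhausted during rotation elimination is reported as "no stable
  matching", and every candidate matching is verified with an O(n²)
  blocking-pair check before being returned. With a symmetric score matrix
  a stable matching essentially always exists (repeatedly matching the
  globally heaviest edge yields one), so the fallback matters only for
  externally supplied preference structures.
* *Maximum-weight matching*: networkx's blossom algorithm; among equally
  optimal matchings the lexicographically smallest pair set is selected by
  committing nodes in ascending id order whenever an optimal completion
  remains.

The pipeline default is the stepwise exclusive mode (stable roommates,
blossom on failure), since the downstream contrast needs symmetric
exclusive pairs. Odd pools leave one cow unmatched and out of the contrast.

## Lactation baseline

Wood's curve `Y(t) = α t^β e^{-γt}` is fitted per cow × lactation to daily
yields by bounded nonlinear least squares (`α ∈ (0, 200]`, `β ∈ (0, 3]`,
`γ ∈ [0, 0.5]`), started from the OLS solution of
`ln Y = ln α + β ln t − γ t` and refined by a trust-region reflective
solver, which never increases the objective from its start. DIM starts at
1 (the curve is degenerate at 0). Groups with fewer than `min_obs = 5`
usable records are skipped — five keeps a 3-parameter fit overdetermined —
and unconverged fits (typically window-censored stays spanning only days)
contribute no residuals. Per-group fixed effects deliberately lean toward
overfitting each cow's own curve; this makes the deviation contrast
conservative, because a curve fitted to a mixture of intact and broken days
absorbs part of any broken-period level shift (roughly half of it in the
synthetic experiments). The variability contrast is essentially unaffected.

## The affinity contrast

For each exclusively matched cow, each resident day is labelled *affinity*
iff its partner is resident in the same pen that day, else *broken*. Daily
deviations (observed − expected) are summarised per period type as mean and
sample SD; types observed fewer than `min_period_days = 7` days are
suppressed to stabilise SDs. Per pen, every cow with both period types
contributes one paired difference `d = mean_dev(affinity) −
mean_dev(broken)`; a one-sided one-sample t-test (affinity higher, per the
scientific hypothesis; two-sided via flag) is run per pen and the raw
p-values are Holm-adjusted across pens. Reported SDs are day-to-day SDs of
the daily residuals pooled over the pen's eligible cows (the "day-to-day
variability" reading; per-cow-mean SDs are computable from the summaries).
An *Overall* row pools descriptively with no test, since pens are the
inference units. A Kolmogorov–Smirnov comparison of the DIM distributions
of the two period types is reported as an advisory confounding diagnostic
(early lactation is intrinsically more variable); it never gates the
analysis.

## Synthetic herd

The generator states a world and the tests measure the pipeline against it:

* **Roster**: each pen is `cows_per_pen` slots (default 54 — the average
  *concurrent* census) kept full by renewal: when a stay ends the slot is
  re-let the next day. Stay lengths follow the four observed residency
  bands (30–90, 91–180, 181–270, 271–365 days; weights 124/99/149/66 from
  their pooled cow counts), first tenants start mid-stay (stationary age),
  and stays are censored at the window edges. This yields near-constant
  occupancy, roughly twice as many unique cows per year as slots, and a
  modest seasonal traffic profile. An optional `short_stay_fraction`
  plants cows below the 30-day analysis filter.
* **Pairs**: `affinity_fraction` of slots (rounded down to an even count)
  are pair slots; mates enter together, one leaves 30–120 days before the
  other — but a pair is never broken before `min_affinity_days = 60` of
  co-residence; shorter stays simply never break.
* **Gate traffic**: spontaneous passages are Poisson(`passes_per_cow_day`,
  default 10) per resident day, uniform over 24 h. On co-resident days the
  trigger role alternates daily within a pair; each trigger passage is
  followed by the partner within `follow_gap_seconds = 30` with probability
  `follow_prob`, and the follower's spontaneous rate is thinned by the same
  probability so every cow's total rate stays at the configured mean — the
  planted signal is timing, not volume. About 27% of passages are tagged
  as milking diversions (≈2.7 milkings/day).
* **Milk**: daily yield is the cow's Wood curve (α lognormal around 17,
  β ~ N(0.25, 0.05) truncated > 0.05, γ ~ N(0.004, 0.001) truncated >
  0.0005 — peaks near 37–40 kg around DIM 60, matching 36–42 kg pen means)
  plus Gaussian noise: SD 0.8 kg/day on affinity/unpaired days, 2.6 kg/day
  with a −0.3 kg/day mean shift on broken days. Defaults are the observed
  overall period SDs and a plausible shift magnitude; all configurable.

What the generator does **not** emulate: feed, weather, disease, oestrus,
milking-permission logic, agonistic interactions, multi-cow affinity
structures, and diurnal traffic rhythms (passages are uniform over the
day). A green recovery test therefore establishes that the pipeline
recovers planted pairwise timing structure and period-dependent noise from
realistically sized, realistically censored data — not that real cows
behave like the generator.

## Numerical and procedural choices

* Tie-breaks are everywhere by ascending cow id; all randomness flows from
  one `numpy` Generator seeded from the config, so identical configs give
  byte-identical artifacts (CSV floats are written with a fixed format, and
  the run manifest contains no timestamps).
* Duplicate (cow, date) milk rows are summed into daily totals with a
  warning; malformed rows are dropped and counted, never imputed.
* Residency is taken from an explicit table when provided; otherwise it is
  inferred from the events by a majority-pen-per-day rule (ties to the
  day's first event) with runs bridged across ≤ 3 silent days. The
  `< 30` total-days filter then removes short-stay cows from every table.
* The statistical-calibration check (type-I error of the pen test under a
  null world) exercises the labelling/summary/test stages on residuals
  drawn from the generator's milk-noise model around the true curves;
  Wood-fit recovery is validated separately. Running 500 full gate-event
  simulations would test the same code paths at ~100× the cost.
* Known limitations: the affinity/broken labelling treats any co-residence
  day as bonded (no bond-formation lag); the paired test assumes per-cow
  mean differences are exchangeable within a pen; the scoring cannot
  distinguish affiliative from agonistic succession; and with weights as
  distances the diameter of a dense network is dominated by its strongest
  ties.
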