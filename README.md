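# herdaffinity

Social-network analysis of dairy-cow sort-gate traffic in automatic milking
system (AMS) barns, and the effect of cow–cow affinity on milk production.

In a guided-flow AMS barn, every cow passes a sorting gate roughly ten times
a day on her way from the resting to the milking or feeding area. Pairs of
cows that repeatedly pass the gate in close succession — *affinity pairs* —
are a behavioural proxy for a social bond. This package, aimed at precision
livestock researchers and dairy-data engineers, turns a timestamped gate log
plus daily milk records into:

1. **Pairwise affinity scores** per pen, by three schemes: fixed 15-minute
   co-presence windows, inverse inter-passage intervals, and a lag-sequence
   score in which the cow at lag *k* of the passage order earns
   `base^-(k-1)` (base 2, up to 4 lags). Scores can be reweighted by
   calendar-month gate traffic (`w(m) = C_min / C_m`) and normalised by
   residency time (`score / sqrt(T_a T_b)`).
2. **Weighted social networks** per pen with the standard metrics —
   density `2E / N(N-1)`, weighted diameter, degree, betweenness.
3. **Exclusive maximum-affinity pairs** via a stepwise procedure: greedy
   top-partner assignment, Irving's stable-roommates algorithm, and a
   maximum-weight (blossom) matching fallback when no stable matching
   exists. Zero-score pairs are excluded.
4. **Wood lactation baselines**: per cow × lactation,
   `Y(t) = α t^β e^{-γt}` fitted by bounded nonlinear least squares, giving
   each cow an expected daily yield to deviate from.
5. **The affinity contrast**: each matched cow's days are labelled
   *affinity* (partner co-resident in the pen) or *broken* (partner gone);
   observed-minus-expected deviations are summarised per period and tested
   per pen with a one-sided paired t-test, Holm-corrected across pens.

Because farm gate logs are proprietary, a first-class synthetic-herd
generator ships with the package: pens are rosters of slots kept full by
turnover, planted pairs pass the gate within seconds of each other with a
configurable follow probability, and daily milk noise has a larger SD (and
a negative mean shift) after a pair is broken — so every stage of the
pipeline can be verified against known ground truth.

## Worked example

```python
from herdaffinity import SyntheticConfig, generate_herd, HerdAffinityModel

herd = generate_herd(SyntheticConfig(n_pens=2, cows_per_pen=40, seed=3))
model = HerdAffinityModel(herd.gate_events, herd.milk_records, herd.residency)
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Herd affinity analysis
================================================================
pens: 2   matched pairs: 109   cows excluded by residency filter: 27

Network metrics (edge weights as path lengths)
pen_id  n_nodes  n_edges  diameter  density  degree_max  degree_min  degree_mean  n_at_max  connected
  pen1      112     3353     0.492    0.539         106          34       59.875         1       True
  pen2      110     3270     0.405    0.545         104          35       59.455         2       True

Wood lactation curve fits
  groups fitted : 222
  groups skipped: 0 (fewer than 5 usable records)
  ...

Difference of actual to expected milk production, kg/day
                        Mean                SD   Paired t-test
Item         Broken Affinity   Broken Affinity        p (Holm)
pen1          -0.02     0.01     1.94     0.80           0.070
pen2          -0.05     0.02     2.17     0.83           0.006
Overall       -0.04     0.01     2.02     0.80              NA

DIM balance: KS statistic 0.193 over 22936 affinity and 3293 broken cow-days
```

Read it as: both pens' networks are dense and fully connected; 109
exclusive pairs were extracted; during *broken* periods cows produce
slightly below their Wood-curve expectation and, more strikingly, their
day-to-day variability is ~2.5× the affinity-period variability (0.80
kg/day vs ~2.0 kg/day here) — the planted broken-period effect, recovered
by the pipeline. The Holm-corrected p-values test, pen by pen, whether the
mean deviation is higher during affinity than after the pair breaks, and
the KS diagnostic confirms the two period types cover similar
days-in-milk, so the contrast is not confounded by lactation stage.

The same pipeline runs from CSV files (`gate_events.csv`,
`milk_records.csv`, optional `residency.csv`) via
`HerdAffinityModel.from_csv(...)` or the CLI:

```bash
herd-affinity simulate --out fixtures/ --seed 1
herd-affinity effect --events fixtures/gate_events.csv \
    --milk fixtures/milk_records.csv --residency fixtures/residency.csv \
    --out results/ --preset reference
herd-affinity run-all --config run.yaml --seed 1
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic herd (4 pens, 54-cow capacity, 365 days)
with the given seed, runs the entire analysis from scratch — scoring,
network metrics, pair matching, lactation fits, the per-pen paired tests —
and prints the full summary report before writing the JSON output. The
method-level verification (scoring against brute-force enumeration,
matching against exhaustive optima, Wood-parameter and planted-effect
recovery, test calibration, end-to-end determinism) lives in
`tests/test_acceptance.py`.
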