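# Methods

## The object under study

The package analyses a weighted directed bipartite network from demand
units to hospitals. Demand units are the Thiessen (Voronoi) cells of the
hospital point set clipped to the study area: one unit per hospital
("one-hospital-one-domain"), so unit ids equal generator-hospital ids and
an edge with `i = j` means a visit to the unit's own hospital. Weights are
monthly visit counts; all coordinates are planar kilometres. Geographic
inputs would need to be projected to a planar CRS before use — the package
deliberately contains no projection machinery.

## Spatial impedance

`r_ij = d_ij · τ_ij`, where `d_ij` is the mean Euclidean distance from
uniform points sampled inside unit i to hospital j (default 2,000 samples,
one point set per unit re-used across hospitals — cheaper and lower
variance than independent sets), and the detour coefficient τ is 1.3 for
ordinary land pairs and 1.8 when the segment from the unit centroid to the
hospital crosses the configured river line. The river-crossing predicate
(opposite sides of a vertical line) is our own operationalization; only
the two τ values themselves are conventional. Monte Carlo error decays as
1/√n_samples (verified empirically); diagonal impedances are strictly
positive because a unit has positive expected distance to its own
generator, which keeps the null model defined for local flows. Degenerate
zero-area units fall back to their representative point with a warning.

## Null model and inference

The counterfactual keeps each origin's total outflow and re-allocates it
over destinations with probability `p_ij ∝ r_ij^-β`. β is estimated by
maximizing the multinomial log-likelihood `Σ w_ij log p_ij(β)` with
bounded scalar search on [0.1, 10] (tolerance 1e-6); solutions at a bound
are flagged, since flows concentrated entirely on nearest destinations
push the optimum to +∞. Probabilities are computed in log space so large β
stays finite. Two scopes exist: *full*, and *nonlocal*, which removes the
diagonal from estimation and simulation alike and renormalizes over the
remaining destinations; β is re-estimated per scope because excluding
short local trips changes the apparent decay.

Significance uses add-one two-tailed Monte Carlo p-values over B = 1,000
replicates (so p is never below 2/(B+1) and never above 1). The metric set
mirrors the network-concentration table: node Gini / effective number /
top-10 share on in-strengths (zero-inflow hospitals stay in N), and edge
count / Gini / effective number / top-1% share on realized cells, with the
1% cutoff taken from each replicate's own realized edge count (ceil),
because null edge counts differ from the observed one.

**Calibration caveat.** When β is re-estimated on the very network being
tested, metrics that the fitted exponent absorbs — above all edge-level
inequality — become strongly conservative (p-values bunch toward 1): the
classic estimated-parameter goodness-of-fit effect. `null_test_suite`
therefore accepts a prespecified β, under which the Monte Carlo test is
exact; the type-I calibration experiment in the test suite uses that mode,
while re-estimation remains the default for data analysis.

## Concentration and channel statistics

Gini uses the sorted-rank formula `Σ (2m − N − 1) x_(m) / (N Σ x)` with no
small-sample correction; it equals half the relative mean absolute
pairwise difference and twice the area between the Lorenz curve and the
diagonal, and both identities are enforced in tests to 1e-9. Node-level
statistics include zero-inflow hospitals in N; edge-level statistics run
over realized (w > 0) edges only, matching the convention that E is the
set of observed paths. Top-k ties are broken by ascending unit id so
reports are deterministic.

Channels partition the realized edges exhaustively: local (`i = j`), intra
(different unit, same district), inter (district boundary crossed). A
unit's district is its generator hospital's district — Voronoi cells can
straddle administrative boundaries, so a one-per-unit label is needed and
this is the only consistent choice. Per channel: `T_c = Σ q ln(N_c q)`
with `q = w/W_c`, `ρ_c = N_c e^{-T_c}`; empty channels yield explicit null
rows rather than errors (single-district cities are legitimate inputs).

## Grade orientation and bypass premium

The local channel is excluded from all grade/bypass statistics (same-unit
visits carry no meaningful displacement). The benchmark `r*_i,g` is the
impedance to the nearest hospital of the grade actually visited, so
`BP_c,g ≥ 0` by construction; a grade with no hospitals yields NaN and a
flag. The bootstrap resamples |E_c| edges per channel with replacement
with probability ∝ weight, evaluates statistics on the resample with drawn
edges as unit-weight observations (the most literal reading of weighted
edge resampling; resampling individual trips is a noted alternative), and
takes percentile intervals; the two channels are resampled independently
for differentials. Significance means the 95% CI excludes zero — no star
levels. If the inter-district tertiary premium falls below the secondary
baseline, the active component is floored at zero with a warning and both
raw values preserved.

## Synthetic generator: what it emulates, what it does not

The generator is the package's substitute for proprietary operator data
and defines the conditions under which the test suite's claims hold.

* **City.** Districts are Voronoi cells of random seed points (guaranteeing
  an exact partition); hospitals are uniform with a grade-dependent pull
  toward the centroid (full `center_bias` for tertiary, half for
  secondary, none for primary), emulating the central clustering of
  high-grade supply. Default 50 hospitals (30/12/8) in a 40×40 km box with
  5 districts. Each hospital gets a 120 m square footprint.
* **OD flows.** A multinomial draw of `total_trips` (default 2×10^5) over
  cells with `p_ij ∝ attraction[g(j)] · friction^(−1[inter])· r_ij^{-β}`,
  uniform origin weights. Defaults β = 2.0, attraction (1, 2, 6), friction
  1.5: attraction and friction are generator-only extensions of the decay
  law so that observed-vs-null contrasts exist to be detected; the null
  model itself has neither.
* **Signaling log.** Hourly pings (Bernoulli-thinned at `ping_rate`) for a
  31-day month: nights (22:00–06:00) at home, weekday work windows
  (09:00–11:00, 13:00–17:00) at the work anchor (80% of users have one),
  Poisson(1)/month hospital visits occupying consecutive in-window hourly
  pings inside the footprint with dwell 60–180 min. Noise: Gaussian jitter
  (σ = 50 m) around anchors, ping-pong insertions (a displaced ping
  sandwiched between two anchor pings within 10 min), and drift outliers
  (a 20 km displaced ping 5 min after a real one, removable by the
  120 km/h speed rule). Anchors are rejected within 300 m of any hospital
  so the on-site exclusion never removes a planted user. All randomness
  descends from one master `SeedSequence` (stream 0 city, stream 1
  flows/log, one spawned child per user), so fixed seeds give bit-identical
  output.

Not emulated: road networks and travel times, tower-quantized positions
(positions are simulated directly; quantization is a possible extension),
commuting trajectories between anchors, night-time emergencies and
inpatient stays, and any within-grade quality heterogeneity — in the
generator the choice *within* a grade is purely distance-driven, so the
synthetic tertiary premium need not exceed the secondary baseline the way
a real quality-seeking population produces. Passing recovery tests
therefore demonstrates the correctness of the pipeline mechanics, not the
realism of any particular premium magnitude.

## Trajectory pipeline choices

Cleaning: records are sorted and deduplicated; a greedy forward pass drops
points implying > 120 km/h from the last kept record; A–B–A triples within
15 min with |AB| ≤ 0.5 km and A≈A′ (≤ 50 m) collapse by dropping B. The
pass is idempotent and order-insensitive. DBSCAN anchor parameters default
to eps = 0.3 km, min_samples = 5 (≈ cell-tower positional scatter);
anchors need ≥ 5 distinct nights/workdays *and* strictly more than 50% of
the user's active ones; among qualifying clusters the most-covered wins
(ties: more points, then smaller centroid y). The resident filter is
strict (> 15 active days). Visit dwell uses the stay's intersection with
the 08:00–11:00 / 13:00–16:00 windows and accepts ≥ 60 min inclusive,
logging exact-60 boundary cases, since strictness at the boundary is
ambiguous at hourly resolution. Stays match hospitals by centroid
containment; overlapping perimeters resolve to the smallest hospital id
(counted). Origins take the most recent same-day pre-visit record within
0.3 km of an anchor, falling back to home; users with no anchors lose the
visit (counted). Home and work anchors may coincide — a user who spends
workdays at home legitimately gets a work anchor there.

## Problem sizes in the shipped experiments

The test suite's statistical experiments run at deliberately desk-sized
scales chosen to keep the whole suite interactive: decay-exponent recovery
on a 50×50 network with 10^6 trips; type-I calibration with 200 runs of
B = 199 replicates on a 20×20 network (500 trips/origin); directional
power over 100 seeds at 2×10^4 trips; bootstrap coverage with 200 runs of
B = 1,000 on 100-edge channels; trajectory recovery with 200 users over 31
days. The demo pipeline uses B = 1,000 everywhere, matching the
recommended analysis setting.

## Known limitations

Straight-line τ-corrected impedance ignores congestion and transit;
Thiessen demand units inherit the modifiable-areal-unit problem; the
bootstrap is percentile (no BCa correction), which slightly undercovers at
small channel sizes; and the premium decomposition is an outcome-level
accounting, not a causal attribution.
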