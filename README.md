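# flowscope

Diagnostics for urban patient-flow networks: who travels where for
hospital care, how concentrated those flows are, and what crossing an
administrative boundary costs in kilometres.

`flowscope` is aimed at health-geography and spatial-equity researchers who
have (or can only simulate) origin–destination hospital-visit data. It
builds a weighted directed demand–supply network **G = (O, D, E, W)** whose
origins are Thiessen (Voronoi) demand units — one per hospital — and whose
destinations are graded hospitals (1 = primary, 2 = secondary,
3 = tertiary), then diagnoses it with four instruments:

1. **Concentration statistics** on hospital in-strengths
   `S_j^in = Σ_i w_ij` and edge weights: Gini, Herfindahl–Hirschman index
   and its effective number `N_eff = 1/HHI`, and cumulative top-k shares.
2. **A distance-decay null model.** Each origin's outflow is held fixed and
   re-allocated with probability
   `p_ij = r_ij^-β / Σ_u r_iu^-β`, where `r_ij = d_ij · τ` is detour-corrected
   impedance (τ = 1.3 overland, 1.8 across a river). β is estimated by
   multinomial maximum likelihood; B randomized networks give add-one
   two-tailed Monte Carlo p-values
   `p = min(1, 2·min(p_right, p_left))` for any network statistic.
3. **Channel decomposition.** Every edge is local (`i = j`), intra-district
   or inter-district; per channel the package reports edge counts, flow
   shares, mean weights, the Theil index
   `T_c = Σ q_ij ln(N_c q_ij)` and effective edges `ρ_c = N_c e^{-T_c}`,
   plus Lorenz curves.
4. **Grade orientation and the bypass premium.** Grade shares `π_c,g`, the
   flow-weighted upgrade rate `UR_c = Σ w_ij 1[g(j) > g(i)] / W_c`, and the
   bypass premium `BP_c,g` — the flow-weighted mean excess impedance over
   the nearest hospital of the *same* grade,
   `r*_i,g = min{ r_im : g(m) = g }`. Inter-minus-intra differentials get
   weighted-bootstrap 95% CIs, and the inter-district tertiary premium is
   split into a passive baseline (the secondary-tier premium) and an active
   quality-seeking surplus.

Because operator signaling data cannot be redistributed, the package ships
a first-class synthetic generator: a city with districts and grade-biased
hospital placement, OD flows drawn from the decay law with grade attraction
and boundary friction, and a full month of hourly signaling pings with
known home/work anchors and planted hospital visits. A trajectory pipeline
(cleaning, >15-active-day resident filter, time-windowed DBSCAN anchors,
100 m on-site exclusion, ≥60 min in-window visit detection, most-recent
anchor origin assignment) turns pings back into visits, so every stage is
testable by ground-truth recovery.

## Worked example

```bash
flowscope run-all --seed 1 --out demo_out
```

runs the whole chain at desk scale (50 hospitals, 5 districts, 200,000
trips, B = 1000 null replicates; ~1 minute) and writes every intermediate
plus four report tables. Highlights of the output it prints:

```
flows: total_flow 200000, n_edges 2465

report_nulltest.csv (full scope)
 beta_hat   metric      observed  null_mean  obs_over_null  p_two_tailed
 1.974      node_gini   0.373     0.101      3.70           0.002
 1.974      top10_share 0.490     0.250      1.96           0.002
 1.974      edge_count  2465      2499.5     0.99           0.002

report_channels.csv
 channel n_edges  flow    mean_flow  theil  effective_edges  effective_ratio
 local   50       60572   1211.44    0.100  45.2             0.904
 intra   772      89476   115.90     0.771  357.2            0.463
 inter   1643     49952   30.40      0.845  705.5            0.429
```

Reading it: the generator plants grade attraction (1, 2, 6) and a 1.5×
boundary-friction penalty, so the observed network concentrates on
tertiary hospitals far beyond the fitted null (node Gini 0.373 vs null
mean 0.101, p = 0.002 — the smallest value reachable with B = 1000), and
the Theil gradient rises from local (0.100) through intra (0.771) to inter
(0.845): crossing scales concentrates flow onto fewer effective paths. The
nonlocal scope re-estimates a steeper β (2.12 vs 1.97) because same-unit
visits are excluded. In this synthetic city the within-grade choice is
purely distance-driven and tertiary hospitals sit near the centre, so the
inter-district tertiary premium (6.39 km) lands *below* the secondary
baseline (10.27 km) and the active component is reported as 0 with a
warning — unlike a real megacity, where quality-seeking pushes the
tertiary premium above the baseline.

Every command is also available stage by stage (`flowscope synth-city`,
`synth-log`, `synth-od`, `trajectories`, `impedance`, `build-network`,
`concentration`, `nulltest`, `channels`, `bypass`), and everything the CLI
does is a thin wrapper over importable functions.

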