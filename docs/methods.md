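# Methods

This note documents the models, parameter choices and numerical decisions
behind `reefplan`, in the order the pipeline runs them.

## Synthetic seascape

The generator produces a rectangular grid of planning units (default
20 × 20 cells of 10 × 10 km) with every layer the analysis consumes. It is
a statistical stand-in for a real regional dataset: it reproduces the
*structure* the method relies on, not any real geography.

* **Administrative units.** Provinces are contiguous row bands
  (`province = row · n_provinces ÷ n_rows`), each assigned to exactly one
  country. Row bands are the simplest partition that is contiguous and
  lets per-province statistics be non-trivial; nothing downstream assumes
  band geometry.
* **Habitats.** Each of the 11 habitat classes is an independent
  Gaussian-smoothed white-noise field thresholded at its 65th percentile;
  the positive excess becomes the per-cell habitat amount (km²), scaled so
  no cell's total exceeds 90% of its area. Smoothing guarantees positive
  neighbour correlation (tested as a Moran's-I-style check). Mangrove is
  confined to "coastal" cells, defined as grid-border cells — land is not
  modelled, and this minimal coastline suffices to exercise the
  coastal-fill logic of the climate downscaling and the mangrove cost
  component. Bioregions are quantile bins of one smoothed field, so each
  is non-empty and spatially coherent.
* **MPAs.** Small MPAs pick habitat-bearing cells (with replacement, so
  coverage can accumulate past the lock-in threshold) and protect a
  uniform 15–65% of the cell's habitat. Large MPAs are random contiguous
  blobs of 5–12 cells.
* **Turtle tracks.** Nesting (western-third reef cells) to foraging
  (eastern-third reef cells) correlated random walks: the heading blends
  persistence (0.55), attraction to a random foraging target (0.45) and
  Gaussian noise, stepping to the best-aligned 8-neighbour. Walks that
  fail to arrive within `6 (H + W)` steps are resampled, with a hard error
  after 8 attempts. How many tracks a real campaign yields is not
  knowable from structure alone; the default of 12 gives corridors that
  overlap enough for accumulation to matter.
* **Reef complexes and dispersal.** Reef cells are clustered into
  complexes by k-means on centroids (with a deterministic even-split
  fallback if a cluster comes out empty). Complex-to-complex flows decay
  exponentially with centroid distance and carry a directional bias from a
  prevailing current (factor `1 + 0.5 cos θ` with the current bearing);
  rows are normalized to a settlement fraction of 0.8, so entries are
  proportions of larvae and row sums stay below 1. The two species differ
  only in decay scale — 120 km ("trout", long-dispersing) versus 30 km
  ("cucumber", short-dispersing), a factor-4 contrast (the config rejects
  anything below 3).
* **Climate forcing.** One coarse cell per 5 × 5 planning cells emulates
  the half-degree-to-10-km scale gap. Monthly SST per cell, model run and
  year (1865–2050) = latitudinal base (≈27 °C ± 0.6) + seasonal cycle
  (±1.6 °C) + quadratic warming reaching +2.4 °C by 2050 + AR(1)
  interannual anomaly (σ = 0.35, ρ = 0.6) + monthly noise (σ = 0.25).
  Aragonite saturation declines linearly from ≈4.0 to ≈2.8 over
  1860–2050 with a static smoothed spatial offset. Coarse cells whose
  footprint touches the grid border are marked invalid — the analogue of
  a coarse land mask — and are filled during downscaling. Two SST runs
  are the default (configurable up to 8); the exceedance machinery is
  exercised at both 2-run and 8-run ensemble sizes in the tests.

What the generator does **not** emulate: real coastline geometry and
polygon MPA boundaries, species-specific turtle movement beyond labelled
random walks, hydrodynamic larval transport, GCM bias structure, and any
covariance between layers (e.g. fishing pressure tracking reef quality).
Passing tests therefore demonstrate the correctness and robustness of the
*method* under realistic statistical structure, not predictions for any
real region.

## Lock-in, cost

A cell is locked when cumulative small-MPA protection strictly exceeds 50%
of its habitat ("exceeded" read literally; the boundary case stays open).
Large MPAs lock `round(0.10 · n_members)` cells, never fewer than one, so
every large MPA contributes; rounding is half-up for determinism. The cost
index min–max rescales foregone fishing profit over reef cells and
population density over mangrove cells and adds them where the respective
habitat occurs, plus a uniform baseline of 0.01 so habitat-free cells are
never free padding. How the two components combine is genuinely open; the
additive form is the simplest strictly monotone choice, and only
monotonicity matters to the optimizer.

## Climate trajectory model

Degree heating months for a year are the maximum over the nine 4-month
windows inside the calendar year of the accumulated positive SST excess
over the warmest month of the 1985–2000 climatology (runs and reference
years averaged). Windows straddling calendar years are not formed — a
documented open choice; the in-year reading keeps DHM a per-year statistic.
Exceedance probabilities `P(DHM > x)`, x = 1..8 °C·month, pool all runs
over a trailing 10-year window (n = runs × 10; truncated early windows are
used and flagged rather than dropped).

Cover dynamics for branching and massive taxa sharing a substrate limit
K = 100%:

```
C_k(t+1) = C_k(t) + r_k · g · C_k(t) · (1 − C(t)/K) − m_k(t) · C_k(t)
g   = clamp(1 + α (Ω_ar − Ω_ref), 0, g_max) · clamp(1 − β max(0, SST − T_opt), 0, 1)
m_k = Σ_{x=1..8} μ_k(x) · [P(DHM > x) − P(DHM > x+1)]
```

The functional forms are this package's design (the qualitative contract
is growth modulated by temperature and aragonite, mortality by
bleaching): logistic growth with a multiplicative calcification/thermal
modifier, and *expected* (not sampled) bleaching mortality over DHM stress
classes, which keeps trajectories deterministic per forcing. Defaults:
branching r = 0.30, μ = 0.05…0.92 across classes; massive r = 0.12,
μ = 0.02…0.60 (faster growth, higher bleaching sensitivity for the
branching form); α = 0.30 per Ω unit, Ω_ref = 3.8, β = 0.15 per °C,
T_opt = 29.5 °C, g_max = 1.5. μ must lie in [0, 1], which together with
class probabilities summing to ≤ 1 guarantees a proper mortality
fraction. Cover starts at 30% in 1865 — split 15/15 between the taxa, an
unstated detail resolved symmetrically — and is clamped to
`0 ≤ C_P, C_M, C_P + C_M ≤ 100` at every step.

Degradation is `d = clamp((C_2010 − C_2030)/C_2010, 0, 1)` (0 where
present cover is 0), interpolated to planning-unit centroids with
piecewise-linear (bilinear) interpolation over valid coarse centres and
nearest-neighbour fill outside their convex hull; degenerate point sets
(fewer than 3 valid centres, or collinear) fall back to nearest-neighbour
everywhere. Reef amounts are multiplied by `1 − d`; other habitats are
untouched.

## Connectivity

Each turtle track is mapped to planning units, consecutive duplicates
collapsed, and consecutive distinct pairs emitted — the all-pairs
alternative would make a track's contribution quadratic in its length and
swamp the accumulation. "Standardized" is read as per-track normalization
to unit total (a config switch restores unit-weight-per-pair), so the
accumulated matrix's mass equals the number of pair-bearing tracks.
Turtle matrices are symmetrized (corridors are used in both directions);
larval matrices stay directed. Complex flows are disaggregated by reef
area: `CV_ij = L_AB (a_i/A_A)(a_j/A_B)` including i = j, which conserves
every pairwise complex flow exactly (tested to 1e−9). The penalty
`b Σ_{i∈R, j∉R} CV_ij` charges selected sources whose flow exits the
reserve; self-recruitment is kept in the matrix and never penalized. The
weight defaults to `b = 0.1 · (total cost) / (total CV mass)` so the
worst-case connectivity penalty is commensurate with, but does not
dominate, the cost term.

## Optimizer

The annealer starts from the locked units plus a random 30% of the rest,
proposes uniformly random single-unit flips (locked units are never
proposed), accepts improvements always and deteriorations with probability
`exp(−Δ/T)`, and cools geometrically over `min(10,000 · n_units, 10^6)`
iterations. The initial temperature is calibrated per run from 256 sampled
uphill move sizes to accept ≈80% of them; the final temperature accepts
<0.1%. Runs finish with greedy passes until no single flip improves, so
every returned solution is 1-flip locally optimal (asserted in tests). The
shortfall penalty is the proportional form `spf · shortfall/target` rather
than Marxan's representation-cost form; in the high-SPF regime used here
(default `spf = 10 · total cost / n_features`) both treat targets as
constraints. One consequence of the proportional form: a best solution can
sit a residual `ε < cheapest cost · T_f / spf_f` below a target — a
vanishing fraction of a continuous-amount target — which is why the
target-achievement tests allow a 0.1% relative tolerance. Per-run seeds
are `scenario_seed + run_index`. The inner loop is numba-compiled; with
the default schedule a 400-unit run takes ≈0.3 s, so a 100-run ensemble
solves in well under a minute.

## Benefits, hotspots, complementarity

Benefit = share of a province's eligible units with selection frequency
≥ 0.5 (inclusive at the boundary). Eligible units are those carrying at
least one conservation feature (a config switch uses all units); in the
synthetic seascape bioregion membership covers every cell, so the two
coincide there. Quartile and decile thresholds use the
linear-interpolation percentile over all provinces pooled regionally, with
inclusive (≥) comparisons so degenerate ties behave sensibly; hotspot
counts are therefore invariant under any strictly monotone per-objective
transform (tested). Clustering scales each objective column by its
maximum, uses Euclidean distances and average linkage (the linkage is a
free choice; average is robust to the small province counts used here),
and annotates each cluster with the objectives for which a member is
top-decile. The dendrogram exports as nested-list JSON and Newick.

## Problem sizes

The default study conditions are a 20 × 20 grid (400 planning units, 11
habitats, 7 bioregions, 6 provinces in 3 countries, 10 FSA sites, 12
tracks, 8 reef complexes, 2 SST runs), chosen so that a full six-objective
analysis with 100 runs per scenario completes in minutes on one core while
every statistic downstream of the optimizer (benefits, quartiles, deciles,
clustering) remains non-degenerate. Unit and property tests use a 12 × 12
seascape and hand-built toys; optimizer correctness is verified against
exhaustive enumeration on ≤ 12-unit instances, where the full subset
lattice is tractable. Full-scale counts remain reachable through the
config.

## Known limitations

* The trajectory model is a minimal two-taxon caricature: no size or age
  structure, no recovery lags after bleaching, no local stressors (by
  construction), and expected rather than stochastic mortality.
* The proportional shortfall penalty can leave the negligible
  sub-target residuals described above.
* Province geometry (row bands) makes spatial adjacency between provinces
  trivial; no inference should be drawn from inter-province distances in
  the synthetic maps.
* The annealer is a heuristic; optimality is only guaranteed empirically
  (and verified on small instances), not provably.
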