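# Methods

## The index

The population bioturbation potential of species *i* at a station is
`BP_p = (B_i/A_i)^0.5 · A_i · M_i · R_i`, with abundance `A_i` (individuals
per 0.1 m² Van Veen grab), station wet biomass `B_i` (g per 0.1 m²), mobility
score `M_i` (1 = fixed tubes … 4 = free movement via burrows) and reworking
score `R_i` (1 = epifauna … 5 = regenerators). We interpret `B_i` as **total
station biomass** (mean individual wet mass × abundance), so `(B/A)^0.5` is
the square root of mean individual mass. Surveys often record mean individual
mass rather than station totals, and this reading keeps the index linear in
abundance; it is the one genuinely open interpretive choice in the formula.
`BP_p` is log10(x+1)-transformed at station level *before* regression, and
model predictions are treated as already log-scaled: `BP_t` is the sum of the
transformed per-species surfaces with no back-transform. Trait scores are
per-species constants.

## Step 1 — occurrence models

Presence/absence at the 284 stations is modelled with pluggable algorithm
adapters over scikit-learn: logistic regression without penalty (GLM),
gradient boosting (GBM: 250 trees, learning rate 0.05, depth 3 — moderate
boosting that fits in seconds on a few hundred stations), and random forest
(RF: 500 trees, `nodesize` 1, `mtry` tuned over {2, 3, 4, 5} by the replicate
mean of (AUC+TSS)/2, ties to the smallest). No MARS implementation is
available in the dependency set; the algorithm slot exists and is skipped
with a logged notice — the pipeline is designed to drop algorithms per
species anyway (a species may end up consensus-of-three or ensemble-of-one).

Each replicate uses an independent **stratified** 70/30 split (stratification
preserves prevalence; plain random splits would occasionally starve the test
set of presences at low prevalence). AUC is the rank-based Mann–Whitney
statistic with ties credited 0.5. TSS = sensitivity + specificity − 1 is
computed at the cut-off maximising TSS on the held-out scores, since a
per-replicate cut-off rule is otherwise undefined. Replicates are robust when
AUC ≥ 0.7 and TSS ≥ 0.4.

The consensus surface is the weighted mean over all robust runs of all
algorithms with weights proportional to the evaluation score (TSS by
default), floored at 0 and normalised to 1 — proportionality is the simplest
faithful reading of "evaluation-weighted", with no decay exponent. AUC is
threshold-free, so the operational map cut-off criterion is TSS
maximisation: candidates are the midpoints between consecutive distinct
consensus scores at the stations, ties resolved to the smallest cut-off, and
binarisation uses `probability ≥ cutoff`. The same fitted runs are projected
onto each scenario year's layers (space-for-time transfer); the cut-off is
estimated once at the baseline year and applied to all years.

## Step 2 — BP regression and the hurdle

Per species, a random-forest regression (500 trees, predictor subset
⌈p/3⌉ = 3 of 8, minimum leaf size 20) of station `bp_log` on the seven
environmental layers plus the step-1 consensus probability. The response is
zero-inflated and noisy — most stations contribute a structural zero — so a
relatively large leaf (≈7% of the 284 rows) is used to smooth the forest's
conditional-mean estimate; small leaves chase sampling noise in the nonzero
tail. Rows are canonically sorted before fitting so predictions are invariant
to input row order at a given seed.

Cross-validation stratifies folds on zero/nonzero response (the motivation
for the 6-fold fallback is keeping ~5 nonzero rows per fold): 10 folds at
≥ 50 presences, 6 below, and below 12 presences a species is flagged
unmodellable. MAE and RMSE are pooled over held-out rows; their percent
versions divide by the station mean of observed `bp_log`, the only mean
available before projection. Variable importance is permutation-based
(mean increase in squared error over 5 permutations of one column, floored at
0, normalised to sum 100) — implementation-independent, unlike impurity-based
importances.

Predicted surfaces are masked with the binary occurrence map: BP is kept
where presence is predicted and set to 0 where absence is predicted (hurdle /
zero-inflated approach, preventing over-projection). The zero-inflation
identity — no cell with BP > 0 and binary = 0 — holds exactly by
construction and is asserted across every species and year.

## Scenario analysis

Totals are plain sums of log-scaled cell values over the analysis region
(cells are near-equal-area at these extents; no area weighting). Gain/loss
is `100·(total_year − total_baseline)/total_baseline` with the baseline year
at 100%; a zero baseline yields an explicit null, never ±infinity. The
"southern" sub-region is a latitude cut-off (a config parameter; 53° N for
the synthetic grid, i.e. its southern half). Contribution shares are
per-species percentages of regional `BP_t` and are scale-invariant. The
BP-weighted latitude centroid summarises range shifts: warming past a
species' thermal optimum moves it poleward.

## The synthetic world

The generator emulates the study system at desk scale so the pipeline can be
validated against known truth:

- **Grid**: 40 × 50 cells at 0.1°, lon 2–7° E, lat 51–55° N, with a
  deterministic coastal land block (~8% of cells). Small enough that a full
  run takes a few minutes on one CPU.
- **Environment**: June/February bottom temperature with a latitudinal
  gradient (warmer south: 10→17 °C June) plus seeded smooth noise; June
  salinity, depth, mud content, median grain size and peak wave stress as
  correlated smooth static fields. Scenario year *k* adds a spatially smooth
  delta whose spatial mean over sea cells is exactly *k*·warming
  (default 1.5 °C per step, i.e. +3 °C by the second step — inside the
  projected range for shelf-sea bottom water) and −*k*·freshening (default
  0.85 per step).
- **Species**: three virtual species with multiplicative Gaussian niches in
  June temperature (optima 11.0 / 16.5 / 13.5 °C, σ = 1.5 °C), salinity,
  depth and mud — a cold-optimum species that warming pushes poleward, a
  warm-optimum species that expands, and an intermediate one. σ = 1.5 °C
  makes the suitability fields spatially structured (near-0/near-1 over most
  of the domain) while keeping 55–90 sampled presences per species out of
  284 stations, mirroring the prevalence range of real surveys.
- **Survey**: 284 stations uniform without replacement over sea cells;
  presence ~ Bernoulli(p); abundance given presence ~ 1 + NegBin(mean
  λ_max·p, dispersion k = 5 — moderate overdispersion typical of benthic
  counts); biomass is the species' fixed mean individual mass.
- **Truth**: the true expected BP per cell uses the *unconditional* expected
  abundance of the survey process, A = p·(1 + λ_max·p), passed through the BP
  formula and log transform; it is exactly 0 where p = 0.

One global seed fans out to per-stage/per-species child seeds by CRC32
hashing, so adding a species never perturbs another's random streams, and
the whole pipeline is bit-reproducible at a fixed seed.

What the generator does **not** emulate: spatially structured survey designs,
stratified water masses or localized cooling, species interactions,
ontogenetic trait variation, observation error in biomass, and real coastline
geometry. Passing recovery tests therefore demonstrates the pipeline's
statistical correctness under its own assumptions, not predictive skill on
real survey data.

## Numerical choices and degenerate inputs

- Missing values: IEEE NaN in memory, explicit nodata on disk (−1 for the
  integer binary band); land cells never acquire values through I/O.
- Station-to-cell assignment: nearest cell centre; stations on land-masked
  cells are rejected with an actionable error.
- Grid comparisons tolerate half a cell on each edge; cut-offs must lie in
  (0, 1); single-class label vectors are errors for AUC/TSS/cut-off search.
- Replicates whose held-out scores are all identical get TSS 0 (no skill)
  rather than an error.
- If every permutation importance is zero (uninformative model) the profile
  is reported flat rather than undefined.

## Problem sizes

The default validation run uses the full study design where it is cheap
(3 species × 3 algorithms × 20 replicates, plus 4 × 20 tuning replicates for
RF) on the 40 × 50 grid — about 3–4 minutes on one CPU. The acceptance
script adds a determinism rerun and a two-year single-species warming
scenario; unit tests use a 20 × 20 world. Typical recovered correlations at
the baseline year are r ≈ 0.86–0.96 between consensus and true occurrence
probability and r ≈ 0.68–0.79 between the final masked BP and the true
expected BP across seeds; the masked correlation is structurally bounded
(≈0.82–0.85 even for an oracle regressor) by the hard zero mask against a
smooth truth field.

## Known limitations

- `BP_t` sums log-scaled BP_p, following the stated pipeline order
  (transform before modelling); summing raw BP would weight large
  populations far more heavily.
- The consensus weighting function and the per-replicate TSS cut-off rule
  are interpretations where the design is verbally specified; both are
  config knobs.
- Percent MAE/RMSE denominators use the station mean of observed log BP;
  other denominators (per-cell means of predictions) would change the
  percentages but not the models.
- Only WGS84 lon/lat grids are supported; no reprojection.
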