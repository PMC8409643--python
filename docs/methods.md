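# Methods

This note documents the models and procedures implemented in `growrisk`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## Problem setting

The package estimates where illegal ("trespass") cannabis cultivation sites
are likely to occur across a forested landscape, from presence-only law
enforcement discovery records and gridded environmental predictors. The
output is a continuous relative-likelihood surface, classified into low /
moderate / high risk, summarized by watershed units, validated against
stream-walking surveys and independent localities, and intersected with
wildlife habitat layers and telemetry-based home ranges.

All analysis happens on one projected grid (meters; 90 m cells by default).
Rasters are stored as ESRI ASCII grids with a JSON sidecar carrying the CRS
identifier; vectors as GeoJSON; localities as CSV. Cells are addressed
row/col with values at cell centers; points are assigned to cells by
half-open intervals; areas are planar (`n_cells * cell_size^2`).

## Maximum-entropy model

The core is a presence-background maximum-entropy (Gibbs) model written
from scratch. Over background locations `i` with feature vectors `f_i`, the
model is `q(i) = exp(lambda . f_i) / Z`. Fitting maximizes the penalized
presence log-likelihood

    mean_p(lambda . f) - log mean_bg exp(lambda . f) - sum_j beta_j |lambda_j|

which is concave; at the optimum `|E_q[f_j] - mean_p[f_j]| <= beta_j` for
every feature (the KKT box, verified in the tests on every fit).

**Features.** Linear, quadratic, pairwise-product, and hinge transforms of
the predictors. Variables are clamped to their training range and scaled to
[0, 1]; every feature column is then rescaled to [0, 1] by its own training
bounds, and projection-time inputs are clamped into that range. Hinge knots
(50 per variable per direction by default) sit at evenly spaced quantiles
of the background sample. Modes: `auto` (all four types), `lqp`
(linear/quadratic/product), `hinge`, plus a diagnostic `linear` mode used
in tests. Threshold and categorical features are omitted: only the three
modes above are tuned, and hinge features subsume thresholds in modern
practice.

**Regularization.** `beta_j = r * c(class, m) * s_j / sqrt(m)` with `m`
presences, `s_j` the presence-sample standard deviation of the feature, and
`c` the standard per-class schedule (piecewise-linear in `m` through
(10, 1.0), (17, 0.6), (30, 0.5), (100, 0.05) for linear/quadratic/product;
0.5 for hinge). `s_j` is floored at 0.01 so no feature is entirely
unpenalized. The user-facing multiplier `r` defaults to 1.

**Solver.** The L1 objective is solved by L-BFGS-B on the standard split
`lambda = a - b`, `a, b >= 0`, which handles the penalty exactly and
returns exact zeros for inactive features. Convergence: projected gradient
below 1e-5 or 500 iterations (the iteration cap mirrors the cited tool's
default; a non-converged fit warns and returns the best iterate).
Coefficients are bounded at |lambda| <= 1e3 purely as an overflow guard —
useful weights for [0, 1] features are orders of magnitude smaller.

**Outputs.** *Raw*: the Gibbs probability normalized to sum to one over the
training background. *Logistic*: `e^H q / (1 + e^H q)` with `H` the entropy
of the fitted distribution (the fixed-prevalence form with tau = 0.5),
computed as `expit(H + ln q)` for overflow safety; a uniform model maps to
0.5 everywhere. Cumulative and cloglog outputs are out of scope.

## Data preparation

- **Thinning** (2000 m): greedy most-crowded-first removal with seeded
  tie-breaks, followed by a re-add pass so the kept set is maximal. Pairs at
  exactly the thinning distance are allowed. Verified against brute-force
  maximum feasible subsets at small n.
- **Background** (10,000 default; 2,000 in the desk preset): uniform over
  eligible cells, with replacement, jittered within cells; deliberately not
  thinned and not excluded at presence cells.
- **Focal averaging** (450 m radius): circular window over cell centers,
  nodata excluded, truncated at edges. Applied to every predictor before
  extraction, approximating the positional footprint of the locality data.
- **Folds**: a random partition of presences into 10 near-equal folds; each
  fold serves once as the 10% test split (the 90/10 split is realized *by*
  the cross-validation, one reading of an ambiguous protocol, recorded here).

## Variable selection and tuning

1. **Correlation grouping**: Pearson |r| > 0.7 (strict) over pooled
   presence + background rows; groups are connected components of the edge
   graph. One winner per group by mean univariate CV test AUC under default
   settings (auto features, multiplier 1), ties lexicographic.
2. **Stepwise jackknife**: repeatedly drop the variable whose omission
   yields the highest mean test AUC; stop when every removal strictly hurts;
   retain the best state visited. Refits reuse the same folds and the same
   per-fold feature definitions (one master expansion per fold, column
   subsets per candidate set), so AUC differences reflect variables, not
   re-derived features or fold noise. Warm starts from the superset solution
   speed up the solves without changing optima.
3. **AICc tuning**: all 3 feature modes x 6 multipliers (0.5, 1, 1.5, 2, 3,
   5) fitted on the full training data; raw output standardized over the
   projection grid; `LL = sum ln p` at presence cells; `K` = nonzero
   weights; `AICc = 2K - 2LL + 2K(K+1)/(n-K-1)`, invalid when `K >= n-1`.
   Winner = minimum AICc; ties prefer the larger multiplier, then the
   simpler mode (lqp < hinge < auto). Order of operations: prune, then tune,
   then refit at the tuned settings.
4. **Importance**: *percent contribution* attributes per-update objective
   gains of a cyclic coordinate-descent pass (from zero, stopping near the
   reference optimum) to each feature's source variable (products split
   evenly); it is path-dependent and approximate by construction, but
   seed-stable. *Permutation importance* is the drop in training AUC after
   permuting one variable across presence + background rows (one seeded
   permutation), floored at zero; both columns are normalized to 100.
5. **Response curves**: the logistic output of a model trained on one
   variable alone, evaluated on an even grid over its training bounds.
   `response_band_center` summarizes a curve by the midpoint of the
   half-maximum interval around the main peak — for flat-topped responses
   the argmax sits on a plateau edge (background density is higher mid-band),
   while the main-lobe midpoint recovers the band center and ignores
   spurious lobes in data-sparse tails.

## Risk classification (Boyce index)

Sliding windows of width 0.1 (101 positions) over [0, 1]: `P` = share of
evaluation presences in the window, `E` = share of the valid landscape;
windows with `E = 0` are dropped. The Boyce index is the Spearman
correlation of P/E with the window midpoint. Class thresholds default to
the lowest suitability from which the P/E curve *stays* at or above 1
(low/moderate: presences occur at least at the availability rate) and 2
(moderate/high) — the "stays above" rule uses the last upcrossing to guard
against noisy curves, and trailing windows containing cells but no
evaluation presences are ignored (with a small evaluation sample such
windows are uninformative and would otherwise veto every threshold); both
thresholds can be overridden, and the choice is recorded in the map
metadata. The P/E = 1 cut is the standard boundary in
the Boyce methodology; the P/E = 2 cut is a documented free parameter.
Evaluation presences default to the thinned presence set (each point is
held out exactly once across folds) scored on the final surface.

## Validation statistics

Survey selection accumulates randomly drawn reaches — plus all same-named
reaches in the drawn reach's sub-watershed — until 1% of network length is
covered. Surveyed kilometers are apportioned to risk classes by line/cell
intersection length (not reach midpoints), matching the stream-km-weighted
expectation `E_c = (km_c / km_total) * N` of the observed-vs-expected
chi-square (df = surveyed classes - 1, continuous p-value). Independent
locality sets get per-class counts/percentages (integer percents for
reporting, raw fractions retained) and, for sites outside the high class,
Euclidean distances to the nearest high cell center (0 inside).

## Space-use overlap

Habitat overlap is the percent of suitable habitat cells in moderate-high
risk. Home ranges use the adaptive local convex hull (a-LoCoH): per
location, a hull over the nearest neighbors added while their cumulative
distance stays within `a` (default: the animal's maximum pairwise location
distance — the standard heuristic, logged per animal and overridable);
hulls sorted by ascending area are unioned until the isopleth fraction
(95%) of locations is covered. Animals need more than 25 locations.
Duplicate coordinates collapse geometrically but count with multiplicity.
Overlap is measured on the rasterized range (cell-center rule) for
consistency with every other raster statistic. Note a known granularity
effect: for uniform locations on a square, boundary hulls are the largest,
sort last, and are cut at the isopleth, so the union trims an edge margin
and its area sits noticeably below the occupied square.

## Synthetic landscapes

Real locality data and GIS sources are not public, so every stage is
exercised on generated landscapes. Predictor fields are Gaussian-kernel-
smoothed white noise with per-layer correlation lengths (elevation 720 m;
vegetation ~900 m; climate ~3.6 km); percent slope is derived from the
elevation field by central differences; distance layers come from generated
streams, roads, private-land and disturbance masks via distance transforms;
a greenness layer is built collinear with canopy (r ~ 0.85) so the
correlation-grouping stage has real work to do.

The true selection surface is the inverse logit of band responses on
elevation (center 1200 m, width 800 m) and slope (center 45%, width 30%)
plus weaker water-proximity and canopy terms. The preset uses flat-topped
bands (exponent 10) with a large in-band/out-of-band contrast (weights 10,
intercept -15), making the suitable region near-binary and covering roughly
a quarter of the extent — matching the strong selectivity of the published
classification, where moderate + high classes cover ~27% of the extent. Two
scale interactions drove this design and are worth knowing about: (i) on an
18 x 18 km desk-scale landscape, 2000 m thinning keeps only ~40-50 of 500
presences, and every isolated low-suitability straggler survives thinning,
so a diffuse truth destroys discrimination; (ii) a short elevation
correlation length fragments the suitable region into patches spread across
the extent, letting thinned presences remain both far apart and in-region.
Presence sampling is proportional to suitability times a detection-bias
surface (a smoothed density of previously "found" sites, mixed
multiplicatively; `bias_strength` is a free simulation knob, not an
estimate). Streams are random monotone lattice paths split into named
reaches within strip-shaped sub-watershed units; grow plots are planted
near streams (within 300 m) proportionally to suitability; habitat layers
come from interval rules on predictors; telemetry is per-animal isotropic
bivariate normal scatter truncated to the grid.

What the generator does *not* emulate: real hydrology and terrain
morphology, temporally varying disturbance, observer-specific detection
models, and telemetry error. Passing tests therefore demonstrate that the
procedures are implemented correctly and behave as expected under known
structure — not that the fitted models would achieve the same performance
on real landscapes.

## Problem sizes and defaults

The desk preset runs the full pipeline on a 200 x 200 grid (90 m cells),
500 presence draws, and 2,000 background points; all procedure parameters
keep their published defaults (2000 m thinning, 450 m focal radius, 10
folds, 500 optimizer iterations, |r| > 0.7, the six multipliers and three
feature modes, 95% isopleths, > 25 locations). With the preset truth this
yields ~40-50 thinned presences, a tuned model with mean 10-fold test AUC
~0.85, a Boyce index > 0.9, and slope/elevation dominating both importance
columns. Unit tests use smaller grids and fewer hinge knots where only the
mechanism is under test.

## Known limitations

- Percent contribution is optimizer-path-dependent (as in the cited
  lineage of tools) and should be read comparatively, not absolutely.
- The AICc `K` counts nonzero weights, which depends on solver tolerance
  near zero (threshold 1e-10 after exact-zero L-BFGS-B bounds).
- Reprojection is out of scope: all inputs must share one projected CRS.
- Survey-km apportionment assumes reaches are polylines on the analysis
  grid's CRS; 3D geometries are not handled.
- With very small thinned sample sizes (a handful of presences per fold),
  per-fold test AUC is high-variance; the mean over folds is the stable
  quantity.
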