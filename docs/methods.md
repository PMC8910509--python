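# Methods

This note documents the models implemented in `esvpipe`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Units and vocabulary

Internal monetary unit is the yuan and internal area unit the hectare (hm²);
1 km² = 100 hm². Conversion to billions happens only in reports. Land
classes are fixed as CL=1 (cultivated), WO=2 (forest), GL=3 (grass), WA=4
(water), CO=5 (construction), UL=6 (unused), WL=7 (wetland); the nine
service functions are FP, RM, GR, CR, WS, WD, SFR, BD, EC. Rasters are
row-major integer grids, origin top-left, nodata = 0; zone maps must share
the grid exactly — there is deliberately no on-the-fly resampling.

## Land-use accounting

`reclassify` maps raw survey codes onto the 7-class scheme through an
editable CSV (the shipped default follows the standard first-digit
convention of the Chinese national land-use survey, with swamp/marsh and
flat codes assigned to wetland rather than unused land). The mapping must
cover every observed code; partial mappings fail loudly with the full list
of offenders.

`tabulate_areas` cross-tabulates class × zone cell counts × cell area and
stores explicit zeros for absent (zone, class) pairs so later joins never
silently drop classes. `transitions` is the cellwise two-year
cross-tabulation; its row and column marginals equal the single-year area
tables by construction, which the tests assert.

The dynamic degree is K = (Lb − La)/max(La, floor) · (1/H) · 100 in percent
per year. The floor defaults to 100 hm² (1 km²): a class absent at the
period start is treated as having occupied one cell, which keeps K finite
and reproduces the convention used for vanishing classes in the source
tables. Both areas must be non-negative and H positive.

## Valuation

Coefficients are stored as a 7 × 9 matrix in yuan/hm² together with the
standard equivalent Eb; equivalence factors are recovered as values/Eb. The
construction-land row is identically zero (an explicit modeling assignment,
enforced as an invariant). The vendored matrix uses Eb = 1793.88 yuan/hm².
`standard_equivalent` exists for users with their own crop statistics
(shares must sum to 1 within 1%); the crop shares and profits behind the
vendored Eb are not public, so Eb is a configured constant rather than a
derived one.

`compute_esv` is the bilinear map area × coefficient; `infer_areas` inverts
it per (year, zone, class) using the function with the largest monetary
value — the most rounding-robust choice when inverting published tables
printed to three decimals of a billion — and skips classes with all-zero
coefficient rows with a warning. On computed tables the round-trip is exact
to machine precision.

Published-table summaries report multi-year class shares as the unweighted
mean of annual shares; this convention reproduces the printed 44.65 / 32.13
/ 17.11 / 5.52% class shares, where weighting by year totals would not.
Tiny published cells (< 0.02 billion yuan) are excluded from round-trip
consistency checks: at three printed decimals their rounding error alone
exceeds the 1% tolerance the larger cells meet.

One naming note: the published narrative uses "water conservation /
containment" for the function the coefficient table labels water supply
(WS); the two are treated as the same function. The back-computed
period change of WS (+1.77 billion yuan) matches the narrated water-
conservation change exactly, supporting the identification.

## Human impact index

HAI is the area-weighted mean of the per-class disturbance coefficients
Pi = {CL 0.67, WO 0.13, GL 0.10, WA 0.12, CO 0.96, UL 0.05, WL 0.15}
(Delphi-elicited inputs; their derivation is out of scope). TA is the
zone's *classified* area (nodata excluded), not a nominal administrative
area, which guarantees HAI ∈ [min Pi, max Pi]. Band boundaries follow the
printed inequalities: high iff HAI > 0.5, medium iff 0.35 ≤ HAI ≤ 0.5 (both
boundaries medium), low iff HAI < 0.35.

## Driver attribution

The driver table has one row per (zone, year) with the fixed feature order
HAI, GPP, Slope, DEM, POP, Temp, GDP, Pre, PM and the zone's total ESV as
response. Years are pooled into a single model by default (with ~30–60
zones and four years, per-year fits are data-starved); a per-year fit is a
matter of filtering the table.

The ensemble is XGBoost (squared error) with fixed, recorded
hyperparameters: 200 trees, depth 3, learning rate 0.1, L2 regularization
1.0, no subsampling, single-threaded, base score set to the response mean.
These are conventional small-n tabular settings chosen for full
determinism: refitting with the same seed is bit-identical. The fitted
booster is extracted into plain arrays (split feature, float32 threshold,
children, leaf value), and all prediction and attribution downstream runs on
that self-contained representation; a test confirms the extracted trees
reproduce XGBoost's own predictions.

### Shapley values

Attribution uses the *interventional* convention with the training table as
background distribution: the value of a feature subset S at instance x is
v(S) = E_z[f(x_S, z_S̄)] over background rows z. For a tree ensemble and a
single background row this game is solved exactly by enumerating leaf
paths: a leaf whose path requires feature set A to follow x and B to follow
z is a unanimity-style game value·1[A ⊆ S, B ∩ S = ∅] with closed-form
Shapley values value·(|A|−1)!|B|!/(|A|+|B|)! for A-members and
−value·|A|!(|B|−1)!/(|A|+|B|)! for B-members; features routing identically
are null players. Averaging over the background gives the exact
interventional Shapley values, so local accuracy, dummy and symmetry hold
up to float round-off — no sampling approximation is involved.

The classical subset-enumeration computation (cost 2^N, capped at N = 15)
ships as `brute_force_shapley` and serves as the independent oracle; the
path algorithm matches it to ~1e-15 in tests. Pairwise Shapley interaction
values use the standard discrete-derivative subset sum, with half the
interaction index on each off-diagonal (symmetric) and the main effect on
the diagonal, so interaction rows sum to the per-feature Shapley values.

Importance is the mean absolute Shapley value across instances, sorted
descending with ties broken by the fixed column order. Dependence tables
export per-instance (feature value, φ, color value) triples, colored by HAI
by default, to expose synergies such as a productivity effect that changes
with disturbance intensity.

## Synthetic data generator

The generator emulates the study's data layout, not its geography: a
7-class 1 km² raster series over contiguous county-like zones with
year-to-year Markov transitions, plus zone-averaged driver covariates.

* **Composition.** Default proportions CL 0.42, WO 0.35, GL 0.02, WA 0.09,
  CO 0.035, UL 0.005, WL 0.08 — a lake-plain agricultural mix dominated by
  cropland and forest, with construction and unused land small but nonzero
  so the dynamic-degree floor path is exercised.
* **Dynamics.** One row-stochastic kernel application per listed year, with
  cropland↔forest exchange dominant and smaller cropland→construction,
  water↔wetland and →unused flows mirroring the qualitative flow structure
  of the study region. The listed years are treated as consecutive Markov
  steps; calendar gaps are not compounded.
* **Zones.** Nearest-seed-point (Voronoi-on-grid) partitions: contiguous,
  deterministic, label set exactly 1..n_zones. Default 33 zones (the
  county count of the study region); the recovery experiments use 60.
* **Drivers.** Each driver is base + land-cover links (linear in zone class
  fractions) + a spatially autocorrelated surface (white noise smoothed
  with a Gaussian kernel, unit variance, scaled) + optional planar gradient
  + zone-level iid noise. Slope is derived from the DEM surface by finite
  differences *before* zonal averaging. Smoothing widths are kept at the
  county scale (σ = 4 cells): wider fields collapse to a handful of
  effective degrees of freedom across zones, which makes drivers
  near-collinear by chance and attribution rankings degenerate. GPP links
  positively to forest/cropland/wetland cover, POP and GDP to construction
  cover, Temp and Pre carry gradients, and PM2.5 links to nothing — it is
  the designed irrelevant control.
* **Planted response.** For ground-truth experiments the response is linear
  in z-scored drivers with a dominant HAI coefficient (−6), moderate GPP
  (+2), small remaining terms (+0.5), no PM term, optional pairwise
  interaction terms, and iid Gaussian noise (sd 0.5). Everything is a pure
  function of the scenario seed.

What passing synthetic tests shows: the accounting, valuation, index and
attribution machinery is correct, deterministic, and able to recover a
planted dominant driver and flag an irrelevant one under realistic
correlation structure. What it does not show: anything about the real
rasters (not shipped), real spatial autocorrelation, measurement error in
the driver products, or the actual driver ranking of the study region.

## Numerical choices and degenerate inputs

* Thresholds from the fitted booster are kept in float32 and inputs are
  cast to float32 for routing, so extracted-tree predictions replicate
  XGBoost's decisions exactly; accumulation is float64.
* Monetary values are never rounded internally; reports round to 2 decimals
  of a billion and HAI to 4 decimals.
* Zero-area zones are skipped (with a warning) in HAI; all-zero coefficient
  rows are skipped (with a warning) in area inversion; empty attribution
  matrices and constant models are handled (all-zero φ, column-order
  ranking).
* The brute-force oracle refuses more than 15 features (2^N cost).
* Grids below 2×2, non-stochastic kernels, non-summing proportions and
  unknown driver names are rejected at scenario construction.

## Experiment sizes

The planted-recovery experiment runs 100 independent scenarios at 60 zones
with 100-tree fits — enough for a two-sided binomial check of the ≥90%
recovery criterion while keeping the whole suite at a few minutes on one
CPU; at 200 trees the measured recovery rates were indistinguishable. The
Shapley oracle comparison uses 20 instances against a 60-row background,
which already exercises every code path of the closed-form algorithm.

## Known limitations

* No monetary deflation across years (the valuation uses one constant-year
  standard equivalent), and no re-derivation of the disturbance
  coefficients or crop statistics behind Eb.
* The unused-land class has nonzero coefficients but no published value
  rows; district totals are defined over the five published classes, so a
  (tiny) unused-land contribution is omitted by construction.
* Raster I/O is plain single-band TIFF without georeferencing tags; zone
  alignment is by array shape, and vector (shapefile) zone ingestion is out
  of scope.
* The interventional background is the training table; other backgrounds
  (e.g. per-year) change the attributions, as they do for any Shapley
  explanation.
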