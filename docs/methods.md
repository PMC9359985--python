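# Methods

## Scope and design

`sdmtransfer` re-creates, as a tested pipeline, the workflow of a
regional presence–background distribution study with a spatial
transferability assessment. Real winter-survey carnivore locations of
the kind such studies use are access-restricted, so the package pairs
the modeling code with a virtual-species generator: every claim the
test suite makes about recovery or transfer is checked against a known
generating process, not against irreproducible field data.

## Data model

Rasters are square-celled grids on a projected plane in km, with an
authoritative boolean validity mask (nodata). Internally row 0 is the
southernmost row; ESRI ASCII and GeoTIFF files use north-up order and
are flipped on I/O. Point-to-cell lookup is half-open
(`col = floor((x − x0)/cell)`), so a point on a cell's left/lower edge
belongs to that cell. ASCII round-trips are value-exact (floats written
as `repr`); GeoTIFF round-trips are exact within float32. GeoTIFF
georeferencing is carried by the pixel-scale and tiepoint tags plus the
GDAL nodata tag; reprojection between coordinate systems is out of
scope.

## Occurrence handling

* **Thinning.** One point per 1-km cell (uniformly random within the
  cell, seeded), then optionally a minimum-distance filter: points are
  visited in seeded random order and kept iff ≥ d_min from every point
  already kept (greedy approximate maximum independent set, the
  spThin-style convention). The pipeline can fit both thinned datasets
  and report the Pearson correlation of the resulting maps.
* **Background.** n points drawn uniformly over valid cells (optionally
  one region only), cells may repeat by default, each draw jittered
  uniformly within its cell. A no-duplicate-cell policy is a flag and
  errors when n exceeds the available cells.
* **Balancing.** Presences get weight 1, background rows weight
  n_p/n_b, so class weight totals are equal (prevalence 0.5). Rows with
  any missing covariate are dropped and counted.
* **Regional balancing.** For transfer comparisons every region is
  subsampled (seeded, uniform) to the smallest region's count.

## Base algorithms

All four native algorithms share a fit/predict contract mapping
covariate vectors to [0, 1].

* **GLM.** Weighted-likelihood logistic regression by IRLS on
  standardized covariates (back-transformed afterwards), linear +
  quadratic terms per variable by default; zero-variance expanded
  columns are excluded. Convergence: relative deviance change ≤ 1e−10.
  Quasi-complete separation is detected as diverging standardized
  coefficients (in-loop bound 30; post-hoc bound 15) and flagged with a
  warning; the fit is still returned.
* **SRE.** Per-variable envelope = [α, 1−α] empirical quantiles of the
  presence values only, α = 0.025, linear-interpolation quantile rule
  (fixed for reproducibility); prediction 1 iff all variables lie
  inside (bounds inclusive).
* **CTA.** Recursive binary partitioning minimizing weighted Gini
  impurity; candidate thresholds are midpoints between consecutive
  distinct sorted values, scanned exactly via cumulative sums (weighted
  Gini for a binary target is an affine function of the weighted
  least-squares split criterion, so one exact scan serves both CTA and
  GBM). Ties: lowest variable index, then lowest threshold. Leaves
  predict the weighted presence fraction. Defaults: max depth 8,
  minimum node weight 1.
* **GBM.** Stagewise boosting on the weighted logistic deviance:
  depth-2 regression trees fit to the gradient residuals y − p, leaf
  values by a single Newton step, learning rate 0.1, 250 trees. The
  initial score is the logit of the weighted prevalence. Training
  deviance is recorded per stage and is non-increasing. 250 trees
  (rather than a larger count) is the package default because held-out
  skill is indistinguishable at these data sizes while fits are twice
  as fast; it is configurable.
* **Adapters.** Random forest, GAM, MaxEnt, FDA and the like enter the
  ensemble through `ModelAdapter` (fit: design → object; predict:
  object, X → [0,1]); the adapter contract is enforced at predict time.

## Evaluation

Cross-validation is three repeated seeded stratified 80/20 splits (not
a three-way partition): the stated 80/20 ratio forces the
repeated-split reading, which is also the biomod2 `NbRunEval`
convention. AUC follows the pairwise-probability definition with ties
counted ½, computed from midranks (exactly equal to the brute-force
count). A presence is classified present at score ≥ τ (inclusive, so
τ = max score still classifies that presence correctly); specificity
counts background scores < τ; TSS = sens + spec − 1 is an exact
identity. The optimized threshold scans the unique pooled scores and
takes the smallest maximizer, provably equivalent to an exhaustive
scan. Permutation importance is the mean over reps (default 5) of
1 − Pearson r between original and column-permuted predictions,
clamped at 0 (1 − r can leave [0, 1] for anticorrelated predictions);
a variable absent from a model scores exactly 0, and constant
predictions define importance 0. Response curves sweep the focal
variable over its observed calibration range with the other variables
held at their calibration medians (median, not mean: the distance
covariates are strongly right-skewed).

## Ensemble

Every (algorithm × CV run) fit is a member weighted by its held-out
metric above the no-skill floor (0.5 for ROC, 0 for TSS):
`w_i ∝ max(score_i − baseline, 0)`. Subtracting the floor keeps
near-random members from receiving near-half weight. The ensemble map
is the weighted cellwise average (nodata in any member propagates); the
committee map is the fraction of members voting present at their own
calibration thresholds; the ensemble threshold is re-optimized on the
ensemble's calibration scores (not averaged from member thresholds).
The weighting metric defaults to ROC and is configurable.

## Transferability

Scheme runs fit the full ensemble pipeline on one region's (balanced)
presences, with background either region-wide ("state
cross-validation") or focal-only ("extrapolation"), and predict the
entire domain. Validation uses the non-focal regions' presences against
a fresh region-wide background sample shared across all six runs (so
validation ROCs are comparable); validation sensitivity uses each run's
own calibration threshold, since it is a property of that model.
Map similarity to the all-region model: Spearman over all jointly valid
cells (midranks; no subsampling — grids at this scale make it cheap),
Schoener's D and Hellinger-based I on cell-normalized surfaces. D and I
are symmetric and invariant to positive rescaling of either map; no
ordering between D and I is assumed.

## Virtual-species generator

Covariate fields are moving-average-smoothed uniform noise (kernel 9
cells) plus deterministic gradients — spatially autocorrelated without
heavyweight geostatistics. The natural-cover field is contrast-stretched
(clipped linear stretch of the central noise range) because real
cover-proportion maps are bimodal: saturated forest blocks against open
farmland. Crops and developed land are threshold exceedances of their
own fields; distance layers are exact Euclidean distance transforms of
those masks; road density is a smoothed field scaled to 0–3 km/km²;
snowfall is a south–north gradient (0–3 m) with 30% noise. Three
vertical bands form the region partition.

True suitability is exactly the inverse-logit of

    η = β₀ + β_nat·natural + β_dc·log1p(dist_crops)
        + β_road·road − |β_snow|·(snow − s_opt)²

with defaults β₀ = −8, β_nat = 7, β_dc = 2.5, β_road = −1,
β_snow = −0.2, s_opt = 2.5 m. The log1p transform gives the saturating
distance-to-crops response seen in field studies (most of the effect
within the first kilometres). The magnitudes were calibrated once so the
virtual species matches the discrimination levels such surveys report —
suitability rising from ~20% to ~80% across the cover gradient, a
truth-map AUC near 0.9 against uniform background, landscape prevalence
~0.1–0.25 — and so that natural cover and distance to crops carry the
top permutation importances; they are not adjusted per experiment.
`dist_developed` enters the covariate stack but not η, giving the
selection and importance machinery a genuine nuisance variable.

Presences are drawn over cells with probability ∝ ψ (optionally × a
bias mask), without replacement by default (one jittered point per
cell, consistent with 1-km thinning); with-replacement draws are
available for sampling-distribution checks. Presets: `homogeneous`
(one process everywhere, overlapping regional covariate ranges),
`range_truncated` (crop cells stamped on an 8-km lattice throughout
region 3, so its distance-to-crops range is truncated by construction),
`null` (all slopes zero — no environmental signal).

What the generator does *not* emulate: survey-effort heterogeneity
beyond a single bias mask, territoriality/movement autocorrelation in
the points, detection error, and temporal structure. Passing tests
therefore demonstrate the machinery is correct and the workflow behaves
as expected under a known logistic process — not that any particular
field system satisfies these assumptions.

## Problem sizes and seeds

Default scenario: 240 × 360 cells at 1 km, 500 presences, 10,000
background points. Transfer analyses draw 1,500 presences so the
balanced per-region count (~460–480) matches the hundreds-per-region
scale at which such comparisons are run in practice. The
range-truncation experiment uses five seeded replicates with two
extrapolation runs each. The byte-level determinism check runs a
reduced 120 × 180 / 2,000-background configuration — determinism does
not depend on problem size. All randomness flows from explicit seeds;
the pipeline derives stage seeds (landscape, sampling, thinning,
background, CV, validation) from one master seed via `SeedSequence`
spawning, and run manifests record the derived seeds plus SHA-256
hashes of every artifact.

## Numerical choices and degenerate inputs

Zero-variance variables: excluded from GLM term expansion; flagged NaN
(not 0) in correlation matrices; zero permutation importance. Constant
maps: map correlation and Spearman are reported as undefined (NaN with
a warning) rather than silently 0. All-zero suitability maps make the
overlap indices undefined (error). Aggregation drops trailing partial
blocks (output dims = floor(fine/factor)) to avoid proportion bias from
undersized blocks, and all-nodata blocks stay nodata. Distance
transforms are exact Euclidean between cell centers
(`scipy.ndimage.distance_transform_edt`), verified against a
brute-force scan. Correlation screening uses |r| ≥ 0.7 as the
collinearity cutoff (the common SDM convention; configurable). When
"best ROC" and "best sensitivity" disagree during variable selection,
ranking is lexicographic: mean CV ROC, then mean sensitivity, then
smaller set, then name — and screening is GLM-only by default (running
the full ensemble over every admissible subset is a flag, since the
subset count grows exponentially).

## Known limitations

Single-CPU, in-memory rasters — appropriate for desk-scale grids
(~10⁵–10⁶ cells), not continental mosaics. The 5-km thinning is greedy,
not an exact maximum independent set. The null-scenario check evaluates
member AUCs on a fresh 500/10,000 evaluation sample rather than the CV
test folds: fold-level AUC at 100 test presences has a standard error
near 0.03, too noisy to certify "≈ 0.5 within 0.05" member-by-member,
while the generalization AUC the claim is actually about is estimated
~2.5× more precisely by the fresh sample. The transferability findings
(extrapolation scheme closer to the regional model; truncated-range
regions transfer worse) are properties of these scenarios, reported per
run, not universal laws.
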