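# sdmtransfer

Ensemble species-distribution modeling (SDM) with an explicit spatial
transferability assessment, exercised end-to-end on virtual-species
landscapes with known ground truth.

The package is aimed at distribution modelers who want to ask: *how far
can a presence–background model calibrated in one region be trusted
outside it?* It implements the complete workflow used in regional
wildlife-distribution studies — occurrence thinning, pseudo-absence
sampling, a multi-algorithm ensemble, threshold optimization, and
map-level niche-overlap comparisons between single-region and
whole-region models — and, because real survey data of this kind is
usually access-restricted, ships a virtual-species generator so every
step can be validated against a known suitability surface.

## The model

Presence points `y = 1` are contrasted with `n_b = 10,000` uniformly
drawn background points (`y = 0`), background rows down-weighted so both
classes carry equal total weight (prevalence 0.5). Four base algorithms
are implemented natively under one fit/predict contract (scores in
`[0, 1]`):

* **GLM** — weighted logistic regression (IRLS), linear + quadratic
  terms;
* **SRE** (BIOCLIM) — per-variable `[α, 1−α]` presence quantile
  envelopes, α = 0.025;
* **CTA** — recursive weighted-Gini classification tree;
* **GBM** — stagewise gradient boosting of depth-2 trees on the logistic
  deviance.

Further algorithms (random forest, GAM, MaxEnt, FDA, ...) plug in
through an adapter contract. Each algorithm is calibrated under
threefold random 80/20 cross-validation; every (algorithm × run) fit
joins the ensemble with weight `w_i ∝ max(ROC_i − 0.5, 0)`. The ensemble
map is the weighted cellwise average; a committee map records the
fraction of members voting "present" at their own optimized thresholds;
the binary map uses the ensemble threshold `τ*` maximizing
`sensitivity + specificity` (TSS = sens + spec − 1).

Transferability is probed by two single-region schemes: **state
cross-validation** (focal-region presences, region-wide background) and
**extrapolation** (background restricted to the focal region). Each
fitted ensemble predicts the whole domain and is validated on the other
regions' presences (validation ROC and sensitivity) and compared to the
all-region model by Spearman rank correlation and the niche-overlap
indices

    D = 1 − ½ Σ|p₁ − p₂|        (Schoener's D)
    I = 1 − ½ Σ(√p₁ − √p₂)²     (Hellinger-based I)

over cell-normalized suitability surfaces (0 = no overlap, 1 =
identical).

## Worked example

```bash
python analysis/01_simulate_landscapes.py
python analysis/02_fit_regional.py
python analysis/03_transferability.py
python analysis/04_range_truncation.py
```

`02_fit_regional.py` fits the all-region ensemble on the default
240 × 360 km homogeneous scenario (500 presences) and prints:

```
ensemble calibration: ROC 0.853, sensitivity 90.0%, specificity 68.6%, TSS 0.586
optimized threshold: 49.3% suitability
suitable area: 27683 km^2 (per region: {'1': 8944, '2': 8973, '3': 9766})
1-cell vs 5-km thinning: n 500 vs 361, map correlation 98.1%
Spearman vs true suitability: 0.956
```

ROC is the probability a presence outscores a background point;
the threshold 49.3% binarizes the suitability map, above which 27,683
km² of the 86,400 km² domain is classed suitable; the 98.1% map
correlation shows the 1-cell and 5-km thinning choices produce nearly
the same map; and Spearman 0.956 against the true suitability surface
confirms the ensemble ranks cells almost exactly like the generating
process.

`03_transferability.py` prints the per-(scheme, region) transfer table.
On the homogeneous landscape both schemes recover maps close to the
all-region model (Schoener's D 0.875–0.924), with the extrapolation
scheme slightly closer on average (mean D 0.917 vs 0.889) — restricting
background to the calibration region prevents the model from carving
out the focal region via chance regional quirks. `04_range_truncation.py`
shows the cost of a truncated covariate range: models extrapolated from
a region that never sees large distances to crops validate worse
elsewhere in 5/5 seeded replicates (mean validation sensitivity 50.1%
vs 66.0%).

A CLI wraps the same pipeline:

```bash
sdmtransfer simulate --preset range_truncated --out data/
sdmtransfer fit-regional --scenario homogeneous --out run/ --seed 1
sdmtransfer transfer --scenario homogeneous --out run_t/ --seed 1
sdmtransfer report --run run/
```

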