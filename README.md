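# growrisk

Presence-background risk mapping for trespass cannabis cultivation sites —
a reusable, tested implementation of the full analysis chain used to map
cultivation risk across forested landscapes and quantify its overlap with
habitat of sensitive forest predators (Pacific fisher, Humboldt marten,
northern spotted owl).

**Who it is for.** Spatial ecologists and conservation analysts who have
presence-only discovery records (e.g., from law enforcement), gridded
environmental predictors, and want a defensible relative-likelihood map
with classified risk, survey-based validation, and wildlife-overlap
statistics — plus a synthetic-landscape generator so the whole pipeline is
testable without any proprietary data.

## The model

Occurrences are presence-only, so the core is a maximum-entropy (Gibbs)
model over background locations: `q(i) = exp(λ·f_i) / Z`, fitted by
maximizing the L1-penalized presence log-likelihood

```
mean_p(λ·f) − log mean_bg exp(λ·f) − Σ_j β_j |λ_j|
```

with linear, quadratic, product and hinge features scaled to [0, 1], and
per-feature penalties `β_j = r · c(class, m) · s_j / √m`. At the optimum the
fitted background expectations match the presence means within the β box
(KKT), the raw output sums to one over the background, and the logistic
output `e^H q / (1 + e^H q)` (H = model entropy) gives a relative
likelihood in (0, 1).

Around that core the package implements the full published procedure:
2000 m occurrence thinning, 10,000 background points, 450 m focal predictor
averaging, |r| > 0.7 correlation grouping with univariate CV-AUC winners,
stepwise jackknife pruning, 18-combination (feature mode × regularization
multiplier) AICc tuning, Boyce-index classification into low/moderate/high
risk, watershed summaries, 1%-of-stream-km ground-truth survey design with
stream-km-weighted chi-square validation, and overlap of moderate-high risk
with habitat rasters and a-LoCoH 95% home ranges.

## Worked example

Run the whole pipeline on the default synthetic landscape (200×200 cells at
90 m, 500 biased presence draws, 2,000 background points):

```python
import growrisk as gr

result = gr.run_synthetic_pipeline(gr.LandscapeConfig(seed=42),
                                   gr.desk_preset(seed=42))
print("retained:", result.trace.retained)
print("tuned settings:", result.tuning.winner)
print("mean 10-fold test AUC:", round(result.mean_test_auc, 3))
print("mean 10% omission:", round(result.mean_omission, 3))
print("Boyce index:", round(result.boyce.boyce_index, 3))
print(gr.class_areas(result.riskmap))
print(result.importance.round(1))
```

prints (seed 42):

```
retained: ['elevation', 'slope', 'stand_age']
tuned settings: ('hinge', 3.0)
mean 10-fold test AUC: 0.858
mean 10% omission: 0.13
Boyce index: 0.974
      class  n_cells  area_km2  percent
0       low    30285  245.3085  75.7125
1  moderate      251    2.0331   0.6275
2      high     9464   76.6584  23.6600
    variable  percent_contribution  permutation_importance
0  elevation                  47.3                    42.0
1      slope                  52.3                    56.7
2  stand_age                   0.4                     1.3
```

Reading this: the selection ladder pruned eleven candidate predictors to
the two truly informative ones (the landscape's true selection surface is a
band on elevation and a band on slope) plus one weak passenger; AICc chose
hinge features with a strong multiplier for the small thinned sample; the
tuned model discriminates held-out presences from background with mean AUC
0.86 without overfitting (10% training omission ≈ 0.13 on test folds); the
Boyce P/E curve rises monotonically with predicted suitability (index
0.97); and the thresholded map assigns ~24% of the landscape to the
moderate-high classes, with importance concentrated on slope and elevation.

The same stages are available from the shell:

```bash
growrisk simulate --seed 42 --outdir out/sim     # synthetic study system
growrisk run      --seed 42 --outdir out/run     # fit, tune, classify
growrisk validate --seed 42 --outdir out/val     # survey chi-square
growrisk overlap  --seed 42 --outdir out/ovl     # habitat / home ranges
```

## Layout

- `src/growrisk/io.py` — grid model, ASCII-grid/GeoJSON/CSV I/O, alignment,
  rasterization, distance transforms
- `src/growrisk/synthetic.py` — landscapes, true surfaces, biased sampling,
  streams/plots, habitat, telemetry
- `src/growrisk/prep.py` — thinning, background, focal stats, extraction,
  CV folds
- `src/growrisk/maxent.py` — features, the L1 maximum-entropy fit,
  predictions, AUC/omission
- `src/growrisk/selection.py` — grouping, jackknife, AICc tuning,
  importance, response curves
- `src/growrisk/classify.py` — Boyce curves, thresholds, risk maps, areas,
  unit summaries
- `src/growrisk/validation.py` — survey design, stream-km chi-square,
  class percentages, distances
- `src/growrisk/overlap.py` — habitat overlap, a-LoCoH home ranges
- `src/growrisk/pipeline.py`, `cli.py` — orchestration and the `growrisk`
  command

See `docs/methods.md` for the full methodological account.
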