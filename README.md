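# envrank

Which environmental factors drive daily hospital admissions?  `envrank` is a
Python package for epidemiologists and environmental-health analysts who
predict daily cardiovascular (CVD) or respiratory (RD) emergency-room
admission counts from daily environmental time series (temperature,
atmospheric pressure, humidity, CO, O₃, PM₁₀, NO₂) and want a defensible,
model-agnostic answer to *which features matter most*.

## What it does

The pipeline follows the standard workflow for this problem class:

1. **Seasonal-trend filtering.**  Each series is decomposed additively with
   STL (LOESS-based seasonal-trend decomposition), `Y_v = T_v + S_v + R_v`,
   and can be replaced by its trend component to emphasise long-term
   structure over the annual cycle and day-to-day noise.
2. **Multicollinearity screening.**  Pearson correlation clusters
   (connected components at a |r| ≥ 0.8 threshold) are collapsed to one
   representative each — daily minimum/mean/maximum/dew-point temperatures
   are near-duplicates and should enter the model once.
3. **Random-forest regression.**  A forest `f̂ : ℝᵈ → ℝ` is tuned by grid
   search over `(n_trees, mtry)` with k-fold cross-validation (k = 5),
   trained on an 80/20 split, and scored by the triple

   - MAE = (1/n) Σ |yᵢ − ŷᵢ|
   - MARE = (1/n) Σ |yᵢ − ŷᵢ| / yᵢ  (zero-count days excluded by default)
   - R² = 1 − SS_res / SS_tot

4. **Three global feature-importance measures** (all model-agnostic):
   - **PFI** — permutation feature importance: the rise in expected loss
     when feature j's column is permuted.
   - **SHAP-style importance** — the mean absolute Shapley value of feature
     j over the data, with exact coalition enumeration (d ≤ 15) and an
     interventional background value function.
   - **κALE** — derivative-based importance built from accumulated local
     effects: the mean of squared interval Newton ratios of the ALE
     construction, scaled by `σ²_{x_j}/σ²_y`; for a linear response
     `β·x_j` with independent features it equals `β² σ²_{x_j}/σ²_y`.
5. **Incremental configurations.**  For each importance ranking, nested
   models `conf_1 ⊂ conf_2 ⊂ … ⊂ conf_d` (top-k features) are trained and
   scored on the same test set; rankings are compared by the area under the
   performance curves and the fastest-decaying ranking is selected.

Because real admission records are typically restricted, the package ships
a synthetic-data generator with a known ground-truth importance structure:
trend + annual seasonality + noise per feature, a strongly inter-correlated
temperature block from one latent series, and Poisson admission counts whose
mean is an additive function of three signal features (Tmin, P_atm, CO).

## Worked example

```python
from envrank import (
    default_spec, generate_environmental_table, correlation_matrix,
    screen_collinearity, split_train_test, tune_forest, predict,
    performance_indices, PfiConfig, pfi, shapley_importance, kappa_ale,
    normalize_importance,
)

table, truth = generate_environmental_table(default_spec(n_days=1500, seed=42))
report = screen_collinearity(correlation_matrix(table), threshold=0.8,
                             policy="user_pin", pins=["Tmin"])
data = table.select_features(report.kept)
train, test = split_train_test(data, 0.8, "random", seed=42)
forest = tune_forest(train, grid=[(100, 2), (100, 3)], k=5, seed=42, target="CVD")
triple = performance_indices(test.targets["CVD"].to_numpy(float),
                             predict(forest, test.features))
for est in (pfi(forest, train, PfiConfig(n_repeats=30, seed=42), target="CVD"),
            shapley_importance(forest, train, n_explain=100, seed=42),
            kappa_ale(forest, train, K=40, target="CVD")):
    norm = normalize_importance(est)
    print(est.measure, norm.ranking[:3])
```

prints

```
true signal order: ['Tmin', 'P_atm', 'CO']
kept after screen: ['Tmin', 'P_atm', 'rh', 'CO', 'o3', 'pm10', 'NO2']
selected hyperparameters: {'n_trees': 100, 'mtry': 3}
test MAE=3.11  MARE=0.251  R2=0.496
  PFI: Tmin=0.45, P_atm=0.27, CO=0.09
 SHAP: Tmin=0.45, P_atm=0.28, CO=0.13
 kALE: Tmin=0.59, P_atm=0.28, CO=0.05
```

The ten generated features collapse to seven after the screen (the
temperature block keeps only Tmin); the tuned forest explains about half of
the day-to-day variance in counts (the rest is Poisson noise); and all three
measures place the three true signal features — and only those — at the top,
in the generating order Tmin > P_atm > CO.

The same stages are available from the shell:

```bash
envrank simulate --n-days 1500 --seed 42 --out table.csv
envrank screen table.csv --pin Tmin
envrank run --seed 42 --out report/
```

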