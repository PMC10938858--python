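# countysvi

County-level suicide analysis for the US: trend statistics, a
gradient-boosted prediction model, Shapley-value feature attribution,
and a composite **Suicide Vulnerability Index (SVI)** on a 0–1 scale.
The package is aimed at public-health analysts and methods researchers
who work with county-year mortality panels (CDC WONDER counts joined to
Census / BLS / County Health Rankings covariates) and want a tested,
reproducible implementation of this analysis — including a synthetic
panel generator so the whole pipeline runs and is validated without any
restricted data.

## The method

Given a panel of 3,140 counties × 10 years with 17 county features
(demographics, socio-economic, health):

1. **Trends** — per-county percent change in annual suicides between
   the first and last year, fractions of counties above change
   thresholds, average county rate per 100,000, national rate by year.
2. **Prediction** — a gradient-boosted tree regressor (XGBoost,
   Poisson objective) of the mean annual suicide count on the 17
   features: 80:20 county split, hyperparameters from grid search with
   10-fold cross-validation on the training split, R² on the held-out
   counties.
3. **Attribution** — Shapley values φ_ij for every county i and
   feature j under the interventional value function
   v(S) = E_b[f(x_S, b_∖S)] with a seeded background sample. Feature
   importance is mean |φ_j|; effect direction is the sign of
   corr(x_j, φ_j). The fast tree-traversal explainer is validated
   against exact subset enumeration.
4. **The index** — for the top p = 5 features, each county gets a
   directional percentile score X_i ∈ [0, 1] (reversed for
   negative-direction features, so low %Female means high
   vulnerability), and

       SVI = Σ_{i=1}^{p} W_i X_i ,   W_i = mean|φ_i| / Σ_j mean|φ_j| ,

   which lies in [0, 1] by construction. Counties are binned into five
   vulnerability classes ([0, 0.2) low … [0.8, 1] high) and exported as
   FIPS-keyed choropleth tables.

See `docs/methods.md` for the generative model behind the synthetic
panels, numerical conventions and known limitations.

## Worked example

```python
from countysvi.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=1, n_counties=300, artifacts_dir="artifacts",
    grid={"max_depth": (2, 3), "learning_rate": (0.1, 0.3), "n_estimators": (200,)},
    cv_folds=5, background_size=50,
)
res = run_pipeline(cfg)
print("chosen params:", res.model.best_params_)
print(f"R2 train={res.model.r2_train_:.3f} cv={res.model.r2_cv_:.3f} test={res.model.r2_test_:.3f}")
print("top 5 features:", res.report.rank[:5])
print("weights:", {f: round(w, 3) for f, w in res.svi_table.weights.weights.items()})
print(res.svi_table.table[["svi", "svi_rounded", "bin"]].head(4))
```

prints

```
chosen params: {'learning_rate': 0.3, 'max_depth': 3, 'n_estimators': 200}
R2 train=1.000 cv=0.757 test=0.950
top 5 features: ['Population', '%White', '%AfricanAmerican', 'MedianAge', '%Female']
weights: {'Population': 0.709, '%White': 0.129, '%AfricanAmerican': 0.065, 'MedianAge': 0.055, '%Female': 0.042}
            svi  svi_rounded      bin
fips
00001  0.461219         0.46  0.4–0.6
00002  0.212374         0.21  0.2–0.4
00003  0.916438         0.92    0.8–1
00004  0.243067         0.24  0.2–0.4
```

Reading the output: the model explains 95% of held-out variance in
mean annual counts at this reduced scale (0.986 at the full 3,140
county default, seed 1); total population dominates the Shapley importance
ranking — counts scale with exposure — followed by the four planted
demographic effects with their correct signs (%White +, %AfricanAmerican −,
MedianAge +, %Female −); the index weights mirror those magnitudes; and
county `00003` lands in the high-vulnerability bin (SVI 0.92) while
`00002` is low-moderate.

The same stages are available from the shell:

```bash
countysvi simulate --n-counties 3140 --seed 1 --out panel.csv
countysvi trends --panel panel.csv --out trends.csv
countysvi fit --panel panel.csv --seed 1 --out model.json
countysvi run --config pipeline.yaml        # full pipeline + manifest
```

Every stage takes explicit seeds, and `run` writes a manifest of
SHA-256 hashes over all artifacts: identical config + seed reproduces
identical files.

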