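# enmrisk

Ensemble ecological-niche modelling and invasion-risk mapping, with a
virtual-species test bed.

`enmrisk` is for spatial ecologists and invasion biologists who want a
tested, reproducible implementation of the classic invasion risk-mapping
workflow: from raw occurrence points and environmental raster layers to a
final map of *risk = habitat suitability x introduction pressure*. Every
stage is a library function, the whole chain is scriptable from a YAML
config via a CLI, and a synthetic virtual-species generator provides
ground-truthed inputs so the entire pipeline can be validated without any
data downloads.

## The method

1. **Presence thinning.** Occurrence records are reduced to one per grid
   cell ("presence cells"), each represented by its geometric cell centre.
2. **Pseudo-absences.** Absence points are drawn uniformly at random from
   the annulus 50 km < d ≤ 100 km around the nearest presence centroid
   (great-circle distance, sphere R = 6371 km), in multiple replicate
   datasets. Case weights give presences and absences equal total
   prevalence: w₀ = n₁/n₀, w₁ = 1.
3. **Collinearity pruning.** Predictors are pruned by stepwise variance
   inflation factor, VIF = 1/(1 − R²), removing the worst offender until
   all VIFs fall below a threshold (default 10).
4. **Model ensemble.** Nine methods — ANN, CTA, FDA, GAM, GBM, GLM, MARS,
   RF and a presence-only Surface Range Envelope (SRE) — are each
   evaluated by repeated random 70/30 splits scored with the ROC AUC
   (weighted Mann–Whitney form). With 9 methods × 10 absence datasets ×
   10 repeats the design performs 900 model fits.
5. **Weighted ensemble (EMmw).** Low-scoring methods are dropped; the rest
   are combined as a weighted mean with wᵢ = AUCᵢ / Σⱼ AUCⱼ.
   Ensemble-vs-member accuracy is compared with Welch's t-test.
6. **Variable importance.** Randomization importance: permute one
   predictor, re-predict, score 1 − r (Pearson correlation of predictions
   before/after). Ensemble importance applies the ensemble weights, sums
   per variable, divides by the number of members, and converts to
   percentages.
7. **Risk map.** A per-region (national) total is distributed over cells
   proportionally to river discharge, bilinearly resampled to the analysis
   grid and min-max rescaled to [0, 1]; risk is the cell-wise product of
   this pressure surface and the [0, 1] EMmw suitability surface.

## Worked example

```python
from enmrisk.pipeline import AnalysisConfig, run_analysis

cfg = AnalysisConfig(methods=("GLM", "RF", "GBM", "SRE"),
                     n_datasets=3, n_per_dataset=1000, n_repeats=3).with_seed(1)
res = run_analysis(cfg)
print(res.retained_vars)            # VIF kept 9 of 10 predictors
print(res.ensemble.weights)         # AUC-proportional member weights
print(res.ensemble_mean_auc)        # cross-validated EMmw accuracy
print(res.truth_correlation())      # recovery of the generating truth
print(res.importance.round(1))      # % importance per method + EMmw row
```

On the default virtual species (64×64 grid, 10 candidate predictors of
which 3 carry the niche signal and one is a 0.99-correlated near-copy,
300 presence cells) this prints:

```
['env01', ..., 'env09']                      # env10 removed, VIF 104.5
{'GLM': 0.262, 'RF': 0.263, 'GBM': 0.262, 'SRE': 0.213}
0.9975
0.8323
      env01  env02  env03  env04  ...
EMmw   31.8   39.7   13.7    3.0  ...
```

i.e. the ensemble discriminates presences from annulus pseudo-absences
with mean AUC 0.997, the suitability map correlates 0.83 with the
generating truth, and the three true effect variables take the top three
ensemble importance ranks.

The same workflow runs stage-by-stage from the shell:

```bash
enmrisk full-run --config config.yml --out run/
# or: enmrisk simulate|thin|absences|select-vars|evaluate|ensemble|importance|risk ...
```

producing CSVs, ASCII-grid rasters (`suitability.asc`, `pressure.asc`,
`risk.asc`) and a JSON manifest with seeds, counts and a config hash.
Re-running a config reproduces every tabular output byte-for-byte.

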