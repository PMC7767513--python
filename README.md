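# cbqsar

QSAR regression toolkit for predicting cannabinoid receptor 1 (CB1R)
binding affinity — pKᵢ = −log₁₀(Kᵢ in mol/L) — of synthetic
cannabinoids from precomputed molecular descriptors.

It is aimed at the small-data regime typical of in-house binding-assay
campaigns: a dozen compounds, hundreds of collinear descriptors.  The
toolkit provides, as scikit-learn-style estimators plus a thin CLI:

* a three-stage descriptor filter chain (near-zero variance →
  pairwise-correlation pruning at |r| > 0.9 → response-correlation
  keep at |r| > 0.3), fit on training rows only;
* forward-selection multiple linear regression driven by adjusted R²,
  with VIF diagnostics;
* NIPALS PLS1 (`X = TP′ + E`, collapsed coefficients
  `b = W(P′W)⁻¹q`) with a leave-one-out Q²/R² component scan;
* the validation battery: R², adjusted R², RMSE, leave-one-out Q²
  with full per-fold refits, predictive R² about the training mean,
  Y-randomization with cRp² = R·√(max(0, R² − R̄r²)), a two-sided
  Grubbs outlier screen, and normal Q-Q residual data;
* a Euclidean-distance applicability domain with threshold
  APD = ⟨d⟩ + Zσ over below-average training pairwise distances;
* a seeded synthetic-data generator planting latent-factor blocks,
  duplicates, junk and constant columns for offline testing;
* the bundled CB1 reference dataset: 15 compounds (THC, JWH-, CRA-,
  CP-series, AM-694, RCS-4) with measured pKᵢ, train/test roles, the
  published MLR and 16-descriptor PLSR coefficient vectors, and the
  reference predictions.

See `docs/methods.md` for the statistical details and conventions.

## Worked example

Fit the full workflow on a seeded synthetic benchmark (100 compounds,
94 descriptor columns of which 8 carry signal):

```python
import cbqsar as q

X, act = q.reference_like_benchmark(seed=1, large=True)
result = q.run_pipeline(X, act, q.PipelineConfig(seed=1))

rep = result.fit_reports["plsr"]
print(result.selected_features)
print(f"R2={rep.r2:.3f}  Q2={rep.q2_loo:.3f}  R2pred={rep.r2_pred:.3f}")
print(f"cRp2={result.y_randomization['plsr'].c_rp2:.3f}")
print(f"APD threshold: {result.apd.threshold_:.3f}")
```

prints

```
['info_01', 'info_03', 'info_05', 'info_06', 'info_07',
 'dup_00_of_info_00', 'dup_02_of_info_02', 'dup_04_of_info_04']
R2=0.982  Q2=0.976  R2pred=0.972
cRp2=0.951
APD threshold: 3.141
```

The filter chain kept exactly the planted signal carriers (for
duplicated columns, one member of each pair) and discarded all junk
and constant columns.  R² is the training fit, Q² the leave-one-out
cross-validated coefficient (each fold refits standardization and
model from scratch), R²pred the score on the 20 held-out compounds
about the training mean.  cRp² > 0.5 means the model comfortably
beats its response-shuffled counterparts.  The applicability-domain
threshold is the nearest-neighbor distance beyond which a query's
prediction should not be trusted.

The same workflow from the shell:

```sh
cbqsar synth --n-compounds 60 --n-informative 2 --beta 0.8,-0.4 \
             --noise-sd 0.1 --seed 11 --out data/
cbqsar fit --descriptors data/descriptors.csv \
           --activities data/activities.csv --model both --out reports/
cbqsar predict --model reports/model.json --name plsr \
               --descriptors data/descriptors.csv --out predictions.csv
```

`cbqsar ref-check` recomputes the bundled reference study's summary
statistics (training R²/RMSE, test RMSE, predictive R², per-compound
residuals, the observed-pKᵢ spread, and the outlier screen) purely
from the shipped table — the underlying descriptor values were never
published, so these are checks of the validation arithmetic, not a
refit.

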