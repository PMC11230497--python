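# braingap

Brain-age-gap (BAG) estimation from higher-order interactions in parcellated
brain signals. The pipeline builds Gaussian-copula O-information matrices
from region × time matrices (fMRI or source-space EEG), feeds them to a
two-layer graph-convolutional age regressor, and analyzes the resulting
brain-age gaps with permutation statistics, ablation feature importance,
exposome gradient-boosting models, and signal-quality scores. A synthetic
cohort generator with planted age/group/exposome effects makes every stage
testable without any data download.

## Modules

| module | what it does |
|---|---|
| `braingap.synthetic` | cohort metadata, latent-factor time series with age-dependent coupling, exposome tables, fixture writer |
| `braingap.hoi` | copula transform, Gaussian entropies, pairwise-vs-rest O-information matrices, normalization |
| `braingap.graphs` | Ω → graph conversion, NaN filtering, age-stratified split, age-interpolation augmentation |
| `braingap.gcn` | two-layer GCN age regressor (NumPy, Adam), grid search with 5-fold CV |
| `braingap.evaluation` | RMSE / R² / Pearson r / Cohen's f² / MDE, BAG, subsample permutation tests, covariate adjustment, within-scanner harmonization |
| `braingap.importance` | node/edge ablation deltas with bootstrap CIs |
| `braingap.exposome` | gradient-boosted BAG regression, repeated 10-fold CV, permutation/MDI (+ optional SHAP) importance with 99% CIs |
| `braingap.quality` | fMRI tSNR-segment ODQ and EEG four-check ODQ scores |
| `braingap.io`, `braingap.pipeline`, `braingap.cli` | TSV I/O, workflow orchestration, CLI |

## CLI

```bash
braingap simulate --n-subjects 20 --n-regions 82 --out fixtures/
braingap omega fixtures/sub-0000_timeseries.tsv --out omega.tsv
braingap quality fixtures/sub-0000_timeseries.tsv --modality fMRI
braingap stats predictions.tsv --out stats/
braingap all --n-subjects 100 --out run/          # full pipeline, synthetic
braingap all --input-dir fixtures/ --out run/     # full pipeline, from files
```

Inputs are plain TSV matrices (first column region label, one sample per
remaining column); neuroimaging/EEG container formats are rejected because
preprocessing and parcellation are out of scope.

## Notes

- All entropies are in nats; O-information > 0 indicates redundancy,
  < 0 synergy.
- The GCN is implemented directly on NumPy arrays (explicit gradients,
  Adam) so the package has no deep-learning framework dependency.
- SHAP importance is an optional adapter: it is reported only when the
  `shap` package is installed; permutation and MDI importance are always
  computed.
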