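# mvhist

Multi-parametric, multi-regional MRI histogram analysis: extract histogram
features from diffusion (p, q) and perfusion (rCBV, MTT, rCBF) maps over
contrast-enhancing (CE) and non-enhancing (NE) tumor regions, cluster
patients by multi-view late integration, validate the clustering with
leave-one-out consensus co-occurrence, rank features by logistic importance,
and evaluate prognostic value with survival (Kaplan-Meier, log-rank, Cox)
and incremental ROC analyses. A synthetic-cohort generator makes every
stage runnable without any external data.

## Layout

| module                | responsibility |
|-----------------------|----------------|
| `mvhist.synthetic`    | synthetic cohorts: log-normal voxel maps, CE/FLAIR/NAWM masks, CSI grids, covariates, proportional-hazards survival |
| `mvhist.features`     | mask algebra (NE = FLAIR ∧ ¬CE), NAWM normalization, 100-bin histogram statistics, patients × 100 feature table in 4 views |
| `mvhist.clustering`   | per-view feature clustering (Ward, 1−\|r\| distance), correlation-medoid centroid selection, per-view patient clustering, late integration |
| `mvhist.validation`   | leave-one-out reruns, consensus co-occurrence matrix, per-cluster consensus means |
| `mvhist.survival`     | feature ranking, maximally selected cutpoints, log-rank, Kaplan-Meier, Cox PH, 12-month incremental AUC |
| `mvhist.mrs`          | CSI voxel occupancy/quality filtering, Wilcoxon + Benjamini-Hochberg metabolite comparison |
| `mvhist.pipeline` / `mvhist.cli` | end-to-end orchestration, JSON config, artifact I/O |

## CLI

```bash
mvhist --show-config                       # print the resolved JSON defaults
mvhist --seed 1 --out run1 run-all         # full synthetic pipeline
mvhist --config cfg.json simulate          # write a cohort (NIfTI + CSV + manifest)
mvhist --config cfg.json features          # patients x 100 feature table
mvhist --config cfg.json cluster           # multi-view clustering
mvhist --config cfg.json loocv             # consensus analysis
```

Artifacts written per run: `features.csv`, `final_labels.csv`,
`centroids.json`, `consensus.csv`, `ranked_features.csv`, `survival.json`,
`mrs.csv`, and the resolved `config.json`. Identical config + seed
reproduce identical artifacts byte for byte.

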