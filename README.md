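# paleoeval

**Evaluate species-distribution-model hindcasts against dated paleozoological
presence/absence records.**

Species distribution models (SDMs) relate where a species occurs today to
environmental covariates and are routinely projected onto past or future
climates — yet they are almost never *tested* across the time spans they are
projected over. Fossil and archaeological records offer truly independent
validation data: a dated faunal assemblage tells us a taxon was present at a
place and time, and an assemblage that lacks it is (cautious) evidence of
absence. `paleoeval` turns a stack of per-time-slice habitat-suitability
rasters and a compilation of dated faunal assemblages into **paleometrics** —
evaluation metrics computed against the fossil record rather than against
modern occurrences — and quantifies how fragile those metrics are to the
fossil record's known biases.

It is a library first (importable API plus `examples/`), with a thin
`paleoeval` command-line wrapper (`simulate`, `evaluate`, `sensitivity`)
for shell use.

## What it computes

For validation sites scored against a suitability surface and binarised at a
threshold *t* (score ≥ *t* predicts presence), the confusion matrix counts
*a* (true positives), *b* (false positives), *c* (false negatives), *d*
(true negatives), and the package reports:

- **threshold-dependent:** TPR = a/(a+c), TNR = d/(b+d), FPR, FNR,
  TSS = TPR + TNR − 1 (and its rescaling (TSS+1)/2), Accuracy, Precision,
  Prevalence, F<sub>β</sub> = (1+β²)·P·TPR / (β²·P + TPR), FDR,
  Sørensen = 2a/(2a+b+c), Jaccard = a/(a+b+c), odds ratio = ad/bc, and
  Cohen's kappa;
- **threshold-independent:** rank-sum AUC = (R − n₁(n₁+1)/2)/(n₁n₂) with
  average ranks for ties; the continuous **Boyce index** (Spearman rank
  correlation between suitability-window mid-points and the
  predicted/expected presence ratio over a background sample); and
  **IMAE** = 1 − mean |label − score| (higher is better);
- **maxSSS** threshold selection (maximising sensitivity + specificity) for
  calibrating *t* on modern presence/absence points.

Metrics with zero denominators are *undefined* (`None` / `NA`), never
coerced to 0 and never raised as errors.

Around the metrics sits the full workflow: reading dated faunal compilations
(CSV/TSV), assigning records to labelled year-BP time slices by full date
interval or interval midpoint, snapping coastal off-grid points to the
nearest valid raster cell (great-circle distance, capped radius), spatial
thinning, buffered/polygon pseudoabsence sampling, TSS-weighted ensembles, a
pluggable model interface with a quadratic-logistic baseline — and a fully
seeded synthetic-data generator so every pipeline step is testable at desk
scale without downloads.

Rasters are read and written as single-band **ESRI ASCII grids** (`.asc`,
plain text, explicit nodata); the default time-slice scheme is eight
Holocene slices jointly covering 200–7850 BP (labels 600, 1500, …, 7500).

## Worked example

```sh
python examples/02_evaluate_hindcast.py
```

generates a synthetic world (eight drifting suitability surfaces over a
coastline mask), a biased fossil record of 200 dated sites, perturbs the
truth into an imperfect "model", and evaluates it:

```
478 sliced observations from 200 sites (47 snapped to the nearest valid cell, 0 unsnappable, 0 dated outside 200-7850 BP)
pooled confusion matrix: a=19 b=91 c=20 d=348
  unit   tpr   tnr    tss  f_score  sorensen   auc  boyce  imae
   600 1.000 0.926  0.926    0.833     0.667 0.963  0.574 0.635
  1500 1.000 0.923  0.923    0.789     0.600 0.962  0.714 0.739
  ...
pooled 0.487 0.793  0.280    0.357     0.255 0.675  0.780 0.646
```

Each dated site contributes one observation to every slice its date
interval overlaps (hence 478 observations from 200 sites). The pooled row
sums the per-slice confusion matrices: the model recovers about half the
fossil presences (TPR 0.49) and most absences (TNR 0.79), with positive
overall skill (TSS 0.28, AUC 0.68) that visibly degrades in the older
slices as the suitability field drifts away from the surface the records
were generated from.

`examples/03_sensitivity_analysis.py` then removes sites in order of
species richness (all sites with richness < k at cutoff k). Because
sparsely sampled sites sit disproportionately in marginal habitat and carry
most false absences, presence-focused metrics (TPR, F-score, Sørensen) tend
to rise while absence-sensitive metrics (TNR, TSS, AUC, Boyce) tend to
fall — which is exactly why presence-focused paleometrics are the safer
guide when absence data are taphonomically suspect.

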