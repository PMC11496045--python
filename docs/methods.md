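# Methods

## The evaluation model

`paleoeval` scores a *hindcast* — a per-time-slice habitat-suitability
surface with values in [0, 1] — against dated paleozoological
presence/absence records. The procedure is:

1. **Temporal slicing.** Each dated assemblage carries an interval
   [latest BP, earliest BP]. In `interval` mode the record joins every
   slice its interval overlaps fully or partially; in `midpoint` mode only
   the slice containing the rounded interval midpoint (half-up). Slices are
   closed integer intervals of years BP; the default scheme's eight slices
   (600: 200–1000, 1500: 1001–2000, …, 7500: 7001–7850) partition 200–7850
   BP exactly, which the tests verify by exhaustive scan. Records wholly
   outside the scheme are dropped with a warning and counted; records
   partially outside join only the overlapping slices.
2. **Presence/absence derivation.** For a chosen target taxon, each
   (site, slice) pair yields exactly one observation: presence if *any*
   assemblage of that site assigned to the slice contains the taxon,
   otherwise absence (presence dominates; the compilation records what was
   found, so absence is inferred). Whether a site dated into a slice only
   by a different assemblage should count as an absence there is genuinely
   ambiguous; the per-(site, slice) dominance rule is this package's
   reading, and `midpoint` mode offers the narrower alternative.
3. **Spatial alignment.** Points are assigned to cells by a north-up,
   cell-center-registered geotransform (WGS84 degrees). A point whose cell
   is invalid (nodata — typically a coastal site at coarse raster
   resolution) snaps to the valid cell with the nearest center by
   great-circle (haversine) distance, ties broken by lowest (row, column)
   within float round-off. The search radius is capped at twice the cell
   diagonal by default: generous for genuine coastal off-grid points,
   conservative enough not to teleport records across seas. Unsnappable
   records are dropped and counted. Each slice's own mask is used, so a
   site near a shifting coastline may legitimately land in different cells
   in different slices.
4. **Scoring.** The suitability of the containing cell is the record's
   score. Predicted presence is `score >= threshold` (boundary inclusive).
   The threshold is supplied per model — normally calibrated on modern
   presence/absence data via `maxsss_threshold`, which scans the observed
   scores and returns the smallest one maximising sensitivity +
   specificity.
5. **Metrics.** Per slice and pooled (pooled confusion matrix = sum of
   per-slice matrices, an invariant the tests assert). Undefined values
   (zero denominators, single-class inputs) propagate as explicit `None` /
   `NA` markers, excluded from aggregation, never coerced to zero.

Per-model means over slices versus pooled matrices are both legitimate
summaries and the package emits both (`aggregation="both"`), asserting
neither as canonical.

## Metric conventions worth stating

- **F-score** takes an explicit `beta`; β=1 is the harmonic mean of
  precision and recall and coincides exactly with the Sørensen index
  (2a/(2a+b+c)), an identity the tests check; β=2 (the default in
  `EvaluationConfig`) weights recall double, the natural choice when false
  absences are less trustworthy than false presences, as in fossil data.
- **Sørensen and Jaccard** use the standard presence-overlap forms
  2a/(2a+b+c) and a/(a+b+c) — the forms consistent with "similarity
  between predicted and observed presences"; *d* plays no role.
- **IMAE** is reported as 1 − MAE so that, like every other metric here,
  larger is better; the raw error is available as `metrics.mae`.
- **AUC** uses the rank-sum (Mann–Whitney) identity with average ranks for
  ties; constant scores therefore give exactly 0.5 (chance), and `None` is
  reserved for single-class input.
- **Continuous Boyce index**: 101 overlapping windows whose width is 0.1 of
  the *background* score range, mid-points evenly spanning that range; each
  window's P/E is (fraction of presence scores in window)/(fraction of
  background in window); windows with empty background are dropped; the
  index is the Spearman correlation of mid-point vs P/E; fewer than three
  usable windows, or a constant P/E profile, is undefined. The background
  defaults to all valid cells of the evaluated slice
  (`boyce_background="grid"`); `"sites"` uses the observation scores
  instead, which is the appropriate choice inside the sensitivity analysis
  (see below). Pooling concatenates per-slice presence scores against
  concatenated per-slice backgrounds, preserving each slice's context.

## Sensitivity analysis

Fossil absence is weak evidence: preservation and recovery are incomplete,
and sparsely sampled sites are the least trustworthy. The sensitivity
analysis removes sites in order of species richness — at cutoff k all sites
with richness < k go — and recomputes the pooled metrics; cutoff 1 is the
unfiltered evaluation. The default maximum cutoff is 5 (drop everything
below five recorded species), extensible to 10. A cutoff that eliminates
all observations (or leaves one class) yields an undefined row, not a
failure. When the Boyce index participates in this analysis the
site-based background is used: with a fixed raster background the index
cannot respond to site filtering by construction.

## The synthetic world

The generator exists so the whole pipeline — including its failure modes —
is testable without external data. What it emulates, and how:

- **Suitability surfaces** are signed mixtures of 25 Gaussian bumps
  (σ = 6 cells) min-max normalised to [0, 1]; each subsequent slice adds a
  fresh smooth field scaled so the mean absolute inter-slice change never
  exceeds `drift` (default 0.05); a second smooth field thresholded at its
  20 % quantile provides a coastline-like validity mask. The default grid
  (50 × 48 cells of 1.8°, lon −23…63.4, lat −45…45) mirrors a
  continental-scale study box at coarse climate-model resolution.
- **Sites** land on random valid cells; a configurable fraction (default
  0.1) is displaced onto an invalid neighbour cell to exercise snapping,
  with the home cells of displaced sites drawn from coastal cells so a
  target always exists.
- **Dating uncertainty**: interval widths uniform between 0.1 and 3 mean
  slice widths around a uniform interval center, so records span anything
  from a fraction of one slice to several.
- **Detection** of the target taxon is Bernoulli with probability
  `ceiling × logistic(slope·(s − 0.5)) × (1 − exp(−richness/recovery_scale))`
  where *s* is the true suitability of the site's cell in its midpoint
  slice. Defaults: slope 6, ceiling 0.6, recovery scale 2. The ceiling
  encodes that preservation-plus-recovery is far from certain even in ideal
  habitat; the recovery factor encodes that a site's richness is a proxy
  for its sampling/preservation quality, so sparse assemblages rarely
  record any given taxon — the pattern real compilations show, where a
  focal taxon is recorded mainly at sites with several documented species.
- **Richness** is geometric (right-skewed, mode 1–2 species) with success
  probability clip(0.85 − 0.65·s, 0.2, 0.9): richer assemblages accumulate
  in more productive, more suitable environments. This suitability–richness
  coupling is the load-bearing taphonomic structure: removing low-richness
  sites then preferentially removes correct absences and missed presences
  in marginal habitat, which is what drives the sensitivity analysis's
  characteristic trend directions (presence metrics up, absence-sensitive
  metrics down).
- **False absences**: a recorded presence is erased with probability
  0.35·exp(−(richness−1)/4) — the sparser the site, the likelier the taxon
  was missed.
- **Imperfect models** for evaluation are made with `perturb_stack`, which
  adds a smooth error field of bounded magnitude to each slice; the
  unperturbed stack is a *perfect* model of its own records and leaves
  discrimination metrics nowhere to degrade.

Everything is driven by explicit seeds; the full generate→evaluate path is
bit-reproducible, which a test asserts.

**What passing tests do and do not show.** The generator reproduces the
statistical *structure* the evaluation assumes — suitability-linked
detection, skewed richness, richness-dependent false absences, dating
uncertainty, off-grid coastal points — not any real climate field, taxon,
or compilation. Demonstrating that the pipeline recovers planted signal
and reproduces the expected bias responses validates the machinery, not
any substantive claim about a real species. Real records add taxonomic
ambiguity, spatially autocorrelated sampling effort, and calibration-curve
dating structure that the generator does not model.

## Measurement choices in the acceptance checks

The end-to-end checks run at n = 200 sites on the default 50 × 48 grid with
all eight slices — sizes chosen so the full suite and the acceptance script
each run in seconds while leaving hundreds of pooled observations. The
sensitivity-trend check averages the metric curves over 32 seeded
world/record/model replicates (NaN-aware mean) before taking Spearman trend
signs across cutoffs 1–5: a single 200-site draw leaves only a few dozen
observations at cutoff 5, where 5-point rank correlations are dominated by
noise; averaging replicates measures the generator's expected behaviour,
which is the property of interest. Permutation-null bands for AUC/TSS use
200 label permutations and the 97.5 % quantile.

## Numerical details

- Snapping and maxSSS tie-breaks are resolved within explicit float
  tolerances (relative 1e-9 on distances, 1e-12 on TPR+TNR); attainable
  distinct values differ by far more in both cases, so the tolerances
  cannot merge genuinely different optima.
- ASCII-grid values outside [0, 1] are clipped on read, with a reported
  per-slice count; nodata cells become NaN behind a boolean mask.
- Great-circle distances use the haversine with R = 6371.0088 km.
- Pseudoabsence sampling is uniform without replacement over eligible valid
  cells (centers ≥ buffer distance from every presence, or outside the
  exclusion polygon), seeded via `numpy.random.default_rng`.
- The baseline model plugin standardises covariates, expands degree-2
  polynomial terms and fits an L2-regularised logistic regression; outputs
  beyond 1e-6 outside [0, 1] are a contract violation, smaller excursions
  are clipped.

## Known limitations

- No coordinate-reference-system transformations or raster resampling: all
  inputs must share one WGS84 lon/lat grid.
- Absence inference treats any assemblage lacking the taxon as an absence
  record; occupancy-style detection modelling is out of scope.
- The eight published SDM algorithm families are deliberately not
  re-implemented; the plugin registry plus the quadratic-logistic baseline
  keep the framework exercisable end-to-end.
- Radiocarbon calibration, taxonomy reconciliation and statistical
  comparison across model families (Kruskal–Wallis / Dunn) are outside the
  package's scope.
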