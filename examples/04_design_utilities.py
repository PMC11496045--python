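"""Occurrence-design utilities: thinning, pseudoabsences, the experiment
grid and the baseline model plugin.

Run:  python examples/04_design_utilities.py
"""

import numpy as np

from paleoeval import (
    DEFAULT_SCHEME,
    QuadraticLogisticModel,
    WorldSpec,
    background_cells,
    ensemble_weighted,
    experiment_grid,
    generate_stack,
    rank_auc,
    run_tasks,
    sample_pseudoabsences,
    thin_to_grid,
)

stack, _ = generate_stack(WorldSpec(seed=4))
grid = stack[stack.labels[0]]
rng = np.random.default_rng(0)

# 1. spatial thinning: clustered sightings -> one point per raster cell
rows, cols, lons, lats = grid.valid_centers()
hot = rng.choice(len(lons), size=40, replace=False)
cloud = np.concatenate(
    [np.column_stack([lons[hot] + rng.normal(0, 0.3, 40),
                      lats[hot] + rng.normal(0, 0.3, 40)]) for _ in range(12)]
)
thinned = thin_to_grid(cloud, grid)
print(f"thinning: {len(cloud)} clustered sightings -> {len(thinned)} "
      "one-per-cell occurrences")

# 2. pseudoabsences outside 100-km buffers, matched in number to presences;
# presences are drawn from high-suitability cells so there is a real
# environmental signal for the model to learn
vals = grid.values[rows, cols]
good = np.nonzero(vals > 0.7)[0]
pick = rng.choice(good, size=25, replace=False)
presences = np.column_stack([lons[pick], lats[pick]])
pseudo = sample_pseudoabsences(presences, grid, n=len(presences), seed=1,
                               buffer_km=100.0)
print(f"pseudoabsences: {len(pseudo)} points sampled outside 100-km buffers "
      f"around {len(presences)} presences")
print(f"background: all {len(background_cells(grid))} valid cells")

# 3. the full experiment design
tasks = experiment_grid(3, 10,
                        ["BART", "GLM", "GAM", "GAU", "SVM", "MaxEnt", "RF",
                         "GBM", "Ensemble"],
                        DEFAULT_SCHEME.labels)
print(f"experiment grid: 3 datasets x 10 replicates x 9 frameworks x "
      f"8 slices = {len(tasks)} projections")

# 4. fit the baseline plugin and project two slices, then ensemble them
covs = {lab: {"suitability": stack[lab]} for lab in stack.labels[:2]}
small = experiment_grid(1, 1, ["logistic"], list(covs))
out = run_tasks(small, {"logistic": QuadraticLogisticModel},
                {(0, 0): (presences, pseudo)}, covs)
surfaces = list(out.values())
ens = ensemble_weighted(surfaces, weights=[0.6, 0.4])
scores = np.concatenate([
    [surfaces[0][grid.transform.index_of(lon, lat)] for lon, lat in presences],
    [surfaces[0][grid.transform.index_of(lon, lat)] for lon, lat in pseudo],
])
labels = np.concatenate([np.ones(len(presences)), np.zeros(len(pseudo))])
print(f"baseline quadratic-logistic plugin: training AUC = "
      f"{rank_auc(scores, labels):.3f}")
print(f"TSS-weighted ensemble of 2 projections: mean suitability "
      f"{np.nanmean(ens):.3f} (cellwise between the members' min and max)")
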