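"""Occurrence/absence design utilities of the SDM workflow.

These are the data-preparation steps that sit upstream of the evaluation:
spatial thinning of clustered occurrences to one point per raster cell,
pseudoabsence sampling outside exclusion buffers or range polygons,
background-cell enumeration, TSS-weighted ensembling of model projections,
and enumeration of the full experiment design (dataset x pseudoabsence
replicate x algorithm x time slice) with a pluggable model interface.

The modelling algorithms themselves are external; :class:`QuadraticLogisticModel`
ships as a transparent baseline plugin (a logistic regression on degree-2
polynomial covariates, the classic parametric SDM) so the whole framework
runs end-to-end.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
from shapely.geometry import Point
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .errors import (
    InfeasibleSampleError,
    MissingPluginError,
    NoValidCellError,
    PluginContractError,
)
from .grids import SuitabilityGrid, haversine_km


@dataclass(frozen=True)
class OccurrenceSet:
    """A named set of occurrence points (lon/lat rows)."""

    label: str
    points: np.ndarray  # shape (n, 2): columns lon, lat
    provenance: str = "other"  # thinned | polygon-cells | other

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


def thin_to_grid(points, grid: SuitabilityGrid, label: str = "thinned") -> OccurrenceSet:
    """Spatial thinning: keep at most one point per raster cell.

    The first point (in input order) falling in each cell is retained;
    points outside the grid extent are dropped.  Output preserves input
    order, so the operation is deterministic and idempotent.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    seen: set[tuple[int, int]] = set()
    kept = []
    for lon, lat in points:
        idx = grid.transform.index_of(float(lon), float(lat))
        if idx is None or idx in seen:
            continue
        seen.add(idx)
        kept.append((lon, lat))
    return OccurrenceSet(
        label=label,
        points=np.asarray(kept, dtype=float).reshape(-1, 2),
        provenance="thinned",
    )


def background_cells(grid: SuitabilityGrid) -> np.ndarray:
    """Centers of every valid cell (row-major), presences included."""
    if grid.n_valid == 0:
        raise NoValidCellError("grid has no valid cells")
    _, _, lons, lats = grid.valid_centers()
    return np.column_stack([lons, lats])


def sample_pseudoabsences(
    presences,
    grid: SuitabilityGrid,
    n: int,
    seed: int,
    buffer_km: float | None = None,
    polygon=None,
) -> np.ndarray:
    """Sample n pseudoabsence points uniformly from eligible valid cells.

    Exactly one exclusion rule applies: ``buffer_km`` keeps only cells whose
    centers are at least that great-circle distance from *every* presence
    point; ``polygon`` (a shapely geometry) keeps only cells outside it.
    Sampling is uniform without replacement and reproducible for a fixed
    seed.  Raises :class:`InfeasibleSampleError` (reporting the eligible
    count) when fewer than n cells qualify.
    """
    if (buffer_km is None) == (polygon is None):
        raise ValueError("specify exactly one of buffer_km or polygon")
    if n < 1:
        raise ValueError("n must be >= 1")
    presences = np.asarray(presences, dtype=float).reshape(-1, 2)
    if grid.n_valid == 0:
        raise NoValidCellError("grid has no valid cells")

    _, _, lons, lats = grid.valid_centers()
    if buffer_km is not None:
        if buffer_km <= 0:
            raise ValueError("buffer_km must be positive")
        eligible = np.ones(lons.shape, dtype=bool)
        for plon, plat in presences:
            eligible &= haversine_km(plon, plat, lons, lats) >= buffer_km
    else:
        eligible = np.array(
            [not polygon.covers(Point(lon, lat)) for lon, lat in zip(lons, lats)]
        )

    idx = np.nonzero(eligible)[0]
    if idx.size < n:
        raise InfeasibleSampleError(requested=n, eligible=int(idx.size))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n, replace=False)
    return np.column_stack([lons[chosen], lats[chosen]])


def ensemble_weighted(predictions: Sequence, weights: Sequence[float]) -> np.ndarray:
    """Cell-wise weighted average of aligned suitability surfaces.

    Intended for TSS-weighted ensembling: pass each member model's skill
    (TSS, or rescaled TSS) as its weight.  Accepts 2-D arrays or
    :class:`SuitabilityGrid` objects; returns a plain array.
    """
    if len(predictions) == 0:
        raise ValueError("need at least one prediction surface")
    arrays = [
        p.values if isinstance(p, SuitabilityGrid) else np.asarray(p, dtype=float)
        for p in predictions
    ]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("prediction surfaces are not aligned")
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(arrays),):
        raise ValueError("one weight per prediction surface required")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() == 0:
        raise ValueError("weights must not be all zero")
    stackarr = np.stack(arrays)
    return np.tensordot(w, stackarr, axes=1) / w.sum()


@dataclass(frozen=True, order=True)
class ExperimentTask:
    """One projection of the experiment design."""

    dataset: int
    replicate: int
    algorithm: str
    slice_label: str


def experiment_grid(
    n_datasets: int,
    n_replicates: int,
    algorithms: Sequence[str],
    slices: Sequence[str],
) -> list[ExperimentTask]:
    """Full Cartesian design, in lexicographic (dataset, replicate,
    algorithm, slice) order; size is the product of the four counts."""
    if n_datasets < 1 or n_replicates < 1 or not algorithms or not slices:
        raise ValueError("all design dimensions must be >= 1")
    return [
        ExperimentTask(d, r, str(alg), str(lab))
        for d, r, alg, lab in itertools.product(
            range(n_datasets), range(n_replicates), algorithms, slices
        )
    ]


class ModelPlugin(Protocol):
    """Contract every modelling-algorithm plugin satisfies."""

    def fit(self, presences, absences, covariates: Mapping[str, SuitabilityGrid]) -> None:
        """Fit on presence and absence points against covariate surfaces."""

    def predict(self, covariates: Mapping[str, SuitabilityGrid]) -> np.ndarray:
        """Suitability in [0, 1] per cell (NaN where any covariate is invalid)."""


def _covariate_matrix(points: np.ndarray, covariates: Mapping[str, SuitabilityGrid]) -> np.ndarray:
    from .grids import extract_suitability

    cols = [
        extract_suitability(grid, points[:, 0], points[:, 1])
        for grid in covariates.values()
    ]
    return np.column_stack(cols)


class QuadraticLogisticModel:
    """Baseline SDM plugin: logistic regression on degree-2 polynomial
    covariate terms, fit to presence (1) vs absence (0) points."""

    def __init__(self, C: float = 1.0):
        self._pipe = make_pipeline(
            StandardScaler(),
            PolynomialFeatures(degree=2, include_bias=False),
            LogisticRegression(C=C, max_iter=1000),
        )
        self._names: tuple[str, ...] | None = None

    def fit(self, presences, absences, covariates):
        presences = np.asarray(presences, dtype=float).reshape(-1, 2)
        absences = np.asarray(absences, dtype=float).reshape(-1, 2)
        x = np.vstack(
            [
                _covariate_matrix(presences, covariates),
                _covariate_matrix(absences, covariates),
            ]
        )
        y = np.concatenate([np.ones(len(presences)), np.zeros(len(absences))])
        keep = ~np.isnan(x).any(axis=1)
        if keep.sum() == 0 or len(set(y[keep])) < 2:
            raise ValueError("need presence and absence points on valid cells")
        self._names = tuple(covariates)
        self._pipe.fit(x[keep], y[keep])

    def predict(self, covariates):
        if self._names is None:
            raise RuntimeError("fit before predict")
        grids = [covariates[name] for name in self._names]
        mask = np.logical_and.reduce([g.mask for g in grids])
        x = np.column_stack([g.values[mask] for g in grids])
        out = np.full(mask.shape, np.nan)
        out[mask] = self._pipe.predict_proba(x)[:, 1]
        return out


def run_tasks(
    tasks: Sequence[ExperimentTask],
    plugins: Mapping[str, Callable[[], ModelPlugin]],
    training_data: Mapping[tuple[int, int], tuple[np.ndarray, np.ndarray]],
    covariates: Mapping[str, Mapping[str, SuitabilityGrid]],
    clip_tolerance: float = 1e-6,
) -> dict[ExperimentTask, np.ndarray]:
    """Execute an experiment design: one suitability surface per task.

    Parameters
    ----------
    plugins:
        algorithm label -> factory returning a fresh :class:`ModelPlugin`.
    training_data:
        (dataset, replicate) -> (presence points, absence points).
    covariates:
        slice label -> {covariate name -> grid}; a model is fitted once per
        (dataset, replicate, algorithm) on the most recent slice's
        covariates and projected onto every slice of its tasks.

    Plugin outputs farther than ``clip_tolerance`` outside [0, 1] raise
    :class:`PluginContractError`; smaller excursions are clipped.
    """
    missing = sorted({t.algorithm for t in tasks} - set(plugins))
    if missing:
        raise MissingPluginError(f"no plugin registered for algorithm(s) {missing}")

    fit_labels = {lab: covs for lab, covs in covariates.items()}
    # fit on the youngest available slice (the "present-day" analogue)
    fit_slice = next(iter(fit_labels))

    fitted: dict[tuple[int, int, str], ModelPlugin] = {}
    results: dict[ExperimentTask, np.ndarray] = {}
    for task in tasks:
        key = (task.dataset, task.replicate, task.algorithm)
        if key not in fitted:
            model = plugins[task.algorithm]()
            pres, absn = training_data[(task.dataset, task.replicate)]
            model.fit(pres, absn, covariates[fit_slice])
            fitted[key] = model
        surface = np.asarray(fitted[key].predict(covariates[task.slice_label]), dtype=float)
        finite = surface[~np.isnan(surface)]
        if finite.size and (
            finite.min() < -clip_tolerance or finite.max() > 1.0 + clip_tolerance
        ):
            raise PluginContractError(
                f"plugin {task.algorithm!r} produced values in "
                f"[{finite.min():.3g}, {finite.max():.3g}], outside [0, 1]"
            )
        results[task] = np.clip(surface, 0.0, 1.0)
    return results
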