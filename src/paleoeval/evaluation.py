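"""Paleometric evaluation of a suitability stack against fossil records.

:func:`paleo_eval` is the pipeline: slice the dated records, snap each
observation onto the evaluated slice's grid, extract suitability, tally a
per-slice confusion matrix at the supplied threshold, and compute the full
metric set per slice and pooled across slices.  The pooled confusion matrix
is by construction the element-wise sum of the per-slice matrices.

:func:`sensitivity_curve` is the taphonomic-bias probe: sites are dropped
in order of species richness (all sites with richness < k removed at cutoff
k) and the pooled metrics recomputed, revealing how much each metric leans
on the sparsely sampled — hence least trustworthy — absence sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import EmptyEvaluationError, MissingSliceError
from .grids import SuitabilityStack, snap_to_valid
from .metrics import (
    ConfusionMatrix,
    MetricSet,
    confusion_from_scores,
    continuous_boyce,
    imae,
    rank_auc,
    threshold_metrics,
)
from .records import (
    DEFAULT_SCHEME,
    PRESENCE,
    PaleoSite,
    TimeSliceScheme,
    assign_time_slices,
    presence_absence_table,
    site_richness,
)


@dataclass(frozen=True)
class EvaluationConfig:
    """Knobs of one paleometric evaluation.

    threshold
        Suitability cut-off converting continuous projections to binary
        presence/absence (``score >= threshold`` predicts presence).
        Normally derived from present-day calibration, e.g. via
        :func:`paleoeval.metrics.maxsss_threshold`.
    slice_mode
        ``"interval"`` assigns a record to every slice its date interval
        overlaps; ``"midpoint"`` only to the slice of the interval midpoint.
    aggregation
        ``"per_slice"``, ``"pooled"`` or ``"both"`` — which metric sets to
        report (confusion matrices are always computed per slice).
    beta
        F-score recall weight; 2 emphasises recall, appropriate when
        absences are the less reliable class.
    boyce_background
        ``"grid"`` scores every valid cell of the evaluated slice as the
        Boyce background; ``"sites"`` uses the observation scores instead.
    """

    threshold: float
    slice_mode: str = "interval"
    aggregation: str = "both"
    beta: float = 2.0
    boyce_background: str = "grid"
    boyce_n_windows: int = 101
    boyce_window_fraction: float = 0.1
    snap_max_radius_km: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.slice_mode not in ("interval", "midpoint"):
            raise ValueError("slice_mode must be 'interval' or 'midpoint'")
        if self.aggregation not in ("pooled", "per_slice", "both"):
            raise ValueError("aggregation must be pooled|per_slice|both")
        if self.boyce_background not in ("grid", "sites"):
            raise ValueError("boyce_background must be 'grid' or 'sites'")


@dataclass
class RecordCounts:
    """Bookkeeping of what happened to the records during evaluation."""

    n_sites: int = 0
    n_sites_out_of_range: int = 0
    n_observations: int = 0
    n_snapped: int = 0  # moved onto a valid cell
    n_dropped_unsnappable: int = 0
    per_slice_observations: dict[str, int] = field(default_factory=dict)


@dataclass
class EvaluationResult:
    per_slice: dict[str, MetricSet]
    pooled: MetricSet | None
    per_slice_cm: dict[str, ConfusionMatrix]
    pooled_cm: ConfusionMatrix
    counts: RecordCounts


def _metric_set(
    scores: np.ndarray,
    labels: np.ndarray,
    background: np.ndarray,
    config: EvaluationConfig,
) -> tuple[MetricSet, ConfusionMatrix]:
    cm = confusion_from_scores(scores, labels, config.threshold)
    ms = threshold_metrics(cm, beta=config.beta)
    ms.auc = rank_auc(scores, labels)
    ms.imae = imae(scores, labels)
    pres_scores = scores[labels == 1]
    if pres_scores.size and background.size:
        ms.boyce = continuous_boyce(
            pres_scores,
            background,
            n_windows=config.boyce_n_windows,
            window_fraction=config.boyce_window_fraction,
        )
    return ms, cm


def paleo_eval(
    stack: SuitabilityStack,
    sites: list[PaleoSite],
    taxon: str,
    scheme: TimeSliceScheme = DEFAULT_SCHEME,
    config: EvaluationConfig | None = None,
) -> EvaluationResult:
    """Evaluate a suitability stack against dated presence/absence records.

    Raises :class:`EmptyEvaluationError` if no observation survives slicing
    and snapping, and :class:`MissingSliceError` if records fall in a slice
    the stack has no raster for.
    """
    if config is None:
        raise ValueError("an EvaluationConfig (with a threshold) is required")

    counts = RecordCounts(n_sites=len({s.site_id for s in sites}))
    counts.n_sites_out_of_range = sum(
        1 for s in sites if not assign_time_slices(s, scheme, config.slice_mode)
    )

    observations = presence_absence_table(sites, taxon, scheme, config.slice_mode)
    used_labels = sorted(
        {o.slice_label for o in observations},
        key=lambda lab: scheme.labels.index(lab),
    )
    missing = [lab for lab in used_labels if lab not in stack.labels]
    if missing:
        raise MissingSliceError(
            f"records assigned to slice(s) {missing} but the stack has no "
            f"raster for them"
        )

    slice_scores: dict[str, np.ndarray] = {}
    slice_labels_: dict[str, np.ndarray] = {}
    for lab in used_labels:
        grid = stack[lab]
        sc, lb = [], []
        for obs in observations:
            if obs.slice_label != lab:
                continue
            snap = snap_to_valid(
                obs.longitude, obs.latitude, grid, config.snap_max_radius_km
            )
            if snap is None:
                counts.n_dropped_unsnappable += 1
                continue
            if snap.moved:
                counts.n_snapped += 1
            sc.append(grid.values[snap.row, snap.col])
            lb.append(1 if obs.status == PRESENCE else 0)
        if sc:
            slice_scores[lab] = np.asarray(sc, dtype=float)
            slice_labels_[lab] = np.asarray(lb, dtype=int)
            counts.per_slice_observations[lab] = len(sc)

    counts.n_observations = sum(counts.per_slice_observations.values())
    if counts.n_observations == 0:
        raise EmptyEvaluationError(
            "no observation survived time-slicing and snapping"
        )

    per_slice: dict[str, MetricSet] = {}
    per_slice_cm: dict[str, ConfusionMatrix] = {}
    backgrounds = []
    for lab, sc in slice_scores.items():
        bg = (
            stack[lab].valid_values()
            if config.boyce_background == "grid"
            else sc
        )
        backgrounds.append(bg)
        ms, cm = _metric_set(sc, slice_labels_[lab], bg, config)
        per_slice_cm[lab] = cm
        if config.aggregation in ("per_slice", "both"):
            per_slice[lab] = ms

    pooled_cm = ConfusionMatrix(0, 0, 0, 0)
    for cm in per_slice_cm.values():
        pooled_cm = pooled_cm + cm

    pooled = None
    if config.aggregation in ("pooled", "both"):
        all_scores = np.concatenate(list(slice_scores.values()))
        all_labels = np.concatenate(list(slice_labels_.values()))
        # pooled Boyce keeps per-slice background context by concatenation
        all_bg = np.concatenate(backgrounds)
        pooled, _ = _metric_set(all_scores, all_labels, all_bg, config)

    return EvaluationResult(
        per_slice=per_slice,
        pooled=pooled,
        per_slice_cm=per_slice_cm,
        pooled_cm=pooled_cm,
        counts=counts,
    )


def sensitivity_curve(
    stack: SuitabilityStack,
    sites: list[PaleoSite],
    taxon: str,
    scheme: TimeSliceScheme = DEFAULT_SCHEME,
    config: EvaluationConfig | None = None,
    max_richness_cutoff: int = 5,
) -> pd.DataFrame:
    """Pooled paleometrics as low-richness sites are progressively removed.

    At cutoff k all sites with species richness < k are excluded, so cutoff
    1 is the unfiltered evaluation.  A cutoff that leaves nothing (or a
    single class) yields undefined metrics (NaN), not a failure.  Default
    cutoff 5 removes everything below five recorded species; 10 extends the
    probe further into the well-sampled sites.
    """
    if config is None:
        raise ValueError("an EvaluationConfig (with a threshold) is required")
    if max_richness_cutoff < 1:
        raise ValueError("max_richness_cutoff must be >= 1")
    richness = site_richness(sites)

    pooled_cfg = EvaluationConfig(
        **{**asdict(config), "aggregation": "pooled"}
    )
    rows = []
    for cutoff in range(1, max_richness_cutoff + 1):
        kept = [s for s in sites if richness[s.site_id] >= cutoff]
        row: dict = {
            "richness_cutoff": cutoff,
            "n_sites": len({s.site_id for s in kept}),
        }
        try:
            res = paleo_eval(stack, kept, taxon, scheme, pooled_cfg)
        except EmptyEvaluationError:
            row["n_observations"] = 0
            row.update({name: None for name in MetricSet.names()})
        else:
            row["n_observations"] = res.counts.n_observations
            row.update(res.pooled.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def metrics_frame(result: EvaluationResult) -> pd.DataFrame:
    """Metric sets as a tidy table: one row per slice plus a pooled row."""
    rows = []
    for lab, ms in result.per_slice.items():
        rows.append({"unit": lab, **ms.to_dict()})
    if result.pooled is not None:
        rows.append({"unit": "pooled", **result.pooled.to_dict()})
    return pd.DataFrame(rows)


def confusion_frame(result: EvaluationResult) -> pd.DataFrame:
    """Confusion matrices as a tidy table: one row per slice plus pooled."""
    rows = [
        {"unit": lab, "a": cm.a, "b": cm.b, "c": cm.c, "d": cm.d}
        for lab, cm in result.per_slice_cm.items()
    ]
    pc = result.pooled_cm
    rows.append({"unit": "pooled", "a": pc.a, "b": pc.b, "c": pc.c, "d": pc.d})
    return pd.DataFrame(rows)


def run_report(result: EvaluationResult, config: EvaluationConfig) -> dict:
    """JSON-ready summary of an evaluation run."""
    return {
        "config": asdict(config),
        "counts": {
            "n_sites": result.counts.n_sites,
            "n_sites_out_of_range": result.counts.n_sites_out_of_range,
            "n_observations": result.counts.n_observations,
            "n_snapped": result.counts.n_snapped,
            "n_dropped_unsnappable": result.counts.n_dropped_unsnappable,
            "per_slice_observations": result.counts.per_slice_observations,
        },
    }
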