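"""Hindcast evaluation metrics ("paleometrics").

All threshold-dependent metrics derive from a 2x2 confusion matrix tallied
at validation sites:

===============  ==================  ==================
                 observed presence   observed absence
predicted pres.  a (true positive)   b (false positive)
predicted abs.   c (false negative)  d (true negative)
===============  ==================  ==================

The prediction rule is ``score >= threshold`` (boundary counts as a
predicted presence).  Metrics with a zero denominator are *undefined* and
returned as ``None`` — never coerced to 0, never raised as an exception —
so that degenerate slices (all-presence, all-absence) propagate cleanly
through aggregation.

Threshold-independent metrics:

* ``rank_auc`` — the rank-sum (Mann-Whitney) form of the area under the ROC
  curve, with average ranks for ties;
* ``continuous_boyce`` — the moving-window continuous Boyce index: Spearman
  rank correlation between suitability-window mid-points and the
  predicted-to-expected (P/E) presence ratio against a background sample;
* ``imae`` — 1 minus the mean absolute error between suitability and the
  0/1 outcome, so that, like every other metric here, larger is better
  (the raw error is available as :func:`mae`).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "confusion_from_scores",
    "threshold_metrics",
    "rescale_tss",
    "rank_auc",
    "continuous_boyce",
    "mae",
    "imae",
    "maxsss_threshold",
]

#: serialization sentinel for undefined metric values, distinct from 0
UNDEFINED = "NA"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts a (TP), b (FP), c (FN), d (TN)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.a + other.a, self.b + other.b, self.c + other.c, self.d + other.d
        )


@dataclass
class MetricSet:
    """Named metric values for one evaluation unit (a slice, or pooled).

    ``None`` marks an undefined value (zero denominator or inapplicable).
    """

    tpr: float | None = None
    tnr: float | None = None
    fpr: float | None = None
    fnr: float | None = None
    tss: float | None = None
    tss_scaled: float | None = None
    accuracy: float | None = None
    precision: float | None = None
    prevalence: float | None = None
    f_score: float | None = None
    fdr: float | None = None
    sorensen: float | None = None
    jaccard: float | None = None
    odds_ratio: float | None = None
    kappa: float | None = None
    auc: float | None = None
    boyce: float | None = None
    imae: float | None = None

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def to_dict(self, undefined=None) -> dict:
        return {
            f.name: (undefined if getattr(self, f.name) is None else getattr(self, f.name))
            for f in fields(self)
        }


def _div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def confusion_from_scores(scores, labels, threshold: float) -> ConfusionMatrix:
    """Tally the confusion matrix of ``score >= threshold`` predictions.

    ``labels`` are 1/True for presence, 0/False for absence.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    if scores.size == 0:
        raise ValueError("empty input")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionMatrix(
        a=int(np.sum(pred & pos)),
        b=int(np.sum(pred & ~pos)),
        c=int(np.sum(~pred & pos)),
        d=int(np.sum(~pred & ~pos)),
    )


def threshold_metrics(cm: ConfusionMatrix, *, beta: float) -> MetricSet:
    """All threshold-dependent metrics of a confusion matrix.

    ``beta`` is the F-score recall weight and is deliberately explicit:
    beta=1 gives the harmonic mean of precision and recall (identical to
    the Sørensen index), beta=2 weights recall twice as heavily — the
    natural choice when false absences are less trustworthy than false
    presences, as in fossil validation data.
    """
    a, b, c, d = cm.a, cm.b, cm.c, cm.d
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")

    m = MetricSet()
    m.tpr = _div(a, a + c)
    m.tnr = _div(d, b + d)
    m.fpr = _div(b, b + d)
    m.fnr = _div(c, a + c)
    if m.tpr is not None and m.tnr is not None:
        m.tss = m.tpr + m.tnr - 1.0
        m.tss_scaled = rescale_tss(m.tss)
    m.accuracy = (a + d) / n
    m.precision = _div(a, a + b)
    m.prevalence = (a + c) / n
    if m.precision is not None and m.tpr is not None:
        m.f_score = _div(
            (1.0 + beta**2) * m.precision * m.tpr,
            beta**2 * m.precision + m.tpr,
        )
    m.fdr = _div(b, a + b)
    m.sorensen = _div(2 * a, 2 * a + b + c)
    m.jaccard = _div(a, a + b + c)
    m.odds_ratio = _div(a * d, b * c)
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    m.kappa = _div(po - pe, 1.0 - pe)
    return m


def rescale_tss(tss: float) -> float:
    """Affine map of TSS from [-1, 1] onto [0, 1]: (TSS + 1) / 2."""
    if not -1.0 <= tss <= 1.0:
        raise ValueError(f"TSS must lie in [-1, 1], got {tss}")
    return (tss + 1.0) / 2.0


def rank_auc(scores, labels) -> float | None:
    """Area under the ROC curve via the rank-sum identity.

    AUC = (R - n1(n1+1)/2) / (n1 n2), with R the sum of the (average, for
    ties) ranks of the presence scores.  Undefined (None) when only one
    class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    n1 = int(np.sum(labels == 1))
    n2 = int(np.sum(labels == 0))
    if n1 == 0 or n2 == 0:
        return None
    ranks = stats.rankdata(scores)  # average ranks for ties
    r = float(ranks[labels == 1].sum())
    return (r - n1 * (n1 + 1) / 2.0) / (n1 * n2)


def continuous_boyce(
    presence_scores,
    background_scores,
    n_windows: int = 101,
    window_fraction: float = 0.1,
) -> float | None:
    """Continuous Boyce index.

    Overlapping suitability windows of width ``window_fraction`` times the
    background score range, with mid-points evenly spanning that range,
    each yield a predicted-to-expected ratio P/E = (fraction of presences
    in the window) / (fraction of background in the window).  Windows with
    no background are dropped.  The index is the Spearman rank correlation
    between window mid-points and P/E; a well-calibrated model predicts
    presences increasingly often as suitability rises, giving values near
    +1.  Undefined (None) with fewer than 3 usable windows or a degenerate
    (constant) P/E profile.
    """
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("presence and background scores must be non-empty")
    if n_windows < 3:
        raise ValueError("n_windows must be at least 3")
    if not 0.0 < window_fraction <= 1.0:
        raise ValueError("window_fraction must lie in (0, 1]")

    lo, hi = float(bg.min()), float(bg.max())
    width = window_fraction * (hi - lo)
    if width == 0.0:
        return None
    mids = np.linspace(lo + width / 2.0, hi - width / 2.0, n_windows)

    pe = []
    used_mids = []
    for mid in mids:
        wlo, whi = mid - width / 2.0, mid + width / 2.0
        e = np.mean((bg >= wlo) & (bg <= whi))
        if e == 0:
            continue
        p = np.mean((pres >= wlo) & (pres <= whi))
        pe.append(p / e)
        used_mids.append(mid)
    if len(pe) < 3:
        return None
    pe = np.asarray(pe)
    if np.all(pe == pe[0]):
        return None
    rho = stats.spearmanr(used_mids, pe).statistic
    return None if np.isnan(rho) else float(rho)


def mae(scores, labels) -> float:
    """Raw mean absolute error between suitability and the 0/1 outcome."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(float)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    return float(np.mean(np.abs(labels - scores)))


def imae(scores, labels) -> float:
    """Index of model absolute error: 1 - MAE, so higher is better."""
    return 1.0 - mae(scores, labels)


def maxsss_threshold(scores, labels) -> float | None:
    """Threshold maximising sensitivity + specificity (equivalently TSS).

    Candidates are the observed scores; ties resolve to the smallest such
    threshold.  Undefined (None) when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    n1 = int(np.sum(labels == 1))
    n2 = int(np.sum(labels == 0))
    if n1 == 0 or n2 == 0:
        return None
    candidates = np.unique(scores)  # ascending
    # vectorised TPR/TNR over candidates: pred[i, j] = scores[j] >= cand[i]
    pred = scores[None, :] >= candidates[:, None]
    pos = labels == 1
    tpr = pred[:, pos].sum(axis=1) / n1
    tnr = (~pred[:, ~pos]).sum(axis=1) / n2
    total = tpr + tnr
    # smallest candidate within float round-off of the optimum (distinct
    # attainable values differ by at least 1/(n1*n2), far above 1e-12)
    k = int(np.argmax(total >= total.max() - 1e-12))
    return float(candidates[k])
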