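"""Metric formulas against independent arithmetic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleoeval.metrics import (
    ConfusionMatrix,
    confusion_from_scores,
    continuous_boyce,
    imae,
    mae,
    maxsss_threshold,
    rank_auc,
    rescale_tss,
    threshold_metrics,
)


def oracle_metrics(a, b, c, d, beta):
    """Direct-arithmetic reference, independent of the implementation."""
    n = a + b + c + d
    out = {}
    out["tpr"] = a / (a + c) if a + c else None
    out["tnr"] = d / (b + d) if b + d else None
    out["fpr"] = b / (b + d) if b + d else None
    out["fnr"] = c / (a + c) if a + c else None
    out["tss"] = (
        out["tpr"] + out["tnr"] - 1
        if out["tpr"] is not None and out["tnr"] is not None
        else None
    )
    out["accuracy"] = (a + d) / n
    out["precision"] = a / (a + b) if a + b else None
    out["prevalence"] = (a + c) / n
    if out["precision"] is not None and out["tpr"] is not None:
        den = beta**2 * out["precision"] + out["tpr"]
        out["f_score"] = (
            (1 + beta**2) * out["precision"] * out["tpr"] / den if den else None
        )
    else:
        out["f_score"] = None
    out["fdr"] = b / (a + b) if a + b else None
    out["sorensen"] = 2 * a / (2 * a + b + c) if 2 * a + b + c else None
    out["jaccard"] = a / (a + b + c) if a + b + c else None
    out["odds_ratio"] = a * d / (b * c) if b * c else None
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    out["kappa"] = (po - pe) / (1 - pe) if 1 - pe else None
    return out


class TestConfusionFromScores:
    def test_perfect_separation(self):
        cm = confusion_from_scores([0.9, 0.1], [1, 0], 0.5)
        assert (cm.a, cm.b, cm.c, cm.d) == (1, 0, 0, 1)

    def test_inversion(self):
        cm = confusion_from_scores([0.9, 0.1], [0, 1], 0.5)
        assert (cm.a, cm.b, cm.c, cm.d) == (0, 1, 1, 0)

    def test_boundary_counts_as_presence(self):
        cm = confusion_from_scores([0.5], [1], 0.5)
        assert cm.a == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_from_scores([0.5, 0.2], [1], 0.5)


class TestThresholdMetrics:
    def test_perfect_classifier(self):
        m = threshold_metrics(ConfusionMatrix(5, 0, 0, 5), beta=1)
        assert m.tss == 1 and m.accuracy == 1 and m.sorensen == 1 and m.kappa == 1

    def test_worked_example_beta1(self):
        m = threshold_metrics(ConfusionMatrix(3, 2, 1, 4), beta=1)
        assert m.tpr == pytest.approx(0.75)
        assert m.tnr == pytest.approx(2 / 3)
        assert m.tss == pytest.approx(0.416667, abs=1e-6)
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.6)
        assert m.f_score == pytest.approx(0.666667, abs=1e-6)
        assert m.sorensen == pytest.approx(0.666667, abs=1e-6)
        assert m.jaccard == pytest.approx(0.5)
        assert m.odds_ratio == pytest.approx(6.0)
        assert m.kappa == pytest.approx(0.4)

    def test_worked_example_beta2(self):
        m = threshold_metrics(ConfusionMatrix(3, 2, 1, 4), beta=2)
        assert m.f_score == pytest.approx(0.714286, abs=1e-6)

    def test_zero_denominators_yield_none_not_exception(self):
        m = threshold_metrics(ConfusionMatrix(0, 0, 0, 4), beta=1)
        assert m.tpr is None and m.tss is None and m.precision is None
        assert m.accuracy == 1.0

    def test_kappa_zero_for_constant_predictions(self):
        # all predicted present: agreement no better than chance
        m = threshold_metrics(ConfusionMatrix(3, 7, 0, 0), beta=1)
        assert m.kappa == pytest.approx(0.0)

    @settings(max_examples=300, deadline=None)
    @given(
        st.tuples(
            st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
        ).filter(lambda t: sum(t) > 0),
        st.sampled_from([0.5, 1.0, 2.0]),
    )
    def test_matches_oracle_and_identities(self, counts, beta):
        a, b, c, d = counts
        m = threshold_metrics(ConfusionMatrix(a, b, c, d), beta=beta)
        ref = oracle_metrics(a, b, c, d, beta)
        for name, want in ref.items():
            got = getattr(m, name)
            if want is None:
                assert got is None, name
            else:
                assert got == pytest.approx(want, abs=1e-12), name
        # TSS identity and probability ranges
        if m.tpr is not None and m.tnr is not None:
            assert m.tss == pytest.approx(m.tpr + m.tnr - 1, abs=1e-12)
        for name in ("tpr", "tnr", "fpr", "fnr", "accuracy", "precision",
                     "prevalence", "fdr", "sorensen", "jaccard"):
            v = getattr(m, name)
            assert v is None or 0.0 <= v <= 1.0
        # Sørensen = F1 and Sørensen-Jaccard identity
        m1 = threshold_metrics(ConfusionMatrix(a, b, c, d), beta=1)
        if m1.f_score is not None and m1.sorensen is not None:
            assert m1.f_score == pytest.approx(m1.sorensen, abs=1e-12)
        if m1.jaccard is not None and m1.sorensen is not None:
            assert m1.sorensen == pytest.approx(
                2 * m1.jaccard / (1 + m1.jaccard), abs=1e-12
            )


class TestRescaleTss:
    @pytest.mark.parametrize("tss,expected", [(1, 1), (-1, 0), (0.416667, 0.708333)])
    def test_affine_map(self, tss, expected):
        assert rescale_tss(tss) == pytest.approx(expected, abs=1e-6)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            rescale_tss(1.2)


def auc_bruteforce(scores, labels):
    """Concordant-pair fraction with ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pres = scores[labels == 1]
    absn = scores[labels == 0]
    total = 0.0
    for p in pres:
        for q in absn:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pres) * len(absn))


class TestRankAuc:
    def test_perfect(self):
        assert rank_auc([0.9, 0.8, 0.4, 0.1], [1, 1, 0, 0]) == 1.0

    def test_worked_example(self):
        assert rank_auc([0.8, 0.6, 0.7, 0.2], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_single_class_undefined(self):
        assert rank_auc([0.5, 0.6], [1, 1]) is None

    def test_matches_bruteforce_with_ties_and_antisymmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(2, 31))
            # coarse rounding forces ties
            scores = np.round(rng.random(n), 1)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            got = rank_auc(scores, labels)
            assert got == pytest.approx(auc_bruteforce(scores, labels), abs=1e-12)
            assert rank_auc(scores, 1 - labels) == pytest.approx(1.0 - got, abs=1e-12)


class TestContinuousBoyce:
    def test_monotone_gradient_is_one(self):
        # presence density rising with suitability over a uniform background:
        # P/E strictly increases with window mid-point, so Spearman = 1
        bg = np.linspace(0.0, 1.0, 1001)
        pres = np.repeat(bg, (1 + 100 * bg).astype(int))
        assert continuous_boyce(pres, bg) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_subsample_null_is_centred(self):
        bg = np.linspace(0.0, 1.0, 1001)
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pres = rng.choice(bg, size=300, replace=False)
            b = continuous_boyce(pres, bg)
            assert -1.0 <= b <= 1.0
            vals.append(b)
        assert abs(np.mean(vals)) < 0.3

    def test_reversed_gradient_negative(self):
        bg = np.linspace(0.0, 1.0, 1001)
        pres = np.repeat(bg, (1 + 100 * (1 - bg)).astype(int))
        b = continuous_boyce(pres, bg)
        assert -1.0 <= b < 0.0

    def test_constant_background_undefined(self):
        assert continuous_boyce([0.5, 0.5], [0.5] * 10) is None

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            continuous_boyce([], [0.1, 0.2])


class TestImae:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [([1, 0], [1, 0], 1.0), ([0.5, 0.5], [1, 0], 0.5), ([0, 1], [1, 0], 0.0)],
    )
    def test_values(self, scores, labels, expected):
        assert imae(scores, labels) == pytest.approx(expected)

    def test_complements_raw_mae(self):
        rng = np.random.default_rng(2)
        s, y = rng.random(40), rng.integers(0, 2, 40)
        assert imae(s, y) == pytest.approx(1.0 - mae(s, y))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            imae([], [])


def maxsss_bruteforce(scores, labels):
    """Best TPR+TNR over a dense threshold sweep."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best = -np.inf
    for t in np.linspace(0.0, 1.0, 2001):
        pred = scores >= t
        tpr = (pred & (labels == 1)).sum() / (labels == 1).sum()
        tnr = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        best = max(best, tpr + tnr)
    return best


class TestMaxSss:
    def test_separated_example(self):
        assert maxsss_threshold([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 0.8

    def test_degenerate_equal_scores(self):
        assert maxsss_threshold([0.4, 0.4, 0.4], [1, 0, 1]) == 0.4

    def test_single_class_undefined(self):
        assert maxsss_threshold([0.2, 0.4], [1, 1]) is None

    def test_achieves_dense_sweep_optimum_and_smallest_tie(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            t = maxsss_threshold(scores, labels)
            pred = scores >= t
            tpr = (pred & (labels == 1)).sum() / (labels == 1).sum()
            tnr = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            assert tpr + tnr == pytest.approx(maxsss_bruteforce(scores, labels), abs=1e-12)
            # smallest threshold among equally good observed candidates
            for cand in np.unique(scores):
                if cand >= t:
                    continue
                p2 = scores >= cand
                v2 = (p2 & (labels == 1)).sum() / (labels == 1).sum() + (
                    ~p2 & (labels == 0)
                ).sum() / (labels == 0).sum()
                # strictly worse: t is the smallest maximizing candidate
                assert v2 < tpr + tnr - 1e-6
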