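"""Every statistic against an independent brute-force oracle, plus the
hand-computed fixtures and library cross-checks."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import collascore as cs
from collascore.agreement_stats import (
    binary_metrics,
    confusion,
    dice,
    icc_2_1,
    multiclass_accuracy,
    per_class_recall,
    roc_auc,
    spearman,
)


# ---------------------------------------------------------------------------
# brute-force oracles (definitional, independent of the implementations)

def bf_auc(scores, labels):
    """Enumerate every positive-negative pair; ties count 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def bf_mcc(tp, tn, fp, fn):
    num = tp * tn - fp * fn
    den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return num / den


def bf_icc_2_1(m):
    """Explicit two-way ANOVA sums of squares."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.mean()
    msr = k * ((m.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((m.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((m - grand) ** 2).sum() - (n - 1) * msr - (k - 1) * msc
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def bf_spearman(x, y):
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


# ---------------------------------------------------------------------------

class TestDice:
    def test_identical_disjoint_half_overlap(self):
        a = np.zeros((10, 10, 10), bool)
        a[:5] = True
        assert dice(a, a) == 1.0
        b = np.zeros_like(a)
        b[5:] = True
        assert dice(a, b) == 0.0
        c = np.zeros_like(a)
        c[2:7] = True  # |c|=500, |a|=500, overlap 300
        assert dice(a, c) == pytest.approx(600 / 1000)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((4, 4, 4), bool)
        assert dice(z, z) == 1.0

    def test_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, (6, 6, 6)) > 0.5
        b = rng.uniform(0, 1, (6, 6, 6)) > 0.5
        assert dice(a, b) == dice(b, a)
        perm = rng.permutation(a.size)
        assert dice(a.ravel()[perm].reshape(a.shape), b.ravel()[perm].reshape(b.shape)) == dice(a, b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2), bool), np.zeros((2, 2, 3), bool))


class TestConfusion:
    def test_perfect_agreement_is_diagonal(self):
        cm = confusion([0, 1, 2, 1], [0, 1, 2, 1], (0, 1, 2))
        assert np.array_equal(cm.counts, np.diag([1, 2, 1]))

    def test_absent_vocabulary_class_keeps_zero_row(self):
        cm = confusion([0, 0], [0, 1], (0, 1, 2))
        assert cm.counts[2].sum() == 0 and cm.counts[:, 2].sum() == 0
        assert cm.total == 2

    def test_transposing_inputs_swaps_marginals(self):
        ref, pred = [0, 0, 1, 2], [1, 0, 1, 0]
        a = confusion(ref, pred, (0, 1, 2))
        b = confusion(pred, ref, (0, 1, 2))
        assert np.array_equal(a.counts, b.counts.T)

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="9"):
            confusion([0, 9], [0, 0], (0, 1))


class TestBinaryMetrics:
    def test_hand_computed_fixture(self):
        # TP=40, TN=30, FP=10, FN=20 with positive class at index 1
        counts = np.array([[30, 10], [20, 40]])
        cm = cs.ConfusionMatrix(counts, ("poor", "good"))
        m = binary_metrics(cm, positive_index=1)
        assert m["accuracy"] == pytest.approx(0.7, abs=1e-9)
        assert m["sensitivity"] == pytest.approx(40 / 60, abs=1e-9)
        assert m["specificity"] == pytest.approx(0.75, abs=1e-9)
        assert m["mcc"] == pytest.approx(bf_mcc(40, 30, 10, 20), abs=1e-9)
        assert m["mcc"] == pytest.approx(0.408, abs=5e-4)

    def test_perfect_classifier_all_ones(self):
        cm = cs.ConfusionMatrix(np.array([[5, 0], [0, 7]]), ("poor", "good"))
        m = binary_metrics(cm)
        for key in ("accuracy", "f1", "sensitivity", "specificity", "mcc"):
            assert m[key] == 1.0

    def test_degenerate_all_positive_no_reference_negatives(self):
        # everything predicted (and referenced) positive: specificity 0/0
        cm = cs.ConfusionMatrix(np.array([[0, 0], [0, 6]]), ("poor", "good"))
        m = binary_metrics(cm)
        assert m["specificity"] is None
        assert "specificity" in m["undefined"]
        assert m["sensitivity"] == 1.0

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            counts = rng.integers(1, 40, (2, 2))
            cm = cs.ConfusionMatrix(counts, ("n", "p"))
            m = binary_metrics(cm)
            tp, tn = counts[1, 1], counts[0, 0]
            fp, fn = counts[0, 1], counts[1, 0]
            assert m["accuracy"] == pytest.approx((tp + tn) / counts.sum())
            assert m["mcc"] == pytest.approx(bf_mcc(tp, tn, fp, fn), abs=1e-12)
            assert m["f1"] == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)

    def test_sklearn_cross_check(self):
        from sklearn.metrics import f1_score, matthews_corrcoef

        rng = np.random.default_rng(7)
        y, p = rng.integers(0, 2, 60), rng.integers(0, 2, 60)
        cm = confusion(y.tolist(), p.tolist(), (0, 1))
        m = binary_metrics(cm, positive_index=1)
        assert m["mcc"] == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)
        assert m["f1"] == pytest.approx(f1_score(y, p), abs=1e-12)


class TestMulticlass:
    def test_diagonal_and_uniform(self):
        assert multiclass_accuracy(cs.ConfusionMatrix(np.diag([3, 4]), (0, 1))) == 1.0
        assert multiclass_accuracy(cs.ConfusionMatrix(np.ones((4, 4), int), range(4))) == 0.25

    def test_recall_empty_row_flagged(self):
        cm = cs.ConfusionMatrix(np.array([[2, 0], [0, 0]]), (0, 1))
        assert per_class_recall(cm, 1) is None
        assert per_class_recall(cm, 0) == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            multiclass_accuracy(cs.ConfusionMatrix(np.zeros((2, 2), int), (0, 1)))


class TestRocAuc:
    def test_fixture_examples(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1])["auc"] == pytest.approx(1.0, abs=1e-9)
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1])["auc"] == pytest.approx(0.75, abs=1e-9)
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1])["auc"] == pytest.approx(0.5, abs=1e-9)

    def test_matches_pair_enumeration_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.uniform(0, 10, n), 1)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert roc_auc(scores, labels)["auc"] == pytest.approx(
                bf_auc(scores, labels), abs=1e-12
            )

    def test_complement_under_score_negation(self):
        rng = np.random.default_rng(4)
        scores = rng.permutation(20).astype(float)  # tie-free
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels)["auc"]
        b = roc_auc(-scores, labels)["auc"]
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels)["auc"] == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestSpearman:
    def test_monotone_and_fixture(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])["rho"] == pytest.approx(1.0)
        # classical d^2 formula on x=[1,2,3], y=[3,1,2]: rho = 1 - 6*4.5... d=(−2,1,1), sum d²=6 → 1−36/24? n=3: 1−6·6/(3·8)=−0.5
        assert spearman([1, 2, 3], [3, 1, 2])["rho"] == pytest.approx(-0.5, abs=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(6)
        x, y = rng.uniform(0, 1, 15), rng.uniform(0, 1, 15)
        assert spearman(x, y)["rho"] == pytest.approx(spearman(y, x)["rho"])

    def test_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(3, 25))
            x = np.round(rng.uniform(0, 5, n), 0)  # ties likely
            y = np.round(rng.uniform(0, 5, n), 0)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert spearman(x, y)["rho"] == pytest.approx(bf_spearman(x, y), abs=1e-12)

    def test_zero_variance_flagged(self):
        out = spearman([1.0, 1.0, 1.0], [1, 2, 3])
        assert out["rho"] is None and out["undefined"]


class TestIcc21:
    def test_identical_raters_give_one(self):
        m = np.column_stack([[1.0, 2, 3, 5], [1.0, 2, 3, 5]])
        assert icc_2_1(m)["icc"] == pytest.approx(1.0)

    def test_offset_fixture_10_over_13(self):
        # rater2 = rater1 + 1 on targets [1,2,3,4]: MSR=10/3, MSC=2, MSE=0
        m = np.column_stack([[1.0, 2, 3, 4], [2.0, 3, 4, 5]])
        out = icc_2_1(m)
        assert out["icc"] == pytest.approx(10 / 13, abs=1e-9)
        assert out["anova"]["msr"] == pytest.approx(10 / 3)
        assert out["anova"]["msc"] == pytest.approx(2.0)
        assert out["anova"]["mse"] == pytest.approx(0.0, abs=1e-12)

    def test_absolute_agreement_penalizes_offset_vs_consistency(self):
        m = np.column_stack([[1.0, 2, 3, 4], [2.0, 3, 4, 5]])
        icc_abs = icc_2_1(m)["icc"]
        # consistency form ICC(3,1) = (MSR - MSE)/(MSR + (k-1) MSE) = 1 here
        assert icc_abs < 1.0

    def test_matches_anova_oracle_on_random_matrices(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(3, 15))
            k = int(rng.integers(2, 5))
            m = rng.normal(size=(n, 1)) + 0.3 * rng.normal(size=(n, k))
            assert icc_2_1(m)["icc"] == pytest.approx(bf_icc_2_1(m), abs=1e-10)

    def test_pingouin_cross_check_point_and_ci(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(10)
        n, k = 12, 3
        m = rng.normal(size=(n, 1)) + 0.4 * rng.normal(size=(n, k))
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "scores": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        type_col = ref["Type"].astype(str)
        row = ref[type_col.isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        out = icc_2_1(m)
        assert out["icc"] == pytest.approx(row["ICC"], abs=1e-9)
        assert out["ci_low"] == pytest.approx(row[ci_col][0], abs=2e-2)
        assert out["ci_high"] == pytest.approx(row[ci_col][1], abs=2e-2)

    def test_constant_matrix_flagged(self):
        out = icc_2_1(np.full((4, 2), 3.0))
        assert out["icc"] is None and out["undefined"]

    def test_incomplete_matrix_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            icc_2_1(m)


@given(st.integers(1, 30), st.integers(1, 30), st.integers(0, 30))
def test_dice_formula_property(na_extra, nb_extra, inter):
    """2|A∩B|/(|A|+|B|) for constructed masks of arbitrary overlap."""
    size = inter + na_extra + nb_extra + 5
    a = np.zeros(size, bool)
    b = np.zeros(size, bool)
    a[: inter + na_extra] = True
    b[:inter] = True
    b[inter + na_extra : inter + na_extra + nb_extra] = True
    expected = 2 * inter / (a.sum() + b.sum())
    assert dice(a.reshape(-1, 1, 1), b.reshape(-1, 1, 1)) == pytest.approx(expected)
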