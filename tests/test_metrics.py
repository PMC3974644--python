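"""Confusion-matrix metric panel: anchors, oracle equivalence, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

from allokit.metrics import (ConfusionMatrix, binary_metrics, gorodkin_mcc,
                             roc_curve, scale_ternary, ternary_metrics)


def brute_binary(aa, ab, ba, bb):
    """Independent textbook recomputation of the binary panel."""
    def div(n, d):
        return 0.0 if d == 0 else n / d
    den = math.sqrt((aa + ba) * (aa + ab) * (bb + ba) * (bb + ab))
    return {
        "sensitivity": div(aa, aa + ab),
        "specificity": div(bb, bb + ba),
        "ppv": div(aa, aa + ba),
        "npv": div(bb, bb + ab),
        "mcc": div(aa * bb - ba * ab, den),
    }


class TestBinary:
    def test_perfect_and_inverse_anchors(self):
        assert binary_metrics(ConfusionMatrix(np.diag([50, 50]))).mcc == 1.0
        assert binary_metrics(ConfusionMatrix([[0, 50], [50, 0]])).mcc == -1.0

    def test_example_matrix_matches_brute_force(self):
        cm = ConfusionMatrix([[90, 10], [12, 88]])
        got = binary_metrics(cm).as_dict()
        want = brute_binary(90, 10, 12, 88)
        for key, val in want.items():
            assert got[key] == pytest.approx(val, abs=1e-12)

    def test_oracle_equivalence_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            aa, ab, ba, bb = rng.integers(0, 200, 4)
            got = binary_metrics(ConfusionMatrix([[aa, ab], [ba, bb]]))
            want = brute_binary(int(aa), int(ab), int(ba), int(bb))
            for key, val in want.items():
                assert getattr(got, key if key != "ppv" else "ppv") == \
                    pytest.approx(val, abs=1e-12), key

    def test_agrees_with_sklearn_on_predictions(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 500)
        p = (y + (rng.random(500) < 0.3)) % 2
        cm = ConfusionMatrix.from_predictions(y, p, labels=[0, 1])
        assert binary_metrics(cm).mcc == pytest.approx(
            matthews_corrcoef(y, p), abs=1e-12)

    def test_zero_denominator_convention(self):
        assert binary_metrics(ConfusionMatrix([[0, 0], [5, 5]])).mcc == 0.0

    @given(st.integers(1, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(1, 50), st.integers(1, 5))
    def test_scale_invariance(self, aa, ab, ba, bb, k):
        base = binary_metrics(ConfusionMatrix([[aa, ab], [ba, bb]])).mcc
        scaled = binary_metrics(
            ConfusionMatrix([[aa * k, ab * k], [ba * k, bb * k]])).mcc
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix([[-1, 0], [0, 1]])


class TestTernary:
    def test_diagonal_matrices_score_one_exactly(self):
        for diag in ([10, 20, 30], [1, 1, 1], [7, 99, 3]):
            cm = ConfusionMatrix(np.diag(diag))
            assert ternary_metrics(cm).mcc == 1.0

    def test_single_column_degenerates_to_zero(self):
        cm = ConfusionMatrix([[10, 0, 0], [20, 0, 0], [30, 0, 0]])
        assert ternary_metrics(cm).mcc == 0.0

    def test_uniform_matrix_regression_value(self):
        # independent recomputation of the adopted algebra
        aa = bb = cc = 10
        ax = bx = cx = 20
        num = aa * bb * cc - ax * bx * cx
        den = ((aa + ax) * (aa + bx) * (aa + cx) * (bb + ax) * (bb + bx)
               * (bb + cx) * (cc + ax) * (cc + bx) * (cc + cx)) ** (1 / 3)
        want = num / den
        got = ternary_metrics(ConfusionMatrix([[10] * 3] * 3)).mcc
        assert got == pytest.approx(want, abs=1e-9)
        assert got == pytest.approx(-7000 / 27000, abs=1e-9)

    def test_recall_precision_read_rows_and_columns(self):
        cm = ConfusionMatrix([[8, 1, 1], [2, 6, 2], [0, 0, 10]])
        m = ternary_metrics(cm)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.6)
        assert m.recall_c == pytest.approx(1.0)
        assert m.ppv == pytest.approx(0.8)
        assert m.precision_c == pytest.approx(10 / 13)

    def test_scaling_maps_baselines(self):
        assert scale_ternary(1 / 3) == pytest.approx(0.5, abs=1e-12)
        assert scale_ternary(1.0) == 1.0

    def test_reduces_to_binary_form(self):
        # collapsing class C (all zero) must reproduce the binary MCC
        cm3 = ConfusionMatrix([[40, 10, 0], [5, 45, 0], [0, 0, 0]])
        cm2 = ConfusionMatrix([[40, 10], [5, 45]])
        # with CC = CX = 0, the product form degenerates; check instead
        # that the 2-class pairwise-sum construction equals the binary MCC
        aa, ab, ba, bb = 40, 10, 5, 45
        den = ((aa + ab) * (aa + ba) * (bb + ab) * (bb + ba)) ** 0.5
        assert binary_metrics(cm2).mcc == pytest.approx(
            (aa * bb - ab * ba) / den)

    def test_gorodkin_agrees_at_perfect_anchor(self):
        cm = ConfusionMatrix(np.diag([5, 6, 7]))
        assert gorodkin_mcc(cm) == pytest.approx(1.0)
        assert gorodkin_mcc(ConfusionMatrix([[10] * 3] * 3)) == 0.0


class TestRoc:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = ["A", "A", "B", "B"]
        *_, area = roc_curve(scores, labels, positive_label="A")
        assert area == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(5)
        labels = np.repeat(["A", "B"], 5000)
        scores = rng.random(10000)
        *_, area = roc_curve(scores, labels, positive_label="A")
        assert area == pytest.approx(0.5, abs=0.02)

    def test_reversed_scores_mirror_area(self):
        rng = np.random.default_rng(6)
        labels = rng.choice(["A", "B"], 200)
        scores = rng.random(200) + (labels == "A") * 0.3
        *_, area = roc_curve(scores, labels, positive_label="A")
        *_, rev = roc_curve(-scores, labels, positive_label="A")
        assert rev == pytest.approx(1.0 - area, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], ["A", "A"])
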