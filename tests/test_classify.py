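"""Splitting, random-forest training, importance, Pareto selection."""

import numpy as np
import pandas as pd
import pytest

from allokit.classify import (pareto_select, run_model, split_data,
                              train_classifier, variable_importance)


def toy_data(n=200, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    y = pd.Series(np.repeat(["A", "B"], n // 2))
    m = len(y)
    x = pd.DataFrame({
        "signal": (y == "A").astype(float) + rng.normal(0, 0.3, m)
        if signal else rng.normal(0, 1, m),
        "noise": rng.normal(0, 1, m),
        "constant": np.ones(m),
    })
    return x, y


class TestSplit:
    def test_stratified_70_30(self):
        x, y = toy_data(100)
        x_tr, x_te, y_tr, y_te = split_data(x, y, 0.7, seed=1)
        assert len(x_tr) == 70 and len(x_te) == 30
        assert (y_tr == "A").sum() == 35 and (y_te == "A").sum() == 15
        assert set(x_tr.index).isdisjoint(x_te.index)

    def test_same_seed_identical(self):
        x, y = toy_data(100)
        a = split_data(x, y, seed=3)[0]
        b = split_data(x, y, seed=3)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_odd_n_proportions_within_one(self):
        x, y = toy_data(100)
        x.loc[100] = [0.0, 0.0, 1.0]
        y.loc[100] = "A"
        _, _, y_tr, y_te = split_data(x, y, 0.7, seed=0)
        for cls in ("A", "B"):
            total = (y == cls).sum()
            assert abs((y_tr == cls).sum() - 0.7 * total) <= 1

    def test_tiny_class_rejected(self):
        x, y = toy_data(100)
        y.iloc[:] = "A"
        y.iloc[0] = "B"
        with pytest.raises(ValueError):
            split_data(x, y)


class TestForest:
    def test_separable_toy_reaches_mcc_one(self):
        x, y = toy_data(200, signal=True)
        x["signal"] = (y == "A").astype(float)  # perfectly separating
        from allokit.classify import run_model
        report = run_model(x, y, n_trees=50, seed=0,
                           importance_permutations=2)
        assert report.external_metrics["mcc"] == 1.0

    def test_permuted_labels_mcc_near_zero(self):
        x, y = toy_data(400, signal=True)
        rng = np.random.default_rng(7)
        y_perm = pd.Series(rng.permutation(y.to_numpy()))
        report = run_model(x, y_perm, n_trees=100, seed=0,
                           importance_permutations=2)
        assert abs(report.external_metrics["mcc"]) <= 0.25

    def test_single_class_rejected(self):
        x, y = toy_data(50)
        with pytest.raises(ValueError):
            train_classifier(x, pd.Series(["A"] * 50))

    def test_three_class_support(self):
        rng = np.random.default_rng(0)
        y = pd.Series(np.repeat(["A", "B", "C"], 60))
        x = pd.DataFrame({
            "f1": np.concatenate([rng.normal(m, 0.3, 60) for m in (0, 2, 4)]),
            "f2": rng.normal(0, 1, 180)})
        report = run_model(x, y, n_trees=100, seed=0,
                           importance_permutations=2)
        assert report.external_metrics["mcc"] > 0.8
        assert "scaled_recall_c" in report.external_metrics

    def test_oob_and_external_auc_agree(self, study_sets):
        from allokit.pipeline import feature_matrix
        xa, ya = feature_matrix(study_sets["allosteric"],
                                study_sets["descriptors"], "allosteric")
        xb, yb = feature_matrix(study_sets["background_balanced"],
                                study_sets["descriptors"], "non_allosteric")
        x = pd.concat([xa, xb], ignore_index=True)
        y = pd.concat([ya, yb], ignore_index=True)
        report = run_model(x, y, n_trees=200, seed=0,
                           importance_permutations=2)
        assert abs(report.oob_auc - report.external_auc) < 0.1


class TestImportance:
    def test_signal_beats_noise_and_constant_zero(self):
        wins = 0
        for seed in range(5):
            x, y = toy_data(300, seed=seed, signal=True)
            x_tr, x_te, y_tr, y_te = split_data(x, y, seed=seed)
            model = train_classifier(x_tr, y_tr, n_trees=100, seed=seed)
            imp = variable_importance(model, x_te, y_te, seed=seed
                                      ).set_index("feature")
            if imp.loc["signal", "permutation_importance"] > \
                    imp.loc["noise", "permutation_importance"]:
                wins += 1
            assert imp.loc["constant", "permutation_importance"] == \
                pytest.approx(0.0, abs=1e-12)
            assert imp.loc["constant", "class_correlation"] == 0.0
        assert wins >= 4

    def test_label_identical_feature_maximal(self):
        # only noise alongside the oracle feature, so no correlated
        # predictor can mask it under permutation
        x, y = toy_data(100, signal=False)
        x["oracle"] = (y == "A").astype(float)
        x_tr, x_te, y_tr, y_te = split_data(x, y, seed=0)
        model = train_classifier(x_tr, y_tr, n_trees=50, seed=0)
        imp = variable_importance(model, x_te, y_te, seed=0
                                  ).set_index("feature")
        assert abs(imp.loc["oracle", "class_correlation"]) == \
            pytest.approx(1.0)
        assert imp["permutation_importance"].idxmax() == "oracle"


class TestPareto:
    def _table(self, points):
        return pd.DataFrame({
            "feature": [f"f{i}" for i in range(len(points))],
            "permutation_importance": [p[0] for p in points],
            "gini_importance": 0.0,
            "class_correlation": [p[1] for p in points],
        })

    def test_non_dominated_points_all_on_front(self):
        out = pareto_select(self._table([(1, 1), (2, 0.5), (0.5, 2)]))
        assert set(out["front"]) == {"f0", "f1", "f2"}

    def test_dominated_point_excluded(self):
        out = pareto_select(self._table([(1, 1), (2, 0.5), (0.5, 2),
                                         (0.1, 0.1)]))
        assert "f3" not in out["front"]

    def test_single_feature_selected(self):
        out = pareto_select(self._table([(0.4, -0.2)]))
        assert out["front"] == ["f0"]

    def test_matches_exhaustive_dominance_check(self):
        rng = np.random.default_rng(2)
        pts = [(float(a), float(b)) for a, b in rng.random((20, 2))]
        out = pareto_select(self._table(pts))
        front = set(out["front"])
        for i, (ai, bi) in enumerate(pts):
            dominated = any(
                (aj >= ai and abs(bj) >= abs(bi))
                and (aj > ai or abs(bj) > abs(bi))
                for j, (aj, bj) in enumerate(pts) if j != i)
            assert (f"f{i}" in front) == (not dominated)
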