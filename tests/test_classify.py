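"""Classification machinery: fold structure, metrics identities, ROC hull,
importance scoring and rank fusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lvmech.classify import (ClassifierSpec, cumulative_rank, default_specs,
                             importance, loocv_splits, metrics, nested_loocv,
                             roc_hull, _make_estimator, _inner_tune)


def _blob_table(n_per_class=10, sep=8.0, p=3, seed=0):
    """Two well-separated Gaussian blobs -> a trivially separable cohort."""
    rng = np.random.default_rng(seed)
    Xh = rng.standard_normal((n_per_class, p))
    Xm = rng.standard_normal((n_per_class, p)) + sep
    df = pd.DataFrame(np.vstack([Xh, Xm]), columns=[f"f{i}" for i in range(p)])
    df.insert(0, "label", ["healthy"] * n_per_class + ["mi"] * n_per_class)
    return df


class TestFoldStructure:
    def test_outer_folds_match_the_worked_four_point_example(self):
        # four subjects {1,2,3,4} (0-based {0,1,2,3}): outer folds train on
        # three and evaluate on the fourth, starting with evaluation on {4}
        folds = [(set(tr.tolist()), te) for tr, te in loocv_splits(4)]
        assert folds == [({0, 1, 2}, 3), ({0, 1, 3}, 2),
                         ({0, 2, 3}, 1), ({1, 2, 3}, 0)]

    def test_inner_folds_of_the_first_outer_fold(self):
        outer_train = np.array([0, 1, 2])  # i.e. subjects {1,2,3}
        inner = [(set(outer_train[tr].tolist()), outer_train[te])
                 for tr, te in loocv_splits(3)]
        assert inner == [({0, 1}, 2), ({0, 2}, 1), ({1, 2}, 0)]

    def test_separable_data_classified_perfectly_by_every_method(self):
        table = _blob_table()
        for spec in default_specs():
            cols = ["f0"] if spec.method == "univariate_lr" else None
            r = nested_loocv(spec, table, seed=1, columns=cols)
            assert r.scores()["error"] == 0.0, spec.method

    def test_small_or_single_class_inputs_rejected(self):
        t = _blob_table(1)
        with pytest.raises(ValueError):
            nested_loocv(ClassifierSpec("lda"), t)
        t2 = _blob_table(5)
        t2["label"] = "healthy"
        with pytest.raises(ValueError):
            nested_loocv(ClassifierSpec("lda"), t2)

    def test_predictions_do_not_leak_the_held_out_label(self):
        """Flipping subject i's label must not change its own prediction."""
        table = _blob_table(6, sep=1.5, seed=3)
        for method, grid, gp in (("knn", (1, 3, 5, 7), "n_neighbors"),
                                 ("lasso_lr", (0.1, 1.0, 10.0), "C")):
            spec = ClassifierSpec(method, grid, gp)
            base = nested_loocv(spec, table, seed=5)
            flipped = table.copy()
            flipped.loc[0, "label"] = "mi"  # was healthy
            alt = nested_loocv(spec, flipped, seed=5)
            assert base.predictions[0] == alt.predictions[0], method

    def test_fast_inner_tuners_match_reference_grid_search(self):
        """The streamlined KNN/lasso tuning must equal the generic path."""
        rng = np.random.default_rng(9)
        X = rng.standard_normal((15, 3))
        y = (X[:, 0] + 0.5 * rng.standard_normal(15) > 0).astype(int)

        def reference(spec):
            best_hp, best_err = spec.grid[0], np.inf
            for hp in spec.grid:
                wrong = 0
                for tr, te in loocv_splits(len(y)):
                    est = _make_estimator(spec.method, hp, 0, X.shape[1])
                    est.fit(X[tr], y[tr])
                    wrong += int(est.predict(X[te:te + 1])[0] != y[te])
                if wrong / len(y) < best_err - 1e-12:
                    best_hp, best_err = hp, wrong / len(y)
            return best_hp

        for spec in (ClassifierSpec("knn", (1, 3, 5, 7), "n_neighbors"),
                     ClassifierSpec("lasso_lr", (0.01, 0.1, 1.0, 10.0), "C")):
            assert _inner_tune(spec, X, y, 0) == reference(spec), spec.method


class TestMetrics:
    def test_reconstructed_knn_counts_give_reported_triple(self):
        s = metrics(tp=7, fn=4, tn=27, fp=0)
        assert round(s["sensitivity"], 2) == 0.64
        assert round(s["specificity"], 2) == 1.00
        assert round(s["error"], 2) == 0.11

    def test_always_healthy_classifier_scores(self):
        s = metrics(tp=0, fn=11, tn=27, fp=0)
        assert s["sensitivity"] == 0.0 and s["specificity"] == 1.0

    def test_perfect_and_inverted_predictions(self):
        assert metrics(5, 7, 0, 0)["error"] == 0.0
        s = metrics(0, 0, 7, 5)
        assert (s["sensitivity"], s["specificity"], s["error"]) == (0.0, 0.0, 1.0)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_identities_hold_for_any_counts(self, tp, tn, fp, fn):
        s = metrics(tp, tn, fp, fn)
        n = tp + tn + fp + fn
        if tp + fn > 0:
            assert s["sensitivity"] == tp / (tp + fn)
        if tn + fp > 0:
            assert s["specificity"] == tn / (tn + fp)
        if n > 0:
            assert s["error"] == (fp + fn) / n

    def test_zero_denominator_flags_not_crashes(self):
        s = metrics(0, 5, 0, 0)
        assert s["undefined"] and np.isnan(s["sensitivity"])
        with pytest.raises(ValueError):
            metrics(-1, 0, 0, 0)


class TestRocHull:
    def test_no_points_gives_chance_level(self):
        assert roc_hull([])["auroc"] == 0.5

    def test_single_perfect_classifier(self):
        assert roc_hull([(0.0, 1.0)])["auroc"] == 1.0

    def test_hand_computed_example(self):
        h = roc_hull([(0.2, 0.8), (0.5, 0.6)])
        assert h["vertices"] == [(0.0, 0.0), (0.2, 0.8), (1.0, 1.0)]
        assert h["auroc"] == pytest.approx(0.80)

    def test_hull_dominates_every_single_point(self, rng):
        pts = [(float(x), float(y)) for x, y in rng.uniform(0, 1, (30, 2))]
        hull_auc = roc_hull(pts)["auroc"]
        for p in pts:
            assert hull_auc >= roc_hull([p])["auroc"] - 1e-12

    def test_points_outside_unit_square_rejected(self):
        with pytest.raises(ValueError):
            roc_hull([(1.2, 0.5)])


class TestImportance:
    def test_heavy_l1_penalty_zeroes_weak_features(self):
        table = _blob_table(12, sep=4.0, p=1, seed=2)
        rng = np.random.default_rng(0)
        table["noise"] = rng.standard_normal(len(table))
        X = table[["f0", "noise"]].to_numpy()
        y = (table["label"] == "mi").astype(int).to_numpy()
        est = _make_estimator("lasso_lr", 0.1, 0, 2)  # strong penalty
        est.fit(X, y)
        coefs = est.named_steps["clf"].coef_[0]
        assert coefs[1] == 0.0 and abs(coefs[0]) > 0

    def test_gp_ard_switches_off_irrelevant_features(self):
        rng = np.random.default_rng(4)
        n = 120
        x1 = np.r_[rng.normal(0, 1, n // 2), rng.normal(3, 1, n // 2)]
        noise = rng.standard_normal(n)
        df = pd.DataFrame({"label": ["healthy"] * (n // 2) + ["mi"] * (n // 2),
                           "signal": x1, "noise": noise})
        imp = importance("gp_ard", df, seed=0)
        assert imp["signal"] > 3 * imp["noise"]
        assert imp["noise"] < 0.25

    def test_duplicated_feature_shares_forest_importance(self):
        rng = np.random.default_rng(8)
        n = 60
        sig = np.r_[rng.normal(0, 1, n // 2), rng.normal(2.5, 1, n // 2)]
        base = pd.DataFrame({"label": ["healthy"] * (n // 2) + ["mi"] * (n // 2),
                             "sig": sig, "junk": rng.standard_normal(n)})
        solo = importance("random_forest", base, seed=0)["sig"]
        dup = base.copy()
        dup["sig_copy"] = dup["sig"]
        shared = importance("random_forest", dup, seed=0)
        assert shared["sig"] < solo
        assert shared["sig_copy"] < solo

    def test_boosted_tree_usage_fraction_bounds(self):
        table = _blob_table(10, sep=3.0, p=4, seed=5)
        imp = importance("boosted_entropy_tree", table, seed=0)
        assert ((imp >= 0) & (imp <= 1)).all()
        assert imp.max() > 0

    def test_unsupported_method_rejected(self):
        with pytest.raises(ValueError):
            importance("lda", _blob_table(), seed=0)


class TestRankFusion:
    def test_single_method_ranks(self):
        t = {"m": pd.Series([0.1, 0.9], index=["a", "b"])}
        r = cumulative_rank(t)
        assert list(r["m"]) == [0, 1]
        assert list(r["accumulated"]) == [0, 1]

    def test_opposite_orderings_tie(self):
        t = {"m1": pd.Series([0.1, 0.9], index=["a", "b"]),
             "m2": pd.Series([0.9, 0.1], index=["a", "b"])}
        assert list(cumulative_rank(t)["accumulated"]) == [1, 1]

    def test_ranks_are_always_permutations(self, rng):
        for _ in range(20):
            scores = rng.uniform(0, 1, 5)
            scores[rng.integers(5)] = scores[rng.integers(5)]  # inject ties
            t = {"m": pd.Series(scores, index=list("abcde"))}
            assert sorted(cumulative_rank(t)["m"]) == [0, 1, 2, 3, 4]

    def test_mismatched_feature_sets_rejected(self):
        t = {"m1": pd.Series([1.0], index=["a"]),
             "m2": pd.Series([1.0], index=["b"])}
        with pytest.raises(ValueError):
            cumulative_rank(t)
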