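"""Range filter, scaler, SVM training, metrics, CV and chain selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from mirsweep.features import UNDEFINED, default_catalog, eligible_names
from mirsweep.structure import InputError
from mirsweep.training import (
    FeatureScaler,
    ModelBundle,
    apply_range_filter,
    compute_metrics,
    cross_validate,
    dataset_to_xy,
    fit_range_filter,
    greedy_parameter_selection,
    grid_search,
    train_svm,
    vectors_to_frame,
)

from oracles import linear_percentile


def _frame(values: dict) -> pd.DataFrame:
    return pd.DataFrame(values)


class TestRangeFilter:
    def test_percentile_window_on_integer_grid_matches_closed_form(self):
        vals = list(range(1, 1001))
        df = _frame({"x": vals})
        rf = fit_range_filter(df, ["x"], overrides={})
        lo, hi = rf.bounds["x"]
        assert lo == pytest.approx(linear_percentile(vals, 0.1))
        assert hi == pytest.approx(linear_percentile(vals, 99.9))
        assert (lo, hi) == (pytest.approx(1.999), pytest.approx(999.001))

    def test_self_pass_rate_at_least_998_per_mille(self):
        rng = np.random.default_rng(0)
        df = _frame({"a": rng.normal(size=2000), "b": rng.exponential(size=2000)})
        rf = fit_range_filter(df, ["a", "b"], overrides={})
        for name in ("a", "b"):
            ok = sum(
                lo <= v <= hi
                for v in df[name]
                for lo, hi in [rf.bounds[name]]
            )
            assert ok / len(df) >= 0.998

    def test_override_rejects_weak_mfe_regardless_of_window(self):
        df = _frame({"ppri_mfe": [-60.0, -55.0, -50.0] * 40})
        rf = fit_range_filter(df, ["ppri_mfe"])
        ok, violated = apply_range_filter(rf, {"ppri_mfe": -10.0})
        assert not ok and violated == ["ppri_mfe"]
        ok2, _ = apply_range_filter(rf, {"ppri_mfe": -25.0})
        assert ok2

    def test_window_edges_are_closed_and_violations_named(self):
        df = _frame({"x": list(range(1, 101)), "y": [0.5] * 100})
        rf = fit_range_filter(df, ["x", "y"], overrides={})
        lo, hi = rf.bounds["x"]
        assert apply_range_filter(rf, {"x": lo, "y": 0.5})[0]
        assert apply_range_filter(rf, {"x": hi, "y": 0.5})[0]
        ok, violated = apply_range_filter(rf, {"x": hi + 1, "y": 0.5})
        assert not ok and violated == ["x"]
        # degenerate window [v, v] allowed
        assert rf.bounds["y"] == (0.5, 0.5)

    def test_undefined_values_always_pass(self):
        df = _frame({"x": [1.0, 2.0, 3.0]})
        rf = fit_range_filter(df, ["x"], overrides={})
        ok, _ = apply_range_filter(rf, {"x": UNDEFINED, "ppri_mfe": UNDEFINED})
        assert ok


class TestScaler:
    def test_train_features_map_into_unit_band_and_roundtrip(self):
        rng = np.random.default_rng(1)
        df = _frame({"a": rng.normal(size=200), "b": rng.uniform(5, 9, size=200)})
        sc = FeatureScaler.fit(df, ["a", "b"])
        Z = sc.transform(df)
        assert Z.min() >= -1.0 and Z.max() <= 1.0
        back = sc.inverse_transform(Z)
        assert np.allclose(back, df.to_numpy(), atol=1e-9)

    def test_undefined_maps_to_minus_one_and_outliers_clip(self):
        df = _frame({"a": [0.0, 1.0, 2.0]})
        sc = FeatureScaler.fit(df, ["a"])
        Z = sc.transform(_frame({"a": [np.nan, 99.0, -99.0]}))
        assert Z[0, 0] == -1.0 and Z[1, 0] == 1.0 and Z[2, 0] == -1.0


class TestMetrics:
    @pytest.mark.parametrize(
        "tp,tn,fp,fn,acc,sens,spec",
        [
            (1, 1, 0, 0, 1.0, 1.0, 1.0),
            (0, 0, 1, 1, 0.0, 0.0, 0.0),
            (50, 30, 10, 10, 0.8, 50 / 60, 30 / 40),
        ],
    )
    def test_formulas(self, tp, tn, fp, fn, acc, sens, spec):
        m = compute_metrics(tp, tn, fp, fn)
        assert m.accuracy == pytest.approx(acc)
        assert m.sensitivity == pytest.approx(sens)
        assert m.specificity == pytest.approx(spec)

    def test_all_zero_rejected(self):
        with pytest.raises(InputError):
            compute_metrics(0, 0, 0, 0)


class TestTrainSVM:
    def _separable(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {"f1": np.r_[rng.normal(3, 0.3, n), rng.normal(-3, 0.3, n)],
             "f2": rng.normal(size=2 * n)}
        )
        y = np.r_[np.ones(n), -np.ones(n)]
        return X, y

    def test_separable_data_reaches_high_cv_accuracy(self):
        X, y = self._separable()
        b = train_svm(X, y, ["f1", "f2"], c_grid=[1.0, 8.0],
                      gamma_grid=[0.125, 0.5], cv_folds=3, seed=0)
        assert b.cv_accuracy >= 0.99

    def test_permuted_labels_score_near_chance(self):
        X, y = self._separable(n=50)
        rng = np.random.default_rng(3)
        accs = []
        for _ in range(20):
            yp = rng.permutation(y)
            _, pooled = cross_validate(X, yp, 5, seed=0)
            accs.append(pooled.accuracy)
        assert abs(float(np.mean(accs)) - 0.5) < 0.08

    def test_same_seed_and_data_give_identical_hyperparameters(self):
        X, y = self._separable()
        grid = dict(c_grid=[0.5, 2.0, 8.0], gamma_grid=[0.03125, 0.125], cv_folds=3)
        b1 = train_svm(X, y, ["f1", "f2"], seed=11, **grid)
        b2 = train_svm(X, y, ["f1", "f2"], seed=11, **grid)
        assert (b1.C, b1.gamma) == (b2.C, b2.gamma)

    def test_single_class_rejected(self):
        X, _ = self._separable()
        with pytest.raises(InputError):
            train_svm(X, np.ones(len(X)), ["f1", "f2"])

    def test_bundle_decision_function_matches_sklearn(self):
        X, y = self._separable()
        b = train_svm(X, y, ["f1", "f2"], c_grid=[2.0], gamma_grid=[0.25],
                      cv_folds=3, seed=0)
        Z = b.scaler.transform(X)
        clf = SVC(C=2.0, gamma=0.25).fit(Z, y)
        assert np.allclose(b.decision_function(Z), clf.decision_function(Z),
                           atol=1e-9)

    def test_bundle_json_roundtrip(self, tmp_path):
        X, y = self._separable()
        b = train_svm(X, y, ["f1", "f2"], c_grid=[2.0], gamma_grid=[0.25],
                      cv_folds=3, seed=0)
        p = tmp_path / "m.json"
        b.save(p)
        b2 = ModelBundle.load(p)
        Z = b.scaler.transform(X)
        assert np.allclose(b.decision_function(Z), b2.decision_function(Z))
        assert b2.params == b.params and b2.backend_id == b.backend_id


class TestCrossValidate:
    def test_fold_sizes_stratified(self):
        X = pd.DataFrame({"f": np.arange(20.0)})
        y = np.r_[np.ones(10), -np.ones(10)]
        folds, pooled = cross_validate(X, y, 2, seed=0)
        assert all(m.total == 10 for m in folds)
        assert pooled.total == 20

    def test_pooled_equals_fold_recount(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"f1": rng.normal(size=40), "f2": rng.normal(size=40)})
        y = np.r_[np.ones(20), -np.ones(20)]
        folds, pooled = cross_validate(X, y, 4, seed=1)
        assert pooled.tp == sum(m.tp for m in folds)
        assert pooled.accuracy == pytest.approx(
            sum(m.tp + m.tn for m in folds) / sum(m.total for m in folds))

    def test_k_larger_than_class_rejected(self):
        X = pd.DataFrame({"f": np.arange(6.0)})
        y = np.r_[np.ones(3), -np.ones(3)]
        with pytest.raises(InputError):
            cross_validate(X, y, 4)


def _tabular_sets(seed, n=40, p=3, informative=None):
    rng = np.random.default_rng(seed)
    names = [f"f{k}" for k in range(p)]
    pos_sets, neg_sets = [], []
    for _ in range(3):
        Xp = rng.normal(size=(n, p))
        Xn = rng.normal(size=(n, p))
        for k in informative or []:
            Xp[:, k] += 1.5
        pos_sets.append(pd.DataFrame(Xp, columns=names))
        neg_sets.append(pd.DataFrame(Xn, columns=names))
    return pos_sets, neg_sets, names


def _oracle_subset_score(pos_sets, neg_sets, cols):
    """Independent reimplementation of the chain score: per-column min-max
    scaling of the pooled set, 2-fold stratified CV with a default RBF SVM,
    averaged over the three dataset pairings."""
    from sklearn.model_selection import StratifiedKFold

    accs = []
    for P, N in zip(pos_sets, neg_sets):
        X = pd.concat([P, N], ignore_index=True)
        y = np.r_[np.ones(len(P)), -np.ones(len(N))]
        A = X[list(cols)].to_numpy(dtype=float)
        mn, mx = A.min(axis=0), A.max(axis=0)
        span = np.where(mx > mn, mx - mn, 1.0)
        Z = np.where(mx > mn, 2.0 * (A - mn) / span - 1.0, 0.0)
        fold_accs = []
        for tr, te in StratifiedKFold(2, shuffle=False).split(Z, y):
            clf = SVC(C=1.0, gamma="scale").fit(Z[tr], y[tr])
            fold_accs.append(np.mean(clf.predict(Z[te]) == y[te]))
        accs.append(np.mean(fold_accs))
    return float(np.mean(accs))


class TestGreedySelection:
    def test_pool_of_three_equals_exhaustive_enumeration(self):
        from itertools import combinations

        pos, neg, names = _tabular_sets(0, n=30, p=3, informative=[0])
        res = greedy_parameter_selection(pos, neg, beam=10, cv_folds=2)
        # with beam >= number of chains the search is exhaustive: the curve
        # must match brute-force enumeration of every subset at every size
        for length, acc in res.curve:
            brute = max(
                _oracle_subset_score(pos, neg, s)
                for s in combinations(names, length)
            )
            assert acc == pytest.approx(brute)
        assert res.best_score == pytest.approx(max(a for _, a in res.curve))

    def test_beam_one_is_classic_forward_selection(self):
        pos, neg, names = _tabular_sets(1, n=30, p=2, informative=[1])
        res = greedy_parameter_selection(pos, neg, beam=1, cv_folds=2)
        singles = sorted(
            ((_oracle_subset_score(pos, neg, (n,)), n) for n in names),
            key=lambda t: (-t[0], t[1]),
        )
        # the chain starts at the best-scoring single parameter
        assert res.chains_by_length[1][0][1] == (singles[0][1],)
        assert res.chains_by_length[2][0][1][0] == singles[0][1]

    def test_curve_is_reported_not_assumed_monotone(self):
        pos, neg, _ = _tabular_sets(2, n=30, p=5, informative=[0, 1])
        res = greedy_parameter_selection(pos, neg, beam=3, cv_folds=2)
        lengths = [l for l, _ in res.curve]
        assert lengths == list(range(1, 6))

    def test_planted_features_recovered_in_chain_prefix(self):
        pos, neg, names = _tabular_sets(7, n=50, p=12, informative=[0, 1, 2])
        res = greedy_parameter_selection(pos, neg, beam=5, cv_folds=2, max_len=5)
        chain5 = res.chains_by_length[5][0][1]
        assert {"f0", "f1", "f2"} <= set(chain5)


class TestCorpusTraining:
    def test_synthetic_corpus_is_learnable(self, small_corpus):
        dataset, _ = small_corpus
        names = eligible_names(default_catalog())
        X, y = dataset_to_xy(dataset, names)
        _, pooled = cross_validate(X, y, 5, seed=0)
        assert pooled.accuracy >= 0.75

    def test_level_change_keeps_auc_stable(self, backend):
        # level sensitivity: AUC within +/-0.05 between level 1 and level 3
        from sklearn.metrics import roc_auc_score
        from mirsweep.simulate import HairpinRecipe, make_labeled_corpus

        names = eligible_names(default_catalog())
        aucs = []
        for level in (1, 3):
            rng = np.random.default_rng(2024)
            ds, _ = make_labeled_corpus(HairpinRecipe(), 40, level=level,
                                        rng=rng, backend=backend)
            X, y = dataset_to_xy(ds, names)
            b = train_svm(X, y, names, c_grid=[8.0], gamma_grid=[2.0**-5],
                          cv_folds=3, seed=0, backend_id=backend.id)
            rng2 = np.random.default_rng(99)
            ds_test, _ = make_labeled_corpus(HairpinRecipe(), 30, level=1,
                                             rng=rng2, backend=backend)
            vecs = [ex.features for ex in ds_test.examples]
            scores = b.score_vectors(vecs)
            y_test = np.array([ex.label for ex in ds_test.examples])
            aucs.append(roc_auc_score(y_test, scores))
        assert abs(aucs[0] - aucs[1]) < 0.05
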