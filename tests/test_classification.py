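import numpy as np
import pytest

from drowsikit.classification import (
    BalanceConfig,
    ModelSpec,
    SplitConfig,
    balance,
    evaluate,
    grid_search,
    metrics_from_predictions,
    load_model,
    save_model,
    split,
    train,
)
from drowsikit.errors import BalancingError, ModelLayoutError, SplitError
from drowsikit.window_labeling import Dataset, WindowSample


def make_dataset(n0: int, n1: int, seed: int = 0, separable: bool = True) -> Dataset:
    """Windows whose EAR rows separate the classes when ``separable``."""
    rng = np.random.default_rng(seed)
    samples = []
    for label, n in ((0, n0), (1, n1)):
        for _ in range(n):
            feats = np.empty((4, 15))
            if separable:
                feats[0] = rng.uniform(0.3, 0.4, 15) if label == 0 else rng.uniform(0.0, 0.1, 15)
            else:
                feats[0] = rng.uniform(0.0, 0.4, 15)
            feats[1] = rng.uniform(0.0, 0.3, 15)
            feats[2] = rng.uniform(300, 340, 15)
            feats[3] = rng.uniform(200, 240, 15)
            samples.append(WindowSample(7, feats, label))
    return Dataset(samples)


class TestBalance:
    def test_meet_at_mean_counts(self):
        ds = make_dataset(1000, 200)
        out = balance(ds, BalanceConfig(seed=0))
        assert out.class_counts == {0: 600, 1: 600}

    def test_already_balanced_is_fixed_point(self):
        ds = make_dataset(300, 300)
        assert balance(ds).class_counts == {0: 300, 1: 300}

    def test_deterministic_under_seed(self):
        ds = make_dataset(100, 30)
        a = balance(ds, BalanceConfig(seed=5))
        b = balance(ds, BalanceConfig(seed=5))
        assert all(
            np.array_equal(x.features, y.features) for x, y in zip(a.samples, b.samples)
        )

    def test_empty_class_rejected(self):
        with pytest.raises(BalancingError):
            balance(make_dataset(50, 0))

    @pytest.mark.parametrize(
        "strategy,expected",
        [("oversample_to_majority", 100), ("undersample_to_minority", 20)],
    )
    def test_other_strategies(self, strategy, expected):
        ds = make_dataset(100, 20)
        out = balance(ds, BalanceConfig(strategy=strategy))
        assert out.class_counts == {0: expected, 1: expected}


class TestSplit:
    def test_70_30_partition(self):
        ds = make_dataset(500, 500)
        tr, te = split(ds, SplitConfig(shuffle_seed=1))
        assert len(tr) == 700 and len(te) == 300
        # stratification preserved
        assert tr.class_counts[0] == tr.class_counts[1] == 350

    def test_disjoint_and_exhaustive(self):
        ds = make_dataset(40, 40)
        tr, te = split(ds, SplitConfig(shuffle_seed=0))
        ids = sorted(id(s) for s in tr.samples + te.samples)
        assert ids == sorted(id(s) for s in ds.samples)

    def test_same_seed_same_split(self):
        ds = make_dataset(40, 40)
        tr1, _ = split(ds, SplitConfig(shuffle_seed=9))
        tr2, _ = split(ds, SplitConfig(shuffle_seed=9))
        assert [id(s) for s in tr1.samples] == [id(s) for s in tr2.samples]

    def test_single_class_stratified_rejected(self):
        with pytest.raises(SplitError):
            split(make_dataset(40, 0))


class TestTrain:
    @pytest.mark.parametrize("kind", ["rf", "svm", "nn"])
    def test_separable_data_fits_perfectly(self, kind):
        ds = make_dataset(120, 120, seed=1)
        model = train(ModelSpec(kind), ds, seed=0)
        X, y = ds.to_arrays()
        assert (model.predict(X) == y).mean() == 1.0

    def test_rf_deterministic_under_seed(self):
        ds = make_dataset(80, 80)
        probe, _ = make_dataset(20, 20, seed=7).to_arrays()
        p1 = train(ModelSpec("rf"), ds, seed=3).predict_score(probe)
        p2 = train(ModelSpec("rf"), ds, seed=3).predict_score(probe)
        assert np.array_equal(p1, p2)

    def test_dimension_mismatch_rejected(self):
        model = train(ModelSpec("rf"), make_dataset(50, 50), seed=0)
        with pytest.raises(ModelLayoutError):
            model.predict(np.zeros((3, 52)))

    def test_save_load_round_trip(self, tmp_path):
        ds = make_dataset(60, 60)
        model = train(ModelSpec("rf"), ds, seed=0)
        save_model(model, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        X, _ = ds.to_arrays()
        assert np.array_equal(model.predict_score(X), back.predict_score(X))


class TestGridSearch:
    def test_singleton_grid_returned(self):
        ds = make_dataset(60, 60)
        best, table = grid_search(ModelSpec("rf"), ds, {"n_estimators": [10]}, folds=3)
        assert best == {"n_estimators": 10}
        assert len(table) == 1

    def test_score_table_exhaustive(self):
        ds = make_dataset(60, 60)
        grid = {"n_estimators": [5, 10], "max_depth": [2, None]}
        _, table = grid_search(ModelSpec("rf"), ds, grid, folds=3)
        assert len(table) == 4

    def test_dominating_configuration_selected(self):
        # depth-1 stumps cannot separate on a 60-dim threshold task as well
        # as unrestricted trees; the unrestricted point must win
        ds = make_dataset(80, 80, seed=2)
        best, _ = grid_search(
            ModelSpec("rf"), ds, {"max_depth": [None, 1], "n_estimators": [10]}, folds=3
        )
        assert best["max_depth"] is None

    def test_bad_folds_rejected(self):
        with pytest.raises(ValueError):
            grid_search(ModelSpec("rf"), make_dataset(10, 10), {"n_estimators": [5]}, folds=1)


def brute_force_metrics(y_true, y_pred):
    """Direct-counting oracle for the point-metric suite."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    div = lambda a, b: a / b if b else 0.0
    sens, spec = div(tp, tp + fn), div(tn, tn + fp)
    p1, p0 = div(tp, tp + fp), div(tn, tn + fn)
    f1 = div(2 * p1 * sens, p1 + sens)
    f0 = div(2 * p0 * spec, p0 + spec)
    return {
        "accuracy": div(tp + tn, len(y_true)),
        "sensitivity": sens,
        "specificity": spec,
        "macro_precision": 0.5 * (p1 + p0),
        "macro_f1": 0.5 * (f1 + f0),
    }


class TestEvaluate:
    def test_hand_computed_confusion(self):
        y_true = [1] * 50 + [0] * 50
        y_pred = [1] * 45 + [0] * 5 + [0] * 40 + [1] * 10
        rep = metrics_from_predictions(y_true, y_pred)
        assert rep.confusion == {"tp": 45, "fn": 5, "tn": 40, "fp": 10}
        assert rep.sensitivity == pytest.approx(0.90)
        assert rep.specificity == pytest.approx(0.80)
        assert rep.accuracy == pytest.approx(0.85)

    def test_matches_counting_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(10, 200))
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            rep = metrics_from_predictions(y_true, y_pred)
            want = brute_force_metrics(y_true.tolist(), y_pred.tolist())
            for key, value in want.items():
                assert getattr(rep, key) == pytest.approx(value), key

    def test_perfect_scorer(self):
        ds = make_dataset(100, 100, seed=4)
        model = train(ModelSpec("rf"), ds, seed=0)
        rep = evaluate(model, ds)
        assert rep.accuracy == 1.0 and rep.roc_auc == pytest.approx(1.0)

    def test_chance_scorer_auc_near_half(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 4000)
        scores = rng.uniform(size=4000)
        rep = metrics_from_predictions(y_true, (scores >= 0.5).astype(int), scores)
        assert rep.roc_auc == pytest.approx(0.5, abs=0.05)

    def test_auc_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(5)
        y_true = rng.integers(0, 2, 300)
        scores = rng.uniform(size=300)
        a = metrics_from_predictions(y_true, (scores >= 0.5).astype(int), scores)
        warped = scores**3  # strictly monotone on [0, 1]
        b = metrics_from_predictions(y_true, (scores >= 0.5).astype(int), warped)
        assert b.roc_auc == pytest.approx(a.roc_auc, abs=1e-12)

    def test_single_class_test_set_reports_points_only(self):
        y_true = np.ones(20, dtype=int)
        rep = metrics_from_predictions(y_true, y_true, np.ones(20))
        assert rep.accuracy == 1.0 and rep.roc_auc is None


def test_end_to_end_reproducible_under_seeds():
    ds = make_dataset(300, 80, seed=6)
    reports = []
    for _ in range(2):
        bal = balance(ds, BalanceConfig(seed=2))
        tr, te = split(bal, SplitConfig(shuffle_seed=2))
        model = train(ModelSpec("rf"), tr, seed=2)
        reports.append(evaluate(model, te).to_dict())
    assert reports[0] == reports[1]
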