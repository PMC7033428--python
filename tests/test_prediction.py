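"""Split protocol, grid-search tuning, aggregation, and the shuffled control."""

import numpy as np
import pytest

from eegrt.features import FeatureMatrix
from eegrt.prediction import (
    EvalResult,
    ModelSpec,
    RepResult,
    SplitScheme,
    default_model_specs,
    evaluate_subject,
    make_splits,
    shuffled_baseline,
    summarize_selected_features,
    tune_and_fit,
)


def _linear_fm(n=48, n_features=10, noise=0.0, seed=0):
    """y depends linearly on feature 0 only."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_features))
    y = 0.6 + 0.2 * X[:, 0] + noise * rng.standard_normal(n)
    return FeatureMatrix(values=X, column_labels=[f"f{i}" for i in range(n_features)],
                         y=y, trial_ids=np.arange(n))


class TestMakeSplits:
    def test_48_trials_split_36_12(self):
        scheme = SplitScheme(base_seed=3)
        for train, test in make_splits(48, scheme):
            assert len(train) == 36 and len(test) == 12

    def test_partition_property(self):
        for train, test in make_splits(47, SplitScheme(base_seed=1)):
            combined = np.sort(np.concatenate([train, test]))
            assert np.array_equal(combined, np.arange(47))
            assert len(np.intersect1d(train, test)) == 0

    def test_deterministic_and_repetition_dependent(self):
        a = make_splits(40, SplitScheme(base_seed=5))
        b = make_splits(40, SplitScheme(base_seed=5))
        assert all(np.array_equal(x[0], y[0]) for x, y in zip(a, b))
        assert not np.array_equal(a[0][0], a[1][0])  # reps differ

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            make_splits(7, SplitScheme())


class TestTuneAndFit:
    def test_single_grid_point_is_chosen(self):
        fm = _linear_fm()
        spec = ModelSpec("lasso", {"alpha": [0.01]})
        tuned = tune_and_fit(spec, fm.values, fm.y, cv_seed=0)
        assert tuned.params == {"alpha": 0.01}

    def test_linear_target_fit_to_high_precision(self):
        """With a weak penalty available, the lasso drives the training MAE
        of an exactly linear target below 1e-3."""
        fm = _linear_fm(noise=0.0)
        spec = ModelSpec("lasso", {"alpha": [1.0, 1e-6]})
        tuned = tune_and_fit(spec, fm.values, fm.y, cv_seed=0)
        pred = tuned.model.predict(fm.values)
        assert np.mean(np.abs(pred - fm.y)) < 1e-3
        assert tuned.params["alpha"] == 1e-6

    def test_tied_scores_resolve_to_first_grid_point(self):
        """A constant target scores every grid point identically, so the tie
        rule must return the first point in grid order."""
        fm = _linear_fm()
        y_const = np.full(fm.n_trials, 0.5)
        spec = ModelSpec("lasso", {"alpha": [0.7, 0.1, 0.01]})
        tuned = tune_and_fit(spec, fm.values, y_const, cv_seed=0)
        assert tuned.params["alpha"] == 0.7

    def test_selection_reports_informative_feature(self):
        fm = _linear_fm(noise=0.01)
        spec = ModelSpec("svr_rbf", {"C": [10.0], "gamma": [0.1],
                                     "epsilon": [0.01]},
                         feature_selection_k_grid=[2])
        tuned = tune_and_fit(spec, fm.values, fm.y, cv_seed=0,
                             column_labels=fm.column_labels)
        assert "f0" in tuned.selected_labels
        assert len(tuned.selected_labels) == 2
        assert tuned.params["n_selected_features"] == 2


class TestAggregation:
    def test_eq1_is_mean_of_per_repetition_means(self):
        """On unequal-size repetitions the unweighted mean of rep means
        differs from the pooled mean — the aggregate must be the former."""
        reps = [
            RepResult(0, 0, np.array([0.1, 0.1, 0.1, 0.1]), {}, None, np.arange(4)),
            RepResult(1, 1, np.array([0.4, 0.4]), {}, None, np.arange(2)),
        ]
        res = EvalResult(per_rep={"lasso": reps})
        assert res.mae_s("lasso") == pytest.approx(0.25)
        pooled = res.pooled_abs_errors("lasso").mean()
        assert pooled == pytest.approx(0.2)
        assert res.mae_s("lasso") != pooled

    def test_two_repetition_arithmetic(self):
        reps = [
            RepResult(0, 0, np.array([0.1, 0.1]), {}, None, np.arange(2)),
            RepResult(1, 1, np.array([0.2, 0.2]), {}, None, np.arange(2)),
        ]
        res = EvalResult(per_rep={"svr_rbf": reps})
        assert res.mae_s("svr_rbf") == pytest.approx(0.15)


class TestEvaluateSubject:
    def test_linear_signal_is_learned(self):
        fm = _linear_fm(noise=0.005, seed=2)
        scheme = SplitScheme(n_repetitions=3, base_seed=0)
        specs = [ModelSpec("lasso", {"alpha": [1e-4, 1e-3]})]
        res = evaluate_subject(fm, specs, scheme)
        assert res.mae_s("lasso") < 0.02
        aggregates = res.aggregates()
        assert set(aggregates.columns) == {"algorithm", "mae_s", "ae_sd_s", "ae_max_s"}
        assert (aggregates["ae_max_s"] >= aggregates["mae_s"]).all()

    def test_all_four_algorithms_run(self):
        fm = _linear_fm(noise=0.05, seed=3)
        scheme = SplitScheme(n_repetitions=2, base_seed=1)
        specs = [
            ModelSpec("lasso", {"alpha": [0.01]}),
            ModelSpec("lasso_lars", {"alpha": [0.01]}),
            ModelSpec("kernel_ridge_rbf", {"alpha": [0.1], "gamma": [0.05]}),
            ModelSpec("svr_rbf", {"C": [10.0], "gamma": [0.05], "epsilon": [0.01]},
                      feature_selection_k_grid=[5]),
        ]
        res = evaluate_subject(fm, specs, scheme)
        assert set(res.per_rep) == {"lasso", "lasso_lars", "kernel_ridge_rbf", "svr_rbf"}
        for alg in res.per_rep:
            assert all(len(r.abs_errors) == 12 for r in res.per_rep[alg])
            assert all((r.abs_errors >= 0).all() for r in res.per_rep[alg])

    def test_empty_specs_rejected(self):
        with pytest.raises(ValueError):
            evaluate_subject(_linear_fm(), [], SplitScheme())


class TestShuffledBaseline:
    def test_reproducible_given_seed(self):
        fm = _linear_fm(noise=0.05, seed=4)
        scheme = SplitScheme(n_repetitions=2, base_seed=9)
        spec = ModelSpec("shuffled_svr_rbf",
                         {"C": [1.0], "gamma": [0.1], "epsilon": [0.05]},
                         feature_selection_k_grid=[5])
        a = shuffled_baseline(fm, scheme, spec)
        b = shuffled_baseline(fm, scheme, spec)
        assert a.mae_s("shuffled_svr_rbf") == b.mae_s("shuffled_svr_rbf")

    def test_strong_signal_beats_shuffled_in_most_repetitions(self):
        """With a strong linear signal the true-label model should win in
        nearly every repetition."""
        fm = _linear_fm(n=48, noise=0.01, seed=5)
        scheme = SplitScheme(n_repetitions=11, base_seed=2)
        grid = {"C": [10.0, 100.0], "gamma": [0.05, 0.2], "epsilon": [0.01]}
        res = evaluate_subject(
            fm, [ModelSpec("svr_rbf", grid, feature_selection_k_grid=[5])], scheme
        )
        shuf = shuffled_baseline(
            fm, scheme,
            ModelSpec("shuffled_svr_rbf", grid, feature_selection_k_grid=[5]),
        )
        true_rep = [r.abs_errors.mean() for r in res.per_rep["svr_rbf"]]
        shuf_rep = [r.abs_errors.mean() for r in shuf.per_rep["shuffled_svr_rbf"]]
        wins = sum(t < s for t, s in zip(true_rep, shuf_rep))
        assert wins >= 10


class TestSelectedFeatureSummary:
    def test_always_selected_feature_counts_n_repetitions(self):
        fm = _linear_fm(noise=0.01, seed=6)
        scheme = SplitScheme(n_repetitions=11, base_seed=4)
        spec = ModelSpec("svr_rbf", {"C": [10.0], "gamma": [0.1], "epsilon": [0.01]},
                         feature_selection_k_grid=[2])
        res = evaluate_subject(fm, [spec], scheme)
        table = summarize_selected_features(res)
        pooled = table[table.subject == "all"].set_index("feature")["count"]
        assert pooled["f0"] == 11
        assert pooled.index[0] == "f0"  # planted feature is the top selection

    def test_no_svr_yields_empty_table_not_error(self):
        res = EvalResult(per_rep={"lasso": []})
        table = summarize_selected_features(res)
        assert table.empty


def test_default_specs_cover_the_four_algorithms():
    specs = default_model_specs(140)
    assert [s.algorithm for s in specs] == [
        "lasso", "lasso_lars", "kernel_ridge_rbf", "svr_rbf"
    ]
    svr = specs[-1]
    assert svr.feature_selection_k_grid[-1] == 140
    assert default_model_specs(30).pop().feature_selection_k_grid[-1] == 30
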