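import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import railsdm as r
from railsdm import ensemble as E
from conftest import make_labelled_points
from oracles import brute_auc


class _StubModel:
    """predict_proba stub returning fixed positive-class probabilities."""

    def __init__(self, probs=None, fn=None):
        self.probs = probs
        self.fn = fn

    def predict_proba(self, X):
        p = np.asarray(self.probs if self.fn is None else self.fn(X), dtype=float)
        if p.ndim == 0:
            p = np.full(len(X), float(p))
        return np.column_stack([1 - p, p])


def stub_ensemble(table, fns):
    """FittedEnsemble whose four members are prediction stubs."""
    members = {
        kind: E.MemberModel(kind, {}, _StubModel(fn=fn), 0.5, 0.0,
                            table.feature_names)
        for kind, fn in zip(E.MEMBER_KINDS, fns)
    }
    pre = E.Preprocessor({}, {}, dict(table.categorical))
    return E.FittedEnsemble(
        members, pre, table.feature_names, table.continuous, table.categorical,
        E.CVSpec(k=2, repeats=1),
    )


def glm_stub_ensemble(table, coef, intercept=0.0):
    """All four members share one linear-logistic scoring rule."""
    coef = np.asarray(coef, dtype=float)

    def fn(X):
        return 1 / (1 + np.exp(-(X @ coef + intercept)))

    return stub_ensemble(table, [fn] * 4)


class TestExtractFeatures:
    def test_cell_centre_lookup(self, grid20):
        stack = r.generate_env_stack(
            grid20, [{"name": "t", "kind": "continuous", "smoothness": 2.0}], 1
        )
        pts = r.OccurrenceSet.from_arrays([3.5], [7.5], "sp")
        table = E.extract_features(pts, [1], stack)
        assert table.df.loc[0, "t"] == stack["t"].values[7, 3]

    def test_same_cell_points_share_rows(self, grid20):
        stack = r.generate_env_stack(
            grid20, [{"name": "t", "kind": "continuous", "smoothness": 2.0}], 1
        )
        pts = r.OccurrenceSet.from_arrays([3.1, 3.9], [7.1, 7.9], "sp")
        table = E.extract_features(pts, [1, 0], stack)
        assert table.df.loc[0, "t"] == table.df.loc[1, "t"]

    def test_matches_per_point_lookup(self, grid20):
        stack = r.generate_env_stack(
            grid20,
            [
                {"name": "t", "kind": "continuous", "smoothness": 2.0},
                {"name": "land", "kind": "categorical", "smoothness": 2.0,
                 "levels": ["a", "b"]},
            ],
            2,
        )
        rng = np.random.default_rng(3)
        x, y = rng.uniform(0, 20, 50), rng.uniform(0, 20, 50)
        pts = r.OccurrenceSet.from_arrays(x, y, "sp")
        table = E.extract_features(pts, np.zeros(50, int), stack)
        for i in range(50):
            row, col = int(y[i]), int(x[i])
            assert table.df.loc[i, "t"] == stack["t"].values[row, col]
            assert table.df.loc[i, "land"] == stack["land"].values[row, col]

    def test_masked_or_off_grid_rejected(self, masked_grid):
        stack = r.EnvStack(
            masked_grid,
            {"t": r.EnvLayer("t", "continuous", np.zeros(masked_grid.shape))},
        )
        with pytest.raises(ValueError):
            E.extract_features(
                r.OccurrenceSet.from_arrays([1.5], [1.5], "sp"), [1], stack
            )


class TestPreprocessor:
    def _table(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {"label": rng.integers(0, 2, n), "a": rng.normal(3, 2, n),
             "b": rng.normal(-1, 0.5, n)}
        )
        return E.FeatureTable(df, ["a", "b"], {})

    def test_training_columns_standardized(self):
        table = self._table()
        pre = E.fit_preprocessor(table)
        out = E.apply_preprocessor(pre, table)
        for c in ("a", "b"):
            assert abs(out.df[c].mean()) < 1e-10
            assert out.df[c].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self):
        table = self._table()
        shifted = E.FeatureTable(
            table.df.assign(a=table.df["a"] + 100.0), ["a", "b"], {}
        )
        z1 = E.apply_preprocessor(E.fit_preprocessor(table), table)
        z2 = E.apply_preprocessor(E.fit_preprocessor(shifted), shifted)
        np.testing.assert_allclose(z1.df["a"], z2.df["a"], atol=1e-9)

    def test_held_out_closed_form(self):
        train = self._table(seed=1)
        pre = E.fit_preprocessor(train)
        held = self._table(seed=2)
        out = E.apply_preprocessor(pre, held)
        expected = (held.df["a"] - pre.centers["a"]) / pre.scales["a"]
        np.testing.assert_allclose(out.df["a"], expected, rtol=1e-12)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"label": [0, 1], "a": [2.0, 2.0]})
        with pytest.raises(ValueError):
            E.fit_preprocessor(E.FeatureTable(df, ["a"], {}))


class TestCollinearityFilter:
    def _table_from_matrix(self, X, y, names):
        df = pd.DataFrame(X, columns=names)
        df["label"] = y
        return E.FeatureTable(df, names, {})

    def test_uncorrelated_features_all_retained(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 3))
        table = self._table_from_matrix(X, rng.integers(0, 2, 500), ["a", "b", "c"])
        assert r.collinearity_filter(table, 0.7) == ["a", "b", "c"]

    def test_duplicated_column_keeps_one(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=300)
        X = np.column_stack([a, a, rng.normal(size=300)])
        table = self._table_from_matrix(X, rng.integers(0, 2, 300), ["a", "b", "c"])
        kept = r.collinearity_filter(table, 0.7)
        assert "c" in kept and len(kept) == 2

    def test_single_linkage_chains_three_features(self):
        # |r|: AB ~0.9, BC ~0.8, AC ~0.5 — all three chain into one group
        rng = np.random.default_rng(3)
        cov = np.array([[1.0, 0.9, 0.5], [0.9, 1.0, 0.8], [0.5, 0.8, 1.0]])
        X = rng.multivariate_normal(np.zeros(3), cov, size=4000)
        y = (X[:, 0] + rng.normal(size=4000) > 0).astype(int)
        table = self._table_from_matrix(X, y, ["a", "b", "c"])
        kept = r.collinearity_filter(table, 0.7)
        assert len(kept) == 1

    def test_categoricals_exempt(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=200)
        df = pd.DataFrame(
            {"label": rng.integers(0, 2, 200), "a": a, "b": a,
             "land": rng.integers(0, 3, 200)}
        )
        table = E.FeatureTable(df, ["a", "b"], {"land": ["x", "y", "z"]})
        kept = r.collinearity_filter(table, 0.7)
        assert "land" in kept and len(kept) == 2


class TestEvaluate:
    def test_perfect_separation(self):
        rep = E.evaluate([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert rep.auc == 1.0 and rep.tss == 1.0

    def test_uninformative_predictions_near_chance(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 2000)
        preds = rng.uniform(size=2000)
        rep = E.evaluate(preds, labels)
        assert abs(rep.auc - 0.5) < 0.05
        assert abs(rep.tss) < 0.05

    def test_hand_enumerated_example(self):
        rep = E.evaluate([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0], threshold=0.5)
        assert rep.auc == 0.75
        assert rep.sensitivity == 0.5
        assert rep.specificity == 0.5
        assert rep.tss == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rank_auc_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        labels = np.r_[np.ones(max(1, n // 3), int),
                       np.zeros(n - max(1, n // 3), int)]
        preds = np.round(rng.uniform(size=n), 2)  # coarse grid forces ties
        assert E.auc_score(labels, preds) == pytest.approx(
            brute_auc(labels, preds), abs=1e-12
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_tss_identity_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        preds = rng.uniform(size=40)
        rep = E.evaluate(preds, labels, threshold=float(rng.uniform(0.1, 0.9)))
        assert rep.tss == rep.sensitivity + rep.specificity - 1
        assert 0 <= rep.sensitivity <= 1 and 0 <= rep.specificity <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            E.evaluate([0.4, 0.6], [1, 1])


class TestFitMember:
    def _separable_table(self, n=80):
        rng = np.random.default_rng(6)
        x = np.r_[rng.normal(2, 1, n // 2), rng.normal(-2, 1, n // 2)]
        df = pd.DataFrame(
            {"label": np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)], "x": x}
        )
        return E.FeatureTable(df, ["x"], {})

    def test_glm_on_separable_data_has_high_cv_auc(self):
        table = self._separable_table()
        m = E.fit_member("GLM", table, E.CVSpec(k=5, repeats=1), [{}], seed=0)
        assert m.cv_auc >= 0.95

    def test_single_point_grid_selected(self):
        table = self._separable_table()
        m = E.fit_member(
            "RF", table, E.CVSpec(k=5, repeats=1),
            [{"mtry": 1, "n_estimators": 50}], seed=0,
        )
        assert m.tuned_params == {"mtry": 1, "n_estimators": 50}

    def test_rf_mtry_choice_matches_recomputed_cv(self):
        table, *_ = make_labelled_points(seed=8, n=160)
        cv = E.CVSpec(k=5, repeats=1)
        grid = [{"mtry": 1, "n_estimators": 50}, {"mtry": 2, "n_estimators": 50}]
        m = E.fit_member("RF", table, cv, grid, seed=3)
        # independently recompute each grid point's CV AUC with the same folds
        X, cont_idx = E._design(table)
        y = table.labels
        splits = E._cv_splits(y, cv, 3)
        means = []
        for params in grid:
            aucs = []
            for tr, te in splits:
                est = E._build_estimator("RF", params, cont_idx, 3)
                est.fit(X[tr], y[tr])
                aucs.append(E.auc_score(y[te], est.predict_proba(X[te])[:, 1]))
            means.append(np.mean(aucs))
        expected = grid[int(np.argmax(means))]
        assert m.tuned_params == expected
        assert m.cv_auc == pytest.approx(max(means))

    def test_identical_seed_identical_cv_auc(self):
        table = self._separable_table()
        cv = E.CVSpec(k=5, repeats=2)
        m1 = E.fit_member("GLM", table, cv, [{}], seed=9)
        m2 = E.fit_member("GLM", table, cv, [{}], seed=9)
        assert m1.cv_auc == m2.cv_auc


class TestEnsemblePrediction:
    def _any_table(self, n=10):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {"label": rng.integers(0, 2, n), "x": rng.normal(size=n)}
        )
        return E.FeatureTable(df, ["x"], {})

    def test_mean_of_fixed_members(self):
        table = self._any_table()
        fns = [lambda X, v=v: np.full(len(X), v) for v in (0.2, 0.4, 0.6, 0.8)]
        ens = stub_ensemble(table, fns)
        np.testing.assert_allclose(E.predict_ensemble(ens, table), 0.5)

    def test_identical_members_pass_through(self):
        table = self._any_table()
        fns = [lambda X: 1 / (1 + np.exp(-X[:, 0]))] * 4
        ens = stub_ensemble(table, fns)
        np.testing.assert_allclose(
            E.predict_ensemble(ens, table), fns[0](E._design(table)[0])
        )

    def test_ensemble_equals_recomputed_member_mean(self, tiny_ensemble):
        ens, table, _ = tiny_ensemble
        preds = E.predict_members(ens, table)
        manual = np.mean(
            np.column_stack([preds[k] for k in E.MEMBER_KINDS]), axis=1
        )
        np.testing.assert_allclose(
            E.predict_ensemble(ens, table), manual, atol=1e-12
        )

    def test_member_and_ensemble_probability_bounds(self, tiny_ensemble):
        ens, table, _ = tiny_ensemble
        for p in E.predict_members(ens, table).values():
            assert p.min() >= 0.0 and p.max() <= 1.0
        p = E.predict_ensemble(ens, table)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_missing_member_rejected(self):
        table = self._any_table()
        ens = stub_ensemble(table, [lambda X: np.full(len(X), 0.5)] * 4)
        bad = dict(ens.members)
        del bad["BRT"]
        with pytest.raises(ValueError):
            E.FittedEnsemble(bad, ens.preprocessor, ens.selected_features,
                             ens.continuous, ens.categorical, ens.cv_spec)


class TestVariableSelection:
    def test_noise_feature_eliminated(self):
        rng = np.random.default_rng(10)
        n = 300
        signal = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "label": (signal + rng.normal(0, 0.3, n) > 0).astype(int),
                "signal": signal,
                "noise": rng.normal(size=n),
            }
        )
        table = E.FeatureTable(df, ["signal", "noise"], {})
        selected = E.rf_variable_selection(
            table, E.CVSpec(k=5, repeats=1), seed=0, n_trees=100
        )
        assert selected == ["signal"]

    def test_identical_copies_reduced_to_single_feature(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=300)
        y = (a + rng.normal(0, 0.5, 300) > 0).astype(int)
        df = pd.DataFrame({"label": y, "a": a, "b": a, "c": a})
        table = E.FeatureTable(df, ["a", "b", "c"], {})
        selected = E.rf_variable_selection(
            table, E.CVSpec(k=5, repeats=1), seed=1, n_trees=100
        )
        assert len(selected) == 1


class TestVariableImportance:
    def test_unused_feature_scores_zero(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {"label": rng.integers(0, 2, 200), "used": rng.normal(size=200),
             "unused": rng.normal(size=200)}
        )
        table = E.FeatureTable(df, ["used", "unused"], {})
        ens = glm_stub_ensemble(table, coef=[2.0, 0.0])
        imp = E.variable_importance(ens, table, n_perm=5, seed=0)
        assert imp.rvi["unused"] == 0.0
        assert imp.rvi["used"] == pytest.approx(1.0)

    def test_normalization_sums_to_one(self, tiny_ensemble):
        ens, table, _ = tiny_ensemble
        imp = E.variable_importance(ens, table, n_perm=3, seed=1)
        assert sum(imp.rvi.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in imp.rvi.values())

    def test_dominant_truth_feature_ranks_first(self, tiny_ensemble):
        # generator truth used a dominant coefficient on f0
        ens, table, _ = tiny_ensemble
        imp = E.variable_importance(ens, table, n_perm=5, seed=2)
        assert imp.top_feature() == "f0"


class TestResponseCurves:
    def test_zero_effect_feature_gives_flat_curve(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(
            {"label": rng.integers(0, 2, 200), "a": rng.normal(size=200),
             "b": rng.normal(size=200)}
        )
        table = E.FeatureTable(df, ["a", "b"], {})
        ens = glm_stub_ensemble(table, coef=[1.5, 0.0])
        _, curve = E.response_curves(ens, table, "b", n_steps=15)
        assert curve.max() - curve.min() < 0.05

    def test_monotone_positive_truth_gives_nondecreasing_curve(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=300)
        y = (rng.uniform(size=300) < 1 / (1 + np.exp(-2 * x))).astype(int)
        df = pd.DataFrame({"label": y, "x": x})
        table = E.FeatureTable(df, ["x"], {})
        member = E.fit_member("GLM", table, E.CVSpec(k=5, repeats=1), [{}], 0)
        ens = stub_ensemble(table, [None] * 4)
        for kind in E.MEMBER_KINDS:
            ens.members[kind] = member
        grid_vals, curve = E.response_curves(ens, table, "x", n_steps=20)
        assert (np.diff(curve) >= -1e-12).all()

    def test_categorical_level_with_positive_offset_is_maximal(self):
        table, *_ = make_labelled_points(
            seed=15, n=400, coefs={"f0": 1.0},
            category_effects={"plain": 0.0, "good": 2.0, "poor": -1.0},
        )
        cv = E.CVSpec(k=5, repeats=1)
        ens = E.fit_ensemble(table, cv, E.default_tuning_grids(fast=True), 15)
        levels, curve = E.response_curves(ens, table, "land")
        assert int(np.argmax(curve)) == 1  # "good" level

    def test_unknown_feature_rejected(self, tiny_ensemble):
        ens, table, _ = tiny_ensemble
        with pytest.raises(KeyError):
            E.response_curves(ens, table, "nope")
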