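import numpy as np
import pandas as pd
import pytest

from enantiokit import (
    CVConfig,
    EnsembleModel,
    build_ensemble,
    feature_provenance_frequency,
    fit_ols,
    loro,
    metrics,
    predict_ensemble,
    select_and_ensemble,
    virtual_screen,
)
from enantiokit.mlr_ensemble import ensemble_weights
from enantiokit.structio import FeatureMatrix


class TestFitOls:
    def test_exact_linear_relation(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        y = 2.0 * X["x"].to_numpy()
        m = fit_ols(X, y)
        # coefficient reported in standardized units: beta_std = 2 * sd(x)
        assert m.coefficients[0] == pytest.approx(2.0 * X["x"].std(ddof=0), abs=1e-10)
        assert m.fit_metrics["r2"] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(m.predict(X), y, atol=1e-10)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        y = rng.normal(size=5)
        m = fit_ols(X, y)
        Z = (X - X.mean()) / X.std(ddof=0)
        A = np.column_stack([np.ones(5), Z.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert m.intercept == pytest.approx(beta[0], abs=1e-10)
        assert np.allclose(m.coefficients, beta[1:], atol=1e-10)

    def test_duplicated_column_raises_rank_deficiency(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=10)
        X = pd.DataFrame({"a": a, "dup": a})
        with pytest.raises(ValueError, match="dependent|rank"):
            fit_ols(X, rng.normal(size=10))


class TestMetrics:
    def test_perfect_prediction(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["mae"] == 0 and m["rmse"] == 0 and m["r2"] == 1.0

    def test_adjusted_r2_formula(self):
        # n=10, p=2, R²=0.9 -> 1 - 0.1*9/7 = 0.871428...
        y = np.arange(10.0)
        resid_scale = np.sqrt(0.1 * np.var(y) * 10 / np.sum(np.ones(10)))
        # construct predictions with exactly R² = 0.9
        e = np.ones(10)
        e[::2] = -1
        e = e - e.mean()
        e *= np.sqrt(0.1 * y.var() * 10 / (e**2).sum())
        m = metrics(y, y - e, p_features=2)
        assert m["r2"] == pytest.approx(0.9, abs=1e-12)
        assert m["adj_r2"] == pytest.approx(0.8714, abs=5e-5)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_small_n_adjusted_undefined(self):
        m = metrics([1.0, 2.0, 3.0], [1.1, 1.9, 3.2], p_features=2)
        assert m["adj_r2"] is None

    def test_agrees_with_definitional_reimplementation(self):
        rng = np.random.default_rng(7)
        y, p = rng.normal(size=50), rng.normal(size=50)
        m = metrics(y, p, p_features=3)
        assert m["mae"] == pytest.approx(np.abs(y - p).mean(), abs=1e-12)
        assert m["rmse"] == pytest.approx(np.sqrt(((y - p) ** 2).mean()), abs=1e-12)
        r2 = 1 - ((y - p) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert m["r2"] == pytest.approx(r2, abs=1e-12)
        assert m["adj_r2"] == pytest.approx(1 - (1 - r2) * 49 / 46, abs=1e-12)


class TestEnsembleWeights:
    def test_inverse_rmse(self):
        assert np.allclose(ensemble_weights([0.2, 0.3]), [0.6, 0.4])

    def test_equal_rmse_uniform(self):
        assert np.allclose(ensemble_weights([0.25, 0.25, 0.25]), 1 / 3)

    def test_zero_rmse_takes_all(self):
        with pytest.warns(UserWarning):
            w = ensemble_weights([0.0, 0.3])
        assert np.allclose(w, [1.0, 0.0])

    def test_single_member(self):
        assert np.allclose(ensemble_weights([0.5]), [1.0])


def _fit_toy_ensemble(seed=0, k=3):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(50, 6)),
        columns=[f"f{i}__TSRC__boltz" for i in range(3)]
        + [f"f{i}__TSRE__min" for i in range(3)],
    )
    signal = 1.2 * X.iloc[:, 0] - 0.7 * X.iloc[:, 3]
    y = (signal + rng.normal(0, 0.1 * signal.std(), 50)).to_numpy()
    model, ranked = select_and_ensemble(X, y, CVConfig(repeats=2, subset_size=2, seed=seed), k=k)
    return X, y, model, ranked


class TestEnsemble:
    def test_prediction_is_weighted_mean_within_member_range(self):
        X, y, model, _ = _fit_toy_ensemble()
        preds = predict_ensemble(model, X)
        for p in preds:
            assert p.per_member.min() - 1e-9 <= p.mean <= p.per_member.max() + 1e-9
            assert p.spread >= 0

    def test_identical_members_zero_spread(self):
        X, y, model, ranked = _fit_toy_ensemble(k=1)
        clone = EnsembleModel(
            members=[model.members[0], model.members[0]],
            weights=np.array([0.5, 0.5]),
            member_cv_rmse=np.array([0.1, 0.1]),
        )
        preds = predict_ensemble(clone, X)
        assert all(p.spread == pytest.approx(0.0, abs=1e-12) for p in preds)

    def test_k1_ensemble_equals_single_model(self):
        X, y, model, _ = _fit_toy_ensemble(k=1)
        preds = predict_ensemble(model, X)
        single = model.members[0].predict(X)
        assert np.allclose([p.mean for p in preds], single)

    def test_weighted_mean_arithmetic(self):
        X, y, model, _ = _fit_toy_ensemble(k=2)
        p = predict_ensemble(model, X.iloc[:1])[0]
        assert p.mean == pytest.approx(float(model.weights @ p.per_member), abs=1e-12)

    def test_json_round_trip(self, tmp_path):
        X, y, model, _ = _fit_toy_ensemble()
        path = tmp_path / "model.json"
        model.to_json(path)
        back = EnsembleModel.from_json(path)
        p0 = predict_ensemble(model, X)[0]
        p1 = predict_ensemble(back, X)[0]
        assert p0.mean == pytest.approx(p1.mean, abs=1e-12)


class TestLoro:
    def _shared_truth_dataset(self, shift_reaction=None, seed=0):
        rng = np.random.default_rng(seed)
        frames, ys, labels = [], [], []
        for rlab in ("rxnA", "rxnB", "rxnC"):
            X = pd.DataFrame(
                rng.normal(size=(20, 5)), columns=[f"f{i}" for i in range(5)]
            )
            y = 1.0 * X["f0"] - 0.5 * X["f2"] + rng.normal(0, 0.1, 20)
            if rlab == shift_reaction:
                y = y + 2.0
            frames.append(X)
            ys.append(y)
            labels += [rlab] * 20
        return pd.concat(frames, ignore_index=True), np.concatenate(ys), np.array(labels)

    def test_shared_truth_transfers(self):
        X, y, labels = self._shared_truth_dataset()
        res = loro(X, y, labels, CVConfig(repeats=2, subset_size=2, seed=0), k=3)
        for stats in res["per_reaction"].values():
            assert stats["mae"] <= 0.2  # 2x the noise sd

    def test_shifted_reaction_stands_out(self):
        X, y, labels = self._shared_truth_dataset(shift_reaction="rxnB")
        res = loro(X, y, labels, CVConfig(repeats=2, subset_size=2, seed=0), k=3)
        maes = {k: v["mae"] for k, v in res["per_reaction"].items()}
        assert maes["rxnB"] > max(maes["rxnA"], maes["rxnC"])

    def test_single_label_rejected(self):
        X, y, labels = self._shared_truth_dataset()
        with pytest.raises(ValueError, match="two distinct"):
            loro(X, y, np.array(["only"] * len(y)), CVConfig(repeats=1, subset_size=2))

    def test_single_row_holdout_r2_undefined(self):
        X, y, labels = self._shared_truth_dataset()
        labels = labels.astype(object)
        labels[0] = "singleton"
        res = loro(X, y, labels, CVConfig(repeats=1, subset_size=2, seed=0), k=2)
        assert res["per_reaction"]["singleton"]["n"] == 1
        assert res["per_reaction"]["singleton"]["r2"] is None


class TestVirtualScreen:
    def test_monotone_truth_recovered_in_ranking(self):
        X, y, model, _ = _fit_toy_ensemble()
        cand = X.iloc[:10]
        table = virtual_screen(model, FeatureMatrix(cand), reference_ddg=-10.0)
        preds = predict_ensemble(model, cand)
        order = np.argsort([-p.mean for p in preds])
        assert list(table.index) == [cand.index[i] for i in order]

    def test_reference_above_all_flags_nothing(self):
        X, y, model, _ = _fit_toy_ensemble()
        table = virtual_screen(model, X.iloc[:5], reference_ddg=1e6)
        assert not table["predicted_improvement"].any()

    def test_single_candidate(self):
        X, y, model, _ = _fit_toy_ensemble()
        table = virtual_screen(model, X.iloc[:1], reference_ddg=-1e6)
        assert len(table) == 1 and bool(table["predicted_improvement"].iloc[0])


class TestProvenanceFrequency:
    def test_counts_by_feature_and_stage(self):
        X, y, model, _ = _fit_toy_ensemble(k=3)
        freq = feature_provenance_frequency(model)
        assert freq["n_members"] == 3
        assert sum(freq["stage_counts"].values()) == sum(
            len(m.feature_names) for m in model.members
        )
        assert max(freq["feature_counts"].values()) <= 3

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            feature_provenance_frequency(_empty_ensemble())


def _empty_ensemble():
    e = object.__new__(EnsembleModel)
    e.members = []
    e.weights = np.array([])
    e.member_cv_rmse = np.array([])
    return e
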