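import numpy as np
import pandas as pd
import pytest

from rusfresp import composition, oplsda
from rusfresp.errors import (
    DegenerateLabelError,
    SchemaError,
    TransferError,
    ValidationError,
)
from rusfresp.synthetic import EffectSpec, generate_cohort


def gaussian_two_class(seed, n=60, p=10, effect=3.0, n_informative=1):
    rng = np.random.default_rng(seed)
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    X = rng.normal(size=(n, p))
    X[y == "b", :n_informative] += effect
    return pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(p)]), y


class TestLassoSelect:
    def test_planted_feature_selected(self):
        hits = 0
        for seed in range(8):
            X, y = gaussian_two_class(seed, n=60, p=51, effect=2.0)
            hits += "f00" in oplsda.lasso_select(X, y, seed=seed)
        assert hits >= 7

    def test_pure_noise_selects_few(self):
        sizes = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(60, 51)))
            X.columns = [f"f{i}" for i in range(51)]
            y = rng.permutation(["a"] * 30 + ["b"] * 30)
            sizes.append(len(oplsda.lasso_select(X, y, seed=seed)))
        assert np.mean(sizes) <= 5

    def test_duplicated_informative_column_keeps_a_representative(self):
        X, y = gaussian_two_class(0, n=60, p=10, effect=3.0)
        X["f_copy"] = X["f00"]
        selected = oplsda.lasso_select(X, y, seed=0)
        assert {"f00", "f_copy"} & set(selected)

    def test_constant_labels_rejected(self):
        X, _ = gaussian_two_class(0)
        with pytest.raises(DegenerateLabelError):
            oplsda.lasso_select(X, np.array(["a"] * len(X)), seed=0)


class TestFitPredict:
    def test_single_aligned_feature_degenerates_gracefully(self):
        y = np.array(["a"] * 10 + ["b"] * 10)
        X = pd.DataFrame({"f": np.where(y == "b", 1.0, -1.0)})
        model = oplsda.fit_oplsda(X, y, n_ortho=1)
        assert model.n_ortho == 0  # nothing orthogonal left to extract
        pred, scores = oplsda.predict(model, X)
        assert (pred == y).all()

    def test_orthogonal_scores_uncorrelated_with_class(self):
        for seed in range(10):
            X, y = gaussian_two_class(seed, n=40, p=8)
            model = oplsda.fit_oplsda(X, y, n_ortho=1)
            ynum = np.where(y == "a", -1.0, 1.0)
            yc = ynum - ynum.mean()
            for _, t_o, _ in model.orthogonal:
                assert abs(t_o @ yc) <= 1e-8 * np.linalg.norm(t_o) * np.linalg.norm(yc)
                assert abs(np.corrcoef(model.t, t_o)[0, 1]) <= 1e-6

    def test_separable_gaussian_training_accuracy(self):
        X, y = gaussian_two_class(1, n=60, p=10, effect=8.0)
        model = oplsda.fit_oplsda(X, y)
        pred, _ = oplsda.predict(model, X)
        assert (pred == y).mean() == 1.0

    def test_duplicated_row_scores_identically(self):
        X, y = gaussian_two_class(2)
        model = oplsda.fit_oplsda(X, y)
        row = X.iloc[[0]]
        twice = pd.concat([row, row])
        _, scores = oplsda.predict(model, twice)
        assert scores[0] == scores[1]

    def test_missing_column_rejected(self):
        X, y = gaussian_two_class(3)
        model = oplsda.fit_oplsda(X, y)
        with pytest.raises(SchemaError):
            oplsda.predict(model, X.drop(columns=["f00"]))

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        X, y = gaussian_two_class(4)
        model = oplsda.fit_oplsda(X, y)
        path = tmp_path / "model.json"
        model.to_json(path)
        again = oplsda.OplsdaModel.from_json(path)
        p1, s1 = oplsda.predict(model, X)
        p2, s2 = oplsda.predict(again, X)
        assert (p1 == p2).all()
        assert np.allclose(s1, s2)


class TestPlsEquivalence:
    def test_zero_ortho_fit_equals_one_component_pls(self):
        from sklearn.cross_decomposition import PLSRegression

        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
            y = np.array(["x"] * 10 + ["z"] * 10)
            rng.shuffle(y)
            model = oplsda.fit_oplsda(X, y, n_ortho=0)
            ynum = np.where(y == "x", -1.0, 1.0)
            pls = PLSRegression(n_components=1, scale=True).fit(X.to_numpy(), ynum)
            beta_mine = (model.c * model.w) / model.scale_
            assert np.abs(beta_mine - pls.coef_.ravel()).max() <= 1e-8


class TestVipScores:
    def test_single_feature_vip_is_one(self):
        y = np.array(["a"] * 6 + ["b"] * 6)
        X = pd.DataFrame({"f": np.r_[np.zeros(6), np.ones(6)] + np.arange(12) * 0.01})
        vip = oplsda.vip_scores(oplsda.fit_oplsda(X, y))
        assert vip["vip"].iloc[0] == pytest.approx(1.0)

    def test_mean_squared_vip_is_one_for_random_models(self):
        for seed in range(20):
            X, y = gaussian_two_class(seed, n=30, p=7)
            vip = oplsda.vip_scores(oplsda.fit_oplsda(X, y))
            assert (vip["vip"] ** 2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_sign_follows_predictive_loading(self):
        X, y = gaussian_two_class(5, n=40, p=6, effect=3.0)
        model = oplsda.fit_oplsda(X, y)
        vip = oplsda.vip_scores(model).set_index("feature")
        for feat, p_j in zip(model.features, model.p):
            assert vip.loc[feat, "sign"] == (1 if p_j >= 0 else -1)


class TestRepeatedCv:
    def test_separated_data_has_high_accuracy(self):
        X, y = gaussian_two_class(0, n=60, p=10, effect=3.0)
        cv = oplsda.repeated_cv(X, y, repetitions=5, seed=0, nested_selection=True)
        assert cv.mean_accuracy >= 0.9

    def test_shuffled_labels_near_chance(self):
        accs = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(60, 10)))
            X.columns = [f"f{i}" for i in range(10)]
            y = rng.permutation(["a"] * 30 + ["b"] * 30)
            cv = oplsda.repeated_cv(X, y, repetitions=3, seed=seed, nested_selection=True)
            accs.append(cv.mean_accuracy)
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_deterministic_for_fixed_seed(self):
        X, y = gaussian_two_class(1)
        a = oplsda.repeated_cv(X, y, repetitions=2, seed=9)
        b = oplsda.repeated_cv(X, y, repetitions=2, seed=9)
        assert a.accuracies == b.accuracies

    def test_class_smaller_than_folds_rejected(self):
        X, y = gaussian_two_class(0, n=8)
        with pytest.raises(ValidationError):
            oplsda.repeated_cv(X, y, folds=5, repetitions=1, seed=0)


class TestPermutationTest:
    def test_planted_signal_beats_all_permutations(self, wasted_pre):
        counts, y = wasted_pre
        rel = composition.relative_abundance(counts)
        res = oplsda.permutation_test(rel, y, n_perm=30, seed=0, unit_variance=False)
        assert res.observed_accuracy > max(res.permuted_accuracies)
        assert res.p_value == pytest.approx(1 / 31)

    def test_zero_permutations_rejected(self, wasted_pre):
        counts, y = wasted_pre
        rel = composition.relative_abundance(counts)
        with pytest.raises(ValidationError):
            oplsda.permutation_test(rel, y, n_perm=0, seed=0)

    def test_deterministic_for_fixed_seed(self):
        X, y = gaussian_two_class(2, n=40, p=8)
        a = oplsda.permutation_test(X, y, n_perm=5, seed=4, inner_repetitions=2)
        b = oplsda.permutation_test(X, y, n_perm=5, seed=4, inner_repetitions=2)
        assert a.permuted_accuracies == b.permuted_accuracies
        assert a.p_value == b.p_value


class TestTransfer:
    @staticmethod
    def _multilevel_wasted(cohort, timepoint=9):
        counts = cohort.asv.at_timepoint(timepoint)
        subj = counts.data.index.get_level_values("subject_id")
        mask = cohort.labels["group"].reindex(subj).isin(["responder", "nonresponder"]).to_numpy()
        counts = type(counts)(counts.data[mask])
        y = (
            cohort.labels["group"]
            .reindex(counts.data.index.get_level_values("subject_id"))
            .to_numpy()
        )
        return composition.multilevel_composition(counts, cohort.taxonomy), y

    def test_transfer_to_identically_generated_cohort(self, cohort):
        X, y = self._multilevel_wasted(cohort)
        selected = oplsda.lasso_select(X, y, seed=0)
        model = oplsda.fit_oplsda(X[selected], y, unit_variance=False)
        other = generate_cohort(EffectSpec(), seed=2)
        X2, y2 = self._multilevel_wasted(other)
        res = oplsda.transfer_predict(model, X2, y2)
        assert res.accuracy >= 0.8
        assert res.feature_overlap == 1.0

    def test_transfer_to_effectless_cohort_is_chance(self, cohort):
        X, y = self._multilevel_wasted(cohort)
        selected = oplsda.lasso_select(X, y, seed=0)
        model = oplsda.fit_oplsda(X[selected], y, unit_variance=False)
        null = generate_cohort(EffectSpec.null(), seed=3)
        X2, y2 = self._multilevel_wasted(null)
        res = oplsda.transfer_predict(model, X2, y2)
        assert 0.3 <= res.accuracy <= 0.7

    def test_no_shared_taxa_rejected(self, cohort):
        X, y = self._multilevel_wasted(cohort)
        selected = oplsda.lasso_select(X, y, seed=0)
        model = oplsda.fit_oplsda(X[selected], y, unit_variance=False)
        foreign = pd.DataFrame(np.ones((4, 2)), columns=["phylum:Qux", "class:Zap"])
        with pytest.raises(TransferError):
            oplsda.transfer_predict(model, foreign)
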