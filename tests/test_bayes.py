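"""Likelihood-ratio tables, naive-Bayes combination and genome scoring."""

import numpy as np
import pandas as pd
import pytest

import targetrank as tr
from targetrank import errors
from targetrank.bayes import LikelihoodRatioNB, assign_grade
from targetrank.profiles import FeatureMatrix


def binary_fixture(tp, t_total, fp, f_total):
    values = np.concatenate(
        [np.ones(tp), np.zeros(t_total - tp), np.ones(fp), np.zeros(f_total - fp)]
    )
    labels = np.concatenate([np.ones(t_total), np.zeros(f_total)])
    return values, labels


class TestFitLrTable:
    def test_raw_ratio_worked_example(self):
        values, labels = binary_fixture(80, 100, 20, 100)
        _, lrs = tr.fit_lr_table(values, labels, kind="binary", alpha=0.0)
        assert lrs[1] == pytest.approx(4.0)
        assert lrs[0] == pytest.approx(0.25)

    def test_equal_distribution_gives_unit_lr(self):
        values, labels = binary_fixture(30, 100, 30, 100)
        _, lrs = tr.fit_lr_table(values, labels, kind="binary", alpha=0.0)
        assert np.allclose(lrs, 1.0)

    def test_smoothed_empty_negative_bin(self):
        # FP_f = 0 with alpha = 0.5: LR = ((TP+0.5)/(T+1)) / (0.5/(F+1))
        values, labels = binary_fixture(40, 100, 0, 50)
        _, lrs = tr.fit_lr_table(values, labels, kind="binary", alpha=0.5)
        expected = ((40 + 0.5) / (100 + 1)) / (0.5 / (50 + 1))
        assert lrs[1] == pytest.approx(expected)
        assert np.isfinite(lrs).all() and (lrs > 0).all()

    def test_continuous_equal_frequency_bins(self, rng):
        v = rng.normal(size=400)
        y = (rng.random(400) < 0.5).astype(float)
        edges, lrs = tr.fit_lr_table(v, y, kind="continuous", n_bins=5)
        assert len(edges) == 4 and len(lrs) == 5
        counts = np.bincount(np.searchsorted(edges, v, side="right"), minlength=5)
        assert counts.max() - counts.min() <= 2  # equal-frequency binning

    def test_missing_class_raises(self):
        with pytest.raises(errors.MissingLabelsError):
            tr.fit_lr_table([1.0, 0.0], [1.0, 1.0], kind="binary")


class TestCombinedLr:
    def _toy_model(self, contributions):
        model = LikelihoodRatioNB()
        model.features_ = [f"f{i}" for i in range(len(contributions))]
        model.kinds_ = {f: "binary" for f in model.features_}
        model.bin_edges_ = {f: np.array([]) for f in model.features_}
        model.lr_tables_ = {
            f: np.array([1.0, c]) for f, c in zip(model.features_, contributions)
        }
        model.classes_ = np.array([0, 1])
        return model

    def test_neutral_contributions(self):
        model = self._toy_model([1.0, 1.0, 1.0])
        values = {f: 1.0 for f in model.features_}
        assert tr.combined_lr(values, model) == pytest.approx(1.0)

    def test_worked_product(self):
        model = self._toy_model([2.0, 3.0, 0.5])
        values = {f: 1.0 for f in model.features_}
        assert tr.combined_lr(values, model) == pytest.approx(3.0)

    def test_missing_feature_is_neutral(self):
        model = self._toy_model([2.0, 5.0])
        assert tr.combined_lr({"f0": 1.0}, model) == pytest.approx(2.0)

    def test_unfitted_model_raises(self):
        with pytest.raises(errors.ModelStateError):
            tr.combined_lr({}, LikelihoodRatioNB())

    def test_log_space_matches_linear_product(self, rng):
        # dual-route check on 1000 random models
        for _ in range(1000):
            k = int(rng.integers(1, 12))
            contributions = rng.lognormal(0, 2, size=k)
            model = self._toy_model(contributions)
            values = {f: 1.0 for f in model.features_}
            linear = float(np.prod(contributions))
            assert tr.combined_lr(values, model) == pytest.approx(linear, rel=1e-9)


class TestNaiveBayesEquivalence:
    def test_combined_lr_equals_posterior_odds_ratio(self, rng):
        # with alpha=0 and binary features, the product of per-feature LRs
        # must equal the naive-Bayes posterior-odds ratio divided by the
        # prior odds, computed directly from empirical joint frequencies
        n_pos, n_neg = 64, 96
        y = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
        X = pd.DataFrame(
            {
                f"f{j}": (rng.random(n_pos + n_neg) < np.where(y == 1, 0.7, 0.3)).astype(float)
                for j in range(3)
            }
        )
        model = LikelihoodRatioNB(alpha=0.0).fit(X, y)
        for _, row in X.drop_duplicates().iterrows():
            direct = 1.0
            for f in X.columns:
                p_pos = (X[f][y == 1] == row[f]).mean()
                p_neg = (X[f][y == 0] == row[f]).mean()
                direct *= p_pos / p_neg
            assert tr.combined_lr(row.to_dict(), model) == pytest.approx(direct, rel=1e-9)

    def test_score_invariant_to_feature_order(self, rng):
        y = np.concatenate([np.ones(30), np.zeros(30)])
        X = pd.DataFrame({f"f{j}": rng.normal(y, 1.0) for j in range(4)})
        a = LikelihoodRatioNB(features=["f0", "f1", "f2", "f3"]).fit(X, y)
        b = LikelihoodRatioNB(features=["f3", "f1", "f0", "f2"]).fit(X, y)
        assert np.allclose(a.combined_lr(X), b.combined_lr(X))


class TestPredictGenome:
    @pytest.fixture()
    def fitted(self, small_matrix, small_gold):
        labeled = sorted(small_gold.positives) + sorted(small_gold.replicate_negatives(0))
        y = np.array([1.0] * len(small_gold.positives) + [0.0] * 40)
        model = LikelihoodRatioNB(
            features=["signal_peptide", "signaling_molecule", "tsps"],
            kinds=small_matrix.kinds,
        )
        return model.fit(small_matrix.data.loc[labeled], y)

    def test_identical_proteins_get_identical_scores(self, small_matrix, fitted):
        data = small_matrix.data.copy()
        # id sorts right after the original so the tie-break puts the
        # pair on adjacent ranks even among a larger tied group
        clone_id = str(data.index[0]) + "_clone"
        data.loc[clone_id] = data.iloc[0]
        result = tr.predict_genome(FeatureMatrix(data, dict(small_matrix.kinds)), fitted)
        t = result.table
        first = t.loc[data.index[0]]
        clone = t.loc[clone_id]
        assert first["combined_lr"] == clone["combined_lr"]
        assert abs(int(first["rank"]) - int(clone["rank"])) == 1

    def test_positive_evidence_increases_score(self, small_matrix, fitted):
        pid = small_matrix.data.index[0]
        base = small_matrix.data.copy()
        base.loc[pid, "signal_peptide"] = 0.0
        raised = base.copy()
        raised.loc[pid, "signal_peptide"] = 1.0
        lr_flag = fitted.lr_tables_["signal_peptide"]
        assert lr_flag[1] > lr_flag[0]  # the flag is positive evidence here
        s0 = tr.predict_genome(FeatureMatrix(base, dict(small_matrix.kinds)), fitted)
        s1 = tr.predict_genome(FeatureMatrix(raised, dict(small_matrix.kinds)), fitted)
        assert s1.table.loc[pid, "combined_lr"] > s0.table.loc[pid, "combined_lr"]

    def test_ranks_match_recomputed_sort(self, small_matrix, fitted):
        result = tr.predict_genome(small_matrix, fitted)
        scores = fitted.combined_lr(small_matrix.data)
        expected = sorted(
            zip(small_matrix.data.index, scores), key=lambda kv: (-kv[1], kv[0])
        )
        by_rank = result.table.sort_values("rank").index.tolist()
        assert by_rank == [pid for pid, _ in expected]
        assert sorted(result.table["rank"]) == list(range(1, len(by_rank) + 1))

    def test_missing_model_feature_raises(self, small_matrix, fitted):
        pruned = FeatureMatrix(
            small_matrix.data.drop(columns=["tsps"]),
            {k: v for k, v in small_matrix.kinds.items() if k != "tsps"},
        )
        with pytest.raises(errors.SchemaError):
            tr.predict_genome(pruned, fitted)

    def test_grades(self):
        assert assign_grade(250.0) == "high"
        assert assign_grade(5.0) == "median"
        assert assign_grade(0.2) == "low"


class TestIncrementalModels:
    def test_nested_feature_sets(self, small_matrix, small_gold):
        ranking = tr.mrmr_rank(small_matrix, small_gold)
        models = tr.incremental_models(ranking, 6, small_gold, small_matrix)
        assert models[0].features_ == [ranking.features[0]]
        for prev, cur in zip(models, models[1:]):
            assert cur.features_[: len(prev.features_)] == prev.features_

    def test_k_max_out_of_range(self, small_matrix, small_gold):
        ranking = tr.mrmr_rank(small_matrix, small_gold)
        with pytest.raises(errors.RangeError):
            tr.incremental_models(ranking, len(ranking.features) + 1, small_gold, small_matrix)


class TestSerialization:
    def test_json_round_trip(self, small_matrix, small_gold, tmp_path):
        labeled = sorted(small_gold.positives) + sorted(small_gold.replicate_negatives(0))
        y = np.array([1.0] * 40 + [0.0] * 40)
        model = LikelihoodRatioNB(
            features=["signal_peptide", "tsps"], kinds=small_matrix.kinds
        ).fit(small_matrix.data.loc[labeled], y)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = LikelihoodRatioNB.from_json(path)
        assert back.features_ == model.features_
        assert np.allclose(
            back.combined_lr(small_matrix.data), model.combined_lr(small_matrix.data)
        )

    def test_sklearn_params(self):
        from sklearn.base import clone

        m = LikelihoodRatioNB(features=["a"], n_bins=4, alpha=0.1)
        cloned = clone(m)
        assert cloned.get_params()["n_bins"] == 4
        assert cloned.get_params()["alpha"] == 0.1
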