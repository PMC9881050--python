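"""ROC/AUC, replicated cross-validation, independent tests and
feature-comparison statistics."""

import numpy as np
import pandas as pd
import pytest

import targetrank as tr
from targetrank import errors
from targetrank.evaluation import benjamini_hochberg
from targetrank.profiles import FeatureMatrix


def pair_ordering_auc(scores, labels):
    """Oracle: fraction of positive-negative pairs ordered correctly
    (ties credited one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert tr.roc_auc([5, 4, 1, 0], [1, 1, 0, 0]).auc == 1.0

    def test_all_tied_scores(self):
        assert tr.roc_auc([1, 1, 1, 1], [1, 0, 1, 0]).auc == 0.5

    def test_worked_example(self):
        assert tr.roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]).auc == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(errors.DegenerateLabelsError):
            tr.roc_auc([1.0, 2.0], [1, 1])

    def test_curve_is_monotone_and_integrates_to_auc(self, rng):
        scores = rng.normal(size=300)
        labels = (rng.random(300) < 0.4).astype(int)
        scores[labels == 1] += 0.8
        r = tr.roc_auc(scores, labels)
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()
        assert np.trapezoid(r.tpr, r.fpr) == pytest.approx(r.auc, abs=1e-12)

    def test_matches_pair_ordering_on_random_sets(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            # quantized scores force plenty of ties
            scores = np.round(rng.normal(size=n), 1)
            assert tr.roc_auc(scores, labels).auc == pytest.approx(
                pair_ordering_auc(scores, labels), abs=1e-12
            )


class TestCrossValidate:
    def test_shuffled_labels_score_at_chance(self, small_matrix, small_genome, rng):
        shuffled = list(rng.permutation(small_genome.protein_ids)[:40])
        gold = tr.build_gold_standard(
            shuffled, small_genome.protein_ids, size=40, n_replicates=8, seed=2
        )
        summary = tr.cross_validate(
            small_matrix, gold, ["signal_peptide", "tsps", "indegree_tf"], seed=2
        )
        assert abs(summary.mean - 0.5) < 3 * max(summary.sd, 0.02)

    def test_deterministic_given_seed(self, small_matrix, small_gold):
        a = tr.cross_validate(small_matrix, small_gold, ["signal_peptide", "tsps"], seed=4)
        b = tr.cross_validate(small_matrix, small_gold, ["signal_peptide", "tsps"], seed=4)
        assert np.array_equal(a.aucs, b.aucs)

    def test_leave_one_out_matches_direct_loop(self, rng):
        from targetrank.bayes import LikelihoodRatioNB

        n = 16
        y = np.array([1.0] * (n // 2) + [0.0] * (n // 2))
        ids = [f"p{i:02d}" for i in range(n)]
        df = pd.DataFrame(
            {"f0": (y + (rng.random(n) < 0.25)) % 2, "f1": rng.normal(y, 1.2)},
            index=ids,
        )
        matrix = FeatureMatrix(df)
        gold = tr.GoldStandard(
            frozenset(np.array(ids)[y == 1]),
            [(0, frozenset(np.array(ids)[y == 0]))],
            frozenset(ids),
        )
        summary = tr.cross_validate(matrix, gold, ["f0", "f1"], folds=n, seed=0)

        labeled = sorted(gold.positives) + sorted(gold.replicate_negatives(0))
        yy = np.array([1.0] * (n // 2) + [0.0] * (n // 2))
        X = matrix.data.loc[labeled]
        held = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            m = LikelihoodRatioNB(features=["f0", "f1"], kinds=matrix.kinds)
            m.fit(X.iloc[keep], yy[keep])
            held[i] = m.decision_function(X.iloc[[i]])[0]
        assert summary.aucs[0] == pytest.approx(tr.roc_auc(held, yy).auc)

    def test_too_few_labeled_raises(self, small_matrix):
        tiny = tr.GoldStandard(
            frozenset(small_matrix.protein_ids[:3]),
            [(0, frozenset(small_matrix.protein_ids[3:6]))],
            frozenset(small_matrix.protein_ids),
        )
        with pytest.raises(errors.InsufficientDataError):
            tr.cross_validate(small_matrix, tiny, ["tsps"], folds=10)


class TestIndependentTest:
    def test_replicate_grid_bookkeeping(self, small_matrix, small_genome):
        ids = small_genome.protein_ids
        train_pos = small_genome.positives[:25]
        test_pos = small_genome.positives[25:40]
        gold = tr.build_gold_standard(
            train_pos, ids, exclusions=set(small_genome.positives),
            size=25, n_replicates=10, seed=3,
        )
        test_negs = tr.sample_negatives(
            ids, set(small_genome.positives), size=15, n_replicates=10, seed=4
        )
        summary = tr.independent_test(
            small_matrix, gold, ["signal_peptide", "signaling_molecule"],
            test_pos, test_negs,
        )
        assert len(summary.aucs) == 100
        assert summary.mean == pytest.approx(np.mean(summary.aucs))
        assert summary.sd == pytest.approx(np.std(summary.aucs, ddof=1))

    def test_train_test_overlap_raises(self, small_matrix, small_gold, small_genome):
        with pytest.raises(errors.LeakageError):
            tr.independent_test(
                small_matrix, small_gold, ["tsps"],
                small_genome.positives[:5], [frozenset(small_genome.protein_ids[:5])],
            )

    def test_matched_test_distribution_scores_like_cv(self, small_genome, small_matrix):
        # train on half the positives, test on the other half: both halves
        # come from the same generative class, so the independent-test AUC
        # should be comparable to the CV AUC
        ids = small_genome.protein_ids
        half = len(small_genome.positives) // 2
        gold = tr.build_gold_standard(
            small_genome.positives[:half], ids,
            exclusions=set(small_genome.positives), size=20, n_replicates=5, seed=5,
        )
        test_negs = tr.sample_negatives(
            ids, set(small_genome.positives), size=20, n_replicates=5, seed=6
        )
        features = ["signal_peptide", "signaling_molecule", "transmembrane"]
        ind = tr.independent_test(
            small_matrix, gold, features, small_genome.positives[half:], test_negs
        )
        cv = tr.cross_validate(small_matrix, gold, features, folds=5, seed=5)
        assert abs(ind.mean - cv.mean) < 0.15


class TestCompareFeatures:
    def test_identical_binary_groups_not_significant(self):
        df = pd.DataFrame(
            {"flag": [1.0] * 10 + [0.0] * 10 + [1.0] * 10 + [0.0] * 10},
            index=[f"p{i}" for i in range(40)],
        )
        matrix = FeatureMatrix(df)
        report = tr.compare_features(matrix, [f"p{i}" for i in range(20)],
                                     [f"p{i}" for i in range(20, 40)])
        assert report.table["p_value"].iloc[0] >= 0.5

    def test_fisher_extreme_table(self):
        # positives all carry the flag, negatives never: one-sided
        # P = 1 / C(20, 10) = 1/184756
        df = pd.DataFrame(
            {"flag": [1.0] * 10 + [0.0] * 10}, index=[f"p{i}" for i in range(20)]
        )
        matrix = FeatureMatrix(df)
        report = tr.compare_features(
            matrix, [f"p{i}" for i in range(10)], [f"p{i}" for i in range(10, 20)]
        )
        assert report.table["p_value"].iloc[0] == pytest.approx(1 / 184756, rel=1e-9)

    def test_bh_worked_example(self):
        adjusted = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_bh_is_monotone_and_above_raw(self, rng):
        p = rng.random(25)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_one_sided_p_matches_permutation_test(self, rng):
        n = 30
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        values = rng.normal(0.9 * y, 1.0, size=n)
        df = pd.DataFrame({"v": values}, index=[f"p{i}" for i in range(n)])
        matrix = FeatureMatrix(df)
        pos = [f"p{i}" for i in range(n // 2)]
        neg = [f"p{i}" for i in range(n // 2, n)]
        report = tr.compare_features(matrix, pos, neg)
        p_model = report.table["p_value"].iloc[0]

        obs = values[: n // 2].mean() - values[n // 2:].mean()
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(values)
            if perm[: n // 2].mean() - perm[n // 2:].mean() >= obs:
                count += 1
        p_perm = count / n_perm
        assert p_model == pytest.approx(p_perm, abs=3 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.01)

    def test_direction_follows_observed_effect(self, small_matrix, small_genome):
        negatives = [p for p in small_genome.protein_ids if p not in set(small_genome.positives)]
        report = tr.compare_features(small_matrix, small_genome.positives, negatives)
        t = report.table.set_index("feature")
        assert t.loc["signal_peptide", "direction"] == "greater"
        assert t.loc["housekeeping", "direction"] == "less"
        assert (t["adjusted_p"] >= t["p_value"] - 1e-15).all()
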