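"""ReliefF ranking, cosine 1-NN classification, nested top-k CV and AUC."""

import numpy as np
import pytest

import _oracles as oracles
from agingaccel import (NnaModel, auc_from_scores, cross_validate_topk, evaluate,
                        fit_nna, nna_predict, relieff_rank, split_cohort,
                        task_labels)
from agingaccel.predictor import RankedGeneList
from conftest import make_matrix


def _toy_cohort(n=90, g=10, seed=0, p_old=0.5):
    rng = np.random.default_rng(seed)
    ages = np.where(rng.random(n) < p_old, 70.0, 30.0)
    return make_matrix(rng.normal(size=(g, n)), ages=ages)


class TestSplitCohort:
    def test_exact_two_to_one_counts_per_stratum(self):
        m = _toy_cohort(n=90, seed=1, p_old=2 / 3)
        train, test = split_cohort(m, "aging", seed=0)
        for part, total in ((train, 60), (test, 30)):
            labels = task_labels(part, "aging")
            assert len(labels) == total
        # each stratum is split 2:1 exactly when divisible
        y_all = task_labels(m, "aging")
        y_tr = task_labels(train, "aging")
        for cls in (0, 1):
            n_cls = (y_all == cls).sum()
            assert (y_tr == cls).sum() == round(n_cls * 2 / 3)

    def test_class_proportions_close(self):
        m = _toy_cohort(n=300, seed=2, p_old=0.6)
        train, test = split_cohort(m, "aging", seed=5)
        p_tr = task_labels(train, "aging").mean()
        p_te = task_labels(test, "aging").mean()
        assert abs(p_tr - p_te) < 0.02

    def test_same_seed_same_split(self):
        m = _toy_cohort(seed=3)
        t1 = split_cohort(m, "aging", seed=7)
        t2 = split_cohort(m, "aging", seed=7)
        assert t1[0].sample_ids == t2[0].sample_ids

    def test_tiny_class_is_error(self):
        m = _toy_cohort(n=10, seed=4, p_old=0.1)
        if task_labels(m, "aging").sum() >= 3:
            pytest.skip("draw produced enough old samples")
        with pytest.raises(ValueError, match="cannot split"):
            split_cohort(m, "aging", seed=0)


class TestReliefF:
    def test_label_copy_feature_ranks_first(self):
        rng = np.random.default_rng(10)
        n = 80
        y = (rng.random(n) < 0.5).astype(int)
        X = rng.normal(size=(50, n))
        X[7] = y.astype(float)  # gene 8 is a pure copy of the label
        m = make_matrix(X, ages=np.where(y, 70.0, 30.0))
        ranking = relieff_rank(m, y)
        assert ranking.genes[0] == "G8"

    def test_agrees_with_naive_reference_on_small_fixture(self):
        rng = np.random.default_rng(11)
        n, g = 40, 20
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(g, n))
        X[3] += 1.5 * y
        m = make_matrix(X, ages=np.where(y, 70.0, 30.0))
        ranking = relieff_rank(m, y, k_neighbors=10)
        expected = oracles.naive_relieff(X.T, y, k=10)
        got = {gene: w for gene, w in zip(ranking.genes, ranking.weights)}
        for i, gene in enumerate(m.genes):
            assert got[gene] == pytest.approx(expected[i], abs=1e-10)

    def test_duplicated_feature_gets_equal_weight(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(10, 60))
        X[4] = X[9]
        y = (rng.random(60) < 0.5).astype(int)
        ranking = relieff_rank(make_matrix(X), y)
        w = dict(zip(ranking.genes, ranking.weights))
        assert w["G5"] == pytest.approx(w["G10"], abs=1e-12)

    def test_sample_permutation_leaves_weights_unchanged(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(15, 50))
        y = (rng.random(50) < 0.5).astype(int)
        m = make_matrix(X)
        perm = rng.permutation(50)
        mp = m.subset_samples([m.sample_ids[i] for i in perm])
        r1 = relieff_rank(m, y)
        r2 = relieff_rank(mp, y[perm])
        w1 = dict(zip(r1.genes, r1.weights))
        w2 = dict(zip(r2.genes, r2.weights))
        for gene in m.genes:
            assert w1[gene] == pytest.approx(w2[gene], abs=1e-9)

    def test_constant_feature_weight_is_zero(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(5, 30))
        X[2] = 3.14
        y = (rng.random(30) < 0.5).astype(int)
        ranking = relieff_rank(make_matrix(X), y)
        assert dict(zip(ranking.genes, ranking.weights))["G3"] == 0.0


class TestNnaPredict:
    def _model(self, refs, labels):
        return NnaModel(selected_genes=[f"G{i+1}" for i in range(refs.shape[1])],
                        reference=refs, reference_labels=np.array(labels))

    def test_exact_match_wins(self):
        model = self._model(np.array([[1.0, 0.0], [0.0, 1.0]]), [0, 1])
        labels, scores = nna_predict(model, np.array([[0.0, 1.0]]))
        assert labels[0] == 1 and scores[0] > 0

    def test_tie_goes_to_class_zero(self):
        # refs (1,0)->0 and (0,1)->1; query (1,1) is equidistant: 1 - 1/sqrt(2)
        model = self._model(np.array([[1.0, 0.0], [0.0, 1.0]]), [0, 1])
        labels, scores = nna_predict(model, np.array([[1.0, 1.0]]))
        assert labels[0] == 0 and scores[0] == pytest.approx(0.0, abs=1e-15)
        # orthogonal query: d0 = 0 exact match, d1 = 1 - cos(90deg) = 1
        _, s2 = nna_predict(model, np.array([[1.0, 0.0]]))
        assert s2[0] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_norm_query_names_sample(self):
        model = self._model(np.array([[1.0, 0.0], [0.0, 1.0]]), [0, 1])
        m = make_matrix(np.zeros((2, 1)), samples=["BADSAMPLE"])
        with pytest.raises(ValueError, match="BADSAMPLE"):
            nna_predict(model, m)


class TestCrossValidation:
    def test_single_informative_gene_keeps_best_k_small(self):
        rng = np.random.default_rng(20)
        n = 100
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(30, n))
        X[0] = y * 4.0 + rng.normal(0, 0.1, n)  # only gene 1 informative
        m = make_matrix(X, ages=np.where(y, 70.0, 30.0))
        ranking = relieff_rank(m, y)
        assert ranking.genes[0] == "G1"
        curve = cross_validate_topk(m, y, ranking, top_models=20, folds=5, seed=0)
        assert curve.mean_accuracy[curve.best_k - 1] == curve.mean_accuracy.max()
        assert curve.best_k <= 5
        # smallest k wins ties: no earlier k attains the max
        assert not np.any(curve.mean_accuracy[:curve.best_k - 1]
                          >= curve.mean_accuracy[curve.best_k - 1])

    def test_nested_scan_matches_direct_reevaluation(self):
        """The incremental top-k scan must equal independently refitting an
        NNA on each top-k panel with the same folds."""
        from sklearn.model_selection import StratifiedKFold
        rng = np.random.default_rng(21)
        n, g = 60, 12
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(g, n))
        X[:3] += 1.2 * y
        m = make_matrix(X)
        ranking = relieff_rank(m, y)
        curve = cross_validate_topk(m, y, ranking, top_models=g, folds=5, seed=9)
        for k in (1, 4, 12):
            correct = 0
            skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=9)
            Xr = m.values.loc[ranking.genes[:k]].to_numpy().T
            for tr, te in skf.split(Xr, y):
                model = NnaModel(selected_genes=ranking.genes[:k],
                                 reference=Xr[tr], reference_labels=y[tr])
                pred, _ = nna_predict(model, Xr[te])
                correct += (pred == y[te]).sum()
            assert curve.mean_accuracy[k - 1] == pytest.approx(correct / n)

    def test_leave_one_out_boundary_runs(self):
        rng = np.random.default_rng(22)
        y = np.array([0, 1] * 5)
        m = make_matrix(rng.normal(size=(5, 10)))
        curve = cross_validate_topk(m, y, relieff_rank(m, y, k_neighbors=3),
                                    top_models=5, folds=10, seed=0)
        assert len(curve.k_values) == 5

    def test_top_models_clipped_with_warning(self):
        rng = np.random.default_rng(23)
        y = np.array([0, 1] * 10)
        m = make_matrix(rng.normal(size=(4, 20)))
        with pytest.warns(UserWarning, match="clipped"):
            curve = cross_validate_topk(m, y, relieff_rank(m, y), top_models=50)
        assert curve.k_values[-1] == 4


class TestEvaluate:
    def test_perfect_separation_gives_auc_one(self):
        assert auc_from_scores(np.array([0, 0, 1, 1]),
                               np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_all_equal_scores_give_half(self):
        assert auc_from_scores(np.array([0, 1, 0, 1]),
                               np.ones(4)) == pytest.approx(0.5)

    def test_known_mixed_case(self):
        # pairs: (0.9,0.8) conc, (0.9,0.2) conc, (0.3,0.8) disc, (0.3,0.2) conc
        auc = auc_from_scores(np.array([1, 0, 1, 0]),
                              np.array([0.9, 0.8, 0.3, 0.2]))
        assert auc == pytest.approx(0.75)

    def test_trapezoid_equals_concordance_on_random_fixtures(self):
        rng = np.random.default_rng(30)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.normal(size=n), 2)  # rounding forces ties
            assert auc_from_scores(y, s) == pytest.approx(
                oracles.concordance_auc(y, s), abs=1e-12)

    def test_single_class_test_set_is_error(self):
        rng = np.random.default_rng(31)
        m = make_matrix(rng.normal(size=(3, 4)))
        model = fit_nna(m, np.array([0, 1, 0, 1]), m.genes)
        with pytest.raises(ValueError, match="single class"):
            evaluate(model, m, np.zeros(4, dtype=int))

    def test_train_evaluate_path_is_deterministic(self, small_cohort):
        m, _ = small_cohort
        from agingaccel import zscore_normalize, filter_missing
        m = zscore_normalize(filter_missing(m))
        outs = []
        for _ in range(2):
            train, test = split_cohort(m, "disease", seed=3)
            y_tr = task_labels(train, "disease")
            ranking = relieff_rank(train, y_tr)
            curve = cross_validate_topk(train, y_tr, ranking, top_models=15,
                                        folds=5, seed=3)
            model = fit_nna(train, y_tr, ranking.top(curve.best_k))
            ev = evaluate(model, test, task_labels(test, "disease"))
            outs.append((curve.best_k, ev["auc"], ev["accuracy"]))
        assert outs[0] == outs[1]
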