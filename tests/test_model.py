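"""Feature filtering, the voting ensemble, metrics and cross-validation."""

import numpy as np
import pandas as pd
import pytest

import cleavesite as cs
from cleavesite.model import auc_score

FAST = cs.ModelConfig(rf_trees=60, random_seed=0)


def _frame(rng, n, m, prefix="f"):
    return pd.DataFrame(rng.normal(size=(n, m)), columns=[f"{prefix}{i}" for i in range(m)])


class TestRemoveUnary:
    def test_constant_column_removed(self, rng):
        X = _frame(rng, 10, 3)
        X["const"] = 7.0
        Xv, dropped = cs.remove_unary(X)
        assert dropped == ["const"] and "const" not in Xv.columns

    def test_single_differing_row_kept(self, rng):
        X = pd.DataFrame({"a": [1.0] * 9 + [2.0]})
        Xv, dropped = cs.remove_unary(X)
        assert dropped == [] and list(Xv.columns) == ["a"]

    def test_column_scan_oracle(self, rng):
        X = _frame(rng, 30, 10)
        for c in ("f2", "f7"):
            X[c] = 1.5
        Xv, dropped = cs.remove_unary(X)
        expect = [c for c in X.columns if X[c].nunique() == 1]
        assert sorted(dropped) == sorted(expect)


class TestSelectFeaturesFDR:
    def test_label_identical_feature_selected(self, rng):
        y = np.array([0, 1] * 30)
        X = _frame(rng, 60, 5)
        X["oracle"] = y.astype(float)
        assert "oracle" in cs.select_features_fdr(X, y)

    def test_constant_feature_excluded(self, rng):
        y = np.array([0, 1] * 30)
        X = _frame(rng, 60, 3)
        X["flat"] = 2.0
        assert "flat" not in cs.select_features_fdr(X, y)

    def test_single_class_errors(self, rng):
        X = _frame(rng, 10, 3)
        with pytest.raises(ValueError, match="class"):
            cs.select_features_fdr(X, np.zeros(10))

    def test_bh_equals_hand_rolled_stepup(self, rng):
        """Selection agrees with a direct Benjamini-Hochberg step-up on the
        per-feature ANOVA p-values."""
        from sklearn.feature_selection import f_classif

        y = rng.integers(0, 2, size=100)
        X = _frame(rng, 100, 40)
        X.iloc[:, :4] = X.iloc[:, :4].values + y[:, None] * 1.2  # planted signal
        got = set(cs.select_features_fdr(X, y, q=0.1))
        _, p = f_classif(X.values, y)
        order = np.argsort(p)
        m = len(p)
        thresh = 0.0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= 0.1 * rank / m:
                thresh = p[idx]
        expect = {X.columns[i] for i in range(m) if p[i] <= thresh}
        assert got == expect


class TestEnsemble:
    def test_separable_gaussians(self, rng):
        """Two well-separated Gaussian classes are learned almost
        perfectly (held-out accuracy >= 0.95)."""
        n = 200
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X = pd.DataFrame(
            rng.normal(size=(n, 4)) + 4.0 * y[:, None],
            columns=[f"g{i}" for i in range(4)],
        )
        idx = rng.permutation(n)
        tr, te = idx[:150], idx[150:]
        model = cs.fit_ensemble(X.iloc[tr], y[tr], FAST)
        acc = (model.predict(X.iloc[te]) == y[te]).mean()
        assert acc >= 0.95

    def test_majority_vote_rule(self, rng):
        """The committee call is the majority of member calls."""
        y = np.array([0, 1] * 40)
        X = _frame(rng, 80, 6)
        X["sig"] = y + rng.normal(scale=0.3, size=80)
        model = cs.fit_ensemble(X, y, FAST)
        Z = model.scaler.transform(X[model.feature_names].values)
        votes = np.stack([m.predict(Z) for m in model.members])
        assert np.array_equal(model.predict(X), (votes.sum(axis=0) >= 2).astype(int))

    def test_score_is_mean_probability(self, rng):
        y = np.array([0, 1] * 40)
        X = _frame(rng, 80, 4)
        X["sig"] = y + rng.normal(scale=0.5, size=80)
        model = cs.fit_ensemble(X, y, FAST)
        Z = model.scaler.transform(X[model.feature_names].values)
        mean_p = np.mean([m.predict_proba(Z)[:, 1] for m in model.members], axis=0)
        assert np.allclose(model.predict_proba(X), mean_p)

    def test_single_class_errors(self, rng):
        X = _frame(rng, 12, 3)
        with pytest.raises(ValueError, match="class"):
            cs.fit_ensemble(X, np.ones(12, int), FAST)

    def test_missing_features_at_predict_named(self, rng):
        y = np.array([0, 1] * 20)
        X = _frame(rng, 40, 6)
        X["sig"] = y.astype(float)
        model = cs.fit_ensemble(X, y, FAST)
        with pytest.raises(ValueError, match="feature"):
            model.predict_proba(X.drop(columns=model.feature_names[:1]))

    def test_determinism(self, rng):
        y = np.array([0, 1] * 30)
        X = _frame(rng, 60, 8)
        X["sig"] = y + rng.normal(scale=0.5, size=60)
        p1 = cs.fit_ensemble(X, y, FAST).predict_proba(X)
        p2 = cs.fit_ensemble(X, y, FAST).predict_proba(X)
        assert np.array_equal(p1, p2)


class TestMetrics:
    def test_perfect_scores(self):
        truth = [0, 0, 1, 1]
        rep = cs.compute_metrics(truth, [0.1, 0.2, 0.8, 0.9])
        assert all(v == 1.0 for v in rep.as_dict().values())

    def test_fixed_confusion_counts(self):
        """TP=2 FP=1 TN=6 FN=1 -> sens 2/3, prec 2/3, spec 6/7, acc 0.8,
        F1 2/3."""
        truth = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.2, 0.7, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        rep = cs.compute_metrics(truth, scores)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (2, 1, 6, 1)
        assert rep.sensitivity == pytest.approx(2 / 3)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.specificity == pytest.approx(6 / 7)
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(2 / 3)

    def test_consistency_identities(self, rng):
        truth = rng.integers(0, 2, size=60)
        truth[:2] = [0, 1]
        scores = rng.random(60)
        rep = cs.compute_metrics(truth, scores)
        n = rep.tp + rep.fp + rep.tn + rep.fn
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / n)
        if rep.precision + rep.sensitivity:
            assert rep.f1 == pytest.approx(
                2 * rep.precision * rep.sensitivity / (rep.precision + rep.sensitivity)
            )

    def test_auc_pair_counting_oracle(self, rng):
        """Rank-statistic AUC equals brute-force counting over all
        positive-negative pairs with ties worth 1/2."""
        for _ in range(10):
            truth = rng.integers(0, 2, size=50)
            truth[:2] = [0, 1]
            scores = np.round(rng.random(50), 1)  # force ties
            pos = scores[truth == 1]
            neg = scores[truth == 0]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert auc_score(truth, scores) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_one_class_auc_undefined(self):
        with pytest.raises(ValueError, match="AUC|class"):
            cs.compute_metrics([1, 1], [0.5, 0.6])


class TestStratifiedCV:
    def _data(self, rng, n=200, m=12, signal=1.0):
        y = np.array([0] * (3 * n // 4) + [1] * (n - 3 * n // 4))
        X = _frame(rng, n, m)
        X.iloc[:, 0] += signal * y
        return X, y

    def test_fold_class_ratios(self, rng):
        from sklearn.model_selection import StratifiedKFold

        X, y = self._data(rng)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        sizes, pos = [], []
        for _, te in skf.split(X, y):
            sizes.append(len(te))
            pos.append(y[te].sum())
        assert max(sizes) - min(sizes) <= 1
        assert max(pos) - min(pos) <= 1

    def test_minority_class_smaller_than_folds_errors(self, rng):
        X = _frame(rng, 30, 4)
        y = np.array([1] * 5 + [0] * 25)
        with pytest.raises(ValueError, match="folds"):
            cs.stratified_cv(X, y, cs.ModelConfig(cv_folds=10))

    def test_permuted_labels_auc_near_half(self, rng):
        """With labels carrying no information the mean CV AUC sits near
        0.5."""
        X = _frame(rng, 400, 10)
        y = rng.permutation([0] * 300 + [1] * 100)
        rep = cs.stratified_cv(X, y, cs.ModelConfig(cv_folds=5, rf_trees=60))
        assert 0.40 <= rep.mean["auc"] <= 0.60

    def test_leakage_canary(self, rng):
        """A feature equal to the held-out labels but constant inside each
        training fold must not inflate test metrics: per-fold selection
        discards it as unary, so AUC stays at chance."""
        n = 200
        y = rng.permutation([0] * 150 + [1] * 50)
        X = _frame(rng, n, 8)
        from sklearn.model_selection import StratifiedKFold

        canary = np.zeros(n)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        folds = list(skf.split(X, y))
        te0 = folds[0][1]
        canary[te0] = y[te0]  # informative only where fold 0 is tested
        X["canary"] = canary
        cfg = cs.ModelConfig(cv_folds=5, rf_trees=60, random_seed=0)
        rep = cs.stratified_cv(X, y, cfg)
        assert rep.mean["auc"] < 0.65

    def test_determinism_of_reports(self, rng):
        X, y = self._data(rng, n=120, m=6)
        cfg = cs.ModelConfig(cv_folds=4, rf_trees=60, random_seed=3)
        r1 = cs.stratified_cv(X, y, cfg)
        r2 = cs.stratified_cv(X, y, cfg)
        assert r1.mean == r2.mean
        assert r1.pooled == r2.pooled


@pytest.fixture(scope="module")
def trained():
    corpus = cs.simulate_corpus(cs.SimConfig(n_sequences=25, seed=11, beta=0.9))
    wins = cs.candidate_windows(corpus)
    X, meta = cs.build_feature_matrix(wins, cs.FeatureConfig())
    return cs.fit_ensemble(X, meta["label"].astype(int).to_numpy(), FAST)


class TestPredictSites:

    def test_no_basic_residues_no_calls(self, trained):
        seq = cs.AnnotatedSequence(id="q", residues="AGAGAGAGAGAGAGAGAGAGAGAGAGAGAG")
        out = cs.predict_sites([seq], trained, cs.FeatureConfig())
        assert len(out) == 0

    def test_site_count_bounded_by_kr_census(self, trained):
        corpus = cs.simulate_corpus(cs.SimConfig(n_sequences=4, seed=13))
        out = cs.predict_sites(corpus, trained, cs.FeatureConfig())
        for seq in corpus:
            n_kr = seq.residues.count("K") + seq.residues.count("R")
            assert (out["seq_id"] == seq.id).sum() <= n_kr
        assert out["probability"].between(0, 1).all()
        assert set(out["call"]) <= {0, 1}

    def test_planted_sites_rank_above_decoys(self, trained):
        """On held-out synthetic data with planted signal the ranking AUC
        is high."""
        test = cs.simulate_corpus(cs.SimConfig(n_sequences=25, seed=99, beta=0.9))
        out = cs.predict_sites(test, trained, cs.FeatureConfig())
        labels = {s.id: s.labels for s in test}
        truth = [int(labels[r.seq_id][int(r.position) - 1]) for r in out.itertuples()]
        assert auc_score(np.array(truth), out["probability"].to_numpy()) >= 0.9
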