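import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloodmark.ml import (
    CandidatePanel,
    PanelDiscovery,
    auc_score,
    aupr_score,
    cv_lasso_select,
    evaluate,
    optimal_cutoff,
    predict_vote,
    select_panel,
    train_ensemble,
    vote_auc,
)
from bloodmark.simulate import generate_cohorts, recovery_config


def auc_pair_counting(scores, labels):
    """Exhaustive U-statistic oracle: count positive/negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_ranking(self):
        assert auc_score([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            n = rng.integers(2, 11)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # force ties
            assert auc_score(scores, labels) == auc_pair_counting(scores, labels)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([0.1, 0.2], [1, 1])

    @given(st.floats(min_value=0.01, max_value=5.0), st.floats(min_value=-3, max_value=3))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_monotone_transform(self, scale, shift):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        transformed = np.exp(scale * scores) + shift
        assert auc_score(scores, labels) == pytest.approx(auc_score(transformed, labels), abs=1e-12)


class TestAupr:
    def test_random_scores_near_prevalence(self):
        rng = np.random.default_rng(1)
        labels = (rng.random(2000) < 0.3).astype(int)
        scores = rng.random(2000)
        assert aupr_score(scores, labels) == pytest.approx(labels.mean(), abs=0.05)

    def test_perfect_separation_gives_one(self):
        assert aupr_score([0.9, 0.8, 0.1], [1, 1, 0]) == pytest.approx(1.0)

    def test_matches_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(3)
        for _ in range(20):
            labels = rng.integers(0, 2, 50)
            if labels.sum() in (0, 50):
                continue
            scores = rng.choice(np.linspace(0, 1, 17), size=50)
            assert aupr_score(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )


class TestOptimalCutoff:
    def test_separable_midpoint(self):
        cut, degenerate = optimal_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert cut == pytest.approx(0.5) and not degenerate

    def test_two_point_tie_resolved_to_smaller(self):
        cut, _ = optimal_cutoff([0.4, 0.6], [1, 0])
        assert cut == pytest.approx(0.5)

    def test_constant_scores_flagged(self):
        cut, degenerate = optimal_cutoff([0.3, 0.3, 0.3], [1, 0, 1])
        assert cut == 0.3 and degenerate

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            scores = rng.choice(np.linspace(0, 1, 11), size=20)
            labels = rng.integers(0, 2, 20)
            if labels.min() == labels.max():
                continue
            cut, _ = optimal_cutoff(scores, labels)
            uniq = np.unique(scores)
            if len(uniq) == 1:
                continue
            best = None
            n1, n0 = labels.sum(), 20 - labels.sum()
            for c in (uniq[:-1] + uniq[1:]) / 2:
                pred = scores >= c
                tp = ((pred) & (labels == 1)).sum()
                tn = ((~pred) & (labels == 0)).sum()
                key = ((tp + tn) / 20, tp / n1 + tn / n0 - 1, -c)
                if best is None or key > best[0]:
                    best = (key, c)
            assert cut == pytest.approx(best[1])


class TestVoteAuc:
    def test_reported_panel_aggregations(self):
        assert vote_auc((0.875, 0.874, 0.849)) == 0.866
        assert vote_auc((0.86, 0.86, 0.857)) == 0.859
        assert vote_auc((1, 1, 1)) == 1.0

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            vote_auc((0.9, 0.9))


class TestSelectPanel:
    def test_sub_two_feature_candidate_skipped(self):
        cands = [
            CandidatePanel(frozenset({"f1"}), cv_auc=0.88, frequency=10, lam=0.1),
            CandidatePanel(frozenset({"f1", "f2", "f3", "f4"}), cv_auc=0.86, frequency=5, lam=0.05),
        ]
        panel = select_panel(cands, rule="best_auc")
        assert set(panel.features) == {"f1", "f2", "f3", "f4"}

    def test_single_candidate_under_both_rules(self):
        cands = [CandidatePanel(frozenset({"a", "b", "c"}), 0.8, 3, 0.1)]
        for rule in ("best_auc", "most_frequent"):
            assert set(select_panel(cands, rule=rule).features) == {"a", "b", "c"}

    def test_auc_tie_broken_by_frequency(self):
        cands = [
            CandidatePanel(frozenset({"a", "b"}), 0.85, 10, 0.1),
            CandidatePanel(frozenset({"c", "d"}), 0.85, 40, 0.1),
        ]
        assert set(select_panel(cands, rule="best_auc").features) == {"c", "d"}

    def test_no_valid_candidate_rejected(self):
        with pytest.raises(ValueError):
            select_panel([CandidatePanel(frozenset({"x"}), 0.9, 1, 0.1)])


class TestEnsemble:
    def test_separable_toy_reaches_training_accuracy_one(self):
        X = np.array([[-2.0], [-1.5], [1.5], [2.0]])
        y = np.array([0, 0, 1, 1])
        model = train_ensemble(X, y, seed=0)
        pred = predict_vote(model, X)
        for m in ("svm", "rf", "ridge"):
            np.testing.assert_array_equal(pred["labels"][m], y)

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] + rng.normal(0, 0.5, 60) > 0).astype(int)
        m1 = train_ensemble(X, y, seed=9)
        m2 = train_ensemble(X, y, seed=9)
        Xt = rng.normal(size=(30, 3))
        np.testing.assert_array_equal(predict_vote(m1, Xt)["vote"], predict_vote(m2, Xt)["vote"])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_ensemble(np.zeros((4, 1)), np.ones(4, dtype=int), seed=0)

    def test_missing_panel_column_rejected(self):
        X = np.array([[-1.0, 0.1], [1.0, -0.2], [-1.1, 0.0], [0.9, 0.3]])
        model = train_ensemble(X, np.array([0, 1, 0, 1]), seed=0)
        with pytest.raises(ValueError, match="panel column"):
            predict_vote(model, X[:, :1])

    def test_vote_majority_rule(self):
        labels = {"svm": np.array([1, 0, 1]), "rf": np.array([1, 0, 0]), "ridge": np.array([0, 0, 1])}
        votes = (labels["svm"] + labels["rf"] + labels["ridge"] >= 2).astype(int)
        np.testing.assert_array_equal(votes, [1, 0, 1])

    def test_unanimity_implies_vote_agreement(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 2))
        y = (X.sum(axis=1) > 0).astype(int)
        model = train_ensemble(X, y, seed=1)
        pred = predict_vote(model, rng.normal(size=(40, 2)))
        lab = pred["labels"]
        agree = (lab["svm"] == lab["rf"]) & (lab["rf"] == lab["ridge"])
        np.testing.assert_array_equal(pred["vote"][agree], lab["svm"][agree])

    def test_single_planted_feature_calibrates_to_bayes_auc(self):
        """One feature with a standardized shift of 2: the monotone-optimal
        ridge scorer reaches the closed-form Bayes AUC Phi(sqrt(2)) = 0.921
        within 0.03, and no model exceeds that optimum (beyond noise)."""
        bound = 0.92135
        ridge_aucs, all_aucs = [], []
        for seed in (11, 12, 13):
            rng = np.random.default_rng(seed)
            n_tr, n_te = 300, 500
            X_tr = np.r_[rng.normal(0, 1, n_tr // 2), rng.normal(2, 1, n_tr // 2)][:, None]
            y_tr = np.r_[np.zeros(n_tr // 2), np.ones(n_tr // 2)].astype(int)
            X_te = np.r_[rng.normal(0, 1, n_te // 2), rng.normal(2, 1, n_te // 2)][:, None]
            y_te = np.r_[np.zeros(n_te // 2), np.ones(n_te // 2)].astype(int)
            model = train_ensemble(X_tr, y_tr, seed=seed)
            pred = predict_vote(model, X_te)
            aucs = {m: auc_score(pred["scores"][m], y_te) for m in ("svm", "rf", "ridge")}
            ridge_aucs.append(aucs["ridge"])
            all_aucs.extend(aucs.values())
        assert np.mean(ridge_aucs) == pytest.approx(bound, abs=0.03)
        assert max(all_aucs) <= bound + 0.03
        assert min(all_aucs) >= bound - 0.10  # RF/SVM approach, never match, the optimum


class TestEvaluate:
    def test_perfect_ranking_auc_one(self):
        scores = {"svm": np.array([0.9, 0.8, 0.3, 0.2])}
        rep = evaluate(scores, [1, 1, 0, 0], [1, 1, 0, 0])
        assert rep.auc["svm"] == 1.0

    def test_reported_accuracy_confidence_interval(self):
        """141 correct of 180: accuracy 0.783 with exact 95% CI
        (0.716, 0.841)."""
        labels = np.r_[np.ones(102), np.zeros(78)].astype(int)
        vote = labels.copy()
        wrong = np.r_[np.arange(20), np.arange(102, 121)]  # 39 errors
        vote[wrong] = 1 - vote[wrong]
        scores = {"svm": vote + 0.1, "rf": vote + 0.1, "ridge": vote + 0.1}
        rep = evaluate(scores, labels, vote)
        assert rep.accuracy == pytest.approx(141 / 180)
        assert rep.accuracy_ci[0] == pytest.approx(0.716, abs=5e-4)
        assert rep.accuracy_ci[1] == pytest.approx(0.841, abs=5e-4)

    def test_score_average_alternative_beats_chance_on_signal(self):
        from bloodmark.ml import score_average_auc

        rng = np.random.default_rng(9)
        labels = np.r_[np.zeros(50), np.ones(50)].astype(int)
        scores = {m: labels + rng.normal(0, 1, 100) for m in ("svm", "rf", "ridge")}
        pooled = score_average_auc(scores, labels)
        singles = [auc_score(s, labels) for s in scores.values()]
        assert pooled > 0.5
        assert pooled >= min(singles)

    def test_vote_auc_is_mean_of_three(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        scores = {m: rng.normal(size=100) for m in ("svm", "rf", "ridge")}
        rep = evaluate(scores, labels, (scores["svm"] > 0).astype(int))
        assert rep.vote_auc == pytest.approx(
            round(np.mean([rep.auc[m] for m in ("svm", "rf", "ridge")]), 3)
        )

    def test_confusion_identities(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        vote = rng.integers(0, 2, 60)
        rep = evaluate({"svm": rng.normal(size=60)}, labels, vote)
        c = rep.confusion
        assert rep.accuracy == pytest.approx((c["tp"] + c["tn"]) / 60)
        assert rep.sensitivity == pytest.approx(c["tp"] / (c["tp"] + c["fn"]))
        assert rep.specificity == pytest.approx(c["tn"] / (c["tn"] + c["fp"]))


class TestCvLassoSelect:
    def _planted(self, seed, n=150, G=203, n_signal=3, delta=1.5):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, G))
        X[:, :n_signal] += delta * y[:, None]
        ids = [f"f{i:03d}" for i in range(G)]
        return X, y, ids

    def test_recovers_planted_features(self):
        """Top-frequency candidate contains >= 2 of 3 planted features in
        >= 90% of replicates."""
        hits = []
        for seed in range(10):
            X, y, ids = self._planted(seed)
            cands = cv_lasso_select(X, y, ids, folds=5, repeats=3, seed=seed)
            top = max(cands, key=lambda c: c.frequency)
            hits.append(len(top.features & {"f000", "f001", "f002"}) >= 2)
        assert np.mean(hits) >= 0.9

    def test_pure_noise_auc_near_chance(self):
        medians = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(80, 40))
            y = rng.integers(0, 2, 80)
            y[:2] = [0, 1]
            cands = cv_lasso_select(X, y, [f"f{i}" for i in range(40)], repeats=2, seed=seed)
            medians.append(np.median([c.cv_auc for c in cands]))
        assert 0.35 <= np.median(medians) <= 0.65

    def test_same_seed_identical_candidates(self):
        X, y, ids = self._planted(0)
        c1 = cv_lasso_select(X, y, ids, repeats=2, seed=5)
        c2 = cv_lasso_select(X, y, ids, repeats=2, seed=5)
        assert [(c.features, c.frequency, c.cv_auc) for c in c1] == [
            (c.features, c.frequency, c.cv_auc) for c in c2
        ]

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 5))
        with pytest.raises(ValueError):
            cv_lasso_select(X, np.ones(20, dtype=int), [f"f{i}" for i in range(5)])

    def test_constant_columns_dropped_with_warning(self):
        X, y, ids = self._planted(1, n=60, G=20)
        X[:, 10] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            cands = cv_lasso_select(X, y, ids[:20], repeats=1, seed=0)
        assert all("f010" not in c.features for c in cands)


class TestCrossDatasetProtocol:
    def test_directions_agree_and_deterministic(self):
        """Symmetric synthetic cohorts: the two train/test directions give
        vote AUCs within 0.04, and a fixed seed reproduces bit-identically."""
        cfg = recovery_config(seed=21, panel_effect=2.0)
        cfg = type(cfg)(**{**cfg.__dict__, "n_per_group": ((60, 0, 60), (60, 0, 60)), "n_features": 300})
        (a, b), (ia, ib), truth = generate_cohorts(cfg)
        model = PanelDiscovery(a, ia, b, ib, repeats=3)
        res = model.fit(seed=1)
        auc_ab = res.report("a_to_b").vote_auc
        auc_ba = res.report("b_to_a").vote_auc
        assert abs(auc_ab - auc_ba) <= 0.04
        res2 = model.fit(seed=1)
        assert res2.report("a_to_b").to_dict() == res.report("a_to_b").to_dict()
        assert res2.panel("b_to_a").features == res.panel("b_to_a").features

    def test_mci_predicted_as_disease_when_signal_shared(self):
        """With MCI carrying the full AD panel signal, most MCI samples
        should be voted into the AD class."""
        from bloodmark.simulate import SimConfig

        cfg = SimConfig(
            n_per_group=((60, 30, 60), (60, 30, 60)),
            n_features=300,
            deg_fraction=0.05,
            deg_effect_range=(0.0, 0.0),
            panel_features=4,
            panel_effect=2.0,
            mci_attenuation=1.0,
            seed=13,
        )
        (a, b), (ia, ib), _ = generate_cohorts(cfg)
        res = PanelDiscovery(a, ia, b, ib, repeats=3).fit(seed=2)
        assert res.mci_as_ad_rate("a_to_b") > 0.7

    def test_summary_mentions_both_directions(self):
        cfg = recovery_config(seed=30, panel_effect=2.0)
        cfg = type(cfg)(**{**cfg.__dict__, "n_per_group": ((40, 0, 40), (40, 0, 40)), "n_features": 150})
        (a, b), (ia, ib), _ = generate_cohorts(cfg)
        res = PanelDiscovery(a, ia, b, ib, repeats=2).fit(seed=3)
        text = res.summary()
        assert "a_to_b" in text and "b_to_a" in text and "vote AUC" in text
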