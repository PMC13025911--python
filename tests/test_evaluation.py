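"""Metrics vs brute-force oracles, DeLong components, CV hygiene."""

import numpy as np
import pandas as pd
import pytest

from wardwatch.evaluation import (EvalReport, OracleSpec, aupr, auroc,
                                  baseline_table, delong_components,
                                  delong_test, kfold_cv, optimal_threshold,
                                  trajectory_summary)


def brute_auroc(scores, labels):
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    return np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])


def brute_aupr(scores, labels):
    """Average precision by explicit descent over the ranked list."""
    order = np.argsort(-np.asarray(scores, float), kind="stable")
    y = np.asarray(labels)[order]
    # ties: average precision is defined on the ranking induced by score;
    # break ties identically to the implementation by sorting tied blocks
    s = np.asarray(scores, float)[order]
    tp = fp = 0
    out = 0.0
    i = 0
    n_pos = y.sum()
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:
            j += 1
        block_tp = y[i:j].sum()
        block_fp = (j - i) - block_tp
        tp += block_tp
        fp += block_fp
        precision = tp / (tp + fp)
        out += precision * block_tp
        i = j
    return out / n_pos


class TestRankingMetrics:
    def test_perfect_and_tied_edge_cases(self):
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auroc([1, 1, 1, 1], [0, 1, 0, 1]) == 0.5
        assert aupr([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_auroc_matches_pair_counting_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(10, 60)
            scores = rng.integers(0, 6, n).astype(float)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert auroc(scores, labels) == pytest.approx(
                brute_auroc(scores, labels), abs=1e-12)

    def test_aupr_matches_threshold_sweep_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(10, 60)
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                continue
            assert aupr(scores, labels) == pytest.approx(
                brute_aupr(scores, labels), abs=1e-10)

    def test_null_aupr_approaches_prevalence(self):
        rng = np.random.default_rng(2)
        n = 100_000
        labels = (rng.uniform(size=n) < 0.07).astype(int)
        scores = rng.normal(size=n)
        assert abs(aupr(scores, labels) - labels.mean()) < 0.01

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])
        with pytest.raises(ValueError):
            aupr([1, 2], [0, 0])


class TestDeLong:
    def brute_components(self, scores, labels):
        scores = np.asarray(scores, float)
        pos = scores[np.asarray(labels) == 1]
        neg = scores[np.asarray(labels) == 0]
        psi = lambda x, y: 1.0 if x > y else (0.5 if x == y else 0.0)
        v10 = np.array([np.mean([psi(x, y) for y in neg]) for x in pos])
        v01 = np.array([np.mean([psi(x, y) for x in pos]) for y in neg])
        return v10, v01

    def test_components_match_quadratic_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = 30
            scores = rng.integers(0, 8, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            a, v10, v01 = delong_components(scores, labels)
            b10, b01 = self.brute_components(scores, labels)
            assert np.allclose(v10, b10, atol=1e-10)
            assert np.allclose(v01, b01, atol=1e-10)
            assert a == pytest.approx(brute_auroc(scores, labels), abs=1e-12)

    def test_identical_scores_are_degenerate(self):
        s = np.array([0.1, 0.9, 0.4, 0.8, 0.2, 0.7])
        y = np.array([0, 1, 0, 1, 0, 1])
        res = delong_test(s, s, y)
        assert res["degenerate"] and res["p"] == 1.0 and res["delta"] == 0.0

    def test_clearly_better_score_is_significant(self):
        rng = np.random.default_rng(4)
        n = 400
        y = (rng.uniform(size=n) < 0.3).astype(int)
        good = y + rng.normal(0, 0.5, n)
        bad = rng.normal(size=n)
        res = delong_test(good, bad, y)
        assert res["p"] < 1e-6 and res["auroc_a"] > res["auroc_b"]


class TestOptimalThreshold:
    def brute(self, scores, labels):
        scores = np.asarray(scores, float)
        labels = np.asarray(labels)
        uniq = np.unique(scores)
        cands = np.concatenate([[uniq[0] - 1],
                                (uniq[:-1] + uniq[1:]) / 2,
                                [uniq[-1] + 1]])
        best = (-np.inf, None)
        for t in cands:
            pred = scores >= t
            j = (pred[labels == 1].mean() + (~pred)[labels == 0].mean() - 1)
            if j > best[0] or (j == best[0] and t > best[1]):
                best = (j, t)
        return best

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(8, 50)
            scores = rng.integers(0, 10, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            t = optimal_threshold(scores, labels)
            j_best, t_best = self.brute(scores, labels)
            assert t == t_best

    def test_perfect_separation_returns_gap_midpoint(self):
        assert optimal_threshold([1, 2, 10, 11], [0, 0, 1, 1]) == 6.0

    def test_returned_cut_attains_maximal_youden_j(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=50)
        labels = (scores + rng.normal(0, 1, 50) > 0).astype(int)
        t = optimal_threshold(scores, labels)
        j_at = lambda c: ((scores >= c)[labels == 1].mean()
                          + (scores < c)[labels == 0].mean() - 1)
        assert all(j_at(t) >= j_at(c) - 1e-12 for c in scores)


class TestKFold:
    def test_leave_one_out_when_k_equals_n(self):
        from wardwatch.evaluation import fold_assignments
        labels = [0, 1] * 10
        folds = fold_assignments(labels, k=20, seed=0)
        assert len(folds) == 20 and all(len(f) == 1 for f in folds)
        assert sorted(int(f[0]) for f in folds) == list(range(20))

    def test_folds_partition_and_stratify(self, cohort2000):
        from sklearn.model_selection import StratifiedKFold
        labels = cohort2000["labels"]
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        seen = []
        for _, te in skf.split(np.zeros(len(labels)), labels):
            assert labels[te].sum() >= 1
            seen.extend(te)
        assert sorted(seen) == list(range(len(labels)))

    def test_oracle_score_cv_recovers_oracle_auroc(self, cohort2000):
        from wardwatch.synthetic import oracle_auroc
        kept, labels = cohort2000["kept"], cohort2000["labels"]
        report = kfold_cv(kept, labels, OracleSpec(),
                          cohort2000["config"].channels, k=10, seed=0)
        pooled = oracle_auroc(kept, labels)
        assert abs(report.auroc_mean - pooled) < 0.02
        assert report.auroc_std >= 0

    def test_report_serializes(self):
        r = EvalReport(model="m", fold_auroc=[0.7, 0.8], fold_aupr=[0.2, 0.3],
                       seed=1)
        d = r.to_dict()
        assert d["auroc_mean"] == pytest.approx(0.75)
        assert "0.750" in r.summary()


class TestBaselineTable:
    def test_identical_groups_give_p_one(self):
        df = pd.DataFrame({"hr": [70, 80, 90, 70, 80, 90.0],
                           "vent": [0, 1, 0, 0, 1, 0]})
        out = baseline_table(df, [1, 1, 1, 0, 0, 0], binary=["vent"])
        assert (out["p_value"] == 1.0).all()

    def test_fisher_matches_hypergeometric_enumeration(self):
        from math import comb
        # 2x2 table [[1, 9], [11, 3]]
        a, b, c, d = 1, 9, 11, 3
        n, r1, c1 = a + b + c + d, a + b, a + c
        def pr(x):
            return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)
        p0 = pr(a)
        enum = sum(pr(x) for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
                   if pr(x) <= p0 + 1e-12)
        df = pd.DataFrame({"flag": [1] * a + [0] * b + [1] * c + [0] * d})
        out = baseline_table(df, [1] * (a + b) + [0] * (c + d), binary=["flag"])
        assert out["p_value"][0] == pytest.approx(enum, rel=1e-9)
        assert out["p_value"][0] == pytest.approx(0.00276, abs=5e-5)

    def test_shifted_groups_are_detected(self):
        rng = np.random.default_rng(7)
        pvals = []
        for rep in range(10):
            x = np.concatenate([rng.normal(0, 1, 200), rng.normal(2, 1, 200)])
            g = np.array([0] * 200 + [1] * 200)
            out = baseline_table(pd.DataFrame({"v": x}), g)
            pvals.append(out["p_value"][0])
        assert np.mean(np.array(pvals) < 1e-3) >= 0.95

    def test_missing_rate_column(self):
        df = pd.DataFrame({"v": [1.0, np.nan, 3.0, 4.0]})
        out = baseline_table(df, [1, 1, 0, 0])
        assert out["missing_rate"][0] == 0.25


class TestTrajectorySummary:
    def test_constant_scores_give_flat_curves(self):
        trajs = [np.full(4, 0.3), np.full(2, 0.3), np.full(3, 0.3)]
        out = trajectory_summary(trajs, [1, 0, 1], align="discharge")
        for g in out["groups"].values():
            assert np.allclose(g["mean"], 0.3)
            assert 0 in g["offsets"] and max(g["offsets"]) == 0

    def test_single_stay_band_is_degenerate(self):
        out = trajectory_summary([np.array([0.1, 0.2]), np.array([0.4])],
                                 [1, 0], align="admission")
        assert out["groups"]["success"]["degenerate"]
        assert np.allclose(out["groups"]["failure"]["mean"], [0.1, 0.2])

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            trajectory_summary([np.array([0.1])], [1], align="discharge")
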