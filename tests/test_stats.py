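"""Tests for the association statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dnabreathing import stats as S


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10, dtype=float)
        assert S.pearson_with_p(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert S.pearson_with_p(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            S.pearson_with_p(np.ones(10), np.arange(10.0))

    def test_listwise_missing_dropped(self):
        x = np.array([1.0, 2, np.nan, 4, 5, 6])
        y = np.array([1.1, 2.2, 3.0, 4.1, np.nan, 6.2])
        r, _ = S.pearson_with_p(x, y)
        r_ref, _ = S.pearson_with_p(x[[0, 1, 3, 5]], y[[0, 1, 3, 5]])
        assert r == pytest.approx(r_ref)

    def test_p_matches_permutation_oracle(self):
        """t-transform p vs exhaustive-ish permutation null at n=8."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        y = 0.8 * x + rng.normal(size=8)
        r, p = S.pearson_with_p(x, y)
        n_perm = 100_000
        perm_rs = np.empty(n_perm)
        xc = (x - x.mean()) / x.std()
        yc = (y - y.mean()) / y.std()
        for k in range(n_perm):
            perm_rs[k] = np.mean(xc * yc[rng.permutation(8)])
        p_perm = float(np.mean(np.abs(perm_rs) >= abs(r) - 1e-12))
        mc_se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        # permutation and t references coincide up to small-sample model error
        assert p == pytest.approx(p_perm, abs=max(0.015, 4 * mc_se))


class TestPerPosition:
    def test_width_one_threshold_equals_alpha(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 1))
        y = rng.normal(size=50)
        res = S.per_position_correlations(x, y)[0]
        assert res.significant_corrected == (res.p_value < 0.05)

    def test_bonferroni_arithmetic_w10(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(60, 10))
        y = rng.normal(size=60)
        for res in S.per_position_correlations(x, y):
            assert res.significant_corrected == (res.p_value < 0.05 / 10)
        # 0.004 < 0.05/10 = 0.005 is the intended boundary behaviour
        assert (0.004 < 0.05 / 10) and not (0.006 < 0.05 / 10)

    def test_planted_position_recovered(self):
        """Effect planted at one position only: that position flags, others rarely."""
        rng = np.random.default_rng(3)
        hits = 0
        false_hits = 0
        n_rep = 20
        for _ in range(n_rep):
            x = rng.normal(size=(400, 6))
            y = 0.45 * x[:, 2] + rng.normal(size=400)
            res = S.per_position_correlations(x, y)
            hits += bool(res[2].significant_corrected)
            false_hits += sum(bool(r.significant_corrected) for i, r in enumerate(res) if i != 2)
        assert hits >= 18
        assert false_hits <= 5


class TestWilcoxon:
    def test_identical_samples(self):
        a = np.arange(10, dtype=float)
        _, p = S.wilcoxon_rank_sum(a, a.copy())
        assert p > 0.9

    def test_constant_data_gives_p_one(self):
        assert S.wilcoxon_rank_sum(np.ones(5), np.ones(7))[1] == 1.0

    def test_disjoint_supports_minimal_p(self):
        a = np.arange(10, 16, dtype=float)
        b = np.arange(0, 5, dtype=float)
        _, p = S.wilcoxon_rank_sum(a, b)
        # minimal attainable two-sided exact p for 6 vs 5: 2 / C(11, 6)
        assert p == pytest.approx(2 / 462, rel=1e-9)

    def test_exact_p_matches_full_enumeration(self):
        a = np.array([1.2, 3.4, 0.5, 7.8, 2.2, 5.1])
        b = np.array([2.9, 4.4, 6.6, 0.1, 3.3])
        stat, p = S.wilcoxon_rank_sum(a, b)
        pooled = np.concatenate([a, b])
        ranks = pooled.argsort().argsort() + 1.0
        obs = ranks[: a.size].sum()
        mean_rank = a.size * (pooled.size + 1) / 2.0
        count = 0
        total = 0
        for combo in itertools.combinations(range(pooled.size), a.size):
            total += 1
            w = ranks[list(combo)].sum()
            if abs(w - mean_rank) >= abs(obs - mean_rank) - 1e-12:
                count += 1
        assert total == 462
        assert p == pytest.approx(count / total, rel=1e-9)


class TestOLS:
    @staticmethod
    def _features(n_strong, n_weak, best_score):
        return pd.DataFrame(
            {"n_strong": n_strong, "n_weak": n_weak, "best_score": best_score}
        )

    def test_exact_recovery_with_orthogonal_design(self):
        rng = np.random.default_rng(4)
        n = 200
        bubble = (np.arange(n) % 2).astype(float)
        cov = self._features(np.zeros(n), np.zeros(n) + rng.integers(0, 3, n), rng.normal(size=n))
        affinity = 0.3 + 2.0 * bubble + 1e-9 * rng.normal(size=n)
        res = S.ols_bubble_regression(affinity, bubble, cov, mode="covariate")
        assert res.effect == pytest.approx(2.0, abs=1e-6)

    def test_null_coefficient_small(self):
        rng = np.random.default_rng(5)
        tstats = []
        for _ in range(20):
            n = 150
            bubble = rng.random(n) < 0.3
            cov = self._features(np.zeros(n), np.zeros(n), rng.normal(size=n))
            affinity = 0.5 + 0.1 * rng.normal(size=n)
            res = S.ols_bubble_regression(affinity, bubble, cov, mode="covariate")
            tstats.append(res.effect / res.se)
        assert np.mean(np.abs(tstats) > 2.1) < 0.3

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        n = 12
        bubble = np.array([1, 0, 1, 0, 0, 1, 0, 1, 1, 0, 0, 1], dtype=float)
        n_strong = rng.integers(0, 3, n).astype(float)
        n_weak = rng.integers(0, 4, n).astype(float)
        score = rng.normal(size=n)
        affinity = rng.random(n)
        res = S.ols_bubble_regression(
            affinity, bubble, self._features(n_strong, n_weak, score), mode="covariate"
        )
        X = np.column_stack([np.ones(n), bubble, n_strong, n_weak, score])
        beta = np.linalg.solve(X.T @ X, X.T @ affinity)  # normal equations
        assert res.effect == pytest.approx(beta[1], rel=1e-8)
        resid = affinity - X @ beta
        sigma2 = resid @ resid / (n - X.shape[1])
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.se == pytest.approx(se, rel=1e-8)

    def test_exclude_strong_drops_rows(self):
        n = 40
        rng = np.random.default_rng(7)
        bubble = (rng.random(n) < 0.5).astype(float)
        n_strong = (np.arange(n) < 10).astype(float)
        cov = self._features(n_strong, np.zeros(n), rng.normal(size=n))
        res = S.ols_bubble_regression(rng.random(n), bubble, cov, mode="exclude_strong")
        assert res.n == 30

    def test_rank_deficiency_flagged(self):
        n = 20
        rng = np.random.default_rng(8)
        cov = self._features(np.zeros(n), np.zeros(n), rng.normal(size=n))
        res = S.ols_bubble_regression(rng.random(n), np.ones(n), cov, mode="covariate")
        assert np.isnan(res.effect) and "rank" in res.note


class TestLogistic:
    def test_two_by_two_equals_log_odds_ratio(self):
        # bubble x bound table: a=30 b=20 (bubble), c=25 d=60 (no bubble)
        bubble = np.concatenate([np.ones(50), np.zeros(85)])
        bound = np.concatenate([np.ones(30), np.zeros(20), np.ones(25), np.zeros(60)])
        res = S.logistic_bubble_regression(bound, bubble)
        expected = np.log((30 * 60) / (20 * 25))
        assert res.effect == pytest.approx(expected, rel=1e-6)

    def test_null_estimate_near_zero(self):
        rng = np.random.default_rng(9)
        effects = []
        for _ in range(10):
            n = 400
            bubble = (rng.random(n) < 0.3).astype(float)
            bound = (rng.random(n) < 0.5).astype(float)
            res = S.logistic_bubble_regression(bound, bubble)
            effects.append(res.effect)
        assert abs(np.mean(effects)) < 0.15

    def test_perfect_separation_flagged(self):
        bubble = np.array([1.0] * 10 + [0.0] * 10)
        bound = bubble.copy()
        res = S.logistic_bubble_regression(bound, bubble)
        assert np.isnan(res.p_value) and "separation" in res.note

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            S.logistic_bubble_regression(np.ones(10), np.zeros(10))


class TestChipFilter:
    @staticmethod
    def _features(n, rng):
        return pd.DataFrame(
            {
                "avg_flip_motif": rng.random(n),
                "n_strong": np.ones(n),
                "n_weak": np.zeros(n),
                "best_score": rng.normal(size=n),
            }
        )

    def test_min_peaks_boundary_inclusive_at_3000(self):
        rng = np.random.default_rng(10)
        n = 6000
        feats = self._features(n, rng)
        bound = np.zeros(n)
        bound[:2999] = 1
        assert S.chip_flip_analysis(feats, bound, tf="TF") is None  # 2999 < 3000
        bound[2999] = 1
        assert S.chip_flip_analysis(feats, bound, tf="TF") is not None  # exactly 3000

    def test_constant_label_flagged(self):
        rng = np.random.default_rng(11)
        feats = self._features(4000, rng)
        res = S.chip_flip_analysis(feats, np.ones(4000), tf="TF", config=S.StatsConfig(min_peaks=0))
        assert np.isnan(res.effect) and res.note

    def test_bonferroni_across_tfs(self):
        rng = np.random.default_rng(12)
        per_tf = {}
        for name in ("A", "B", "C"):
            feats = self._features(4000, rng)
            bound = (rng.random(4000) < 0.9).astype(float)
            per_tf[name] = (feats, bound)
        results = S.chip_flip_analyses(per_tf, config=S.StatsConfig(min_peaks=100))
        assert len(results) == 3
        for r in results:
            assert r.significant_corrected == (r.p_value < 0.05 / 3)
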