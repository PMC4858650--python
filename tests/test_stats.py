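"""Statistical battery: exact oracles and structural properties."""

import math

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, strategies as hst

from hepaspect.stats import (
    anova_nk,
    delong_compare,
    group_summary,
    pearson,
    percent_change,
    roc,
)


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=10)
        res = pearson(x, y)
        # brute-force covariance / (sigma_x sigma_y)
        r_ref = float(((x - x.mean()) * (y - y.mean())).sum()
                      / math.sqrt(((x - x.mean()) ** 2).sum()
                                  * ((y - y.mean()) ** 2).sum()))
        t = r_ref * math.sqrt((10 - 2) / (1 - r_ref**2))
        p_ref = 2 * st.t.sf(abs(t), 10 - 2)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p_two_tailed == pytest.approx(p_ref, rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson([1.0, 2.0, 3.0], [1.0, 2.0])

    @given(a=hst.floats(0.1, 10.0), b=hst.floats(-5.0, 5.0),
           sign=hst.sampled_from([-1.0, 1.0]))
    def test_affine_invariance(self, a, b, sign):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=12)
        base = pearson(x, y).r
        assert pearson(sign * a * x + b, y).r == pytest.approx(sign * base, abs=1e-9)


# ---------------------------------------------------------------------------
# ANOVA + Newman-Keuls
# ---------------------------------------------------------------------------


class TestAnovaNK:
    def test_identical_groups_null(self):
        g = [1.0, 2.0, 3.0]
        res = anova_nk([g, g])
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert not any(pp.significant for pp in res.posthoc)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(loc=0.8, size=6)
        res = anova_nk([a, b])
        t, p_t = st.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t**2, rel=1e-10)
        assert res.p == pytest.approx(p_t, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_nk([[1.0], [1.0, 2.0]])
        with pytest.raises(ValueError):
            anova_nk([[1.0, 2.0]])

    def test_posthoc_covers_all_pairs(self):
        rng = np.random.default_rng(3)
        res = anova_nk([rng.normal(size=6) for _ in range(4)])
        pairs = {(pp.group_i, pp.group_j) for pp in res.posthoc}
        assert pairs == {(i, j) for i in range(4) for j in range(i + 1, 4)}

    def test_nonrejection_blocking(self):
        """A pair nested inside a non-significant span is never declared
        significant, even if its own q exceeds the critical value."""
        rng = np.random.default_rng(4)
        q_crit_cache = {}
        for rep in range(200):
            groups = [rng.normal(size=5) for _ in range(4)]
            res = anova_nk(groups, pair_pvalues=False)
            means = [np.mean(g) for g in groups]
            order = np.argsort(means)
            rank = {int(g): r for r, g in enumerate(order)}
            sig = {}
            for pp in res.posthoc:
                lo = min(rank[pp.group_i], rank[pp.group_j])
                hi = max(rank[pp.group_i], rank[pp.group_j])
                sig[(lo, hi)] = pp.significant
            for (lo, hi), s in sig.items():
                if s:
                    enclosing = [sig[k] for k in sig
                                 if k[0] <= lo and hi <= k[1] and k != (lo, hi)]
                    assert all(enclosing)

    def test_widest_span_is_range_test(self):
        """For k groups the widest-span NK comparison is the studentized
        range test of the extreme means."""
        rng = np.random.default_rng(5)
        groups = [rng.normal(loc=m, size=6) for m in (0.0, 0.5, 2.0)]
        res = anova_nk(groups)
        widest = [pp for pp in res.posthoc if pp.span == 3][0]
        means = np.array([np.mean(g) for g in groups])
        mse = np.mean([np.var(g, ddof=1) for g in groups])
        q_ref = (means.max() - means.min()) / math.sqrt(mse / 6)
        assert widest.q == pytest.approx(q_ref, rel=1e-10)
        p_ref = st.studentized_range.sf(q_ref, 3, 15)
        assert widest.p_nk == pytest.approx(p_ref, rel=1e-9)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def auc_by_pair_counting(scores, labels):
    """Brute-force Mann-Whitney AUC: wins + half ties over all pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        r = roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == pytest.approx(1.0)

    def test_curve_endpoints_and_area(self):
        rng = np.random.default_rng(6)
        scores = rng.integers(0, 5, size=40).astype(float)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        r = roc(scores, labels)
        assert (r.one_minus_specificities[0], r.sensitivities[0]) == (0.0, 0.0)
        assert (r.one_minus_specificities[-1], r.sensitivities[-1]) == (1.0, 1.0)
        area = np.trapezoid(r.sensitivities, r.one_minus_specificities)
        assert r.auc == pytest.approx(area, abs=0)

    def test_auc_equals_pair_counting_on_random_fixtures(self):
        """Exact agreement with the pair-counting oracle, ties included."""
        rng = np.random.default_rng(7)
        for _ in range(120):
            n = int(rng.integers(6, 30))
            scores = rng.integers(0, 6, size=n).astype(float)  # many ties
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.min() == labels.max():
                continue
            r = roc(scores, labels)
            assert r.auc == pytest.approx(auc_by_pair_counting(scores, labels), abs=1e-12)

    def test_cross_check_against_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(8)
        scores = rng.normal(size=50)
        labels = (rng.uniform(size=50) < 0.4).astype(int)
        assert roc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_lower_direction_flips_auc(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([1, 1, 0, 0])
        assert roc(scores, labels, direction="lower").auc == pytest.approx(1.0)
        assert roc(scores, labels, direction="higher").auc == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1.0, 2.0], [1, 1])


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------


class TestDeLong:
    def test_identical_scores_null(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=30)
        y = (rng.uniform(size=30) < 0.5).astype(int)
        y[:2] = [0, 1]
        res = delong_compare(s, s, y)
        assert res.z == 0.0 and res.p_two_tailed == 1.0

    def test_swap_negates_z(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(size=40), rng.normal(size=40)
        y = np.array([0, 1] * 20)
        r1 = delong_compare(a, b, y)
        r2 = delong_compare(b, a, y)
        assert r1.z == pytest.approx(-r2.z, rel=1e-12)
        assert r1.p_two_tailed == pytest.approx(r2.p_two_tailed, rel=1e-12)

    def test_variance_nonnegative_random(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a, b = rng.normal(size=24), rng.normal(size=24)
            y = np.array([0, 1] * 12)
            res = delong_compare(a, b, y)
            assert res.var_diff >= 0.0
            assert 0.0 <= res.p_two_tailed <= 1.0

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([1.0, 2.0, 3.0], [1.0, 2.0], [0, 1, 1])

    def test_detects_large_auc_difference(self):
        rng = np.random.default_rng(12)
        y = np.array([0, 1] * 25)
        a = y + rng.normal(scale=0.3, size=50)   # strong marker
        b = rng.normal(size=50)                  # uninformative
        res = delong_compare(a, b, y)
        assert res.auc_a > res.auc_b
        assert res.p_two_tailed < 0.01


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def test_percent_change():
    assert percent_change(10.0, 10.0) == 0.0
    assert percent_change(10.0, 5.0) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        percent_change(0.0, 1.0)


def test_group_summary_matches_formula():
    rng = np.random.default_rng(13)
    vals = rng.normal(size=9)
    s = group_summary({"g": vals, "single": [3.0], "const": [2.0, 2.0]})
    assert s["g"].mean == pytest.approx(vals.mean())
    assert s["g"].sem == pytest.approx(vals.std(ddof=1) / 3.0)
    assert s["single"].sem == 0.0 and not s["single"].sem_defined
    assert s["const"].sem == 0.0 and s["const"].sem_defined
    with pytest.raises(ValueError):
        group_summary({"empty": []})
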