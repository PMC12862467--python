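import numpy as np
import pytest

from omrad.errors import InputError
from omrad.evaluation import (
    ContingencyResult,
    association_table,
    auc_mann_whitney,
    format_p,
    km_logrank,
    roc_auc_ci,
    youden_cutoff,
)


# ---------------------------------------------------------------------------
# AUC


def oracle_auc(scores, labels):
    """All-pairs concordance with ties counted 1/2."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_ranking(self):
        auc, (lo, hi) = roc_auc_ci([1, 2, 3, 4], [0, 0, 1, 1])
        assert auc == 1.0
        assert lo <= auc <= hi <= 1.0

    def test_three_of_four_concordant(self):
        auc, _ = roc_auc_ci([1, 3, 2, 4], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        a1, _ = roc_auc_ci(s, y)
        a2, _ = roc_auc_ci(np.exp(3 * s), y)
        assert a1 == pytest.approx(a2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_brute_force(self, seed):
        rng = np.random.default_rng(300 + seed)
        s = rng.choice(np.linspace(0, 1, 12), size=30)  # ties included
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        auc, _ = roc_auc_ci(s, y)
        assert auc == pytest.approx(oracle_auc(s, y), abs=1e-12)
        assert auc_mann_whitney(s, y) == pytest.approx(oracle_auc(s, y), abs=1e-12)

    def test_delong_ci_covers_and_shrinks(self):
        rng = np.random.default_rng(8)
        n = 500
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        s = y + rng.normal(scale=1.0, size=n)
        _, (lo_small, hi_small) = roc_auc_ci(s[:50], y[:50])
        _, (lo_big, hi_big) = roc_auc_ci(s, y)
        assert (hi_big - lo_big) < (hi_small - lo_small)

    def test_single_class_raises(self):
        with pytest.raises(InputError):
            roc_auc_ci([1, 2, 3], [1, 1, 1])


class TestYouden:
    def test_perfect_separation(self):
        cut, j = youden_cutoff([0.0, 1.0, 10.0, 11.0], [0, 0, 1, 1])
        assert j == pytest.approx(1.0)
        assert cut == pytest.approx(5.5)

    def test_identical_scores_give_zero_j(self):
        cut, j = youden_cutoff([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])
        assert j == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_brute_force(self, seed):
        rng = np.random.default_rng(400 + seed)
        s = rng.choice(np.linspace(-2, 2, 15), size=40)
        y = rng.integers(0, 2, size=40)
        y[0], y[1] = 0, 1
        cut, j = youden_cutoff(s, y)
        # brute force over a fine threshold sweep
        best = -1.0
        for c in np.unique(s):
            for cc in (c - 1e-9, c + 1e-9):
                pred = s >= cc
                sens = (pred & (y == 1)).sum() / (y == 1).sum()
                spec = (~pred & (y == 0)).sum() / (y == 0).sum()
                best = max(best, sens + spec - 1)
        assert j == pytest.approx(max(best, 0.0), abs=1e-12)


# ---------------------------------------------------------------------------
# survival


class TestKMLogrank:
    def test_identical_groups_statistic_zero(self):
        times = np.array([3.0, 5.0, 7.0, 9.0] * 2)
        events = np.array([1, 1, 0, 1] * 2)
        groups = np.array(["high"] * 4 + ["low"] * 4)
        out = km_logrank(groups, times, events)
        assert out["logrank_statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["logrank_p"] == pytest.approx(1.0)

    def test_km_median_equals_empirical_median_without_censoring(self, rng):
        t_high = rng.exponential(10, size=51)
        t_low = rng.exponential(30, size=51)
        groups = np.array(["high"] * 51 + ["low"] * 51)
        times = np.concatenate([t_high, t_low])
        out = km_logrank(groups, times, np.ones(102, dtype=int))
        assert out["groups"]["high"]["median"] == pytest.approx(np.median(t_high), rel=1e-9)
        assert out["groups"]["low"]["median"] == pytest.approx(np.median(t_low), rel=1e-9)
        # KM without censoring reduces to the empirical survivor function
        curve = dict(out["groups"]["high"]["curve"])
        for t, s in list(curve.items())[1:]:
            assert s == pytest.approx((t_high > t).mean(), abs=1e-12)

    def test_toy_logrank_matches_hand_computation(self):
        # group A times {1,2,3}, group B {4,5,6}, all events.
        # Risk sets: t=1: 6 at risk (3A), O_A=1 E_A=.5 V=.25
        #            t=2: 5 (2A), O_A=1 E_A=.4 V=.24
        #            t=3: 4 (1A), O_A=1 E_A=.25 V=.1875
        #            t=4,5,6: no A at risk after t=3 -> E_A=0,V=0
        # (O-E)=3-1.15=1.85; V=.6775; chi2 = 1.85^2/.6775 = 5.0517...
        groups = np.array(["high"] * 3 + ["low"] * 3)
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.ones(6, dtype=int)
        out = km_logrank(groups, times, events)
        assert out["logrank_statistic"] == pytest.approx(1.85**2 / 0.6775, rel=1e-6)

    def test_reverse_km_median_followup_without_events(self, rng):
        from omrad.evaluation import median_followup_reverse_km

        # all censored: reverse KM is the plain KM of the follow-up times
        times = rng.uniform(10, 90, size=101)
        med = median_followup_reverse_km(times, np.zeros(101, dtype=int))
        assert med == pytest.approx(np.median(times), rel=1e-9)

    def test_empty_group_raises(self):
        with pytest.raises(InputError):
            km_logrank(np.array(["high", "high"]), np.array([1.0, 2.0]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# contingency tests


class TestAssociation:
    @pytest.mark.parametrize(
        "table,expected_p,test_name",
        [
            ([[188, 79], [50, 45]], ".003", "chi-square-yates"),
            ([[136, 50], [59, 53], [42, 21]], ".002", "chi-square"),
            ([[93, 61], [86, 38], [58, 25]], ".192", "chi-square"),
            ([[208, 107], [30, 17]], ".895", "chi-square-yates"),
            ([[175, 98], [63, 26]], ".305", "chi-square-yates"),
            ([[28, 14], [210, 110]], ">.999", "chi-square-yates"),
        ],
    )
    def test_printed_association_pvalues(self, table, expected_p, test_name):
        res = association_table(np.array(table))
        assert res.test == test_name
        assert res.p_formatted == expected_p

    def test_uniform_table_no_association(self):
        res = association_table(np.array([[10, 10], [10, 10]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_formatted == ">.999"

    def test_low_expected_counts_use_fisher(self):
        res = association_table(np.array([[2, 8], [7, 1]]))
        assert res.test == "fisher"
        from scipy.stats import fisher_exact

        assert res.p == pytest.approx(fisher_exact([[2, 8], [7, 1]]).pvalue)

    def test_rxc_fisher_matches_r_reference(self):
        # 3x2 with small counts; reference value from the standard
        # conditional exact test (fisher.test in R: 0.02510701)
        table = np.array([[1, 8], [5, 4], [7, 2]])
        res = association_table(table)
        assert res.test == "fisher"
        assert res.p == pytest.approx(0.02510701, abs=1e-6)

    def test_per_patient_arrays_accepted(self):
        group = ["high"] * 5 + ["low"] * 5
        var = ["yes", "yes", "no", "no", "no", "yes", "no", "no", "no", "no"]
        res = association_table(group, var)
        assert isinstance(res, ContingencyResult)
        assert res.observed.sum() == 10

    def test_empty_margin_raises(self):
        with pytest.raises(InputError):
            association_table(np.array([[0, 0], [3, 4]]))


def test_format_p_rules():
    assert format_p(0.0031) == ".003"
    assert format_p(0.9994) == ".999"
    assert format_p(0.99951) == ">.999"
    assert format_p(0.0004) == "<.001"
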