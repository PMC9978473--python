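import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import levelpost as lp
from levelpost.stats import PairedSample


def signed_rank_p_bruteforce(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(ranks)
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ])
    eps = 1e-9
    p_low = (ws <= w_obs + eps).mean()
    p_high = (ws >= w_obs - eps).mean()
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxonSignedRank:
    def test_all_positive_n6_exact_p(self):
        res = lp.wilcoxon_signed_rank(PairedSample.from_arrays([0] * 6, [1, 2, 3, 4, 5, 6]))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 64)
        assert res.statistic == 21.0

    def test_identical_conditions_degenerate(self):
        res = lp.wilcoxon_signed_rank(PairedSample.from_arrays([1, 2, 3], [1, 2, 3]))
        assert res.degenerate and res.p_value == 1.0

    def test_swapping_conditions_negates_statistic(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=12)
        a = lp.wilcoxon_signed_rank(PairedSample.from_arrays(x, y))
        b = lp.wilcoxon_signed_rank(PairedSample.from_arrays(y, x))
        assert a.statistic == -b.statistic
        assert a.p_value == pytest.approx(b.p_value)

    @pytest.mark.parametrize("n", range(4, 13))
    def test_exact_p_matches_full_sign_enumeration(self, n):
        rng = np.random.default_rng(n)
        for trial in range(3):
            x = rng.normal(size=n)
            y = x + rng.normal(0.5, 1.0, size=n)
            if trial == 2:  # force tied absolute differences
                y = x + np.round((y - x) * 2) / 2
            d = y - x
            if np.all(d == 0):
                continue
            res = lp.wilcoxon_signed_rank(PairedSample.from_arrays(x, y))
            assert res.p_value == pytest.approx(signed_rank_p_bruteforce(d), abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.integers(-5, 5), min_size=2, max_size=10))
    def test_enumeration_agreement_on_integer_differences(self, diffs):
        # integer differences stress ties and zero handling simultaneously
        x = np.zeros(len(diffs))
        y = np.asarray(diffs, dtype=float)
        res = lp.wilcoxon_signed_rank(PairedSample.from_arrays(x, y))
        assert res.p_value == pytest.approx(signed_rank_p_bruteforce(y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_exact_on_tie_free_samples(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = x + rng.normal(0.3, 1.0, size=15)
        res = lp.wilcoxon_signed_rank(PairedSample.from_arrays(x, y))
        ref = sps.wilcoxon(y, x, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = x + rng.normal(0.5, 1.0, size=40)
        res = lp.wilcoxon_signed_rank(PairedSample.from_arrays(x, y))
        assert res.method == "normal"
        ref = sps.wilcoxon(y, x, method="approx", correction=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_sample_validation(self):
        with pytest.raises(lp.ValidationError):
            PairedSample(ids=(1, 1), x=np.array([1.0, 2.0]), y=np.array([1.0, 2.0]))
        with pytest.raises(lp.ValidationError):
            PairedSample.from_arrays([1.0], [2.0])


class TestWilcoxonRankSum:
    def test_minimum_rank_sum_example(self):
        res = lp.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.statistic == 6.0  # minimum possible rank sum for 3 of 6
        # enumeration over C(6,3) = 20 assignments: only one is as extreme
        assert res.p_value == pytest.approx(2 * 1 / 20)

    def test_identical_groups_p_one(self):
        res = lp.wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value == pytest.approx(1.0)

    def test_group_swap_leaves_p_unchanged(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(1, 1, size=9)
        a = lp.wilcoxon_rank_sum(x, y)
        b = lp.wilcoxon_rank_sum(y, x)
        assert a.p_value == pytest.approx(b.p_value)

    def test_empty_group_rejected(self):
        with pytest.raises(lp.ValidationError):
            lp.wilcoxon_rank_sum([], [1.0])


class TestPairedDispersionTest:
    def test_pure_location_shift_is_degenerate(self):
        # integer-valued data so the shifted deviations are bitwise equal
        rng = np.random.default_rng(4)
        x = rng.integers(0, 100, size=11).astype(float)
        res = lp.paired_dispersion_test(PairedSample.from_arrays(x, x + 3.0))
        assert res.degenerate and res.p_value == 1.0

    def test_tripled_dispersion_detected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = 3 * (x - np.median(x)) + np.median(x)
        res = lp.paired_dispersion_test(PairedSample.from_arrays(x, y))
        assert res.statistic > 0
        assert res.p_value < 0.01

    def test_swapping_conditions_negates_statistic(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=15)
        y = 2 * x + rng.normal(0, 0.1, size=15)
        a = lp.paired_dispersion_test(PairedSample.from_arrays(x, y))
        b = lp.paired_dispersion_test(PairedSample.from_arrays(y, x))
        assert a.statistic == pytest.approx(-b.statistic)


class TestBlindedManifest:
    def test_headline_slot_count(self):
        m = lp.generate_blinded_manifest(
            [f"case{i}" for i in range(20)],
            ["expert", "dl_adjusted", "dl_raw"],
            n_raters=3,
            levels=[f"L{i}" for i in range(20)],
            seed=0,
        )
        assert m.n_slots == 3600  # 3 raters x 20 cases x 20 levels x 3 sets

    def test_seeded_determinism_and_seed_sensitivity(self):
        args = (["a", "b", "c"], ["s1", "s2"], 2, ["x", "y"])
        base = lp.generate_blinded_manifest(*args, seed=7)
        again = lp.generate_blinded_manifest(*args, seed=7)
        assert base.table.equals(again.table) and base.alias_map == again.alias_map
        orders = set()
        for seed in range(100):
            m = lp.generate_blinded_manifest(*args, seed=seed)
            orders.add(tuple(map(tuple, m.table[["rater", "case", "contour_set_alias"]].values)))
        assert len(orders) > 90  # different seeds give different permutations

    def test_each_presentation_once_per_rater_and_bijection(self):
        m = lp.generate_blinded_manifest(["a", "b", "c"], ["s1", "s2"], 3, ["x", "y", "z"], seed=1)
        t = m.table
        # bijection between rows and (rater, case, set, level) tuples
        assert not t.duplicated(["rater", "case", "contour_set_alias", "level"]).any()
        per_rater = t.groupby(["rater", "case", "contour_set_alias"])["presentation_index"].nunique()
        assert (per_rater == 1).all()
        # aliases hide the true set names
        assert set(t["contour_set_alias"]) == {"set_1", "set_2"}

    def test_duplicate_ids_rejected(self):
        with pytest.raises(lp.ValidationError):
            lp.generate_blinded_manifest(["a", "a"], ["s1"], 1, ["x"], seed=0)


class TestSummarizeRatings:
    @staticmethod
    def _table(values_by_set, cases=4, raters=2, levels=("x", "y")):
        rows = []
        for cset, offset in values_by_set.items():
            for c in range(cases):
                for r in range(1, raters + 1):
                    for lv in levels:
                        rows.append(
                            {"rater": r, "case": f"c{c}", "contour_set_alias": cset,
                             "level": lv, "rating": offset(c)}
                        )
        import pandas as pd

        return pd.DataFrame(rows)

    def test_constant_ratings(self):
        table = self._table({"A": lambda c: 80.0})
        s = lp.summarize_ratings(table)
        row = s.per_set.loc["A"]
        assert row["mean"] == row["median"] == 80.0
        assert row["iqr_high"] - row["iqr_low"] == 0.0

    def test_uniform_shift_flagged_by_paired_test(self):
        table = self._table({"A": lambda c: 70.0 + c, "B": lambda c: 75.0 + c})
        s = lp.summarize_ratings(table)
        res = s.comparisons[("A", "B")]
        assert res.statistic > 0  # every case difference favours B
        assert res.p_value < 0.2  # n = 4, smallest attainable two-sided p is 1/8

    def test_three_value_summary(self):
        table = self._table({"A": lambda c: [70.0, 80.0, 90.0][c]}, cases=3)
        row = lp.summarize_ratings(table).per_set.loc["A"]
        assert row["mean"] == 80.0 and row["median"] == 80.0

    def test_out_of_range_ratings_rejected(self):
        table = self._table({"A": lambda c: 101.0})
        with pytest.raises(lp.ValidationError):
            lp.summarize_ratings(table)
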