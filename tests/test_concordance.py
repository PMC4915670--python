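"""Distance matrices, Mantel tests, pair enumeration and level comparisons."""
import itertools
import math

import hypothesis as hyp
import hypothesis.strategies as st
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from morphocompare import (compact_letter_display, enumerate_pairs,
                           euclidean_distance_matrix, group_and_compare,
                           mantel_test)
from morphocompare.concordance import (IncompleteDesignError, SpecimenMatrix,
                                       ZeroVarianceError,
                                       expected_pair_count)


def _dm(rng, n, p=4):
    return euclidean_distance_matrix(rng.standard_normal((n, p)))


class TestEuclideanDistanceMatrix:
    def test_three_four_five(self):
        d = euclidean_distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0],
                                                [0.0, 8.0]]))
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == 0.0
        np.testing.assert_allclose(d, d.T)

    def test_identical_rows_distance_zero(self):
        x = np.ones((3, 4))
        x[2] = 2.0
        assert euclidean_distance_matrix(x)[0, 1] == 0.0

    def test_matches_naive_double_loop(self, rng):
        x = rng.standard_normal((6, 4))
        d = euclidean_distance_matrix(x)
        naive = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                naive[i, j] = math.sqrt(((x[i] - x[j]) ** 2).sum())
        np.testing.assert_allclose(d, naive, atol=1e-12)

    def test_missing_values_name_individuals(self, rng):
        vals = rng.standard_normal((4, 3))
        vals[1, 0] = np.nan
        m = SpecimenMatrix("sp1", "site1", "M1", 1,
                           [f"i{j}" for j in range(4)], vals)
        with pytest.raises(ValueError, match="i1"):
            euclidean_distance_matrix(m)


class TestMantel:
    def test_self_comparison_r_one(self, rng):
        a = _dm(rng, 10)
        res = mantel_test(a, a, n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_symmetry_exact(self, rng):
        a, b = _dm(rng, 12), _dm(rng, 12)
        assert mantel_test(a, b, n_perm=9, seed=0).R == \
            mantel_test(b, a, n_perm=9, seed=0).R

    def test_exact_mode_matches_exhaustive_enumeration(self, rng):
        """At n = 5 the exact permutation p equals a brute-force enumeration
        of all 120 row permutations computed with scipy's pearsonr."""
        a, b = _dm(rng, 5), _dm(rng, 5)
        res = mantel_test(a, b, method="exact")
        iu = np.triu_indices(5, 1)
        av = a[iu]
        r_obs = stats.pearsonr(av, b[iu]).statistic
        count = 0
        total = 0
        for perm in itertools.permutations(range(5)):
            bp = b[np.ix_(perm, perm)][iu]
            r = stats.pearsonr(av, bp).statistic
            count += r >= r_obs - 1e-12
            total += 1
        assert res.n_perm == total == 120
        assert res.p == pytest.approx(count / total)
        assert res.R == pytest.approx(r_obs)

    def test_agrees_with_skbio(self, rng):
        """R matches scikit-bio's Mantel exactly; one-sided p agrees within
        Monte-Carlo error at 999 permutations."""
        a, b0 = _dm(rng, 12), _dm(rng, 12)
        b = 0.7 * a + 0.3 * b0  # correlated pair, non-trivial p
        res = mantel_test(a, b, n_perm=999, seed=1, method="random")
        r_sk, p_sk, _ = skbio_mantel(DistanceMatrix(a), DistanceMatrix(b),
                                     method="pearson", permutations=999,
                                     alternative="greater")
        assert res.R == pytest.approx(float(r_sk), abs=1e-10)
        assert res.p == pytest.approx(float(p_sk), abs=0.05)

    def test_increasing_noise_decreases_r(self, rng):
        base = rng.standard_normal((12, 4))
        means = []
        for sigma in (0.1, 1.0, 4.0):
            rs = []
            for seed in range(20):
                r2 = np.random.default_rng(seed)
                noisy = base + sigma * r2.standard_normal(base.shape)
                rs.append(mantel_test(euclidean_distance_matrix(base),
                                      euclidean_distance_matrix(noisy),
                                      n_perm=0, method="random").R)
            means.append(np.mean(rs))
        assert means[0] > means[1] > means[2]

    def test_seeded_determinism(self, rng):
        a, b = _dm(rng, 15), _dm(rng, 15)
        p1 = mantel_test(a, b, n_perm=199, seed=5).p
        p2 = mantel_test(a, b, n_perm=199, seed=5).p
        assert p1 == p2

    def test_zero_variance_rejected(self):
        a = np.zeros((5, 5))
        with pytest.raises(ZeroVarianceError):
            mantel_test(a, a)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="square"):
            mantel_test(_dm(rng, 5), _dm(rng, 6))


class TestEnumeratePairs:
    @staticmethod
    def _keys(n_sp=3, n_site=3, n_meas=3, n_rep=3):
        return [(f"sp{s}", f"site{t}", f"M{m}", r)
                for s in range(n_sp) for t in range(n_site)
                for m in range(n_meas) for r in range(1, n_rep + 1)]

    def test_repeatability_counts(self):
        pairs = enumerate_pairs(self._keys(), "repeatability")
        assert len(pairs) == 81 == expected_pair_count(3, 3, 3, 3,
                                                       "repeatability")
        # per-measurer-per-species boxes of 9
        per_box = {}
        for ka, _ in pairs:
            per_box[(ka[0], ka[2])] = per_box.get((ka[0], ka[2]), 0) + 1
        assert set(per_box.values()) == {9}
        # within-measurer, ordered repeats
        assert all(ka[2] == kb[2] and ka[3] < kb[3] for ka, kb in pairs)

    def test_reproducibility_counts(self):
        pairs = enumerate_pairs(self._keys(), "reproducibility")
        assert len(pairs) == 243 == expected_pair_count(3, 3, 3, 3,
                                                        "reproducibility")
        per_species = {}
        for ka, _ in pairs:
            per_species[ka[0]] = per_species.get(ka[0], 0) + 1
        assert set(per_species.values()) == {81}
        assert all(ka[2] < kb[2] for ka, kb in pairs)

    def test_single_measurer_reproducibility_empty(self):
        pairs = enumerate_pairs(self._keys(n_meas=1), "reproducibility")
        assert pairs == []

    def test_incomplete_design_lists_missing(self):
        keys = self._keys()[:-2]
        with pytest.raises(IncompleteDesignError, match="missing"):
            enumerate_pairs(keys, "repeatability")


class TestGroupAndCompare:
    @staticmethod
    def _table(groups: dict, group_col="method"):
        rows = []
        for g, vals in groups.items():
            for v in vals:
                rows.append({group_col: g, "R": v})
        return pd.DataFrame(rows)

    def test_kruskal_wallis_closed_form(self):
        """Groups {1,2,3},{4,5,6},{7,8,9}: H = 7.2 by the rank formula."""
        table = self._table({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        res = group_and_compare(table, "method")
        assert res["omnibus"]["H"].iloc[0] == pytest.approx(7.2)

    def test_identical_groups_share_one_letter(self):
        table = self._table({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        res = group_and_compare(table, "method")
        assert res["omnibus"]["H"].iloc[0] == pytest.approx(0.0)
        assert set(res["summaries"]["letter"]) == {"a"}

    def test_separated_groups_get_distinct_letters(self):
        table = self._table({
            "hi": list(np.linspace(0.9, 0.99, 10)),
            "mid": list(np.linspace(0.5, 0.59, 10)),
            "lo": list(np.linspace(0.1, 0.19, 10))})
        res = group_and_compare(table, "method")
        letters = dict(zip(res["summaries"]["group"],
                           res["summaries"]["letter"]))
        assert len({letters["hi"], letters["mid"], letters["lo"]}) == 3
        summary = res["summaries"].set_index("group")
        assert summary.loc["hi", "mean"] == pytest.approx(np.mean(
            np.linspace(0.9, 0.99, 10)))
        assert summary.loc["hi", "n"] == 10

    def test_letter_display_chain_structure(self):
        """a ~ b and b ~ c but a != c: b shares a letter with both."""
        letters = compact_letter_display(["a", "b", "c"],
                                         {frozenset(("a", "c"))})
        assert set(letters["b"]) & set(letters["a"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])


@hyp.given(st.data())
@hyp.settings(max_examples=50, derandomize=True, deadline=None)
def test_letter_display_is_consistent_with_significance_graph(data):
    """For any significance graph: every group gets a letter, significantly
    different groups never share one, and non-different groups always do."""
    n = data.draw(st.integers(2, 6))
    groups = [f"g{i}" for i in range(n)]
    all_pairs = list(itertools.combinations(groups, 2))
    sig = {frozenset(p) for p in all_pairs
           if data.draw(st.booleans(), label=str(p))}
    letters = compact_letter_display(groups, sig)
    assert all(letters[g] for g in groups)
    for a, b in all_pairs:
        shared = set(letters[a]) & set(letters[b])
        if frozenset((a, b)) in sig:
            assert not shared, (a, b, letters)
        else:
            assert shared, (a, b, letters)


def test_null_kruskal_rejection_rate_near_alpha():
    """Omnibus Kruskal-Wallis on same-distribution groups rejects at ~alpha."""
    rej = 0
    n_rep = 1000
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        groups = {g: rng.standard_normal(9) for g in "abc"}
        H, p = stats.kruskal(*groups.values())
        rej += p < 0.05
    assert 0.035 <= rej / n_rep <= 0.065
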