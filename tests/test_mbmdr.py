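"""Unit and property tests for the MB-MDR pair statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

import gammamaxt as gm
from gammamaxt.dataset import MISSING, Dataset
from gammamaxt.kernels import (
    FixedPairKernel,
    all_pair_statistics,
    eval_pairs,
    ids_to_pairs,
    pair_count,
    pairs_to_ids,
)
from gammamaxt.mbmdr import (
    HLOTable,
    PairCrossTab,
    categorize_cells,
    correct_main_effects,
    crosstab_pair,
    mbmdr_statistic,
    pair_statistic,
    scan_all_pairs,
)


def _dataset(genos, trait, trait_type="binary"):
    return Dataset(genotypes=np.array(genos), trait=np.array(trait, float),
                   trait_type=trait_type)


class TestPairEnumeration:
    def test_roundtrip(self):
        s = 17
        ids = np.arange(pair_count(s))
        a, b = ids_to_pairs(ids, s)
        assert (a < b).all()
        assert np.array_equal(pairs_to_ids(a, b, s), ids)

    def test_lexicographic_order(self):
        a, b = ids_to_pairs(np.arange(6), 4)
        assert list(zip(a, b)) == [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


class TestCrosstab:
    def test_counts_and_missing_exclusion(self):
        ds = _dataset(
            [[0, 0], [0, 0], [1, 2], [MISSING, 0]], [1, 0, 1, 0], "binary"
        )
        ct = crosstab_pair(ds, (0, 1))
        assert ct.counts[0, 0] == 2 and ct.cases[0, 0] == 1
        assert ct.counts[1, 2] == 1 and ct.cases[1, 2] == 1
        assert ct.counts.sum() == 3  # the individual missing at SNP1 is dropped

    def test_all_missing_gives_empty_cells(self):
        ds = _dataset([[MISSING, 0], [MISSING, 1]], [1, 0], "binary")
        ct = crosstab_pair(ds, (0, 1))
        assert ct.counts.sum() == 0

    def test_self_pair_rejected(self, make_null):
        with pytest.raises(ValueError, match="self-pair"):
            crosstab_pair(make_null(), (3, 3))

    def test_totals_match_independent_recount(self, make_null):
        ds = make_null(n_snps=6, n_ind=300, missing_rate=0.1, seed=5)
        ct = crosstab_pair(ds, (1, 4))
        ok = sum(
            1
            for i in range(ds.n_individuals)
            if ds.genotypes[i, 1] >= 0 and ds.genotypes[i, 4] >= 0
        )
        assert ct.counts.sum() == ok


class TestCategorize:
    def test_empty_cell_is_O(self):
        counts = np.zeros((3, 3), int)
        cases = np.zeros((3, 3), int)
        counts[1, 1], cases[1, 1] = 200, 100
        ct = PairCrossTab(counts=counts, trait_type="binary", cases=cases)
        hlo = categorize_cells(ct, "binary")
        assert hlo.labels[0, 0] == "O"  # empty
        assert hlo.labels[1, 1] == "O"  # cell == everyone: margin zero

    def test_binary_hand_chisquared(self):
        # one cell of 10 cases/0 controls vs rest 90 cases/100 controls:
        # chi2 = 200*(10*100)^2 / (10*190*100*100) ~= 10.53 > 2.706 -> H
        counts = np.zeros((3, 3), int)
        cases = np.zeros((3, 3), int)
        counts[0, 0], cases[0, 0] = 10, 10
        counts[2, 2], cases[2, 2] = 190, 90
        ct = PairCrossTab(counts=counts, trait_type="binary", cases=cases)
        hlo = categorize_cells(ct, "binary", alpha_cell=0.1)
        assert hlo.labels[0, 0] == "H"
        assert hlo.labels[2, 2] == "L"

    def test_zero_variance_contrast_is_O(self):
        # continuous: every cell has the same constant trait value
        counts = np.array([[3, 3, 0], [3, 3, 0], [0, 0, 0]])
        s = counts * 2.0
        q = counts * 4.0
        ct = PairCrossTab(
            counts=counts, trait_type="continuous", trait_sum=s, trait_sumsq=q
        )
        hlo = categorize_cells(ct, "continuous")
        assert (hlo.labels == "O").all()

    def test_alpha_cell_domain(self):
        ct = PairCrossTab(counts=np.zeros((3, 3), int), trait_type="binary",
                          cases=np.zeros((3, 3), int))
        with pytest.raises(ValueError):
            categorize_cells(ct, "binary", alpha_cell=1.5)


class TestStatistic:
    def test_all_O_gives_exact_zero(self):
        # constant genotypes: the single occupied cell is everyone -> O -> 0.0
        ds = _dataset(np.zeros((40, 2), int), [0, 1] * 20, "binary")
        assert pair_statistic(ds, (0, 1)) == 0.0

    def test_single_H_cell_matches_2x2_chisquared(self):
        counts = np.zeros((3, 3), int)
        cases = np.zeros((3, 3), int)
        counts[0, 0], cases[0, 0] = 20, 20
        counts[1, 1], cases[1, 1] = 180, 80
        ct = PairCrossTab(counts=counts, trait_type="binary", cases=cases)
        hlo = categorize_cells(ct, "binary")
        assert hlo.labels[0, 0] == "H"
        t = mbmdr_statistic(hlo, ct, "binary")
        table = np.array([[20, 0], [80, 100]])
        expected = chi2_contingency(table, correction=False)[0]
        assert t == pytest.approx(expected, abs=1e-9)

    def test_max_of_H_and_L_branches(self, make_null):
        ds = make_null(n_snps=4, n_ind=400, seed=9)
        ct = crosstab_pair(ds, (0, 1))
        hlo = categorize_cells(ct, ds.trait_type, alpha_cell=0.6)
        h_only = HLOTable(labels=np.where(hlo.labels == "H", "H", "O"))
        l_only = HLOTable(labels=np.where(hlo.labels == "L", "L", "O"))
        t = mbmdr_statistic(hlo, ct, ds.trait_type)
        th = mbmdr_statistic(h_only, ct, ds.trait_type)
        tl = mbmdr_statistic(l_only, ct, ds.trait_type)
        assert t == max(th, tl)

    def test_symmetry_in_pair_order(self, make_null):
        for tt in ("binary", "continuous"):
            ds = make_null(trait_type=tt, n_snps=5, n_ind=150, missing_rate=0.05,
                           seed=3)
            for pair in [(0, 1), (2, 4)]:
                assert pair_statistic(ds, pair) == pytest.approx(
                    pair_statistic(ds, pair[::-1]), rel=1e-12
                )


@pytest.mark.parametrize("trait_type", ["binary", "continuous"])
@pytest.mark.parametrize("missing_rate", [0.0, 0.08])
def test_vectorized_kernels_match_scalar(make_null, trait_type, missing_rate):
    """The three vectorized execution paths agree with the per-pair reference."""
    ds = make_null(trait_type=trait_type, n_snps=10, n_ind=120,
                   missing_rate=missing_rate, seed=11)
    ids = np.arange(ds.n_pairs)
    a, b = ids_to_pairs(ids, ds.n_snps)
    scalar = np.array([pair_statistic(ds, (i, j)) for i, j in zip(a, b)])
    assert np.allclose(all_pair_statistics(ds), scalar, rtol=1e-10, atol=1e-10)
    assert np.allclose(eval_pairs(ds, a, b), scalar, rtol=1e-10, atol=1e-10)
    kern = FixedPairKernel(ds, np.column_stack([a, b]))
    assert np.allclose(kern.stats(ds.trait), scalar, rtol=1e-10, atol=1e-10)


class TestScan:
    @pytest.mark.parametrize("trait_type", ["binary", "continuous"])
    def test_top_n_matches_bruteforce_sort(self, make_null, trait_type):
        ds = make_null(trait_type=trait_type, n_snps=20, n_ind=100,
                       missing_rate=0.05, seed=21)
        top = scan_all_pairs(ds, n=15)
        ids = np.arange(ds.n_pairs)
        a, b = ids_to_pairs(ids, ds.n_snps)
        stats = np.array([pair_statistic(ds, (i, j)) for i, j in zip(a, b)])
        order = np.lexsort((ids, -stats))[:15]
        assert np.allclose(top.stats, stats[order])
        assert np.array_equal(
            pairs_to_ids(top.pairs[:, 0], top.pairs[:, 1], ds.n_snps), ids[order]
        )

    def test_three_snps_three_pairs(self, make_null):
        ds = make_null(n_snps=3, n_ind=60)
        with pytest.warns(UserWarning):
            top = scan_all_pairs(ds, n=10)  # n > m triggers the warning path
        assert len(top) == 3

    def test_n_exceeding_pairs_warns(self, make_null):
        ds = make_null(n_snps=4, n_ind=60)
        with pytest.warns(UserWarning, match="exceeds"):
            scan_all_pairs(ds, n=100)

    def test_tie_break_is_lowest_pair_id(self, make_null):
        ds = make_null(n_snps=6, n_ind=100, seed=2)
        # duplicating a SNP column creates exactly tied statistics
        g = np.column_stack([ds.genotypes, ds.genotypes[:, 0]])
        dup = Dataset(genotypes=g, trait=ds.trait, trait_type=ds.trait_type)
        top = scan_all_pairs(dup, n=dup.n_pairs)
        ids = pairs_to_ids(top.pairs[:, 0], top.pairs[:, 1], dup.n_snps)
        # ties must be ordered by increasing pair id within equal statistics
        for k in range(len(top) - 1):
            if top.stats[k] == top.stats[k + 1]:
                assert ids[k] < ids[k + 1]


class TestMainEffectCorrection:
    def test_residuals_orthogonal_to_dummies(self, make_null):
        ds = make_null(trait_type="continuous", n_snps=8, n_ind=200, seed=4)
        adj = correct_main_effects(ds)
        assert adj.trait_type == "continuous"
        for j in range(ds.n_snps):
            for code in (1, 2):
                d = (ds.genotypes[:, j] == code).astype(float)
                if d.std() == 0:
                    continue
                r = np.corrcoef(adj.trait, d)[0, 1]
                assert abs(r) < 1e-8

    def test_trait_linear_in_dummies_residuals_vanish(self, make_null):
        ds = make_null(trait_type="continuous", n_snps=5, n_ind=150, seed=6)
        g = ds.genotypes[:, 2]
        trait = 1.5 + 2.0 * (g == 1) - 0.7 * (g == 2)
        adj = correct_main_effects(ds.with_trait(trait))
        assert np.abs(adj.trait).max() < 1e-8

    def test_constant_trait_rejected(self, make_null):
        ds = make_null(trait_type="continuous", n_snps=4, n_ind=50)
        with pytest.raises(ValueError, match="degenerate trait"):
            correct_main_effects(ds.with_trait(np.ones(50)))

    def test_pair_local_adjustment_kills_pure_main_effect(self, make_null):
        # a trait exactly linear in one SNP's dummies leaves zero residual
        # signal for any pair containing that SNP under local correction
        ds = make_null(trait_type="continuous", n_snps=6, n_ind=200, seed=7)
        g = ds.genotypes[:, 1]
        trait = 0.8 * (g == 1) + 2.1 * (g == 2)
        raw = ds.with_trait(trait + 0.01 * np.random.default_rng(0).standard_normal(200))
        top = scan_all_pairs(raw, n=raw.n_pairs, adjust_main=True)
        with_snp1 = np.array([1 in p for p in top.pairs])
        # adjusted statistics for SNP-1 pairs collapse toward the null range
        assert top.stats[with_snp1].max() <= np.median(top.stats) + 12.0

    def test_main_effect_snp_demoted_after_adjustment(self, make_null):
        ds = make_null(trait_type="continuous", n_snps=15, n_ind=400, seed=8)
        g = ds.genotypes[:, 0].astype(float)
        trait = 2.0 * g + np.random.default_rng(1).standard_normal(400)
        raw = ds.with_trait(trait)
        top_raw = scan_all_pairs(raw, n=1)
        assert 0 in top_raw.pairs[0]
        adj = correct_main_effects(raw)
        top_adj = scan_all_pairs(adj, n=1)
        assert 0 not in top_adj.pairs[0]


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    data=st.data(),
    n_ind=st.integers(24, 60),
    n_snps=st.integers(3, 6),
    binary=st.booleans(),
)
def test_statistic_invariants_on_random_data(data, n_ind, n_snps, binary):
    """T >= 0 always, and T == 0 exactly when the table is all-O."""
    geno = data.draw(
        st.lists(
            st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=n_snps,
                     max_size=n_snps),
            min_size=n_ind, max_size=n_ind,
        )
    )
    if binary:
        trait = data.draw(
            st.lists(st.sampled_from([0.0, 1.0]), min_size=n_ind, max_size=n_ind)
        )
    else:
        trait = data.draw(
            st.lists(
                st.floats(-3, 3, allow_nan=False, width=32),
                min_size=n_ind, max_size=n_ind,
            )
        )
    ds = Dataset(genotypes=np.array(geno), trait=np.array(trait),
                 trait_type="binary" if binary else "continuous")
    ct = crosstab_pair(ds, (0, 1))
    hlo = categorize_cells(ct, ds.trait_type)
    t = mbmdr_statistic(hlo, ct, ds.trait_type)
    assert t >= 0.0
    if (hlo.labels == "O").all():
        assert t == 0.0
    else:
        vec = all_pair_statistics(ds)
        assert vec[0] == pytest.approx(t, rel=1e-10, abs=1e-10)
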