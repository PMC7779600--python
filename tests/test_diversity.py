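"""Closed-form diversity statistics, AMOVA vs brute-force oracle, catalogues."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from durumpanel import (
    MISSING,
    GroupScheme,
    amova,
    mean_pairwise_differences,
    nei_distance,
    nei_gene_diversity,
    pairwise_fst,
    pic,
    sfs,
    shannon_evenness,
    unique_alleles,
)
from durumpanel.diversity import group_summaries, haploid_freqs

from conftest import make_matrix


class TestClosedForms:
    def test_nei_monomorphic_is_zero(self):
        assert nei_gene_diversity(np.array([0.0]), np.array([10.0]))[0] == 0.0

    def test_nei_unbiased_small_sample(self):
        # n/(n-1) * (1 - 0.25 - 0.25) = (10/9) * 0.5
        he = nei_gene_diversity(np.array([0.5]), np.array([10.0]))[0]
        assert he == pytest.approx(10 / 9 * 0.5)

    def test_nei_asymptotic_limit(self):
        he = nei_gene_diversity(np.array([0.5]), np.array([1e9]))[0]
        assert he == pytest.approx(0.5, abs=1e-8)

    def test_nei_undefined_below_two_copies(self):
        assert np.isnan(nei_gene_diversity(np.array([0.5]), np.array([1.0]))[0])

    def test_pic_maximum(self):
        assert pic(np.array([0.5]))[0] == pytest.approx(0.375)

    def test_pic_monomorphic(self):
        assert pic(np.array([0.0]))[0] == 0.0

    def test_pic_direct_evaluation(self):
        # p=0.1: 1 - (0.01+0.81) - 2*0.01*0.81 = 0.1638
        assert pic(np.array([0.1]))[0] == pytest.approx(0.1638)

    def test_shannon_equal_frequencies(self):
        h, e5 = shannon_evenness(np.array([0.5]))
        assert h[0] == pytest.approx(np.log(2))
        assert e5[0] == 1.0

    def test_shannon_monomorphic(self):
        h, e5 = shannon_evenness(np.array([1.0]))
        assert h[0] == 0.0 and np.isnan(e5[0])

    def test_shannon_skewed(self):
        p = 0.9
        h, e5 = shannon_evenness(np.array([p]))
        h_exp = -(p * np.log(p) + 0.1 * np.log(0.1))
        lam = p**2 + 0.1**2
        assert h[0] == pytest.approx(h_exp)
        assert e5[0] == pytest.approx((1 / lam - 1) / (np.exp(h_exp) - 1))
        assert e5[0] < 1

    @given(st.floats(min_value=1e-6, max_value=0.999999))
    @settings(max_examples=200, deadline=None)
    def test_he_at_least_pic(self, p):
        """He >= PIC for any biallelic frequency (algebraic identity)."""
        he = 1 - p**2 - (1 - p) ** 2  # large-n limit of the estimator
        assert he >= pic(np.array([p]))[0] - 1e-12


class TestSfs:
    def test_direct_binning(self):
        h = sfs([0.07, 0.08, 0.12])
        assert h.counts[1] == 2  # [0.05, 0.10)
        assert h.counts[2] == 1  # [0.10, 0.15)
        assert h.counts.sum() == 3

    def test_empty_input(self):
        assert sfs([]).counts.sum() == 0

    def test_half_boundary_in_last_bin(self):
        assert sfs([0.5]).counts[-1] == 1

    def test_above_half_raises(self):
        with pytest.raises(ValueError):
            sfs([0.6])


class TestPairwiseDifferences:
    def test_identical_pair(self):
        G = make_matrix([[0, 2, 0], [0, 2, 0]])
        assert mean_pairwise_differences(G) == 0.0

    def test_enumerated_triplet(self):
        # haploid 0/1 profiles [0,0,1],[0,1,1],[1,1,1]: diffs 1, 2, 1
        G = make_matrix(np.array([[0, 0, 2], [0, 2, 2], [2, 2, 2]]))
        assert mean_pairwise_differences(G) == pytest.approx((1 + 2 + 1) / 3)

    def test_missing_rescaled_to_total_loci(self):
        # pair complete at 2 of 4 loci, 1 difference -> 1 * 4/2 = 2
        G = make_matrix(np.array([[0, 2, MISSING, 0], [2, 2, 0, MISSING]]))
        assert mean_pairwise_differences(G) == pytest.approx(2.0)

    def test_brute_force_on_random_panel(self):
        rng = np.random.default_rng(5)
        calls = rng.choice([0, 2], size=(6, 12))
        G = make_matrix(calls)
        hap = calls // 2
        pairs = [
            np.sum(hap[a] != hap[b])
            for a, b in itertools.combinations(range(6), 2)
        ]
        assert mean_pairwise_differences(G) == pytest.approx(np.mean(pairs))


def brute_force_amova(hap: np.ndarray, labels: list[str]):
    """Independent sums-of-squares AMOVA oracle on haploid 0/1 rows."""
    n = len(labels)
    d2 = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            d2[a, b] = np.sum(hap[a] != hap[b])
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    ss_total = sum(d2[a, b] for a in range(n) for b in range(a + 1, n)) / n
    ss_within = 0.0
    for idx in groups.values():
        ss_within += sum(
            d2[a, b] for a in idx for b in idx if a < b
        ) / len(idx)
    ss_among = ss_total - ss_within
    g = len(groups)
    ms_among = ss_among / (g - 1)
    ms_within = ss_within / (n - g)
    sizes = np.array([len(v) for v in groups.values()], float)
    n_c = (n - (sizes**2).sum() / n) / (g - 1)
    var_among = (ms_among - ms_within) / n_c
    return var_among, ms_within, var_among / (var_among + ms_within)


class TestAmova:
    def test_fixed_difference_gives_fst_one(self):
        calls = np.vstack([np.zeros((3, 5)), np.full((3, 5), 2)]).astype(int)
        G = make_matrix(calls)
        scheme = GroupScheme("s", {f"acc{i}": ("A" if i < 3 else "B") for i in range(6)})
        res = amova(G, scheme, n_perm=0)
        assert res.fst == pytest.approx(1.0)
        assert res.pct_among == pytest.approx(100.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        calls = rng.choice([0, 2], size=(6, 10))
        labels = ["A", "A", "A", "B", "B", "B"]
        G = make_matrix(calls)
        scheme = GroupScheme("s", dict(zip(G.accession_ids, labels)))
        res = amova(G, scheme, n_perm=0)
        va, vw, fst = brute_force_amova(calls // 2, labels)
        assert res.var_among == pytest.approx(va, abs=1e-10)
        assert res.var_within == pytest.approx(vw, abs=1e-10)
        assert res.fst == pytest.approx(fst, abs=1e-10)

    def test_three_group_oracle_and_percentages(self):
        rng = np.random.default_rng(13)
        calls = rng.choice([0, 2], size=(9, 8))
        labels = ["A"] * 3 + ["B"] * 2 + ["C"] * 4
        G = make_matrix(calls)
        scheme = GroupScheme("s", dict(zip(G.accession_ids, labels)))
        res = amova(G, scheme, n_perm=0)
        va, vw, fst = brute_force_amova(calls // 2, labels)
        assert res.fst == pytest.approx(fst, abs=1e-10)
        assert res.pct_among + res.pct_within == pytest.approx(100.0)

    def test_null_split_fst_near_zero(self):
        rng = np.random.default_rng(14)
        calls = rng.choice([0, 2], size=(40, 300))
        G = make_matrix(calls)
        scheme = GroupScheme("s", {a: ("A" if i < 20 else "B")
                                   for i, a in enumerate(G.accession_ids)})
        res = amova(G, scheme, n_perm=200, seed=1)
        assert abs(res.fst) < 0.02
        assert res.p_value > 0.05

    def test_permutation_p_detects_structure(self, tiny_panel):
        G, _, _ = tiny_panel
        res = amova(G, tiny_panel.scheme(), n_perm=200, seed=3)
        assert res.fst > 0.03
        assert res.p_value <= 0.01

    def test_singleton_group_excluded(self):
        calls = np.vstack([np.zeros((3, 5)), np.full((3, 5), 2),
                           np.full((1, 5), 2)]).astype(int)
        G = make_matrix(calls)
        scheme = GroupScheme("s", {**{f"acc{i}": "A" for i in range(3)},
                                   **{f"acc{i}": "B" for i in range(3, 6)},
                                   "acc6": "C"})
        res = amova(G, scheme, n_perm=0)
        assert res.df_among == 1  # C dropped


class TestPairwiseFst:
    def test_consistent_with_two_group_amova(self):
        rng = np.random.default_rng(15)
        calls = rng.choice([0, 2], size=(9, 20))
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        G = make_matrix(calls)
        scheme = GroupScheme("s", dict(zip(G.accession_ids, labels)))
        fst, pval, dxy = pairwise_fst(G, scheme, n_perm=0)
        for x, y in (("A", "B"), ("A", "C"), ("B", "C")):
            pair = GroupScheme("p", {a: l for a, l in zip(G.accession_ids, labels)
                                     if l in (x, y)})
            assert fst.loc[x, y] == pytest.approx(amova(G, pair, n_perm=0).fst)

    def test_fixed_pair_is_one_identical_near_zero(self):
        calls = np.vstack([np.zeros((3, 6)), np.full((3, 6), 2),
                           np.zeros((3, 6))]).astype(int)
        G = make_matrix(calls)
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        scheme = GroupScheme("s", dict(zip(G.accession_ids, labels)))
        fst, _, _ = pairwise_fst(G, scheme, n_perm=0)
        assert fst.loc["A", "B"] == pytest.approx(1.0)
        assert fst.loc["A", "C"] == pytest.approx(0.0, abs=1e-9)


class TestNeiDistance:
    def test_identical_profiles_zero(self):
        calls = np.vstack([np.tile([0, 2, 0, 2], (3, 1)),
                           np.tile([0, 2, 0, 2], (3, 1))]).astype(int)
        G = make_matrix(calls)
        scheme = GroupScheme("s", {a: ("A" if i < 3 else "B")
                                   for i, a in enumerate(G.accession_ids)})
        D = nei_distance(G, scheme)
        assert D.loc["A", "B"] == pytest.approx(0.0)

    def test_hand_computed_two_locus_table(self):
        # group A freqs (alt): (1.0, 0.5); group B freqs: (0.5, 0.0)
        A = np.array([[2, 2], [2, 0]])
        B = np.array([[2, 0], [0, 0]])
        G = make_matrix(np.vstack([A, B]))
        scheme = GroupScheme("s", {a: ("A" if i < 2 else "B")
                                   for i, a in enumerate(G.accession_ids)})
        jx = np.mean([1.0**2 + 0.0**2, 0.5**2 + 0.5**2])
        jy = np.mean([0.5**2 + 0.5**2, 0.0**2 + 1.0**2])
        jxy = np.mean([1.0 * 0.5 + 0.0 * 0.5, 0.5 * 0.0 + 0.5 * 1.0])
        expected = -np.log(jxy / np.sqrt(jx * jy))
        D = nei_distance(G, scheme)
        assert D.loc["A", "B"] == pytest.approx(expected)
        assert D.loc["B", "A"] == D.loc["A", "B"]
        assert (D.values >= 0).all()


class TestUniqueAlleles:
    def _three_group_panel(self):
        rng = np.random.default_rng(21)
        calls = rng.choice([0, 2], size=(15, 40), p=[0.8, 0.2])
        labels = ["A"] * 5 + ["B"] * 5 + ["C"] * 5
        return make_matrix(calls), labels

    def test_unique_and_rare_flags(self):
        calls = np.zeros((30, 2), dtype=int)
        calls[0:3, 0] = 2   # minor allele only in A (freq 3/10 in A)
        calls[0, 1] = 2     # minor allele only in A (freq 1/10 in A)
        G = make_matrix(calls)
        labels = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        scheme = GroupScheme("s", dict(zip(G.accession_ids, labels)))
        cat, summary = unique_alleles(G, scheme)
        assert set(cat["owner_group"]) == {"A"}
        by_marker = cat.set_index("marker_id")
        assert not by_marker.loc["m0", "rare"]
        assert not by_marker.loc["m1", "rare"]  # 0.1 >= 0.05
        assert summary.loc[summary["group"] == "A", "n_unique"].item() == 2

    def test_shared_allele_not_unique(self):
        calls = np.zeros((20, 1), dtype=int)
        calls[0, 0] = 2
        calls[10, 0] = 2
        G = make_matrix(calls)
        labels = ["A"] * 10 + ["B"] * 10
        cat, _ = unique_alleles(G, GroupScheme("s", dict(zip(G.accession_ids, labels))))
        assert len(cat) == 0

    def test_matches_exhaustive_scan(self):
        G, labels = self._three_group_panel()
        scheme = GroupScheme("s", dict(zip(G.accession_ids, labels)))
        cat, _ = unique_alleles(G, scheme)
        hap = G.calls // 2
        expected = set()
        for j in range(G.n_markers):
            col = hap[:, j]
            p = col.mean()
            minor = col if p <= 0.5 else 1 - col
            present = {lab for lab, v in zip(labels, minor) if v == 1}
            if len(present) == 1:
                expected.add((G.marker_ids[j], next(iter(present))))
        got = set(zip(cat["marker_id"], cat["owner_group"]))
        assert got == expected


class TestGroupSummaries:
    def test_layout_and_ranges(self, tiny_panel):
        G, _, _ = tiny_panel
        summaries = group_summaries(G, tiny_panel.scheme())
        assert {s.group for s in summaries} == {"landrace", "modern"}
        for s in summaries:
            assert 0 < s.n_polymorphic_loci <= G.n_markers
            assert 0 <= s.nei_gene_diversity <= 1
            assert 0 <= s.pic <= 0.375 + 1e-12
            finite_maf = s.maf_per_locus[np.isfinite(s.maf_per_locus)]
            assert ((finite_maf >= 0) & (finite_maf <= 0.5)).all()
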