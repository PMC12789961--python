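"""Distinctiveness metrics: Δ+, allelic overlap, Jost's D_est, pairwise AMOVA.

Each closed-form implementation is checked against an independent oracle:
exhaustive pair enumeration for Δ+, direct formula evaluation with exact
fractions for D_est, and an O(N^2) distance-matrix computation for the
AMOVA sums of squares.
"""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from kbagen.allele_stats import AlleleCountTable, count_alleles, frequencies
from kbagen.datamodel import Locus
from kbagen.distinct_metrics import (
    ALLELIC_WEIGHTS,
    HierarchyWeights,
    allelic_overlap,
    amova_pairwise,
    amova_per_area,
    avtd,
    dest_per_area,
    overlap_per_area,
    pairwise_dest,
)

from conftest import dataset_from_calls, duplicate_individuals

CLASSIC = HierarchyWeights(1.0, 2.0)


def freq_table(area_freqs, locus_sizes, n_copies=60.0):
    """Frequency table from {area: [per-locus freq vector]} specs."""
    areas = list(area_freqs)
    n_loci = len(locus_sizes)
    A = max(locus_sizes)
    loci = [
        Locus(f"L{l+1}", "microsatellite", tuple(str(a + 1) for a in range(m)))
        for l, m in enumerate(locus_sizes)
    ]
    counts = np.zeros((len(areas), n_loci, A))
    copies = np.full((len(areas), n_loci), float(n_copies))
    for k, a in enumerate(areas):
        for l in range(n_loci):
            counts[k, l, : locus_sizes[l]] = np.asarray(area_freqs[a][l]) * n_copies
    t = AlleleCountTable(areas, loci, counts, copies)
    return t, frequencies(t)


def avtd_enumeration(present, w_same, w_diff):
    """Oracle: exhaustive sum over unordered pairs of (locus, allele) labels."""
    pairs = list(itertools.combinations(present, 2))
    total = sum(w_same if a[0] == b[0] else w_diff for a, b in pairs)
    return total / len(pairs)


class TestAvtd:
    def test_mixed_presence_equals_hand_value(self):
        # present: {L1:a, L1:b, L2:a}; pairs (1+2+2)/3 = 5/3 with classic weights
        _, f = freq_table({"A": [[0.5, 0.5], [1.0, 0.0]]}, [2, 2])
        assert avtd(f, "A", CLASSIC) == pytest.approx(5 / 3)

    @pytest.mark.parametrize("weights", [CLASSIC, ALLELIC_WEIGHTS, HierarchyWeights(1, 3)])
    def test_matches_pair_enumeration_oracle(self, weights):
        _, f = freq_table(
            {"A": [[0.4, 0.4, 0.2], [0.9, 0.1, 0.0], [1.0]]}, [3, 3, 1]
        )
        present = [("L1", 1), ("L1", 2), ("L1", 3), ("L2", 1), ("L2", 2), ("L3", 1)]
        w_same, w_diff = weights.resolved()
        expected = avtd_enumeration(present, w_same, w_diff)
        assert avtd(f, "A", weights) == pytest.approx(expected)

    def test_single_locus_gives_same_locus_weight(self):
        _, f = freq_table({"A": [[0.3, 0.3, 0.4]]}, [3])
        assert avtd(f, "A", CLASSIC) == pytest.approx(1.0)

    def test_one_allele_per_locus_gives_cross_locus_weight(self):
        _, f = freq_table({"A": [[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]]}, [2, 2, 2])
        assert avtd(f, "A", CLASSIC) == pytest.approx(2.0)

    def test_bounded_by_weights(self):
        _, f = freq_table({"A": [[0.5, 0.5], [0.7, 0.2, 0.1]]}, [2, 3])
        v = avtd(f, "A", CLASSIC)
        assert 1.0 <= v <= 2.0

    def test_presence_threshold_drops_trace_alleles(self):
        _, f = freq_table({"A": [[0.99, 0.01], [1.0, 0.0]]}, [2, 2])
        assert avtd(f, "A", CLASSIC, presence_threshold=0.02) == pytest.approx(2.0)

    def test_fewer_than_two_alleles_is_nan(self):
        _, f = freq_table({"A": [[1.0, 0.0]]}, [2])
        assert np.isnan(avtd(f, "A", CLASSIC))

    def test_invariant_under_sample_duplication(self, small_mixed):
        clean = small_mixed.subset_individuals(
            np.flatnonzero(~small_mixed.missing.any(axis=1))
        )
        f1 = frequencies(count_alleles(clean))
        f2 = frequencies(count_alleles(duplicate_individuals(clean)))
        for area in f1.areas:
            assert avtd(f1, area, CLASSIC) == avtd(f2, area, CLASSIC)

    def test_standardization_rescales_to_max(self):
        w = HierarchyWeights(1, 2, standardize_to=100)
        _, f = freq_table({"A": [[0.5, 0.5], [1.0, 0.0]]}, [2, 2])
        assert avtd(f, "A", w) == pytest.approx(100 * (5 / 3) / 2)


class TestOverlap:
    def test_identical_frequencies_give_one(self):
        spec = {"A": [[0.3, 0.7], [0.5, 0.5]], "B": [[0.3, 0.7], [0.5, 0.5]]}
        _, f = freq_table(spec, [2, 2])
        for method in ("czekanowski", "pianka"):
            assert allelic_overlap(f, "A", "B", method).value == pytest.approx(1.0)

    def test_disjoint_support_gives_zero(self):
        spec = {"A": [[1.0, 0.0]], "B": [[0.0, 1.0]]}
        _, f = freq_table(spec, [2])
        for method in ("czekanowski", "pianka"):
            assert allelic_overlap(f, "A", "B", method).value == pytest.approx(0.0)

    def test_half_overlap_hand_values(self):
        spec = {"A": [[0.5, 0.5]], "B": [[1.0, 0.0]]}
        _, f = freq_table(spec, [2])
        assert allelic_overlap(f, "A", "B", "czekanowski").value == pytest.approx(0.5)
        assert allelic_overlap(f, "A", "B", "pianka").value == pytest.approx(0.5 / np.sqrt(0.5))

    def test_symmetry_and_range(self, small_mixed):
        from kbagen.preprocess import impute_mean_dosage
        f = frequencies(count_alleles(impute_mean_dosage(small_mixed)))
        for a, b in itertools.combinations(f.areas, 2):
            o1 = allelic_overlap(f, a, b).value
            o2 = allelic_overlap(f, b, a).value
            assert o1 == pytest.approx(o2)
            assert 0.0 <= o1 <= 1.0

    def test_per_area_is_mean_over_partners(self):
        spec = {
            "A": [[1.0, 0.0, 0.0]],
            "B": [[0.0, 1.0, 0.0]],
            "C": [[0.0, 1.0, 0.0]],
        }
        _, f = freq_table(spec, [3])
        # A shares nothing: mean(0, 0) = 0; B pairs: (0 with A, 1 with C) -> 0.5
        assert overlap_per_area(f, "A") == pytest.approx(0.0)
        assert overlap_per_area(f, "B") == pytest.approx(0.5)

    def test_single_area_raises(self):
        _, f = freq_table({"A": [[0.5, 0.5]]}, [2])
        with pytest.raises(ValueError):
            overlap_per_area(f, "A")


def dest_oracle_single_locus(counts_a, counts_b, n_a, n_b):
    """Exact-fraction evaluation of the two-population D_est estimator chain."""
    pa = [Fraction(c, 2 * n_a) for c in counts_a]
    pb = [Fraction(c, 2 * n_b) for c in counts_b]
    hs_obs = 1 - Fraction(1, 2) * (sum(p**2 for p in pa) + sum(p**2 for p in pb))
    pbar = [(x + y) / 2 for x, y in zip(pa, pb)]
    ht_obs = 1 - sum(p**2 for p in pbar)
    n_harm = Fraction(2) / (Fraction(1, n_a) + Fraction(1, n_b))
    hs = (2 * n_harm / (2 * n_harm - 1)) * hs_obs
    ht = ht_obs + hs / (2 * n_harm * 2)
    return float((ht - hs) / (1 - hs) * 2)


class TestDest:
    def test_fully_fixed_disjoint_areas_give_one(self, two_area_fixed):
        t = count_alleles(two_area_fixed)
        assert pairwise_dest(t, "north", "south").value == pytest.approx(1.0)

    def test_identical_areas_give_small_negative_sampling_artifact(self, two_area_identical):
        """Identical samples yield the exact small negative value of the
        corrected estimator, -H_S / [(2n-1)(1 - H_S^)] * s/(s-1), which
        vanishes as n grows (the estimator is unbiased over independent
        samples, not at literally identical ones)."""
        t = count_alleles(two_area_identical)
        got = pairwise_dest(t, "east", "west").value
        expected = dest_oracle_single_locus([15, 15], [15, 15], 15, 15)
        assert got == pytest.approx(expected, abs=1e-12)
        assert expected < 0
        assert abs(got) < 2 / (2 * 15 - 1)  # O(1/n) sampling term

    def test_matches_exact_fraction_oracle(self):
        # areaA counts (30, 30), areaB counts (50, 10), 30 individuals each
        loc = Locus("L1", "snp", ("1", "2"))
        counts = np.array([[[30.0, 30.0]], [[50.0, 10.0]]])
        t = AlleleCountTable(["A", "B"], [loc], counts, np.full((2, 1), 60.0))
        expected = dest_oracle_single_locus([30, 30], [50, 10], 30, 30)
        assert pairwise_dest(t, "A", "B").value == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, small_mixed):
        from kbagen.preprocess import impute_mean_dosage
        t = count_alleles(impute_mean_dosage(small_mixed))
        for a, b in itertools.combinations(t.areas, 2):
            assert pairwise_dest(t, a, b).value == pytest.approx(
                pairwise_dest(t, b, a).value
            )

    def test_per_area_is_mean_of_pairwise(self, small_mixed):
        from kbagen.preprocess import impute_mean_dosage
        t = count_alleles(impute_mean_dosage(small_mixed))
        expected = np.mean(
            [pairwise_dest(t, "A", o).value for o in ("B", "C")]
        )
        assert dest_per_area(t, "A") == pytest.approx(expected)

    def test_divergent_area_scores_highest(self):
        spec = {
            "A": [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]],
            "B": [[0.0, 0.5, 0.5], [0.5, 0.0, 0.5]],
            "C": [[0.0, 0.5, 0.5], [0.5, 0.0, 0.5]],
        }
        t, _ = freq_table(spec, [3, 3])
        scores = {a: dest_per_area(t, a) for a in t.areas}
        assert scores["A"] == max(scores.values())
        assert scores["A"] > scores["B"]

    def test_duplication_drift_below_absolute_band(self, two_area_fixed):
        t1 = count_alleles(two_area_fixed)
        t2 = count_alleles(duplicate_individuals(two_area_fixed))
        d1 = pairwise_dest(t1, "north", "south").value
        d2 = pairwise_dest(t2, "north", "south").value
        assert abs(d1 - d2) <= 0.01


def amova_oracle(ds, area_a, area_b):
    """Independent O(N^2) evaluation of the AMOVA sums of squares."""
    table = ds.area_table()
    groups = [table[area_a], table[area_b]]
    ix = np.concatenate(groups)
    x = ds.dosage[ix].reshape(len(ix), -1)
    N = len(ix)

    def d2(i, j):
        return 0.25 * float(np.sum((x[i] - x[j]) ** 2))

    ss_total = sum(d2(i, j) for i, j in itertools.combinations(range(N), 2)) / N
    ss_within = 0.0
    offset = 0
    for g in groups:
        ng = len(g)
        ss_within += (
            sum(d2(i, j) for i, j in itertools.combinations(range(offset, offset + ng), 2))
            / ng
        )
        offset += ng
    ss_among = ss_total - ss_within
    n_a, n_b = len(groups[0]), len(groups[1])
    ms_among, ms_within = ss_among / 1, ss_within / (N - 2)
    n0 = (N - (n_a**2 + n_b**2) / N) / 1
    sigma2_w = ms_within
    sigma2_a = (ms_among - ms_within) / n0
    return ss_among, ss_within, sigma2_a, sigma2_w


class TestAmova:
    def test_fixed_disjoint_areas_give_phi_one(self, two_area_fixed):
        comp = amova_pairwise(two_area_fixed, "north", "south")
        assert comp.phi_st == pytest.approx(1.0)
        assert comp.sigma2_w == pytest.approx(0.0)

    def test_identical_areas_give_nonpositive_sigma2_a(self, two_area_identical):
        comp = amova_pairwise(two_area_identical, "east", "west")
        assert comp.sigma2_a <= 1e-12
        assert comp.phi_st <= 1e-12

    def test_components_match_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            n_a, n_b = rng.integers(2, 7, size=2)
            rows = []
            for i in range(n_a):
                rows.append((f"a{i}", "A", [tuple(rng.choice(["1", "2", "3"], 2)) for _ in range(3)]))
            for i in range(n_b):
                rows.append((f"b{i}", "B", [tuple(rng.choice(["1", "2", "3"], 2)) for _ in range(3)]))
            ds = dataset_from_calls(rows, ["L1", "L2", "L3"])
            comp = amova_pairwise(ds, "A", "B")
            ss_among, ss_within, s2a, s2w = amova_oracle(ds, "A", "B")
            assert comp.ss_among == pytest.approx(ss_among, abs=1e-9)
            assert comp.ss_within == pytest.approx(ss_within, abs=1e-9)
            assert comp.sigma2_a == pytest.approx(s2a, abs=1e-9)
            assert comp.sigma2_w == pytest.approx(s2w, abs=1e-9)

    def test_ss_decomposition_and_df(self, small_mixed):
        from kbagen.preprocess import impute_mean_dosage
        ds = impute_mean_dosage(small_mixed)
        comp = amova_pairwise(ds, "A", "B")
        N = 8
        assert comp.df_among + comp.df_within == N - 1
        assert comp.ss_total == pytest.approx(comp.ss_among + comp.ss_within)

    def test_ss_among_doubles_under_duplication_sigma2_stable(self, two_area_identical):
        ds = two_area_identical
        dd = duplicate_individuals(ds)
        s1 = amova_pairwise(ds, "east", "west")
        s2 = amova_pairwise(dd, "east", "west")
        assert s2.ss_among == pytest.approx(2 * s1.ss_among, rel=1e-9)
        # variance component is a per-individual quantity: stays put
        assert abs(s2.sigma2_a - s1.sigma2_a) < 0.05 * max(abs(s1.sigma2_w), 1e-9)

    def test_per_area_mean_and_two_area_equivalence(self, two_area_fixed):
        single = amova_pairwise(two_area_fixed, "north", "south").sigma2_a
        assert amova_per_area(two_area_fixed, "north") == pytest.approx(single)

    def test_degenerate_group_raises(self):
        rows = [("i1", "A", [("1", "1")]), ("i2", "B", [("1", "2")]), ("i3", "B", [("2", "2")])]
        ds = dataset_from_calls(rows, ["L1"])
        with pytest.raises(ValueError, match="fewer than 2"):
            amova_pairwise(ds, "A", "B")
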