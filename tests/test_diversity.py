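"""Diversity statistics against analytic and enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

from ssrpop.diversity import (
    AlleleFrequencies,
    allele_frequencies,
    allelic_richness,
    diversity_stats,
    frequent_allele_chi2,
    private_and_unique_alleles,
    probability_of_identity,
)
from tests.conftest import make_table


def freqs_from(p_by_locus, n=1000):
    return AlleleFrequencies(
        loci=list(p_by_locus),
        counts={l: {100 + 2 * i: int(round(p * n))
                    for i, p in enumerate(ps)}
                for l, ps in p_by_locus.items()})


def test_allele_frequencies_counting():
    t = make_table([[(100, 100)], [(100, 102)], [()]])
    f = allele_frequencies(t)["all"]
    assert f.n_copies["L01"] == 4          # missing call excluded
    assert f.freqs["L01"] == {100: 0.75, 102: 0.25}


def test_allele_frequencies_empty_group_flagged():
    t = make_table([[(100, 100), ()]])
    f = allele_frequencies(t)["all"]
    assert f.undefined_loci == ["L02"]


def test_frequencies_sum_to_one_per_group(collection):
    _, table, truth = collection
    grouping = dict(truth.group_labels.items())
    for f in allele_frequencies(table, grouping).values():
        for locus in f.loci:
            if f.freqs[locus]:
                assert sum(f.freqs[locus].values()) == pytest.approx(1.0)


class TestProbabilityOfIdentity:
    def test_biallelic_half(self):
        per_locus, cum = probability_of_identity(freqs_from({"L1": [0.5, 0.5]}))
        assert per_locus["L1"] == pytest.approx(0.375)
        assert cum == pytest.approx(0.375)

    def test_monomorphic_locus_contributes_factor_one(self):
        _, cum = probability_of_identity(
            freqs_from({"L1": [0.5, 0.5], "L2": [1.0]}))
        assert cum == pytest.approx(0.375)

    @pytest.mark.parametrize("k", [2, 3, 4, 6])
    def test_uniform_alleles_closed_form(self, k):
        per_locus, _ = probability_of_identity(freqs_from({"L1": [1 / k] * k}))
        assert per_locus["L1"] == pytest.approx((2 * k - 1) / k**3)

    def test_product_over_independent_loci(self):
        _, cum = probability_of_identity(
            freqs_from({"L1": [0.5, 0.5], "L2": [0.5, 0.5]}))
        assert cum == pytest.approx(0.140625)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_genotype_pair_enumeration(self, seed):
        """Oracle: P_ID = sum over genotypes of P(genotype)^2 under HWE."""
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(rng.integers(2, 7)))
        expected = 0.0
        for i, pi in enumerate(p):
            for j, pj in enumerate(p):
                prob = pi**2 if i == j else 2 * pi * pj
                if i <= j:
                    expected += prob**2
        freqs = AlleleFrequencies(loci=["L1"], counts={"L1": {0: 1}})
        freqs.freqs = {"L1": {i: float(x) for i, x in enumerate(p)}}
        per_locus, _ = probability_of_identity(freqs)
        assert per_locus["L1"] == pytest.approx(expected, rel=1e-12)


class TestAllelicRichness:
    def test_two_by_two_enumeration_value(self):
        assert allelic_richness({100: 2, 102: 2}, g=2) == pytest.approx(5 / 3)

    def test_matches_exhaustive_enumeration(self):
        counts = {1: 3, 2: 2, 3: 1}
        copies = [a for a, c in counts.items() for _ in range(c)]
        for g in range(1, len(copies) + 1):
            expected = np.mean([len(set(s))
                                for s in itertools.combinations(copies, g)])
            assert allelic_richness(counts, g) == pytest.approx(expected)

    def test_full_draw_gives_allele_count(self):
        assert allelic_richness({1: 4, 2: 3, 3: 1}, g=8) == pytest.approx(3.0)

    def test_single_copy_gives_one(self):
        assert allelic_richness({1: 5, 2: 5}, g=1) == pytest.approx(1.0)

    def test_monotone_in_g_and_matches_monte_carlo(self, rng):
        counts = {a: int(c) for a, c in enumerate(rng.integers(1, 20, 8), 1)}
        copies = np.array([a for a, c in counts.items() for _ in range(c)])
        prev = 0.0
        for g in (2, 5, 10, 20):
            ar = allelic_richness(counts, g)
            assert ar >= prev
            prev = ar
            sims = [len(np.unique(rng.choice(copies, g, replace=False)))
                    for _ in range(2000)]
            se = np.std(sims, ddof=1) / math.sqrt(len(sims))
            assert abs(ar - np.mean(sims)) < 3 * max(se, 1e-9)

    def test_oversampling_is_an_error(self):
        with pytest.raises(ValueError):
            allelic_richness({1: 2, 2: 2}, g=5)


class TestDiversityStats:
    def test_uniform_alleles_effective_number(self):
        t = make_table([[(100, 102)], [(104, 106)]])
        row = diversity_stats(t).set_index("locus").loc["L01"]
        assert row["N_A"] == 4
        assert row["N_E"] == pytest.approx(4.0)   # k uniform alleles: N_E = k

    def test_he_correction_and_bounds(self):
        t = make_table([[(100, 102)], [(100, 102)], [(100, 100)]])
        row = diversity_stats(t).set_index("locus").loc["L01"]
        assert row["He"] >= row["He_uncorrected"]
        assert 0 <= row["He_uncorrected"] <= row["He"] <= 1
        assert row["N_E"] <= row["N_A"]
        # He = (1 - sum p^2) * N/(N-1) with p = (2/3, 1/3), N = 6 copies
        assert row["He"] == pytest.approx((1 - (4 + 1) / 9) * 6 / 5)

    def test_all_homozygotes_have_zero_ho(self):
        t = make_table([[(100, 100)], [(102, 102)]])
        assert diversity_stats(t).set_index("locus").loc["L01", "Ho"] == 0.0

    def test_rare_allele_count_strictly_below_threshold(self):
        # p = 0.05 exactly is NOT rare ("below 5 %")
        counts = {100: 1, 102: 19}
        f = AlleleFrequencies(loci=["L1"], counts={"L1": counts})
        assert f.freqs["L1"][100] == 0.05
        t = make_table([[(102, 102)]] * 9 + [[(100, 102)]])
        row = diversity_stats(t).set_index("locus").loc["L01"]
        assert row["N_B"] == 0

    def test_invariant_to_accession_order(self, collection, rng):
        _, table, _ = collection
        perm = rng.permutation(table.n_accessions)
        shuffled = table.subset([table.accession_ids[i] for i in perm])
        a = diversity_stats(table).set_index("locus").sort_index()
        b = diversity_stats(shuffled).set_index("locus").sort_index()
        assert np.allclose(a["He"], b["He"], equal_nan=True)
        assert np.allclose(a["Ho"], b["Ho"], equal_nan=True)


def test_private_and_unique_alleles():
    t = make_table([
        [(100, 102)],   # 102 shared with g2; 100 private to g1 (two carriers)
        [(100, 104)],   # 104 unique: only this accession carries it
        [(102, 106)],   # g2
        [(106, 106)],
    ])
    grouping = {"A000": "g1", "A001": "g1", "A002": "g2", "A003": "g2"}
    res = private_and_unique_alleles(t, grouping).set_index("group")
    assert res.loc["g1", "private"] == 2     # alleles 100 and 104
    assert res.loc["g1", "unique"] == 1      # allele 104
    assert res.loc["g2", "private"] == 1     # allele 106 (102 is shared)
    assert res.loc["g2", "unique"] == 0      # 106 carried by two accessions


class TestFrequentAlleleChi2:
    def test_identical_compositions_give_zero_statistic(self):
        rows = [[(100, 102)], [(100, 104)]]
        t = make_table(rows + rows, ids=list("ABCD"))
        grouping = {"A": "g1", "B": "g1", "C": "g2", "D": "g2"}
        res = frequent_allele_chi2(t, grouping).iloc[0]
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0)

    def test_disjoint_two_by_two_table(self):
        # groups fixed for different alleles: table [[10, 0], [0, 10]]
        t = make_table([[(100, 100)]] * 5 + [[(102, 102)]] * 5,
                       ids=[f"X{i}" for i in range(10)])
        grouping = {f"X{i}": ("g1" if i < 5 else "g2") for i in range(10)}
        res = frequent_allele_chi2(t, grouping).iloc[0]
        assert res["chi2"] == pytest.approx(20.0)
        assert res["df"] == 1

    def test_three_balanced_groups_not_significant(self):
        rows = [[(100, 102)], [(100, 104)], [(102, 104)]]
        t = make_table(rows * 3, ids=list("ABCDEFGHI"))
        grouping = {a: f"g{i // 3}" for i, a in enumerate("ABCDEFGHI")}
        res = frequent_allele_chi2(t, grouping).iloc[0]
        assert res["p_value"] > 0.99
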