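"""Diversity and differentiation statistics against hand-computed oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from rescuegen import popgen as P
from rescuegen.containers import GenotypeTable, HaplotypeSet
from rescuegen.synth import simulate_haplotypes
from tests.conftest import random_genotype_table


def _single_locus_table(genotypes: list[tuple[int, int]], pop: str = "A") -> GenotypeTable:
    geno = np.array([[g] for g in genotypes])
    return GenotypeTable(
        [f"i{k}" for k in range(len(genotypes))], [pop] * len(genotypes), ["L1"], geno
    )


class TestExpectedHeterozygosity:
    def test_monomorphic_locus_is_zero(self):
        t = _single_locus_table([(100, 100)] * 5)
        per, mean = P.expected_heterozygosity(t)
        assert per[0] == 0.0 and mean == 0.0

    def test_unbiased_estimator_two_equal_alleles(self):
        # 10 diploids all heterozygous 100/102: p = q = 0.5
        t = _single_locus_table([(100, 102)] * 10)
        per, _ = P.expected_heterozygosity(t)
        assert per[0] == pytest.approx((20 / 19) * 0.5)

    def test_invariant_under_allele_relabeling(self):
        g1 = [(100, 102), (100, 100), (102, 104), (104, 104)]
        g2 = [(200, 250), (200, 200), (250, 300), (300, 300)]
        _, he1 = P.expected_heterozygosity(_single_locus_table(g1))
        _, he2 = P.expected_heterozygosity(_single_locus_table(g2))
        assert he1 == pytest.approx(he2)


class TestHomozygosityByLocus:
    def test_extreme_individuals(self):
        geno = np.array([
            [[100, 102], [140, 142]],  # all het -> HL 0
            [[100, 100], [140, 140]],  # all hom -> HL 1
        ])
        t = GenotypeTable(["het", "hom"], ["A", "A"], ["L1", "L2"], geno)
        hl = P.homozygosity_by_locus(t)
        assert hl[0] == 0.0 and hl[1] == 1.0

    def test_weighting_by_locus_variability(self):
        # population of 4: locus A has E=0.5 (alleles 50/50), locus B E=0.375 (6/2)
        geno = np.array([
            [[100, 100], [140, 140]],  # hom at both
            [[100, 102], [140, 140]],
            [[102, 102], [140, 142]],
            [[100, 102], [140, 142]],
        ])
        t = GenotypeTable(list("abcd"), ["A"] * 4, ["LA", "LB"], geno)
        hl = P.homozygosity_by_locus(t)
        e_a = 1 - 2 * 0.5**2              # 0.5
        e_b = 1 - (6 / 8) ** 2 - (2 / 8) ** 2  # 0.375
        # individual b: hom at LB only -> E_b/(E_a+E_b)
        assert hl[1] == pytest.approx(e_b / (e_a + e_b))
        # individual c: hom at LA only -> E_a/(E_a+E_b) (heavier weight)
        assert hl[2] == pytest.approx(e_a / (e_a + e_b))
        assert hl[2] > hl[1]

    def test_missing_locus_excluded_from_both_sums(self):
        geno = np.array([
            [[100, 100], [0, 0]],
            [[100, 102], [140, 142]],
            [[102, 102], [140, 140]],
        ])
        t = GenotypeTable(list("abc"), ["A"] * 3, ["L1", "L2"], geno)
        hl = P.homozygosity_by_locus(t)
        assert hl[0] == 1.0  # only L1 observed, homozygous


class TestAllelicRichness:
    def test_monomorphic_is_one(self):
        t = _single_locus_table([(100, 100)] * 20)
        per, _ = P.allelic_richness(t, g=10)
        assert per[0] == pytest.approx(1.0)

    def test_g_equal_to_sample_gives_observed_count(self):
        t = _single_locus_table([(100, 102), (104, 104), (100, 104)])
        per, _ = P.allelic_richness(t, g=6)
        assert per[0] == pytest.approx(3.0)

    def test_rarefaction_combinatorial_oracle(self):
        # allele counts (27, 1) among N = 28 genes, g = 2
        t = _single_locus_table([(100, 100)] * 13 + [(100, 102)])
        per, _ = P.allelic_richness(t, g=2)
        expect = 1.0 + (1.0 - math.comb(27, 2) / math.comb(28, 2))
        assert per[0] == pytest.approx(expect)

    def test_undersized_locus_excluded(self):
        t = _single_locus_table([(100, 102)] * 3)
        with pytest.warns(UserWarning, match="rarefaction"):
            per, mean = P.allelic_richness(t, g=28)
        assert math.isnan(per[0]) and math.isnan(mean)


class TestPrivateAlleles:
    def test_identical_sets_give_zero(self):
        geno = np.tile(np.array([[100, 102]]), (6, 1)).reshape(6, 1, 2)
        t = GenotypeTable(list("abcdef"), ["A"] * 3 + ["B"] * 3, ["L1"], geno)
        assert P.private_alleles(t) == {"A": 0, "B": 0}

    def test_planted_unique_allele_counted(self, two_pop_table):
        counts = P.private_alleles(two_pop_table)
        # north carries 102 privately at LocA; south carries nothing unique at
        # LocB; alleles 104 appear in both pops at LocA
        assert counts["north"] >= 1

    def test_sum_equals_total_minus_shared(self):
        rng = np.random.default_rng(5)
        t = random_genotype_table(rng, n_pops=3, n_per_pop=10, n_loci=5, missing_rate=0)
        counts = P.private_alleles(t)
        total = shared = 0
        for j in range(t.n_loci):
            owners: dict[int, set[str]] = {}
            for p in t.population_names:
                for a in P.allele_counts(t.population(p), j):
                    owners.setdefault(a, set()).add(p)
            total += len(owners)
            shared += sum(1 for s in owners.values() if len(s) > 1)
        assert sum(counts.values()) == total - shared


class TestPairwiseFst:
    def test_fixed_differences_give_one(self):
        a = _single_locus_table([(100, 100)] * 10, "A")
        b = _single_locus_table([(102, 102)] * 10, "B")
        assert P.pairwise_fst(a, b).statistic == pytest.approx(1.0)

    def test_panmictic_pool_gives_near_zero(self):
        rng = np.random.default_rng(42)
        thetas = []
        for rep in range(20):
            geno = 100 + 2 * rng.integers(0, 5, size=(200, 8, 2))
            a = GenotypeTable([f"a{k}" for k in range(100)], ["A"] * 100,
                              [f"L{j}" for j in range(8)], geno[:100])
            b = GenotypeTable([f"b{k}" for k in range(100)], ["B"] * 100,
                              [f"L{j}" for j in range(8)], geno[100:])
            thetas.append(P.pairwise_fst(a, b).statistic)
        assert abs(np.mean(thetas)) < 0.01
        assert max(abs(t) for t in thetas) < 0.02

    def test_symmetric_in_population_order(self, two_pop_table):
        a = two_pop_table.population("north")
        b = two_pop_table.population("south")
        assert P.pairwise_fst(a, b).statistic == pytest.approx(
            P.pairwise_fst(b, a).statistic
        )

    def test_permutation_p_small_for_fixed_differences(self):
        a = _single_locus_table([(100, 100)] * 12, "A")
        b = _single_locus_table([(102, 102)] * 12, "B")
        res = P.pairwise_fst(a, b, n_perm=99, seed=0)
        assert res.p_value <= 0.05


class TestPhiSt:
    def test_identical_sets_near_zero(self):
        seqs = ["ACGTACGTAC", "ACGTACGTAT", "ACGAACGTAC"]
        a = HaplotypeSet([f"a{k}" for k in range(3)], ["A"] * 3, seqs)
        b = HaplotypeSet([f"b{k}" for k in range(3)], ["B"] * 3, seqs)
        res = P.pairwise_phist(a, b)
        assert res.statistic <= 0.01

    def test_reciprocally_monophyletic_near_one(self):
        a = HaplotypeSet(["a1", "a2"], ["A"] * 2, ["AAAAAAAAAA"] * 2)
        b = HaplotypeSet(["b1", "b2"], ["B"] * 2, ["CCCCCCCCCC"] * 2)
        assert P.pairwise_phist(a, b).statistic == pytest.approx(1.0)

    def test_manual_amova_oracle_six_sequences(self):
        # pop A: two copies of h1, one h2 (1 diff); pop B: three copies of h3
        # (h3 is 4 diffs from h1, 5 from h2)
        h1 = "AAAAAAAAAA"
        h2 = "AAAAAAAAAC"
        h3 = "CCCCAAAAAA"
        a = HaplotypeSet(["a1", "a2", "a3"], ["A"] * 3, [h1, h1, h2])
        b = HaplotypeSet(["b1", "b2", "b3"], ["B"] * 3, [h3, h3, h3])
        # hand AMOVA: n = 6, P = 2, n_c = 3
        # SS_total = (sum of all pairwise diffs)/6; within A: (1+1)/3; within B: 0
        d_sum = (1 + 1) + (4 + 4 + 4) * 2 + (5 + 5 + 5)  # A-pairs + A-B pairs + ...
        # enumerate: pairs within A: (a1,a2)=0,(a1,a3)=1,(a2,a3)=1 -> 2
        # pairs within B: 0; cross pairs: a1-b*: 4*3, a2-b*: 4*3, a3-b*: 5*3 = 39
        ss_total = (2 + 0 + 39) / 6
        ss_within = 2 / 3 + 0 / 3
        ss_among = ss_total - ss_within
        sigma_w = ss_within / (6 - 2)
        sigma_a = (ss_among / 1 - sigma_w) / 3
        expect = sigma_a / (sigma_a + sigma_w)
        assert P.pairwise_phist(a, b).statistic == pytest.approx(expect)

    def test_no_variation_flagged_undefined(self):
        a = HaplotypeSet(["a1", "a2"], ["A"] * 2, ["AAAA", "AAAA"])
        b = HaplotypeSet(["b1", "b2"], ["B"] * 2, ["AAAA", "AAAA"])
        res = P.pairwise_phist(a, b)
        assert math.isnan(res.statistic) and res.flags


class TestAlleleSizePermutation:
    def test_no_p_value_when_nperm_zero(self, two_pop_table):
        res = P.allele_size_permutation_test(two_pop_table, n_perm=0)
        assert res.p_value is None and math.isfinite(res.statistic)

    def test_monomorphic_locus_excluded(self):
        geno = np.concatenate([
            np.tile(np.array([[[100, 100], [140, 142]]]), (5, 1, 1)),
            np.tile(np.array([[[100, 100], [150, 152]]]), (5, 1, 1)),
        ])
        t = GenotypeTable([f"i{k}" for k in range(10)], ["A"] * 5 + ["B"] * 5,
                          ["mono", "poly"], geno)
        res = P.allele_size_permutation_test(t, n_perm=0)
        res_excl = P.allele_size_permutation_test(t, n_perm=0, exclude=["mono"])
        assert res.statistic == pytest.approx(res_excl.statistic)

    def test_stepwise_size_shift_detected(self):
        rng = np.random.default_rng(0)
        # population B shifted +20 bp at every locus: strong size signal,
        # same allele-identity differentiation
        base = 100 + 2 * rng.integers(0, 4, size=(30, 5, 2))
        geno = np.concatenate([base, base + 20])
        t = GenotypeTable([f"i{k}" for k in range(60)], ["A"] * 30 + ["B"] * 30,
                          [f"L{j}" for j in range(5)], geno)
        res = P.allele_size_permutation_test(t, n_perm=199, seed=1)
        assert res.p_value < 0.01

    def test_null_p_values_roughly_uniform(self):
        # sizes carry no extra information when genotypes are panmictic draws
        rng = np.random.default_rng(3)
        pvals = []
        for rep in range(60):
            geno = 100 + 2 * rng.integers(0, 4, size=(40, 3, 2))
            t = GenotypeTable([f"i{k}" for k in range(40)], ["A"] * 20 + ["B"] * 20,
                              [f"L{j}" for j in range(3)], geno)
            pvals.append(P.allele_size_permutation_test(t, n_perm=59, seed=rep).p_value)
        # add-one permutation p-values are slightly conservative; demand only
        # rough uniformity
        assert 0.25 < np.mean(pvals) < 0.75


class TestMtdnaSummary:
    def test_single_haplotype(self):
        h = HaplotypeSet(["a", "b"], ["A"] * 2, ["ACGT", "ACGT"])
        hd, pi, s = P.mtdna_summary(h)
        assert (hd, pi, s) == (0.0, 0.0, 0)

    def test_two_sequences_one_difference(self):
        h = HaplotypeSet(["a", "b"], ["A"] * 2, ["A" * 99 + "C", "A" * 100])
        hd, pi, s = P.mtdna_summary(h)
        assert hd == pytest.approx(1.0)
        assert pi == pytest.approx(0.01)
        assert s == 1

    def test_gap_sites_pairwise_deleted(self):
        h = HaplotypeSet(["a", "b"], ["A"] * 2, ["AC-T", "ACGT"])
        _, pi, s = P.mtdna_summary(h)
        assert pi == 0.0 and s == 0

    def test_hd_invariant_to_relabeling(self, small_alignment):
        hd1, _, _ = P.mtdna_summary(small_alignment)
        reordered = HaplotypeSet(
            small_alignment.sequence_ids[::-1],
            small_alignment.populations[::-1],
            small_alignment.sequences[::-1],
        )
        hd2, _, _ = P.mtdna_summary(reordered)
        assert hd1 == pytest.approx(hd2)


class TestNeutralityTests:
    def test_d_undefined_without_segregating_sites(self):
        h = HaplotypeSet(list("abc"), ["A"] * 3, ["ACGT"] * 3)
        assert math.isnan(P.tajimas_d(h))

    def test_star_expansion_gives_negative_d(self):
        negatives = 0
        for seed in range(30):
            h = simulate_haplotypes(1, 10, length=300, shared_fraction=0.0,
                                    haplotypes_per_pop=1, singleton_excess=5,
                                    seed=seed)
            if P.tajimas_d(h) < 0:
                negatives += 1
        assert negatives >= 28

    def test_fus_fs_matches_exact_ewens_enumeration(self):
        from sympy.functions.combinatorial.numbers import stirling

        h = HaplotypeSet([f"s{i}" for i in range(5)], ["A"] * 5,
                         ["AAAA", "AAAC", "AACC", "AAAA", "CAAA"])
        theta = P.mean_pairwise_differences(h)
        n, k = 5, 4
        rising = 1.0
        for i in range(n):
            rising *= theta + i
        probs = [
            float(stirling(n, j, kind=1, signed=False)) * theta**j / rising
            for j in range(n + 1)
        ]
        sp = sum(probs[k:])
        expect = math.log(sp / (1 - sp))
        assert P.fus_fs(h) == pytest.approx(expect, rel=1e-9)

    def test_neutral_fixtures_keep_d_in_band(self):
        inside = total = 0
        for seed in range(50):
            h = simulate_haplotypes(1, 15, length=300, shared_fraction=0.0,
                                    haplotypes_per_pop=4, seed=seed)
            d = P.tajimas_d(h)
            if math.isnan(d):
                continue
            total += 1
            if -2 < d < 2:
                inside += 1
        assert total >= 40 and inside / total >= 0.9


class TestSummaryTables:
    def test_bounds_and_columns(self):
        rng = np.random.default_rng(11)
        t = random_genotype_table(rng, n_pops=3, n_per_pop=15, n_loci=6,
                                  missing_rate=0.05)
        haps = simulate_haplotypes(3, 8, length=200, shared_fraction=0.3, seed=1)
        # align population names with the genotype table ("pop00" -> "p0")
        rename = {f"pop{k:02d}": f"p{k}" for k in range(3)}
        haps = HaplotypeSet(
            haps.sequence_ids, [rename[p] for p in haps.populations], haps.sequences)
        df = P.diversity_summary(t, haps, rarefaction_genes=10)
        assert set(df["population"]) == {"p0", "p1", "p2"}
        for col in ("He", "Ho", "Hd"):
            assert ((df[col] >= 0) & (df[col] <= 1)).all()
        assert (df["AR"] >= 1).all()
        hl = P.homozygosity_by_locus(t)
        ok = np.isfinite(hl)
        assert ((hl[ok] >= 0) & (hl[ok] <= 1)).all()
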