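import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from mhcdepth import (
    AlleleTable,
    GenotypeMatrix,
    HaplotypeSet,
    SiteRecord,
    aggregate_gene_table,
    allelic_diversity,
    assign_alleles,
    classify_site_effects,
    filter_rare_alleles,
    load_koala_gene_table,
    nucleotide_diversity,
    weir_cockerham_fst,
)
from tests.conftest import make_matrix


def hapset(seq_counts, gene="UA"):
    """HaplotypeSet with each sequence repeated count times (one hap per
    pseudo-individual, alternating hap index to stay unique)."""
    entries = []
    i = 0
    for seq, count in seq_counts:
        for _ in range(count):
            entries.append((f"K{i // 2}", i % 2 + 1, seq))
            i += 1
    return HaplotypeSet(gene, entries)


class TestAssignAlleles:
    def test_counts_and_label_order(self):
        table = assign_alleles(hapset([("AAAA", 4), ("CCCC", 2)]))
        assert list(table.alleles) == ["H1", "H2"]
        assert table.alleles["H1"] == "AAAA"
        assert table.total_counts().tolist() == [4, 2]

    def test_tie_broken_lexicographically(self):
        table = assign_alleles(hapset([("CCCC", 2), ("AAAA", 2)]))
        assert table.alleles["H1"] == "AAAA"

    def test_single_allele(self):
        table = assign_alleles(hapset([("ACGT", 6)]))
        assert table.n_alleles == 1
        assert allelic_diversity(table.total_counts()) == 0.0

    def test_unresolved_precondition(self):
        with pytest.raises(ValueError, match="unresolved"):
            assign_alleles(hapset([("ACNT", 2)]))

    def test_per_region_counts(self):
        hs = hapset([("AAAA", 4), ("CCCC", 2)])
        region_of = {f"K{i}": ("north" if i < 2 else "south") for i in range(3)}
        table = assign_alleles(hs, region_of)
        assert table.counts.loc["H1", "north"] == 4
        assert table.counts.loc["H2", "south"] == 2


class TestFilterRareAlleles:
    def test_count_four_of_900_removed(self):
        table = assign_alleles(hapset([("AAAA", 896), ("CCCC", 4)]))
        out = filter_rare_alleles(table)
        assert list(out.alleles) == ["H1"]
        assert out.n_sequences == 896

    def test_count_five_of_900_retained(self):
        table = assign_alleles(hapset([("AAAA", 895), ("CCCC", 5)]))
        out = filter_rare_alleles(table)
        assert list(out.alleles) == ["H1", "H2"]

    def test_count_one_of_100_retained(self):
        table = assign_alleles(hapset([("AAAA", 99), ("CCCC", 1)]))
        assert filter_rare_alleles(table).n_alleles == 2

    def test_label_order_preserved(self):
        table = assign_alleles(
            hapset([("AAAA", 500), ("CCCC", 300), ("GGGG", 96), ("TTTT", 4)])
        )
        out = filter_rare_alleles(table)
        assert list(out.alleles) == ["H1", "H2", "H3"]

    def test_all_removed_errors(self):
        table = assign_alleles(hapset([("AAAA", 2), ("CCCC", 2)]))
        with pytest.raises(ValueError):
            filter_rare_alleles(table, min_freq=0.9)


def pi_brute(seqs):
    tot, pairs = 0.0, 0
    for a, b in itertools.combinations(seqs, 2):
        tot += sum(x != y for x, y in zip(a, b)) / len(a)
        pairs += 1
    return tot / pairs


def h_brute(counts):
    # probability two sequences drawn without replacement carry different alleles
    labels = [i for i, c in enumerate(counts) for _ in range(c)]
    diff = sum(a != b for a, b in itertools.permutations(labels, 2))
    n = len(labels)
    return diff / (n * (n - 1))


class TestDiversityStatistics:
    def test_two_sequences_one_difference(self):
        seqs = ["A" * 100, "A" * 99 + "G"]
        assert nucleotide_diversity(seqs) == pytest.approx(0.01)

    def test_identical_sequences(self):
        assert nucleotide_diversity(["ACGT"] * 5) == 0.0

    def test_four_sequences_match_brute_force(self):
        seqs = ["ACGTACGTAC", "ACGTACGTAG", "TCGTACGAAC", "ACGAACGTAC"]
        assert nucleotide_diversity(seqs) == pytest.approx(pi_brute(seqs), abs=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(["ACG", "ACGT"])

    def test_allelic_diversity_values(self):
        assert allelic_diversity([10]) == 0.0
        assert allelic_diversity([1, 1]) == pytest.approx(1.0)
        assert allelic_diversity([450, 450]) == pytest.approx(0.50056, abs=5e-6)

    def test_random_sets_match_enumeration_oracles(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 8))
            L = int(rng.integers(5, 20))
            seqs = ["".join(rng.choice(list("ACGT"), L)) for _ in range(n)]
            assert nucleotide_diversity(seqs) == pytest.approx(
                pi_brute(seqs), abs=1e-12
            )
            counts = rng.integers(1, 6, size=int(rng.integers(2, 5)))
            assert allelic_diversity(counts) == pytest.approx(
                h_brute(list(counts)), abs=1e-12
            )


class TestSnpEffect:
    def test_synonymous_and_nonsynonymous(self):
        # GCT (Ala): third-position C is synonymous, second-position T->V is not
        ref = "GCTAAA"
        assert classify_site_effects(ref, [(2, "T", "C")]) == ["synonymous"]
        assert classify_site_effects(ref, [(1, "C", "T")]) == ["nonsynonymous"]

    def test_minus_strand_matches_full_translation_oracle(self):
        rng = np.random.default_rng(1)
        genomic = "".join(rng.choice(list("ACGT"), 12))
        for offset in range(12):
            ref = genomic[offset]
            for alt in "ACGT":
                if alt == ref:
                    continue
                mutated = genomic[:offset] + alt + genomic[offset + 1 :]
                aa_ref = str(Seq(genomic).reverse_complement().translate())
                aa_alt = str(Seq(mutated).reverse_complement().translate())
                expected = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
                got = classify_site_effects(genomic, [(offset, ref, alt)], strand="-")
                assert got == [expected], (offset, ref, alt)

    def test_partial_codon_indeterminate(self):
        # frame offset 1: position 0 precedes the first complete codon
        assert classify_site_effects("GCTA", [(0, "G", "A")], frame_offset=1) == [
            "indeterminate"
        ]

    def test_reference_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            classify_site_effects("GCT", [(0, "A", "C")])


class TestWeirCockerhamFst:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([0, 1, 2], p=[0.49, 0.42, 0.09], size=(20, 400)).astype(
            np.int8
        )
        labels = ["p1"] * 200 + ["p2"] * 200
        m = make_matrix(calls, individuals=[f"K{i}" for i in range(400)],
                        region_labels=labels)
        _, fst = weir_cockerham_fst(m)
        assert abs(fst) < 0.02

    def test_fixed_difference_gives_one(self):
        calls = np.concatenate(
            [np.full((1, 100), 2, np.int8), np.zeros((1, 100), np.int8)], axis=1
        )
        labels = ["p1"] * 100 + ["p2"] * 100
        m = make_matrix(calls, individuals=[f"K{i}" for i in range(200)],
                        region_labels=labels)
        _, fst = weir_cockerham_fst(m)
        assert fst == pytest.approx(1.0)

    def test_toy_fixture_matches_hand_computed_components(self):
        # pop1 genotypes 0,0,1,1,2 ; pop2 genotypes 0,1,1,1,0
        # hand evaluation of the 1984 formulas:
        # n_bar=5, n_c=5, p_bar=0.35, s2=0.005, h_bar=0.5
        # a = -0.02, b = 0.0, c = 0.25, fst = -0.02/0.23
        calls = np.array([[0, 0, 1, 1, 2, 0, 1, 1, 1, 0]], dtype=np.int8)
        labels = ["p1"] * 5 + ["p2"] * 5
        m = make_matrix(calls, individuals=[f"K{i}" for i in range(10)],
                        region_labels=labels)
        per_site, fst = weir_cockerham_fst(m)
        assert per_site.a.iloc[0] == pytest.approx(-0.02, abs=1e-12)
        assert per_site.b.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert per_site.c.iloc[0] == pytest.approx(0.25, abs=1e-12)
        assert fst == pytest.approx(-0.02 / 0.23, abs=1e-12)

    def test_monomorphic_sites_excluded(self):
        calls = np.zeros((3, 10), dtype=np.int8)
        calls[1, :4] = 1  # one polymorphic site
        labels = ["p1"] * 5 + ["p2"] * 5
        m = make_matrix(calls, individuals=[f"K{i}" for i in range(10)],
                        region_labels=labels)
        per_site, _ = weir_cockerham_fst(m)
        assert len(per_site) == 1 and per_site.pos.iloc[0] == m.sites[1].pos

    def test_monotone_in_simulated_differentiation(self):
        from scipy.stats import spearmanr

        from mhcdepth import default_config, simulate_truth

        levels = np.linspace(0.0, 0.6, 10)
        fsts = []
        for d in levels:
            cfg = default_config(
                seed=4,
                n_regions=4,
                n_individuals_per_region=25,
                differentiation=float(d),
            )
            _, fst = weir_cockerham_fst(simulate_truth(cfg).true_genotypes())
            fsts.append(fst)
        assert spearmanr(levels, fsts).statistic > 0.9


class TestAggregateGeneTable:
    def test_published_koala_aggregates(self):
        table = load_koala_gene_table()
        agg = aggregate_gene_table(table)
        assert agg["overall"]["n_alleles"]["sum"] == 180
        assert agg["class_I"]["n_alleles"]["sum"] == 75
        assert agg["class_II"]["n_alleles"]["sum"] == 105
        assert agg["overall"]["n_alleles"]["mean"] == 7.5
        assert agg["overall"]["n_alleles"]["max"] == 27
        assert agg["overall"]["n_snps_nonsynonymous"]["sum"] == 164
        assert agg["overall"]["n_snps_nonsynonymous"]["mean"] == 6.83
        assert agg["overall"]["n_snps"]["min"] == 1
        assert agg["overall"]["n_snps"]["max"] == 53

    def test_from_stats_objects(self):
        from mhcdepth import GeneDiversityStats

        stats = [
            GeneDiversityStats("a", 10, 3, 1, 0.01, 2, 0.5),
            GeneDiversityStats("b", 10, 5, 2, 0.03, 4, 0.6),
        ]
        agg = aggregate_gene_table(stats)
        assert agg["overall"]["n_alleles"]["sum"] == 6
        assert agg["overall"]["pi"]["mean"] == pytest.approx(0.02, abs=1e-9)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_gene_table([])
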