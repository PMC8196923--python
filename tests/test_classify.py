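"""Database mapping, confidence tiers, OI detection, curation rules."""

import itertools

import numpy as np
import pytest

from igmine.calling import AlleleCall
from igmine.classify import (
    GeneCategoryMap,
    assign_confidence,
    detect_oi_genes,
    filter_false_positives,
    map_to_known,
    pairwise_p_distances,
)
from igmine.core_io import (
    CodingSegment,
    GeneAnnotation,
    IgmineError,
    KnownAlleleRecord,
    KnownVariantSiteList,
)


def allele(seq, support=10, gene="IGHV1-8", allele_id=None, signature=(), tier="AS2"):
    return AlleleCall(
        gene_name=gene,
        allele_id=allele_id or f"{gene}_01",
        sequence=seq,
        support_total=support,
        supporters=tuple((f"S{i}", 0) for i in range(support)),
        variant_signature=signature,
        tier=tier,
    )


class TestMapToKnown:
    def test_full_length_exact_match(self):
        a = allele("ACGTACGT")
        db = [KnownAlleleRecord("IMGT", "X*01", "ACGTACGT", "full_with_leader")]
        assert map_to_known(a, db) == [("IMGT", "X*01")]

    def test_v_region_only_substring_match(self):
        a = allele("AAACGTACGTTT")
        db = [KnownAlleleRecord("IgPdb", "X*01", "CGTACG", "v_region_only")]
        assert map_to_known(a, db) == [("IgPdb", "X*01")]

    def test_single_mismatch_anywhere_fails(self):
        a = allele("ACGTACGT")
        db = [
            KnownAlleleRecord("IMGT", "X*01", "ACGTACGA", "full_with_leader"),
            KnownAlleleRecord("IgPdb", "X*02", "ACGTACGA", "v_region_only"),
        ]
        assert map_to_known(a, db) == []

    def test_full_length_requires_equality_not_substring(self):
        a = allele("AAACGTACGTTT")
        db = [KnownAlleleRecord("IMGT", "X*01", "CGTACG", "full_with_leader")]
        assert map_to_known(a, db) == []


class TestAssignConfidence:
    @pytest.mark.parametrize(
        "support,known,expected",
        [
            (19, False, "AS2"),
            (100, False, "AS2"),
            (18, False, "AS3"),
            (7, False, "AS3"),
            (6, False, "DISCARDED"),
            (1, False, "DISCARDED"),
            (4, True, "AS1"),
            (3, True, "DISCARDED"),
            (5008, True, "AS1"),
        ],
    )
    def test_tier_boundaries(self, support, known, expected):
        assert assign_confidence(allele("ACGT", support=support), known) == expected

    def test_threshold_monotonicity(self):
        """Raising the novel-support thresholds never grows the novel set."""
        supports = list(range(1, 40))
        def novel_count(min_rare, min_frequent):
            return sum(
                assign_confidence(
                    allele("ACGT", support=s), False,
                    min_rare=min_rare, max_rare=min_frequent - 1,
                    min_frequent=min_frequent,
                ) in ("AS2", "AS3")
                for s in supports
            )
        base = novel_count(7, 19)
        assert novel_count(8, 19) <= base
        assert novel_count(7, 25) == base  # AS2/AS3 boundary shifts, union fixed
        assert novel_count(10, 25) <= base


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate(seq, k, rng):
    seq = list(seq)
    for pos in rng.choice(len(seq), size=k, replace=False):
        seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
    return "".join(seq)


class TestDetectOI:
    def test_identical_pair_is_oi(self):
        rng = np.random.default_rng(0)
        a = random_seq(rng, 300)
        seqs = {"G1": a, "G2": a, "G3": mutate(a, 60, rng), "G4": random_seq(rng, 300)}
        cats = detect_oi_genes(seqs)
        assert cats.category("G1") == "OI" and cats.category("G2") == "OI"
        assert cats.category("G3") == "SE" and cats.category("G4") == "SE"
        assert frozenset({"G1", "G2"}) in cats.oi_groups

    def test_one_percent_divergence_is_oi_ten_percent_is_not(self):
        rng = np.random.default_rng(1)
        a = random_seq(rng, 300)
        seqs = {
            "close1": a,
            "close2": mutate(a, 3, rng),    # p-distance 0.01
            "far": mutate(a, 30, rng),      # p-distance 0.10
            "out1": random_seq(rng, 300),
            "out2": random_seq(rng, 300),
        }
        # oracle: hand-computed p-distance matrix
        names, mat = pairwise_p_distances(seqs)
        i, j = names.index("close1"), names.index("close2")
        assert mat[i, j] == pytest.approx(3 / 300)
        cats = detect_oi_genes(seqs)
        assert cats.category("close1") == "OI" and cats.category("close2") == "OI"
        assert cats.category("far") == "SE"

    def test_permutation_invariance_and_symmetry(self):
        rng = np.random.default_rng(2)
        a = random_seq(rng, 300)
        base = {
            "G1": a, "G2": mutate(a, 2, rng),
            "G3": random_seq(rng, 300), "G4": random_seq(rng, 300),
        }
        reference = detect_oi_genes(base)
        for perm in itertools.permutations(base):
            shuffled = {k: base[k] for k in perm}
            got = detect_oi_genes(shuffled)
            assert got.categories == reference.categories
            assert sorted(map(sorted, got.oi_groups)) == sorted(
                map(sorted, reference.oi_groups)
            )

    def test_two_sequences_fall_back_to_direct_distance(self):
        rng = np.random.default_rng(3)
        a = random_seq(rng, 300)
        cats = detect_oi_genes({"G1": a, "G2": mutate(a, 3, rng)})
        assert cats.category("G1") == "OI"
        cats = detect_oi_genes({"G1": a, "G2": mutate(a, 30, rng)})
        assert cats.category("G1") == "SE"

    def test_fixed_pairs_become_ga_even_if_similar(self):
        rng = np.random.default_rng(4)
        a = random_seq(rng, 300)
        seqs = {"P1": a, "P2": mutate(a, 1, rng), "G3": random_seq(rng, 300)}
        cats = detect_oi_genes(seqs, group_gene_pairs=[("P1", "P2")])
        assert cats.category("P1") == "GA" and cats.category("P2") == "GA"
        assert cats.oi_groups == []

    def test_oi_relation_transitively_closed(self):
        rng = np.random.default_rng(5)
        a = random_seq(rng, 600)
        seqs = {
            "G1": a,
            "G2": mutate(a, 5, rng),
            "G3": mutate(a, 5, rng),
            "out": random_seq(rng, 600),
        }
        cats = detect_oi_genes(seqs)
        groups = [g for g in cats.oi_groups if "G1" in g]
        assert groups and groups[0] == frozenset({"G1", "G2", "G3"})


def j_gene(name="IGHJ1", start=0, end=9):
    return GeneAnnotation(
        gene_name=name, locus="IGH", chrom="chr14", start=start, end=end,
        strand="+", gene_type="J", functionality="functional",
        coding_segments=(CodingSegment(start, end, 0),),
    )


class TestFilterRules:
    def test_rule1_removes_premature_stop_in_functional_gene(self):
        gene = j_gene()
        bad = allele("ATGTAAGCA", gene="IGHJ1", signature=((3, "G", "T"),))
        ok = allele("ATGGGAGCA", gene="IGHJ1", allele_id="IGHJ1_02")
        retained, removed = filter_false_positives(
            [bad, ok],
            KnownVariantSiteList(frozenset({("chr14", 3, "G", "T")})),
            GeneCategoryMap(categories={"IGHJ1": "SE"}),
            [],
            {"IGHJ1": gene},
        )
        assert [r.allele.allele_id for r in removed] == ["IGHJ1_01"]
        assert removed[0].reasons == ("STOP_CODON",)
        assert [a.allele_id for a in retained] == ["IGHJ1_02"]

    def test_rule1_exempts_pseudogenes(self):
        gene = GeneAnnotation(
            gene_name="IGHJ1", locus="IGH", chrom="chr14", start=0, end=9,
            strand="+", gene_type="J", functionality="pseudogene",
            coding_segments=(CodingSegment(0, 9, 0),),
        )
        bad = allele("ATGTAAGCA", gene="IGHJ1", signature=((3, "G", "T"),))
        retained, removed = filter_false_positives(
            [bad], KnownVariantSiteList(frozenset({("chr14", 3, "G", "T")})),
            GeneCategoryMap(categories={"IGHJ1": "SE"}), [], {"IGHJ1": gene},
        )
        assert removed == [] and len(retained) == 1

    def test_rule2_removes_unlisted_variant_but_exempts_as1(self):
        gene = j_gene()
        sig = ((4, "G", "A"),)
        novel = allele("ATGGAAGCA", gene="IGHJ1", signature=sig, tier="AS3")
        known = allele(
            "ATGGAAGCA", gene="IGHJ1", allele_id="IGHJ1_02", signature=sig, tier="AS1"
        )
        empty_sites = KnownVariantSiteList(frozenset())
        retained, removed = filter_false_positives(
            [novel, known], empty_sites,
            GeneCategoryMap(categories={"IGHJ1": "SE"}), [], {"IGHJ1": gene},
        )
        assert [r.allele.allele_id for r in removed] == ["IGHJ1_01"]
        assert removed[0].reasons == ("UNSUPPORTED_VARIANT",)
        assert [a.allele_id for a in retained] == ["IGHJ1_02"]

    def test_rule2_retains_fully_listed_allele(self):
        gene = j_gene()
        sig = ((4, "G", "A"),)
        novel = allele("ATGGAAGCA", gene="IGHJ1", signature=sig, tier="AS3")
        retained, removed = filter_false_positives(
            [novel], KnownVariantSiteList(frozenset({("chr14", 4, "G", "A")})),
            GeneCategoryMap(categories={"IGHJ1": "SE"}), [], {"IGHJ1": gene},
        )
        assert removed == [] and len(retained) == 1

    def test_unknown_gene_rejected(self):
        with pytest.raises(IgmineError, match="unknown gene"):
            filter_false_positives(
                [allele("ACGT")], KnownVariantSiteList(frozenset()),
                GeneCategoryMap(categories={}), [], {},
            )

    def test_rule3_shared_exclusive_mutation_across_group(self):
        """One IGHA1 allele and two IGHA2 alleles share an exclusive mutation
        at the same aligned position: all three are removed, none else."""
        rng = np.random.default_rng(6)
        base = random_seq(rng, 120)
        # make the toy C genes non-functional so rule 1 stays out of the way
        genes = {
            name: GeneAnnotation(
                gene_name=name, locus="IGH", chrom="chr14", start=s, end=s + 120,
                strand="+", gene_type="C", functionality="ORF",
            )
            for name, s in (("IGHA1", 0), ("IGHA2", 1000))
        }
        a2_base = mutate(base, 3, rng)
        shared_pos = 60
        shared_alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[base[shared_pos]]
        def put(seq, pos, alt):
            return seq[:pos] + alt + seq[pos + 1 :]
        a1_bad = allele(put(base, shared_pos, shared_alt), gene="IGHA1",
                        allele_id="IGHA1_02", tier="AS3")
        a2_bad1 = allele(put(a2_base, shared_pos, shared_alt), gene="IGHA2",
                         allele_id="IGHA2_02", tier="AS3")
        a2_bad2 = allele(put(put(a2_base, shared_pos, shared_alt), 90,
                             {"A": "C", "C": "G", "G": "T", "T": "A"}[a2_base[90]]),
                         gene="IGHA2", allele_id="IGHA2_03", tier="AS3")
        a1_ok = allele(base, gene="IGHA1", allele_id="IGHA1_01", tier="AS1")
        a2_ok = allele(a2_base, gene="IGHA2", allele_id="IGHA2_01", tier="AS1")
        dbs = [
            KnownAlleleRecord("IMGT", "IGHA1*01", base, "full_with_leader"),
            KnownAlleleRecord("IMGT", "IGHA2*01", a2_base, "full_with_leader"),
        ]
        cats = GeneCategoryMap(
            categories={"IGHA1": "OI", "IGHA2": "OI"},
            oi_groups=[frozenset({"IGHA1", "IGHA2"})],
        )
        retained, removed = filter_false_positives(
            [a1_ok, a1_bad, a2_ok, a2_bad1, a2_bad2],
            KnownVariantSiteList(frozenset()), cats, dbs, genes,
        )
        removed_ids = sorted(r.allele.allele_id for r in removed)
        assert removed_ids == ["IGHA1_02", "IGHA2_02", "IGHA2_03"]
        assert all(r.reasons == ("SHARED_GROUP_MUTATION",) for r in removed)
        assert sorted(a.allele_id for a in retained) == ["IGHA1_01", "IGHA2_01"]

    def test_rule3_db_attested_mutation_not_removed(self):
        """The same shared mutation is safe when a database allele carries it."""
        rng = np.random.default_rng(7)
        base = random_seq(rng, 120)
        genes = {
            name: GeneAnnotation(
                gene_name=name, locus="IGH", chrom="chr14", start=s, end=s + 120,
                strand="+", gene_type="C", functionality="ORF",
            )
            for name, s in (("IGHA1", 0), ("IGHA2", 1000))
        }
        a2_base = mutate(base, 3, rng)
        pos, alt = 60, {"A": "C", "C": "G", "G": "T", "T": "A"}[base[60]]
        def put(seq):
            return seq[:pos] + alt + seq[pos + 1 :]
        a1_m = allele(put(base), gene="IGHA1", allele_id="IGHA1_02", tier="AS3")
        a2_m = allele(put(a2_base), gene="IGHA2", allele_id="IGHA2_02", tier="AS3")
        dbs = [
            KnownAlleleRecord("IMGT", "IGHA1*01", base, "full_with_leader"),
            KnownAlleleRecord("IMGT", "IGHA1*02", put(base), "full_with_leader"),
            KnownAlleleRecord("IMGT", "IGHA2*01", a2_base, "full_with_leader"),
        ]
        cats = GeneCategoryMap(
            categories={"IGHA1": "OI", "IGHA2": "OI"},
            oi_groups=[frozenset({"IGHA1", "IGHA2"})],
        )
        retained, removed = filter_false_positives(
            [a1_m, a2_m],
            KnownVariantSiteList(frozenset()), cats, dbs, genes,
        )
        assert removed == [] and len(retained) == 2

    def test_tier_partition_on_pipeline_output(self, small_result):
        for a in small_result.all_alleles():
            assert a.tier in ("AS1", "AS2", "AS3")
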