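"""Allele calling: merging, ordering, naming, translation, stop screening."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from igmine.calling import (
    AlleleCall,
    call_alleles,
    lift_position,
    order_alleles,
    rename_ranked,
    screen_stop_codon,
    translate_allele,
)
from igmine.core_io import CodingSegment, GeneAnnotation, IgmineError
from igmine.haplotypes import HaplotypeObservation

# independent codon oracle for the translation tests (not Biopython)
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_translate(cds: str) -> str:
    return "".join(
        CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3)
    )


def obs(seq, sample, phase=0, gene="IGHV1-8", signature=()):
    return HaplotypeObservation(
        sample_id=sample, phase=phase, gene_name=gene, sequence=seq,
        variant_signature=signature,
    )


def expand(alleles):
    """Inverse of call_alleles: one observation per supporter."""
    return [
        obs(a.sequence, s, p, a.gene_name, a.variant_signature)
        for a in alleles
        for s, p in a.supporters
    ]


class TestCallAlleles:
    def test_merge_count_and_name(self):
        observations = [obs("AAAA", f"S{i}") for i in range(10)] + [
            obs("CCCC", f"T{i}") for i in range(3)
        ]
        alleles = call_alleles(observations)
        assert [(a.allele_id, a.support_total) for a in alleles] == [
            ("IGHV1-8_01", 10),
            ("IGHV1-8_02", 3),
        ]

    def test_single_class(self):
        alleles = call_alleles([obs("ACGT", f"S{i}", p) for i in range(2504) for p in (0, 1)])
        assert len(alleles) == 1
        assert alleles[0].support_total == 5008

    def test_equal_support_tie_breaks_lexicographically(self):
        observations = [obs("CCCC", f"S{i}") for i in range(3)] + [
            obs("AAAA", f"T{i}") for i in range(3)
        ]
        alleles = call_alleles(observations)
        assert alleles[0].sequence == "AAAA" and alleles[0].allele_id == "IGHV1-8_01"

    def test_empty_input_empty_output(self):
        assert call_alleles([]) == []

    def test_mixed_genes_rejected(self):
        with pytest.raises(IgmineError, match="multiple genes"):
            call_alleles([obs("AAAA", "S1"), obs("AAAA", "S2", gene="IGHV1-9")])

    def test_support_conservation(self, small_result, small_truth):
        for gene, info in small_truth["genes"].items():
            total = sum(r["support"] for r in info["alleles"])
            assert total == info["n_observations"]

    def test_idempotence_on_expansion(self):
        observations = [obs("AAAA", f"S{i}") for i in range(7)] + [
            obs("CCCC", f"T{i}") for i in range(4)
        ]
        first = call_alleles(observations)
        second = call_alleles(expand(first))
        assert [(a.allele_id, a.sequence, a.support_total, a.supporters) for a in first] == [
            (a.allele_id, a.sequence, a.support_total, a.supporters) for a in second
        ]

    def test_monotonicity_adding_observations(self):
        base = [obs("AAAA", f"S{i}") for i in range(5)] + [obs("CCCC", "T0")]
        before = {a.sequence: a.support_total for a in call_alleles(base)}
        after = {
            a.sequence: a.support_total
            for a in call_alleles(base + [obs("GGGG", "U0"), obs("AAAA", "S99")])
        }
        assert all(after[seq] >= n for seq, n in before.items())


class TestOrdering:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.text(alphabet="ACGT", min_size=4, max_size=4), st.integers(1, 5)),
            min_size=1, max_size=4, unique_by=lambda t: t[0],
        )
    )
    def test_permutation_invariance_and_bruteforce_order(self, spec):
        alleles = [
            AlleleCall(
                gene_name="G", allele_id=f"G_{i:02d}", sequence=seq,
                support_total=n, supporters=tuple((f"S{i}-{j}", 0) for j in range(n)),
                variant_signature=(),
            )
            for i, (seq, n) in enumerate(spec)
        ]
        expected = sorted(alleles, key=lambda a: (-a.support_total, a.sequence))
        for perm in itertools.permutations(alleles):
            assert order_alleles(list(perm)) == expected

    def test_rename_ranked_contiguous(self):
        alleles = [
            AlleleCall("G", "G_09", "AAAA", 5, tuple((f"S{i}", 0) for i in range(5)), ()),
            AlleleCall("G", "G_03", "CCCC", 2, (("T0", 0), ("T1", 0)), ()),
        ]
        renamed = rename_ranked(alleles)
        assert [a.allele_id for a in renamed] == ["G_01", "G_02"]


def v_gene(reference_len=30):
    """Toy V gene: coding = [0,6) + [12,30), intron in between."""
    return GeneAnnotation(
        gene_name="IGHV1-8", locus="IGH", chrom="chr14", start=0, end=reference_len,
        strand="+", gene_type="V", functionality="functional",
        coding_segments=(CodingSegment(0, 6, 0), CodingSegment(12, reference_len, 0)),
    )


def allele_for(seq, signature=()):
    return AlleleCall(
        gene_name="IGHV1-8", allele_id="IGHV1-8_01", sequence=seq,
        support_total=1, supporters=(("S1", 0),), variant_signature=signature,
    )


class TestTranslation:
    def test_single_codon(self):
        gene = GeneAnnotation(
            gene_name="IGHJ1", locus="IGH", chrom="chr14", start=0, end=3,
            strand="+", gene_type="J", functionality="functional",
            coding_segments=(CodingSegment(0, 3, 0),),
        )
        assert translate_allele(allele_for("ATG"), gene) == "M"

    def test_two_codons(self):
        gene = GeneAnnotation(
            gene_name="IGHJ1", locus="IGH", chrom="chr14", start=0, end=6,
            strand="+", gene_type="J", functionality="functional",
            coding_segments=(CodingSegment(0, 6, 0),),
        )
        assert translate_allele(allele_for("ATGGCC"), gene) == "MA"

    def test_spliced_frame_offset_against_codon_oracle(self):
        #         coding1     intron    coding2 (frame offset 1 trimmed)
        seq = "ATGGCC" + "TTTTTT" + "AATGCACGTACGTACGTA"
        gene = GeneAnnotation(
            gene_name="IGHV1-8", locus="IGH", chrom="chr14", start=0, end=30,
            strand="+", gene_type="V", functionality="functional",
            coding_segments=(CodingSegment(0, 6, 1), CodingSegment(12, 30, 0)),
        )
        spliced = (seq[0:6] + seq[12:30])[1:]
        assert translate_allele(allele_for(seq), gene) == oracle_translate(spliced)

    def test_minus_strand_translates_gene_sense(self):
        from igmine.core_io import reverse_complement

        forward_seq = "ATGGCC" + "TTTTTT" + "AATGCACGTACGTACGTA"
        gene = GeneAnnotation(
            gene_name="IGHV1-8", locus="IGH", chrom="chr14", start=0, end=30,
            strand="-", gene_type="V", functionality="functional",
            coding_segments=(CodingSegment(0, 18, 0), CodingSegment(24, 30, 0)),
        )
        # gene-sense sequence is the reverse complement of the forward strand
        allele = allele_for(reverse_complement(forward_seq))
        spliced = reverse_complement(forward_seq[0:18] + forward_seq[24:30])
        assert translate_allele(allele, gene) == oracle_translate(spliced)


class TestStopScreen:
    def test_canonical_stop_detected(self):
        gene = GeneAnnotation(
            gene_name="IGHJ1", locus="IGH", chrom="chr14", start=0, end=9,
            strand="+", gene_type="J", functionality="functional",
            coding_segments=(CodingSegment(0, 9, 0),),
        )
        assert screen_stop_codon(allele_for("ATGTAAGCC"), gene) is True
        assert screen_stop_codon(allele_for("ATGGCCGCA"), gene) is False
        # a stop at the natural end is not premature
        assert screen_stop_codon(allele_for("ATGGCCTAA"), gene) is False

    def test_snp_creating_tga_detected(self):
        gene = GeneAnnotation(
            gene_name="IGHJ1", locus="IGH", chrom="chr14", start=0, end=9,
            strand="+", gene_type="J", functionality="functional",
            coding_segments=(CodingSegment(0, 9, 0),),
        )
        healthy = "ATGTGGGCA"  # M W A
        mutated = "ATGTGAGCA"  # TGG -> TGA
        assert oracle_translate(mutated)[1] == "*"
        assert screen_stop_codon(allele_for(healthy), gene) is False
        assert screen_stop_codon(allele_for(mutated, ((5, "G", "A"),)), gene) is True

    def test_short_coding_rejected(self):
        gene = GeneAnnotation(
            gene_name="IGHJ1", locus="IGH", chrom="chr14", start=0, end=2,
            strand="+", gene_type="J", functionality="functional",
            coding_segments=(CodingSegment(0, 2, 0),),
        )
        with pytest.raises(IgmineError, match="codon"):
            screen_stop_codon(allele_for("AT"), gene)


class TestLiftPosition:
    def test_insertion_shifts_downstream_only(self):
        gene = v_gene()
        signature = ((4, "A", "ATT"),)
        assert lift_position(gene, signature, 3) == 3
        assert lift_position(gene, signature, 10) == 12

    def test_deletion_clamps_inside_span(self):
        gene = v_gene()
        signature = ((4, "AGG", "A"),)
        assert lift_position(gene, signature, 10) == 8
        assert lift_position(gene, signature, 6) == 5  # inside the deleted span
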