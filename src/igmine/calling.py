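"""Collapse identical haplotypes into alleles; name, order and translate them.

An allele is a distinct reconstructed haplotype sequence over a gene
interval. Identical haplotypes are merged and their multiplicity is the
allele's support. Alleles are sorted by descending support (ties broken by
ascending sequence, for determinism) and named ``<gene>_<rank>`` with the
rank zero-padded to two digits, e.g. ``IGHV1-8_01``.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from Bio.Seq import Seq

from .core_io import GeneAnnotation, IgmineError, reverse_complement
from .haplotypes import HaplotypeObservation, Variant


@dataclass
class AlleleCall:
    gene_name: str
    allele_id: str
    sequence: str
    support_total: int
    supporters: tuple[tuple[str, int], ...]  # (sample_id, phase)
    variant_signature: tuple[Variant, ...]  # representative signature
    per_population_support: dict[str, int] = field(default_factory=dict)
    tier: str = "DISCARDED"  # AS1 | AS2 | AS3 | DISCARDED
    category: str = "SE"  # SE | GA | OI
    db_matches: tuple[tuple[str, str], ...] = ()
    curation_flags: tuple[str, ...] = ()
    protein: Optional[str] = None

    def __post_init__(self):
        if self.support_total != len(self.supporters):
            raise IgmineError(
                f"{self.allele_id}: support_total != number of supporters"
            )


def _rank_width(n_alleles: int) -> int:
    return max(2, len(str(n_alleles)))


def order_alleles(alleles: Sequence[AlleleCall]) -> list[AlleleCall]:
    """Stable total order: support descending, then sequence ascending."""
    return sorted(alleles, key=lambda a: (-a.support_total, a.sequence))


def call_alleles(observations: Sequence[HaplotypeObservation]) -> list[AlleleCall]:
    """Merge identical haplotype sequences of one gene into ranked alleles.

    The merge key is the sequence string: distinct variant signatures that
    yield the same sequence (equivalent indel placements) merge; the
    representative signature is the lexicographically smallest one.
    """
    if not observations:
        return []
    gene_names = {o.gene_name for o in observations}
    if len(gene_names) != 1:
        raise IgmineError(f"observations span multiple genes: {sorted(gene_names)}")
    gene_name = gene_names.pop()

    by_seq: dict[str, list[HaplotypeObservation]] = defaultdict(list)
    for obs in observations:
        by_seq[obs.sequence].append(obs)

    calls = []
    for seq, obs_list in by_seq.items():
        supporters = tuple(sorted((o.sample_id, o.phase) for o in obs_list))
        signature = min(o.variant_signature for o in obs_list)
        calls.append(
            AlleleCall(
                gene_name=gene_name,
                allele_id="",
                sequence=seq,
                support_total=len(obs_list),
                supporters=supporters,
                variant_signature=signature,
            )
        )
    ordered = order_alleles(calls)
    width = _rank_width(len(ordered))
    for rank, allele in enumerate(ordered, start=1):
        allele.allele_id = f"{gene_name}_{rank:0{width}d}"
    return ordered


def rename_ranked(alleles: Sequence[AlleleCall]) -> list[AlleleCall]:
    """Re-sort and re-name a per-gene allele list (after filtering)."""
    ordered = order_alleles(alleles)
    width = _rank_width(len(ordered))
    for rank, allele in enumerate(ordered, start=1):
        allele.allele_id = f"{allele.gene_name}_{rank:0{width}d}"
    return ordered


# ---------------------------------------------------------------------------
# coordinate lifting and translation


def lift_position(gene: GeneAnnotation, signature: Sequence[Variant], pos: int) -> int:
    """Map a genomic position to an offset in the forward-built haplotype.

    Indels earlier in the gene shift downstream offsets by |alt| - |ref|.
    A position falling inside a deleted span maps to the edit site, clamped
    to the replacement's length.
    """
    shift = 0
    for vpos, ref, alt in signature:
        if vpos + len(ref) <= pos:
            shift += len(alt) - len(ref)
        elif vpos < pos:
            # inside the edited span
            return (vpos - gene.start + shift) + min(pos - vpos, len(alt))
    return pos - gene.start + shift


def spliced_coding_sequence(
    sequence: str, gene: GeneAnnotation, signature: Sequence[Variant]
) -> str:
    """Gene-sense spliced coding sequence of one allele.

    Coding segment coordinates (genomic) are lifted through the allele's
    indels; segments are concatenated in genomic order, reverse complemented
    for '-' strand genes, and the frame offset of the gene-sense first
    segment is trimmed.
    """
    if not gene.coding_segments:
        raise IgmineError(f"{gene.gene_name}: no coding segments annotated")
    forward = sequence if gene.strand == "+" else reverse_complement(sequence)
    segs = sorted(gene.coding_segments, key=lambda s: s.start)
    parts = []
    for seg in segs:
        a = lift_position(gene, signature, seg.start)
        b = lift_position(gene, signature, seg.end)
        parts.append(forward[a:b])
    spliced = "".join(parts)
    first = segs[0] if gene.strand == "+" else segs[-1]
    if gene.strand == "-":
        spliced = reverse_complement(spliced)
    spliced = spliced[first.frame :]
    if len(spliced) < 3:
        raise IgmineError(f"{gene.gene_name}: coding sequence shorter than one codon")
    return spliced


def translate_allele(allele: AlleleCall, gene: GeneAnnotation) -> str:
    """Translate the spliced coding sequence with the standard genetic code."""
    cds = spliced_coding_sequence(allele.sequence, gene, allele.variant_signature)
    cds = cds[: len(cds) - len(cds) % 3]
    return str(Seq(cds).translate())


def screen_stop_codon(allele: AlleleCall, gene: GeneAnnotation) -> bool:
    """True iff the translated coding sequence stops before its natural end."""
    protein = translate_allele(allele, gene)
    return "*" in protein[:-1]
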