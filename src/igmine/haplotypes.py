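"""Per-sample, per-phase reconstruction of gene-length haplotype sequences.

A diploid sample contributes two haplotypes per gene, obtained by applying
the phased non-reference alleles of one phase to the reference slice of the
gene interval. Sequences are stored in gene-sense orientation (reverse
complemented for '-' strand genes) so downstream translation and database
comparison are orientation-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core_io import (
    GeneAnnotation,
    IgmineError,
    PhasedVariantRecord,
    ReferenceGenome,
    reverse_complement,
)

logger = logging.getLogger(__name__)

Variant = tuple[int, str, str]  # (genomic pos, ref, alt)


@dataclass(frozen=True)
class HaplotypeObservation:
    sample_id: str
    phase: int  # 0 | 1
    gene_name: str
    sequence: str  # gene-sense orientation
    variant_signature: tuple[Variant, ...]  # ascending genomic position

    def __post_init__(self):
        if not self.sequence:
            raise IgmineError("empty haplotype sequence")
        positions = [v[0] for v in self.variant_signature]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise IgmineError("variant signature positions must strictly increase")


def build_haplotype(
    sample_id: str,
    phase: int,
    gene: GeneAnnotation,
    reference_slice: str,
    variants: Sequence[Variant],
) -> HaplotypeObservation:
    """Apply one phase's non-reference alleles to the gene's reference slice.

    Edits are applied in descending genomic position so earlier offsets stay
    valid; overlapping ref spans on the same phase are rejected, which makes
    this equivalent to simultaneous application.
    """
    if len(reference_slice) != gene.length:
        raise IgmineError(
            f"{gene.gene_name}: reference slice length {len(reference_slice)} "
            f"!= gene interval length {gene.length}"
        )
    ordered = sorted(variants, key=lambda v: v[0])
    for (p1, r1, _), (p2, _, _) in zip(ordered, ordered[1:]):
        if p1 + len(r1) > p2:
            raise IgmineError(
                f"{gene.gene_name} sample {sample_id} phase {phase}: conflicting "
                f"edits at positions {p1} and {p2}"
            )
    seq = reference_slice
    for pos, ref, alt in reversed(ordered):
        off = pos - gene.start
        if off < 0 or pos + len(ref) > gene.end:
            raise IgmineError(
                f"{gene.gene_name}: variant at {pos} crosses the gene boundary"
            )
        if seq[off : off + len(ref)] != ref:
            raise IgmineError(
                f"{gene.gene_name}: REF mismatch at {pos}: VCF says {ref!r}, "
                f"reference has {reference_slice[off : off + len(ref)]!r}"
            )
        seq = seq[:off] + alt + seq[off + len(ref) :]
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return HaplotypeObservation(
        sample_id=sample_id,
        phase=phase,
        gene_name=gene.gene_name,
        sequence=seq.upper(),
        variant_signature=tuple(ordered),
    )


def variants_in_gene(
    records: Iterable[PhasedVariantRecord], gene: GeneAnnotation
) -> list[PhasedVariantRecord]:
    """Records whose REF span lies inside the gene interval.

    A record whose span crosses the gene boundary is an annotation problem
    and raises rather than being silently truncated.
    """
    out = []
    for rec in records:
        if rec.chrom != gene.chrom:
            continue
        if rec.pos >= gene.end or rec.end <= gene.start:
            continue
        if rec.pos < gene.start or rec.end > gene.end:
            raise IgmineError(
                f"variant {rec.chrom}:{rec.pos} (ref {rec.ref!r}) crosses the "
                f"boundary of gene {gene.gene_name}"
            )
        out.append(rec)
    return out


def extract_all_haplotypes(
    records: Sequence[PhasedVariantRecord],
    samples: Sequence[str],
    genes: Sequence[GeneAnnotation],
    reference: ReferenceGenome,
    missing_policy: str = "drop",
) -> list[HaplotypeObservation]:
    """Build every (sample, phase, gene) haplotype.

    With no missing genotypes the result holds exactly 2 x n_samples x n_genes
    observations. ``missing_policy``: 'drop' (default) removes both of a
    sample's haplotypes for any gene whose interval contains a missing call,
    with a logged warning; 'strict' raises.
    """
    observations: list[HaplotypeObservation] = []
    for gene in genes:
        ref_slice = reference.fetch(gene.chrom, gene.start, gene.end)
        gene_records = variants_in_gene(records, gene)
        for si, sample in enumerate(samples):
            gts = [rec.genotypes[si] for rec in gene_records]
            if any(a < 0 or b < 0 for a, b in gts):
                if missing_policy == "strict":
                    raise IgmineError(
                        f"missing genotype for sample {sample} in gene "
                        f"{gene.gene_name}"
                    )
                logger.warning(
                    "sample %s dropped for gene %s (missing genotype)",
                    sample,
                    gene.gene_name,
                )
                continue
            for phase in (0, 1):
                variants = [
                    (rec.pos, rec.ref, rec.alts[gt[phase] - 1])
                    for rec, gt in zip(gene_records, gts)
                    if gt[phase] > 0
                ]
                observations.append(
                    build_haplotype(sample, phase, gene, ref_slice, variants)
                )
    return observations
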