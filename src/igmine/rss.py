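"""Recombination signal sequence (RSS) extraction, localization and scoring.

An RSS is a conserved heptamer (canonically CACAGTG), a 12- or 23-bp spacer
and a conserved nonamer (canonically ACAAAAACC) flanking every V, D and J
gene: 3' of V genes, 5' of J genes, and on both sides of D genes. Windows
of 40 bases (23-bp spacer class) or 30 bases (12-bp spacer class) adjacent
to the gene boundary are extracted and orientation-normalized so that the
sequence reads from the gene boundary outward, with the canonical heptamer
nearest the boundary. Mutations in the heptamer/nonamer (especially the
first three heptamer bases, CAC) and deviating spacer lengths depress
recombination frequency, so mismatch counts, spacer length and
heptamer-to-boundary distance are reported per gene and per haplotype.

Some pseudogenes carry their RSS 10-30 bases away from the gene boundary;
the locator therefore scans up to ``boundary_slack`` (default 30) bases of
displacement, auto-extending the window so a displaced RSS still fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .core_io import (
    GeneAnnotation,
    IgmineError,
    PhasedVariantRecord,
    ReferenceGenome,
    reverse_complement,
)
from .haplotypes import extract_all_haplotypes

CANONICAL_HEPTAMER = "CACAGTG"
CANONICAL_NONAMER = "ACAAAAACC"
STOP_CODONS = ("TAA", "TAG", "TGA")

DEFAULT_BOUNDARY_SLACK = 30
DEFAULT_SPACER_SLACK = 3
WINDOW_LENGTHS = {23: 40, 12: 30}


@dataclass
class RSSRecord:
    gene_name: str
    side: str  # 5prime | 3prime
    window_sequence: str  # nominal window, boundary-outward orientation
    heptamer_offset: int
    heptamer: str
    nonamer_offset: int
    nonamer: str
    spacer_length: int
    boundary_distance: int
    heptamer_mismatches: int
    nonamer_mismatches: int
    first3_heptamer_intact: bool
    heptamer_found: bool
    stop_codon_in_gap: bool = False
    haplotype_variants: tuple = ()


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def rss_window_interval(
    gene: GeneAnnotation, side: str, extension: int = 0
) -> tuple[int, int, bool]:
    """Genomic interval of the RSS window and whether to reverse complement.

    The normalized window reads from the gene boundary outward on the strand
    where the canonical motifs appear (away-from-gene for both the 3' RSS of
    V genes and the 5' RSS of J genes).
    """
    rss = gene.rss_side(side)
    if rss is None:
        raise IgmineError(f"{gene.gene_name}: no {side} RSS annotated")
    length = WINDOW_LENGTHS[rss.spacer_class] + extension
    gene_sense_downstream = (side == "3prime")
    if gene.strand == "-":
        genomic_after_gene = not gene_sense_downstream
    else:
        genomic_after_gene = gene_sense_downstream
    if genomic_after_gene:
        start, end = gene.end, gene.end + length
    else:
        start, end = gene.start - length, gene.start
    # boundary-outward reading: forward for windows after the gene,
    # reverse-complemented for windows before it
    return start, end, not genomic_after_gene


def extract_rss_window(
    gene: GeneAnnotation,
    side: str,
    reference: ReferenceGenome,
    extension: int = 0,
) -> str:
    start, end, revcomp = rss_window_interval(gene, side, extension)
    seq = reference.fetch(gene.chrom, start, end)
    return reverse_complement(seq) if revcomp else seq


def locate_and_score(
    window: str,
    spacer_class: int,
    gene_name: str = "",
    side: str = "",
    boundary_slack: int = DEFAULT_BOUNDARY_SLACK,
    spacer_slack: int = DEFAULT_SPACER_SLACK,
    check_stop_in_gap: bool = False,
) -> RSSRecord:
    """Localize heptamer and nonamer in a boundary-outward window.

    The heptamer is the 7-mer minimizing the Hamming distance to CACAGTG
    among boundary distances 0..boundary_slack (ties to the boundary-nearest
    offset); the nonamer is the 9-mer minimizing the distance to ACAAAAACC
    within the expected spacer length +/- spacer_slack. A best heptamer with
    more than 3 mismatches is flagged not-found rather than an error.
    """
    nominal = WINDOW_LENGTHS[spacer_class]
    if len(window) < nominal:
        raise IgmineError(f"window shorter than nominal length {nominal}")
    best_h: Optional[tuple[int, int]] = None  # (mismatches, offset)
    max_h_off = min(boundary_slack, len(window) - 7)
    for off in range(max_h_off + 1):
        mm = _hamming(window[off : off + 7], CANONICAL_HEPTAMER)
        if best_h is None or mm < best_h[0]:
            best_h = (mm, off)
            if mm == 0:
                break
    h_mm, h_off = best_h
    heptamer = window[h_off : h_off + 7]
    found = h_mm <= 3

    h_end = h_off + 7
    expected_n_off = h_end + spacer_class
    best_n: Optional[tuple[int, int, int]] = None  # (mismatch, |delta|, offset)
    for n_off in range(
        max(h_end, expected_n_off - spacer_slack), expected_n_off + spacer_slack + 1
    ):
        if n_off + 9 > len(window):
            continue
        mm = _hamming(window[n_off : n_off + 9], CANONICAL_NONAMER)
        cand = (mm, abs(n_off - expected_n_off), n_off)
        if best_n is None or cand < best_n:
            best_n = cand
    if best_n is None:
        n_off = min(expected_n_off, len(window) - 9)
        best_n = (_hamming(window[n_off : n_off + 9], CANONICAL_NONAMER), 0, n_off)
    n_mm, _, n_off = best_n
    nonamer = window[n_off : n_off + 9]

    stop_in_gap = False
    if check_stop_in_gap and h_off >= 3:
        gap = window[:h_off]
        stop_in_gap = any(
            gap[i : i + 3] in STOP_CODONS for i in range(len(gap) - 2)
        )

    return RSSRecord(
        gene_name=gene_name,
        side=side,
        window_sequence=window[:nominal],
        heptamer_offset=h_off,
        heptamer=heptamer,
        nonamer_offset=n_off,
        nonamer=nonamer,
        spacer_length=n_off - h_end,
        boundary_distance=h_off,
        heptamer_mismatches=h_mm,
        nonamer_mismatches=n_mm,
        first3_heptamer_intact=heptamer[:3] == CANONICAL_HEPTAMER[:3],
        heptamer_found=found,
        stop_codon_in_gap=stop_in_gap,
    )


def scan_gene_rss(
    gene: GeneAnnotation,
    reference: ReferenceGenome,
    boundary_slack: int = DEFAULT_BOUNDARY_SLACK,
) -> list[RSSRecord]:
    """Reference-level RSS records for every annotated side of a gene."""
    records = []
    for rss in gene.rss_sides:
        window = extract_rss_window(gene, rss.side, reference, extension=boundary_slack)
        records.append(
            locate_and_score(
                window,
                rss.spacer_class,
                gene_name=gene.gene_name,
                side=rss.side,
                boundary_slack=boundary_slack,
                check_stop_in_gap=(gene.gene_type == "V" and rss.side == "3prime"),
            )
        )
    return records


def rss_haplotype_variants(
    gene: GeneAnnotation,
    side: str,
    vcf_records: Sequence[PhasedVariantRecord],
    samples: Sequence[str],
    reference: ReferenceGenome,
    boundary_slack: int = DEFAULT_BOUNDARY_SLACK,
) -> list[tuple[str, int, RSSRecord]]:
    """Per-haplotype RSS windows, scored like the reference window.

    Returns (distinct window sequence, haplotype support, scored record),
    most-supported first; reuses the haplotype engine on the window interval.
    """
    rss = gene.rss_side(side)
    if rss is None:
        raise IgmineError(f"{gene.gene_name}: no {side} RSS annotated")
    start, end, revcomp = rss_window_interval(gene, side, extension=boundary_slack)
    pseudo = GeneAnnotation(
        gene_name=f"{gene.gene_name}~rss{side}",
        locus=gene.locus,
        chrom=gene.chrom,
        start=start,
        end=end,
        strand="-" if revcomp else "+",
        gene_type=gene.gene_type,
        functionality=gene.functionality,
    )
    window_records = [
        r for r in vcf_records if r.chrom == gene.chrom and start <= r.pos < end
    ]
    observations = extract_all_haplotypes(
        window_records, samples, [pseudo], reference
    )
    from collections import Counter

    counts = Counter(o.sequence for o in observations)
    out = []
    for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        rec = locate_and_score(
            seq,
            rss.spacer_class,
            gene_name=gene.gene_name,
            side=side,
            boundary_slack=boundary_slack,
        )
        out.append((seq, n, rec))
    return out
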