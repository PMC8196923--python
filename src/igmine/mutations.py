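"""Per-gene alignments of mined and database alleles and mutation profiling.

Alleles of one gene (mined plus database records) are stacked into a
column-indexed alignment. The canonical state of each column is a
majority-rule consensus anchored on the database alleles when any exist.
Every non-consensus (column, base) observation is a *mutation*, classified
as ``known`` when some database allele carries the same base at the same
column and ``new`` otherwise. Counting is at (column, base) granularity by
default: a different substitution at a previously mutating column still
counts as new (switchable to column-only granularity).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Align import PairwiseAligner

from .calling import AlleleCall, lift_position
from .core_io import GeneAnnotation, IgmineError, KnownAlleleRecord, reverse_complement

logger = logging.getLogger(__name__)

# column key: (anchor position, insert rank); rank 0 = the anchor position
# itself, rank k>0 = k-th inserted column after it
ColumnKey = tuple[int, int]

NO_COVERAGE = "."
GAP = "-"


def _unit_cost_aligner() -> PairwiseAligner:
    return PairwiseAligner(
        mode="global",
        match_score=0,
        mismatch_score=-1,
        open_gap_score=-1,
        extend_gap_score=-1,
    )


@dataclass
class AlignedRow:
    name: str
    origin: str  # "mined" or a database source name
    cells: dict[ColumnKey, str]


@dataclass
class GeneAlignment:
    gene_name: str
    anchor: str  # consensus of modal-length mined alleles
    rows: list[AlignedRow]
    excluded: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[ColumnKey]:
        cols = set()
        for row in self.rows:
            cols.update(row.cells)
        return sorted(cols)

    def db_rows(self) -> list[AlignedRow]:
        return [r for r in self.rows if r.origin != "mined"]

    def mined_rows(self) -> list[AlignedRow]:
        return [r for r in self.rows if r.origin == "mined"]


def _stack_equal(seq: str) -> dict[ColumnKey, str]:
    return {(i, 0): c for i, c in enumerate(seq)}


def _align_to_anchor(anchor: str, seq: str) -> dict[ColumnKey, str]:
    """Global unit-cost alignment of one sequence against the anchor."""
    aln = _unit_cost_aligner().align(anchor, seq)[0]
    a_str, s_str = aln[0], aln[1]
    cells: dict[ColumnKey, str] = {}
    anchor_pos = -1  # position of the last consumed anchor base
    insert_rank = 0
    for a_ch, s_ch in zip(a_str, s_str):
        if a_ch == "-":
            insert_rank += 1
            if s_ch != "-":
                cells[(anchor_pos, insert_rank)] = s_ch
        else:
            anchor_pos += 1
            insert_rank = 0
            cells[(anchor_pos, 0)] = s_ch if s_ch != "-" else GAP
    return cells


def _anchor_partial(anchor: str, seq: str, max_divergence: float = 0.10):
    """Best min-Hamming placement of a shorter sequence inside the anchor.

    Returns (offset, mismatches) or None when the best placement diverges by
    more than ``max_divergence`` of the partial's length.
    """
    if len(seq) > len(anchor):
        return None
    best = None
    for off in range(len(anchor) - len(seq) + 1):
        mm = sum(1 for a, b in zip(anchor[off : off + len(seq)], seq) if a != b)
        if best is None or mm < best[1]:
            best = (off, mm)
            if mm == 0:
                break
    if best is None or best[1] > max_divergence * len(seq):
        return None
    return best


def _majority(chars: Sequence[str]) -> str:
    counts = Counter(chars)
    top = max(counts.values())
    return min(c for c, n in counts.items() if n == top)


def align_gene_alleles(
    mined: Sequence[AlleleCall],
    db: Sequence[KnownAlleleRecord],
    gene_name: Optional[str] = None,
) -> GeneAlignment:
    """Stack mined and database alleles of one gene into an alignment.

    Equal-length sequences stack column-for-column on the anchor (the
    majority consensus of modal-length mined alleles). Length-changing
    alleles are placed by global unit-cost alignment; V-region-only or
    partial database records are anchored by best substring placement and
    padded with no-coverage markers. Partial records diverging by more than
    10% of their length are excluded with a warning.
    """
    if not mined:
        raise IgmineError("align_gene_alleles requires at least one mined allele")
    if gene_name is None:
        gene_name = mined[0].gene_name
    lengths = Counter(len(a.sequence) for a in mined)
    modal_len = max(lengths, key=lambda L: (lengths[L], -L))
    modal_seqs = [a.sequence for a in mined if len(a.sequence) == modal_len]
    anchor = "".join(_majority([s[i] for s in modal_seqs]) for i in range(modal_len))

    rows: list[AlignedRow] = []
    excluded: list[str] = []
    for allele in mined:
        seq = allele.sequence
        cells = _stack_equal(seq) if len(seq) == modal_len else _align_to_anchor(anchor, seq)
        rows.append(AlignedRow(allele.allele_id, "mined", cells))
    for rec in db:
        name = f"{rec.source}|{rec.allele_name}"
        if rec.completeness == "full_with_leader" and len(rec.sequence) == modal_len:
            rows.append(AlignedRow(name, rec.source, _stack_equal(rec.sequence)))
        elif rec.completeness == "full_with_leader":
            rows.append(AlignedRow(name, rec.source, _align_to_anchor(anchor, rec.sequence)))
        else:
            placed = _anchor_partial(anchor, rec.sequence)
            if placed is None:
                logger.warning(
                    "db allele %s cannot be anchored in gene %s; excluded",
                    name,
                    gene_name,
                )
                excluded.append(name)
                continue
            off, _ = placed
            cells = {(off + i, 0): c for i, c in enumerate(rec.sequence)}
            rows.append(AlignedRow(name, rec.source, cells))
    return GeneAlignment(gene_name=gene_name, anchor=anchor, rows=rows, excluded=excluded)


# ---------------------------------------------------------------------------
# mutation classification


@dataclass
class Mutation:
    column: ColumnKey
    base: str
    status: str  # "known" | "new"
    region: str  # LEADER | V-REGION | INTRON | CH1.. | OTHER


@dataclass
class MutationProfile:
    gene_name: str
    alignment: GeneAlignment
    consensus: dict[ColumnKey, str]
    per_allele: dict[str, list[Mutation]]  # row name -> mutations

    def new_counts(self, name: str) -> tuple[int, int]:
        """(full-sequence, V-region-only) counts of new mutations."""
        muts = self.per_allele.get(name, [])
        full = sum(1 for m in muts if m.status == "new")
        vreg = sum(1 for m in muts if m.status == "new" and m.region == "V-REGION")
        return full, vreg


def _region_labels(gene: Optional[GeneAnnotation], anchor_len: int) -> list[str]:
    labels = ["OTHER"] * anchor_len
    if gene is None:
        return labels
    for reg in gene.regions:
        a, b = gene.to_gene_sense(reg.start, reg.end)
        for i in range(max(a, 0), min(b, anchor_len)):
            labels[i] = reg.label
    return labels


def classify_mutations(
    alignment: GeneAlignment,
    gene: Optional[GeneAnnotation] = None,
    position_only: bool = False,
) -> MutationProfile:
    """Identify mutating positions and classify them as known or new.

    Consensus per column is the majority base over database rows covering it
    when any exist, otherwise over mined rows (ties break to the
    lexicographically smallest base). A (column, base) is ``new`` iff no
    database row carries it; with ``position_only`` a column already
    mutating in a database allele makes every base at it known.
    """
    db_rows = alignment.db_rows()
    mined_rows = alignment.mined_rows()
    columns = alignment.columns
    labels = _region_labels(gene, len(alignment.anchor))

    consensus: dict[ColumnKey, str] = {}
    db_bases: dict[ColumnKey, set[str]] = defaultdict(set)
    for col in columns:
        db_chars = [r.cells[col] for r in db_rows if col in r.cells and r.cells[col] != NO_COVERAGE]
        for c in db_chars:
            db_bases[col].add(c)
        if db_chars:
            consensus[col] = _majority(db_chars)
        else:
            mined_chars = [
                r.cells.get(col, GAP) for r in mined_rows if r.cells.get(col, NO_COVERAGE) != NO_COVERAGE
            ]
            consensus[col] = _majority(mined_chars) if mined_chars else GAP

    def region_of(col: ColumnKey) -> str:
        p = col[0]
        return labels[p] if 0 <= p < len(labels) else "OTHER"

    per_allele: dict[str, list[Mutation]] = {}
    for row in alignment.rows:
        muts = []
        for col, ch in sorted(row.cells.items()):
            if ch == NO_COVERAGE or ch == consensus[col]:
                continue
            if position_only:
                known = any(
                    b != consensus[col] for b in db_bases[col]
                )
            else:
                known = ch in db_bases[col]
            muts.append(
                Mutation(column=col, base=ch, status="known" if known else "new",
                         region=region_of(col))
            )
        per_allele[row.name] = muts
    return MutationProfile(
        gene_name=alignment.gene_name,
        alignment=alignment,
        consensus=consensus,
        per_allele=per_allele,
    )


def count_new_mutations(profile: MutationProfile, allele: AlleleCall) -> tuple[int, int]:
    return profile.new_counts(allele.allele_id)


def summarize_new_mutation_counts(
    profiles: dict[str, MutationProfile], alleles_by_gene: dict[str, list[AlleleCall]]
) -> "pandas.DataFrame":
    """Table of allele counts per number of new mutating positions.

    Rows = new-mutation count; columns = full sequence vs V region only.
    """
    import pandas as pd

    full_counter: Counter = Counter()
    vreg_counter: Counter = Counter()
    for gene_name, alleles in alleles_by_gene.items():
        profile = profiles.get(gene_name)
        if profile is None:
            continue
        for allele in alleles:
            full, vreg = profile.new_counts(allele.allele_id)
            full_counter[full] += 1
            vreg_counter[vreg] += 1
    max_n = max([*full_counter, *vreg_counter, 0])
    data = {
        "new_mutations": list(range(max_n + 1)),
        "complete_sequence": [full_counter.get(i, 0) for i in range(max_n + 1)],
        "v_region_only": [vreg_counter.get(i, 0) for i in range(max_n + 1)],
    }
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# constant-gene protein allotype collapsing


def collapse_protein_allotypes(
    alleles: Sequence[AlleleCall], gene: GeneAnnotation
) -> list[list[AlleleCall]]:
    """Group C-gene alleles whose CH1-CH3 domains translate identically.

    Groups with more than one member carry only synonymous nucleotide
    differences across the constant domains.
    """
    from Bio.Seq import Seq

    ch_regions = [r for r in gene.regions if r.label in ("CH1", "CH2", "CH3")]
    if not ch_regions:
        raise IgmineError(f"{gene.gene_name}: no CH1-CH3 regions annotated")
    ch_regions.sort(key=lambda r: r.start)

    groups: dict[str, list[AlleleCall]] = defaultdict(list)
    for allele in alleles:
        forward = (
            allele.sequence if gene.strand == "+" else reverse_complement(allele.sequence)
        )
        parts = []
        for reg in ch_regions:
            a = lift_position(gene, allele.variant_signature, reg.start)
            b = lift_position(gene, allele.variant_signature, reg.end)
            parts.append(forward[a:b])
        spliced = "".join(parts)
        if gene.strand == "-":
            spliced = reverse_complement(spliced)
        spliced = spliced[: len(spliced) - len(spliced) % 3]
        protein = str(Seq(spliced).translate())
        groups[protein].append(allele)
    return [groups[p] for p in sorted(groups)]
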