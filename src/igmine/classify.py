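"""Confidence tiers, gene categories and false-positive curation.

Tiers: AS1 (known: matched in IMGT, IgPdb or VBASE2 Class-1 and supported by
at least 4 haplotypes), AS2 (novel, frequent: at least 19 haplotypes), AS3
(novel, rare: 7-18 haplotypes); anything else is discarded. Gene categories:
GA (annotated duplicated gene pairs), OI (operationally indistinguishable
paralogs, detected from a neighbor-joining tree of the per-locus gene
reference sequences with a patristic-distance threshold), SE (the rest).

Curation applies three rules: (1) drop functional-gene alleles with an
in-frame stop codon; (2) drop novel alleles carrying a variant absent from
the external known-variant site list; (3) within a GA/OI group, a mutation
exclusive to the mined set that recurs in alleles of two or more distinct
genes marks every carrier as a mis-mapping artifact, unless that mutation is
attested in a database across multiple alleles.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calling import AlleleCall, screen_stop_codon
from .core_io import (
    GeneAnnotation,
    IgmineError,
    KnownAlleleRecord,
    KnownVariantSiteList,
)
from .mutations import align_gene_alleles, classify_mutations

logger = logging.getLogger(__name__)

KNOWN_SOURCES = ("IMGT", "IgPdb", "VBASE2_class1")

DEFAULT_MIN_KNOWN = 4
DEFAULT_MIN_RARE = 7
DEFAULT_MAX_RARE = 18
DEFAULT_MIN_FREQUENT = 19
DEFAULT_OI_THRESHOLD = 0.02


# ---------------------------------------------------------------------------
# database mapping


def map_to_known(
    allele: AlleleCall, dbs: Sequence[KnownAlleleRecord]
) -> list[tuple[str, str]]:
    """Exact matches of an allele against known-allele database records.

    Full-with-leader records must equal the allele sequence exactly;
    V-region-only or partial records must occur as an exact contiguous
    substring. Zero mismatches in both cases.
    """
    matches = []
    for rec in dbs:
        if rec.completeness == "full_with_leader":
            if rec.sequence == allele.sequence:
                matches.append((rec.source, rec.allele_name))
        else:
            if rec.sequence in allele.sequence:
                matches.append((rec.source, rec.allele_name))
    return matches


def assign_confidence(
    allele: AlleleCall,
    has_known_match: bool,
    min_known: int = DEFAULT_MIN_KNOWN,
    min_rare: int = DEFAULT_MIN_RARE,
    max_rare: int = DEFAULT_MAX_RARE,
    min_frequent: int = DEFAULT_MIN_FREQUENT,
) -> str:
    s = allele.support_total
    if has_known_match:
        return "AS1" if s >= min_known else "DISCARDED"
    if s >= min_frequent:
        return "AS2"
    if min_rare <= s <= max_rare:
        return "AS3"
    return "DISCARDED"


# ---------------------------------------------------------------------------
# gene categories (SE / GA / OI)


@dataclass
class GeneCategoryMap:
    categories: dict[str, str]  # gene name -> SE | GA | OI
    oi_groups: list[frozenset[str]] = field(default_factory=list)
    group_gene_pairs: list[tuple[str, str]] = field(default_factory=list)

    def category(self, gene_name: str) -> str:
        return self.categories.get(gene_name, "SE")

    def groups_of(self, gene_name: str) -> Optional[frozenset[str]]:
        for grp in self.oi_groups:
            if gene_name in grp:
                return grp
        for a, b in self.group_gene_pairs:
            if gene_name in (a, b):
                return frozenset((a, b))
        return None


def _p_distance(a: str, b: str) -> float:
    """Proportion of mismatching aligned columns (gaps count as mismatches)."""
    if len(a) == len(b):
        if not a:
            return 0.0
        return sum(x != y for x, y in zip(a, b)) / len(a)
    from .mutations import _unit_cost_aligner

    aln = _unit_cost_aligner().align(a, b)[0]
    s1, s2 = aln[0], aln[1]
    return sum(x != y for x, y in zip(s1, s2)) / len(s1)


def pairwise_p_distances(sequences: dict[str, str]) -> tuple[list[str], np.ndarray]:
    names = sorted(sequences)
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _p_distance(sequences[names[i]], sequences[names[j]])
            mat[i, j] = mat[j, i] = d
    return names, mat


def _transitive_closure(pairs: set[tuple[str, str]]) -> list[frozenset[str]]:
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set[str]] = defaultdict(set)
    for x in parent:
        groups[find(x)].add(x)
    return sorted((frozenset(g) for g in groups.values() if len(g) >= 2), key=sorted)


def detect_oi_genes(
    gene_reference_sequences: dict[str, str],
    group_gene_pairs: Sequence[tuple[str, str]] = (),
    oi_threshold: float = DEFAULT_OI_THRESHOLD,
) -> GeneCategoryMap:
    """Partition genes into SE / GA / OI categories.

    A neighbor-joining tree is built from the pairwise p-distance matrix of
    the gene reference sequences; leaf pairs whose patristic distance is at
    most ``oi_threshold`` are operationally indistinguishable, and their
    transitive closure forms the OI groups. Genes in the fixed duplicated
    pairs are GA regardless; the remainder are SE. With fewer than three
    sequences (no tree possible) the p-distances are thresholded directly.
    """
    ga_genes = {g for pair in group_gene_pairs for g in pair}
    names, mat = pairwise_p_distances(gene_reference_sequences)
    close_pairs: set[tuple[str, str]] = set()
    if len(names) >= 3:
        from skbio import DistanceMatrix
        from skbio.tree import nj

        tree = nj(DistanceMatrix(mat, ids=names))
        tip_dist = tree.tip_tip_distances(endpoints=names)
        arr = np.asarray(tip_dist.data)
        ids = list(tip_dist.ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if arr[i, j] <= oi_threshold:
                    close_pairs.add((ids[i], ids[j]))
    else:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if mat[i, j] <= oi_threshold:
                    close_pairs.add((names[i], names[j]))

    # GA assignment wins over OI membership
    close_pairs = {
        (a, b) for a, b in close_pairs if a not in ga_genes and b not in ga_genes
    }
    oi_groups = _transitive_closure(close_pairs)
    categories: dict[str, str] = {}
    for name in names:
        if name in ga_genes:
            categories[name] = "GA"
        elif any(name in grp for grp in oi_groups):
            categories[name] = "OI"
        else:
            categories[name] = "SE"
    for g in ga_genes:
        categories.setdefault(g, "GA")
    return GeneCategoryMap(
        categories=categories,
        oi_groups=oi_groups,
        group_gene_pairs=[tuple(p) for p in group_gene_pairs],
    )


# ---------------------------------------------------------------------------
# false-positive filtering


@dataclass
class RemovedAllele:
    allele: AlleleCall
    reasons: tuple[str, ...]


def _rule3_groups(categories: GeneCategoryMap) -> list[frozenset[str]]:
    groups = list(categories.oi_groups)
    for pair in categories.group_gene_pairs:
        groups.append(frozenset(pair))
    # deduplicate
    seen = set()
    out = []
    for g in groups:
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


def _shared_group_mutation_ids(
    group: frozenset[str],
    alleles_by_gene: dict[str, list[AlleleCall]],
    dbs_by_gene: dict[str, list[KnownAlleleRecord]],
) -> set[str]:
    """Allele ids removed by rule 3 inside one GA/OI group.

    The group's mined and database alleles are aligned together; a mutation
    (aligned column, base) carried by no database allele and by mined
    alleles of two or more distinct genes flags every carrier.
    """
    mined = [a for g in sorted(group) for a in alleles_by_gene.get(g, [])]
    if not mined:
        return set()
    db = [r for g in sorted(group) for r in dbs_by_gene.get(g, [])]
    alignment = align_gene_alleles(mined, db, gene_name="+".join(sorted(group)))
    profile = classify_mutations(alignment)
    gene_of = {a.allele_id: a.gene_name for a in mined}

    carriers: dict[tuple, set[str]] = defaultdict(set)
    for allele_id, muts in profile.per_allele.items():
        if allele_id not in gene_of:
            continue
        for m in muts:
            if m.status == "new":  # absent from every database allele
                carriers[(m.column, m.base)].add(allele_id)
    removed: set[str] = set()
    for _, ids in carriers.items():
        genes_hit = {gene_of[i] for i in ids}
        if len(genes_hit) >= 2:
            removed.update(ids)
    return removed


def filter_false_positives(
    alleles: Sequence[AlleleCall],
    site_list: KnownVariantSiteList,
    categories: GeneCategoryMap,
    dbs: Sequence[KnownAlleleRecord],
    genes: dict[str, GeneAnnotation],
) -> tuple[list[AlleleCall], list[RemovedAllele]]:
    """Apply the three curation rules; returns (retained, removed-with-reasons).

    Rule 1 removes functional-gene alleles with an in-frame stop codon.
    Rule 2 removes novel (AS2/AS3) alleles carrying any variant absent from
    the external site list; AS1 alleles are exempt. Rule 3 removes shared
    exclusive mutations within GA/OI groups (see module docstring).
    """
    reasons: dict[str, list[str]] = defaultdict(list)
    alleles_by_gene: dict[str, list[AlleleCall]] = defaultdict(list)
    for allele in alleles:
        if allele.gene_name not in genes:
            raise IgmineError(f"allele {allele.allele_id} references unknown gene")
        alleles_by_gene[allele.gene_name].append(allele)

    for allele in alleles:
        gene = genes[allele.gene_name]
        # rule 1: in-frame stop codons (functional genes only)
        if gene.functionality == "functional" and gene.coding_segments:
            if screen_stop_codon(allele, gene):
                reasons[allele.allele_id].append("STOP_CODON")
        # rule 2: novel alleles must carry only externally attested variants
        if allele.tier in ("AS2", "AS3"):
            for pos, ref, alt in allele.variant_signature:
                if (gene.chrom, pos, ref, alt) not in site_list:
                    reasons[allele.allele_id].append("UNSUPPORTED_VARIANT")
                    break

    # rule 3: shared exclusive mutations within GA/OI groups
    dbs_by_gene: dict[str, list[KnownAlleleRecord]] = defaultdict(list)
    for rec in dbs:
        dbs_by_gene[rec.gene_name].append(rec)
    for group in _rule3_groups(categories):
        for allele_id in _shared_group_mutation_ids(group, alleles_by_gene, dbs_by_gene):
            reasons[allele_id].append("SHARED_GROUP_MUTATION")

    retained, removed = [], []
    for allele in alleles:
        if allele.allele_id in reasons:
            flags = tuple(dict.fromkeys(reasons[allele.allele_id]))
            allele.curation_flags = flags
            removed.append(RemovedAllele(allele=allele, reasons=flags))
        else:
            retained.append(allele)
    return retained, removed
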