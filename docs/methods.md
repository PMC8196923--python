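# Methods

## Overview

`igmine` mines germline immunoglobulin (IG) alleles from a phased
multi-sample VCF. The underlying observation model is simple: over a gene
interval, the sequence carried on one parental chromosome of one individual
(a *haplotype*) is obtained by substituting that phase's non-reference
alleles into the reference slice. A diploid cohort of *N* samples therefore
contributes exactly 2*N* independent haplotypes per gene (5,008 for a
2,504-sample cohort), and a germline *allele* is a distinct haplotype
sequence, supported by the number of haplotypes that carry it. Somatic
hypermutation (SHM) and sequencing error appear as essentially private
variation, so a minimum-support rule separates germline alleles from noise.

## Haplotype reconstruction

Variants of one phase are applied to the reference slice in descending
genomic position, so earlier offsets stay valid while indels shift the
sequence. Overlapping REF spans on one phase are rejected as conflicting
edits, which makes descending application equivalent to simultaneous
application. Variants whose REF span crosses the gene boundary raise an
error: that is an annotation problem, not data to be silently truncated.
Sequences are stored in gene-sense orientation (reverse complemented for
'-' strand genes) so translation and database comparison never have to
consider strand. Records with symbolic ALTs (`<CN*>`, breakends) are
excluded and counted; copy-number variation is out of scope. Missing
genotypes drop that sample's two haplotypes for the affected gene under the
default policy (`strict` raises instead) — the intended inputs are fully
phased and imputed cohorts where this never triggers.

## Allele calling

Identical haplotype sequences of one gene are merged; the merge key is the
sequence string, not the variant signature, so equivalent indel placements
merge. Alleles are ordered by support descending; equal supports tie-break
on ascending sequence, purely for determinism. Names are
`<gene>_<rank>` with the rank zero-padded to two digits, widening only
beyond 99 alleles. After curation the surviving alleles of each gene are
re-ranked so the final identifiers are contiguous from `_01`.

## Confidence tiers

* **AS1 (known)** — exact match in IMGT, IgPdb or VBASE2 Class-1 and at
  least 4 supporting haplotypes. Full-length database records must equal
  the allele exactly (leader included); V-region-only or partial records
  must occur as an exact contiguous substring. Zero mismatches either way.
* **AS2 (frequent novel)** — unmatched, at least 19 haplotypes (hence at
  least 10 distinct individuals).
* **AS3 (rare novel)** — unmatched, 7–18 haplotypes (at least 4
  individuals).
* Anything else is discarded. The thresholds (4, 7, 18, 19) are
  configuration values with these defaults.

## Gene categories (SE / GA / OI)

Short-read mapping cannot distinguish near-identical paralogs, so their
alleles deserve extra suspicion. Per locus and gene type (V and C genes
only — D and J genes are short and unambiguous), a neighbor-joining tree
(scikit-bio) is built from the pairwise p-distance matrix of the gene
reference sequences; p-distance is the proportion of mismatching aligned
columns, computed directly for equal lengths and over a unit-cost global
alignment otherwise. Leaf pairs with patristic distance ≤ 0.02 are
*operationally indistinguishable* (OI); the relation is transitively closed
into OI groups. "Sharing a clade with short branch length" could also be
read as a siblings-only criterion; the leaf-pair reading was chosen because
it is permutation-invariant and degrades gracefully when more than two
paralogs cluster. With fewer than three sequences no tree exists and the
p-distances are thresholded directly. Annotated duplicated pairs (e.g.
IGHV1-69/IGHV1-69D) are *group* (GA) genes regardless of tree distance;
everything else is *self-evident* (SE).

## False-positive curation

1. **Stop codons** — alleles of functional genes whose spliced coding
   sequence (coordinates lifted through the allele's indels) translates to
   a stop before the natural end are removed. Pseudogenes are exempt.
2. **Externally unattested variants** — novel (AS2/AS3) alleles carrying
   any variant absent from the external known-variant site list (the union
   of large variation catalogs) are removed. Known (AS1) alleles are
   exempt: database identity is stronger evidence than catalog membership.
3. **Shared exclusive mutations in GA/OI groups** — the group's mined and
   database alleles are aligned together; a mutation (aligned column,
   base) carried by *no* database allele but by mined alleles of two or
   more distinct genes in the group indicates read mis-mapping, and every
   carrier is removed. Presence in any database allele exempts the
   mutation; this subsumes the looser "present across multiple database
   alleles" exemption, which only differs for a mutation attested exactly
   once — we treat single attestation as sufficient evidence of a genuine
   variant.

## Population annotation

Supporting haplotypes are aggregated per population and superpopulation
(AFR, AMR, EAS, EUR, SAS). The distribution category is a function of the
superpopulation presence pattern: **ALL** (all five), **AFR** (only
Africans), **AFR_SHARED** (Africans plus some but not all others),
**NON_AFR** (no African support). Presence for the category means ≥ 1
supporting haplotype; the separate binary presence vector uses ≥ 4
haplotypes per population, matching the convention used for tree-figure
annotation. Both thresholds are configurable; the category threshold is
the genuinely open choice, and it only affects alleles with 1–3 haplotypes
in a superpopulation. Samples split into Set-Blood (EBV genome coverage
strictly below 20X, or source unreported) versus Set-EBV (the rest, i.e.
EBV-transformed cell lines); coverage exactly 20X is Set-EBV because the
blood definition is a strict inequality.

## RSS scanning

A recombination signal sequence is a heptamer (canonical CACAGTG), a 12- or
23-bp spacer, and a nonamer (canonical ACAAAAACC), 3' of V genes, 5' of J
genes and on both sides of D genes. Windows of 40 bases (23-bp class) or
30 bases (12-bp class) adjacent to the gene boundary are extracted and
normalized to read from the boundary outward, the orientation in which the
canonical motifs appear. The heptamer is the 7-mer minimizing Hamming
distance to the canonical within 0–30 bases of the boundary (ties to the
nearest offset); more than 3 mismatches flags "not found" rather than
erroring. The nonamer is the best 9-mer within ±3 bases of the expected
spacer end, so deviant spacers (e.g. the 22-bp J-gene spacers) are
measured, not forced. Because some pseudogene RSSs sit 10–30 bases from
the gene boundary, windows are internally extended by the boundary slack
so a displaced RSS still fits; the nominal window length is what is
reported. Indels inside the motifs are not modeled — they shift offsets
instead. V-gene records also flag a stop codon in the gap between boundary
and heptamer. Per-haplotype RSS windows reuse the haplotype engine on the
window interval and are collapsed and scored like alleles.

## Mutation patterns

Per gene, mined and database alleles are stacked into a column-indexed
alignment: equal-length sequences align position-for-position on an anchor
(the majority consensus of modal-length mined alleles); length-changing
alleles are placed by unit-cost global alignment (Biopython), insertions
creating explicit insert columns; V-region-only records are anchored by
best substring placement and padded with no-coverage markers, and are
excluded with a warning if they diverge by more than 10% of their length.
The consensus state per column is the majority over database alleles when
any cover it (they anchor the gene's canonical state), else over mined
alleles; ties break to the lexicographically smallest base. Every
non-consensus (column, base) is a mutation, *known* if some database allele
carries the same base at that column and *new* otherwise. Novelty is
counted at (column, base) granularity by default — a different substitution
at a known mutating column is still new; a `position_only` switch gives the
looser column-level reading. Counts are reported for the full sequence and
for V-region columns only, and summarized as a table of allele counts per
new-mutation count. C-gene alleles are additionally collapsed into
allotype groups by identical translated CH1–CH3 domains; multi-member
groups carry only synonymous differences.

## Synthetic cohort generator

The generator emulates the structure of a phased diploid cohort: a panel of
populations mapped to the five superpopulations, two haplotypes per sample,
genes laid out on contigs with planted canonical RSS flanks, planted
alleles assigned to exact haplotype counts in chosen populations, and
optional singleton noise variants. The default configuration is the study
condition set: 2,504 samples in the standard 26 populations (61–113
samples each, 5,008 haplotypes per gene), ~77.5% of samples EBV-derived
(coverage ≥ 20X) and the rest blood or unreported, planted supports
bracketing every tier boundary (3/4, 6/7, 18/19), population targeting
exercising all four distribution categories, a GA pair, an OI paralog pair
at p-distance ≈ 0.01, both RSS spacer classes, a 22-bp-spacer J gene, and a
pseudogene with its RSS displaced 15 bases. V genes are 45 bp leader +
84 bp intron + 294 bp V region; C genes are three 99-bp CH domains; coding
stretches are generated stop-free codon-wise so no spurious stop-codon
removals occur. A machine-readable truth table records every distinct
haplotype sequence with exact support, per-population counts, expected
tier, category and curation outcome; it is computed by direct counting and
string comparison at generation time, independently of the pipeline code.

Noise variants model SHM/sequencing error as private singletons. They are
placed on haplotypes carrying the reference allele, so planted supports
stay at their configured values; support erosion of rare alleles by noise
on their carriers is real but deliberately not simulated — the robustness
property under test is that singletons never *create* emitted alleles.
What the generator does not emulate: linkage disequilibrium, demographic
structure, genotyping error correlation, copy-number variation, and genes
absent from the reference assembly. Passing the end-to-end tests therefore
shows correctness of the mining logic under the stated observation model,
not robustness to every artifact of real short-read cohorts.

Identical seeds produce byte-identical bundles: all randomness flows from
one `numpy` generator, files are written in fixed order, and the VCF and
FASTA outputs are rendered directly as text.

## Numerical and degenerate-input choices

* Equal-support ordering ties break on sequence; consensus ties break on
  the smallest base — both purely for determinism.
* Coding sequences are trimmed to whole codons before translation; a
  trailing natural stop is not "premature".
* `detect_oi_genes` with < 3 sequences falls back to direct distance
  thresholding; empty allele inputs yield empty outputs rather than
  errors.
* Problem sizes in tests and in the acceptance script (a full 2,504-sample
  cohort for the main run; 10–50 seeded small cohorts for robustness
  sweeps) were chosen so each check completes in seconds while still
  exercising cohort-scale accounting.

## Known limitations

* Exact-match database mapping cannot credit a known allele observed with
  an adjacent novel leader variant; it lands in AS2/AS3 instead.
* The rule-3 alignment assumes group members are alignable to a common
  anchor; grossly length-divergent paralogs would need curated anchoring.
* Allele identifiers are support-ranked, hence not stable across cohorts.
* RSS localization is motif-proximity based; a heavily degenerate heptamer
  (> 3 mismatches) is flagged rather than scored, and motif-internal
  indels are not modeled.
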