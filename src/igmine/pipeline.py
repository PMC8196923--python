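"""End-to-end orchestration: extract -> call -> classify -> annotate -> rss
-> mutation patterns, with stage-count bookkeeping and deterministic outputs.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import calling, classify, mutations, populations, rss
from .core_io import (
    GeneAnnotation,
    IgmineError,
    KnownAlleleRecord,
    ReferenceGenome,
    read_gene_annotation,
    read_known_db,
    read_phased_vcf,
    read_sample_panel,
    read_site_list,
    write_allele_metadata_tsv,
    write_alleles_fasta,
)
from .haplotypes import HaplotypeObservation, extract_all_haplotypes

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    reference: str
    annotation: str
    panel: str
    databases: dict[str, str]  # source -> FASTA path
    site_list: str
    outdir: str = "igmine_out"
    min_known: int = classify.DEFAULT_MIN_KNOWN
    min_rare: int = classify.DEFAULT_MIN_RARE
    max_rare: int = classify.DEFAULT_MAX_RARE
    min_frequent: int = classify.DEFAULT_MIN_FREQUENT
    oi_threshold: float = classify.DEFAULT_OI_THRESHOLD
    presence_threshold: int = populations.DEFAULT_PRESENCE_THRESHOLD
    ebv_cutoff: float = populations.DEFAULT_EBV_CUTOFF
    missing_policy: str = "drop"
    position_only_novelty: bool = False
    group_gene_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.min_rare > self.min_frequent:
            raise IgmineError("min_rare must be <= min_frequent")
        for v in (self.min_known, self.min_rare, self.min_frequent):
            if v <= 0:
                raise IgmineError("support thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "group_gene_pairs" in raw:
            raw["group_gene_pairs"] = tuple(tuple(p) for p in raw["group_gene_pairs"])
        return cls(**raw)


@dataclass
class PipelineResult:
    observations_per_gene: dict[str, int]
    alleles_by_gene: dict[str, list[calling.AlleleCall]]  # final retained, ranked
    removed: list[classify.RemovedAllele]
    discarded_count: int
    categories: classify.GeneCategoryMap
    distributions: dict[str, populations.PopulationDistribution]  # allele_id ->
    rss_records: list[rss.RSSRecord]
    rss_haplotypes: dict[tuple[str, str], list]  # (gene, side) -> scored windows
    profiles: dict[str, mutations.MutationProfile]
    mutation_summary: "object"
    stage_counts: dict[str, int]

    def all_alleles(self) -> list[calling.AlleleCall]:
        return [a for alleles in self.alleles_by_gene.values() for a in alleles]


def _detect_categories(
    genes: list[GeneAnnotation],
    reference: ReferenceGenome,
    group_gene_pairs,
    oi_threshold: float,
) -> classify.GeneCategoryMap:
    """SE/GA/OI detection per (locus, gene type) over the reference sequences.

    Only V and C genes are candidates for operational indistinguishability;
    D and J genes are short and unambiguous, so they default to SE.
    """
    from .core_io import reverse_complement

    categories: dict[str, str] = {}
    oi_groups = []
    groups: dict[tuple[str, str], list[GeneAnnotation]] = defaultdict(list)
    for g in genes:
        groups[(g.locus, g.gene_type)].append(g)
    present = {g.gene_name for g in genes}
    pairs = [p for p in group_gene_pairs if p[0] in present and p[1] in present]
    for (locus, gtype), members in sorted(groups.items()):
        if gtype not in ("V", "C") or len(members) < 2:
            for g in members:
                categories[g.gene_name] = (
                    "GA" if any(g.gene_name in p for p in pairs) else "SE"
                )
            continue
        seqs = {}
        for g in members:
            s = reference.fetch(g.chrom, g.start, g.end)
            seqs[g.gene_name] = reverse_complement(s) if g.strand == "-" else s
        sub = classify.detect_oi_genes(seqs, pairs, oi_threshold)
        categories.update(sub.categories)
        oi_groups.extend(sub.oi_groups)
    return classify.GeneCategoryMap(
        categories=categories, oi_groups=oi_groups, group_gene_pairs=pairs
    )


def run_all(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("igmine")
    root.addHandler(handler)
    try:
        return _run_all(config, outdir)
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_all(config: PipelineConfig, outdir: Path) -> PipelineResult:
    stage_counts: dict[str, int] = {}

    # --- load
    for name in ("vcf", "reference", "annotation", "panel", "site_list"):
        if not Path(getattr(config, name)).exists():
            raise IgmineError(f"input file for {name!r} not found: {getattr(config, name)}")
    genes = read_gene_annotation(config.annotation)
    genes_by_name = {g.gene_name: g for g in genes}
    reference = ReferenceGenome(config.reference)
    panel = read_sample_panel(config.panel)
    site_list = read_site_list(config.site_list)
    db_records: list[KnownAlleleRecord] = []
    for source, path in sorted(config.databases.items()):
        if not Path(path).exists():
            raise IgmineError(f"database file not found: {path}")
        db_records.extend(read_known_db(path, source=source))
    known_dbs = [r for r in db_records if r.source in classify.KNOWN_SOURCES]
    vcf = read_phased_vcf(config.vcf)
    logger.info("loaded %d variant records, %d samples", len(vcf.records), len(vcf.samples))

    # --- extract
    observations = extract_all_haplotypes(
        vcf.records, vcf.samples, genes, reference, missing_policy=config.missing_policy
    )
    obs_by_gene: dict[str, list[HaplotypeObservation]] = defaultdict(list)
    for obs in observations:
        obs_by_gene[obs.gene_name].append(obs)
    stage_counts["haplotype_observations"] = len(observations)
    logger.info("extracted %d haplotype observations", len(observations))

    # --- call
    raw_by_gene = {g.gene_name: calling.call_alleles(obs_by_gene[g.gene_name]) for g in genes}
    n_raw = sum(len(v) for v in raw_by_gene.values())
    stage_counts["raw_alleles"] = n_raw
    logger.info("called %d raw alleles", n_raw)

    # --- classify: db mapping + tiers
    tiered = []
    discarded = 0
    for gene_alleles in raw_by_gene.values():
        for allele in gene_alleles:
            matches = classify.map_to_known(allele, known_dbs)
            allele.db_matches = tuple(matches)
            allele.tier = classify.assign_confidence(
                allele,
                has_known_match=bool(matches),
                min_known=config.min_known,
                min_rare=config.min_rare,
                max_rare=config.max_rare,
                min_frequent=config.min_frequent,
            )
            if allele.tier == "DISCARDED":
                discarded += 1
            else:
                tiered.append(allele)
    stage_counts["discarded_low_support"] = discarded
    stage_counts["tiered_alleles"] = len(tiered)
    assert discarded + len(tiered) == n_raw

    # --- gene categories
    categories = _detect_categories(
        genes, reference, config.group_gene_pairs, config.oi_threshold
    )
    for allele in tiered:
        allele.category = categories.category(allele.gene_name)

    # --- curation
    retained, removed = classify.filter_false_positives(
        tiered, site_list, categories, known_dbs, genes_by_name
    )
    stage_counts["removed_false_positive"] = len(removed)
    stage_counts["retained_alleles"] = len(retained)
    assert len(retained) + len(removed) == len(tiered)
    for reason in ("STOP_CODON", "UNSUPPORTED_VARIANT", "SHARED_GROUP_MUTATION"):
        stage_counts[f"removed_{reason.lower()}"] = sum(
            1 for r in removed if reason in r.reasons
        )

    # --- final naming and per-tier counts
    alleles_by_gene: dict[str, list[calling.AlleleCall]] = {}
    for g in genes:
        mine = [a for a in retained if a.gene_name == g.gene_name]
        alleles_by_gene[g.gene_name] = calling.rename_ranked(mine)
    for tier in ("AS1", "AS2", "AS3"):
        stage_counts[f"final_{tier}"] = sum(
            1 for a in retained if a.tier == tier
        )

    # --- population annotation
    distributions = {}
    for allele in retained:
        gene = genes_by_name[allele.gene_name]
        dist = populations.annotate_population(
            allele,
            panel,
            presence_threshold=config.presence_threshold,
            ebv_cutoff=config.ebv_cutoff,
        )
        distributions[allele.allele_id] = dist
        try:
            allele.protein = calling.translate_allele(allele, gene) if gene.coding_segments else None
        except IgmineError:
            allele.protein = None

    # --- RSS
    rss_records = []
    rss_haplotypes = {}
    for g in genes:
        for rec in rss.scan_gene_rss(g, reference):
            rss_records.append(rec)
            rss_haplotypes[(g.gene_name, rec.side)] = rss.rss_haplotype_variants(
                g, rec.side, vcf.records, vcf.samples, reference
            )

    # --- mutation patterns
    db_by_gene: dict[str, list[KnownAlleleRecord]] = defaultdict(list)
    for rec in db_records:
        db_by_gene[rec.gene_name].append(rec)
    profiles = {}
    for g in genes:
        mine = alleles_by_gene[g.gene_name]
        if not mine:
            continue
        alignment = mutations.align_gene_alleles(mine, db_by_gene.get(g.gene_name, []))
        profiles[g.gene_name] = mutations.classify_mutations(
            alignment, gene=g, position_only=config.position_only_novelty
        )
    summary = mutations.summarize_new_mutation_counts(profiles, alleles_by_gene)

    # --- outputs
    final = [a for g in genes for a in alleles_by_gene[g.gene_name]]
    write_alleles_fasta(final, outdir / "alleles.fasta")
    write_allele_metadata_tsv(final, outdir / "alleles.tsv")
    _write_distribution_tsv(final, distributions, outdir / "allele_populations.tsv")
    _write_rss_tsv(rss_records, outdir / "rss.tsv")
    _write_mutation_tsv(profiles, outdir / "mutations.tsv")
    summary.to_csv(outdir / "mutation_summary.tsv", sep="\t", index=False)
    with open(outdir / "stage_counts.json", "w") as fh:
        json.dump(stage_counts, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("stage counts: %s", stage_counts)

    return PipelineResult(
        observations_per_gene={g: len(v) for g, v in obs_by_gene.items()},
        alleles_by_gene=alleles_by_gene,
        removed=removed,
        discarded_count=discarded,
        categories=categories,
        distributions=distributions,
        rss_records=rss_records,
        rss_haplotypes=rss_haplotypes,
        profiles=profiles,
        mutation_summary=summary,
        stage_counts=stage_counts,
    )


def _write_distribution_tsv(final, distributions, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "allele_id\tcategory\tper_superpopulation\tper_population\t"
            "set_blood\tset_ebv\tpresence\n"
        )
        for a in final:
            d = distributions[a.allele_id]
            sp = ";".join(f"{k}:{v}" for k, v in sorted(d.per_superpopulation.items()))
            pp = ";".join(f"{k}:{v}" for k, v in sorted(d.per_population.items()))
            pres = ";".join(p for p, ok in sorted(d.presence_vector.items()) if ok) or "."
            fh.write(
                f"{a.allele_id}\t{d.category}\t{sp}\t{pp}\t"
                f"{d.set_blood_support}\t{d.set_ebv_support}\t{pres}\n"
            )


def _write_rss_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\tside\theptamer\theptamer_mismatches\tnonamer\t"
            "nonamer_mismatches\tspacer_length\tboundary_distance\t"
            "first3_intact\theptamer_found\tstop_in_gap\n"
        )
        for r in records:
            fh.write(
                f"{r.gene_name}\t{r.side}\t{r.heptamer}\t{r.heptamer_mismatches}\t"
                f"{r.nonamer}\t{r.nonamer_mismatches}\t{r.spacer_length}\t"
                f"{r.boundary_distance}\t{int(r.first3_heptamer_intact)}\t"
                f"{int(r.heptamer_found)}\t{int(r.stop_codon_in_gap)}\n"
            )


def _write_mutation_tsv(profiles, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tallele\tcolumn\tinsert_rank\tbase\tstatus\tregion\n")
        for gene_name in sorted(profiles):
            profile = profiles[gene_name]
            for name in sorted(profile.per_allele):
                for m in profile.per_allele[name]:
                    fh.write(
                        f"{gene_name}\t{name}\t{m.column[0]}\t{m.column[1]}\t"
                        f"{m.base}\t{m.status}\t{m.region}\n"
                    )


# ---------------------------------------------------------------------------
# observation TSV (intermediate format for the stage-wise CLI)


def write_observations_tsv(observations, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tphase\tgene\tsequence\tsignature\n")
        for o in observations:
            sig = ";".join(f"{p}:{r}:{a}" for p, r, a in o.variant_signature) or "."
            fh.write(f"{o.sample_id}\t{o.phase}\t{o.gene_name}\t{o.sequence}\t{sig}\n")


def read_observations_tsv(path) -> list[HaplotypeObservation]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sample", "phase", "gene", "sequence", "signature"]:
            raise IgmineError("bad observations TSV header")
        for line in fh:
            if not line.strip():
                continue
            sample, phase, gene, seq, sig = line.rstrip("\n").split("\t")
            signature = (
                tuple(
                    (int(p), r, a)
                    for p, r, a in (tok.split(":") for tok in sig.split(";"))
                )
                if sig != "."
                else ()
            )
            out.append(
                HaplotypeObservation(
                    sample_id=sample,
                    phase=int(phase),
                    gene_name=gene,
                    sequence=seq,
                    variant_signature=signature,
                )
            )
    return out
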