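"""Deterministic synthetic cohort generator.

Emits a complete toy input bundle — reference FASTA, gene annotation TSV,
phased multi-sample VCF, sample panel, known-allele database FASTAs,
external known-variant site list — together with a machine-readable truth
table listing every planted allele with its exact haplotype support,
population counts, expected confidence tier and expected curation outcome.

The generator emulates the structure of a phased diploid population cohort:
a configurable panel of populations grouped into the five continental
superpopulations, two haplotypes per sample, planted allele haplotypes at
controlled (exact) frequencies, and optional singleton noise variants that
mimic somatic hypermutation or sequencing error (support 1, far below the
seven-haplotype threshold for calling a rare allele). The default
configuration reproduces the real study conditions: 2,504 samples in 26
populations (5,008 haplotypes per gene), roughly 1,941 of the samples from
EBV-transformed cell lines (coverage >= 20X) and the rest blood-derived or
unreported. Identical seeds yield byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core_io import (
    GeneAnnotation,
    CodingSegment,
    IgmineError,
    Region,
    RSSSide,
    SampleInfo,
    SamplePanel,
    KnownVariantSiteList,
    write_gene_annotation,
    write_sample_panel,
    write_site_list,
    reverse_complement,
)
from .rss import CANONICAL_HEPTAMER, CANONICAL_NONAMER, WINDOW_LENGTHS

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A"}

# 1000-genomes-style panel: population -> (superpopulation, n_samples)
COHORT_PANEL: dict[str, tuple[str, int]] = {
    "YRI": ("AFR", 108), "LWK": ("AFR", 99), "GWD": ("AFR", 113),
    "MSL": ("AFR", 85), "ESN": ("AFR", 99), "ASW": ("AFR", 61),
    "ACB": ("AFR", 96),
    "MXL": ("AMR", 64), "PUR": ("AMR", 104), "CLM": ("AMR", 94),
    "PEL": ("AMR", 85),
    "CHB": ("EAS", 103), "JPT": ("EAS", 104), "CHS": ("EAS", 105),
    "CDX": ("EAS", 93), "KHV": ("EAS", 99),
    "CEU": ("EUR", 99), "TSI": ("EUR", 107), "FIN": ("EUR", 99),
    "GBR": ("EUR", 91), "IBS": ("EUR", 107),
    "GIH": ("SAS", 103), "PJL": ("SAS", 96), "BEB": ("SAS", 86),
    "STU": ("SAS", 102), "ITU": ("SAS", 102),
}

EBV_FRACTION = 1941 / 2504  # cell-line-derived share of the cohort


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class PlantedVariant:
    kind: str  # "snp" | "ins" | "del"
    offset: int  # gene-sense offset
    payload: Optional[str] = None  # snp: explicit alt; ins: inserted bases
    del_length: int = 0


@dataclass(frozen=True)
class PlantedAllele:
    label: str
    variants: tuple[PlantedVariant, ...]
    count: int = 0  # used when pop_counts is None
    pop_counts: Optional[tuple[tuple[str, int], ...]] = None
    in_dbs: tuple[tuple[str, str], ...] = ()  # (source, completeness)
    listed_in_sites: bool = True
    plant_stop: bool = False
    expect_rule3_removed: bool = False


@dataclass(frozen=True)
class GeneSpec:
    name: str
    locus: str
    chrom: str
    strand: str = "+"
    gene_type: str = "V"
    functionality: str = "functional"
    leader_len: int = 45
    intron_len: int = 84
    vregion_len: int = 294
    ch_len: int = 99  # per CH domain (C genes)
    j_len: int = 51
    d_len: int = 31
    rss_spacers: tuple[tuple[str, int], ...] = ()  # (side, spacer class)
    rss_gap: tuple[tuple[str, int], ...] = ()  # boundary displacement per side
    spacer_override: tuple[tuple[str, int], ...] = ()  # actual planted spacer
    paralog_of: Optional[str] = None
    paralog_diffs: int = 0
    paralog_diff_positions: tuple[int, ...] = ()  # explicit, overrides random
    planted: tuple[PlantedAllele, ...] = ()
    ref_in_dbs: tuple[tuple[str, str], ...] = ()

    def sense_length(self) -> int:
        if self.gene_type == "V":
            return self.leader_len + self.intron_len + self.vregion_len
        if self.gene_type == "C":
            return 3 * self.ch_len
        if self.gene_type == "J":
            return self.j_len
        return self.d_len

    def sense_regions(self) -> list[tuple[str, int, int]]:
        if self.gene_type == "V":
            a, b = self.leader_len, self.leader_len + self.intron_len
            return [("LEADER", 0, a), ("INTRON", a, b), ("V-REGION", b, b + self.vregion_len)]
        if self.gene_type == "C":
            L = self.ch_len
            return [("CH1", 0, L), ("CH2", L, 2 * L), ("CH3", 2 * L, 3 * L)]
        return []

    def sense_coding(self) -> list[tuple[int, int]]:
        if self.gene_type == "V":
            a, b = self.leader_len, self.leader_len + self.intron_len
            return [(0, a), (b, b + self.vregion_len)]
        if self.gene_type == "C":
            return [(0, 3 * self.ch_len)]
        if self.gene_type == "J":
            return [(0, self.j_len)]
        return []


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    superpopulation: str
    n_samples: int


@dataclass(frozen=True)
class FixtureConfig:
    seed: int
    populations: tuple[PopulationSpec, ...]
    genes: tuple[GeneSpec, ...]
    group_gene_pairs: tuple[tuple[str, str], ...] = ()
    noise_rate: float = 0.0
    ebv_fraction: float = EBV_FRACTION
    pad: int = 100

    @property
    def n_samples(self) -> int:
        return sum(p.n_samples for p in self.populations)


# ---------------------------------------------------------------------------
# sequence helpers


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    while True:
        s = "".join(BASES[i] for i in rng.integers(0, 4, n))
        if CANONICAL_HEPTAMER not in s:
            return s


def _rand_coding(rng: np.random.Generator, n: int) -> str:
    """Stop-free codon-wise random sequence; n must be a multiple of 3."""
    codons = []
    while len(codons) * 3 < n:
        c = "".join(BASES[i] for i in rng.integers(0, 4, 3))
        if c not in STOPS:
            codons.append(c)
    s = "".join(codons)
    if CANONICAL_HEPTAMER in s:
        return _rand_coding(rng, n)
    return s


def _codon_context(coding: Sequence[tuple[int, int]], off: int) -> Optional[tuple[int, int]]:
    """(spliced codon start offset within segment chain, phase) of a sense offset."""
    cum = 0
    for a, b in coding:
        if a <= off < b:
            idx = cum + (off - a)
            return idx // 3, idx % 3
        cum += b - a
    return None


def _spliced(seq: str, coding: Sequence[tuple[int, int]]) -> str:
    return "".join(seq[a:b] for a, b in coding)


def _creates_stop(seq: str, coding: Sequence[tuple[int, int]], off: int, alt: str) -> bool:
    ctx = _codon_context(coding, off)
    if ctx is None:
        return False
    mutated = seq[:off] + alt + seq[off + 1 :]
    sp = _spliced(mutated, coding)
    codon_i = ctx[0]
    return sp[3 * codon_i : 3 * codon_i + 3] in STOPS


def _safe_snp_alt(seq: str, coding: Sequence[tuple[int, int]], off: int) -> str:
    ref = seq[off]
    alt = _NEXT_BASE[ref]
    for _ in range(3):
        if not _creates_stop(seq, coding, off, alt):
            return alt
        alt = _NEXT_BASE[alt]
        if alt == ref:
            alt = _NEXT_BASE[alt]
    raise IgmineError(f"no stop-free substitution at offset {off}")


def _stop_snp(seq: str, coding: Sequence[tuple[int, int]], used: set[int]) -> tuple[int, str]:
    """First (offset, alt) in the coding chain whose substitution creates a stop."""
    for a, b in coding:
        for off in range(a, b):
            if any(abs(off - u) < 4 for u in used):
                continue
            for alt in BASES:
                if alt != seq[off] and _creates_stop(seq, coding, off, alt):
                    return off, alt
    raise IgmineError("no stop-creating substitution found")


def _codon_at(seq: str, coding: Sequence[tuple[int, int]], off: int) -> tuple[str, int]:
    ctx = _codon_context(coding, off)
    sp = _spliced(seq, coding)
    return sp[3 * ctx[0] : 3 * ctx[0] + 3], ctx[1]


def _aa_snp(
    seq: str, coding: Sequence[tuple[int, int]], start_off: int, synonymous: bool
) -> tuple[int, str]:
    """First third-codon-position substitution at/after ``start_off`` that is
    synonymous (or nonsynonymous and stop-free, with ``synonymous=False``)."""
    from Bio.Seq import Seq

    for a, b in coding:
        if b <= start_off:
            continue
        for off in range(max(a, start_off), b):
            ctx = _codon_context(coding, off)
            if ctx is None or ctx[1] != 2:
                continue
            codon, _ = _codon_at(seq, coding, off)
            aa = str(Seq(codon).translate())
            for alt in BASES:
                if alt == seq[off]:
                    continue
                new_codon = codon[:2] + alt
                if new_codon in STOPS:
                    continue
                new_aa = str(Seq(new_codon).translate())
                if (new_aa == aa) == synonymous:
                    return off, alt
    raise IgmineError("no suitable coding substitution found")


# ---------------------------------------------------------------------------
# the generator


@dataclass
class _BuiltGene:
    spec: GeneSpec
    annotation: GeneAnnotation
    sense_seq: str
    # per planted label: resolved gene-sense (offset, ref, alt) tuples
    resolved: dict[str, tuple[tuple[int, str, str], ...]]


def _resolve_variants(
    spec: GeneSpec, sense_seq: str, rng: np.random.Generator
) -> dict[str, tuple[tuple[int, str, str], ...]]:
    coding = spec.sense_coding()
    resolved: dict[str, tuple[tuple[int, str, str], ...]] = {}
    for allele in spec.planted:
        used = {v.offset for v in allele.variants}
        out = []
        for v in allele.variants:
            if v.kind == "snp":
                ref = sense_seq[v.offset]
                alt = v.payload or _safe_snp_alt(sense_seq, coding, v.offset)
                if alt == ref:
                    raise IgmineError(f"{spec.name}/{allele.label}: alt equals ref")
                out.append((v.offset, ref, alt))
            elif v.kind in ("syn", "nonsyn"):
                off, alt = _aa_snp(sense_seq, coding, v.offset, v.kind == "syn")
                out.append((off, sense_seq[off], alt))
            elif v.kind == "ins":
                if spec.strand == "-":
                    raise IgmineError("indel planting is limited to '+' strand genes")
                ref = sense_seq[v.offset]
                out.append((v.offset, ref, ref + (v.payload or "TT")))
            elif v.kind == "del":
                if spec.strand == "-":
                    raise IgmineError("indel planting is limited to '+' strand genes")
                k = v.del_length or 2
                ref = sense_seq[v.offset : v.offset + 1 + k]
                out.append((v.offset, ref, ref[0]))
            else:
                raise IgmineError(f"unknown planted variant kind {v.kind!r}")
        if allele.plant_stop:
            off, alt = _stop_snp(sense_seq, coding, used)
            out.append((off, sense_seq[off], alt))
        out.sort()
        for (o1, r1, _), (o2, _, _) in zip(out, out[1:]):
            if o1 + len(r1) + 2 > o2:
                raise IgmineError(
                    f"{spec.name}/{allele.label}: planted variants too close"
                )
        resolved[allele.label] = tuple(out)
    return resolved


def _build_reference(
    config: FixtureConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[_BuiltGene]]:
    """Lay out every gene cassette (with planted RSS flanks) on its contig."""
    sense_seqs: dict[str, str] = {}
    # generate gene-sense sequences first so paralogs can copy their parent
    for spec in config.genes:
        if spec.paralog_of is None:
            if spec.gene_type == "V":
                seq = (
                    _rand_coding(rng, spec.leader_len)
                    + _rand_seq(rng, spec.intron_len)
                    + _rand_coding(rng, spec.vregion_len)
                )
            elif spec.gene_type == "C":
                seq = _rand_coding(rng, 3 * spec.ch_len)
            elif spec.gene_type == "J":
                seq = _rand_coding(rng, spec.j_len)
            else:
                seq = _rand_seq(rng, spec.d_len)
            sense_seqs[spec.name] = seq
    for spec in config.genes:
        if spec.paralog_of is not None:
            parent = sense_seqs.get(spec.paralog_of)
            if parent is None:
                raise IgmineError(f"{spec.name}: paralog parent not built first")
            seq = list(parent)
            coding = spec.sense_coding()
            if spec.paralog_diff_positions:
                positions = sorted(spec.paralog_diff_positions)
            else:
                positions = sorted(
                    rng.choice(len(parent), size=spec.paralog_diffs, replace=False).tolist()
                )
            for off in positions:
                seq[off] = _safe_snp_alt("".join(seq), coding, off)
            sense_seqs[spec.name] = "".join(seq)

    contigs: dict[str, list[str]] = {}
    cursors: dict[str, int] = {}
    built: list[_BuiltGene] = []
    for spec in config.genes:
        chrom = spec.chrom
        contigs.setdefault(chrom, [])
        cursors.setdefault(chrom, 0)
        sense = sense_seqs[spec.name]
        gaps = dict(spec.rss_gap)
        spacers = dict(spec.spacer_override)

        def layout(side: str, spacer_class: int) -> str:
            gap = _rand_seq(rng, gaps.get(side, 0))
            spacer = _rand_seq(rng, spacers.get(side, spacer_class))
            tail = _rand_seq(rng, 12)
            return gap + CANONICAL_HEPTAMER + spacer + CANONICAL_NONAMER + tail

        rss_map = dict(spec.rss_spacers)
        up_sense = ""
        down_sense = ""
        if "5prime" in rss_map:
            up_sense = reverse_complement(layout("5prime", rss_map["5prime"]))
        if "3prime" in rss_map:
            down_sense = layout("3prime", rss_map["3prime"])
        cassette_sense = up_sense + sense + down_sense
        forward = (
            cassette_sense if spec.strand == "+" else reverse_complement(cassette_sense)
        )
        pad = _rand_seq(rng, config.pad)
        cursor = cursors[chrom] + len(pad)
        if spec.strand == "+":
            start = cursor + len(up_sense)
        else:
            start = cursor + len(down_sense)
        end = start + len(sense)
        contigs[chrom].append(pad + forward)
        cursors[chrom] = cursor + len(forward)

        def genomic(a: int, b: int) -> tuple[int, int]:
            if spec.strand == "+":
                return start + a, start + b
            return end - b, end - a

        regions = tuple(
            Region(label, *genomic(a, b)) for label, a, b in spec.sense_regions()
        )
        coding = tuple(
            CodingSegment(*genomic(a, b), 0) for a, b in spec.sense_coding()
        )
        annotation = GeneAnnotation(
            gene_name=spec.name,
            locus=spec.locus,
            chrom=chrom,
            start=start,
            end=end,
            strand=spec.strand,
            gene_type=spec.gene_type,
            functionality=spec.functionality,
            regions=tuple(sorted(regions, key=lambda r: r.start)),
            coding_segments=tuple(sorted(coding, key=lambda c: c.start)),
            rss_sides=tuple(RSSSide(s, c) for s, c in spec.rss_spacers),
        )
        built.append(
            _BuiltGene(
                spec=spec,
                annotation=annotation,
                sense_seq=sense,
                resolved=_resolve_variants(spec, sense, rng),
            )
        )
    # trailing pad so RSS windows plus slack stay inside the contig
    for chrom in contigs:
        contigs[chrom].append(_rand_seq(rng, config.pad))
    return {c: "".join(parts) for c, parts in contigs.items()}, built


def _sense_to_genomic(
    gene: GeneAnnotation, variant: tuple[int, str, str]
) -> tuple[int, str, str]:
    off, ref, alt = variant
    if gene.strand == "+":
        return gene.start + off, ref, alt
    if len(ref) != 1 or len(alt) != 1:
        raise IgmineError("indels on '-' strand genes are not supported")
    return gene.end - off - 1, reverse_complement(ref), reverse_complement(alt)


def _apply_sense(seq: str, variants: Sequence[tuple[int, str, str]]) -> str:
    for off, ref, alt in sorted(variants, reverse=True):
        if seq[off : off + len(ref)] != ref:
            raise IgmineError("planted variant REF mismatch")
        seq = seq[:off] + alt + seq[off + len(ref) :]
    return seq


@dataclass
class FixtureBundle:
    outdir: Path
    reference: Path
    vcf: Path
    annotation: Path
    panel: Path
    databases: dict[str, Path]
    site_list: Path
    truth: Path


def generate_fixture(config: FixtureConfig, outdir: str | Path) -> FixtureBundle:
    """Write the complete input bundle plus truth table; fully seed-determined."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # panel -----------------------------------------------------------------
    samples: list[str] = []
    sample_pop: dict[str, str] = {}
    for pop in config.populations:
        for i in range(pop.n_samples):
            sid = f"{pop.name}{i + 1:04d}"
            samples.append(sid)
            sample_pop[sid] = pop.name
    pop_super = {p.name: p.superpopulation for p in config.populations}
    n = len(samples)
    n_ebv = int(round(config.ebv_fraction * n))
    order = rng.permutation(n)
    ebv_idx = set(order[:n_ebv].tolist())
    panel_info: dict[str, SampleInfo] = {}
    blood_rank = 0
    for i, sid in enumerate(samples):
        if i in ebv_idx:
            cov = round(20.0 + 40.0 * rng.random(), 1)
            panel_info[sid] = SampleInfo(sample_pop[sid], pop_super[sample_pop[sid]], cov, True)
        else:
            blood_rank += 1
            if blood_rank % 10 == 0:
                panel_info[sid] = SampleInfo(sample_pop[sid], pop_super[sample_pop[sid]], None, False)
            else:
                cov = round(19.0 * rng.random(), 1)
                panel_info[sid] = SampleInfo(sample_pop[sid], pop_super[sample_pop[sid]], cov, True)
    panel = SamplePanel(panel_info)

    # reference and genes ---------------------------------------------------
    contigs, built = _build_reference(config, rng)

    # haplotype assignment --------------------------------------------------
    n_haps = 2 * n
    hap_pop = [sample_pop[samples[h // 2]] for h in range(n_haps)]
    assignments: dict[str, list[str]] = {}
    noise: dict[str, dict[int, tuple[int, str, str]]] = {}
    for bg in built:
        labels = ["REF"] * n_haps
        taken = [False] * n_haps
        for allele in bg.spec.planted:
            wanted: list[tuple[Optional[str], int]]
            if allele.pop_counts is not None:
                wanted = [(p, k) for p, k in allele.pop_counts]
            else:
                wanted = [(None, allele.count)]
            for pop_name, k in wanted:
                assigned = 0
                for h in range(n_haps):
                    if assigned == k:
                        break
                    if taken[h]:
                        continue
                    if pop_name is not None and hap_pop[h] != pop_name:
                        continue
                    labels[h] = allele.label
                    taken[h] = True
                    assigned += 1
                if assigned < k:
                    raise IgmineError(
                        f"{bg.spec.name}/{allele.label}: cannot assign {k} haplotypes"
                        + (f" in population {pop_name}" if pop_name else "")
                    )
        assignments[bg.spec.name] = labels

        gene_noise: dict[int, tuple[int, str, str]] = {}
        if config.noise_rate > 0:
            planted_offsets = {
                o for vs in bg.resolved.values() for (o, r, a) in vs for o in range(o, o + len(r))
            }
            coding = bg.spec.sense_coding()
            pool = [
                off
                for off in range(len(bg.sense_seq))
                if all(abs(off - p) >= 4 for p in planted_offsets)
            ]
            pool_rank = 0
            for h in range(n_haps):
                # noise lands on reference-allele haplotypes: it mimics SHM or
                # sequencing error in otherwise unremarkable genomes
                if labels[h] != "REF":
                    continue
                if rng.random() < config.noise_rate:
                    if pool_rank >= len(pool):
                        break
                    off = pool[int(rng.integers(0, len(pool)))]
                    while off in {v[0] for v in gene_noise.values()}:
                        off = pool[int(rng.integers(0, len(pool)))]
                    alt = _safe_snp_alt(bg.sense_seq, coding, off)
                    gene_noise[h] = (off, bg.sense_seq[off], alt)
        noise[bg.spec.name] = gene_noise

    # VCF -------------------------------------------------------------------
    sites: dict[tuple[str, int, str], dict[str, int]] = {}
    hap_variants: dict[tuple[str, int], dict[int, tuple[str, str]]] = {}
    for bg in built:
        gene = bg.annotation
        labels = assignments[bg.spec.name]
        for h in range(n_haps):
            sense_vars = list(bg.resolved.get(labels[h], ()))
            if h in noise[bg.spec.name]:
                sense_vars.append(noise[bg.spec.name][h])
            for sv in sense_vars:
                pos, ref, alt = _sense_to_genomic(gene, sv)
                key = (gene.chrom, pos, ref)
                alts = sites.setdefault(key, {})
                alts.setdefault(alt, 0)
                hap_variants.setdefault((gene.chrom, h), {})[pos] = (ref, alt)

    vcf_path = outdir / "cohort.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(contigs):
            fh.write(f"##contig=<ID={chrom},length={len(contigs[chrom])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for (chrom, pos, ref) in sorted(sites):
            alts = sorted(sites[(chrom, pos, ref)])
            alt_index = {a: i + 1 for i, a in enumerate(alts)}
            gts = []
            for si in range(n):
                pair = []
                for phase in (0, 1):
                    h = 2 * si + phase
                    hv = hap_variants.get((chrom, h), {})
                    if pos in hv and hv[pos][0] == ref:
                        pair.append(str(alt_index[hv[pos][1]]))
                    else:
                        pair.append("0")
                gts.append("|".join(pair))
            fh.write(
                f"{chrom}\t{pos + 1}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )

    # reference FASTA -------------------------------------------------------
    ref_path = outdir / "reference.fasta"
    with open(ref_path, "w") as fh:
        for chrom in sorted(contigs):
            fh.write(f">{chrom}\n")
            seq = contigs[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    # annotation, panel -----------------------------------------------------
    annot_path = outdir / "genes.tsv"
    write_gene_annotation([bg.annotation for bg in built], annot_path)
    panel_path = outdir / "panel.tsv"
    write_sample_panel(panel, panel_path)

    # databases -------------------------------------------------------------
    db_records: dict[str, list[tuple[str, str, str]]] = {}

    def vregion_of(bg: _BuiltGene, label: str) -> str:
        for reg_label, a, b in bg.spec.sense_regions():
            if reg_label == "V-REGION":
                local = [
                    (off - a, ref, alt)
                    for (off, ref, alt) in bg.resolved.get(label, ())
                    if a <= off < b
                ]
                return _apply_sense(bg.sense_seq[a:b], local)
        raise IgmineError(f"{bg.spec.name}: no V-REGION for v_region_only record")

    allele_sense: dict[tuple[str, str], str] = {}
    for bg in built:
        allele_sense[(bg.spec.name, "REF")] = bg.sense_seq
        for allele in bg.spec.planted:
            allele_sense[(bg.spec.name, allele.label)] = _apply_sense(
                bg.sense_seq, bg.resolved[allele.label]
            )
        members = [("REF", bg.spec.ref_in_dbs)] + [
            (a.label, a.in_dbs) for a in bg.spec.planted
        ]
        counter = 0
        for label, in_dbs in members:
            for source, completeness in in_dbs:
                counter += 1
                seq = allele_sense[(bg.spec.name, label)]
                if completeness in ("v_region_only", "partial"):
                    seq = vregion_of(bg, label)
                db_records.setdefault(source, []).append(
                    (f"{bg.spec.name}*t{counter:02d}", seq, completeness)
                )

    db_paths: dict[str, Path] = {}
    for source in sorted(db_records):
        path = outdir / f"db_{source}.fasta"
        with open(path, "w") as fh:
            for name, seq, completeness in db_records[source]:
                fh.write(f">{source}|{name}|{completeness}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        db_paths[source] = path

    # site list -------------------------------------------------------------
    listed: set[tuple[str, int, str, str]] = set()
    for bg in built:
        gene = bg.annotation
        for allele in bg.spec.planted:
            if not allele.listed_in_sites:
                continue
            for sv in bg.resolved[allele.label]:
                pos, ref, alt = _sense_to_genomic(gene, sv)
                listed.add((gene.chrom, pos, ref, alt))
    site_path = outdir / "site_list.tsv"
    write_site_list(KnownVariantSiteList(frozenset(listed)), site_path)

    # truth table -----------------------------------------------------------
    truth = _truth_table(config, built, assignments, noise, panel, samples, db_records)
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return FixtureBundle(
        outdir=outdir,
        reference=ref_path,
        vcf=vcf_path,
        annotation=annot_path,
        panel=panel_path,
        databases=db_paths,
        site_list=site_path,
        truth=truth_path,
    )


def _expected_gene_categories(
    config: FixtureConfig, built: list[_BuiltGene], oi_threshold: float = 0.02
) -> dict[str, str]:
    """Expected SE/GA/OI labels from direct pairwise p-distances (clean
    fixtures make the NJ patristic distances equal the input distances)."""
    ga = {g for pair in config.group_gene_pairs for g in pair}
    cats = {}
    groups: dict[tuple[str, str], list[_BuiltGene]] = {}
    for bg in built:
        groups.setdefault((bg.spec.locus, bg.spec.gene_type), []).append(bg)
    for (_, gtype), members in groups.items():
        for bg in members:
            name = bg.spec.name
            if name in ga:
                cats[name] = "GA"
                continue
            if gtype not in ("V", "C"):
                cats[name] = "SE"
                continue
            is_oi = False
            for other in members:
                if other.spec.name == name or other.spec.name in ga:
                    continue
                a, b = bg.sense_seq, other.sense_seq
                if len(a) == len(b):
                    d = sum(x != y for x, y in zip(a, b)) / len(a)
                    if d <= oi_threshold:
                        is_oi = True
            cats[name] = "OI" if is_oi else "SE"
    return cats


def _truth_table(config, built, assignments, noise, panel, samples, db_records):
    from collections import Counter, defaultdict

    from .classify import (
        DEFAULT_MIN_KNOWN,
        DEFAULT_MIN_RARE,
        DEFAULT_MAX_RARE,
        DEFAULT_MIN_FREQUENT,
    )

    n_haps = 2 * len(samples)
    gene_cats = _expected_gene_categories(config, built)
    truth: dict = {"n_samples": len(samples), "genes": {}, "seed": config.seed}
    for bg in built:
        gene = bg.spec.name
        labels = assignments[gene]
        label_info = {a.label: a for a in bg.spec.planted}
        hap_seqs: dict[int, str] = {}
        hap_label: dict[int, str] = {}
        for h in range(n_haps):
            variants = list(bg.resolved.get(labels[h], ()))
            lab = labels[h]
            if h in noise[gene]:
                variants.append(noise[gene][h])
                lab = "NOISE"
            hap_seqs[h] = _apply_sense(bg.sense_seq, variants)
            hap_label[h] = lab

        by_seq: dict[str, list[int]] = defaultdict(list)
        for h, s in hap_seqs.items():
            by_seq[s].append(h)

        db_seqs = [
            (src, name, seq, completeness)
            for src, recs in db_records.items()
            for (name, seq, completeness) in recs
        ]

        rows = []
        for seq, haps in by_seq.items():
            support = len(haps)
            per_pop = Counter()
            per_super = Counter()
            blood = ebv = 0
            for h in haps:
                sid = samples[h // 2]
                info = panel[sid]
                per_pop[info.population] += 1
                per_super[info.superpopulation] += 1
                if info.ebv_coverage is None or info.ebv_coverage < 20.0:
                    blood += 1
                else:
                    ebv += 1
            matches = [
                (src, name)
                for src, name, dseq, completeness in db_seqs
                if (completeness == "full_with_leader" and dseq == seq)
                or (completeness != "full_with_leader" and dseq in seq)
            ]
            known = bool(matches)
            if known:
                tier = "AS1" if support >= DEFAULT_MIN_KNOWN else "DISCARDED"
            elif support >= DEFAULT_MIN_FREQUENT:
                tier = "AS2"
            elif DEFAULT_MIN_RARE <= support <= DEFAULT_MAX_RARE:
                tier = "AS3"
            else:
                tier = "DISCARDED"
            label = hap_label[haps[0]]
            flags = []
            spec_allele = label_info.get(label)
            if spec_allele is not None and tier != "DISCARDED":
                if spec_allele.plant_stop and bg.spec.sense_coding():
                    flags.append("STOP_CODON")
                if not spec_allele.listed_in_sites and tier in ("AS2", "AS3"):
                    flags.append("UNSUPPORTED_VARIANT")
                if spec_allele.expect_rule3_removed:
                    flags.append("SHARED_GROUP_MUTATION")
            presence = {sp for sp, k in per_super.items() if k >= 1}
            if presence == {"AFR", "AMR", "EAS", "EUR", "SAS"}:
                pop_cat = "ALL"
            elif presence == {"AFR"}:
                pop_cat = "AFR"
            elif "AFR" in presence:
                pop_cat = "AFR_SHARED"
            else:
                pop_cat = "NON_AFR"
            rows.append(
                {
                    "label": label,
                    "sequence": seq,
                    "support": support,
                    "per_population": dict(sorted(per_pop.items())),
                    "per_superpopulation": dict(sorted(per_super.items())),
                    "set_blood": blood,
                    "set_ebv": ebv,
                    "db_matches": sorted(matches),
                    "expected_tier": tier,
                    "expected_flags": flags,
                    "expected_removed": bool(flags),
                    "expected_population_category": pop_cat,
                }
            )
        # final ranks over alleles that survive tiering and curation
        kept = [
            r for r in rows if r["expected_tier"] != "DISCARDED" and not r["expected_removed"]
        ]
        kept.sort(key=lambda r: (-r["support"], r["sequence"]))
        width = max(2, len(str(len(kept))))
        for rank, r in enumerate(kept, start=1):
            r["expected_allele_id"] = f"{gene}_{rank:0{width}d}"
        for r in rows:
            r.setdefault("expected_allele_id", None)
        rows.sort(key=lambda r: (-r["support"], r["sequence"]))

        spacers = dict(bg.spec.spacer_override)
        rss_truth = {
            side: {
                "window_length": WINDOW_LENGTHS[spacer_class],
                "spacer_length": spacers.get(side, spacer_class),
                "boundary_distance": dict(bg.spec.rss_gap).get(side, 0),
                "heptamer_mismatches": 0,
                "nonamer_mismatches": 0,
            }
            for side, spacer_class in bg.spec.rss_spacers
        }
        truth["genes"][gene] = {
            "n_observations": n_haps,
            "expected_gene_category": gene_cats[gene],
            "alleles": rows,
            "rss": rss_truth,
        }
    return truth


# ---------------------------------------------------------------------------
# YAML loading


def config_from_dict(raw: dict) -> FixtureConfig:
    def variants(items):
        return tuple(
            PlantedVariant(
                kind=v["kind"],
                offset=int(v["offset"]),
                payload=v.get("payload"),
                del_length=int(v.get("del_length", 0)),
            )
            for v in items
        )

    def planted(items):
        return tuple(
            PlantedAllele(
                label=a["label"],
                variants=variants(a.get("variants", [])),
                count=int(a.get("count", 0)),
                pop_counts=(
                    tuple((p, int(k)) for p, k in a["pop_counts"])
                    if a.get("pop_counts")
                    else None
                ),
                in_dbs=tuple((s, c) for s, c in a.get("in_dbs", [])),
                listed_in_sites=bool(a.get("listed_in_sites", True)),
                plant_stop=bool(a.get("plant_stop", False)),
                expect_rule3_removed=bool(a.get("expect_rule3_removed", False)),
            )
            for a in items
        )

    genes = tuple(
        GeneSpec(
            name=g["name"],
            locus=g["locus"],
            chrom=g["chrom"],
            strand=g.get("strand", "+"),
            gene_type=g.get("gene_type", "V"),
            functionality=g.get("functionality", "functional"),
            rss_spacers=tuple((s, int(c)) for s, c in g.get("rss_spacers", [])),
            rss_gap=tuple((s, int(c)) for s, c in g.get("rss_gap", [])),
            spacer_override=tuple((s, int(c)) for s, c in g.get("spacer_override", [])),
            paralog_of=g.get("paralog_of"),
            paralog_diffs=int(g.get("paralog_diffs", 0)),
            paralog_diff_positions=tuple(g.get("paralog_diff_positions", [])),
            planted=planted(g.get("planted", [])),
            ref_in_dbs=tuple((s, c) for s, c in g.get("ref_in_dbs", [])),
        )
        for g in raw["genes"]
    )
    populations = tuple(
        PopulationSpec(p["name"], p["superpopulation"], int(p["n_samples"]))
        for p in raw["populations"]
    )
    return FixtureConfig(
        seed=int(raw.get("seed", 0)),
        populations=populations,
        genes=genes,
        group_gene_pairs=tuple(tuple(p) for p in raw.get("group_gene_pairs", [])),
        noise_rate=float(raw.get("noise_rate", 0.0)),
        ebv_fraction=float(raw.get("ebv_fraction", EBV_FRACTION)),
    )


def config_from_yaml(path) -> FixtureConfig:
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
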