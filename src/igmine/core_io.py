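"""Domain types and I/O for every external format the pipeline touches.

All coordinates are 0-based half-open internally; only VCF I/O converts
(VCF files are 1-based). Sequences are uppercase DNA throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

SUPERPOPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")
LOCI = ("IGH", "IGK", "IGL")
GENE_TYPES = ("V", "D", "J", "C")
FUNCTIONALITIES = ("functional", "pseudogene", "ORF")
REGION_LABELS = ("LEADER", "INTRON", "V-REGION", "CH1", "CH2", "CH3", "OTHER")
DB_SOURCES = ("IMGT", "IgPdb", "VBASE2_class1", "other")
COMPLETENESS = ("full_with_leader", "v_region_only", "partial")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class IgmineError(Exception):
    """Base class for validation and policy errors."""


# ---------------------------------------------------------------------------
# gene annotation


@dataclass(frozen=True)
class Region:
    label: str
    start: int
    end: int


@dataclass(frozen=True)
class CodingSegment:
    start: int
    end: int
    frame: int = 0


@dataclass(frozen=True)
class RSSSide:
    side: str  # "5prime" | "3prime"
    spacer_class: int  # 12 | 23


@dataclass(frozen=True)
class GeneAnnotation:
    """One IG gene: genomic interval, strand, sub-regions, coding layout, RSS sides."""

    gene_name: str
    locus: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_type: str
    functionality: str
    regions: tuple[Region, ...] = ()
    coding_segments: tuple[CodingSegment, ...] = ()
    rss_sides: tuple[RSSSide, ...] = ()

    def __post_init__(self):
        if self.start >= self.end:
            raise IgmineError(f"{self.gene_name}: start must be < end")
        if self.locus not in LOCI:
            raise IgmineError(f"{self.gene_name}: unknown locus {self.locus!r}")
        if self.strand not in ("+", "-"):
            raise IgmineError(f"{self.gene_name}: strand must be + or -")
        if self.gene_type not in GENE_TYPES:
            raise IgmineError(f"{self.gene_name}: unknown gene type {self.gene_type!r}")
        if self.functionality not in FUNCTIONALITIES:
            raise IgmineError(
                f"{self.gene_name}: unknown functionality {self.functionality!r}"
            )
        spans = []
        for reg in self.regions:
            if reg.label not in REGION_LABELS:
                raise IgmineError(f"{self.gene_name}: unknown region label {reg.label!r}")
            if not (self.start <= reg.start < reg.end <= self.end):
                raise IgmineError(
                    f"{self.gene_name}: region {reg.label} outside gene interval"
                )
            spans.append((reg.start, reg.end, reg.label))
        spans.sort()
        for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise IgmineError(
                    f"{self.gene_name}: regions {l1} and {l2} overlap"
                )
        for seg in self.coding_segments:
            if not (self.start <= seg.start < seg.end <= self.end):
                raise IgmineError(f"{self.gene_name}: coding segment outside gene")
        for rss in self.rss_sides:
            if rss.side not in ("5prime", "3prime"):
                raise IgmineError(f"{self.gene_name}: bad RSS side {rss.side!r}")
            if rss.spacer_class not in (12, 23):
                raise IgmineError(
                    f"{self.gene_name}: spacer class must be 12 or 23"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def rss_side(self, side: str) -> Optional[RSSSide]:
        for rss in self.rss_sides:
            if rss.side == side:
                return rss
        return None

    def to_gene_sense(self, start: int, end: int) -> tuple[int, int]:
        """Map a genomic sub-interval to offsets in the gene-sense sequence."""
        if self.strand == "+":
            return start - self.start, end - self.start
        return self.end - end, self.end - start


# ---------------------------------------------------------------------------
# VCF


@dataclass(frozen=True)
class PhasedVariantRecord:
    chrom: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    # per-sample (phase0 allele index, phase1 allele index) into [ref]+alts;
    # -1 marks a missing call
    genotypes: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.ref:
            raise IgmineError(f"{self.chrom}:{self.pos}: empty REF")
        n_alleles = 1 + len(self.alts)
        for a, b in self.genotypes:
            if a >= n_alleles or b >= n_alleles:
                raise IgmineError(
                    f"{self.chrom}:{self.pos}: genotype index exceeds allele count"
                )

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)


class VcfData(NamedTuple):
    records: list[PhasedVariantRecord]
    samples: list[str]
    n_symbolic_dropped: int


def _is_symbolic(alt: str) -> bool:
    return alt.startswith("<") or "[" in alt or "]" in alt or alt == "*"


def read_phased_vcf(
    path: str | Path,
    region: Optional[tuple[str, int, int]] = None,
    on_unphased: str = "error",
) -> VcfData:
    """Read a phased multi-sample VCF into 0-based records.

    ``region`` is (chrom, start, end), 0-based half-open, filtering on POS.
    Symbolic/CNV ALTs (``<CN*>``, breakends) are dropped and counted.
    ``on_unphased``: 'error' (default) rejects '/' genotypes naming sample and
    position; 'coerce' accepts them as if phased.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[PhasedVariantRecord] = []
    dropped = 0
    for v in vcf:
        alts = tuple(v.ALT)
        if any(_is_symbolic(a) for a in alts) or not alts:
            dropped += 1
            continue
        pos0 = v.POS - 1
        if region is not None:
            chrom, start, end = region
            if v.CHROM != chrom or not (start <= pos0 < end):
                continue
        gts = []
        for i, g in enumerate(v.genotypes):
            a, b, phased = g[0], g[1], bool(g[-1])
            if a >= 0 and b >= 0 and not phased and on_unphased == "error":
                raise IgmineError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{v.CHROM}:{v.POS}"
                )
            gts.append((a, b))
        records.append(
            PhasedVariantRecord(
                chrom=v.CHROM, pos=pos0, ref=v.REF, alts=alts, genotypes=tuple(gts)
            )
        )
    if dropped:
        logger.info("dropped %d symbolic/CNV records", dropped)
    records.sort(key=lambda r: (r.chrom, r.pos))
    return VcfData(records, samples, dropped)


# ---------------------------------------------------------------------------
# sample panel


@dataclass(frozen=True)
class SampleInfo:
    population: str
    superpopulation: str
    ebv_coverage: Optional[float]  # None = source not reported
    source_reported: bool


@dataclass
class SamplePanel:
    samples: dict[str, SampleInfo]

    def __post_init__(self):
        pop_to_super: dict[str, str] = {}
        for sid, info in self.samples.items():
            if info.superpopulation not in SUPERPOPULATIONS:
                raise IgmineError(
                    f"sample {sid}: unknown superpopulation {info.superpopulation!r}"
                )
            prev = pop_to_super.setdefault(info.population, info.superpopulation)
            if prev != info.superpopulation:
                raise IgmineError(
                    f"population {info.population} maps to multiple superpopulations"
                )

    def __getitem__(self, sample_id: str) -> SampleInfo:
        try:
            return self.samples[sample_id]
        except KeyError:
            raise IgmineError(f"unknown sample {sample_id!r}") from None

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.samples

    def __len__(self) -> int:
        return len(self.samples)


def read_sample_panel(path: str | Path) -> SamplePanel:
    """Panel TSV: sample, pop, superpop, ebv_coverage (empty/'.' = not reported)."""
    samples: dict[str, SampleInfo] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for need in ("sample", "pop", "superpop", "ebv_coverage"):
            if need not in idx:
                raise IgmineError(f"panel file missing column {need!r}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            sid = f[idx["sample"]]
            if sid in samples:
                raise IgmineError(f"duplicate sample {sid!r} in panel")
            cov_raw = f[idx["ebv_coverage"]].strip()
            if cov_raw in ("", "."):
                cov, reported = None, False
            else:
                cov, reported = float(cov_raw), True
            samples[sid] = SampleInfo(
                population=f[idx["pop"]],
                superpopulation=f[idx["superpop"]],
                ebv_coverage=cov,
                source_reported=reported,
            )
    return SamplePanel(samples)


def write_sample_panel(panel: SamplePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpop\tsuperpop\tebv_coverage\n")
        for sid, info in panel.samples.items():
            cov = "." if info.ebv_coverage is None else f"{info.ebv_coverage:g}"
            fh.write(f"{sid}\t{info.population}\t{info.superpopulation}\t{cov}\n")


# ---------------------------------------------------------------------------
# known-allele databases


@dataclass(frozen=True)
class KnownAlleleRecord:
    source: str
    allele_name: str
    sequence: str
    completeness: str

    def __post_init__(self):
        if self.source not in DB_SOURCES:
            raise IgmineError(f"unknown database source {self.source!r}")
        if self.completeness not in COMPLETENESS:
            raise IgmineError(f"unknown completeness {self.completeness!r}")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise IgmineError(
                f"{self.source}|{self.allele_name}: non-ACGT characters {sorted(bad)}"
            )

    @property
    def gene_name(self) -> str:
        """Gene part of the allele name (before '*' or trailing '_NN' rank)."""
        name = self.allele_name
        if "*" in name:
            return name.split("*")[0]
        if "_" in name:
            head, _, tail = name.rpartition("_")
            if tail.isdigit():
                return head
        return name


def read_known_db(path: str | Path, source: Optional[str] = None) -> list[KnownAlleleRecord]:
    """FASTA with headers ``source|allele_name|completeness``.

    If ``source`` is given it overrides the header's first field.
    """
    from Bio import SeqIO

    records = []
    seen: set[tuple[str, str]] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        if len(parts) != 3:
            raise IgmineError(
                f"database header {rec.description!r} is not source|name|completeness"
            )
        src = source or parts[0]
        key = (src, parts[1])
        if key in seen:
            raise IgmineError(f"duplicate allele name {parts[1]!r} in source {src}")
        seen.add(key)
        records.append(
            KnownAlleleRecord(
                source=src,
                allele_name=parts[1],
                sequence=str(rec.seq).upper(),
                completeness=parts[2],
            )
        )
    return records


def write_known_db(records: Sequence[KnownAlleleRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.source}|{rec.allele_name}|{rec.completeness}\n")
            for i in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# known-variant site list


@dataclass(frozen=True)
class KnownVariantSiteList:
    """Union of external variant catalogs as (chrom, pos0, ref, alt) tuples."""

    sites: frozenset[tuple[str, int, str, str]]

    def __contains__(self, site: tuple[str, int, str, str]) -> bool:
        return site in self.sites

    def __len__(self) -> int:
        return len(self.sites)


def read_site_list(path: str | Path) -> KnownVariantSiteList:
    """Site-list TSV: chrom, pos (0-based), ref, alt."""
    sites = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["chrom", "pos", "ref", "alt"]:
            raise IgmineError("site list must have columns chrom, pos, ref, alt")
        for line in fh:
            if not line.strip():
                continue
            chrom, pos, ref, alt = line.rstrip("\n").split("\t")[:4]
            sites.add((chrom, int(pos), ref, alt))
    return KnownVariantSiteList(frozenset(sites))


def write_site_list(sites: KnownVariantSiteList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(sites.sites):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


# ---------------------------------------------------------------------------
# gene annotation TSV

_ANNOT_COLUMNS = [
    "gene", "locus", "chrom", "start", "end", "strand", "type",
    "functionality", "regions", "coding", "rss",
]


def _parse_regions(raw: str) -> tuple[Region, ...]:
    if raw in ("", "."):
        return ()
    out = []
    for tok in raw.split(";"):
        label, span = tok.split(":")
        s, e = span.split("-")
        out.append(Region(label, int(s), int(e)))
    return tuple(out)


def _parse_coding(raw: str) -> tuple[CodingSegment, ...]:
    if raw in ("", "."):
        return ()
    out = []
    for tok in raw.split(";"):
        span, frame = tok.split(":")
        s, e = span.split("-")
        out.append(CodingSegment(int(s), int(e), int(frame)))
    return tuple(out)


def _parse_rss(raw: str) -> tuple[RSSSide, ...]:
    if raw in ("", "."):
        return ()
    out = []
    for tok in raw.split(";"):
        side, spacer = tok.split(":")
        out.append(RSSSide(side, int(spacer)))
    return tuple(out)


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    names: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ANNOT_COLUMNS:
            raise IgmineError(
                f"gene annotation columns must be {_ANNOT_COLUMNS}, got {header}"
            )
        for line in fh:
            if not line.strip():
                continue
            f = dict(zip(_ANNOT_COLUMNS, line.rstrip("\n").split("\t")))
            if f["gene"] in names:
                raise IgmineError(f"duplicate gene name {f['gene']!r}")
            names.add(f["gene"])
            genes.append(
                GeneAnnotation(
                    gene_name=f["gene"],
                    locus=f["locus"],
                    chrom=f["chrom"],
                    start=int(f["start"]),
                    end=int(f["end"]),
                    strand=f["strand"],
                    gene_type=f["type"],
                    functionality=f["functionality"],
                    regions=_parse_regions(f["regions"]),
                    coding_segments=_parse_coding(f["coding"]),
                    rss_sides=_parse_rss(f["rss"]),
                )
            )
    return genes


def write_gene_annotation(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOT_COLUMNS) + "\n")
        for g in genes:
            regions = ";".join(f"{r.label}:{r.start}-{r.end}" for r in g.regions) or "."
            coding = (
                ";".join(f"{c.start}-{c.end}:{c.frame}" for c in g.coding_segments)
                or "."
            )
            rss = ";".join(f"{r.side}:{r.spacer_class}" for r in g.rss_sides) or "."
            fh.write(
                f"{g.gene_name}\t{g.locus}\t{g.chrom}\t{g.start}\t{g.end}\t"
                f"{g.strand}\t{g.gene_type}\t{g.functionality}\t{regions}\t"
                f"{coding}\t{rss}\n"
            )


# ---------------------------------------------------------------------------
# reference genome


class ReferenceGenome:
    """Thin wrapper over an indexed FASTA giving 0-based half-open slices."""

    def __init__(self, path: str | Path):
        from pyfaidx import Fasta

        self._fasta = Fasta(str(path), sequence_always_upper=True)

    def contigs(self) -> list[str]:
        return list(self._fasta.keys())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fasta:
            raise IgmineError(f"contig {chrom!r} not in reference")
        contig = self._fasta[chrom]
        if start < 0 or end > len(contig):
            raise IgmineError(
                f"interval {chrom}:{start}-{end} outside contig of length {len(contig)}"
            )
        return str(contig[start:end])


# ---------------------------------------------------------------------------
# allele FASTA + metadata TSV (duck-typed over AlleleCall to avoid a cycle)

_ALLELE_COLUMNS = [
    "gene", "allele_id", "support", "tier", "category", "db_matches",
    "curation_flags", "supporters", "signature", "per_pop", "protein",
]


def _fmt_signature(signature) -> str:
    return ";".join(f"{p}:{r}:{a}" for p, r, a in signature) or "."


def _parse_signature(raw: str):
    if raw in ("", "."):
        return ()
    out = []
    for tok in raw.split(";"):
        p, r, a = tok.split(":")
        out.append((int(p), r, a))
    return tuple(out)


def write_alleles_fasta(alleles, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alleles:
            fh.write(f">{a.allele_id}\n")
            for i in range(0, len(a.sequence), 80):
                fh.write(a.sequence[i : i + 80] + "\n")


def write_allele_metadata_tsv(alleles, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ALLELE_COLUMNS) + "\n")
        for a in alleles:
            db = ";".join(f"{s}:{n}" for s, n in a.db_matches) or "."
            flags = ";".join(a.curation_flags) or "."
            sup = ";".join(f"{s}:{p}" for s, p in a.supporters)
            pp = ";".join(f"{k}:{v}" for k, v in sorted(a.per_population_support.items())) or "."
            fh.write(
                f"{a.gene_name}\t{a.allele_id}\t{a.support_total}\t{a.tier}\t"
                f"{a.category}\t{db}\t{flags}\t{sup}\t"
                f"{_fmt_signature(a.variant_signature)}\t{pp}\t{a.protein or '.'}\n"
            )


def read_alleles(fasta_path: str | Path, tsv_path: str | Path):
    """Reconstruct AlleleCall objects from the FASTA + metadata TSV pair."""
    from Bio import SeqIO

    from .calling import AlleleCall

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    alleles = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ALLELE_COLUMNS:
            raise IgmineError(f"allele metadata columns must be {_ALLELE_COLUMNS}")
        for line in fh:
            if not line.strip():
                continue
            f = dict(zip(_ALLELE_COLUMNS, line.rstrip("\n").split("\t")))
            if f["allele_id"] not in seqs:
                raise IgmineError(f"allele {f['allele_id']} missing from FASTA")
            db = (
                tuple(tuple(tok.split(":", 1)) for tok in f["db_matches"].split(";"))
                if f["db_matches"] != "."
                else ()
            )
            flags = tuple(f["curation_flags"].split(";")) if f["curation_flags"] != "." else ()
            supporters = tuple(
                (tok.rsplit(":", 1)[0], int(tok.rsplit(":", 1)[1]))
                for tok in f["supporters"].split(";")
            )
            pp = (
                {k: int(v) for k, v in (tok.split(":") for tok in f["per_pop"].split(";"))}
                if f["per_pop"] != "."
                else {}
            )
            alleles.append(
                AlleleCall(
                    gene_name=f["gene"],
                    allele_id=f["allele_id"],
                    sequence=seqs[f["allele_id"]],
                    support_total=int(f["support"]),
                    supporters=supporters,
                    variant_signature=_parse_signature(f["signature"]),
                    per_population_support=pp,
                    tier=f["tier"],
                    category=f["category"],
                    db_matches=db,
                    curation_flags=flags,
                    protein=None if f["protein"] == "." else f["protein"],
                )
            )
    return alleles
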