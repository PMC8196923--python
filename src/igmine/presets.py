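"""Ready-made fixture configurations.

``default_fixture_config`` reproduces the study conditions: a 2,504-sample
cohort in 26 populations (5,008 haplotypes per gene) with planted alleles
whose supports bracket every confidence-tier boundary (3/4 for known, 6/7
and 18/19 for novel alleles), population targeting that exercises all four
distribution categories, duplicated (GA) and operationally
indistinguishable (OI) gene pairs, RSS flanks of both spacer classes, and a
J gene with the 22-bp spacer deviation. ``small_fixture_config`` is a
5-population scale-down for fast unit tests with identical thresholds.
``rule3_fixture_config`` reconstructs the shared-exclusive-mutation
curation scenario: one IGHA1 allele and two IGHA2 alleles carrying the same
exclusive mutation at the same aligned position, all three of which must be
removed as mis-mapping artifacts.
"""

from __future__ import annotations

from .simulate import (
    COHORT_PANEL,
    FixtureConfig,
    GeneSpec,
    PlantedAllele,
    PlantedVariant,
    PopulationSpec,
)

AFR_POPS = ("YRI", "LWK", "GWD", "MSL", "ESN", "ASW", "ACB")

IMGT_FULL = (("IMGT", "full_with_leader"),)
IGPDB_FULL = (("IgPdb", "full_with_leader"),)
VB_FULL = (("VBASE2_class1", "full_with_leader"),)


def spread_counts(pops: tuple[str, ...], total: int) -> tuple[tuple[str, int], ...]:
    """Distribute ``total`` haplotypes over populations as evenly as possible."""
    base, rem = divmod(total, len(pops))
    return tuple(
        (p, base + (1 if i < rem else 0)) for i, p in enumerate(pops) if base or i < rem
    )


def cohort_populations() -> tuple[PopulationSpec, ...]:
    return tuple(
        PopulationSpec(name, superpop, size)
        for name, (superpop, size) in COHORT_PANEL.items()
    )


def _snp(off: int) -> PlantedVariant:
    return PlantedVariant("snp", off)


def _v_battery(all_pops: tuple[str, ...], afr: tuple[str, ...],
               eur_pop: str, eas_pop: str, sas_pop: str,
               scale_known: int = 120) -> tuple[PlantedAllele, ...]:
    """Planted alleles bracketing every tier boundary for one V gene.

    Offsets: 5 is in the leader, >=141 in the V region (leader 45 +
    intron 84 layout); all at least 4 bp apart.
    """
    return (
        PlantedAllele("kn_all", ( _snp(150),), pop_counts=spread_counts(all_pops, scale_known),
                      in_dbs=IMGT_FULL),
        PlantedAllele("kn4", (_snp(5),), pop_counts=((eur_pop, 4),), in_dbs=IGPDB_FULL),
        PlantedAllele("kn3", (_snp(158),), pop_counts=((eas_pop, 3),), in_dbs=IMGT_FULL),
        PlantedAllele("nv19", (_snp(166), PlantedVariant("ins", 60, "TT")),
                      pop_counts=spread_counts(afr, 19)),
        PlantedAllele("nv18", (_snp(174),),
                      pop_counts=spread_counts((afr[0], eur_pop), 18)),
        PlantedAllele("nv7", (_snp(182),), pop_counts=((eas_pop, 7),)),
        PlantedAllele("nv6", (_snp(190),), pop_counts=((sas_pop, 6),)),
    )


def default_fixture_config(seed: int = 1) -> FixtureConfig:
    all_pops = tuple(COHORT_PANEL)
    one_per_super = ("YRI", "MXL", "CHB", "CEU", "GIH")
    genes = (
        GeneSpec(
            name="IGHV1-8", locus="IGH", chrom="chr14", strand="+",
            rss_spacers=(("3prime", 23),),
            planted=_v_battery(all_pops, AFR_POPS, "CEU", "CHB", "GIH"),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHV1-69", locus="IGH", chrom="chr14", strand="+",
            rss_spacers=(("3prime", 23),),
            planted=(
                PlantedAllele("nv19", (_snp(160),), pop_counts=spread_counts(AFR_POPS, 19)),
            ),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHV1-69D", locus="IGH", chrom="chr14", strand="+",
            rss_spacers=(("3prime", 23),),
            paralog_of="IGHV1-69", paralog_diffs=2,
            paralog_diff_positions=(200, 260),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHV3-23", locus="IGH", chrom="chr14", strand="-",
            rss_spacers=(("3prime", 23),),
            planted=(
                PlantedAllele(
                    "eas30", (_snp(150),),
                    pop_counts=(("CDX", 4), ("CHB", 2), ("CHS", 5), ("JPT", 10), ("KHV", 9)),
                    in_dbs=IMGT_FULL,
                ),
                PlantedAllele("kn_all", (_snp(160),), pop_counts=spread_counts(all_pops, 60),
                              in_dbs=IMGT_FULL),
            ),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHV3-15", locus="IGH", chrom="chr14", strand="+",
            rss_spacers=(("3prime", 23),),
            planted=(
                PlantedAllele("nv20", (_snp(200),),
                              pop_counts=spread_counts(one_per_super, 20)),
                PlantedAllele("fp_stop", (_snp(210),), pop_counts=(("CEU", 19),),
                              plant_stop=True),
                PlantedAllele("fp_unlisted", (_snp(220),), pop_counts=(("TSI", 19),),
                              listed_in_sites=False),
            ),
            ref_in_dbs=IMGT_FULL + (("IgPdb", "v_region_only"),),
        ),
        GeneSpec(
            name="IGHV3-16", locus="IGH", chrom="chr14", strand="+",
            functionality="pseudogene",
            rss_spacers=(("3prime", 23),), rss_gap=(("3prime", 15),),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHJ4", locus="IGH", chrom="chr14", gene_type="J",
            rss_spacers=(("5prime", 23),), ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHJ6", locus="IGH", chrom="chr14", gene_type="J",
            rss_spacers=(("5prime", 23),), spacer_override=(("5prime", 22),),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHD3-10", locus="IGH", chrom="chr14", gene_type="D",
            rss_spacers=(("5prime", 12), ("3prime", 12)),
            planted=(
                PlantedAllele("nv19", (_snp(10),), pop_counts=spread_counts(all_pops, 26)),
            ),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHA1", locus="IGH", chrom="chr14", gene_type="C",
            planted=(
                PlantedAllele("syn", (PlantedVariant("syn", 110),),
                              pop_counts=spread_counts(one_per_super, 25)),
                PlantedAllele("nonsyn", (PlantedVariant("nonsyn", 210),),
                              pop_counts=spread_counts(one_per_super, 20)),
            ),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHA2", locus="IGH", chrom="chr14", gene_type="C",
            paralog_of="IGHA1", paralog_diffs=3,
            paralog_diff_positions=(30, 150, 250),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGKV1-5", locus="IGK", chrom="chr2", strand="+",
            rss_spacers=(("3prime", 12),),
            planted=(
                PlantedAllele("nv19", (_snp(170),), pop_counts=spread_counts(AFR_POPS, 19)),
            ),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGKJ1", locus="IGK", chrom="chr2", gene_type="J",
            rss_spacers=(("5prime", 23),), ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGLV2-14", locus="IGL", chrom="chr22", strand="+",
            rss_spacers=(("3prime", 23),),
            planted=(
                PlantedAllele("nv7", (_snp(180),), pop_counts=(("LWK", 7),)),
            ),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGLJ1", locus="IGL", chrom="chr22", gene_type="J",
            rss_spacers=(("5prime", 12),), ref_in_dbs=IMGT_FULL,
        ),
    )
    return FixtureConfig(
        seed=seed,
        populations=cohort_populations(),
        genes=genes,
        group_gene_pairs=(("IGHV1-69", "IGHV1-69D"),),
    )


def small_fixture_config(seed: int = 1, noise_rate: float = 0.0) -> FixtureConfig:
    pops = (
        PopulationSpec("YRI", "AFR", 20),
        PopulationSpec("MXL", "AMR", 12),
        PopulationSpec("CHB", "EAS", 12),
        PopulationSpec("CEU", "EUR", 12),
        PopulationSpec("GIH", "SAS", 12),
    )
    names = tuple(p.name for p in pops)
    genes = (
        GeneSpec(
            name="IGHV1-8", locus="IGH", chrom="chr14", strand="+",
            rss_spacers=(("3prime", 23),),
            planted=_v_battery(names, ("YRI",), "CEU", "CHB", "GIH", scale_known=30),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHV1-69", locus="IGH", chrom="chr14", strand="+",
            rss_spacers=(("3prime", 23),),
            planted=(
                PlantedAllele("nv19", (_snp(160),), pop_counts=(("YRI", 19),)),
            ),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHV1-69D", locus="IGH", chrom="chr14", strand="+",
            rss_spacers=(("3prime", 23),),
            paralog_of="IGHV1-69", paralog_diffs=2,
            paralog_diff_positions=(200, 260),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHV3-23", locus="IGH", chrom="chr14", strand="-",
            rss_spacers=(("3prime", 23),),
            planted=(
                PlantedAllele("kn_all", (_snp(160),), pop_counts=spread_counts(names, 20),
                              in_dbs=IMGT_FULL),
            ),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHJ6", locus="IGH", chrom="chr14", gene_type="J",
            rss_spacers=(("5prime", 23),), spacer_override=(("5prime", 22),),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHD3-10", locus="IGH", chrom="chr14", gene_type="D",
            rss_spacers=(("5prime", 12), ("3prime", 12)),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHA1", locus="IGH", chrom="chr14", gene_type="C",
            planted=(
                PlantedAllele("syn", (PlantedVariant("syn", 110),),
                              pop_counts=spread_counts(names, 25)),
            ),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHA2", locus="IGH", chrom="chr14", gene_type="C",
            paralog_of="IGHA1", paralog_diffs=3,
            paralog_diff_positions=(30, 150, 250),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGKV1-5", locus="IGK", chrom="chr2", strand="+",
            rss_spacers=(("3prime", 12),),
            planted=(
                PlantedAllele("nv19", (_snp(170),), pop_counts=(("YRI", 19),)),
            ),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGLV2-14", locus="IGL", chrom="chr22", strand="+",
            rss_spacers=(("3prime", 23),),
            planted=(
                PlantedAllele("nv7", (_snp(180),), pop_counts=(("YRI", 7),)),
            ),
            ref_in_dbs=IMGT_FULL,
        ),
    )
    return FixtureConfig(
        seed=seed,
        populations=pops,
        genes=genes,
        group_gene_pairs=(("IGHV1-69", "IGHV1-69D"),),
        noise_rate=noise_rate,
    )


def rule3_fixture_config(seed: int = 1) -> FixtureConfig:
    """IGHA1/IGHA2 shared-exclusive-mutation scenario.

    The mutation at offset 120 is planted in one IGHA1 allele and two IGHA2
    alleles; it is absent from the databases, so all three must be removed.
    A fourth IGHA2 allele with a private mutation must be retained.
    """
    pops = (
        PopulationSpec("YRI", "AFR", 30),
        PopulationSpec("CEU", "EUR", 30),
    )
    shared = _snp(120)
    genes = (
        GeneSpec(
            name="IGHA1", locus="IGH", chrom="chr14", gene_type="C",
            planted=(
                PlantedAllele("r3a", (shared,), pop_counts=(("YRI", 10),),
                              expect_rule3_removed=True),
            ),
            ref_in_dbs=IMGT_FULL,
        ),
        GeneSpec(
            name="IGHA2", locus="IGH", chrom="chr14", gene_type="C",
            paralog_of="IGHA1", paralog_diffs=3,
            paralog_diff_positions=(30, 180, 250),
            planted=(
                PlantedAllele("r3b", (shared, _snp(140)), pop_counts=(("CEU", 9),),
                              expect_rule3_removed=True),
                PlantedAllele("r3c", (shared, _snp(160)), pop_counts=(("YRI", 8),),
                              expect_rule3_removed=True),
                PlantedAllele("ok", (_snp(200),), pop_counts=(("CEU", 19),)),
            ),
            ref_in_dbs=IMGT_FULL,
        ),
    )
    return FixtureConfig(seed=seed, populations=pops, genes=genes)
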