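"""Population and sample-source annotation of alleles.

Each allele's supporting haplotypes are aggregated per population and per
superpopulation (AFR, AMR, EAS, EUR, SAS), yielding a distribution
category: ALL (present in every superpopulation), AFR (only in Africans),
AFR_SHARED (in Africans plus some but not all others), NON_AFR (absent from
Africans). Presence for the category is one supporting haplotype or more;
the separate binary presence vector uses the display threshold of four
haplotypes per population. Supporters are also split by sample source:
Set-Blood (EBV genome coverage below 20X, or source not reported) versus
Set-EBV (the remaining, EBV-transformed cell-line samples).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .calling import AlleleCall
from .core_io import SUPERPOPULATIONS, IgmineError, SamplePanel

DEFAULT_PRESENCE_THRESHOLD = 4
DEFAULT_EBV_CUTOFF = 20.0


@dataclass
class PopulationDistribution:
    per_population: dict[str, int]
    per_superpopulation: dict[str, int]
    category: str  # ALL | AFR | AFR_SHARED | NON_AFR
    presence_vector: dict[str, bool]
    set_blood_support: int
    set_ebv_support: int


def categorize_presence(present_superpops: set[str]) -> str:
    """Distribution category from the set of superpopulations with support."""
    if not present_superpops:
        raise IgmineError("allele with no supporting superpopulation")
    if present_superpops == set(SUPERPOPULATIONS):
        return "ALL"
    if "AFR" in present_superpops:
        return "AFR" if present_superpops == {"AFR"} else "AFR_SHARED"
    return "NON_AFR"


def split_blood_ebv(
    allele: AlleleCall, panel: SamplePanel, ebv_cutoff: float = DEFAULT_EBV_CUTOFF
) -> tuple[int, int]:
    """Supporter counts in (Set-Blood, Set-EBV).

    A supporter falls in Set-Blood iff its sample's EBV coverage is strictly
    below the cutoff or the source was not reported; otherwise Set-EBV.
    """
    blood = ebv = 0
    for sample_id, _phase in allele.supporters:
        info = panel[sample_id]
        if info.ebv_coverage is None or info.ebv_coverage < ebv_cutoff:
            blood += 1
        else:
            ebv += 1
    return blood, ebv


def annotate_population(
    allele: AlleleCall,
    panel: SamplePanel,
    presence_threshold: int = DEFAULT_PRESENCE_THRESHOLD,
    category_threshold: int = 1,
    ebv_cutoff: float = DEFAULT_EBV_CUTOFF,
) -> PopulationDistribution:
    """Aggregate an allele's supporters into a population distribution."""
    per_pop: Counter = Counter()
    per_super: Counter = Counter()
    for sample_id, _phase in allele.supporters:
        info = panel[sample_id]
        per_pop[info.population] += 1
        per_super[info.superpopulation] += 1
    present = {sp for sp, n in per_super.items() if n >= category_threshold}
    blood, ebv = split_blood_ebv(allele, panel, ebv_cutoff)
    dist = PopulationDistribution(
        per_population=dict(per_pop),
        per_superpopulation=dict(per_super),
        category=categorize_presence(present),
        presence_vector={p: n >= presence_threshold for p, n in per_pop.items()},
        set_blood_support=blood,
        set_ebv_support=ebv,
    )
    assert sum(dist.per_population.values()) == allele.support_total
    assert sum(dist.per_superpopulation.values()) == allele.support_total
    assert dist.set_blood_support + dist.set_ebv_support == allele.support_total
    allele.per_population_support = dict(per_pop)
    return dist
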