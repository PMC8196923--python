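import json
from pathlib import Path

import pytest

from igmine.pipeline import PipelineConfig, run_all
from igmine.presets import small_fixture_config
from igmine.simulate import generate_fixture


def write_vcf(path: Path, lines: list[str], samples: list[str]) -> Path:
    """Hand-written VCF for parser tests; ``lines`` are pre-formatted rows."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=chr14,length=100000>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for line in lines:
            fh.write(line + "\n")
    return path


def pipeline_config_for(bundle, outdir, **overrides) -> PipelineConfig:
    kwargs = dict(
        vcf=str(bundle.vcf),
        reference=str(bundle.reference),
        annotation=str(bundle.annotation),
        panel=str(bundle.panel),
        databases={s: str(p) for s, p in bundle.databases.items()},
        site_list=str(bundle.site_list),
        outdir=str(outdir),
        group_gene_pairs=(("IGHV1-69", "IGHV1-69D"),),
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_fixture")
    return generate_fixture(small_fixture_config(seed=1), outdir)


@pytest.fixture(scope="session")
def small_truth(small_bundle):
    with open(small_bundle.truth) as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def small_result(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_out")
    return run_all(pipeline_config_for(small_bundle, outdir))
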