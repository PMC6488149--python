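from __future__ import annotations

import pytest

from panelburden import (
    PopulationSpec,
    RunConfig,
    ScenarioConfig,
    run_full,
    simulate_cohort,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={contig},length=10000000>
##INFO=<ID=Func,Number=1,Type=String,Description="Genic context">
##INFO=<ID=ExonicFunc,Number=1,Type=String,Description="Exonic consequence">
##INFO=<ID=1000g2015aug_all,Number=1,Type=Float,Description="1000G AF">
##INFO=<ID=esp6500siv2_all,Number=1,Type=Float,Description="ESP AF">
##INFO=<ID=ExAC_nontcga_ALL,Number=1,Type=Float,Description="ExAC AF">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


@pytest.fixture
def make_vcf(tmp_path):
    """Write a hand-crafted VCF; records are (pos, ref, alts, info, genotype cells)."""

    def _make(records, samples=("S1", "S2"), contig="chr1", name="test.vcf"):
        path = tmp_path / name
        lines = [VCF_HEADER.format(contig=contig, samples="\t".join(samples)).rstrip("\n")]
        for pos, ref, alts, info, cells in records:
            lines.append(
                f"{contig}\t{pos}\t.\t{ref}\t{','.join(alts)}\t100\tPASS\t{info}\tGT:DP\t"
                + "\t".join(cells)
            )
        path.write_text("\n".join(lines) + "\n")
        return path

    return _make


def small_scenario(seed: int = 11) -> ScenarioConfig:
    """Desk-sized two-population cohort with every decoy kind present."""
    return ScenarioConfig(
        populations=[
            PopulationSpec("White", 12, 2.0e-5, 4.0),
            PopulationSpec("Black", 10, 2.6e-5, 1.0),
        ],
        exome_size=400_000,
        panel_size=40_000,
        n_capture_blocks=40,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    root = tmp_path_factory.mktemp("cohort")
    return simulate_cohort(small_scenario(), root)


def run_config_for(sim, out_dir=None, **overrides) -> RunConfig:
    kwargs = dict(
        cohort="testcohort",
        vcf=sim.vcf_path,
        coverage_dir=sim.root / "coverage",
        capture_bed=sim.region_paths["capture"],
        panel_bed=sim.region_paths["panel"],
        populations=sim.populations_path,
        mask_beds={
            "tandem_repeat": sim.region_paths["tandem_repeat"],
            "segdup": sim.region_paths["segdup"],
        },
        ccds_bed=sim.region_paths["ccds"],
        output_dir=out_dir,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    return run_full(run_config_for(small_cohort))
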