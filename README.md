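# panelburden

Rare protein-truncating variant burden testing against gene panels, with
population-specific background rates normalised by per-individual callable
sites.

## The problem

Multigene panel testing assumes that a curated panel of predisposition genes
captures inherited risk equally well across populations. A direct way to
probe that assumption in a sequenced case cohort is to ask, population by
population: does the panel carry more rare protein-truncating variants (PTVs
— stop gain, stop loss, frameshift indels, canonical splice-site variants)
than expected from that population's own exome-wide background PTV rate?  A
population can carry the *largest* exome-wide burden of truncating mutations
and still show *no* excess in the panel — the signature of predisposition
genes that current panels do not cover.

`panelburden` implements that analysis end to end for germline exome data:

1. **Filtering** — ANNOVAR-annotated VCFs are reduced to rare PTVs: per-sample
   calls with depth < 3 become missing, sites with missing rate > 0.1 are
   dropped, only truncating consequence classes are kept, sites above 2%
   allele frequency in any reference source (1000 Genomes, ESP, ExAC) are
   removed, as are indels > 20 bp, carrier calls with depth < 15, and
   positions in tandem-repeat or segmental-duplication masks or outside the
   capture territory.
2. **Exposure** — for each individual *j* of population *i*, the callable
   exome length `L_ij` (positions of the capture region with read depth ≥ 15)
   and the callable panel length `l_ij` (panel ∩ capture, same criteria),
   from per-sample coverage BEDs or per-base depth tables.
3. **Burden testing** — the background rate is the pooled ratio

       λ_i = Σ_j M_ij / Σ_j L_ij

   (M = per-individual exome-wide PTV count). Panel enrichment is the exact
   two-sided Poisson rate test of `x = Σ_j m_ij` observed panel events
   against mean `λ_i · T`, `T = Σ_j l_ij` (the construction of R's
   `poisson.test(x, T, r)`), with a 95% central Poisson interval as the
   "random expectation" band.  Between-group contrasts use Fisher's exact
   test on panel mutation rates (or carrier prevalence) and the Mann-Whitney
   U test on per-individual exome-wide counts.  Cross-cohort meta-analysis
   pools counts and exposures before re-testing.
4. **Simulation** — a synthetic-cohort generator emits complete cohorts
   (annotated VCF, coverage BEDs, region BEDs, ground-truth manifest) with
   configurable population rates, panel enrichment factors, coverage dropout
   and per-filter decoy variants, plus fast count-level simulators for
   calibration and power studies.

The packaged default panel is a 19-gene breast-cancer predisposition list
(ATM, BRCA1, BRCA2, BRIP1, CDH1, CHEK2, MLH1, MSH2, MSH6, NBN, PALB2, PMS2,
PTEN, RAD51C, RAD51D, STK11, TP53, MUTYH, BARD1); gene-to-interval mapping is
always a user-supplied BED.

## Worked example

Simulate a two-population cohort in which Blacks have the higher exome-wide
truncating rate (6.5e-7 vs 5e-7 per callable position) but only Whites carry
panel enrichment (4x), then run the full pipeline on the generated files:

```python
from panelburden import (PopulationSpec, RunConfig, ScenarioConfig,
                         run_full, simulate_cohort)

cfg = ScenarioConfig(
    populations=[PopulationSpec("White", 48, 5e-7, 4.0),
                 PopulationSpec("Black", 40, 6.5e-7, 1.0)],
    seed=7,
)
sim = simulate_cohort(cfg, "example_cohort")
bundle = run_full(RunConfig(
    cohort="example", vcf=sim.vcf_path, coverage_dir=sim.root / "coverage",
    capture_bed=sim.region_paths["capture"], panel_bed=sim.region_paths["panel"],
    populations=sim.populations_path,
    mask_beds={"tandem_repeat": sim.region_paths["tandem_repeat"],
               "segdup": sim.region_paths["segdup"]},
))
for r in bundle.results:
    print(f"{r.population}: lambda={r.lambda_hat:.3g}/bp  x={r.x_obs}  "
          f"expected={r.expected:.2f}  interval={r.expectation_interval}  "
          f"p={r.p_poisson:.3g}")
```

prints

```
Black: lambda=6.34e-07/bp  x=4  expected=2.26  interval=(0, 6)  p=0.297
White: lambda=5e-07/bp  x=7  expected=2.19  interval=(0, 5)  p=0.00735
```

The estimated background rates recover the generating values; the White
panel count (7 observed vs 2.19 expected, outside the 95% expectation
interval) is significantly enriched (p = 0.0074) while the Black panel count
is compatible with its own background (p = 0.30) — even though the
Mann-Whitney comparison of per-individual exome-wide counts confirms the
*higher* overall burden in Blacks (p = 4.8e-4 in this run).  That reversal —
highest exome-wide burden, no panel excess — is the pattern the pipeline is
designed to expose.

The same stages are scriptable from a shell:

```sh
panelburden simulate --scenario scenario.yaml --out cohort/ --seed 7
panelburden run --config run.yaml --out results/
panelburden meta --config discovery.yaml --config validation.yaml --out meta/
```

with `filter`, `exposure` and `burden` subcommands for stage-by-stage use.

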