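"""End-to-end orchestration: filter -> exposure -> burden -> report.

:func:`run_full` executes one cohort from an annotated VCF, per-sample
coverage BEDs and region BEDs through the filter cascade, the callable-site
exposure table and the per-population burden tests, writing figure-ready
tables (per-sample exome-wide counts, panel event/carrier percentages,
observed-vs-expected with random-expectation intervals) plus a results TSV
and a run manifest.  :func:`run_meta` pools two or more cohorts per shared
population and re-runs the exact tests on the pooled aggregates.

Populations below a configurable sample-size floor are flagged rather than
dropped: with a handful of individuals the burden tests are reported but
carry little power.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .burden_stats import (
    BurdenResult,
    PopulationBurden,
    analyze_population,
    fisher_rate_comparison,
    mannwhitney_burden,
    pool_burdens,
)
from .callable_sites import ExposureTable, build_exposure_table
from .io_formats import (
    ConfigurationError,
    HET,
    HOM_ALT,
    RegionSet,
    Variant,
    read_coverage_bed,
    read_regions,
    read_vcf,
    region_intersect,
    write_results,
)
from .variant_filtering import FilterConfig, FilterReport, run_cascade

log = logging.getLogger("panelburden")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    cohort: str
    vcf: Path
    coverage_dir: Path
    capture_bed: Path
    panel_bed: Path
    populations: Path
    mask_beds: dict[str, Path] = field(default_factory=dict)
    ccds_bed: Path | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    ccds_restrict: bool = False
    fisher_mode: str = "events_vs_exposure"
    fisher_reference: str | None = None
    mw_reference: str | None = None
    min_samples_warn: int = 5
    level: float = 0.95
    output_dir: Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vcf", "coverage_dir", "capture_bed", "panel_bed", "populations"):
            setattr(self, name, Path(getattr(self, name)))
        self.mask_beds = {k: Path(v) for k, v in self.mask_beds.items()}
        if self.ccds_bed is not None:
            self.ccds_bed = Path(self.ccds_bed)
        if self.output_dir is not None:
            self.output_dir = Path(self.output_dir)
        if self.fisher_mode not in ("events_vs_exposure", "carriers"):
            raise ConfigurationError(f"unknown fisher mode {self.fisher_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        kwargs = dict(raw)
        for key in ("vcf", "coverage_dir", "capture_bed", "panel_bed", "populations"):
            if key not in kwargs:
                raise ConfigurationError(f"{path}: missing required key {key!r}")
            kwargs[key] = resolve(kwargs[key])
        kwargs["mask_beds"] = {
            k: resolve(v) for k, v in (kwargs.get("mask_beds") or {}).items()
        }
        if kwargs.get("ccds_bed"):
            kwargs["ccds_bed"] = resolve(kwargs["ccds_bed"])
        if kwargs.get("output_dir"):
            kwargs["output_dir"] = resolve(kwargs["output_dir"])
        if "filter" in kwargs and kwargs["filter"] is not None:
            kwargs["filter"] = FilterConfig.from_mapping(kwargs["filter"])
        kwargs.setdefault("cohort", path.stem)
        return cls(**kwargs)

    def validate(self) -> None:
        """Fail fast, before any compute, on missing inputs."""
        for label, p in [
            ("vcf", self.vcf),
            ("coverage_dir", self.coverage_dir),
            ("capture_bed", self.capture_bed),
            ("panel_bed", self.panel_bed),
            ("populations", self.populations),
            *[(f"mask_beds[{k}]", v) for k, v in self.mask_beds.items()],
            *([("ccds_bed", self.ccds_bed)] if self.ccds_bed else []),
        ]:
            if not Path(p).exists():
                raise ConfigurationError(f"{self.cohort}: {label} path does not exist: {p}")
        if self.ccds_restrict and self.ccds_bed is None:
            raise ConfigurationError(
                f"{self.cohort}: ccds_restrict requires a ccds_bed"
            )


# ---------------------------------------------------------------------------
# Result bundles
# ---------------------------------------------------------------------------

@dataclass
class RunBundle:
    cohort: str
    config: RunConfig
    filter_report: FilterReport
    exposure: ExposureTable
    burdens: dict[str, PopulationBurden]
    results: list[BurdenResult]
    tables: dict[str, pd.DataFrame]
    surviving: list[Variant]
    out_dir: Path | None = None


@dataclass
class MetaBundle:
    cohorts: list[RunBundle]
    pooled: dict[str, PopulationBurden]
    results: list[BurdenResult]
    tables: dict[str, pd.DataFrame]
    excluded_populations: list[str]
    out_dir: Path | None = None


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def read_population_table(path: str | Path) -> dict[str, str]:
    tbl = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in tbl.columns}
    if "sample_id" not in cols or "population" not in cols:
        raise ConfigurationError(
            f"{path}: population table needs sample_id and population columns"
        )
    return dict(zip(tbl[cols["sample_id"]].astype(str), tbl[cols["population"]].astype(str)))


def event_counts(
    variants: Iterable[Variant], samples: Sequence[str], region: RegionSet | None = None
) -> dict[str, int]:
    """Number of qualifying mutation events per sample.

    An event is a carrier call (het or hom) of a surviving variant; with a
    region, only variants anchored inside it are counted.
    """
    counts = {s: 0 for s in samples}
    for v in variants:
        if region is not None and not region.contains(v.chrom, v.pos0):
            continue
        for sample, call in v.sample_calls.items():
            if call.genotype in (HET, HOM_ALT) and sample in counts:
                counts[sample] += 1
    return counts


def _reference_label(preferred: str | None, default: str, labels: Sequence[str]) -> str:
    if preferred is not None:
        if preferred not in labels:
            raise ConfigurationError(
                f"reference population {preferred!r} not among {sorted(labels)}"
            )
        return preferred
    return default if default in labels else sorted(labels)[0]


def _attach_comparisons(
    results: list[BurdenResult],
    burdens: Mapping[str, PopulationBurden],
    exome_counts: Mapping[str, np.ndarray],
    fisher_reference: str | None,
    mw_reference: str | None,
) -> None:
    """Pairwise Fisher and Mann-Whitney contrasts plus Bonferroni columns.

    Fisher contrasts run against the White group by default (both the
    rate-per-position and the carrier-prevalence table); the Mann-Whitney
    exome-wide comparison runs against the Black group by default.  No
    multiplicity correction governs significance calls; the Bonferroni column
    is reported for transparency only.
    """
    labels = list(burdens)
    if len(labels) < 2:
        for res in results:
            res.bonferroni["poisson_enrichment"] = min(1.0, res.p_poisson * len(results))
        return
    fisher_ref = _reference_label(fisher_reference, "White", labels)
    mw_ref = _reference_label(mw_reference, "Black", labels)
    n_contrasts = len(labels) - 1
    for res in results:
        res.bonferroni["poisson_enrichment"] = min(1.0, res.p_poisson * len(results))
        label = res.population
        if label != fisher_ref:
            for mode, tag in (
                ("events_vs_exposure", "fisher_events"),
                ("carriers", "fisher_carriers"),
            ):
                p = fisher_rate_comparison(burdens[label], burdens[fisher_ref], mode=mode)
                key = f"{tag}_vs_{fisher_ref}"
                res.comparisons[key] = p
                res.bonferroni[key] = min(1.0, p * n_contrasts)
        if label != mw_ref:
            p = mannwhitney_burden(exome_counts[label], exome_counts[mw_ref])
            key = f"mannwhitney_exome_vs_{mw_ref}"
            res.comparisons[key] = p
            res.bonferroni[key] = min(1.0, p * n_contrasts)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_full(cfg: RunConfig) -> RunBundle:
    """Execute the whole pipeline for one cohort."""
    cfg.validate()
    log.info("cohort %s: thresholds %s", cfg.cohort, json.dumps(cfg.filter.to_dict()))

    capture = read_regions(cfg.capture_bed, name="capture")
    panel = read_regions(cfg.panel_bed, name="panel")
    masks = {role: read_regions(path, name=role) for role, path in cfg.mask_beds.items()}
    if cfg.ccds_restrict:
        ccds = read_regions(cfg.ccds_bed, name="ccds")
        capture = region_intersect(capture, ccds, name="capture")
        log.info("cohort %s: CCDS harmonisation on", cfg.cohort)
    panel_in_capture = region_intersect(panel, capture, name="panel")

    sample_pop = read_population_table(cfg.populations)

    from cyvcf2 import VCF

    vcf_samples = list(VCF(str(cfg.vcf)).samples)
    unassigned = [s for s in vcf_samples if s not in sample_pop]
    if unassigned:
        raise ConfigurationError(
            f"{cfg.cohort}: samples without population assignment: "
            + ", ".join(unassigned[:5])
        )
    missing_cov = [
        s for s in vcf_samples if not (cfg.coverage_dir / f"{s}.bed").exists()
    ]
    if missing_cov:
        raise ConfigurationError(
            f"{cfg.cohort}: no coverage profile for: " + ", ".join(missing_cov[:5])
        )

    variants = list(read_vcf(cfg.vcf, check_against=capture))
    regions = {"capture": capture, **masks}
    filter_cfg = cfg.filter
    missing_roles = [
        r for r in list(filter_cfg.masks) + list(filter_cfg.restrict_to)
        if r not in regions
    ]
    if missing_roles:
        raise ConfigurationError(
            f"{cfg.cohort}: filter needs region(s) {missing_roles} but no BED was supplied"
        )
    surviving, report = run_cascade(variants, filter_cfg, regions)
    for line in report.log_lines():
        log.info("cohort %s: %s", cfg.cohort, line)

    profiles = [
        read_coverage_bed(cfg.coverage_dir / f"{s}.bed", s) for s in vcf_samples
    ]
    exposure = build_exposure_table(
        profiles, {"capture": capture, "panel": panel_in_capture}, samples=vcf_samples
    )

    exome_by_sample = event_counts(surviving, vcf_samples, region=capture)
    panel_by_sample = event_counts(surviving, vcf_samples, region=panel_in_capture)

    burdens: dict[str, PopulationBurden] = {}
    exome_vectors: dict[str, np.ndarray] = {}
    for label in sorted(set(sample_pop[s] for s in vcf_samples)):
        members = [s for s in vcf_samples if sample_pop[s] == label]
        pb = PopulationBurden(
            population=label,
            samples=members,
            M=np.array([exome_by_sample[s] for s in members]),
            L=np.array([exposure.length(s, "capture") for s in members]),
            m=np.array([panel_by_sample[s] for s in members]),
            l=np.array([exposure.length(s, "panel") for s in members]),
            cohorts=[cfg.cohort] * len(members),
        )
        burdens[label] = pb
        exome_vectors[label] = pb.M
        if pb.n_samples < cfg.min_samples_warn:
            log.warning(
                "cohort %s: population %s has only %d samples; "
                "burden estimates will be unstable",
                cfg.cohort, label, pb.n_samples,
            )

    results = [
        analyze_population(
            burdens[label],
            cohort=cfg.cohort,
            level=cfg.level,
            small_sample_min=cfg.min_samples_warn,
        )
        for label in burdens
    ]
    _attach_comparisons(
        results, burdens, exome_vectors, cfg.fisher_reference, cfg.mw_reference
    )

    tables = _figure_tables(cfg.cohort, burdens, results, sample_pop, exome_by_sample)
    bundle = RunBundle(
        cohort=cfg.cohort,
        config=cfg,
        filter_report=report,
        exposure=exposure,
        burdens=burdens,
        results=results,
        tables=tables,
        surviving=surviving,
    )
    if cfg.output_dir is not None:
        _write_bundle(bundle, cfg.output_dir)
    return bundle


def _figure_tables(
    cohort: str,
    burdens: Mapping[str, PopulationBurden],
    results: Sequence[BurdenResult],
    sample_pop: Mapping[str, str],
    exome_by_sample: Mapping[str, int],
) -> dict[str, pd.DataFrame]:
    exome_rows = [
        {"cohort": cohort, "sample_id": s, "population": p, "exome_events": exome_by_sample[s]}
        for s, p in sample_pop.items()
        if s in exome_by_sample
    ]
    total_events = sum(pb.sum_m for pb in burdens.values()) or 1
    panel_rows = []
    for label, pb in burdens.items():
        panel_rows.append(
            {
                "cohort": cohort,
                "population": label,
                "n_samples": pb.n_samples,
                "panel_events": pb.sum_m,
                "percent_of_panel_events": 100.0 * pb.sum_m / total_events,
                "events_per_mb_panel": 1e6 * pb.sum_m / pb.sum_l if pb.sum_l else np.nan,
                "n_carriers": pb.n_carriers,
                "carrier_percent": 100.0 * pb.n_carriers / pb.n_samples,
            }
        )
    oe_rows = []
    for res in results:
        lo, hi = res.expectation_interval
        oe_rows.append(
            {
                "cohort": cohort,
                "population": res.population,
                "x_obs": res.x_obs,
                "expected": res.expected,
                "interval_lo": lo,
                "interval_hi": hi,
                "obs_per_individual": res.x_obs / res.n_samples,
                "expected_per_individual": res.expected / res.n_samples,
                "p_poisson": res.p_poisson,
            }
        )
    return {
        "exome_counts": pd.DataFrame(exome_rows),
        "panel_summary": pd.DataFrame(panel_rows),
        "observed_expected": pd.DataFrame(oe_rows),
    }


def _write_bundle(bundle: RunBundle, out_dir: Path) -> None:
    """Write every output table; remove partial outputs on failure."""
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        def emit(name: str, writer) -> None:
            path = out_dir / name
            writer(path)
            written.append(path)

        emit("filter_report.tsv", lambda p: bundle.filter_report.to_frame().to_csv(p, sep="\t", index=False))
        emit("exposure.tsv", lambda p: bundle.exposure.to_tsv(p))
        emit("results.tsv", lambda p: write_results(bundle.results, p))
        for name, frame in bundle.tables.items():
            emit(f"{name}.tsv", lambda p, fr=frame: fr.to_csv(p, sep="\t", index=False))
        manifest = {
            "cohort": bundle.cohort,
            "seed": bundle.config.seed,
            "thresholds": bundle.config.filter.to_dict(),
            "ccds_restrict": bundle.config.ccds_restrict,
            "n_variants_surviving": len(bundle.surviving),
            "outputs": [p.name for p in written] + ["manifest.json"],
        }
        emit(
            "manifest.json",
            lambda p: Path(p).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n"),
        )
        bundle.out_dir = out_dir
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------

def run_meta(
    cohorts: Sequence[RunConfig | RunBundle],
    output_dir: str | Path | None = None,
    fisher_reference: str | None = None,
    mw_reference: str | None = None,
) -> MetaBundle:
    """Pool two or more cohorts and re-test on the pooled aggregates."""
    if len(cohorts) < 2:
        raise ConfigurationError(
            "meta-analysis needs at least two cohorts; use run_full for a single cohort"
        )
    bundles = [c if isinstance(c, RunBundle) else run_full(c) for c in cohorts]

    label_sets = [set(b.burdens) for b in bundles]
    shared = sorted(set.intersection(*label_sets))
    everything = sorted(set.union(*label_sets))
    excluded = [lab for lab in everything if lab not in shared]
    for lab in excluded:
        log.warning("meta: population %s present in only some cohorts; excluded", lab)
    if not shared:
        raise ConfigurationError("meta-analysis: cohorts share no population labels")

    pooled = {
        lab: pool_burdens([b.burdens[lab] for b in bundles]) for lab in shared
    }
    results = [
        analyze_population(pooled[lab], cohort="meta") for lab in shared
    ]
    exome_vectors = {lab: pooled[lab].M for lab in shared}
    _attach_comparisons(
        results, pooled, exome_vectors, fisher_reference, mw_reference
    )
    tables = {
        "meta_observed_expected": pd.DataFrame(
            [
                {
                    "population": r.population,
                    "x_obs": r.x_obs,
                    "expected": r.expected,
                    "interval_lo": r.expectation_interval[0],
                    "interval_hi": r.expectation_interval[1],
                    "p_poisson": r.p_poisson,
                }
                for r in results
            ]
        )
    }
    meta = MetaBundle(
        cohorts=bundles,
        pooled=pooled,
        results=results,
        tables=tables,
        excluded_populations=excluded,
    )
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results(results, out / "meta_results.tsv")
        tables["meta_observed_expected"].to_csv(
            out / "meta_observed_expected.tsv", sep="\t", index=False
        )
        meta.out_dir = out
    return meta
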