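"""Synthetic multi-population cohorts with known truncating-mutation structure.

Two generators share one data-generating model:

* :func:`simulate_cohort` writes a complete, self-contained cohort to disk —
  annotated VCF, per-sample callable-interval BEDs, region BEDs (capture,
  panel, repeat/segdup masks, CCDS), a population table and a ground-truth
  manifest — so every pipeline stage can be exercised without any download.
* :func:`simulate_burden_grid` / :func:`simulate_null_grid` skip the file
  layer and draw the per-sample counts and exposures directly, for
  calibration and power studies at many replicates.

The model: each individual's callable territory is the capture region minus a
random dropout fraction.  Panel events are Poisson with mean
``enrichment * exome_rate * l_j`` on the individual's panel callable length
``l_j``; off-panel events are Poisson with mean ``exome_rate * (L_j - l_j)``.
Events are placed uniformly at random within callable intervals (no hotspot
structure — the downstream test assumes a homogeneous per-position rate), all
carriers are diploid heterozygotes, and every generated event carries
annotations that pass the full filter cascade.  Decoy variants are engineered
to fail exactly one named filter each; common-variant decoys exercise the
allele-frequency filter.  Every stochastic choice flows from one explicit
seed, and identical seeds give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .burden_stats import poisson_two_sided
from .io_formats import (
    ConfigurationError,
    FRAMESHIFT_INDEL,
    RegionSet,
    SPLICE_SITE,
    STOPGAIN,
    STOPLOSS,
)

TRUNCATING_CHOICES = (SPLICE_SITE, STOPGAIN, STOPLOSS, FRAMESHIFT_INDEL)

_FREQ_KEYS = ("1000g2015aug_all", "esp6500siv2_all", "ExAC_nontcga_ALL")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    label: str
    n_samples: int
    exome_rate: float = 1.5e-6  # truncating events per callable position
    panel_enrichment: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError(f"{self.label}: need at least one sample")
        if self.exome_rate < 0 or self.panel_enrichment < 0:
            raise ConfigurationError(f"{self.label}: rates must be non-negative")


def _default_populations() -> list[PopulationSpec]:
    return [PopulationSpec("pop1", 40, 1.5e-6, 1.0)]


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic cohort.

    Defaults describe a single 40-sample population with an exome-wide
    truncating rate of 1.5e-6 per callable position over a 30 Mb capture
    territory and a 100 kb panel, no panel enrichment, and per-sample coverage
    dropout uniform on [0, 0.2].
    """

    populations: list[PopulationSpec] = field(default_factory=_default_populations)
    exome_size: int = 30_000_000
    panel_size: int = 100_000
    n_capture_blocks: int = 300
    chrom: str = "chr1"
    coverage_dropout: tuple[float, float] = (0.0, 0.2)
    common_variant_count: int = 5
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    decoy_counts: dict[str, int] = field(
        default_factory=lambda: {
            "missense": 2,
            "long_indel": 1,
            "low_depth": 1,
            "masked_region": 1,
            "high_missingness": 1,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel_size > self.exome_size:
            raise ConfigurationError("panel cannot exceed the capture territory")
        if self.panel_size < 1 or self.exome_size < 1:
            raise ConfigurationError("region sizes must be positive")
        lo, hi = self.coverage_dropout
        if not (0.0 <= lo <= hi < 1.0):
            raise ConfigurationError("coverage_dropout must satisfy 0 <= lo <= hi < 1")
        if self.n_capture_blocks < 4:
            raise ConfigurationError("need at least 4 capture blocks")
        known = {"missense", "long_indel", "low_depth", "masked_region", "high_missingness"}
        unknown = set(self.decoy_counts) - known
        if unknown:
            raise ConfigurationError(f"unknown decoy kinds: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pops = [PopulationSpec(**p) for p in raw.pop("populations", [])]
        kwargs = dict(raw)
        for key in ("coverage_dropout", "common_maf_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(populations=pops or _default_populations(), **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "populations": [
                {
                    "label": p.label,
                    "n_samples": p.n_samples,
                    "exome_rate": p.exome_rate,
                    "panel_enrichment": p.panel_enrichment,
                }
                for p in self.populations
            ],
            "exome_size": self.exome_size,
            "panel_size": self.panel_size,
            "n_capture_blocks": self.n_capture_blocks,
            "chrom": self.chrom,
            "coverage_dropout": list(self.coverage_dropout),
            "common_variant_count": self.common_variant_count,
            "common_maf_range": list(self.common_maf_range),
            "decoy_counts": dict(self.decoy_counts),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

def build_layout(cfg: ScenarioConfig) -> dict[str, RegionSet]:
    """Deterministic region geometry for a scenario.

    The capture territory is ``n_capture_blocks`` equal blocks separated by
    gaps on one synthetic contig; the panel occupies the first blocks (so
    panel is a subset of capture); the repeat and segmental-duplication masks
    sit inside two off-panel capture blocks; CCDS is the central 80% of every
    capture block.
    """
    n = cfg.n_capture_blocks
    block = cfg.exome_size // n
    if block < 10:
        raise ConfigurationError("capture blocks too small; reduce n_capture_blocks")
    gap = max(block // 3, 10)
    remainder = cfg.exome_size - block * n
    capture = []
    cursor = gap
    for i in range(n):
        size = block + (remainder if i == n - 1 else 0)
        capture.append((cfg.chrom, cursor, cursor + size))
        cursor += size + gap

    panel: list[tuple[str, int, int]] = []
    need = cfg.panel_size
    for chrom, s, e in capture:
        if need <= 0:
            break
        take = min(e - s, need)
        panel.append((chrom, s, s + take))
        need -= take
    n_panel_blocks = len(panel)
    if n_panel_blocks >= n - 2:
        raise ConfigurationError(
            "panel occupies nearly the whole capture; no room for off-panel masks"
        )

    def inner_third(iv):
        chrom, s, e = iv
        length = e - s
        return (chrom, s + length // 3, s + length // 3 + max(length // 3, 1))

    tr_block = capture[n_panel_blocks + (n - n_panel_blocks) // 2]
    sd_block = capture[n_panel_blocks + 3 * (n - n_panel_blocks) // 4]
    tandem = [inner_third(tr_block)]
    segdup = [inner_third(sd_block)]

    ccds = []
    for chrom, s, e in capture:
        trim = (e - s) // 10
        if e - trim > s + trim:
            ccds.append((chrom, s + trim, e - trim))

    return {
        "capture": RegionSet(capture, name="capture"),
        "panel": RegionSet(panel, name="panel"),
        "tandem_repeat": RegionSet(tandem, name="tandem_repeat"),
        "segdup": RegionSet(segdup, name="segdup"),
        "ccds": RegionSet(ccds, name="ccds"),
    }


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _dropout_callable(
    rng: np.random.Generator, capture: RegionSet, fraction: float
) -> RegionSet:
    """Remove one random sub-interval of the given fraction from each block."""
    kept: list[tuple[str, int, int]] = []
    for chrom, s, e in capture.intervals():
        cut = int(round(fraction * (e - s)))
        if cut <= 0:
            kept.append((chrom, s, e))
            continue
        if cut >= e - s:
            continue
        offset = int(rng.integers(0, e - s - cut + 1))
        if offset > 0:
            kept.append((chrom, s, s + offset))
        if s + offset + cut < e:
            kept.append((chrom, s + offset + cut, e))
    return RegionSet(kept, name=capture.name)


def _draw_positions(
    rng: np.random.Generator,
    region: RegionSet,
    k: int,
    used: set[tuple[str, int]],
) -> list[tuple[str, int]]:
    """``k`` distinct uniform 0-based positions from a region set."""
    if k == 0:
        return []
    ivals = list(region.intervals())
    if not ivals:
        raise ConfigurationError("cannot place events in an empty region")
    lengths = np.array([e - s for _, s, e in ivals], dtype=np.int64)
    cums = np.concatenate([[0], np.cumsum(lengths)])
    total = int(cums[-1])
    out: list[tuple[str, int]] = []
    attempts = 0
    while len(out) < k:
        attempts += 1
        if attempts > 1000 * k + 1000:
            raise ConfigurationError("region too small for the requested event count")
        u = int(rng.integers(0, total))
        idx = int(np.searchsorted(cums, u, side="right")) - 1
        chrom, s, _ = ivals[idx]
        pos = (chrom, s + (u - int(cums[idx])))
        if pos not in used:
            used.add(pos)
            out.append(pos)
    return out


_BASES = ("A", "C", "G", "T")


def _alleles_for(rng: np.random.Generator, consequence: str, long_indel: bool = False):
    ref_base = _BASES[int(rng.integers(0, 4))]
    if consequence == FRAMESHIFT_INDEL:
        dlen = 21 if long_indel else int(rng.integers(1, 4))
        if long_indel or rng.integers(0, 2) == 0:  # deletion
            return ref_base + "A" * dlen, ref_base
        return ref_base, ref_base + "A" * dlen
    alt = _BASES[(int(rng.integers(1, 4)) + _BASES.index(ref_base)) % 4]
    return ref_base, alt


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------

@dataclass
class TruthManifest:
    """Ground truth emitted with every simulated cohort."""

    params: dict
    sample_truth: dict[str, dict]  # sample -> {population, exome_events, panel_events}
    variant_truth: dict[str, dict]  # key -> {kind, expected_disposition, carrier}
    exposures: dict[str, dict]  # sample -> {capture: L, panel: l}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": self.params,
            "sample_truth": self.sample_truth,
            "variant_truth": self.variant_truth,
            "exposures": self.exposures,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


@dataclass
class SimulatedCohort:
    root: Path
    vcf_path: Path
    coverage_paths: dict[str, Path]
    region_paths: dict[str, Path]
    populations_path: Path
    truth_path: Path
    manifest: TruthManifest


# ---------------------------------------------------------------------------
# File-level simulator
# ---------------------------------------------------------------------------

def _write_bed(region: RegionSet, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in region.intervals():
            fh.write(f"{chrom}\t{s}\t{e}\n")


def simulate_cohort(cfg: ScenarioConfig, outdir: str | Path) -> SimulatedCohort:
    """Write a complete synthetic cohort and its ground-truth manifest."""
    rng = np.random.default_rng(cfg.seed)
    root = Path(outdir)
    (root / "regions").mkdir(parents=True, exist_ok=True)
    (root / "coverage").mkdir(exist_ok=True)

    layout = build_layout(cfg)
    capture, panel = layout["capture"], layout["panel"]
    masks = layout["tandem_repeat"].union(layout["segdup"], name="masks")
    offpanel_clean = capture.subtract(panel).subtract(masks, name="offpanel")

    samples: list[str] = []
    sample_pop: dict[str, str] = {}
    for spec in cfg.populations:
        for k in range(spec.n_samples):
            sid = f"{spec.label}_{k:03d}"
            samples.append(sid)
            sample_pop[sid] = spec.label

    # per-sample callable intervals and exposures
    coverage_paths: dict[str, Path] = {}
    callable_by_sample: dict[str, RegionSet] = {}
    exposures: dict[str, dict] = {}
    lo, hi = cfg.coverage_dropout
    for sid in samples:
        f = float(rng.uniform(lo, hi))
        callable_iv = _dropout_callable(rng, capture, f)
        callable_by_sample[sid] = callable_iv
        exposures[sid] = {
            "capture": callable_iv.intersect(capture).total_length,
            "panel": callable_iv.intersect(panel).total_length,
        }

    # true events
    used: set[tuple[str, int]] = set()
    variants: list[dict] = []
    sample_truth: dict[str, dict] = {}
    spec_by_label = {p.label: p for p in cfg.populations}
    for sid in samples:
        spec = spec_by_label[sample_pop[sid]]
        l_j = exposures[sid]["panel"]
        L_j = exposures[sid]["capture"]
        n_panel = int(rng.poisson(spec.panel_enrichment * spec.exome_rate * l_j))
        n_off = int(rng.poisson(spec.exome_rate * max(L_j - l_j, 0)))
        panel_callable = callable_by_sample[sid].intersect(panel)
        off_callable = callable_by_sample[sid].intersect(offpanel_clean)
        placements = [
            (pos, True) for pos in _draw_positions(rng, panel_callable, n_panel, used)
        ] + [
            (pos, False) for pos in _draw_positions(rng, off_callable, n_off, used)
        ]
        for (chrom, pos0), in_panel in placements:
            consequence = TRUNCATING_CHOICES[int(rng.integers(0, 4))]
            ref, alt = _alleles_for(rng, consequence)
            variants.append(
                {
                    "chrom": chrom,
                    "pos": pos0 + 1,
                    "ref": ref,
                    "alt": alt,
                    "consequence": consequence,
                    "freqs": {},
                    "carrier": sid,
                    "carrier_depth": int(rng.integers(20, 61)),
                    "kind": "event",
                    "expected_disposition": "pass",
                    "in_panel": in_panel,
                    "missing_samples": [],
                }
            )
        sample_truth[sid] = {
            "population": sample_pop[sid],
            "exome_events": n_panel + n_off,
            "panel_events": n_panel,
        }

    # decoys: each engineered to fail exactly one filter
    n_total = len(samples)

    def add_decoy(kind: str, disposition: str) -> None:
        region = layout["tandem_repeat"] if kind == "masked_region" else offpanel_clean
        if kind == "masked_region" and rng.integers(0, 2) == 1:
            region = layout["segdup"]
        (chrom, pos0), = _draw_positions(rng, region, 1, used)
        consequence = (
            "other" if kind == "missense" else TRUNCATING_CHOICES[int(rng.integers(0, 3))]
        )
        ref, alt = (
            _alleles_for(rng, FRAMESHIFT_INDEL, long_indel=True)
            if kind == "long_indel"
            else _alleles_for(rng, consequence)
        )
        carrier = samples[int(rng.integers(0, n_total))]
        depth = (
            int(rng.integers(max(3, 1), 15)) if kind == "low_depth" else int(rng.integers(20, 61))
        )
        missing: list[str] = []
        if kind == "high_missingness":
            k_miss = n_total // 10 + 1  # strictly > 10% of samples
            pool = [s for s in samples if s != carrier]
            order = rng.permutation(len(pool))
            missing = [pool[int(i)] for i in order[:k_miss]]
        variants.append(
            {
                "chrom": chrom,
                "pos": pos0 + 1,
                "ref": ref,
                "alt": alt,
                "consequence": FRAMESHIFT_INDEL if kind == "long_indel" else consequence,
                "freqs": {},
                "carrier": carrier,
                "carrier_depth": depth,
                "kind": f"decoy:{kind}",
                "expected_disposition": disposition,
                "in_panel": False,
                "missing_samples": missing,
            }
        )

    disposition_of = {
        "missense": "non_truncating",
        "long_indel": "long_indel",
        "low_depth": "low_depth",
        "masked_region": "masked_region",
        "high_missingness": "missingness",
    }
    for kind in ("missense", "long_indel", "low_depth", "masked_region", "high_missingness"):
        for _ in range(cfg.decoy_counts.get(kind, 0)):
            add_decoy(kind, disposition_of[kind])

    flo, fhi = cfg.common_maf_range
    for _ in range(cfg.common_variant_count):
        (chrom, pos0), = _draw_positions(rng, offpanel_clean, 1, used)
        consequence = TRUNCATING_CHOICES[int(rng.integers(0, 3))]
        ref, alt = _alleles_for(rng, consequence)
        n_sources = int(rng.integers(1, len(_FREQ_KEYS) + 1))
        keys = [_FREQ_KEYS[int(i)] for i in rng.permutation(len(_FREQ_KEYS))[:n_sources]]
        freqs = {key: float(rng.uniform(flo, fhi)) for key in sorted(keys)}
        variants.append(
            {
                "chrom": chrom,
                "pos": pos0 + 1,
                "ref": ref,
                "alt": alt,
                "consequence": consequence,
                "freqs": freqs,
                "carrier": samples[int(rng.integers(0, n_total))],
                "carrier_depth": int(rng.integers(20, 61)),
                "kind": "decoy:common",
                "expected_disposition": "common_maf",
                "in_panel": False,
                "missing_samples": [],
            }
        )

    variants.sort(key=lambda v: (v["chrom"], v["pos"], v["ref"], v["alt"]))

    # --- write files ------------------------------------------------------
    region_paths = {}
    for name, region in layout.items():
        path = root / "regions" / f"{name}.bed"
        _write_bed(region, path)
        region_paths[name] = path

    for sid in samples:
        path = root / "coverage" / f"{sid}.bed"
        _write_bed(callable_by_sample[sid], path)
        coverage_paths[sid] = path

    populations_path = root / "populations.tsv"
    with open(populations_path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for sid in samples:
            fh.write(f"{sid}\t{sample_pop[sid]}\n")

    vcf_path = root / "cohort.vcf"
    _write_vcf(vcf_path, cfg, variants, samples)

    variant_truth = {
        f"{v['chrom']}:{v['pos']}:{v['ref']}>{v['alt']}": {
            "kind": v["kind"],
            "expected_disposition": v["expected_disposition"],
            "carrier": v["carrier"],
            "in_panel": v["in_panel"],
        }
        for v in variants
    }
    manifest = TruthManifest(
        params={
            "seed": cfg.seed,
            "exome_size": cfg.exome_size,
            "panel_size": cfg.panel_size,
            "coverage_dropout": list(cfg.coverage_dropout),
            "populations": [
                {
                    "label": p.label,
                    "n_samples": p.n_samples,
                    "exome_rate": p.exome_rate,
                    "panel_enrichment": p.panel_enrichment,
                }
                for p in cfg.populations
            ],
        },
        sample_truth=sample_truth,
        variant_truth=variant_truth,
        exposures=exposures,
    )
    truth_path = root / "truth.json"
    manifest.to_json(truth_path)
    cfg.to_yaml(root / "scenario.yaml")

    return SimulatedCohort(
        root=root,
        vcf_path=vcf_path,
        coverage_paths=coverage_paths,
        region_paths=region_paths,
        populations_path=populations_path,
        truth_path=truth_path,
        manifest=manifest,
    )


def _write_vcf(
    path: Path, cfg: ScenarioConfig, variants: list[dict], samples: list[str]
) -> None:
    """Plain-text VCF 4.2 with ANNOVAR-style INFO keys and GT:DP genotypes."""
    max_pos = max((v["pos"] + len(v["ref"]) for v in variants), default=1)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=panelburden-simulate",
        f"##contig=<ID={cfg.chrom},length={max_pos + 10_000}>",
        '##INFO=<ID=Func,Number=1,Type=String,Description="Genic context">',
        '##INFO=<ID=ExonicFunc,Number=1,Type=String,Description="Exonic consequence">',
        '##INFO=<ID=1000g2015aug_all,Number=1,Type=Float,Description="1000 Genomes AF">',
        '##INFO=<ID=esp6500siv2_all,Number=1,Type=Float,Description="ESP6500 AF">',
        '##INFO=<ID=ExAC_nontcga_ALL,Number=1,Type=Float,Description="ExAC non-TCGA AF">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for v in variants:
        info_parts = []
        if v["consequence"] == SPLICE_SITE:
            info_parts.append("Func=splicing")
        else:
            info_parts.append("Func=exonic")
            if v["consequence"] == STOPGAIN:
                info_parts.append("ExonicFunc=stopgain")
            elif v["consequence"] == STOPLOSS:
                info_parts.append("ExonicFunc=stoploss")
            elif v["consequence"] == FRAMESHIFT_INDEL:
                kind = (
                    "frameshift_deletion"
                    if len(v["ref"]) > len(v["alt"])
                    else "frameshift_insertion"
                )
                info_parts.append(f"ExonicFunc={kind}")
            else:
                info_parts.append("ExonicFunc=nonsynonymous_SNV")
        for key in _FREQ_KEYS:
            if key in v["freqs"]:
                info_parts.append(f"{key}={v['freqs'][key]:.6g}")
        missing = set(v["missing_samples"])
        cells = []
        for sid in samples:
            if sid == v["carrier"]:
                cells.append(f"0/1:{v['carrier_depth']}")
            elif sid in missing:
                cells.append("0/0:2")
            else:
                cells.append("0/0:35")
        lines.append(
            f"{v['chrom']}\t{v['pos']}\t.\t{v['ref']}\t{v['alt']}\t100\tPASS\t"
            + ";".join(info_parts)
            + "\tGT:DP\t"
            + "\t".join(cells)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Count-level simulators (calibration / power harness)
# ---------------------------------------------------------------------------

def simulate_burden_grid(
    cfg: ScenarioConfig,
    replicates: int,
    seed: int | None = None,
    keep_counts: bool = False,
) -> dict[str, dict[str, np.ndarray]]:
    """Replicate-level burden statistics drawn directly from the model.

    For every population and replicate: per-sample exposures under random
    coverage dropout, Poisson panel and off-panel event counts, the pooled
    background-rate estimate, and the exact two-sided Poisson enrichment
    p-value of the panel count.  Returns per-population arrays of length
    ``replicates`` (and the per-sample exome count matrix ``M`` when
    ``keep_counts`` is set, for rank-based between-group comparisons).
    """
    if replicates < 1:
        raise ConfigurationError("need at least one replicate")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lo, hi = cfg.coverage_dropout
    out: dict[str, dict[str, np.ndarray]] = {}
    for spec in cfg.populations:
        f = rng.uniform(lo, hi, size=(replicates, spec.n_samples))
        L = np.rint(cfg.exome_size * (1.0 - f)).astype(np.int64)
        l = np.rint(cfg.panel_size * (1.0 - f)).astype(np.int64)
        m = rng.poisson(spec.panel_enrichment * spec.exome_rate * l)
        M = m + rng.poisson(spec.exome_rate * (L - l))
        lam = M.sum(axis=1) / L.sum(axis=1)
        x = m.sum(axis=1)
        T = l.sum(axis=1)
        mu = lam * T
        p = np.array(
            [
                poisson_two_sided(int(xi), float(Ti), float(li))
                for xi, Ti, li in zip(x, T, lam)
            ]
        )
        res = {
            "p": p,
            "x": x,
            "T": T,
            "mu": mu,
            "lambda_hat": lam,
            "enriched": x > mu,
        }
        if keep_counts:
            res["M"] = M
        out[spec.label] = res
    return out


@dataclass
class NullCalibration:
    pvalues: np.ndarray
    alpha: float

    @property
    def rejection_rate(self) -> float:
        return float((self.pvalues < self.alpha).mean())


def simulate_null_grid(
    cfg: ScenarioConfig,
    replicates: int,
    seed: int | None = None,
    alpha: float = 0.05,
) -> NullCalibration:
    """Poisson-test p-values under the no-enrichment null.

    The scenario's enrichment factors are forced to 1 so the panel event rate
    per callable position equals the exome-wide rate; the returned rejection
    rate at ``alpha`` measures the empirical size of the test.
    """
    if replicates < 1:
        raise ConfigurationError("need at least one replicate")
    null_cfg = ScenarioConfig(
        populations=[
            PopulationSpec(p.label, p.n_samples, p.exome_rate, 1.0)
            for p in cfg.populations
        ],
        exome_size=cfg.exome_size,
        panel_size=cfg.panel_size,
        n_capture_blocks=cfg.n_capture_blocks,
        chrom=cfg.chrom,
        coverage_dropout=cfg.coverage_dropout,
        common_variant_count=cfg.common_variant_count,
        common_maf_range=cfg.common_maf_range,
        decoy_counts=dict(cfg.decoy_counts),
        seed=cfg.seed,
    )
    grid = simulate_burden_grid(null_cfg, replicates, seed=seed)
    pvalues = np.concatenate([res["p"] for res in grid.values()])
    return NullCalibration(pvalues=pvalues, alpha=alpha)


def simulate_reversal_study(
    replicates: int,
    seed: int,
    n_samples: int = 40,
    rate_a: float = 2.25e-6,
    rate_b: float = 1.5e-6,
    enrichment_b: float = 5.0,
    exome_size: int = 30_000_000,
    panel_size: int = 100_000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-population contrast: A mutates faster exome-wide, only B is enriched.

    Population A has the higher exome-wide truncating rate but no panel
    enrichment; population B the lower exome rate but an enriched panel.  Per
    replicate: the two-sided Mann-Whitney comparison of per-sample exome-wide
    counts (A vs. B) and each population's Poisson panel-enrichment test.
    """
    cfg = ScenarioConfig(
        populations=[
            PopulationSpec("A", n_samples, rate_a, 1.0),
            PopulationSpec("B", n_samples, rate_b, enrichment_b),
        ],
        exome_size=exome_size,
        panel_size=panel_size,
        seed=seed,
    )
    from .burden_stats import mannwhitney_burden

    grid = simulate_burden_grid(cfg, replicates, seed=seed, keep_counts=True)
    a, b = grid["A"], grid["B"]
    rows = []
    for i in range(replicates):
        mw_p = mannwhitney_burden(a["M"][i], b["M"][i])
        rows.append(
            {
                "mw_p": mw_p,
                "a_mean_higher": float(a["M"][i].mean() > b["M"][i].mean()),
                "p_a": a["p"][i],
                "enriched_a": bool(a["enriched"][i]),
                "p_b": b["p"][i],
                "enriched_b": bool(b["enriched"][i]),
            }
        )
    frame = pd.DataFrame(rows)
    frame["reversal"] = (
        (frame["mw_p"] < alpha)
        & (frame["a_mean_higher"] > 0)
        & ((frame["p_b"] < alpha) & frame["enriched_b"])
        & ~((frame["p_a"] < alpha) & frame["enriched_a"])
    )
    return frame
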