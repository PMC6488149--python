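"""The rare protein-truncating variant filter cascade.

Raw annotated calls are reduced to analysis-ready rare truncating mutations by
a fixed sequence of filters:

1. genotype missingness — per-sample calls with read depth < 3 become missing,
   and a site whose missing fraction exceeds 0.1 is dropped;
2. consequence class — only protein-truncating classes survive (splice site,
   frameshift indel, stop gain, stop loss); missense is excluded by design;
3. minor allele frequency — a site reported above 2% in any reference
   frequency source (1000 Genomes / ESP / ExAC by default) is dropped; a site
   absent from all sources is retained (absence of evidence of commonness);
4. structural / positional — long indels (> 20 bp), carrier calls with read
   depth < 15, positions inside repeat or segmental-duplication masks, and
   positions outside every required region (the capture territory).

All inequalities are strict exactly as configured: missing rate > 0.1 removes,
frequency > 0.02 removes (retained at exactly 0.02), indel length > 20
removes, depth < 15 removes.

The variant-level depth rule is applied per carrier: an event (sample,
variant) with carrier depth below the threshold is discarded while the site
survives for better-covered carriers; only a site left with no qualifying
carrier is dropped outright.  This keeps site filtering consistent with the
per-individual event accounting used downstream.

Every removal is attributed to exactly one filter in a :class:`FilterReport`
whose counts satisfy the conservation identity
``input = sum(removed) + surviving``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import (
    ConfigurationError,
    DataError,
    HET,
    HOM_ALT,
    MISSING,
    RegionSet,
    SampleCall,
    TRUNCATING_CLASSES,
    Variant,
)

#: Cascade stages in their fixed application order.
STAGE_NAMES = (
    "missingness",
    "non_truncating",
    "common_maf",
    "long_indel",
    "low_depth",
    "masked_region",
    "outside_restriction",
)


@dataclass
class FilterConfig:
    """Thresholds and region roles for the filter cascade.

    Every filter is individually neutralisable: ``genotype_depth_min=0`` with
    ``site_missing_rate_max=1`` disables missingness, ``maf_max=1`` disables
    the frequency filter, ``indel_length_max=None`` disables the length
    filter, ``variant_depth_min=0`` disables the depth filter, and empty
    ``masks`` / ``restrict_to`` disable the positional filters.  Adding
    ``"other"`` to ``truncating_classes`` disables the class filter.
    """

    genotype_depth_min: int = 3
    site_missing_rate_max: float = 0.1
    maf_max: float = 0.02
    indel_length_max: int | None = 20
    variant_depth_min: int = 15
    truncating_classes: frozenset[str] = TRUNCATING_CLASSES
    masks: tuple[str, ...] = ("tandem_repeat", "segdup")
    restrict_to: tuple[str, ...] = ("capture",)

    def __post_init__(self) -> None:
        if self.genotype_depth_min < 0 or self.variant_depth_min < 0:
            raise ConfigurationError("depth thresholds must be non-negative")
        if not (0.0 < self.maf_max <= 1.0):
            raise ConfigurationError("maf_max must be in (0, 1]")
        if not (0.0 <= self.site_missing_rate_max <= 1.0):
            raise ConfigurationError("site_missing_rate_max must be in [0, 1]")
        if self.indel_length_max is not None and self.indel_length_max < 0:
            raise ConfigurationError("indel_length_max must be non-negative")
        self.truncating_classes = frozenset(self.truncating_classes)
        self.masks = tuple(self.masks)
        self.restrict_to = tuple(self.restrict_to)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "FilterConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown filter options: {sorted(unknown)}")
        return cls(**dict(mapping))

    def to_dict(self) -> dict:
        return {
            "genotype_depth_min": self.genotype_depth_min,
            "site_missing_rate_max": self.site_missing_rate_max,
            "maf_max": self.maf_max,
            "indel_length_max": self.indel_length_max,
            "variant_depth_min": self.variant_depth_min,
            "truncating_classes": sorted(self.truncating_classes),
            "masks": list(self.masks),
            "restrict_to": list(self.restrict_to),
        }


@dataclass
class FilterStage:
    name: str
    n_input: int
    n_removed: int

    @property
    def n_surviving(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class FilterReport:
    """Per-filter accounting plus a per-variant disposition trace."""

    stages: list[FilterStage] = field(default_factory=list)
    dispositions: dict[str, str | None] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return self.stages[0].n_input if self.stages else 0

    @property
    def n_surviving(self) -> int:
        return self.stages[-1].n_surviving if self.stages else 0

    def removed_by(self, stage: str) -> int:
        for s in self.stages:
            if s.name == stage:
                return s.n_removed
        raise KeyError(stage)

    def check_conservation(self) -> None:
        total_removed = 0
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur.n_input != prev.n_surviving:
                raise AssertionError(
                    f"stage chaining broken at {cur.name}: "
                    f"{cur.n_input} != {prev.n_surviving}"
                )
        total_removed = sum(s.n_removed for s in self.stages)
        if self.n_input != total_removed + self.n_surviving:
            raise AssertionError("conservation identity violated")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "filter": s.name,
                    "n_input": s.n_input,
                    "n_removed": s.n_removed,
                    "n_surviving": s.n_surviving,
                }
                for s in self.stages
            ]
        )

    def log_lines(self) -> list[str]:
        lines = [f"filter cascade: {self.n_input} variants in"]
        for s in self.stages:
            lines.append(
                f"  {s.name:<20s} removed {s.n_removed:>6d}  surviving {s.n_surviving:>6d}"
            )
        lines.append(f"filter cascade: {self.n_surviving} variants out")
        return lines


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------

def apply_genotype_missingness(v: Variant, cfg: FilterConfig) -> Variant | None:
    """Mark low-depth calls missing; drop the site if too many are missing.

    Returns the (new) variant when retained, ``None`` when removed.
    """
    if not v.sample_calls:
        raise DataError(f"{v.key}: variant carries no sample calls")
    calls = {}
    n_missing = 0
    for sample, call in v.sample_calls.items():
        if call.genotype == MISSING or call.depth < cfg.genotype_depth_min:
            calls[sample] = SampleCall(MISSING, call.depth)
            n_missing += 1
        else:
            calls[sample] = SampleCall(call.genotype, call.depth)
    if n_missing / len(calls) > cfg.site_missing_rate_max:
        return None
    return v.replace_calls(calls)


def classify_truncating(v: Variant, cfg: FilterConfig) -> bool:
    """True iff the annotated consequence is a configured truncating class."""
    return v.consequence in cfg.truncating_classes


def apply_maf_filter(v: Variant, cfg: FilterConfig) -> bool:
    """True (retained) unless any frequency source exceeds the MAF cutoff.

    Sources absent from the annotation never remove a variant: an allele
    unobserved in the reference panels cannot be shown to be common.
    """
    return not any(f > cfg.maf_max for f in v.freqs.values())


def _passes_length(v: Variant, cfg: FilterConfig) -> bool:
    return cfg.indel_length_max is None or v.indel_length <= cfg.indel_length_max


def _trim_low_depth_carriers(v: Variant, cfg: FilterConfig) -> Variant | None:
    """Remove carrier events below the variant-level depth threshold.

    Returns ``None`` when no qualifying carrier remains.
    """
    if cfg.variant_depth_min <= 0:
        return v
    calls = {}
    n_carriers = 0
    for sample, call in v.sample_calls.items():
        if call.genotype in (HET, HOM_ALT) and call.depth < cfg.variant_depth_min:
            calls[sample] = SampleCall(MISSING, call.depth)
        else:
            calls[sample] = SampleCall(call.genotype, call.depth)
            if call.genotype in (HET, HOM_ALT):
                n_carriers += 1
    if n_carriers == 0:
        return None
    return v.replace_calls(calls)


def _in_any_mask(v: Variant, masks: Sequence[RegionSet]) -> bool:
    return any(m.contains(v.chrom, v.pos0) for m in masks)


def _in_all_restrictions(v: Variant, restrict: Sequence[RegionSet]) -> bool:
    return all(r.contains(v.chrom, v.pos0) for r in restrict)


def apply_structural_filters(
    v: Variant,
    cfg: FilterConfig,
    masks: Sequence[RegionSet] = (),
    restrict: Sequence[RegionSet] = (),
) -> bool:
    """Variant-level view of the structural filters (True = retained).

    A variant is removed when its indel length exceeds the cutoff, when no
    carrier reaches the depth threshold, when its anchor position falls in any
    exclusion mask, or when it falls outside any required region.
    """
    if not _passes_length(v, cfg):
        return False
    if _trim_low_depth_carriers(v, cfg) is None:
        return False
    if _in_any_mask(v, masks):
        return False
    if not _in_all_restrictions(v, restrict):
        return False
    return True


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def run_cascade(
    variants: Iterable[Variant],
    cfg: FilterConfig,
    regions: Mapping[str, RegionSet] | None = None,
) -> tuple[list[Variant], FilterReport]:
    """Apply the full cascade in its fixed order and account for every removal.

    ``regions`` must supply every region named by ``cfg.masks`` and
    ``cfg.restrict_to``.  The cascade is idempotent: filtering its own output
    (with the same configuration) changes nothing.
    """
    regions = regions or {}
    for role in list(cfg.masks) + list(cfg.restrict_to):
        if role not in regions:
            raise ConfigurationError(
                f"filter configuration references region {role!r} but it was not supplied"
            )
    masks = [regions[m] for m in cfg.masks]
    restrict = [regions[r] for r in cfg.restrict_to]

    report = FilterReport()
    current = list(variants)
    dispositions: dict[str, str | None] = {v.key: None for v in current}

    def run_stage(name: str, survivors_of):
        nonlocal current
        n_in = len(current)
        nxt: list[Variant] = []
        for v in current:
            out = survivors_of(v)
            if out is None:
                dispositions[v.key] = name
            else:
                nxt.append(out)
        report.stages.append(FilterStage(name, n_in, n_in - len(nxt)))
        current = nxt

    run_stage("missingness", lambda v: apply_genotype_missingness(v, cfg))
    run_stage("non_truncating", lambda v: v if classify_truncating(v, cfg) else None)
    run_stage("common_maf", lambda v: v if apply_maf_filter(v, cfg) else None)
    run_stage("long_indel", lambda v: v if _passes_length(v, cfg) else None)
    run_stage("low_depth", lambda v: _trim_low_depth_carriers(v, cfg))
    run_stage("masked_region", lambda v: None if _in_any_mask(v, masks) else v)
    run_stage(
        "outside_restriction",
        lambda v: v if _in_all_restrictions(v, restrict) else None,
    )

    report.dispositions = dispositions
    report.check_conservation()
    return current, report
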