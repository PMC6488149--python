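"""Per-individual callable-site exposures.

The burden tests normalise mutation counts by the number of positions at
which a mutation *could* have been observed in each individual: the exome
exposure L (positions of the capture territory callable in that sample) and
the panel exposure l (callable positions of the gene panel, itself restricted
to the capture territory).  Both are plain interval intersections of a
sample's coverage profile with a named region set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import (
    ConfigurationError,
    CoverageProfile,
    RegionSet,
    ensure_consistent_contigs,
)


def callable_length(profile: CoverageProfile, region: RegionSet) -> int:
    """Number of positions of ``region`` callable in this sample.

    Equals the total length of the intersection between the sample's
    qualifying intervals and the region; an empty profile contributes zero.
    Disjoint contig naming between a non-empty profile and a non-empty region
    is treated as an input error rather than silently returning zero.
    """
    q = profile.qualifying_intervals
    if q and region:
        ensure_consistent_contigs(
            q.chroms(), region.chroms(),
            context=f"coverage profile {profile.sample_id} vs region {region.name!r}",
        )
    return q.intersect(region).total_length


@dataclass
class ExposureTable:
    """Callable lengths keyed by (sample, region name)."""

    frame: pd.DataFrame  # columns: sample_id, region, callable_length

    def length(self, sample_id: str, region: str) -> int:
        sel = self.frame[
            (self.frame["sample_id"] == sample_id) & (self.frame["region"] == region)
        ]
        if sel.empty:
            raise KeyError((sample_id, region))
        return int(sel["callable_length"].iloc[0])

    def totals(self, region: str) -> int:
        return int(
            self.frame.loc[self.frame["region"] == region, "callable_length"].sum()
        )

    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.frame["sample_id"]))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExposureTable":
        return cls(pd.read_csv(path, sep="\t"))


def build_exposure_table(
    profiles: Iterable[CoverageProfile],
    regions: Mapping[str, RegionSet],
    samples: Sequence[str] | None = None,
) -> ExposureTable:
    """Complete (sample x region) table of callable lengths.

    When ``samples`` is given, every listed sample must have a profile; a
    missing one is an error naming the sample.  Region sets are used as
    supplied — the caller pre-intersects the panel with the capture territory
    (and with CCDS when harmonising across capture kits).
    """
    by_id = {p.sample_id: p for p in profiles}
    if samples is None:
        samples = list(by_id)
    else:
        missing = [s for s in samples if s not in by_id]
        if missing:
            raise ConfigurationError(
                f"no coverage profile for sample(s): {', '.join(missing)}"
            )
    rows = [
        {
            "sample_id": sid,
            "region": region_name,
            "callable_length": callable_length(by_id[sid], region),
        }
        for sid in samples
        for region_name, region in regions.items()
    ]
    return ExposureTable(pd.DataFrame(rows, columns=["sample_id", "region", "callable_length"]))
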