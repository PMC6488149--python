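"""Readers, writers and genomic-interval primitives for the burden pipeline.

Coordinate conventions
----------------------
VCF records are 1-based (``Variant.pos`` keeps the VCF convention).  All
:class:`RegionSet` intervals are 0-based half-open, as in BED.  Membership of a
variant in a region is tested at the 0-based anchor position ``pos - 1`` (for
indels this is the anchor base of the VCF record).  Strand is ignored
throughout: burden counting is strand-free.

Contig naming must be consistent across every input; nothing is renamed
silently.  A ``chr1`` / ``1`` style mismatch between a VCF and a region file
raises :class:`ContigMismatchError` instead of being auto-harmonised, because
silent renaming corrupts interval arithmetic.

Annotation fields (functional consequence and reference-population allele
frequencies) are consumed from INFO keys, ANNOVAR dialect by default
(:class:`AnnotationScheme`); consequence prediction is never recomputed here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PipelineError(Exception):
    """Base class for all panelburden errors."""


class ParseError(PipelineError):
    """A malformed input file; the message names the offending line."""


class ContigMismatchError(PipelineError):
    """Inputs use incompatible contig naming (e.g. ``chr1`` vs ``1``)."""


class DataError(PipelineError):
    """A value violates its domain (e.g. an allele frequency outside [0,1])."""


class ConfigurationError(PipelineError):
    """A run configuration is incomplete or inconsistent."""


# ---------------------------------------------------------------------------
# Consequence classes and genotypes
# ---------------------------------------------------------------------------

SPLICE_SITE = "splice_site"
FRAMESHIFT_INDEL = "frameshift_indel"
STOPGAIN = "stopgain"
STOPLOSS = "stoploss"
OTHER = "other"

#: The protein-truncating consequence classes.
TRUNCATING_CLASSES = frozenset({SPLICE_SITE, FRAMESHIFT_INDEL, STOPGAIN, STOPLOSS})

CONSEQUENCE_CLASSES = TRUNCATING_CLASSES | {OTHER}

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

GENOTYPES = frozenset({HOM_REF, HET, HOM_ALT, MISSING})


@dataclass(frozen=True)
class AnnotationScheme:
    """How consequence and frequency annotations are keyed in the VCF INFO field.

    The defaults follow the ANNOVAR table_annovar naming: ``Func`` carries the
    genic context (``splicing`` marks canonical splice-site variants),
    ``ExonicFunc`` carries the exonic consequence, and each frequency source is
    one Float key.  Keys are configurable so other annotation dialects can be
    mapped without touching the reader.
    """

    func_key: str = "Func"
    exonic_func_key: str = "ExonicFunc"
    splice_values: tuple[str, ...] = ("splicing", "exonic;splicing", "splicing;exonic")
    consequence_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "stopgain": STOPGAIN,
            "stoploss": STOPLOSS,
            "frameshift_insertion": FRAMESHIFT_INDEL,
            "frameshift_deletion": FRAMESHIFT_INDEL,
            "frameshift_block_substitution": FRAMESHIFT_INDEL,
        }
    )
    frequency_keys: Mapping[str, str] = field(
        default_factory=lambda: {
            "1000g": "1000g2015aug_all",
            "esp": "esp6500siv2_all",
            "exac": "ExAC_nontcga_ALL",
        }
    )

    def consequence_of(self, func: str | None, exonic_func: str | None) -> str:
        if func is not None and func in self.splice_values:
            return SPLICE_SITE
        if exonic_func is not None:
            return self.consequence_map.get(exonic_func, OTHER)
        return OTHER


# ---------------------------------------------------------------------------
# Variant
# ---------------------------------------------------------------------------

@dataclass
class SampleCall:
    genotype: str
    depth: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise DataError(f"unknown genotype {self.genotype!r}")
        if self.depth < 0:
            raise DataError(f"negative read depth {self.depth}")


@dataclass
class Variant:
    """One annotated alternate allele (multi-allelic records are decomposed).

    ``pos`` is the 1-based VCF position; ``freqs`` maps frequency-source name
    to an allele frequency in [0, 1] and simply omits sources with no entry
    (absence is meaningful: an unobserved variant passes the MAF filter).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str = OTHER
    freqs: dict[str, float] = field(default_factory=dict)
    sample_calls: dict[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"{self.key}: VCF position must be >= 1")
        if self.alt == self.ref:
            raise DataError(f"{self.key}: ALT equals REF")
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise DataError(f"{self.key}: unknown consequence {self.consequence!r}")
        for source, f in self.freqs.items():
            if not (0.0 <= f <= 1.0):
                raise DataError(
                    f"{self.key}: allele frequency {f} from {source!r} outside [0,1]"
                )

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def pos0(self) -> int:
        """0-based anchor position used for region membership."""
        return self.pos - 1

    def carriers(self) -> list[str]:
        """Samples carrying the alternate allele (het or hom)."""
        return [
            s for s, c in self.sample_calls.items() if c.genotype in (HET, HOM_ALT)
        ]

    def replace_calls(self, calls: dict[str, SampleCall]) -> "Variant":
        return dataclasses.replace(self, sample_calls=calls, freqs=dict(self.freqs))


# ---------------------------------------------------------------------------
# RegionSet
# ---------------------------------------------------------------------------

class RegionSet:
    """A named, strand-agnostic collection of 0-based half-open intervals.

    Intervals are normalised on construction: per chromosome they are sorted
    and overlapping or abutting intervals are merged, so normalisation is
    idempotent and insensitive to input order.
    """

    __slots__ = ("name", "_ivals")

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = (), name: str = ""):
        self.name = name
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if start < 0 or start >= end:
                raise DataError(
                    f"invalid interval {chrom}:{start}-{end} (need 0 <= start < end)"
                )
            per_chrom.setdefault(str(chrom), []).append((start, end))
        self._ivals: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted(per_chrom):
            merged_s: list[int] = []
            merged_e: list[int] = []
            for start, end in sorted(per_chrom[chrom]):
                if merged_e and start <= merged_e[-1]:
                    merged_e[-1] = max(merged_e[-1], end)
                else:
                    merged_s.append(start)
                    merged_e.append(end)
            self._ivals[chrom] = (
                np.asarray(merged_s, dtype=np.int64),
                np.asarray(merged_e, dtype=np.int64),
            )

    # -- inspection ---------------------------------------------------------

    def chroms(self) -> list[str]:
        return list(self._ivals)

    def intervals(self) -> Iterator[tuple[str, int, int]]:
        for chrom, (starts, ends) in self._ivals.items():
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield chrom, s, e

    def per_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self._ivals.get(chrom, (empty, empty))

    @property
    def total_length(self) -> int:
        return int(
            sum((e - s).sum() for s, e in self._ivals.values())
        )

    def __bool__(self) -> bool:
        return bool(self._ivals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return list(self.intervals()) == list(other.intervals())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        n = sum(len(s) for s, _ in self._ivals.values())
        return f"RegionSet({self.name!r}, {n} intervals, {self.total_length} bp)"

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a single 0-based position."""
        starts, ends = self.per_chrom(chrom)
        if not len(starts):
            return False
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < ends[i]

    # -- set algebra --------------------------------------------------------

    def intersect(self, other: "RegionSet", name: str | None = None) -> "RegionSet":
        out: list[tuple[str, int, int]] = []
        for chrom in self._ivals:
            a_s, a_e = self._ivals[chrom]
            b_s, b_e = other.per_chrom(chrom)
            i = j = 0
            while i < len(a_s) and j < len(b_s):
                s = max(a_s[i], b_s[j])
                e = min(a_e[i], b_e[j])
                if s < e:
                    out.append((chrom, int(s), int(e)))
                if a_e[i] <= b_e[j]:
                    i += 1
                else:
                    j += 1
        return RegionSet(out, name=name or f"{self.name}&{other.name}")

    def subtract(self, other: "RegionSet", name: str | None = None) -> "RegionSet":
        out: list[tuple[str, int, int]] = []
        for chrom in self._ivals:
            a_s, a_e = self._ivals[chrom]
            b_s, b_e = other.per_chrom(chrom)
            j = 0
            for s, e in zip(a_s.tolist(), a_e.tolist()):
                cur = s
                while j < len(b_s) and b_e[j] <= cur:
                    j += 1
                k = j
                while k < len(b_s) and b_s[k] < e:
                    if b_s[k] > cur:
                        out.append((chrom, cur, int(b_s[k])))
                    cur = max(cur, int(b_e[k]))
                    k += 1
                if cur < e:
                    out.append((chrom, cur, e))
        return RegionSet(out, name=name or f"{self.name}-{other.name}")

    def union(self, other: "RegionSet", name: str | None = None) -> "RegionSet":
        return RegionSet(
            list(self.intervals()) + list(other.intervals()),
            name=name or f"{self.name}|{other.name}",
        )


def region_intersect(a: RegionSet, b: RegionSet, name: str | None = None) -> RegionSet:
    """Positions present in both region sets (commutative)."""
    return a.intersect(b, name=name)


def ensure_consistent_contigs(
    chroms_a: Iterable[str], chroms_b: Iterable[str], context: str = ""
) -> None:
    """Raise :class:`ContigMismatchError` on a chr-prefix style mismatch.

    Two non-empty contig collections that share no name, but would share names
    after toggling a ``chr`` prefix, are declared mismatched.
    """
    a, b = set(chroms_a), set(chroms_b)
    if not a or not b or (a & b):
        return

    def toggle(c: str) -> str:
        return c[3:] if c.startswith("chr") else "chr" + c

    if {toggle(c) for c in a} & b:
        raise ContigMismatchError(
            f"contig naming mismatch{' in ' + context if context else ''}: "
            f"{sorted(a)[:3]} vs {sorted(b)[:3]}; rename inputs consistently"
        )
    raise ContigMismatchError(
        f"no shared contigs{' in ' + context if context else ''}: "
        f"{sorted(a)[:3]} vs {sorted(b)[:3]}"
    )


# ---------------------------------------------------------------------------
# Coverage profiles
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    """Per-sample intervals of positions passing the depth/quality criteria.

    The qualifying intervals are produced upstream (positions with read depth
    >= 15 under mapping quality > 20 and base quality > 13, ignoring anomalous
    read pairs); this type only stores and intersects them.
    """

    sample_id: str
    qualifying_intervals: RegionSet


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_regions(path: str | Path, name: str = "") -> RegionSet:
    """Read a 3+ column BED file into a normalised :class:`RegionSet`."""
    path = Path(path)
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval {fields[0]}:{start}-{end}"
                )
            intervals.append((fields[0], start, end))
    return RegionSet(intervals, name=name or path.stem)


def read_coverage_bed(path: str | Path, sample_id: str) -> CoverageProfile:
    """Read a per-sample BED of qualifying (callable) intervals."""
    return CoverageProfile(sample_id, read_regions(path, name=f"callable:{sample_id}"))


def read_depth_table(
    path: str | Path, sample_id: str, min_depth: int = 15
) -> CoverageProfile:
    """Convert a per-base depth table to qualifying intervals.

    The table has three columns (chrom, pos, depth) with 1-based positions;
    positions with depth >= ``min_depth`` become 0-based half-open intervals,
    with consecutive positions merged.
    """
    tbl = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "depth"], comment="#"
    )
    keep = tbl[tbl["depth"] >= min_depth]
    intervals = [
        (str(row.chrom), int(row.pos) - 1, int(row.pos)) for row in keep.itertuples()
    ]
    return CoverageProfile(
        sample_id, RegionSet(intervals, name=f"callable:{sample_id}")
    )


def _info_get(info, key: str):
    try:
        return info.get(key)
    except Exception:
        return None


def read_vcf(
    path: str | Path,
    scheme: AnnotationScheme | None = None,
    decompose: bool = True,
    check_against: RegionSet | None = None,
) -> Iterator[Variant]:
    """Stream :class:`Variant` objects from an annotated VCF.

    One Variant is emitted per alternate allele; multi-allelic records are
    decomposed, with each sample's genotype re-expressed relative to the
    single alternate allele under consideration.  Records lacking a recognised
    consequence key are classed ``other``; missing frequency keys stay absent
    (they are *not* zero).  ``check_against`` triggers a contig-naming check
    against a supplied region set.
    """
    from cyvcf2 import VCF  # deferred: import cost only when VCFs are read

    scheme = scheme or AnnotationScheme()
    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises plain OSError on malformed input
        raise ParseError(f"{path}: cannot open as VCF ({exc})") from exc
    samples = list(vcf.samples)
    seen_chroms: set[str] = set()
    for rec in vcf:
        chrom = str(rec.CHROM)
        if check_against is not None and chrom not in seen_chroms:
            seen_chroms.add(chrom)
            ensure_consistent_contigs(
                [chrom], check_against.chroms(), context=f"{path} vs region set"
            )
        func = _info_get(rec.INFO, scheme.func_key)
        exonic = _info_get(rec.INFO, scheme.exonic_func_key)
        if exonic == ".":
            exonic = None
        consequence = scheme.consequence_of(func, exonic)
        freqs: dict[str, float] = {}
        for source, key in scheme.frequency_keys.items():
            raw = _info_get(rec.INFO, key)
            if raw is None or raw == ".":
                continue
            try:
                freqs[source] = float(raw)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: {chrom}:{rec.POS}: non-numeric frequency "
                    f"{raw!r} for key {key!r}"
                ) from exc
        alts = list(rec.ALT) if decompose else list(rec.ALT)[:1]
        if samples:
            fmt_dp = rec.format("DP")
            if fmt_dp is not None:
                depths = np.asarray(fmt_dp).reshape(len(samples), -1)[:, 0]
            else:
                depths = rec.gt_depths
            genotypes = rec.genotypes
        else:
            depths = np.empty(0, dtype=int)
            genotypes = []
        for alt_index, alt in enumerate(alts, start=1):
            calls: dict[str, SampleCall] = {}
            for si, sample in enumerate(samples):
                alleles = [a for a in genotypes[si][:-1]]
                depth = int(depths[si]) if depths[si] >= 0 else 0
                if any(a < 0 for a in alleles):
                    gt = MISSING
                else:
                    n_alt = sum(1 for a in alleles if a == alt_index)
                    gt = (HOM_REF, HET, HOM_ALT)[min(n_alt, 2)]
                calls[sample] = SampleCall(genotype=gt, depth=depth)
            yield Variant(
                chrom=chrom,
                pos=int(rec.POS),
                ref=str(rec.REF),
                alt=str(alt),
                consequence=consequence,
                freqs=dict(freqs),
                sample_calls=calls,
            )


# ---------------------------------------------------------------------------
# Panel definition
# ---------------------------------------------------------------------------

def load_panel_genes(panel: str = "breast_cancer") -> list[str]:
    """Return the packaged gene-symbol list for a named panel.

    The default panel is the 19-gene breast-cancer predisposition panel
    (BARD1 plus 18 genes shared between curated predisposition lists and the
    common commercial panels).  Only symbols are packaged; the mapping of
    symbols to genomic intervals is always an input BED.
    """
    ref = resources.files("panelburden").joinpath(f"data/{panel}_panel.txt")
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise ConfigurationError(f"unknown panel {panel!r}") from exc
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def panel_region_from_bed(
    path: str | Path, genes: Sequence[str], name: str = "panel", strict: bool = True
) -> RegionSet:
    """Select the intervals of ``genes`` from a 4-column gene BED.

    The fourth BED column carries the gene symbol.  With ``strict`` (default)
    a panel gene absent from the BED raises, because a silently shrunken panel
    corrupts the exposure denominator.
    """
    wanted = set(genes)
    found: set[str] = set()
    intervals: list[tuple[str, int, int]] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: gene BED needs 4 columns")
            if fields[3] in wanted:
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
                found.add(fields[3])
    missing = wanted - found
    if missing and strict:
        raise ConfigurationError(
            f"{path}: no intervals for panel genes: {', '.join(sorted(missing))}"
        )
    return RegionSet(intervals, name=name)


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "cohort",
    "population",
    "region",
    "test",
    "n_samples",
    "sum_m",
    "sum_l",
    "sum_M",
    "sum_L",
    "lambda_hat",
    "T",
    "x_obs",
    "expected",
    "interval_lo",
    "interval_hi",
    "p_value",
    "p_bonferroni",
    "small_sample",
]


def write_results(results, path: str | Path) -> pd.DataFrame:
    """Write burden results as a TSV with a deterministic column order.

    Accepts :class:`~panelburden.burden_stats.BurdenResult` objects (or
    anything exposing ``to_rows()``).  Values round-trip through
    :func:`read_results` at full double precision.  An empty collection is a
    contract violation, not an empty file.
    """
    rows: list[dict] = []
    for res in results:
        rows.extend(res.to_rows())
    if not rows:
        raise DataError("write_results called with no results")
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return frame


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
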