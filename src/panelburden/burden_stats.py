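"""Burden statistics: background-rate estimation and enrichment tests.

The model: within population *i*, truncating mutation events occur
homogeneously at an unknown per-callable-position rate.  The background rate
is estimated exome-wide as the pooled ratio

    lambda_i = (sum_j M_ij) / (sum_j L_ij)

over individuals *j*, where M is the per-individual truncating event count
and L the per-individual callable exome length.  Panel enrichment is then an
exact Poisson rate test of the observed panel event count x = sum_j m_ij
against mean mu = lambda_i * T with panel exposure T = sum_j l_ij.

The two-sided Poisson p-value follows the classical "sum of no-more-probable
outcomes" construction (as in R's poisson.test): p is the total probability
of all counts k with Pr(k) <= Pr(x) * (1 + 1e-7), the small relative
tolerance guarding against ties lost to floating point.  The same convention
is used for the Fisher exact test on 2x2 tables.

Between-group contrasts: Fisher's exact test compares panel mutation rates
(events vs. remaining callable positions, or carriers vs. non-carriers), and
the Mann-Whitney U test compares per-individual exome-wide event counts,
exact for small untied samples and normal-approximated with midranks and
tie-corrected variance otherwise.

Cross-cohort meta-analysis pools counts and exposures (which preserves the
exact tests) rather than combining p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import special, stats

from .io_formats import DataError

__all__ = [
    "PopulationBurden",
    "BurdenResult",
    "estimate_lambda",
    "poisson_two_sided",
    "expectation_interval",
    "fisher_exact_2x2",
    "fisher_rate_comparison",
    "mannwhitney_burden",
    "pool_burdens",
    "meta_pooled",
    "analyze_population",
]

_REL_TOL = 1e-7  # relative tolerance for probability ties (reference convention)


# ---------------------------------------------------------------------------
# Aggregates
# ---------------------------------------------------------------------------

@dataclass
class PopulationBurden:
    """Per-population event counts and callable exposures.

    Vectors are indexed by sample: ``M``/``L`` are exome-wide event counts and
    callable lengths, ``m``/``l`` their panel counterparts.  A carrier is a
    sample with at least one panel event.
    """

    population: str
    samples: list[str]
    M: np.ndarray
    L: np.ndarray
    m: np.ndarray
    l: np.ndarray
    cohorts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int64)
        self.L = np.asarray(self.L, dtype=np.int64)
        self.m = np.asarray(self.m, dtype=np.int64)
        self.l = np.asarray(self.l, dtype=np.int64)
        n = len(self.samples)
        for name in ("M", "L", "m", "l"):
            vec = getattr(self, name)
            if len(vec) != n:
                raise DataError(f"{self.population}: {name} has length {len(vec)} != {n}")
            if (vec < 0).any():
                raise DataError(f"{self.population}: negative values in {name}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def carriers(self) -> np.ndarray:
        return self.m >= 1

    @property
    def n_carriers(self) -> int:
        return int(self.carriers.sum())

    @property
    def sum_M(self) -> int:
        return int(self.M.sum())

    @property
    def sum_L(self) -> int:
        return int(self.L.sum())

    @property
    def sum_m(self) -> int:
        return int(self.m.sum())

    @property
    def sum_l(self) -> int:
        return int(self.l.sum())


@dataclass
class BurdenResult:
    """Outputs of the panel-enrichment analysis for one population."""

    population: str
    cohort: str = ""
    region: str = "panel"
    n_samples: int = 0
    sum_m: int = 0
    sum_l: int = 0
    sum_M: int = 0
    sum_L: int = 0
    lambda_hat: float = 0.0
    T: int = 0
    x_obs: int = 0
    expected: float = 0.0
    expectation_interval: tuple[int, int] = (0, 0)
    p_poisson: float = 1.0
    comparisons: dict[str, float] = field(default_factory=dict)
    bonferroni: dict[str, float] = field(default_factory=dict)
    small_sample: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.expectation_interval
        if lo > hi or self.expected < 0:
            raise DataError(f"{self.population}: malformed expectation interval")

    def to_rows(self) -> list[dict]:
        base = {
            "cohort": self.cohort,
            "population": self.population,
            "region": self.region,
            "n_samples": self.n_samples,
            "sum_m": self.sum_m,
            "sum_l": self.sum_l,
            "sum_M": self.sum_M,
            "sum_L": self.sum_L,
            "lambda_hat": self.lambda_hat,
            "T": self.T,
            "x_obs": self.x_obs,
            "expected": self.expected,
            "interval_lo": self.expectation_interval[0],
            "interval_hi": self.expectation_interval[1],
            "small_sample": self.small_sample,
        }
        rows = [
            dict(
                base,
                test="poisson_enrichment",
                p_value=self.p_poisson,
                p_bonferroni=self.bonferroni.get("poisson_enrichment", float("nan")),
            )
        ]
        for test, p in self.comparisons.items():
            rows.append(
                dict(
                    base,
                    test=test,
                    p_value=p,
                    p_bonferroni=self.bonferroni.get(test, float("nan")),
                )
            )
        return rows


# ---------------------------------------------------------------------------
# Rate estimation
# ---------------------------------------------------------------------------

def estimate_lambda(pb: PopulationBurden) -> float:
    """Pooled exome-wide background rate sum(M) / sum(L).

    This is a ratio of pooled sums, *not* the mean of per-sample ratios, so
    unevenly covered individuals are weighted by their callable exposure.
    """
    if pb.sum_L <= 0:
        raise DataError(f"{pb.population}: total callable exposure is zero")
    return pb.sum_M / pb.sum_L


# ---------------------------------------------------------------------------
# Exact Poisson machinery
# ---------------------------------------------------------------------------

def _pois_logpmf(k: float, mu: float) -> float:
    return float(special.xlogy(k, mu) - mu - special.gammaln(k + 1.0))


def _pois_cdf(k: float, mu: float) -> float:
    if k < 0:
        return 0.0
    return float(special.pdtr(k, mu))


def _pois_sf(k: float, mu: float) -> float:
    """P(X > k)."""
    if k < 0:
        return 1.0
    return float(special.pdtrc(k, mu))


def poisson_two_sided(x: int, T: float, r: float) -> float:
    """Exact two-sided Poisson rate test p-value for x events at exposure T.

    Under the null the count is Poisson with mean ``mu = r * T``; the p-value
    sums the probabilities of all outcomes no more probable than ``x`` (to a
    relative tolerance of 1e-7).  The observed count itself always qualifies,
    so the p-value lies in (0, 1] for any achievable outcome.
    """
    if not float(x).is_integer() or x < 0:
        raise DataError(f"observed count must be a non-negative integer, got {x}")
    x = int(x)
    if T <= 0:
        raise DataError(f"exposure must be positive, got {T}")
    if r < 0:
        raise DataError(f"rate must be non-negative, got {r}")
    mu = r * T
    if mu == 0.0:
        return 1.0 if x == 0 else 0.0
    if x == mu:
        return 1.0
    log_d = _pois_logpmf(x, mu) + math.log1p(_REL_TOL)

    if x < mu:
        # right-hand boundary: smallest y >= ceil(mu) with pmf(y) <= pmf(x)*(1+tol);
        # the pmf is non-increasing there, so binary search applies.
        lo = math.ceil(mu)
        hi = int(mu + 10.0 * math.sqrt(mu) + 100.0)
        while _pois_logpmf(hi, mu) > log_d:
            hi = 2 * hi + 100
        while lo < hi:
            mid = (lo + hi) // 2
            if _pois_logpmf(mid, mu) <= log_d:
                hi = mid
            else:
                lo = mid + 1
        return min(1.0, _pois_cdf(x, mu) + _pois_sf(lo - 1, mu))

    # x > mu: left-hand boundary: largest y <= floor(mu) with pmf(y) <= d
    # (pmf non-decreasing up to the mode).
    right = _pois_sf(x - 1, mu)
    lo, hi = 0, math.floor(mu)
    if _pois_logpmf(lo, mu) > log_d:
        return min(1.0, right)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _pois_logpmf(mid, mu) <= log_d:
            lo = mid
        else:
            hi = mid - 1
    return min(1.0, right + _pois_cdf(lo, mu))


def expectation_interval(T: float, r: float, level: float = 0.95) -> tuple[int, int]:
    """Central interval of the Poisson(r*T) random expectation.

    ``lo`` is the largest count whose lower tail P(X <= lo-1) still fits under
    alpha/2; ``hi`` the smallest count with P(X <= hi) >= 1 - alpha/2.  By
    construction the interval covers at least ``level`` of the mass, so it is
    (mildly conservatively) the plotted "random expectation" box.
    """
    if T <= 0:
        raise DataError(f"exposure must be positive, got {T}")
    if r < 0:
        raise DataError(f"rate must be non-negative, got {r}")
    if not (0.0 < level < 1.0):
        raise DataError(f"level must be in (0,1), got {level}")
    mu = r * T
    if mu == 0.0:
        return (0, 0)
    alpha = (1.0 - level) / 2.0
    hi = int(stats.poisson.ppf(1.0 - alpha, mu))
    lo = int(stats.poisson.ppf(alpha, mu))  # smallest k with cdf(k) >= alpha
    if _pois_cdf(lo, mu) <= alpha:  # exact boundary hit: one step further
        lo += 1
    return (lo, hi)


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    Sums hypergeometric probabilities of all tables with the observed margins
    that are no more probable than the observed one (relative tolerance 1e-7).
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(int(v) != v or v < 0 for v in cells):
        raise DataError(f"2x2 table cells must be non-negative integers: {cells}")
    a, b, c, d = (int(v) for v in cells)
    n_total = a + b + c + d
    if n_total == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    support_lo = max(0, col1 - (c + d))
    support_hi = min(row1, col1)
    ks = np.arange(support_lo, support_hi + 1)
    pmf = stats.hypergeom.pmf(ks, n_total, row1, col1)
    p_obs = pmf[a - support_lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum())
    return min(1.0, p)


def fisher_rate_comparison(
    a: PopulationBurden,
    b: PopulationBurden,
    mode: Literal["events_vs_exposure", "carriers"] = "events_vs_exposure",
) -> float:
    """Fisher exact comparison of panel mutation burden between two groups.

    ``events_vs_exposure`` (default) contrasts panel event counts against the
    remaining panel callable positions per group — a per-position rate
    comparison.  ``carriers`` contrasts carrier vs. non-carrier individuals —
    the carrier-prevalence comparison.  Symmetric in group order.
    """
    if a.n_samples == 0 or b.n_samples == 0:
        raise DataError("both groups must be non-empty")
    if mode == "events_vs_exposure":
        table = [
            [a.sum_m, a.sum_l - a.sum_m],
            [b.sum_m, b.sum_l - b.sum_m],
        ]
    elif mode == "carriers":
        table = [
            [a.n_carriers, a.n_samples - a.n_carriers],
            [b.n_carriers, b.n_samples - b.n_carriers],
        ]
    else:
        raise DataError(f"unknown fisher mode {mode!r}")
    if min(table[0] + table[1]) < 0:
        raise DataError(f"negative cell in contingency table {table}")
    return fisher_exact_2x2(table)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _mannwhitney_exact_midrank(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p under the permutation null, ties allowed.

    Enumerates the distribution of the group-A rank sum over all label
    assignments by dynamic programming over doubled midranks (which are
    integers), then doubles the smaller tail (capped at 1), the usual exact
    two-sided convention.
    """
    pooled = np.concatenate([a, b])
    r2 = np.rint(2.0 * stats.rankdata(pooled)).astype(np.int64)
    n_a = len(a)
    w_obs = int(r2[:n_a].sum())
    max_sum = int(r2.sum())
    # counts[j, s] = number of j-subsets of the pooled midranks with sum s
    counts = np.zeros((n_a + 1, max_sum + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for r in r2.tolist():
        for j in range(n_a, 0, -1):  # descending so each midrank is used once
            counts[j, r:] += counts[j - 1, : max_sum + 1 - r]
    dist = counts[n_a]
    total = dist.sum()
    p_le = dist[: w_obs + 1].sum() / total
    p_ge = dist[w_obs:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def mannwhitney_burden(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U comparison of per-sample event counts.

    Exact (permutation) when both groups have at most 10 samples, otherwise
    the normal approximation with midranks, tie-corrected variance and
    continuity correction.  Per-sample mutation counts are small integers, so
    ties are the norm and midranks are essential.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DataError("both groups must be non-empty")
    if len(a) <= 10 and len(b) <= 10:
        return _mannwhitney_exact_midrank(a, b)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------

def pool_burdens(burdens: Sequence[PopulationBurden]) -> PopulationBurden:
    """Concatenate same-population burdens from several cohorts.

    Pooling per-sample vectors sums every aggregate (events and exposures)
    while retaining cohort provenance, so the single-cohort exact tests apply
    unchanged to the pooled data.
    """
    if not burdens:
        raise DataError("nothing to pool")
    labels = {pb.population for pb in burdens}
    if len(labels) != 1:
        raise DataError(f"cannot pool different populations: {sorted(labels)}")
    cohorts: list[str] = []
    for k, pb in enumerate(burdens):
        tags = pb.cohorts if pb.cohorts else [f"cohort{k}"] * pb.n_samples
        cohorts.extend(tags)
    return PopulationBurden(
        population=burdens[0].population,
        samples=[s for pb in burdens for s in pb.samples],
        M=np.concatenate([pb.M for pb in burdens]),
        L=np.concatenate([pb.L for pb in burdens]),
        m=np.concatenate([pb.m for pb in burdens]),
        l=np.concatenate([pb.l for pb in burdens]),
        cohorts=cohorts,
    )


def meta_pooled(
    per_cohort: Sequence[PopulationBurden],
    test: Literal["poisson", "fisher"] = "poisson",
    others_per_cohort: Sequence[PopulationBurden] | None = None,
    fisher_mode: Literal["events_vs_exposure", "carriers"] = "events_vs_exposure",
) -> float:
    """Meta-analysis p-value after pooling counts and exposures across cohorts.

    For ``poisson`` the pooled aggregates feed the single-cohort enrichment
    test (with the background rate re-estimated from the pooled exome data).
    For ``fisher`` a second list with the comparison group's per-cohort
    burdens is required.
    """
    pooled = pool_burdens(per_cohort)
    if test == "poisson":
        lam = estimate_lambda(pooled)
        return poisson_two_sided(pooled.sum_m, pooled.sum_l, lam)
    if test == "fisher":
        if others_per_cohort is None:
            raise DataError("fisher meta-analysis needs the comparison group")
        other = pool_burdens(others_per_cohort)
        return fisher_rate_comparison(pooled, other, mode=fisher_mode)
    raise DataError(f"unknown meta test {test!r}")


# ---------------------------------------------------------------------------
# Per-population analysis
# ---------------------------------------------------------------------------

def analyze_population(
    pb: PopulationBurden,
    cohort: str = "",
    level: float = 0.95,
    small_sample_min: int = 5,
) -> BurdenResult:
    """Panel-enrichment analysis for one population.

    Estimates the exome-wide background rate, forms the panel expectation
    lambda*T, and runs the exact two-sided Poisson test of the observed panel
    count against it.  Between-group comparisons are attached separately.
    """
    lam = estimate_lambda(pb)
    T = pb.sum_l
    x = pb.sum_m
    if T <= 0:
        raise DataError(f"{pb.population}: panel exposure is zero")
    return BurdenResult(
        population=pb.population,
        cohort=cohort,
        n_samples=pb.n_samples,
        sum_m=pb.sum_m,
        sum_l=pb.sum_l,
        sum_M=pb.sum_M,
        sum_L=pb.sum_L,
        lambda_hat=lam,
        T=T,
        x_obs=x,
        expected=lam * T,
        expectation_interval=expectation_interval(T, lam, level=level),
        p_poisson=poisson_two_sided(x, T, lam),
        small_sample=pb.n_samples < small_sample_min,
    )
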