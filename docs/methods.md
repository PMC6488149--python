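# Methods

## Model

Within population *i*, rare protein-truncating mutation events are modelled
as a homogeneous Poisson process over an individual's callable positions: a
single per-position rate per population, no per-gene or per-site variation.
The background rate is estimated exome-wide as the pooled ratio

    λ_i = Σ_j M_ij / Σ_j L_ij ,

where `M_ij` is the number of qualifying truncating events observed in
individual *j* and `L_ij` that individual's callable length of the capture
territory (positions with read depth ≥ 15 under the coverage-production
quality gates). The pooled ratio, not a mean of per-sample ratios, is used so
that unevenly covered individuals contribute in proportion to their exposure.

Panel enrichment then asks whether the observed panel event count
`x = Σ_j m_ij` is compatible with `Poisson(λ_i · T)`, `T = Σ_j l_ij`, where
`l_ij` is the callable length of panel ∩ capture in individual *j*. Note that
the panel is part of the exome, so panel events also appear in `M`; at
realistic panel/exome exposure ratios (~1/300) the resulting dependence of
λ̂ on `x` is negligible, and the synthetic studies (calibration, recovery)
quantify its effect rather than assume it away.

An *event* is one carrier call of one surviving variant in one sample;
zygosity does not matter (a homozygote counts once), and a *carrier* is an
individual with at least one panel event.

## Statistical tests

* **Exact Poisson rate test** (two-sided): p is the total `Poisson(μ)`
  probability of all outcomes no more probable than the observed count,
  where probabilities within a relative tolerance of 1e-7 count as tied —
  the classical construction (identical to R's `poisson.test`), implemented
  with regularized-gamma tail sums and a binary search for the opposite-tail
  boundary (the pmf is monotone on either side of the mode). Verified
  against an independent pmf-summation oracle to ~1e-13 relative error over
  x ∈ [0, 50] × μ ∈ [0.1, 20], and against R to 12 digits during
  development.
* **Expectation interval**: the central Poisson interval
  [largest k with CDF(k−1) ≤ α/2, smallest k with CDF(k) ≥ 1−α/2] at
  α = 0.05. By construction its coverage is ≥ 95% (mildly conservative, as
  for any discrete distribution); μ = 0 yields (0, 0).
* **Fisher exact test** (two-sided) for between-group contrasts, with the
  same no-more-probable-outcomes convention and tie tolerance. Two table
  constructions are reported side by side, because "mutation rate"
  comparisons can reasonably mean either: `events_vs_exposure`
  ([Σm, Σl − Σm] per group — rate per callable position, the default) and
  `carriers` ([carriers, non-carriers] per group — carrier prevalence).
* **Mann-Whitney U** (two-sided) for per-individual exome-wide counts.
  Counts are small integers with heavy ties, so midranks are used
  throughout. With ≤ 10 samples per group the exact permutation null is
  computed by a subset-sum dynamic program over doubled midranks and the
  smaller tail is doubled (capped at 1); otherwise the normal approximation
  with tie-corrected variance and continuity correction applies (matching
  R's `wilcox.test` defaults).
* **Meta-analysis** pools per-sample vectors (hence counts and exposures)
  across cohorts per population and re-runs the single-cohort exact test on
  the pooled aggregates. Pooling preserves exactness for count/exposure
  statistics, which combining p-values would not; populations present in
  only some cohorts are excluded with a warning.
* Significance is read at two-sided 0.05 with no multiplicity adjustment;
  a Bonferroni column is emitted for transparency only.

## Filter cascade

Fixed order: genotype missingness → consequence class → allele frequency →
indel length → carrier depth → exclusion masks → capture restriction. All
inequalities are strict exactly as configured: depth < 3 makes a call
missing, missing rate > 0.1 removes the site (exactly 0.1 survives),
frequency > 0.02 removes (exactly 0.02 survives), indel length > 20 removes,
depth < 15 removes. A variant absent from every frequency source is
*retained* — absence of evidence of commonness — which is how
annotation-driven rare-variant filtering must behave for alleles unobserved
in reference panels.

Two deliberate interpretations, exposed for sensitivity analysis:

* The variant-level depth rule is applied **per carrier**: an event whose
  carrier has depth < 15 is discarded while the site survives for
  better-covered carriers (a site is dropped only when no qualifying carrier
  remains). A site-wide rule would contradict the per-individual event
  accounting of the rate estimator.
* Masks remove **variants**, not callable positions: the exposure
  denominators are not mask-subtracted (`callable_sites` takes regions as
  given, so a caller who prefers mask-subtracted denominators can pass
  capture ∖ masks). At realistic mask fractions the difference in λ̂ is well
  under the Monte-Carlo noise of the studies shipped here.

Coordinates: VCF positions are 1-based; all interval sets are 0-based
half-open; membership is tested at `pos − 1` (the indel anchor base). Strand
is ignored. Contig naming must match across inputs — a `chr1`/`1` style
mismatch raises instead of being silently harmonised.

## Synthetic cohorts

The generator emulates: population-specific exome-wide rates with a
multiplicative panel enrichment factor; per-sample coverage dropout (one
random gap per capture block, fraction uniform in a configured range);
ANNOVAR-style annotation fields sufficient to drive every filter; common
variants above the MAF cutoff; and one decoy class per filter (missense,
> 20 bp indel, carrier depth < 15, masked position, missing rate > 0.1),
each engineered to fail exactly that filter. The ground-truth manifest
records per-sample event counts, per-variant intended dispositions and
per-sample exposures; tests require the pipeline to recover it exactly.

Defaults are the study conditions of the shipped analyses: 40 samples,
exome rate 1.5e-6 per callable position, 30 Mb capture, 100 kb panel,
dropout uniform on [0, 0.2], enrichment 1. The acceptance script's
cohort-level scenarios use a background rate of 5e-7/position (≈ 15 rare
truncating events per individual), a 30% higher rate in the Black
population, and 4x/3x panel enrichment in Whites/Hispanics — chosen once as
a realistic regime for rare-PTV analyses of this kind.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: no site-frequency spectrum beyond the
rare/common dichotomy, no linkage or haplotype structure, no mutational
hotspots, no annotation error, no batch effects between cohorts, no
sex-chromosome ploidy, and coverage dropout that is independent across
samples rather than platform-structured. Real-data conclusions additionally
depend on upstream calling and annotation quality, which the pipeline
consumes as given.

## Numerical and degenerate-input choices

* Probability ties in both exact tests use relative tolerance 1e-7 (the
  reference convention); all p-values are clamped to (0, 1] except the
  impossible-outcome case x > 0 with μ = 0, which returns 0.
* `μ = 0`: Poisson p = 1 at x = 0; expectation interval (0, 0).
* Zero total exome exposure is an error (no rate is estimable); zero panel
  exposure is an error for the enrichment test.
* Multi-allelic records are decomposed before any filter; each alternate
  allele is an independent variant whose genotypes are re-expressed against
  that allele.
* Empty results collections refuse to serialise (no silent empty tables);
  results TSVs round-trip at full double precision (`%.17g`).
* Every stochastic routine takes an explicit seed; identical seeds produce
  byte-identical simulated cohorts.

## Known limitations

* **Exact-test conservatism at small expected counts.** The two-sided exact
  Poisson test is discrete: its achievable size at the 0.05 level falls
  below nominal when μ = λT is small. The shipped calibration study
  (10,000 null cohorts at the default scenario, μ ≈ 5.4) measures an
  empirical rejection rate near 0.037 — valid (never anti-conservative in
  that study) but below 5%; the corresponding acceptance check against a
  5% ± 1% band therefore fails by design of the test, not by defect of the
  implementation. At larger panel exposure or cohort size the size
  approaches nominal.
* The single-rate-per-population model ignores gene-level rate variation;
  a strongly mutable panel would inflate apparent enrichment. No
  covariate-adjusted or variance-component (SKAT-style) alternative is
  provided.
* Between-group Fisher contrasts treat positions as independent Bernoulli
  trials; familial relatedness or population substructure within a labelled
  group is not modelled.
* The asymptotic Mann-Whitney branch is an approximation; with group sizes
  just above the exact-path cutoff (10) and extreme tie structure its
  p-values can differ noticeably from the exact permutation null.
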