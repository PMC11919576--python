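# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, the numerical choices, and the limitations a user
should know before applying the pipeline to real cohorts.

## Burden testing

### Carrier tables

The unit of testing is the feature (gene or regulatory segment). Under the
dominant model a case sample is a carrier if it holds ≥ 1 qualifying
alternate allele at any of the feature's variants; missing genotypes count
as non-carriers and are surfaced as a per-feature `missing_rate` column so
the assumption is visible. For summary-only control cohorts the control
"carrier" count is the sum of alternate allele counts (AC) over qualifying
variants, capped at the cohort size N — i.e., each counted allele is
treated as a distinct carrier. This slightly overstates control carriers
when homozygotes or multi-variant carriers exist, which makes the test
conservative for case enrichment; for genotyped control cohorts true
carrier counting is used instead.

The table orientation is `[[case carriers, case non-carriers],
[control carriers, control non-carriers]]` and the test is the one-sided
exact probability of case enrichment, P(X ≥ a) for X hypergeometric with
all margins fixed. The tail is accumulated from `logpmf` values with
log-sum-exp, so p-values far below double underflow of individual terms
are still exact to relative precision ~1e-15. The sample odds ratio is
reported alongside (infinite when b·c = 0 with a·d > 0).

### Qualifying, benign and filter rules

* coding qualifying: max population AF ≤ 0.01 and consequence ∈
  {missense, lof} (boundary values qualify);
* noncoding qualifying: AF ≤ 0.001 and deleterious by all three
  predictors (GERP++, GWAVA, CADD flags, consumed as input annotations);
* benign (calibration) sets: rare synonymous (coding mode) or rare
  noncoding with zero deleterious flags;
* region filters: a callable mask (bases with ≥ 90% of samples covered in
  both cohorts, intersected from the two fraction-covered tracks) and
  removal of low-complexity regions.

The Bonferroni threshold is α divided by the number of features actually
tested in the run and is reported in every output row; the number of
features is a property of the user's annotation, not a constant of the
method.

### λ95 and the quality-tranche sweep

Because cases and controls are called separately, residual quality
differences masquerade as burden signal. The sweep thresholds case
variants at the (1 − q) quantile of their site-quality metric for each
grid value q, runs the benign burden scan, and summarises calibration
with λ95: transform each p to the χ²₁ quantile Q(1 − p); λ95 is the
empirical 95th percentile (linear interpolation) divided by 3.841459.
The chosen tranche is the largest q with λ95 inside the tolerance band
(default [0.95, 1.05]) — ties break toward keeping more data.

Two numerical points matter here.

1. **Mid-p for calibration.** At 51 cases the exact test's p-values are
   markedly discrete and sub-uniform; raw Fisher p-values give null λ95
   around 0.85–0.93, which a [0.95, 1.05] band would misread as cohort
   mismatch. The calibration scan therefore uses the mid-p variant
   (subtract half the probability of the observed table), the standard
   correction for QQ/inflation diagnostics of discrete tests. The
   association scan itself keeps the plain exact tail.
2. **Estimator noise.** λ95 is a 95th-percentile order statistic: at 1000
   tested features its sampling sd is ≈ 0.045 even on perfectly null
   data. A ±0.05 tolerance band will therefore occasionally (roughly 1–2
   seeds in 20) find no tranche in tolerance on clean data; the sweep
   then reports `chosen_tranche = None` with a diagnostic rather than
   silently discarding variants. On clean data it never prefers a
   reduced tranche over full inclusion.

### Descriptive summaries

`mutations_per_mb` computes per-sample, per-class variant densities
(count / class length in Mb), class means ± sd, and pooled-variance
t-tests of each class against the coding class with BH adjustment.
`variant_sharing_summary` reports the fraction of observed variants
carried by exactly one case (plus the full sharing histogram); variants
with no case carrier are excluded from the denominator since they are
unobservable in a real cohort.

## CNV consensus

Within a sample, calls from the two callers are paired greedily by best
reciprocal overlap (≥ 50%, same type — a deletion is never merged with a
duplication), each call used at most once; the consensus interval
averages the two starts and the two ends, rounding half up. Averaging
keeps the consensus inside the union and around the intersection of its
parents. Across samples, consensus calls of the same type are linked by
the same ≥ 50% reciprocal rule and connected components become regions;
the region interval is the coordinate-wise mean of member calls, the
patient frequency the number of distinct supporting samples. The output
is sorted by descending frequency and is invariant to input order;
re-clustering its own output reproduces it.

Patient frequency counts connected-component members. Under per-sample
caller false-negative rate f, a carrier survives both callers with
probability (1 − f)², so recovered frequencies are systematically
(1 − f)² of the biological truth — a property of dual-caller intersection
itself, not of the clustering. Recovery tests therefore compare against
the per-sample consensus truth.

The case/control comparison per region is a one-sided Fisher test on
carrier counts with BH adjustment — a deliberate, transparent region-level
stand-in for read-depth-based comparison tools, which operate on signal
this package does not model.

## Methylome pipeline

CpGs below 5 reads are removed first; β = methylated/(methylated +
unmethylated). The built-in HMR caller is a threshold segmenter (runs of
≥ 4 consecutive covered CpGs with β ≤ 0.5 and inter-CpG gaps ≤ 500 bp,
spanning first to last CpG) — a deliberately simple, fully specified
stand-in for HMM-based segmenters, and external HMR BEDs are accepted
directly via `hmrs_from_bed`. Uncovered CpGs break runs.

The recurrence scan tiles each chromosome in non-overlapping 100-bp
windows anchored at coordinate 0 (determinism; only the window size is a
modelling choice). HMRs longer than 10 kb are discarded as non-focal
before scanning. A window qualifies when ≥ 5% of samples (boundary
inclusive) have an overlapping HMR; maximal runs of adjacent qualifying
windows merge, and the reported `sample_fraction` is recomputed as the
fraction of samples with an HMR overlapping the merged region.
Annotation uses first-overlap precedence promoter > enhancer > dyadic and
island > shore > shelf.

Differential testing operates on the region × sample matrix of
coverage-weighted mean β (pooled reads, not averaged per-CpG βs). The
candidate regions are the recurrent HMRs computed on cases and controls
jointly — the definition stays inside the pipeline and requires no outside
region list. The test is the pooled-variance two-sample t-test (a Welch
switch is provided), BH-adjusted; rows with < 2 values per group, or zero
variance in both groups at equal means, are excluded and flagged. Δβ is
case minus control on the β scale, direction is `hypo` when Δβ < 0, the
DMR set is q ≤ 0.05 (configurable, echoed in output), and the headline
selection takes recurrent regions in > 10% of case samples with
Δβ < −0.1 (both strict, matching the reported selection rule). Gene
mapping takes promoter/exon/intron overlap, each gene once; enrichment is
the hypergeometric upper tail P(X ≥ overlap) over a user universe with BH
adjustment at q ≤ 0.05.

## Synthetic cohort model

The generator's defaults are the study conditions the analyses were
designed for: 51 genotyped cases, 350 genotyped in-house controls, 9197
summary-only controls, 48/45 case/control methylomes.

* **Genome.** Two 5-Mb chromosomes tiled in 10-kb units: one 2-kb gene
  per tile (promoter, two exons, an intron), one 1-kb regulatory segment
  (eight classes round-robin), low-complexity stretches on every fifth
  tile. Small enough for minute-scale end-to-end runs; dense enough for
  1000 genes.
* **Genotypes.** Carriers are drawn per feature per sample at the
  configured rate (background 0.01 for qualifying coding, 0.10 for rare
  synonymous, per-segment analogues for noncoding), then assigned to one
  of the feature's sites, so the per-feature carrier probability is
  exactly the configured rate. Risk genes (default three at case rate
  0.3 vs control 0.01) are elevated in cases only. Summary controls are
  never materialised as genotypes — per-site AC ~ Binomial(N, rate/sites),
  AN = 2N. Site quality is N(25, 5); the optional artifact stratum adds
  case-only synonymous sites (carrier rate 0.25 in about a third of
  genes) with quality drawn below the genuine 5% tail, sized so that
  artifact sites are ~4–5% of case sites and the 95% tranche separates
  them almost exactly — the scenario in which tranche calibration is the
  right remedy. A common-variant background at per-class densities
  (coding 14.7/Mb, regulatory classes 15.2–20.5/Mb) supports the
  mutation-rate tables.
* **CNV.** Twenty 5-kb truth regions with patient frequencies from 39
  down to 3 (three quarters deletions). Each carrier's region appears in
  each caller independently with probability 1 − FN (default 0.1),
  boundaries jittered with sd 50 bp (degenerate draws resampled); each
  caller adds Poisson(1) false positives per sample.
* **Methylomes.** Regions of 20 CpGs (40-bp spacing) on successive
  promoters: background β 0.85; recurrent-HMR blocks at β 0.10 present in
  a per-region 5–60% of samples; private blocks at 2% presence;
  differential regions at control β 0.25 with the case mean shifted by
  ±0.2 (90% negative). A per-sample-region Gaussian effect (sd 0.05)
  supplies biological variance; per-CpG counts are beta-binomial
  (ρ = 0.02, ρ = 0 degenerates to binomial) at Poisson(30) depth.
  The planted differential regions are intermediate-methylation HMRs in
  both groups so that they enter the DMR candidate set through the same
  recurrence scan as everything else — no truth information leaks into
  the analysis path.
* **Randomness.** Everything derives from one root seed through named
  substreams (one per logical output), so outputs are byte-identical
  across runs and stable when one component's draws change.

What the generator does **not** emulate: linkage disequilibrium, realistic
site-frequency spectra, sex chromosomes, read-level noise, batch- or
cell-composition effects in methylation, and caller-specific error
signatures beyond jitter/FP/FN. Passing recovery tests therefore
demonstrates correctness of the analysis logic under the stated noise
models, not performance on real data.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open everywhere internally; VCF and
  Bismark positions (1-based) convert at the I/O boundary. A printed
  region of the form chr19:15783859–15791329 has length end − start =
  7470 under this convention; sources that print end − start − 1 differ
  by one, which is documented rather than replicated.
* Coordinate averaging rounds half up (`floor(x + 0.5)`) for determinism.
* p = 0 inputs to λ95 are clipped to the smallest positive float with a
  warning; λ95 requires ≥ 20 p-values.
* Fisher inputs are validated (non-negative integers, positive row
  sums); the odds ratio returns NaN for the 0/0 case.
* Zero-coverage CpGs have undefined β and can never seed an HMR; regions
  with no covered CpG in any sample are dropped from the methylation
  matrix with a warning.
* The t-test marks zero-pooled-variance rows with unequal means as
  infinitely separated (p = 0) and excludes equal-mean constant rows.

## Limitations

* The control-carrier AC approximation and the cap at N make the burden
  test conservative in extreme tables; published p-values derived from a
  different table construction will not match exactly.
* λ95's order-statistic noise (above) means tranche selection should be
  read jointly with the reported per-tranche λ95 values, not as a binary.
* Cross-sample CNV clustering by connected components can chain calls
  whose ends differ; the averaged interval is then a compromise
  coordinate. Patient frequency counts component members, one per sample.
* The DMR units are pipeline-defined recurrent HMRs; studies that test
  fixed windows or probe sets will report different region counts for the
  same data.
* Single-threaded by design; the toy genome keeps full-pipeline runs in
  minutes on one CPU.
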