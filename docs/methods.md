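# Methods

This note documents the models, algorithms and numerical choices behind
`sparseselect`, and what its synthetic data do and do not establish about
real data.

## The problem

Haplotype-based selection scans look for the footprint of a recent
advantageous allele: an unusually long stretch of sequence carried intact at
an unusually high frequency, because selection outpaced recombination.
Their power depends critically on marker density — on a sparse genotyping
array (~1 SNP per 10 kb) few markers remain on the swept haplotype to anchor
it, and phasing is less accurate.  The package implements a full synthetic
pipeline for studying this: sweep and neutral simulation at array-era
densities, four scans (the empirical long-haplotype score, iHS, XP-EHH,
windowed Fst), phasing switch-error evaluation, power estimation, and the
haplotype similarity index for classifying signals shared across
populations.

## Sweep simulation

`simdata.simulate_sweep` is a forward-in-time Wright–Fisher simulator with
genic (additive, fitness `1 + s` per derived copy) selection:

* **Defaults** are the study conditions: `Ne = 17,469` diploids,
  `s = 0.01`, `mu = 3e-8` per bp per generation, 1 cM/Mb baseline
  recombination, 100-kb regions, samples of 120 haplotypes (a
  HapMap2-panel-like size; the conditioning target is the *sample* derived
  allele frequency, within ±0.05 of `target_daf`).
* **Rescaling.**  Forward simulation at `Ne ≈ 17,000` is infeasible at desk
  scale, so the population is rescaled by `Q` (default 50): size `Ne/Q`,
  with `s`, `mu` and `r` multiplied by `Q`.  The population-scaled
  compound parameters `Ne·s`, `Ne·mu·L` and `Ne·r·L` are preserved exactly
  (`SweepConfig.rescaled()` keeps `Ne/Q` fractional; the engine rounds the
  haplotype count to the nearest even integer).  Rescaling preserves sweep
  signatures to first order but inflates per-generation drift, one reason
  absolute power values can shift slightly relative to other simulators.
* **Initialization.**  The starting population (2·Ne/Q haplotypes) is an
  equilibrium sample from the neutral coalescent (msprime) at the rescaled
  parameters; the advantageous mutation is injected on one random haplotype
  at the region midpoint.
* **Dynamics.**  Each generation draws two fitness-weighted parents per
  offspring, recombines with Poisson crossovers placed by the genetic map's
  inverse CDF, and adds Poisson infinite-sites mutations at uniform physical
  positions.  The simulation stops at the first generation where the
  population frequency reaches the target (fixation for `target_daf = 1`),
  then samples without replacement; sample-frequency conditioning is by
  rejection with a cap of 500 forward attempts (the initial equilibrium
  population is reused across attempts; mutation, selection and sampling
  randomness are fresh).
* **Neutral regions** come directly from the neutral coalescent at the
  natural (unrescaled) parameters — the classical choice for null panels —
  and satisfy Watterson's expectation for the segregating-site count.
* **Two-population pairs** (`simulate_population_pair`) start both demes
  from one shared equilibrium population and evolve them independently (the
  target under selection) for the sweep's duration, with a shared
  site ledger so the panels stay position-aligned.  Divergence is therefore
  on the sweep's timescale (~1,000 natural generations), enough for XP-EHH
  and Fst contrasts; it does not model any particular human population pair.

## Recombination maps

The default map (`map_model="hotspot"`) is a simplified hotspot model of
the kind array-era coalescent simulators generate around a stated baseline:
hotspot centres from a Poisson process (mean spacing 10 kb), width 2 kb,
lognormal intensities (σ = 1.5), a uniform background carrying 10% of the
map, and the region total normalized to exactly `baseline × length`
(population-average maps are what the scans consume).  This matters more
than it may appear: with a strictly uniform map and near-uniform SNP
spacing, a candidate haplotype's genetic span and SNP count are almost
perfectly correlated, so the long-haplotype score's two empirical p-values
collapse into one and its null calibration degrades badly.  Hotspot
structure decorrelates the two evidence channels.  A `"uniform"` map
remains available and is what the toy fixtures in the tests use.

## Array ascertainment and thinning

`ascertain_array` emulates a fixed genotyping array: sites with sample
MAF ≥ 0.05 are kept with probability `m / E[S_common]`, where `m` is the
target marker count per neutral region (200 per 100 kb, HapMap2-like) and
`E[S_common]` is the expected number of common neutral sites from the
standard frequency spectrum (`theta · Σ 1/i` over the common range) — a
closed-form calibration, not a fitted constant.  Two consequences are
deliberate and central to the science:

* a swept region, having lost diversity, carries **fewer markers** than a
  neutral region (the "double whammy" of sparse data), and
* a sweep at fixation leaves almost **no** typable marker on its
  haplotype, which is why power there collapses.

`thin_uniform` (uniform subsampling, focal site retained, exact count
`round(f·M)`) models the further 20-fold density reduction to an
array like the ~55,000-SNP panel; `thin_by_template` reproduces
template-based matching to a fixed marker list (exact position else nearest
neighbour, ties to the lower coordinate, duplicates collapsed).

## The long-haplotype scan

A candidate is a maximal pair (SNP interval, allele string) carried intact
by at least `f·H` haplotypes; maximal means no one-SNP extension on either
side retains the threshold.  `haplops` enumerates **all** maximal candidates
exactly: for each interval start, the partition of haplotypes by their
string is refined SNP by SNP (compiled kernel), and each partition block is
recorded when it splits, together with the carrier-count range for which it
is maximal — one pass serves the whole frequency grid (0.05 … 0.95 in steps
of 0.05).  Brute-force enumeration over all intervals and strings reproduces
the candidate set verbatim on small panels (a standing test).  The greedy
seed-and-grow view (`longest_haplotype_at`: extend the side losing fewest
carriers, ties extend left, allele ties keep the ancestral allele) is kept
for locus-centred profiles; its output is always one of the exhaustive
maximal candidates.

Scoring: a candidate at frequency `f` receives two empirical p-values — the
proportion of same-frequency candidates genome-wide whose genetic span (cM)
is at least as large, and likewise for SNP count — and the score is
`p_cM · p_snp · N_total`.  Ranks are inclusive, so `p ≥ 1/N_total`; for a
candidate scored against a pool that does not contain it the count is
clipped to ≥ 1.  Scores below 0.05 are called; the score is not a p-value
and can exceed 1.  Overlapping significant haplotypes (≥ 1 bp) merge into
regions whose inferred advantageous-allele frequency is the highest
significant core frequency.  Note the score's empirical construction
guarantees a small number of "significant" candidates per frequency stratum
in any genome (expected ≈ `0.05·(1 − ln(0.05/N_f))` under independence of
the two p-values): even neutral genomes yield a handful of calls, which is
faithful to how the method behaves on real data.

For standalone simulated regions (the power study), the genome-wide null at
each frequency is the pooled candidate set of the matched neutral regions,
and each region — selected and null alike — is summarized by the minimum
score of its candidates over the grid; the detection threshold is the 1%
lower quantile (linear interpolation) of the null region scores.

## EHH statistics

EHH is computed combinatorially: `Σ C(n_g, 2) / C(n_core, 2)` over groups
of haplotypes identical from the focal SNP to the query SNP (focal column
included; for allele-defined cores the curve starts at exactly 1).  iHS
integrates EHH against genetic distance by the trapezoid rule separately
for ancestral and derived cores, truncating at the first SNP below
EHH = 0.05 (that trapezoid included) or at a physical gap above 2.5 Mb;
trapezoids over gaps of 20–200 kb are damped by `20 kb / gap`, and larger
non-truncating gaps by 0.1 — the 200-kb endpoint of the damping range,
a fixed choice isolated in one function.  Raw iHS is
`ln(iHH_ancestral / iHH_derived)` (sweeps on the derived allele push it
negative) and is standardized within 20 equal-width derived-frequency bins
(population-of-bin moments, ddof 0, hence exactly idempotent; degenerate
bins yield flagged NaN).

XP-EHH uses the SNPs shared by target and reference within 1 Mb of the
focal site.  The integration boundary is the shared SNP whose *pooled*
(both populations) EHH is nearest 0.04 within [0.03, 0.05] — pooling is
symmetric, which keeps the statistic exactly antisymmetric under swapping
the populations; distance to the focal SNP and then the left side break
ties.  Both populations are integrated in bp over the same interval and the
raw statistic is the log-ratio, standardized genome-wide.

Window calling follows the standard recipe: non-overlapping windows (1 Mb
default), proportion of |z| > 2 for iHS, window maximum for XP-EHH, top 1%
of windows with ties included; windows without scored SNPs are excluded,
zero-proportion windows are never called, and an all-equal window statistic
calls nothing.

## Fst

Per SNP, the two-population variance-components (ANOVA/θ) estimator on
haploid allele counts (MSP/MSG with the `n_c` correction) — mean ≈ 0 when
frequencies coincide, exactly 1 at a fixed difference, NaN when both
populations are monomorphic.  Windows slide 500 kb in 250-kb steps
(half-window, a documented choice; the sliding step is not standardized),
use the mean of the three largest per-SNP values, drop windows with fewer
than five SNPs, and call the top 1% with ties.

## Haplotype similarity index

For `K` selected haplotype forms compared at their `L` common SNPs
(intersection of the forms' SNPs within the bp overlap of their intervals),
the similarity matrix holds `1 − l/L` with integer discordance counts `l`.
HSI is the leading eigenvalue over the trace (= `K` exactly).  Shared
origin is called at HSI ≥ 0.98, convergent evolution at ≤ 0.90,
indeterminate between — inclusive thresholds.

## Evaluation machinery

* **Switch error**: per individual, orientation flips between consecutive
  heterozygous sites over (hets − 1); individuals with < 2 hets are
  skipped; a wholesale swap of the two haplotypes is no error; population
  rate is the unweighted mean.  `inject_switches` provides ground truth by
  flipping phase at each het with a given probability.
* **Power**: fraction of selected scores strictly below the null's 1%
  linear-interpolation quantile (≥ 100 null scores required).  Strict
  inequality and the quantile convention are fixed choices; the estimator
  is invariant under monotone transforms of both score sets.
* **Region overlap**: a call overlaps the reference set if it shares ≥ 1 bp
  with any reference region, counted once.
* **Clustering**: Pearson correlation of binary region-indicator rows,
  distance `1 − r`, Ward minimum-variance linkage on the usual
  squared-Euclidean embedding (scipy's `ward`, conceptually R's `hclust`
  ward.D2); zero-variance rows are excluded and flagged; dendrograms export
  as Newick.

## Scale of the shipped experiments

The test suite and acceptance script run the power study at 200 selected +
200 null regions per arm (the original design used 2,000 + 2,000) — chosen
as the package's standard desk-scale configuration; the 1% null quantile is
then estimated from 200 scores and carries visible sampling noise (a few
percentage points in power).  The cross-density consistency experiment runs
10 replicate genomes of 24 independent 200-kb regions (each its own
chromosome) with 3 planted sweeps, windows equal to the region length and
the usual top-1% calling: 200-kb windows keep ~20 markers per window after
thinning, enough that tied window statistics do not distort call counts,
while staying cheap enough to replicate.

## What the synthetic data do not show

* Panmictic, constant-size populations only: no bottlenecks, growth or
  migration, although such demography is known to mimic or mask sweeps.
* Two-population pairs diverge only over the sweep's duration from a shared
  equilibrium; site-frequency spectra and LD of real population pairs
  (e.g. African vs East Asian panels) are richer.
* The array model (MAF ≥ 0.05, density calibrated on the neutral spectrum)
  is a first-order emulation of SNP-array ascertainment; real array design
  involved discovery-panel bias and local tagging choices.
* Statistical phasing itself is out of scope; switch errors are injected
  synthetically at a chosen rate rather than produced by a phasing model.
* At sparse density the power of the long-haplotype score for sweeps at
  *low* frequencies (≤ 0.6) is essentially zero in this pipeline: neutral
  panels contain plenty of moderately long haplotypes at such core
  frequencies, and an `s = 0.01` sweep is already substantially recombined
  by the time it first reaches them.  Higher low-frequency power would
  require either stronger selection or data features outside this
  generator.
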