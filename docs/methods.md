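# Methods

## Setting and assumptions

The package analyzes call matrices from inbred crop collections: every
accession is a homozygous line, so at a biallelic locus each line contributes
exactly one allele observation.  Two marker systems are supported — dominant
presence/absence (DArT-type, calls 0/1) and codominant SNPs (calls 0/1/2,
where 2 marks a heterozygote).  Under full homozygosity true heterozygotes
should not occur; in polyploid wheat they arise when a marker's flanking
sequence also matches a homoeologous subgenome and reads from both copies are
merged.  All downstream statistics therefore run on recoded 0/1 matrices and
use haploid-style estimators with observed heterozygosity fixed at zero.

Files follow the DArT-report layout (marker per row, accession per column);
in memory matrices are accession-per-row so columns are loci.  Missing calls
use a dedicated sentinel (−1) that is never a legal call.  Region output is
BED (0-based half-open); everything internal is 1-based inclusive, and the
conversion happens only in the region writer, which documents it in its
header comments.

## Heterozygote recoding

Per marker, the set of observed non-missing values decides the repair:
{0,2} → 2s become 1; {1,2} → 2s become 0; {0,1,2} → 2s become missing.  The
rationale: when only one homozygote class is visible alongside 2s, the 2s are
the other class read through a homoeolog; when both classes are visible the
2s cannot be attributed and are dropped.  A column observing only 2 is wholly
recoded to missing — neither homozygote class anchors a correction, so the
marker carries no usable information; this degenerate case sits outside the
three rules above and is the package's own choice.  Recoding is idempotent
and its output never contains a 2.

## Filtering

Order is fixed: recode (SNPs) → duplicate removal → missing filter → MAF
filter.  Recoding precedes deduplication because profiles are only comparable
after artifact repair.  Thresholds are strict as worded in the protocol they
implement: a marker with *more than* 10% missing data is removed (exactly 10%
survives); a marker with MAF *below* 0.05 is removed (exactly 0.05 survives).
MAF uses pairwise deletion (non-missing calls only); an all-missing marker
has undefined MAF and is removed.

**Duplicate profiles.**  Two markers are duplicates when their calls agree at
every accession where both are scored *and* they share at least one scored
accession.  Requiring identical full vectors would make the "keep the least
missing member" rule vacuous, so compatibility-modulo-missingness is the
operative definition.  The relation is not transitive; grouping is greedy in
input-column order against each group's seed column, which makes the
partition deterministic.  Within a group the member with the fewest missing
cells is kept, ties resolved toward the earliest column.  The implementation
builds the compatibility relation with three dense matrix products (O(L²)
memory; ~150 MB of float32 at L = 6000), which keeps the step a few seconds
at the marker counts the package targets.

The genome scan uses a second marker set produced with the duplicate step
skipped (`skip_dedup=True`) and restricted to located markers: nearby markers
sharing a profile are exactly the signal a fixation scan wants to keep.

## PIC

Botstein PIC for a biallelic locus, `1 − (p² + q²) − 2p²q²`, evaluated at the
pairwise-deleted call frequency.  For dominant markers on inbred lines the
band-presence frequency is itself an allele-frequency estimate, so no
Hardy–Weinberg back-correction is applied by default; the classic
dominant-marker correction (null-allele frequency √(1−p)) is available behind
`dominant_correction=True` for outbred material.

## Marker placement

Hits pass at E-value strictly below 5e-10 and identity strictly above 90%.
The best passing hit per marker is chosen by lowest E-value, then highest
bitscore, then highest identity.  If the best score is tied across different
chromosomes the marker is left unplaced — an arbitrary choice would inject
false marker order into the scan; a same-chromosome tie takes the lowest
coordinate.  The placement position is `min(s_start, s_end)` so strand does
not affect windowing.  Density profiles tile non-overlapping windows
(default 10 Mb, configurable — no single published window width exists for
such plots) from position 1; window w covers positions
[w·W + 1, (w+1)·W], so a marker at W + 1 falls in the second window.

## Diversity statistics

With per-population frequency p̂ from n scored lines:

* `Hs = n/(n−1) · (1 − p̂² − q̂²)` per locus; population Hs is the mean over
  loci; loci with fewer than two scored lines in a population are skipped for
  that population (logged), not zero-filled.
* `Ht = ñ/(ñ−1) · (1 − p̄² − q̄²)`, with p̄ the unweighted mean frequency over
  populations scored at the locus and ñ their harmonic mean sample size.
  Applying the *same* small-sample factor to within and total diversity was a
  deliberate choice among the correction variants in circulation: it
  guarantees Ht ≥ mean(Hs) locus by locus (Jensen's inequality on p ↦ p²) and
  makes differentiation exactly zero when populations share identical
  frequencies at equal sample sizes, at the cost of Jost D slightly
  overshooting 1 (by ñ/(ñ−1)) in the complete-private-fixation corner at
  small n.
* Jost `D = (Ht − H̄s)/(1 − H̄s) · k/(k−1)` per locus with k the populations
  scored there; the overall value is computed from loci-averaged Ht and H̄s
  (ratio of averages, the "overall" convention of hierarchical-statistics
  packages), scaled by K/(K−1) with K the number of groups.
* Pairwise FST is multi-locus Weir–Cockerham θ: per-locus variance components
  a (among) and b (within) with observed heterozygosity 0 — the haploid
  specialization appropriate for inbred lines — combined as Σa/Σ(a+b).  Loci
  monomorphic across the pair, or with fewer than two observations in either
  sample, contribute nothing.  Small negative estimates are reported as
  computed; `FstMatrix.clamped_frame()` renders the non-negative version for
  summary tables.

A diploid-coded variant (each line counted as two identical alleles,
correction 2n/(2n−1)) is exposed behind `coding="diploid"` because published
tables do not always state which coding the toolchain used; the haploid form
is the default as the statistically honest one for selfing lines.

Monomorphic-marker accounting treats an all-missing marker as monomorphic but
flags it separately.

## Ordination

Distance: Euclidean on per-marker mean-imputed calls divided by √L, so
complementary accessions are at distance 1.  Mean imputation keeps the
distance metric proper; an accession with no scored calls is an error, not a
guess.  PCoA is classical scaling (double-center −D²/2, `eigh`, coordinates =
eigenvectors·√λ).  Negative eigenvalues are truncated, not corrected
(Cailliez/Lingoes corrections change interpoint distances); their count and
summed magnitude are reported on the result.  Variance explained is taken
over positive eigenvalues only.

## Fixed-region scan

Per-marker Hs is computed separately within reference-role and landrace-role
accessions over the scan marker set, and markers are sorted by (chromosome,
position).  "Consecutive" means adjacent in that sort order — the scan walks
markers along chromosomes, not fixed windows.  Candidate intervals are
maximal runs of markers with reference Hs = 0, tested exactly (|Hs| ≤ 1e-12;
a monomorphic locus yields exactly zero in the estimator, so no looser
tolerance is needed).  A run is called when it has ≥5 zero markers, ≥5 of its
own markers with landrace Hs > 0.1 (the diverse markers are counted inside
the run's physical interval — the track is shared, so none can be
interleaved from outside), and the first-to-last marker span strictly exceeds
5 Mb.  Region boundaries are the run's first and last marker positions;
boundary error against an injected truth interval is therefore at most one
inter-marker gap per side.  Runs are not merged across interrupting non-zero
markers; `max_interrupt` (default 0) exists purely for sensitivity analysis.

## Synthetic data generator

The generator emulates the structure the analysis assumes rather than any
specific dataset: K inbred populations drawn from the Balding–Nichols model
(`p_k ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F)`, variance p₀(1−p₀)F around an
ancestral frequency p₀), one haploid Bernoulli draw per line and locus,
uniform marker placement along chromosomes, and four optional injections with
recorded truth: missing calls, homoeolog heterozygote artifacts in the three
column patterns the recoder repairs, duplicated columns carrying extra
missing cells, and intervals where the reference pool is forced monomorphic
while landrace frequencies are resampled into [0.2, 0.8].

Defaults describe a durum-type collection: 7 populations of
(25, 12, 37, 18, 14, 65, 20) landraces (one dominant admixed pool, two small
subspecies-like pools), 23 reference varieties, 10,000 markers on 14
chromosomes of 600 Mb, F = 0.3, ancestral frequencies uniform on (0.1, 0.9),
5% missing, artifacts on 5% of markers, 10% duplicated profiles.  A single F
governs all populations and the reference pool — the simplest model
consistent with pairwise differentiation in the 0.2–0.45 range; real
collections show much wider FST spreads driven by subspecies structure, which
the generator does not attempt to mimic.  One global seed is split into named
`SeedSequence` children (ancestral, population frequencies, genotypes,
placements, memberships, missing, regions, artifacts, duplicates), so
enlarging one dimension does not perturb the draws of another sub-generator.

What passing tests on this generator do show: the estimators recover known
parameters (θ̂ within ±0.03 of F at two populations of 50 and 2000 loci), the
QC chain inverts the injections it is built to repair, and the scan recovers
injected fixed intervals with brute-force-verified calling logic.  What they
do not show: robustness to linkage disequilibrium, clustered marker
placement, genotyping error beyond the modeled artifact patterns, or
admixture between populations — none of which the generator produces.

## Problem sizes and numerics

The test suite runs at reduced scale (hundreds of markers, tens of lines per
population; the parameter-recovery and scan-recovery checks use 10–20
replicate seeds).  `scripts/acceptance.py` runs the full pipeline at 214
accessions × 6000 markers plus a recovery fixture, a few seconds on one CPU;
marker counts were scaled below the tens of thousands a real study produces
to keep the dense duplicate-compatibility step light, and the methods are
size-independent beyond that.  All analysis stages are deterministic;
randomness exists only in the generator and flows from the config seed.

## Known limitations

* Population assignment is consumed, not inferred: admixture estimation
  (fastSTRUCTURE-style) is out of scope, and membership vectors are expected
  as input (argmax assignment, ties toward the lowest population index).
* The dedup definition (compatibility modulo missingness, greedy seeding) is
  one defensible reading of "same allelic profile"; published marker counts
  produced by a different reading would differ, which is why the QC report
  logs every removed id per step.
* PCoA percentages depend on the distance and standardization convention;
  other toolchains (e.g. genlight-based ones) will not match to the decimal.
* No AMOVA, no bootstrap confidence intervals over loci, no formal selection
  tests — the scan is a descriptive diversity contrast.
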