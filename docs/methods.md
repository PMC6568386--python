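# Methods

`tailscan` implements a cross-population selection-signature analysis for
medium-density SNP-array data, of the kind used to contrast fat-tail and
thin-tail sheep breeds: extended-haplotype statistics (EHH, EHHS, iES,
Rsb), allele-frequency differentiation (Wright FST, Pearson chi-square with
Bonferroni control), rule-based candidate-region calling shared across
breed comparisons, runs of homozygosity (ROH) and percentile-threshold ROH
islands, and a forward Wright-Fisher simulator that generates synthetic
two-population array data with a known, optional selective sweep.

## Statistical model

### Extended haplotype homozygosity

For carriers of allele *a* at a focal SNP, EHH at a flanking marker *x* is
the probability that two randomly drawn carrier haplotypes are identical at
every marker from the focal SNP through *x*:

    EHH_a(x) = sum_g C(n_g, 2) / C(n_a, 2)

where the carriers are partitioned into groups *g* of identical haplotype
stretches.  EHH is 1 at the focal SNP and non-increasing outward.  The
site-specific version averages the two per-allele curves weighted by
squared allele frequencies, normalized so EHHS(focal) = 1:

    EHHS(x) = (p^2 EHH_0(x) + q^2 EHH_1(x)) / (p^2 + q^2)

The normalization by p^2 + q^2 makes iES comparable across focal-allele
frequencies; any constant factor cancels in the standardized Rsb.  iES is
the trapezoidal area under the EHHS curve against physical distance (bp)
on both sides of the focal SNP.  Integration on each side stops at the
first of: the EHHS cut-off (default 0.05; the crossing point is linearly
interpolated), the chromosome terminus, or an inter-marker gap larger than
`max_gap_bp` (default 500 kb); each condition is flagged per SNP.  Physical
distance is used because no genetic map is assumed for array data.  A
focal SNP needs at least two carriers of each allele; other SNPs are
flagged and excluded downstream.

### Rsb

Rsb contrasts iES between a selected-candidate population (fat-tail, first)
and a reference population (thin-tail):

    Rsb = ln(iES_pop1 / iES_pop2)

Raw ln-ratios are standardized by median-centering and scaling by the
classical (n-1) standard deviation, then transformed to a one-sided score
`-log10(1 - Phi(Rsb))` using the standard normal survival function (stable
for large arguments).  A score of 3.3 corresponds to a one-sided P of
5e-4; a score of 4 to 1e-4.  Positive scores indicate extended haplotype
homozygosity in the first (fat-tail) population.  Standardization is an
explicit choice: applying Phi to raw ln-ratios would make significance
scale-dependent; raw values are also emitted so the choice is transparent.

### FST and chi-square

Per SNP, Wright's allele-frequency FST with unweighted within-population
heterozygosity:

    pbar = (p1 + p2)/2;  HT = 2 pbar (1 - pbar)
    HS = (2 p1 (1-p1) + 2 p2 (1-p2)) / 2;  FST = (HT - HS)/HT

defined as 0 when HT = 0.  The chi-square statistic is Pearson's on the
2x2 allele-count table (1 df, no continuity correction), with Bonferroni
adjustment `min(1, P * m)` over the m tested SNPs.  No sample-size
weighting or finite-sample correction is applied; Weir-Cockerham-style
estimators would be a reasonable alternative but the allele-frequency form
is the simplest defensible reading of the approach being reproduced.

### Candidate regions

Per comparison, SNPs with score >= 3.3 are chained while consecutive
significant SNPs are at most 200 kb apart; chains with >= 2 SNPs become
regions bounded by their first and last significant SNP.  Regions from
different comparisons are clustered when their intervals, each extended
200 kb in both directions, intersect on the same chromosome (transitive
closure); clusters supported by >= 2 distinct comparisons are reported,
spanning the union of the raw member intervals.  The extension-based
definition of "present in two or more comparisons" is the only reading
consistent with published tables in which same-row intervals do not
overlap raw but do after a 200 kb extension.  Chi-square corroboration
flags a region when a Bonferroni-significant SNP lies within 200 kb of its
boundaries (inclusive).  Gene annotation lists features overlapping a
region by >= 1 bp, from BED (0-based half-open, converted on read) or GFF3
(1-based inclusive) input.  All coordinates are 1-based inclusive.

### ROH and islands

A run of homozygosity satisfies five criteria: span >= 1 Mb; at most one
heterozygous and one missing call; >= 30 SNPs; average spacing
(span/n_snps) <= 100 kb; no inter-marker gap > 1 Mb.  Calling enumerates
every maximal SNP-index window satisfying the het/missing budgets and the
gap rule exactly (two-pointer sweep), applies the count/length/density
filters, and resolves overlapping survivors greedily by length (ties to
the leftmost).  This replaces the sliding-window heuristic of common
tooling with an exact, oracle-testable search; run edges can therefore
differ slightly from window-based callers, and numeric parity with them is
not claimed.  Locus homozygosity for a group is the fraction of its
individuals whose ROH covers each SNP.  ROH islands are maximal runs of
SNPs whose incidence reaches the genome-wide 0.9999 quantile (linear
interpolation, ties at the threshold included — the reading that
reconciles a nominal top-10^-4 selection with islands tens of SNPs long),
merged across gaps <= 1 Mb and reported when >= 3 SNPs (both configurable;
the threshold is computed genome-wide, not per chromosome).

### Population structure

Pairwise identity-by-state distances (1 minus mean shared-allele fraction
over jointly called SNPs) and classical Torgerson MDS (double-centred
squared distances, eigendecomposition, top-k positive axes; variance
fractions relative to the sum of positive eigenvalues).  Comparison groups
are declared by the user, not inferred from the embedding.

## Synthetic data generator

The simulator emulates two breed-like diploid populations genotyped on a
medium-density array:

- **Map**: `n_chrom` = 3 chromosomes of 100 Mb with 2,000 markers each on
  a jittered regular grid (~50 kb spacing), mirroring how genotyping
  arrays are engineered for even coverage; uniform random placement would
  create marker deserts real arrays avoid.
- **Founders and LD**: `n_founder_haplotypes` = 20 founder haplotypes with
  per-SNP allele frequencies Uniform(0.1, 0.9); an ancestral pool is built
  by mosaic copying of founder segments with geometric lengths (mean 10
  markers, ~0.5 Mb), creating block-wise ancestral LD.
- **Demography**: the pool splits into two populations of `ne` = 800
  diploids each, evolving independently for 100 generations of random
  mating with Poisson-distributed crossovers (1e-8 per bp per meiosis);
  `n1` = `n2` = 50 diploids are sampled at the end.  Keeping the evolving
  size well above the sample size is essential: with census = sample = 50,
  drift fixes roughly half the markers per population and background
  haplotype sharing swamps any sweep signal — far more drift than array
  studies of livestock breeds exhibit.
- **Sweep**: genic fitness 1 : 1+s : 1+2s at a chosen focal SNP in one
  population.  By default the favoured allele enters as a single new copy
  when selection switches on (45 generations before sampling) and the
  replicate is deterministically re-drawn (seed + attempt counter; shared
  pre-onset history) until its final frequency lands in [0.72, 0.88].
  This window defines the scenario the statistic targets — a strong hard
  sweep near, but short of, fixation at sampling time.  The regimes
  outside it are measurably invisible to Rsb: a sweep completed long
  before sampling has no remaining haplotype contrast, a sweep from
  common standing variation is soft (many haplotype backgrounds), and a
  fixed sweep leaves the focal region monomorphic and unscannable.
  Setting `init_freq` switches to standing variation; the accepted attempt
  number and full frequency trajectories are part of the truth record.
- **Output**: phased PED/MAP via the package's own writer (allele order
  encodes phase), optional injected missingness, plus a truth file.

What the generator does **not** emulate: array ascertainment bias, per-SNP
genotyping error, mutation after the founder generation, demographic
events (bottlenecks, migration, admixture), overlapping generations, and
variable recombination (no hotspots).  Passing tests therefore show that
the statistics behave correctly for drift + recombination + selection at
array-like marker density — not that thresholds transfer quantitatively to
any particular empirical data set.

## Numerical choices

- Genotypes are coded as counts of the file-wise minor allele (ties broken
  alphabetically, the later allele becoming the counted one); missing is
  "0 0" in PED.  QC filter order is fixed: non-autosomal markers, then
  samples by missingness, then SNP call rate, then MAF computed on the
  retained samples (global across groups, configurable).
- The genome scan (`ies_table`) runs a numba kernel; the readable
  numpy/python curve API (`ehh_decay`, `ehhs_site`, `integrate_ies`) is
  the reference semantics and the test suite asserts exact agreement
  between the two on random instances, alongside a brute-force
  prefix-hashing oracle.
- EHH walks stop early once EHH reaches 0 (it cannot recover); EHHS walks
  stop once the value falls below the integration cut-off.
- Degenerate cases: monomorphic focal SNPs are flagged, not errors, in
  table computations; FST is 0 where HT = 0; chi-square is 0 with P = 1 at
  zero marginals; an all-equal incidence vector has no island structure
  and raises; standardization of a zero-variance scan raises.
- Region clustering is a sorted sweep whose output is independent of input
  order; overlap everywhere means >= 1 shared bp on 1-based inclusive
  coordinates.

## Calibration findings

Two empirical properties of the scan, established with the bundled
simulator and reported by `scripts/acceptance.py`, are worth knowing:

- **Sweep recovery.**  With s = 0.2 sweeps in the fat-tail population of
  two comparisons (the second population split into two thin-tail groups),
  the truth locus falls inside a shared candidate region in >= 90% of
  seeded replicates at the default scale.
- **Neutral calibration.**  Under fully neutral simulations the fraction
  of SNPs reaching score 3.3 is roughly 1e-3 — about twice the nominal
  5e-4.  The excess persists when drift is removed (a 10-generation split
  gives the same rate) and shrinks only slowly with larger evolving
  populations: it reflects neutral coalescent "pseudo-sweep" patches plus
  the heavier-than-Gaussian far tail of the standardized ln-iES ratio.
  The Gaussian transform is therefore an approximation that over-rejects
  at stringent thresholds — one reason empirical scans often prefer
  rank-based thresholds.  Fixed-threshold results from this pipeline
  should be read with that calibration in mind.

## Problem sizes

Defaults keep a full simulate-scan-call cycle at about 20-30 s on one
core: 6,000 markers, 2 x 50 samples, ne = 800.  The test suite's
calibration and recovery checks aggregate 20 seeded replicates each; the
oracle-equivalence suites run 100-300 random instances per statistic.

## Worked combinatorics for the tiny fixture

The `tiny` fixture (4 phased diploids, 10 SNPs at 100 kb spacing on one
chromosome) is small enough to check EHH by hand.  In `pop1` (haplotype
rows 0-3), rows {0, 1} carry allele 0 at the first SNP and rows {2, 3}
allele 1.  Each carrier pair remains identical from SNP 0 through SNP 4
and first differs at SNP 5, so both per-allele EHH curves are
1, 1, 1, 1, 1, 0 over markers 0-5, and with p = q = 1/2 the EHHS curve is
identical.  The right-side iES at cut-off 0.05 is the 400 kb rectangle
under EHHS = 1 plus the interpolated crossing segment
0.5 x (1 + 0.05) x 95,000 = 49,875 bp, i.e. 449,875 bp in total; the left
side is empty because the focal SNP sits at the chromosome start (flagged
as a chromosome-end truncation).  The test suite asserts these numbers.

## Known limitations

- No phasing algorithm: EHH-side analyses require phase, taken from the
  simulator or from PED allele order (`read_plink(phased=True)`), with
  optional per-group modal imputation of missing pairs.  Statistical
  phasing should happen upstream.
- The exact-enumeration ROH caller matches its stated criteria exactly but
  not necessarily the run edges of sliding-window callers.
- Wright's FST (unweighted HS) ignores unequal sample sizes.
- Bundled published coordinates are inputs for interval operations only;
  nothing in the package attempts to reproduce the upstream genotype-level
  results they came from.
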