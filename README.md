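# tailscan

Cross-population selection-signature scanning for medium-density SNP-array
data, built around the analysis design used to map loci under selection for
the fat-tail phenotype in sheep: divergently selected populations (fat-tail
vs thin-tail breeds) are contrasted with an extended-haplotype statistic,
corroborated by allele-frequency differentiation, and cross-checked against
runs-of-homozygosity islands.

It is a library plus a `tailscan` command line for population geneticists
who want a tested, reproducible version of this pipeline — either to run on
their own PLINK-format array data or to study the behaviour of the
statistics on simulated data with known truth.

## The statistics

For each focal SNP and population, the extended haplotype homozygosity
EHH_a(x) is the probability that two random carriers of allele *a* are
identical from the focal SNP through marker *x*.  The site-specific curve
weights the two alleles by squared frequency,

    EHHS(x) = (p² EHH₀(x) + q² EHH₁(x)) / (p² + q²),

and iES is the area under EHHS against physical distance on both sides of
the focal SNP.  Between a selected-candidate population (1) and a reference
population (2),

    Rsb = ln(iES₁ / iES₂),

standardized (median, SD) and transformed to a one-sided score
−log₁₀(1 − Φ(Rsb)); scores ≥ 3.3 (P ≤ 5·10⁻⁴) are significant.  Candidate
regions are chains of ≥ 2 significant SNPs within 200 kb, reported when
shared by ≥ 2 comparisons after a ±200 kb extension, and corroborated by
Bonferroni-significant Pearson χ² SNPs (on the 2×2 allele-count table)
within the same flank; Wright's FST accompanies the χ² values.  ROH are
called per individual by exact enumeration under the standard five criteria
(≥ 1 Mb, ≤ 1 het, ≤ 1 missing, ≥ 30 SNPs, ≤ 100 kb/SNP density, ≤ 1 Mb
gaps); ROH islands are runs of SNPs whose per-group coverage incidence
reaches the genome-wide 0.9999 quantile.  See `docs/methods.md` for
formulas, defaults, and numerical choices.

A forward Wright–Fisher simulator (`tailscan.simulate`) generates phased
two-population array data with realistic LD and an optional recent hard
selective sweep, with full truth records — the substrate for the package's
calibration and power tests.

## Worked example

Simulate two populations with a selective sweep (s = 0.2) in `pop1`, split
the neutral population into two thin-tail groups, and scan both
comparisons:

```python
from tailscan import ehh_core
from tailscan.simulate import SimParams, SweepSpec, simulate_two_pops
from tailscan.rsb_scan import rsb_scan
from tailscan.regions import significant_clusters, shared_regions

ds, truth = simulate_two_pops(
    SimParams(seed=42, sweep=SweepSpec(chrom=1, pos_bp=50_000_000, s=0.2))
)
groups = ds.groups[:]
half = [i for i, g in enumerate(groups) if g == "pop2"]
for i in half[:25]: groups[i] = "thinA"
for i in half[25:]: groups[i] = "thinB"
ds.groups = groups

tabs = {g: ehh_core.ies_table(ehh_core.haplotype_set(ds, g))
        for g in ("pop1", "thinA", "thinB")}
scans = [rsb_scan(tabs["pop1"], tabs["thinA"], "1"),
         rsb_scan(tabs["pop1"], tabs["thinB"], "2")]
for s in scans:
    print(f"comparison {s.comparison.iloc[0]}: {len(s)} SNPs scanned, "
          f"{(s.score >= 3.3).sum()} significant, max score {s.score.max():.2f}")
shared = shared_regions([significant_clusters(s) for s in scans])
for r in shared:
    print(f"shared region chr{r.chrom}:{r.start_bp:,}-{r.end_bp:,}  "
          f"comparisons={sorted(r.comparisons)}  snps={len(r.snp_ids)}")
print("truth focal:", truth.focal_chrom, f"{truth.focal_pos_bp:,}")
```

Output:

```
comparison 1: 5443 SNPs scanned, 126 significant, max score 9.45
comparison 2: 5432 SNPs scanned, 141 significant, max score 8.51
shared region chr1:44,978,391-53,737,290  comparisons=['1', '2']  snps=144
truth focal: 1 50,007,478
```

Both comparisons light up around 50 Mb on chromosome 1; the sharing rule
collates them into one candidate region that contains the true selected
locus.  The same analysis runs from a single YAML config
(`tailscan run --config config.yaml`; see the `tailscan.pipeline`
docstring for the layout), and each stage is available standalone
(`tailscan qc|mds|ies|rsb|fst|roh|islands|regions|simulate`).

The package also ships the coordinate tables of a published sheep
fat-tail selection scan (`tailscan.datasets`): applying `shared_regions`
to its 30 per-comparison intervals reproduces the published collation into
14 candidate regions on 10 chromosomes, and intersecting those with the
published fat-tail ROH islands recovers the two overlapping islands it
reported.

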