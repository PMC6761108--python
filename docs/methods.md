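# Methods notes

This note records the models, defaults and numerical choices behind
`admixscan`, and what the synthetic-data generator does and does not
emulate.

## Scope and data model

The package starts where local-ancestry inference ends: it consumes phased
diploid genotypes (0/1 haplotypes, allele 0 ancestral where the ancestral
state is known), a genetic map, and per-haplotype ancestry labels with
tract posteriors. Coordinates are 1-based; regions carry inclusive printed
endpoints and their length is `end − start`, the convention under which
published interval sizes (e.g. a 448.4-kb centromeric interval) reproduce
exactly. Ancestral-allele orientation happens once at VCF load (`AA` INFO
field); every downstream statistic assumes 0 = ancestral.

The pipeline stage order is fixed: QC → ancestry scan → inversion
genotyping → stratified rescans → selection statistics → FCS → Procrustes.
One global seed drives everything; each stochastic stage derives a child
generator from the seed plus a stage tag (CRC32), so runs are reproducible
bit for bit and stages are insensitive to each other's draw counts.

## Synthetic cohorts

**Reference panels.** Per SNP, an ancestral frequency p ~ Uniform(0.05,
0.95); each population's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F)
(Balding-Nichols), with drift F per population — defaults (0.10, 0.10,
0.20) for EUR/AFR/NAT, putting pairwise Fst near the (F₁+F₂)/2 range seen
between continental groups, with the Native-American component the most
drifted. F = 0 short-circuits to exact sharing of p. Two sampling modes:

- *mosaic* (default): K = 20 founder haplotypes per population, i.i.d.
  Bernoulli(pop frequency) per SNP; each panel haplotype is a mosaic of
  founders with switch rate ρ = 1 per Morgan. This creates within-
  population LD, which the EHH statistics require. A 2% per-site flip is
  then applied to each panel haplotype ("residual diversity since
  founding"): without it, any two haplotypes sharing a founder are
  identical indefinitely and EHH plateaus near 1/K ≈ the 0.05 integration
  floor, censoring essentially every integral at the chromosome ends.
- *frequency-level* (`founders=None`): haplotypes drawn i.i.d. from the
  population frequencies, no LD and no flip noise. This is the mode whose
  Hudson-Fst expectation equals F analytically, and the one used by the
  drift-recovery checks; the mosaic adds founder-sharing variance that
  inflates Fst by roughly (1−F)(1/K − 1/n).

**Admixed cohort.** Each haplotype's ancestry is a Markov chain along the
map: over an increment of Δ Morgans the state is redrawn from the
admixture vector π with probability 1 − exp(−gΔ) (silent self-switches
allowed, so the expected observable switch count is g·L·(1−Σπ²) per
haplotype of map length L). Defaults: π = (0.77, 0.14, 0.09) — the
EUR/AFR/NAT means reported for southeastern-Brazilian cohorts, normalized
to sum to 1 — and g = 15 generations, a plausible but unasserted
post-colonial timescale (exposed in config). Alleles are copied
tract-wise from one uniformly chosen panel haplotype of the tract's
ancestry, preserving within-ancestry LD; the truth matrix records every
label, and truth tract posteriors are 1.

**Planted ancestry deviation.** Post-hoc resampling: each haplotype's
in-region ancestry is redrawn from the target proportions and its alleles
re-copied from the new ancestry's panel. This targets the scan's
detection contract (a locus whose ancestry proportions shifted after
admixture), not the dynamics of selection — no allele-frequency
trajectory or time-depth is modelled.

**Planted inversion.** Two class haplotypes (NI, I) differing at a
fraction d (default 0.3) of in-region SNPs; every panel haplotype gets a
class by its population's inverted-class frequency, every cohort
haplotype by the frequency of its local ancestry at the region midpoint;
in-region alleles are overwritten by the class haplotype plus 2%
within-class noise. Overwriting whole regions suppresses recombination
between classes, reproducing the long-range-LD signature that makes
inversions genotypeable from SNP data.

**Scale defaults.** Chromosomes default to 20 Mb / 20 cM with 1500 SNPs
(≈13 kb spacing — array-like density at 1 cM/Mb), cohorts to 100
individuals, panels to 60 haplotypes. These desk-scale sizes keep the full
test suite in minutes; everything is configurable upward. What passing
tests show is that the machinery detects the planted structure it is
specified to detect under these conditions — not that power estimates
transfer to real cohorts, whose genomes are ~150× longer with
correspondingly tighter genome-wide SDs.

## QC

Site filters run in a fixed order — unmapped, non-autosomal,
strand-ambiguous (A/T, C/G), Hardy-Weinberg (exact conditional test,
p < 0.01), missingness (> 2%), MAF (< 0.01) — attributing each SNP to the
first filter it fails so category counts always sum to the total removed.
The HWE test is the exact conditional test (sum of probabilities of
heterozygote counts no more likely than observed given the allele
counts), computed in log-space with a relative tolerance of 1e-12 when
comparing probabilities; a chi-square variant is available behind a flag.

Individual filters: heterozygosity outliers beyond k = 2 population SDs
of the mean rate (note that at very small n no point can exceed 2 SDs —
the maximum |z| with population SD is (n−1)/√n); IBS > 0.85 duplicate
pairs (lower index kept); greedy relatedness pruning that repeatedly
removes the individual with the most above-0.125 edges (ties broken by
higher missingness, then higher index) until no edge remains. In the
pipeline the GRM-based greedy step is opt-in (`qc.relatedness_threshold`):
on short simulated genomes the GRM's estimation noise (SD ≈ 1/√(effective
independent SNPs)) swamps the 0.125 third-degree threshold, which is
meaningful only at array scale.

LD pruning is the sliding 50-SNP window / 5-SNP step / r² > 0.5 rule on
composite (dosage) correlation — the filter runs pre-phasing, so haplotype
r² would be anachronistic. The later-index SNP of a violating pair is
removed; windows never straddle chromosomes.

## Ancestry deviation scan

μ_a and σ_a are computed per ancestry over all autosomal SNPs of the
analysis set (not per chromosome). Flags are two-sided — both excess and
deficit are informative, and the two directions of a three-way composition
mirror each other. σ_a = 0 yields no flags. Adjacent flagged SNPs of one
ancestry, direction and chromosome merge into intervals (single-SNP
intervals are widened by 1 bp to keep endpoints distinct). The 4.42 SD
default corresponds to a two-sided normal tail of 9.9 × 10⁻⁶; it is a
config value inherited from neutrality-simulation calibrations in the
admixture-scan literature, not derived internally.

The posterior audit counts tracts intersecting a region and those below
a 0.9 posterior cutoff: the tract, not the SNP, is the unit, matching how
local-ancestry software reports uncertainty. Stratified rescans subset to
NI/NI or I/I homozygotes (heterozygotes are never included, as the two
haplotype backgrounds cannot be separated) and rerun the identical scan.

## Haplotype statistics

EHH at offset x is Σ_h C(n_h,2)/C(n,2) over distinct extended haplotypes
among carriers — computed by incremental partition refinement (each step
splits groups by the next allele), which equals direct pair counting
exactly and is O(carriers) per SNP step. The core column itself is
excluded from the extension (constant within an allele class; for the
pooled "all" class this keeps EHH(0) = 1). iHH integrates EHH
trapezoidally over cM, separately on each side, including only segments
with EHH ≥ 0.05 (the floor); integrals that hit a chromosome end or a
> 200 kb gap before the floor are censored and excluded from
standardization by default, preventing edge-of-chromosome deflation.
These defaults (floor 0.05, 200-kb gap, MAF ≥ 0.05 for allele-partitioned
statistics, 50 equal-count DAF bins) are the established defaults of the
EHH-scan tradition and are all exposed.

Standardization: iHS-family statistics within equal-count derived-allele-
frequency bins (bins with < 2 usable SNPs merge downward); XP-EHH and
ΔiHH_derived genome-wide, following each statistic's source convention.
XP-EHH stays signed (positive = longer haplotypes in the target) on the
grounds that selection in the target is the upper tail; an absolute-value
mode exists. ΔiHH_derived is implemented as iHH_D(target) −
iHH_D(reference), standardized then folded — one defensible reading of a
statistic whose published definition is terse.

Hudson's Fst uses the unbiased two-population estimator; windowed values
are ratio-of-averages (ΣN/ΣD), which is the consistent aggregate — the
mean of per-SNP ratios is Jensen-biased low and is not used. PBS clips
Fst to [0, 1−10⁻⁶] before T = −ln(1−Fst) and may legitimately be
negative. PBS is computed per SNP (the FCS is per SNP); in the pipeline
each reference configuration uses its reference panel as the second
population and the next panel (cyclically) as the outgroup, since a
dedicated outgroup population is not part of the three-population
simulation. |iHS| and |ΔiHH| are intrapopulation statistics of the target
cohort and are shared across configurations.

## Fisher combined score

Empirical p = (number of values at least as extreme)/N over non-missing
values — the maximum-rank treatment of ties, which guarantees p ∈ (0, 1]
and is conservative. Missing statistics contribute p = 1 rather than
dropping the SNP, keeping the SNP set identical across the five tracks
(each missing value is logged with its reason). Under independence,
2·ln(10)·FCS is χ² with 2k degrees of freedom; the acceptance suite
verifies this on simulated nulls, and the empirical-rank construction
makes the marginal outlier rate exactly 1% by design for tie-free values
with N divisible by 100.

Blocks are 100 consecutive SNPs per chromosome (the final partial block
keeps its true size and its proportion uses it); blocks never straddle
chromosomes, avoiding chimeric regions. The call threshold is the
higher-type empirical 99.5th percentile of block proportions with a
strictly-greater rule: since proportions live on a grid of multiples of
1/block-size, ties are heavy and the strict rule keeps the called
fraction ≤ 0.5% under the null (with few blocks the threshold equals the
maximum and nothing can be called — region calling needs ≥ ~200 blocks to
be meaningful). A block called under several reference configurations
gets a compound "X or Y" label.

## Inversion genotyping and Procrustes

IBS(i,j) = mean over SNPs of (2 − |gᵢ − gⱼ|)/2 on 0/1/2 dosages, missing
excluded pairwise. Classical (Torgerson) MDS double-centers the squared
distances and keeps only positive-eigenvalue axes. The EM fits a
three-component Gaussian mixture on MDS axis 1 (a 2-axis diagonal-
covariance mode exists), tolerance 10⁻⁶ on the log-likelihood, iteration
cap 10⁶. Initialization is a deterministic, seedless multi-start — centre
triplets at the (10,50,90), (2,50,98) and (min,mid,max) quantiles, equal
variances, HWE-consistent weights at q = 0.5 — keeping the best final
log-likelihood; a single percentile start can lock onto a local optimum
that splits the majority homozygote cluster. Mixing weights may be tied
to (q², 2q(1−q), (1−q)²) (`hwe_tied`). Components are ordered by mean;
the higher-weight extreme cluster is NI/NI by default, overridable by
anchor individuals of known genotype. Degenerate inputs (zero spread, or
an emptied component) return a flagged single-cluster fall-back rather
than an error. The log-likelihood trace is kept and asserted
non-decreasing in tests.

Procrustes: both configurations centred, optimal rotation and uniform
scale from the SVD of XᵀY, m² = 1 − (Σ singular values)²/(ssX·ssY),
correlation √(1−m²). The permutation test shuffles rows of Y; the p-value
uses the add-one estimator, so p ≥ 1/(n_perm+1) and is never zero. Random
control regions are sampled uniformly within chromosomes at exactly the
requested length, avoiding the excluded region; they may overlap each
other (a flag forbids it).

## Known limitations

- No forward-in-time selection dynamics, mutation model, genotyping
  error, phasing error, or sex chromosomes in the generator; planted
  signals are mechanism-level, not evolutionary simulations.
- Local-ancestry calls are inputs; their error modes (reference
  misspecification, tract-boundary uncertainty) are represented only
  through the posterior columns the audit consumes.
- The per-reference-configuration labelling of called regions is an
  interpretation of a study design whose full attribution scheme is not
  published; output headers mark it as such.
- Desk-scale genomes make some array-scale heuristics (GRM relatedness
  thresholds, 50 DAF bins) degenerate; both are configurable and the
  defaults documented above state when they are meaningful.
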