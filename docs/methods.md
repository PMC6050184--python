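# Methods

## The question and the data model

Supplementation stocking moves fish from donor (source) populations into
recipient (sink) lakes. Two population-genetic consequences are expected:
admixture raises neutral diversity in stocked lakes, and the added gene flow
counteracts drift, letting purifying selection remove putatively deleterious
variants more efficiently than in small isolated lakes, where deleterious
alleles can drift upward and even fix.

All statistics consume one central object: an individuals × loci matrix of
alternate-allele dosages in {0, 1, 2} with an explicit missing sentinel
(never conflated with dosage 0), plus a population map (individual → lake),
a lake table (area in hectares, coordinates, altitude, stocked status), an
optional sink × source stocking-mass matrix (kg), and a per-locus protein
annotation table (alignment support, reference/alternate codon, effect
score on the PROVEAN scale, where more negative means more damaging).

## Filters

Individuals with a missing fraction strictly above 30% are removed first.
SNP filters are then applied in a fixed order so attrition counts are
reproducible — biallelic (at VCF parse time) → per-population call rate
(≥ 50% in *every* population; a SNP failing in one lake is dropped globally,
giving a single shared panel) → pooled minor-allele frequency (strictly
> 0.05) → one SNP per locus (lowest position wins, a deterministic,
order-independent tie-break). Each removed SNP is charged to the first
filter it fails, so the counts sum to the input size, and filtering is
idempotent.

## Diversity and differentiation

Expected heterozygosity uses the small-sample correction
2p(1−p)·n/(n−1) per SNP (GENEPOP-style gene diversity), with n the local
number of genotyped individuals; per-lake means run over SNPs genotyped in
that lake, monomorphic SNPs contributing zeros. π is the mean corrected
heterozygosity over locally variant sites, divided by `sites_per_locus`
(default 1). With ~80 bp sequenced per GBS locus, `sites_per_locus = 80`
expresses π per sequenced site and reproduces the 10⁻³ magnitude of the
study's printed values; the analysis drivers use 80.

Pairwise FST is the Weir–Cockerham (1984) θ: per-locus variance components
a (among populations), b (among individuals within populations) and
c (within individuals) computed from sample sizes, allele frequencies and
observed heterozygote fractions, then combined across loci as a ratio of
sums (not a mean of per-locus ratios). Loci with fewer than two populations
carrying calls, n̄ ≤ 1 or n_c ≤ 0 are skipped. Negative θ is reported as
computed; clamping only at ±1. Significance and percentile confidence
intervals come from resampling loci with replacement (default 1,000
replicates); the p-value is the fraction of replicates with θ ≤ 0. The
component array is put in a canonical (lexicographically sorted) order
before resampling so bootstrap results do not depend on locus order, and
each population pair gets an independent child seed of the user seed, so
results do not depend on pair enumeration order either.

## Deleterious annotation and load

Protein hits are kept with ≥ 25 identical residues (of the 26 possible for
an 80-bp read) and ≥ 95% identity. The retained codon pair is translated
under the standard genetic code; identical amino acids mean synonymous,
stop gain/loss is flagged nonsense and excluded from the class analyses.
Nonsynonymous changes carry the side-chain category of both residues —
Pos {R,H,K}, Neg {D,E}, Unc {S,T,N,Q}, Hyd {A,V,I,L,M,F,Y,W}, Cys {C},
Sel {U}, Gly {G}, Pro {P} — as an ordered (directed) and unordered pair.
The effect class is deleterious strictly below −2.5, neutral strictly
above; scores exactly at the threshold, or absent, are "unclassified" and
excluded from load statistics.

The **deleterious allele** at each deleterious SNP is the globally minor
allele, so its local frequency can reach 1 — a lake can fix a deleterious
allele, which is precisely the signal of drift overwhelming selection that
the load statistics are designed to expose. Per lake:

- `del_present` — deleterious SNPs with local deleterious-allele
  frequency > 0 (fixed ones count);
- `del_proportion` — `del_present` over the panel-wide number of
  deleterious SNPs;
- `load_ratio` — `del_proportion / prop_polymorphic`; scale-free, > 1 when
  a lake retains deleterious variants out of proportion to its overall
  polymorphism (weak purging);
- `mean_del_maf` — mean local frequency over *present* deleterious SNPs;
- `n_fixed_del`, `prop_lowfreq` (< 0.05 among present SNPs).

## Group tests

Welch's unequal-variance t test is the default two-group comparison (the
published non-integer df = 8.863 is diagnostic of Welch; a pooled-variance
variant sits behind a flag), two-sided throughout. Effect scores are
compared across substitution classes by classical one-way ANOVA twice:
over the 36 directed classes and over the 21 unordered classes — the
contrast between the two is what shows that the direction of an amino-acid
change matters. Singleton classes are retained (they add between-group
signal but no within-group df). The population effect on deleterious allele
frequencies is a one-way MANOVA in long layout (loci as replicates,
population as the factor): Pillai's trace with the standard F
approximation, reducing exactly to the ANOVA F for a univariate response.
The implementation is cross-checked against statsmodels' MANOVA in the test
suite.

## Spatial basis and constrained ordination

Coordinates are projected to meters on a local tangent plane
(equirectangular about the centroid, Earth radius 6,371,000 m) with
altitude as z; exact geodesy is unnecessary at a few hundred km extent.
The db-MEM basis truncates the 3-D Euclidean distance matrix at the longest
minimum-spanning-tree edge (override available), replaces larger distances
by 4× the threshold, double-centers −D²/2 and keeps eigenvectors with
eigenvalues > 10⁻⁹ × the largest. On the packaged 24-lake table this yields
9 axes (truncation ≈ 411 km); an independent PCNM computation on identical
coordinates agrees (8 axes above its stricter tolerance). The published
count of 16 axes is not recoverable from this construction; the retention
rule is the standard positive-eigenvalue criterion and the count is treated
as data-dependent, not a constant.

PCoA Gower-centers the (non-negative, symmetric) FST matrix; negative
eigenvalues are reported but excluded from variance proportions
(no Lingoes/Cailliez correction by default); axes with ≥ 5% of the positive
variance are the ordination response. The stocking matrix is divided
row-wise by lake area (density of stocking, not raw mass, measures
pressure), Hellinger-transformed (√ of row-relative values; all-zero rows
of never-stocked lakes stay zero), and summarized by covariance PCA with
broken-stick retention — the longest prefix of components whose variance
proportion is at least the broken-stick expectation
b_k = (1/p)·Σ_{i=k..p} 1/i (the comparison is inclusive so a single
positive-variance axis is retained when p = 1).

RDA is multivariate least squares of the centered response on centered
predictors: R² = SS(fit)/SS(total), Ezekiel-adjusted with m = rank(X);
collinear predictor columns are dropped greedily with a report. Partial RDA
residualizes both response and predictors on the conditioning block and
reports the **semipartial** R² (fraction of the original response variance),
so on orthogonalized designs R²(x|z) + R²(z) = R²([x z]) to 10⁻⁸. When the
conditioning block spans the predictors the partial fraction is zero and a
zero-R² result is returned. Global significance uses permutation of
response rows; partial models permute reduced-model residuals
(Freedman–Lane), p = (exceedances + 1)/(n_perm + 1). Rows are first put
into a canonical joint order so the p-value is exactly invariant to how the
caller ordered the rows.

**Forward selection** is greedy over named predictor blocks with a
max-statistic step test: at each step the partial pseudo-F of every
remaining candidate (given the already-selected blocks) is computed, one
shared set of permutations yields the null distribution of the *maximum* F
across candidates, and the best candidate enters while its max-statistic
p ≤ α (default 0.05, 999 permutations). Testing the maximum controls the
per-step family-wise false-selection rate at α no matter how many
candidates compete — a flat per-candidate α overselects (one noise
variable sneaks in roughly 1−(1−α)^k of the time), while correcting
candidate-wise p-values collides with the permutation floor 1/(n_perm+1)
and loses all power once candidates are numerous. Measured on planted-signal
simulations this rule recovers exactly the informative predictor in ≥ 95%
of replicates and selects from pure noise at ≈ α per step.

VIF is 1/(1−R²) of each predictor on the others, ∞ flagged under perfect
collinearity.

## Imputation and DAPC

Missing dosages are imputed by the within-lake modal dosage (ties to the
lower dosage; lake-locus cells with no calls fall back to the global mode).
This deterministic rule replaces random-forest imputation: it is seedless,
dependency-light, and respects the population structure that drives
genotype frequencies. DAPC-style structure analysis runs k-means
(20 restarts, seeded) for K = 1..30 on the leading genotype PCs (smallest
set explaining ≥ 90% variance, capped at n/3), scores each K with
BIC(K) = n·ln(WSS_K/n) + K·ln(n), and — because the BIC curve is near-flat
beyond the true cluster count — picks the smallest K within 2 BIC units of
the minimum. Posterior memberships (Q matrix) come from linear discriminant
analysis on the same PCs; rows sum to 1 by construction.

## The synthetic-data generator

Each lake is an isolated Wright–Fisher deme founded by binomial sampling
from a shared ancestral pool (allele frequencies uniform on [0.05, 0.95] by
default; a beta option exists). Per generation: deterministic viability
selection on deleterious loci (genotype fitnesses 1, 1−hs, 1−s against the
derived allele; s = 0.05, h = 0.5), then binomial resampling of 2Nₑ
gametes. Loci are unlinked and all classes share the founder law, so with
s = 0 the deleterious and synonymous spectra are statistically identical —
selection is the only asymmetry (verified by a Kolmogorov–Smirnov test in
the suite).

Effective sizes scale sublinearly with lake area,
Nₑ = clip(10·area_ha^0.3, 40, 250): small lakes drift hard, large lakes
retain diversity. Sixty-five generations of isolation under these sizes
span pairwise θ ≈ 0.05–0.5 with median ≈ 0.23, the drift-driven
differentiation regime of the study system, and the neutral closed form
E[FST] = 1−(1−1/2Nₑ)^G is recovered within three standard errors when the
generator is run with constant Nₑ and selection off.

Stocking is modelled as replacement admixture: donor lakes are the largest
**wild (never-stocked)** populations — supplementation in this system uses
wild fish, and, just as importantly, donors drawn from stocked lakes
cross-homogenize until donor identity carries no genetic signal. Each
stocked lake draws one (sometimes two) donors with geometric usage weights
(a few dominant sources), and the recorded mass per sink–source pair is
delivered in three pulses spread over generations 0.4G–0.8G; each pulse
replaces round(kg · fish_per_kg / pulses) breeders (capped at Nₑ/2 and the
donor's Nₑ) with binomial draws from the donor's current frequencies.
Leaving the final fifth of the run pulse-free gives selection time to purge
introduced deleterious alleles while the added neutral polymorphism
persists — the mechanism behind the study's central contrast. Under these
defaults the stocked group's mean load ratio falls below the unstocked
group's in ≈ 24/25 seeds.

Sampling draws each lake's published sample size (578 individuals total)
under local Hardy–Weinberg proportions, with 10% genotypes masked at random
to exercise the filters. Annotations assign codon pairs consistent with
each class (enumerated from the genetic code) and effect scores from
N(−5, 1.2²) truncated below −2.5 for deleterious loci and N(0, 1) truncated
above −2.5 for nonsynonymous-neutral loci; synonymous loci carry no score.
All randomness flows from one seed; identical seeds give byte-identical
output files.

### What the generator does not emulate

Linkage and hitchhiking; site-frequency spectra conditioned on a real
demographic history (founders are draws from a parametric law, not a
coalescent); locus-specific read-depth/missingness structure; hatchery
domestication selection; tetrasomic inheritance and paralogy artifacts of
salmonid genomes; environmental selection (so "outlier" loci exist only via
a user-supplied exclusion list). Passing tests therefore validate the
estimators and the pipeline logic under a known truth, not the biological
completeness of the data model.

### Detectability of the stocking signal in ordination

Under the default strong-drift conditions the stocking fraction of FST
variance is a few percent and is not reliably detectable with 24 sites —
consistent with constrained ordination on this design being intrinsically
marginal. The end-to-end validation of the db-RDA chain therefore uses a
designed clear-signal scenario (constant Nₑ = 150, G = 50, five pulses per
pair late in the run from distinct wild donors): there, forward selection
recovers the stocking axes and the partial db-RDA reports a positive,
significant semipartial fraction (≈ 0.15–0.37) in ≈ 24/25 seeds.

## Numerical conventions

Positions are 1-based as in VCF; internal matrices are 0-indexed. Missing
dosage is −1, never 0. Eigen-decompositions symmetrize their input and cut
at 10⁻⁹ relative tolerance; rank decisions use `matrix_rank` with a scaled
tolerance; collinear columns are dropped in input order. Permutation
p-values never report 0 (the +1 convention). Bootstrap CIs are 2.5/97.5
percentiles. Report tables round proportions and ratios to 2 decimals and
π to 3 significant digits.

## Known limitations

- The load ratio is undefined in a lake with zero polymorphic SNPs
  (raised as an error rather than silently infinite).
- The MANOVA layout treats loci as independent replicates; linkage or
  shared ancestry among loci would inflate its significance.
- The db-MEM axis count depends on the truncation rule; only the
  construction, not a specific count, is guaranteed.
- Bootstrap FST p-values test θ ≤ 0 and are one-sided by construction.
- With fewer than ~5 sites per population the WC84 components are noisy
  and pairs can be skipped entirely; the estimator is not defined for a
  single population.
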