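# Methods

`admixscape` separates the genetic footprint of historical translocations
from contemporary, landscape-driven gene flow in heavily managed
populations.  The pipeline is: admixture estimation → kriged ancestry
surfaces → Simpson's-diversity genetic-edge detection → transect genomic
clines → genotype-based geolocation and dispersal.  A frequency-level
forward simulator provides ground truth for every stage.

## Forward simulator (`simdata`)

**Model.**  A 2-D stepping-stone grid of demes, each of diploid size `Ne`.
K founder gene pools diverge from a common ancestor under the
Balding–Nichols model: ancestral frequencies are Uniform(0.05, 0.95) and
pool frequencies are Beta(p(1−θ)/θ, (1−p)(1−θ)/θ), so θ is the expected
FST among pools (verified against a Weir–Cockerham estimator in the test
suite).  Per generation, in fixed order: (1) deterministic migration at
rate `m` to each of the four neighbors, multiplied by the permeability of
any barrier segment the edge crosses; (2) Wright–Fisher binomial drift
(2·Ne draws per locus); (3) scheduled translocation pulses
`p_target ← (1−c)·p_target + c·p_source`; (4) colonization of empty demes
from occupied neighbors, with founder size `Ne_found` (default Ne/10) to
produce allele surfing.  Deme ancestry proportions follow the identical
linear recursion *without* noise, giving a deterministic truth for
admixture-recovery tests; they stay on the simplex to < 1e−9.

**Sampling.**  Individuals are instantiated only at export: genotypes are
Binomial(2, p_deme) per locus, coordinates are deme centers plus uniform
jitter.  Translocated individuals carry source-deme genotypes with
target-deme coordinates — the defining decoupling of human-moved animals.
`displace_coordinates` additionally emulates post-natal dispersal (the
genotype marks natal origin; the sampling locality moves).

**What the simulator does not emulate** — and hence what passing tests do
not demonstrate about real data: linkage (loci are independent, matching
the pipeline's one-SNP-per-locus input), selection, sex-biased migration,
age structure, pedigrees, and individual-level ancestry blocks.  The last
omission matters for the cline stage (below).

## Filters (`genio`)

The standard reduced-representation cascade: per-site missingness ≤ 50%,
minor-allele count ≥ 2 (computed on observed alleles), ≤ 70% site
heterozygosity (paralog screen), per-sample completeness ≥ 50%, one SNP
per locus.  Order is fixed (missingness → MAC → het → samples → thinning)
and each site is charged to the first rule it fails, so report counts are
additive.  Geolocation panels subsample 5000 SNPs with MAF > 10%.

## Admixture (`admix`)

The standard binomial admixture likelihood, g_ij ~ Binomial(2, Σ_k q_ik
f_kj), fit by the classic block EM (responsibility updates for Q and F
jointly).  EM is slower than quasi-Newton alternatives but monotone and
simple; the log-likelihood trace is asserted non-decreasing.  Missing
genotypes drop out of the likelihood (missing-at-random).  Convergence is
Δℓ < 1e−6 within 2000 iterations by default; cross-validation uses looser
settings (1e−3, 200) since ranking K does not need fully polished optima.
K is selected by hiding 10% of observed genotype entries per fold and
scoring ĝ = 2π on the hidden entries; replicate runs are aligned by
Hungarian matching on column correlations before averaging.

## Ancestry surfaces and edges (`surface`)

Each ancestry component is interpolated by ordinary kriging with an
exponential variogram fit by count-weighted least squares (IDW power 2 is
available as a fallback).  Kriging with local neighborhoods (32 nearest
points) agrees with a dense solve to 1e−6 on small instances and
interpolates exactly at data points when the nugget is zero.  Layers are
clamped to [0, 1] and renormalized per cell; cells farther than 2× the
mean nearest-neighbor spacing from any sample are masked to suppress
extrapolation artifacts at the sampling edge.  Simpson's diversity
D = 1 − Σ_k p_k² reduces the K layers to one; genetic edges are the cells
at or above the 90th percentile of D, with ridge cells retained by
gradient-direction non-maximum suppression and components labeled at
8-connectivity.  Grid default: 200 cells on the longest axis
(60 in the bundled validation experiments, which keeps kriging of
repeated scenarios inside a desktop run).

## Genomic clines (`clines`)

Two-stage fit.  The hybrid index h (genome-wide ancestry between the two
parental sets of a transect, which are defined by an estimated-ancestry
threshold of 0.8) is maximum-likelihood under P(alt) = h·p1 + (1−h)·p0,
found by bounded scalar optimization; its 2-log-likelihood-unit support
interval is reported.  With h fixed, each locus gets the cline function
φ(h) = h + 2h(1−h)(α + β(2h−1)), clamped to [1e−6, 1−1e−6] inside the
likelihood.  Priors α, β ~ Normal(0, τ²) with τ² ~ Inverse-Gamma(1, 1)
Gibbs-updated; (α_i, β_i) move by joint random-walk Metropolis with
per-locus proposal scales adapted during burn-in toward 20–50% acceptance.
Split-R̂ is reported per parameter.  Defaults are desk-scale (20 000
iterations, half burn-in, thin 10, 4 chains); the validation experiments
that repeat the fit across many seeds use 3000/1500 × 2 chains.  Fixing h
first slightly understates posterior uncertainty relative to a joint
sampler; parental allele frequencies are treated as known.

Outliers: locus i is flagged when its posterior-median α (or β) falls
outside the central 95% interval of Normal(0, τ̂) with τ̂ the posterior
median hyper-SD — the "excess ancestry relative to the learned prior"
rule.  Transects are classified by s = MAD(β)/(MAD(α)+MAD(β)):
β-dominant above 0.6, α-dominant below 0.4, mixed between (thresholds
configurable).

**Known limitation.**  Under this neutral, LD-free, frequency-level
simulator the barrier/expansion contrast in s is weak.  Three structural
reasons, established during validation: (1) drift deviations expressed at
a single intermediate-h level are an unidentifiable mixture of α and β,
so the posterior splits them evenly; (2) by symmetry, the per-locus
asymmetric (α-like) and symmetric (β-like) components of barrier leakage
have equal variance when the two crossing directions drift independently;
(3) β's design weight 2h(1−h)(2h−1) carries less information than α's
2h(1−h), so even null data give MAD(β) ≳ MAD(α).  Real hybrid zones add
ancestry-block structure (LD) that concentrates signal in steepness;
frequency-level simulation cannot.  The bundled barrier scenario therefore
uses a semipermeable river (permeability 0.2, small-Ne contact zone,
transect-weighted sampling), which yields β-leaning scores (s mostly
0.45–0.6) but not a clean separation past the 0.6 label line; the
expansion scenario (refugial surfing, sampled shortly after secondary
contact) sits consistently α-ward of it without crossing the 0.4 line.
The classification experiment is retained and reported as measured.

## Geolocation and dispersal (`dispersal`)

The geolocation estimator is a Prevosti-distance-weighted centroid:
references are all other samples (leave-one-out), weights
exp(−d_P/bandwidth), bandwidth defaulting to half the median pairwise
panel distance (the validation experiments use 0.1× the median, which
concentrates weight on close genetic matches and makes the bootstrap
error track local sampling density).  This deterministic estimator stands
where a neural-network assigner would in a production study; it is weaker
on nonlinear structure and its bootstrap clouds are tighter, so the 10 km
error filter binds less often than it would with a higher-variance
assigner.  Uncertainty comes from 100 bootstrap pseudo-replicates over
panel SNPs (not individuals); the bootstrap-centroid error is the mean
distance of replicate predictions from their centroid, and dispersal is
the sampling-locality-to-centroid distance.  Cohort comparisons use Welch
t-tests of male vs female dispersal within age class.  Prevosti
dissimilarity-to-neighbors profiles (5 km radius; isolated samples
excluded) provide the independent relatedness-decay view.

## Validation experiments (`experiments`)

Reference conditions shared by the test suite and `scripts/acceptance.py`:

- **K=3 recovery/CV**: 12×12 grid, three founder strips, θ=0.2, Ne=100,
  m=0.05, T=30, L=500, N=150; CV over K=1..6, 2 folds, 10 seeds.
- **Cline recovery**: 300 loci × 60 individuals, α*, β* ~ Uniform(−1, 1),
  δ=0.9 panels, 20 000 MCMC iterations × 4 chains; null calibration at
  200 loci with α*=β*=0.
- **Barrier/expansion classification**: scenarios above, 10 seeds each.
- **Edge robustness**: barrier landscape, 150 samples, 10% translocated
  across the river; ridge displacement in cells against the relative drop
  in the Mantel (Pearson) correlation of Prevosti vs geographic distance.
- **Dispersal**: 12×12 quadrant landscape (θ=0.3, Ne=30, T=150), 8×
  denser sampling in the west, 16 independent >12 km transfers, resident
  dispersal 3.5 km (F) vs 7 km (M) ×  lognormal(0, 0.2) noise.

Problem sizes were chosen so the full suite runs on a single desktop CPU.

## Numerical choices

Cluster frequencies clamped to [1e−6, 1−1e−6]; φ and allele probabilities
clamped identically inside likelihoods; kriging systems jitter-and-retry
once on singularity (duplicate points); variogram parameters bounded
non-negative; EM ties in CV broken by the smallest K (argmin); Dirichlet/
binomial draws all flow from one `numpy` Generator per run so every stage
is byte-reproducible under a fixed seed.
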