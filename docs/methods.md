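# Methods

`relictabc` implements the demographic-inference core of a two-refugium
phylogeography analysis: a structured-coalescent simulator, a catalogue of
competing origin scenarios, approximate Bayesian computation (ABC) for
model choice and parameter estimation from multilocus phased sequence
data, the supporting population-genetic summary statistics, substitution-
rate calibration, and climate-niche / isolation-by-environment (IBE)
statistics. A synthetic-data module generates study-shaped inputs with
known truth, so every claim the tests make is checked against a ground
truth or an independent oracle.

## The inference problem

Two refugial regions — a southern/southwestern one (SEA) and a
northeastern one (NEA) — hold 24 sampled populations (12 + 12) of a
long-lived tree, genotyped at 27 unlinked nuclear low-copy loci
(154–944 bp, two phased haplotypes per individual). Competing origin
histories are compared: *split* models, in which one region's population
is founded by an expansion of a fraction of the other's with little or no
change in the origin's size, and *vicariance* models, in which an
ancestral population whose size is the sum of the two daughters' sizes
divides. Options add bidirectional gene flow and post-divergence
bottlenecks, giving a fixed catalogue of 6 split + 9 vicariance
scenarios.

## Coalescent simulator (`coalsim`)

Time is measured in units of 4·N_ref generations (N_ref = 10,000 diploids
by default). With k lineages in a population of relative size x the total
coalescence rate is k(k−1)/x per unit time, so a pair in a size-1
population waits Exponential(2), E[T₂] = 0.5 — this pins the time scale,
and every other rate follows from it. Backward migration moves single
lineages at rate 4·N_ref·m per lineage per unit time. Demographic events
(merges, instantaneous size changes, migration-matrix changes) apply at
scheduled times; a guard raises an error if lineages are stranded in
isolated populations with no future event to rescue them.

Mutations follow the infinite-sites model: Poisson with mean θ_locus ×
(total branch length in 4N units) — equivalently θ/2 per unit of 2N
generations, the textbook convention — so E[S] = θ for a sampled pair and
E[S] = θ·a_{n−1} (Watterson) in general. Loci are unlinked with no
intra-locus recombination; haplotypes are paired arbitrarily into
diploids since every statistic used is haplotype-based. A fixed per-locus
substream scheme ([seed, locus_index]) keeps earlier loci bit-identical
when loci are added.

Unit conversions live in `calibrate`: the nuclear substitution rate is
derived from a fossil-calibrated chloroplast rate via an exact integer
cpDNA:nDNA ratio (3:16), with the published point estimate and HPD bounds
emerging from rounding only at presentation; per-locus mutation
parameters use u = µ·k·g with generation time g = 15 y by default; times
convert between coalescent units and ka linearly and exactly.

## Scenario grammar and priors (`scenarios`)

A split scenario compiled backward in time: the derived population merges
into the origin at T; the ancestral size equals the origin's size at
divergence ("minimal or no change", exact equality by default). The
founder fraction f sets the derived population's size to f·N_anc during a
founding phase [T_found, T]. Under instantaneous size changes a size
change of zero duration cannot affect genealogies, so scenarios without a
derived-side bottleneck record f but it is inert — a deliberate,
documented consequence of the instantaneous-change model. Vicariance
scenarios set N_anc to the sum of the two sizes at divergence (bottleneck
sizes when bottlenecked, present sizes otherwise).

Default priors bracket the study's reported estimates: sizes log-uniform
on [10², 10⁵] diploids, divergence time uniform on [50, 1500] ka,
bottleneck times uniform on [10, 1500] ka constrained below T by
rejection, Nm log-uniform on [10⁻³, 10], f uniform on [0.01, 1]. All
priors are overridable and serialized with the catalogue.

## Summary statistics (`sumstats`)

Per locus: nucleotide diversity π (mean pairwise difference per site,
pairwise deletion of N/−), haplotype diversity H_d = n(1−Σp²)/(n−1),
segregating sites S, Watterson's θ per site, Tajima's D (1989 constants),
Fu's F_S, and the Ewens–Watterson homozygosity test. Fu's F_S uses the
Ewens sampling formula with unsigned Stirling numbers of the first kind
computed by a log-space recurrence, with θ̂_π on the per-locus (not
per-site) scale; the tail probability S′ = P(K ≥ k_obs) gives
F_S = ln(S′/(1−S′)), clamped at ±700 when S′ is numerically 0 or 1. The
Ewens–Watterson null is sampled by the Chinese-restaurant construction
with θ tuned so E[K] = k_obs and draws retained when K = k_obs; the
p-value is two-sided. Allelic richness uses hypergeometric rarefaction,
A_R = Σ[1 − C(N−N_i, g)/C(N, g)], exact by construction (integer
binomials); the default depth g is the smallest gene-copy count among the
groups compared.

Differentiation uses a Hudson-type multilocus F_ST = 1 − ΣH_w/ΣH_b
(ratio of sums across loci), H_b the mean between-group pairwise
difference count and H_w the *plug-in* within-group mean (ordered pairs
including self, divided by n²), averaged over the two groups. The plug-in
form makes F_ST exactly 0 when the two groups carry identical haplotype
multisets and keeps it in [0, 1] on nested samples, at the cost of a
≈ +1/n offset under panmixia — negligible at the study's 90 haplotypes
per region, ~0.06 at the 16-haplotype ABC scale, and identical on the
observed and simulated sides of the ABC distance, so model comparison is
unaffected. A permutation test (haplotypes shuffled between groups)
provides p-values.

The ABC feature vector is fixed-order and named: per region and pooled,
mean and variance over loci of {π, S, H_d, Tajima's D} plus the fraction
of loci where D is undefined (undefined values are imputed as 0 with that
paired indicator, never dropped); then private segregating-site counts
per region and the pooled between-region F_ST. A fast path computes the
identical vector directly from 0/1 derived-allele matrices; a test pins
the two paths to each other.

## ABC (`abc`)

Reference tables pair prior draws with simulated feature vectors,
per-row seeds derived from (master seed, row index) so tables are
identical for any worker count. Model choice pools tables, standardizes
features by the pooled median absolute deviation (zero-MAD features
dropped with a record), and accepts exactly floor(tolerance × pooled N)
nearest rows by Euclidean distance. Posterior model probabilities come
from the accepted-row shares (rejection) or an L2-regularized multinomial
logistic regression evaluated at the observed vector (mnlogistic), with a
fall-back to the rejection shares on failure.

Parameter estimation adjusts the winning model's accepted draws by
weighted local-linear regression (Epanechnikov weights in distance;
ridge-stabilized normal equations), on log scale for sizes/rates/times
and logit scale for parameters with bounded uniform priors, then
back-transforms; a single-hidden-layer network adjustment is available as
an option. Point estimates are weighted medians; intervals are 95%
highest-posterior-density (HPD) intervals computed by a sliding window
over the weighted empirical CDF (shortest window holding the target
mass). At the desk scales used in the tests, a 12,000-row table with
tolerance 0.025 (300 accepted rows) gives well-behaved adjustments;
much smaller tables make local-linear adjustment overconfident, which is
the known small-reference-table regime of ABC.

## Niche and IBE statistics (`ibe_niche`)

PCA is correlation-based (the 19 climate variables mix °C and mm);
constant variables are dropped with a warning and each loading vector is
signed so its largest-magnitude element is positive. Geographic distance
is haversine (R = 6371 km) log-transformed as ln(d + 1 km). Mantel and
partial Mantel statistics correlate distance-matrix triangles, permuting
the genetic matrix's rows/columns jointly, one-tailed for positive IBE by
default (two-tailed by flag); the partial statistic is the first-order
partial correlation recomputed per permutation. An F_ST/(1−F_ST)
linearization helper is provided.

Niche overlap on co-registered suitability rasters (ESRI ASCII grid I/O,
nodata honored, no silent resampling): suitabilities normalize to sum 1
over shared cells; Schoener's D = 1 − ½Σ|p−q| and Hellinger-based
I = 1 − ½Σ(√p−√q)². The background test fits a pluggable fit/predict
suitability model to each region's occurrence climates, compares the
observed overlap to overlaps against models fitted to random
background-buffer points (0.5°-style disks around occurrences, degree
space), and reports two-tailed p-values from the null ranks. Background
points are drawn with replacement (random points may repeat cells);
without-replacement draws from a pool no larger than the occurrence
sample degenerate to a point null. The default model is a Mahalanobis
climate envelope, suitability = exp(−½·d²), with the covariance shrunk
50/50 toward a scaled identity: occurrence samples are routinely no
larger than the variable count, where the raw covariance is singular and
the test's null badly miscalibrated. With these defaults the measured
type-I error at α = 0.05 is ≈ 0.05–0.06 over 200 null worlds.

## Synthetic worlds (`synthetic_data`)

The sequence world emulates the study design: 24 populations (12 + 12)
with 2–6 diploids each (90 individuals, the study's per-population
counts), 27 loci of 154–944 bp with θ from the calibrated nuclear rate,
and a flagship vicariance history — divergence 583 ka, post-divergence
bottlenecks around 91/109 ka, present sizes 32,000 (SEA) and
N_SEA/asymmetry (NEA; 16,000 at the default 2:1 θ asymmetry). Bottleneck
sizes scale as N_SEA_b = 8,000 and N_NEA_b = N_SEA_b/asymmetry²
(= 2,000, the severe shrinkage scale reported for the system). The NEA
side matches the reported ~2,000; the SEA bottleneck is milder by design:
a forward pair-coalescence calculation shows that equally severe
bottlenecks in both regions would erase the ~2:1 regional diversity
asymmetry the generator must reproduce, because the post-bottleneck epoch
(~100 ka ≈ 6,700 generations) contributes symmetrically to within-region
diversity. With these defaults the simulated worlds show SEA/NEA π ratios
near 2 and inter-region F_ST ≈ 0.72–0.78.

Within regions the simulated demes are panmictic; population labels are
sampling structure only. Real data add within-region substructure,
selection, sequencing error and phase uncertainty — passing tests
therefore validate the estimators and the inference machinery under the
stated model, not robustness to those violations.

The climate world draws 19 variables from a two-factor latent model (a
precipitation-like block and a temperature-like block of loadings) with
region-dependent factor shifts (default 2 SD per factor), over occurrence
points (default 65 SEA + 35 NEA) and a lat/lon grid. The background grid
expresses only a fraction (default 0.5) of the occurrence-level shift, so
occupied niches diverge beyond availability; at fraction 1 the background
test correctly finds nothing beyond availability, at fraction 0 its power
against 2-SD shifts is near 1. Spatial autocorrelation of real climate
rasters is not emulated. All generators are seed-deterministic and write
their truth (parameters, loadings, per-occurrence latent factors) next to
the data.

## Problem sizes and numerical choices

Stochastic checks run at desk scale: coalescent closed forms at 20,000
replicates (3-standard-error bands); ABC model recovery with 1,500
simulations per model × 3 candidate models, 8 loci, 8+8 haplotypes;
parameter recovery with a 12,000-row table, tolerance 0.025, 20
pseudo-observed replicates; Mantel calibration over 400 null datasets ×
299 permutations; background-test calibration over 200 null worlds × 99
replicates. Ties in permutation p-values are counted in the rejection
region ((1 + count)/(1 + n_perm)). Degenerate inputs are errors, not
NaNs: fewer than two haplotypes, unequal alignment lengths, rarefaction
depth exceeding gene copies, non-co-registered rasters, zero-variance
distance triangles.

## Known limitations

- No recombination, gene conversion, selection or sequencing error in the
  generative model; phase is treated as known.
- The plug-in F_ST's +1/n offset (documented above) matters for very
  small groups compared in isolation.
- The founder fraction is inert in split scenarios without a derived-side
  bottleneck (instantaneous-change model).
- Exact per-scenario prior choices of the original 6/9 catalogue are not
  recoverable from the study's main text; the grammar covers the option
  space and the ids document the reconstruction.
- Region-level rarefied allelic richness depends on the rarefaction
  convention; region- and population-level values are not comparable
  across conventions and no attempt is made to match both simultaneously.
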