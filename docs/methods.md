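# Methods

## The estimation problem

For a sessile organism continuously distributed in two dimensions, limited
dispersal produces isolation by distance (IbD): genetic distance between
individuals grows — equivalently, kinship decays — linearly with the
logarithm of geographic distance. The slope of that relationship is set by
Wright's genetic neighbourhood size,

    NS = 4 π D σ²,

where D is the density of (genetically distinct) individuals per m² and σ²
is the mean squared *axial* parent–offspring displacement per generation.
Given an IbD slope and an independent density estimate, σ follows as
`sqrt(NS / (4 π D))`. Under a Gaussian dispersal kernel, σ equals 1.25 ×
the mean Euclidean parent–offspring distance; σ says nothing about the
kernel's tail shape.

Two pairwise statistics are supported, combined across loci as ratios of
sums (numerators and denominators summed separately, then divided — the
Weir–Cockerham convention):

* **Rousset's â** (genetic distance, from identity-in-state probabilities):
  slope b > 0 under IbD; NS = 1/b. The within-individual identity Q̂_w is
  estimated sample-wide rather than per pair — the lower-variance plug-in;
  exact numerical parity with GENEPOP is not promised, and a per-pair
  variant is not implemented.
* **Loiselle's F** (kinship from allele-frequency deviation products with a
  finite-sample correction): slope b < 0 under IbD; NS = (1 − F(1))/(−b),
  where F(1) is mean kinship among neighbouring pairs (default radius: the
  current σ estimate; first iteration uses the 5% distance quantile). The
  alternative literal reading NS = 1/(−b(1 − F(1))) is exposed behind a
  flag but is not the default: the standard Sp-statistic form is the
  literature-consistent one and matches the published worked examples
  (e.g. sqrt(94/(4π·0.33)) = 4.76 against a printed resampling median of
  4.77). Loiselle's F is robust to inbreeding and is auto-selected when any
  location shows jackknife-supported F_IS > 0.

Both metrics are computed only between genet representatives and only for
within-location pairs; distances are 2D Euclidean after per-plot
flattening (best-fit plane by SVD, normal component dropped, plot
centroids kept in the common frame) with a 0.01 m floor for coincident
colonies.

## Confidence intervals

Pairs share individuals, so pair-level OLS standard errors are invalid.
All slope uncertainty comes from resampling loci:

* percentile bootstrap over loci (default 1000 draws, multinomial locus
  weights, pair values rebuilt by ratio of sums, regression refit), or
* delete-one-locus jackknife, SE = sqrt(((L−1)/L) Σ (b₍₋ₗ₎ − b̄)²).

A slope is significant when the 95% interval excludes zero. A coverage
caveat, demonstrated by the validation suite: locus resampling conditions
on the realized spatial genealogy. On forward-simulated data the interval
is well calibrated for locus-sampling noise (~95% coverage when loci are
the only noise source) but under-covers the theoretical Wright–Malécot
slope across replicate populations (~60% at neighbourhood sizes of 4–380),
because between-replicate variance in the realized pedigree and local
density is invisible to locus resampling. Published analyses built on
locus-resampling CIs share this property.

## Iterative spatial-scale adjustment

IbD slopes reflect recent dispersal only within the drift–migration
equilibrium range, roughly σ to 10σ–50σ. `iterate_sigma` therefore loops:
fit over the current window (initially the full within-location range),
convert to σ, reset the window to [σ, k·σ] (k default 20, allowed 10–50),
and refit, until σ changes by < 5% (relative) or 20 iterations. The full
window/slope/σ history is recorded. A wrong-sign slope or a window with
fewer than 3 pairs stops the loop with a "scale-unresolved" flag rather
than a number. Density re-expression at the neighbourhood area 4πσ² is
supported through an optional callable density source; with a fixed
density estimate no re-expression occurs.

## Densities

* **Census density D_c**: genets per m² from per-plot genet counts; the
  central value pools plots, and the interval is the min–max of per-plot
  densities (each plot is one census estimate).
* **Effective density D_e**: an externally supplied N_e (e.g. a sibship
  estimate with its CI) divided by the sampled area. N_e inference itself
  is out of scope.

## Monte-Carlo σ distributions

Uncertainty in NS and D is propagated by 2000 paired draws (the published
convention) of σ = sqrt(NS/(4πD)). NS draws come preferentially from the
locus-bootstrap slope draws (keeping the slope→NS dependence exact); when
only printed central values and 95% CIs are available, NS and D are drawn
from a **two-piece lognormal**: exp(μ + s_lo·Z) for Z < 0 and
exp(μ + s_hi·Z) for Z ≥ 0, with μ = ln(median) and s_lo, s_hi matched to
the CI endpoints. This family was chosen for positivity and strongly
asymmetric printed intervals (e.g. NS 35 with CI 4–2309); it preserves the
median exactly and matches both endpoints. NS and D draws are independent
(no joint structure is available). Census densities can alternatively be
resampled directly from per-plot values. Draws with a slope inconsistent
with IbD give a non-finite σ; these are truncated at zero and counted, and
more than 50% of them flags the slope as indistinguishable from zero. The
summary is the median and the 5th–95th percentile interval of finite
draws.

## Clone detection

The pairwise metric is the shared-allele (Prevosti-type) distance on
dosages: one minus the mean over co-typed loci of 1 − |dᵢ − dⱼ|/2 —
robust to missingness and standard in clone calling. Technical replicates
(repeat samples of one colony) bound the genotyping-error scale. The
calibrated threshold uses a walk-up gap rule: the low mode is the
replicate distances plus any non-replicate distances at or below the
replicate maximum (presumptive clones — true clone pairs are
statistically indistinguishable from replicate pairs); candidates above
are absorbed while each step stays within the low mode's spread (floored
at half the replicate maximum and at 0.01); the threshold is the midpoint
of the first larger gap. If the walk absorbs the entire distribution the
error scale grades into unrelated pairs and the threshold falls back to
the 95th percentile of replicate distances with a warning. Pairs with
fewer than 20% co-typed loci are excluded from calibration as unstable.

Genets are single-linkage connected components at the threshold (somatic
mutation chains argue for single linkage); replicates are always
co-grouped. One representative per genet — lowest missingness, ties by id
order — enters all downstream analyses. Clonal spatial structure is
summarised by within-genet colony-pair distances (median, fraction ≤ 1 m).

## Genotype filtering

Cascade order: individuals above the missingness cap (default 50%) first,
then loci by minor-allele count (default ≥ 3) and per-locus missingness.
Depth filters (minimum depth, maximum depth as a multiple of the mean)
apply at VCF read time when FORMAT/DP is present and are skipped with a
log line otherwise. Physical linkage is removed by keeping one SNP per RAD
contig, chosen uniformly under a fixed seed. Filtering is idempotent on
realistic data; a pathological table could in principle lose additional
individuals on a second pass because locus removal changes individual
missing fractions.

## The forward simulator

A constant-size population of N diploids evolves in a w × h m arena with
reflecting boundaries for G non-overlapping generations; the defaults
describe a ~100 × 100 m reef patch at 0.2 genets/m², metre-scale
dispersal, 500 unlinked biallelic SNPs and 50 generations.

* **Gene dispersal calibration.** Offspring are placed at the mother plus
  isotropic Gaussian noise of axial SD σ_g; fathers are sampled among
  adults with Gaussian kernel weights exp(−r²/(2·mating_radius²)). A
  maternal gene moves with variance σ_g²; a paternal gene moves with
  σ_g² + mating_radius² (axially), so the pooled axial gene-dispersal
  variance is σ_g² + (1 − s)·mating_radius²/2 with selfing rate s. σ_g is
  solved so this equals σ_true² exactly. The default mating_radius is
  σ_true/2, keeping the kernel share of dispersal variance at 1/8: mates
  are discrete neighbours, and a large kernel share lets sparse local
  configurations distort the realized calibration. The truth record keeps
  all offspring-to-parent displacements; their pooled axial SD matches
  σ_true within a few percent (reflecting boundaries compress edge
  displacements slightly, ~7% at σ = 10 m in an 82 m arena — an
  acknowledged edge effect).
* **Selfing** with probability s raises F_IS toward the equilibrium
  s/(2 − s) (verified across a selfing grid up to 0.9, mirroring heavily
  inbred taxa).
* **Clonality as fission.** With the configured rate a parent is replaced
  by two fragments of identical genotype: one at the parent position, one
  displaced by Gaussian noise (default SD 0.4 m). A clone dyad is thus one
  Rayleigh(sd) displacement apart, reproducing the observed "most clones
  under 1 m" regime; repeated fission produces longer within-genet chains.
* **Genetics.** Founder allele frequencies are Beta-distributed (default
  uniform); loci are unlinked, mutation-free (drift dominates at these
  timescales), and transmitted by Mendelian segregation. Allele-frequency
  expectations are conserved across generations (drift only).
* **Observation layer.** Rectangular 25 × 4 m survey plots are sampled
  exhaustively; genotyping noise flips each allele call independently
  (default checks use 0.5–1%), masks entries at the missingness rate, and
  appends technical-replicate samples (independent noisy re-observations
  of a colony sharing its coordinates and replicate label).

What the simulator does not emulate: overlapping generations and age
structure, larval transport by currents, selection, linked loci, depth
stratification, and spatially heterogeneous habitat. Passing recovery
tests therefore demonstrate estimator correctness under the model's own
assumptions, not robustness to these real-data features.

## Validation problem sizes

The heaviest check simulates N = 2000, L = 500, G = 50 at density
0.3 m⁻² for σ_true ∈ {1, 3, 10} m, 7 replicates each, sampling eight
25 × 4 m plots grouped into two locations (mirroring multi-plot,
multi-location survey designs); the full pipeline recovers σ within a
factor of two in ≥ 80% of replicates. Null calibration uses 200 panmictic
replicates (n = 60, L = 200); clone-threshold calibration uses 40 runs at
1% allele error and 500 loci. Published-table reproduction feeds printed
NS and density values through the Monte-Carlo machinery at 2000 draws and
recovers the printed medians within ±10% (typically ±5%).

## Known limitations

* The locus-resampling CI under-covers across replicate populations (see
  above); treat slope CIs as genotyping uncertainty, not total
  uncertainty.
* The two-piece lognormal is a stated stand-in for whatever distribution
  family produced a given published interval.
* Very small neighbourhoods (NS ≲ 10) push the Wright–Malécot
  approximation; σ point estimates remain usable (factor-2 accuracy) but
  slope-level theory comparisons degrade.
* Plot flattening assumes each plot is approximately planar; strongly
  curved substrate would need the supplementary 3D treatment upstream.
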