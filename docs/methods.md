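# Methods

## The empirical distribution of singletons

For a sample of `n` chromosomes typed at biallelic loci with known ancestral
state, a *singleton* is a derived allele carried by exactly one chromosome.
Let `xi1_i` be the number of singletons carried by chromosome `i` and
`xi1 = sum_i xi1_i` their total. The empirical distribution of singletons is

    p_hat_i = xi1_i / xi1,   i = 1..n,

each chromosome's share of the sample's singleton variation. Under the
coalescent, conditional on the locus genealogy, a singleton falls on
chromosome `i` with probability `tau_i / tau1`, the ratio of its external
branch length to the total external branch length; hence

    p_i = E[tau_i / tau1],   E[p_hat_i] = p_i,   E[xi1_i] ~= theta * p_i.

The estimator is unbiased regardless of demography, Hardy-Weinberg deviation
or linkage, which is what makes it usable as an *individual-level* (rather
than population-level) measure of genetic diversity. In a panmictic
constant-size population `p_i = 1/n`, `E[tau1] = 2` (coalescent units) and
`E[xi1] = theta`.

Caveats implemented as documented behaviour rather than corrections:

* **Missing data.** Singleton status is judged among non-missing calls only;
  loci with fewer than two calls are skipped (and counted). Missingness can
  promote higher-frequency alleles to apparent singletons, which is why the
  ABC pipeline imposes the observed missingness on simulated data rather
  than ignoring it.
* **Folded spectra.** When the ancestral state is unknown (`folded=True`)
  the minor allele plays the role of the derived allele. This is a known
  bias source; the default follows the polarized theory.
* **Related individuals** share rare variation and should be removed before
  analysis; the package does not attempt kinship filtering.

### Units and the mutation clock

Branch lengths are measured in coalescent units in which the waiting time
for `k` lineages is exponential with rate `k(k-1)/2`, so `E[tau1] = 2` for
any `n`. Mutations fall on a branch of length `tau` as Poisson with mean
`theta * tau / 2`, giving `E[xi1] = theta` in the neutral model with
`theta = 2 N mu`. Times supplied in generations (split times, expansion
onsets) are converted at the configuration boundary by dividing by `2 N1`.

One deliberate exception: the split-model *study* interprets its per-locus
theta, drawn uniformly on (5, 10), as the Watterson-style `4 N mu`
parameter of standard coalescent simulators and therefore doubles it on the
package's clock (`SplitModelParams.watterson_theta`, default True). This
reading yields ~28k polymorphic sites and ~12k singletons per 1,000 loci in
our runs, the regime the study design targets, while the `2 N mu` reading
produces roughly half as many sites. Setting the flag to False restores the
plain clock.

## The split model

Two populations of haploid size `N1 = 50,000` and `N2 = s * N1`
(`s` in (0.01, 0.5), the shrink rate) diverged `t` generations ago
(`t` uniform on (1,000; 10,000)). Population 1 grew exponentially from an
ancestral size `NA = 5,000` starting 10,000 generations ago (backward: size
`exp(-beta * tau)` relative to `N1` with `beta = ln(N1/NA) / 0.1` per
coalescent unit, constant `NA` deeper); population 2 is constant at `s * N1`
until its lineages join population 1 at the split. There is no migration.
Samples are 50 + 50 chromosomes, `L = 1,000` unlinked infinite-sites loci.
The event-driven simulator inverts the integrated coalescent intensity in
closed form during the growth phase; `replicate_split_study` redraws
`(theta, t)` each replicate by default (the replication design is ambiguous;
a fixed-parameter mode is provided).

The simulator is cross-checked against msprime on the identical scenario
(mean segregating sites and singleton counts within 3 Monte-Carlo SE) and
collapses to the neutral Kingman coalescent in the degenerate limit
(`s -> 1`, `t -> 0`, `NA = N1`), verified distributionally.

With `s = 0.33` the expanding population carries visibly more singleton
share per chromosome than the shrunken one (`pi_1 ~ 0.0128` vs.
`pi_2 ~ 0.0072` per chromosome, ratio ~1.77 in our runs); the ratio grows
past 10 when `s <= 0.10` and is insensitive to the split time over its
range.

## Range expansions

A two-phase demic simulator:

* **Forward (deterministic).** A lattice of demes with carrying capacities
  `C` (0 = sea). The origin deme is seeded with the ancestral size; each
  generation every deme grows logistically (`N += r N (1 - N/C)`) and a
  fraction `m` of the grown deme emigrates, split equally among habitable
  von Neumann neighbours. Densities and directed migrant counts are
  recorded every generation. Determinism here confines all randomness to
  the genetic phase, making histories reproducible and cheap.
* **Backward (stochastic).** Per locus independently, lineages trace the
  recorded history: the backward migration probability from deme `j` to
  neighbour `i` is proportional to the recorded forward migrants `i -> j`
  that generation; two lineages in a deme of recorded size `N` coalesce
  with probability `1/N` per generation (multiple mergers resolved
  sequentially). Lineages surviving to the start of the history coalesce in
  a panmictic ancestral population of the ancestral size (geometric waiting
  times). Mutations are Poisson per branch at the per-locus per-generation
  rate; loci are unlinked.

Default parameters of the continental scenarios: 87 x 83 grid, `m = 0.07`,
`r = 0.1`, 1,600 generations, ancestral size 200, mutation rate 1e-5 per
locus per generation, 30,000 loci. Carrying-capacity schemes: homogeneous
(C = 100 on land), vegetation (60 semi-desert / 30 extreme desert and rain
forest / 100 otherwise), and the ABC variant (100 / 20 / 10). The packaged
Africa-like raster is a *stylized* coastline polygon with latitude-band
vegetation classes, generated programmatically - it reproduces the grid
dimensions and the qualitative geography, not any particular digitized map.
The pre-expansion lag is genetically inert under a constant ancestral size
and is retained only as an interface-level nuisance parameter.

Sampling designs: population mode (10 haploids at each of 30 quasi-uniform
occupied sites, chosen by k-means over the occupied region) and individual
mode (single chromosomes at sites jittered from population centres with
Gaussian SD 2 degrees and snapped to the nearest occupied cell). The
placement of sites is our choice; the originals are unpublished.

What the demo-scale tests show: on a 20 x 20 grid the expansion leaves the
expected diversity gradient (per-site mean `p_hat` and expected
heterozygosity both decline with distance from the origin, Spearman p <
0.01) and the singleton-based and heterozygosity-based kriged surfaces are
positively correlated. Full-grid magnitudes (e.g. published map
correlations) are only expected at the 87 x 83 / 30,000-locus scale.

## Kriging

Ordinary kriging with an exponential variogram
`gamma(h) = nugget + sill (1 - exp(-h/range))` fitted to the binned
empirical semivariogram by least squares weighted by bin pair counts.
Distances are great-circle (km) above 5-degree extents, Euclidean below
(overridable). Duplicate points are averaged; with zero nugget the
predictor interpolates exactly; weights sum to one by the unbiasedness
constraint. Default surface resolution 1 degree; the mask comes from the
habitat raster. These are our choices - the underlying study names only
"kriging".

## ABC origin inference

Summary statistic: chromosomes are k-means-clustered on their coordinates
(k user-set; `choose_k` finds the largest k whose smallest cluster meets a
size floor); the statistic is, per group, the mean singleton count of a
group member divided by the total singleton count. It is invariant to
relabelling within groups and, for equal group sizes, sums to `k/n`.

Prior: origin uniform on the lon/lat box (-16..40 E, 5..30 N by default)
with a triangular down-weighting over the outer 20% of each coordinate
range and zero mass on uninhabitable cells (rejection sampling); nuisance
parameters (migration rate 0.01-0.2, growth rate 0.05-0.5, duration
500-3,000, ancestral size 50-1,000, lag 50-500) uniform. The nuisance
ranges are package defaults standing in for unpublished values and are all
exposed in configuration.

Estimation: statistics are standardized by table-wide median absolute
deviation; the `tolerance` fraction nearest in Euclidean distance is
accepted with Epanechnikov weights. Adjustments: none (rejection),
local-linear (Beaumont-style weighted regression, the deterministic
default), or an ensemble of single-hidden-layer feed-forward regressions
(default 250 members) mirroring the neural-network family; the ensemble's
internals are our choice. The joint origin posterior is a weighted 2D
Gaussian KDE on a 100 x 100 grid, zeroed outside the prior support and on
water, then renormalized; point estimates are the grid mode and weighted
means; intervals are equal-tailed by default with an HPD option.

Desk-scale behaviour (20 x 20 grid, 300-row table, 250 loci, 20 test data
sets): posterior-mean origins correlate with the truth at R^2 ~ 0.6-0.8 per
coordinate, degrade sharply with a 100-row table, and never leave the prior
support. Accuracy keeps improving with table size; high-precision recovery
needs reference tables of tens of thousands of rows, which is cluster-scale
computation and not attempted in the test suite.

## Numerical and design notes

* All randomness flows from `numpy.random.Generator`s threaded explicitly;
  reference-table rows record their spawned seeds, making builds resumable
  and reproducible.
* Ties and degenerate inputs: zero-singleton profiles are flagged undefined
  (never silently zero); trees with zero external length are excluded from
  theoretical distributions with a warning; duplicate kriging points are
  averaged; empty-deme lineage strandings raise with generation and cell.
* The heterozygosity estimator uses the small-sample correction
  `2 p (1-p) k/(k-1)` with `k` non-missing calls; the uncorrected version
  is a biased alternative the package does not expose.
* Genotype containers are int8 matrices with -1 for missing ("9" in .geno
  files); loci are rows in .geno by convention here, with a transpose flag.

## Limitations

* The expansion simulator omits long-distance dispersal, density-dependent
  migration, two-layer (wild/cultivated) dynamics, within-locus
  recombination and selection; equivalence with full-featured spatial
  simulators is claimed only at the level of the summary statistics tested.
* The synthetic Africa-like raster and accession coordinates are stylized
  stand-ins; analyses of real data should supply real rasters (ESRI ASCII)
  and coordinates (CSV).
* Passing desk-scale tests demonstrates the mechanisms (gradients,
  identifiability, calibration) at small problem sizes, not the published
  full-scale magnitudes.
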