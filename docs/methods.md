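# Methods

`picopop` estimates the genomic differentiation of a single planktonic
species from per-station metagenomic allele counts and attributes it to
geographic, environmental or oceanographic separation.  This note documents
the statistical model at each stage, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the
numerical conventions.

## Input model

The unit of observation is a *cell*: one biallelic SNP at one sampling
station, carrying a reference and an alternate read count pooled over all
individuals in the sample (pool-seq-like).  Zero coverage is an absent
observation, never frequency zero.  Multi-allelic variant records are
reduced to biallelic by keeping the alternate allele with the largest total
read support across stations; indels are dropped.

## Coverage filter

Metagenomic read recruitment produces two characteristic artefacts: spurious
low-support calls and sites whose coverage is far above the sample mean
because reads of closely related taxa are recruited.  Both are handled by a
per-station window on vertical coverage c:

    keep cell  iff  min_cov <= c < mu + s * sigma   (and alt reads >= min_alt)

with `min_cov = 4`, `s = 2`, and mu, sigma the mean and sample (n-1)
standard deviation of coverage over that station's covered SNPs
(coverage >= 1).  The window is computed per station because mean coverage
varies by more than two orders of magnitude between samples; a global window
would remove whole stations rather than artefact sites.  The upper bound is
strict, so a station whose SNPs all share one coverage value retains
nothing — a degenerate input the filter reports rather than hides.  A
station with fewer than two covered SNPs has no defined sigma; only the
lower bound applies there and a warning is logged.  `min_alt = 1` encodes
that a variant call requires at least one variant-supporting read; both the
support mode (total vs alternate reads) and `min_alt` are configurable
because pooled tables from different callers differ in this convention.

## Pairwise FST

For one SNP and one pair of stations with alternate-allele frequencies
p1, p2 and pbar = (p1 + p2)/2:

    H_T = 2 pbar (1 - pbar),  H_S = p1(1 - p1) + p2(1 - p2),
    FST = (H_T - H_S) / H_T.

The mean frequency is taken over the two stations of the pair only.  In
sparse data each pair shares a different SNP subset, so a grand mean across
all stations would mix information across incomparable site sets.  SNPs
fixed for the same allele in both stations (H_T = 0) are uninformative and
excluded.  The pair's genomic distance is the **median** per-SNP FST over
shared SNPs (robust to the long right tail of the per-SNP FST distribution
at low coverage); a pair sharing no SNP gets a missing entry.  The global
FST is the mean of non-missing pairwise entries.  No finite-sample
(Weir–Cockerham-style) correction is applied; the estimator is the plain
two-population Wright form, and read sampling therefore inflates it at low
coverage — the suite asserts that this inflation shrinks monotonically as
coverage grows.  An important consequence, visible in the acceptance
output, is that the median-of-ratios statistic under a Balding–Nichols
truth with F = 0.15 sits well below 0.15: the two-sample between-station
variance is an F/2-scale quantity and the median lies below the mean.  The
estimator is validated against an independently coded simulation oracle,
not against the nominal F.

Differentiation classes follow the conventional bins: < 0.05 little,
[0.05, 0.15] moderate, (0.15, 0.25] high, > 0.25 very high.

Station dendrograms use complete-linkage agglomeration on the pairwise
matrix with missing entries replaced by the mean of the non-missing ones.
Imputation exists **only** for clustering and heatmaps; the regression
stage always drops missing pairs instead.

## Distance layers

**Geographic.**  Stations snap to the nearest sea cell of a land/sea raster
(within a configurable radius, default 300 km); the distance is the
shortest path on the 8-connected sea-cell graph with haversine edge weights
(spherical Earth, R = 6371 km), so routes never cross land.  8-connectivity
overestimates true geodesics by at most ~8% (the lattice metric constant);
grid resolution is the accuracy knob.

**Environmental.**  PCA of the standardized (optionally log1p-normalized)
environmental variables; axes whose eigenvalue strictly exceeds the mean
eigenvalue are retained (Kaiser–Guttman; the mean is 1 for correlation
PCA), and the distance is Euclidean over the retained-axis scores.  Scores
already scale with the square root of their eigenvalue, so no further
weighting is applied by default; a `varfrac` flag multiplies axes by their
variance fraction for users who want minor axes attenuated further.  If no
axis exceeds the mean (an exactly degenerate spectrum), the function
refuses and asks for an explicit axis count.  Eigenvector signs are fixed
by making each axis' largest-magnitude loading positive.

**Oceanographic.**  Two directed Lagrangian products are accepted: the
probability of connection (PC) per dispersal horizon (3, 6, 12 months) and
the mean connection time (MCT, days).  PC is averaged over horizons per
direction — the average integrates seasonal to annual circulation — and
then symmetrized by the maximum of the two directions; MCT by the minimum.
Taking the easier directed route as the pair's effective separation matches
how asymmetric advection limits gene flow.  MCT is treated strictly as a
time in days.

## Driver regression

Normalized genomic distances y = FST/(1 - FST) (the standard linearization
for regression on distance) are modelled by OLS:

    y = b0 + b_geo x_geo + b_env x_env + b_pc x_pc + b_mct x_mct + e.

All 2^4 covariate subsets are fitted exhaustively (intercept always
included) and the model minimizing

    BIC = n ln(RSS/n) + k ln(n)

is selected, k counting all coefficients including the intercept; ties
resolve to the smaller model.  The selected model is compared with the
intercept-only null by an F test and coefficients are screened by two-sided
t tests at 0.05.  Pairs sharing a station are not independent, so these
p-values are anti-conservative; a Mantel-style permutation p-value
(stations permuted jointly on both axes of the response matrix) is
available as a cross-check but is deliberately not the headline output,
because the primary contract is the plain linear-model analysis.
Rank-deficient designs drop the collinear term with a warning.  RSS is
floored at 1e-300 inside the logarithm to keep exact fits finite.

## Synthetic-data generator

The generator produces a complete study with known truth: a rectangular
basin (optionally split by a meridional land ridge with a southern strait
into two sub-basins), stations on distinct sea cells numbered west to east,
nine correlated environmental variables (temperature, salinity, five
nutrients, oxygen, chlorophyll-a) driven by an east-west
warm/oligotrophic gradient plus two latent water-mass factors, directed PC
matrices decaying exponentially with over-sea distance with multiplicative
lognormal asymmetry, and MCT growing linearly with distance at a nominal
5 km/day with lognormal noise.

Frequency scenarios (ancestral p ~ U(0.05, 0.95) per SNP):

* **island** — Balding–Nichols: station frequencies are
  Beta(p(1-F)/F, (1-p)(1-F)/F), i.e. mean p and variance F p(1-p).  Chosen
  because the closed-form variance permits moment tests and an independent
  simulation oracle.
* **ibd** — logit frequencies follow a Gaussian process over stations with
  covariance sigma^2 exp(-d_sea/L), default sigma = 1.2, L = 2000 km
  (roughly linear decay across a ~3600 km basin).  A GP was preferred to an
  explicit coalescent because it gives direct control of the decay length
  at negligible cost.
* **ibe** — logit(p_s) = logit(p) + beta_env e1_s + noise, with e1 the
  station score on the dominant environmental axis (default) or a named
  variable, beta_env = 1.2 and per-cell logit noise 0.35.
* **null** — all stations share p.

The ibd and ibe scenarios add a station-level drift term: a constant logit
offset per station, N(0, tau^2), shared by all SNPs.  It represents
baseline differentiation from unmeasured drivers and sets how much of the
pair-to-pair variance the focal driver explains.  The presets use tau = 1.0
(ibe) and 0.4 (ibd), sized once so that the selected model explains a
minority share of the variance (around 15–25% for ibe) — the regime the
method is meant for, where the driver is real but most differentiation is
unexplained — while remaining recoverable in a large majority of
replicates at the default design (13 stations, 3000 SNPs, 10x coverage).
Connectivity noise (lognormal sigma 0.8 on PC, 0.7 on MCT) keeps the
Lagrangian layers honest proxies rather than deterministic functions of
distance; without it PC/MCT are exact monotone transforms of the
geographic layer and no subset selection could distinguish them.

Read counts are Poisson (or negative-binomial with variance
mean + mean^2/k for over-dispersed, zero-inflated coverage) per cell, with
alternate counts Binomial(c, true frequency).  SNPs covered nowhere vanish
from the table; at mean coverages well below 1x this reproduces station
pairs with no shared SNP.

All stages draw from seed streams derived from a single seed
(`default_rng([seed, stream])`), so identical configurations write
byte-identical files, and regenerating reads does not move the geography.

**What the generator does not emulate:** linkage between SNPs (sites are
independent), reference bias and mapping error, within-station population
substructure, multi-allelic sites and indels, real coastline geometry, and
seasonal environmental variability.  Passing recovery tests therefore show
that the estimators recover the structure they assume, at realistic
sparsity — not that real metagenomes satisfy those assumptions.

## Problem sizes in the test suite

The suite and the acceptance script run the full design at 13 stations and
2000–3000 SNPs, with 100 replicates per recovery scenario, 100 random
datasets for the brute-force BIC comparison and 100 random tables for the
filter oracle; oracle comparisons on 5-station tables use plain
double-loop implementations.  These sizes give Monte-Carlo tolerances of
a few percent on medians and selection rates while the whole suite stays
interactive.

## Known limitations

* The FST estimator is biased upward at low coverage (no correction for
  binomial read sampling); comparisons are meaningful between pairs of
  similar coverage, and absolute values at <10x should be read as upper
  bounds.
* OLS on distance matrices ignores the dependence of pairs sharing a
  station; the permutation cross-check mitigates but does not remove this.
* Least-cost sea distances depend on raster resolution and 8-connectivity;
  they are reproducible, not navigationally exact.
* The Kaiser–Guttman criterion is a heuristic; an explicit axis count can
  be forced where the eigenvalue spectrum is flat.
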