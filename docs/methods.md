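# Methods

This note records the statistical procedures `ncmorph` implements, the
defaults it ships with and why, the design choices made where the protocol
was genuinely open, and what the synthetic-data tests do and do not
demonstrate.

## Data model and units

Raw characters are linear measurements in micrometres; bilateral characters
are averaged across sides (a missing side falls back to the present side; a
fully missing character excludes the record from multivariate stages but not
from univariate summaries of its other characters). Cephalic size
CS = (CL + CW)/2 is the size proxy. The 13 ratio indices divide by CS, except
PreOc/CL (preocular distance scales with head length, and the published
summary statistics use that denominator; a reduced-index listing elsewhere
writes PreOc/CS, which we treat as a typographical variant and resolve to
PreOc/CL everywhere) and the pure shape ratio CL/CW. Nest centroids are
unweighted arithmetic means over a colony's workers; singleton nests are
retained in every stage.

## Removal of allometric variance

The correction rescales index *y* at head size CS (mm) to
`y · (k·0.9 + d) / (k·CS + d)`, the value the fitted linear size–shape
relation predicts at the 0.9 mm reference size. Properties relied on
downstream: identity at CS = 0.9; linearity in *y* with a positive factor
(specimen ordering at fixed CS is preserved); and removal of the fitted
trend (the OLS slope of corrected values on CS is zero up to sampling error).
The denominator must stay positive over the observed CS range; the code
raises otherwise rather than silently flipping signs.

Lines are fitted by OLS per species at worker level and pooled by the
unweighted arithmetic mean of (k, d) — the only reading of "averaging the two
species" that yields a single shared correction function from per-species
fits. Pooled-data OLS is available as an alternative
(`fit_allometric_line` on the combined sample). When the species labels are
not yet known (the unsupervised stage), the packaged published lines or a
pooled fit are used for all records, since the correction must not presuppose
the classification it feeds. CS enters the RAV formula in millimetres; this
module's boundary is the single µm→mm conversion point.

The 13 packaged (k, d) pairs reproduce their printed reference-size constants
to ≤ 2×10⁻⁴ — the printing precision; the worst case (9×10⁻⁵) is the EL line,
whose constant was printed as 0.3207 but computes to 0.32079.

## Cluster-number estimation and wild cards

Ward linkage on Euclidean distances of raw nest-centroid characters (in µm)
is the default representation; per-variable z-scoring is available but off by
default. The protocol's "statistical threshold" for accepting a partition is
implemented as mean-silhouette-width maximisation over k = 2..6 with an
acceptance threshold of 0.50 — the conventional boundary between weak and
reasonable cluster structure; below it the data are declared a single group
(k = 1). This criterion is this package's own declared stand-in for the
original protocol's unpublished internals, validated against the published
outcomes (two clusters from the hierarchical route; the k-means route
collapsing to one group on marginally separated data). The gap statistic
(uniform bounding-box reference, first-local-rise rule) is available as an
alternative criterion.

k-means uses 100 restarts at a fixed seed and keeps the lowest
within-cluster sum of squares; results are bit-reproducible given the seed.
Partitions are compared under optimal one-to-one cluster matching (Hungarian
assignment on the contingency table); nests whose matched labels disagree —
including all nests of clusters left unmatched when the two routes disagree
on k — are wild cards.

## Discriminant stage

Stepwise selection uses the Wilks'-Λ partial-F criterion with the classic
F-to-enter 3.84 and F-to-remove 2.71 (the defaults of the statistical
package named by the source protocol; both configurable). With one variable
and two groups the entry statistic reduces to the squared two-sample t — a
unit test pins this. The discriminant itself is Fisher's two-class direction
w = S⁻¹(μ₊ − μ₋) on the pooled within-group covariance, offset so the
group-mean midpoint scores 0, oriented so a designated group scores positive.
Wild-card resolution trains on concordant nests, assigns wild cards by the
majority score sign of their workers (ties broken by the mean nest score;
an exact-zero mean is flagged unassignable), and iterates with reassigned
nests included until a fixed point (cap 20 iterations; non-convergence is
reported, not hidden).

Error rates are resubstitution by default — the convention of the published
rates, which were evaluated on the training workers — with leave-one-out
available alongside and labelled as such. Nest-level classification uses the
nest mean of worker scores, which under linearity equals scoring the nest
centroid.

The per-character comparison table runs equal-variance ("type 2") two-sided
t-tests over CS plus the 13 indices (14 tests) with Holm flags; the
latitude analysis is a Pearson correlation of worker discriminant scores with
latitude, p from t = R·√((n−2)/(1−R²)) on n−2 df.

## Ordination

PCA is computed by eigendecomposition of the correlation matrix of the
7-index reduced set (CL/CW, HTL/CS, MGr/CS, NOL/CS, PeSH/CS, PreOc/CL,
PrGr/CS) at nest-mean level, so eigenvalues sum to 7 and component scores are
exactly uncorrelated; each component's sign is fixed by making its
largest-magnitude loading positive. Group overlap is the count of each
group's nests covered by the other group's convex hull in the PC1×PC2 plane
(boundary points count as overlapping; a collinear group degrades to a
zero-area polygon with counts still defined). Whether the original overlap
figure was drawn in two or three dimensions is not stated; two is the
default, the component pair is configurable.

## Exact co-occurrence tests

`fisher_exact` computes the hypergeometric distribution of the top-left cell
in log-space (log-gamma terms, log-sum-exp accumulation). Conventions:

- **two-sided (min-likelihood)**, the default: sum of all tables with the
  observed margins whose point probability is ≤ the observed one, compared
  with relative tolerance 1×10⁻⁷ — the convention of standard exact-test
  implementations, verified against exhaustive integer enumeration for every
  table with cells ≤ 15 and against `scipy.stats.fisher_exact`.
- **one-sided** tails, and **doubling** (twice the smaller tail, capped at 1).

The association report (`table3_report`) uses the one-tailed test by
default: the mimicry hypothesis is directional (mimics should co-occur with
their model *more* often), and the one-tailed convention is the one that
reproduces the published association p-values — notably 0.0295 for the
mimic/*Cr. schmidti* table, where the min-likelihood two-sided value is
0.0455. Holm's step-down correction (i-th smallest p times m−i+1, running
maximum, capped at 1) is applied across the four models; the largest of the
four p-values is invariant under Holm, which is why 0.0295 appears
identically raw and corrected.

Only the class-by-model *margins* of the published survey are available, not
the joint presence pattern within a class, so the packaged site table is
expanded from class-level counts with a synthetic joint structure
(`sites_from_class_counts`); every 2×2 analysis depends on the margins alone,
which the expansion reproduces exactly.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design: 40 + 46 nests, 3 minor workers
per nest, CS ~ N(0.89 mm, 0.05) truncated to [0.70, 1.06] (matching the
observed extremes), each index following its published allometric line plus
a nest-level random effect (σ = 1% of the index's reference value) and
residual noise (σ = 2%), and raw characters back-computed from CS and the
drawn indices so that index recomputation inverts the generator exactly.
Sites draw model presence independently per model with class-conditional
probabilities (the empirical survey proportions by default). One seed feeds
independent named substreams (CS, nest effects, residuals, latitudes, sites),
so changing one component leaves the others' draws untouched.

Species differ by opposite intercept shifts of ±6% of each index's
reference value, with the sign pattern of the observed between-species
differences (so the between-species axis is not a pure size-like shift).
The scale is the package's own choice, derived as the smallest offset at
which the prescribed silhouette criterion detects the two groups robustly
across seeds: Euclidean clustering of raw nest centroids is dominated by the
shared size axis, and at offsets emulating the real species pair (±2%) the
mean silhouette at k = 2 stays near 0.42 — below the 0.50 acceptance
threshold — although the nest-level Mahalanobis separation is large (~9).
That marginal regime is deliberately available (`species_offset=0.02`) and is
exercised in a test where the k-means route collapses to a single group, the
behaviour reported for the real data; it illustrates that the silhouette
rule sees only Euclidean structure while the discriminant stage sees the
full covariance.

Consequences for interpretation: passing synthetic-recovery tests shows the
pipeline's machinery is correct (clustering, wild-card logic, discriminant,
error accounting), under Gaussian noise, linear allometry, equal
workers-per-nest and a diagonal index covariance. Real data add skewness,
correlated measurement error, unequal and tiny nest series, and species
differences an order of magnitude subtler; the defaults are a clear-signal
regime, not a difficulty benchmark. The worker-level Bayes error implied by
the default configuration is ≈ 0, so a 0% discriminant error on synthetic
data is the expected outcome, not over-fitting.

The null calibration of the exact test uses 1000 replicates of 200 sites
split 100/100 with presence probability 0.5. Exact tests are conservative at
small n because of discreteness — at the survey's own 60 sites the attainable
type-I rate sits well below 3% — so the calibration uses a size at which the
attainable level approaches the nominal 5%.

## Numerical conventions and degenerate inputs

CSV round trips are bit-exact (shortest-repr floats on write, `float()`
parsing on read). Scatter matrices use log-determinants with singularity
checks; collinear candidates are skipped during stepwise entry with the
offending set named on a hard failure. Ward heights are nondecreasing by
construction; Newick export encodes branch lengths as height differences so
root-to-leaf depths equal the root merge height. Zero-valued groove depths
(MGr, PrGr) are legal; all other characters must be positive. Ties in
k-means are resolved by the restart stream at fixed seed; ties in wild-card
votes by the mean nest score, with exact zero flagged rather than guessed.

## Known limitations

- The cluster-number criterion is a documented stand-in; the original
  protocol's exact internals are unpublished here.
- The published discriminant's coefficients were printed only as an
  unreadable figure; the package re-derives an equivalent discriminant and
  validates via error rates and the sign convention, never via coefficient
  equality.
- No nonlinear allometry, no caste handling beyond minor workers, no
  spatial statistics or range-map construction.
- Checks that require the original specimen-level dataset (86 real nest
  centroids; the published 3.5%/5.6%/2.0% error rates; the published
  per-character table) cannot run without that file and are reported as
  failures with instructions, not skipped.
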