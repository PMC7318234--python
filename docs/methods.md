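# Methods

This note records the models implemented in ednakit, the defaults and why
they were chosen, the numerical conventions that are pinned rather than
implied, and what the synthetic test bed does and does not establish.

## Threshold calibration and assignment

For each query the anchor is the taxon of its best hit (highest identity,
ties by bitscore). Hits are classed relative to the anchor as congeneric
(same genus, different species), confamilial (same family, different
genus) or ordinal (same order, different family); the query's mean identity
per class is computed, the per-query means are pooled across queries, and a
percentile (default 95) of each pooled distribution becomes a threshold.

Two mappings from pooled distributions to thresholds are provided.
`adjacent` (default): the threshold for assigning at rank *r* comes from
the distribution one level broader — congeneric identities bound the
species call, confamilial identities set `genus_min`, ordinal identities
set `family_min`. The logic is that the identity of a hit to a *different*
species in the same genus tells you how similar non-conspecific sequences
get; a match above the 95th percentile of that distribution is unlikely to
be a different species. `direct` reads `genus_min` off the congeneric and
`family_min` off the confamilial distribution, with the ordinal
distribution as a floor check. The species band is fixed at [99, 100] and
never calibrated; genus/family minima are strict (`>`) bounds.

Percentiles use linear interpolation between order statistics (position
1 + p(n−1), numpy's default), pinned so tests are exact. Levels with fewer
than `calibration_min_n` (default 5) pooled means fall back to the
configured defaults (genus 93, family 89) with a warning, as does a
calibration that violates the ordering family < genus < species floor.

Assignment cascade: with best identity *b* and the set of hits tied at *b*,
a species is called if *b* lies in the species band and the tied hits name
one species, or several of which exactly one is on the regional checklist
(flagged as a checklist tie-break). Otherwise, above `genus_min`, the same
rule applies to the tied hits' genera; above `family_min`, to their
families (no checklist at family rank); otherwise unassigned. Identity ties
are exact float equality, which is appropriate for BLAST's three-decimal
output. Cross-barcode consolidation promotes a group to species level if
either barcode achieved it; conflicting species within one variant group
resolve to the lowest common rank and are logged, mirroring cases a real
survey would send to manual curation.

## Decontamination

"Frequency" in the control filter means relative abundance within a
replicate, computed against the replicate's sequencing depth captured when
the table was built and carried unchanged through row-removal filters.
This has two consequences: the comparison is not confounded by depth
differences between controls and samples, and each filter is exactly
idempotent (recomputing denominators after removals would make a second
pass remove more). A taxon is removed iff its maximum relative abundance
over control replicates is ≥ its maximum over water-sample replicates and
it actually occurs in a control; raw-count comparison is available by
config. Filter order is blacklist → control frequency → replicate support;
the audit ledger records every removal with a reason code and the numbers
behind it. The single-replicate rule is applied dataset-wide by default
(the stricter reading); the 3-of-4 within-sample variant zeroes a taxon
within each water sample lacking support and drops rows left empty.
Control columns never count as replicate support.

## Rarefaction and community matrices

Rarefaction draws without replacement (multivariate hypergeometric) to a
common depth per PCR replicate — the stated standardisation unit — with
the median of per-replicate totals (rounded half up; even counts average
the central pair first) as the default depth. Replicates at or below the
target pass unchanged rather than being dropped (dropping is available by
flag); both decisions are logged. Barcodes are merged before rarefaction.
Aggregation to water samples or sites sums counts; presence is any nonzero
member, so presence-then-aggregate equals aggregate-then-presence.

## Raup–Crick

Per site pair, `n_sim` (default 9999) independent pairs of null
communities are simulated, preserving each site's observed richness.
Under the default `frequency_weighted` null, species are drawn without
replacement with probability proportional to their occurrence frequency
across sites, implemented with exponential-race (Gumbel top-k) keys; the
`equiprobable` null draws uniformly, making the null shared count
hypergeometric — the closed form used for verification. Ties contribute
half (the ½ term), so duplicated sites in a rich pool score near 0 and
disjoint sites near 1. The per-pair null is simulated independently per
pair, and the taxon axis is canonicalised by sorted label before drawing,
so the result is bitwise invariant to taxon-column permutation at a fixed
seed. Sites with zero taxa get dissimilarity 1 with a warning.

## Multivariate tests

PERMANOVA is computed directly from squared dissimilarities
(SS_total = (1/N)Σ_{i<j} d²; SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d²), with
permutation p-values using the (1 + exceedances)/(1 + n_perm) convention —
guaranteeing p > 0 and making p = 0.001 attainable at 999 permutations.
Permuted statistics count as exceedances at F_perm ≥ F_obs − 1e−10, so an
all-tied null gives p = 1. The dispersion test embeds the matrix by PCoA
retaining positive-eigenvalue axes only (a simplification of the
imaginary-part correction, reasonable because inverse-normal-transformed
matrices are near-embeddable), measures Euclidean distances to group
centroids, and permutes group labels over those distances; all-identical
points define F = 0; singleton groups are excluded with a warning. The
inverse normal transformation maps upper-triangle ranks through Blom
scores (r − 3/8)/(m + 1/4) to normal quantiles and shifts by the minimum
so the result remains a non-negative dissimilarity.

CAP fits an LDA with equal priors and pooled covariance (the
smallest-assumption classical formulation) on the first m PCoA axes and
reports leave-one-out allocation success per m; `auto` takes the m
maximising success, smallest m on ties. UPGMA is implemented directly so
the tie-break (lexicographically smallest pair of cluster labels, a
cluster labelled by its smallest leaf) is pinned; node heights are half
the merge distance, making the tree ultrametric with cophenetic distances
equal to merge distances. Clustering defaults to the raw Raup–Crick
matrix; the transformation is applied (when the dispersion test fails) for
PERMANOVA only.

## Species accumulation and species–area models

The exact analytic mean uses the hypergeometric form with a numerically
stable product for the binomial ratio. The SD accompanying the exact mean
is estimated from permutations of unit orderings (default 1000) — the
resampling analogue of an unconditional SD, which would otherwise require
an extrapolated pool estimate; confidence bands are labelled accordingly.

Model forms: Arrhenius k·n^z; Gleason k + slope·log n; Gitay
(k + slope·log n)²; Lomolino Smax/(1 + slope^(log(xmid/n))) with natural
logs (the parameterisation in common ecological use; "Lomolino model"
admits variants, so it is pinned). Fitting is least squares over a
deterministic multi-start grid (Smax ∈ {1, 1.5, 2}·max S, slope ∈
{1.5, 2, 4}, xmid ∈ quartiles of n; closed-form linear starts for the
log-linear models) with tight tolerances, best start by RSS. AIC is the
Gaussian form n·log(RSS/n) + 2(p+1), counting the error variance as a
parameter; only relative AIC matters for selection, and equal-RSS ties go
to the smaller model. Only the Lomolino model has an asymptote; when a
non-asymptotic model wins, the detected fraction is explicitly undefined
rather than approximated. Accumulation units are configurable (sites by
default; water samples or replicates for within-site curves).

## Synthetic data: what it emulates and what it does not

The generator mirrors the survey design: up to six habitat types (five
surface types and a deep offshore stratum), default four sites per
habitat, three water samples per site, four PCR replicates per sample, two
barcodes sharing replicate identifiers so merged taxa sum per replicate,
and field/extraction/PCR controls. Occupancy is habitat-structured: each
*genus* has a home habitat (so variants resolvable only to genus never
blur the habitat signal), species are specialists with probability
`habitat_specificity` (default 0.8), occupy home-habitat sites with
probability 0.9 and, if generalists, foreign sites with probability 0.25.
Read counts are lognormal-Poisson (default log-mean 4, log-SD 1) with
gamma-distributed per-replicate depth factors (shape 4), so per-replicate
totals vary severalfold and rarefaction to the median is a real operation.
Hit identities are drawn around level means of 99.7/96/93/89 (species/
genus/family/order, SD 0.4), chosen so the calibrated thresholds land just
above 93% (genus) and 89% (family) — the regime the method is designed
for. Contamination is injected at the taxon level into controls at
`contamination_rate` (default 0.02 of a typical replicate depth per
contaminant taxon) and into samples at a tenth of that by default, with
domestic taxa concentrated in PCR controls and two genuine pool species
leaking into field/extraction controls at trace level — giving the control
filter true positives and true negatives. One master seed feeds
stage-keyed RNG streams (CRC-derived spawn keys), so identical
configurations are bit-identical and stages are independently
reproducible.

Not emulated: sequencing error and chimeras (upstream of scope), tag
jumping, PCR efficiency differences between taxa, spatial autocorrelation
between neighbouring sites, eDNA transport between habitats, and reference
databases with missing or mislabelled taxa. Passing tests therefore show
the pipeline's operations are correct and recover planted structure; they
do not show that real surveys meet these assumptions — in real data the
habitat signal is weaker (dispersal homogenises communities) and species
calls are limited by reference completeness.

## Numerical conventions and degenerate inputs

Deterministic orderings everywhere a tie could make output
seed-dependent: hit screening sorts by (bitscore, identity, accession);
UPGMA ties break lexicographically; equal-AIC fits keep the first-listed
model; `auto` CAP picks the smallest best m. Strict validation is
preferred to coercion: identities outside [0, 100], non-integer or
negative counts, rank gaps in lineages, duplicated row ids and unknown
sample-sheet columns are errors, not warnings. Degenerate inputs with a
defined answer are pinned: all-zero replicate columns pass rarefaction
unchanged with a warning; a zero-taxon site has Raup–Crick dissimilarity 1
to everything; identical points give dispersion F = 0; a PERMANOVA with
all-tied distances gives p = 1.

## Problem sizes in tests and checks

The verification suite uses pools of 4–8 taxa where a closed form exists,
exhaustive enumeration up to 6 units, 10^5 null simulations for
convergence checks, 100 replicates for noisy Lomolino recovery, and a
20-site, 150-species study for the end-to-end run — sizes at which every
oracle is exact or its Monte-Carlo error is quantifiable. The analysis
scripts run the full 24-site, two-season design with the production
default of 9999 null simulations.
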