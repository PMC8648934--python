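# Methods

## Epochs and scenarios

The analysis contrasts two community states on a fixed cell universe.
The **Holocene** flora is every species' native range, *including*
recently extinct species — the pre-Columbian baseline. The
**Anthropocene** flora removes a scenario-specific set of IUCN-like
status categories and adds the invaded cells of surviving naturalized
species. The removed sets are nested — best case {recently extinct} ⊂
business as usual {+CR} ⊂ increased extinction {+EN} ⊂ worst case {+VU} —
which makes per-cell Anthropocene richness provably non-increasing along
that order (asserted exactly in the tests). Extinction acts at the
species level: a removed species disappears from native *and* invaded
cells. The "no superinvasives" scenario is best case minus the invaded
occurrences (not the native ones) of detected superinvaders; whether such
a scenario should also exclude recent extinctions is genuinely open, so
both variants are constructible from `ScenarioSpec` flags.

Superinvaders are naturalized species whose invaded range size (occupied
cells) within a level-3 region exceeds that region's Tukey fence
Q3 + 1.5×IQR; quartiles use linear interpolation between order statistics
(the common default; configurable convention documented here because the
underlying rule does not fix one). Regions with fewer than 4 naturalized
species are skipped — quartiles on 1–3 points are noise. A species
flagged in any region is a superinvader everywhere.

The 100-year extinction probabilities by category (LC 0.001, NT/CD 0.01,
VU 0.1, EN 0.67, CR 0.999) are fixed constants; `sample_stochastic_extinctions`
uses them for a Monte-Carlo alternative to the categorical scenarios.

## Diversity metrics

**Faith's PD** is rooted: a cell's branch set is the union of
root-to-tip paths of its species, so the root path is always included.
This follows the tip-to-root definition of the summed-branch-length
measure; an assemblage of one species has PD equal to its root-path
length, not zero. All branch-set machinery is polytomy-safe because only
branch sets, never node degrees, enter any formula.

**SES-PD** permutes tip labels over *all* tips of the phylogeny (not only
species observed in the matrix; `shuffle_over="observed"` gives the
restricted variant), keeping tree shape and assemblages fixed, and
reports z = (obs − mean)/SD with the sample (n−1) SD. Cells whose PD is
shuffle-invariant — all tips present, or a star tree with equal branch
lengths — have a degenerate null (SD = 0) and get a *missing* SES, never 0.

**β-diversity** is pairwise within level-3 regions (an all-pairs mode
exists behind `scope="all"`); each cell's value is the unweighted mean of
its dissimilarities to the other cells of its region, and single-cell
regions are missing. Simpson turnover min(b,c)/(a+min(b,c)) is the
primary index because it is insensitive to richness differences; Sorensen
and Jaccard are computed from the same a/b/c decomposition for
sensitivity. Pairs where both cells are empty are missing; pairs with
exactly one empty member score 1 under the Simpson convention (a = 0),
configurable to missing via `empty_pair`. On a star tree with equal
branch lengths the phylogenetic decomposition is the species
decomposition scaled by the branch length, so phylogenetic and taxonomic
indices coincide exactly — a closed-form limit the tests assert.

**Δ metrics** are relative changes (v_anthro − v_holo)/v_holo, missing
when the Holocene value is ≤ 0 or absent. Applied to SES values (which
can be tiny or negative) the ratio is unstable; rows with non-positive
baselines are flagged missing rather than reported, and the instability
for small positive baselines is visible in the summary ranges — a known
limitation of relative change on z-scores.

## Permutation tests of Darwin's naturalization hypothesis

The regional statistic is the mean patristic distance from each
non-native to its nearest neighbor in the recipient (native) flora. The
null reassigns the non-native label set (same size) uniformly within the
regional species pool — natives ∪ non-natives — treating unselected
species as the recipient flora; a whole-tree pool is available as a
sensitivity mode. Reading the tip shuffle as regional keeps the
comparison aligned with the recipient-flora question; p-values use the
add-one rule (r+1)/(n+1), two-sided via the doubled smaller tail. The
superinvader relatedness test shuffles the superinvader label among
non-natives and is one-sided (smaller mean distance to other non-natives
= more related than chance), matching the direction of the claim it
tests. Multi-tree runs report elementwise medians (mean of the middle
pair for even counts).

Calibration on the replicate-region design (64-tip birth–death pools, 12
non-natives, 199 permutations): the empirical type-I error over 500
uniform-naturalization regions sits inside the exact binomial 99%
interval at α = 0.05, and power against strongly clustered naturalization
(selection weight e^{−λd}, λ = 10 per myr) exceeds 0.8 over 100
replicates. Pool size matters: with 32-tip pools and 5 non-natives even
the λ→∞ limit rejects only ~half the time — the statistic needs enough
non-natives for its null distribution to separate.

## Continental exchange

A naturalized species with origin d and invaded cells in continents
r1…rk contributes one unit of species flow to each (d, rᵢ). PD flow is
the rooted PD of the full species set on a flow (branch-union, so shared
stems are counted once within a flow). Net PD per species exchanged
divides the PD a recipient continent's Holocene flora (union of species
over its cells) gains from a donor's flow by the species count of that
flow. When several donors contribute overlapping branches the attribution
is ambiguous; the default processes donors sequentially in the
hierarchy's continent order (documented, deterministic), and
`mode="shapley"` averages the marginal gain over all donor orders exactly
(donor counts are ≤ 8, so the 2^n subset table is cheap). Both modes
conserve the recipient's total PD gain; they differ only in how shared
stems are credited. Species with multiple origin continents are
disallowed in the data model; the generator guarantees a single origin.

Family-composition correlations between two recipient continents use
per-family counts of received naturalized species over the union of
families (zeros included), Spearman with average ranks; fewer than 3
families with nonzero totals gives a missing value.

## The synthetic flora generator

The generator emulates the statistical structure of the global inputs the
analysis is designed around, at desk scale:

- **Tree** — ultrametric birth–death tree conditioned on the extant tip
  count (birth 1.0, death 0.3 per myr; retry-until-success conditioning).
  Determinism under a fixed seed matters more than biological realism
  here; any ultrametric generator would do.
- **Spatial hierarchy** — n_continents × regions_per_continent ×
  cells_per_region (default 5 × 2 × 10), mirroring the two TDWG levels
  the analysis consumes. Cells are opaque identifiers; contiguity is 1-D
  (cells ordered within a region) because no downstream metric sees
  geometry, only incidence.
- **Native ranges** — one home continent per species, a contiguous block
  of cells whose size is log-normal (mean 6 cells, σ = 0.75 on the log
  scale, parameterized so the continuous mean equals the configured
  mean), spilling into the adjacent region of the same continent when it
  outgrows one region.
- **Statuses** — 0.5% recently extinct and 5% naturalized by default,
  the shares of the ~2×10⁵-species study flora (1065 recently extinct,
  10,138 naturalized of 205,456); fractional counts round half-up so the
  documented example counts are exact (200 species → 1 extinct, 10
  naturalized). Category weights (LC 0.55, NT/CD 0.10, VU 0.20, EN 0.10,
  CR 0.05) keep most species unthreatened while giving the nested
  scenarios visibly different extinction sets; they are a design choice,
  not an estimate. Families are k basal subtrees (default 10), split
  largest-first, so family labels are phylogenetically coherent.
- **Naturalizations** — cross-continental only (invaded cells disjoint
  from native cells by construction). Total invaded range sizes are
  Pareto-tailed (scale 4 cells, shape 1.3 — heavy enough that a few
  species invade many regions), laid down as contiguous blocks across
  randomly ordered foreign regions. The planted superinvader subset
  (10% of naturalized species) is cosmopolitan — every foreign cell —
  mimicking near-ubiquitous weeds and guaranteeing genuine range-size
  outliers. The λ knob concentrates *which* species naturalize
  (selection weight e^{−λd} to a random seed species); it exists for
  power studies and is 0 (uniform) by default, a deliberate null rather
  than a claim about how naturalization works.

All stages draw from counter-based child streams of one master seed, so
datasets are byte-reproducible and adding a stage never perturbs earlier
streams.

What the generator does *not* emulate: climate and habitat covariates,
range-size–extinction-risk correlation, phylogenetically clustered
extinction, 2-D spatial autocorrelation, region-size heterogeneity, and
future colonizations. Passing tests therefore show that the *metrics and
machinery* behave correctly under a known data-generating process — e.g.
that naturalizations rather than extinctions drive Δβ when invaded
ranges are broad — not that real floras have any particular effect size.

## Problem sizes and numerical choices

The standard test/acceptance design is 200 species on 100 cells; SES
metrics use 200 randomizations in the drivers' quick paths and 1000 by
default in the library; permutation tests use 199 permutations in
calibration suites and 1000 by default. Superinvader-recovery checks use
40-cell regions (n = 500 species, 12% naturalized, 2% superinvaders):
the per-region outlier rule needs regions large enough that typical
invaders occupy a small share — with 10-cell regions an ordinary invader
can fill a region outright and the fence never separates. Tolerances:
exact assertions for set algebra and closed-form limits; `pytest.approx`
defaults for branch-length sums; Monte-Carlo comparisons at 10⁴ draws use
absolute tolerances of 0.03–0.05 on p and z.

## Known limitations

- Relative Δ on SES values is reported but unstable near zero baselines
  (see above); comparisons of SES maps are better made on the raw z
  difference, which the change tables also contain.
- The one-empty-cell β convention (index 1) is a modelling choice;
  sensitivity available via `empty_pair="missing"`.
- Name reconciliation is out of scope: identifiers must match the tree's
  tip labels exactly (case- and underscore-sensitive).
- No raster/SDM handling, no map projections, no mixed-model driver fits
  — the change tables are exported in a form suitable for such modeling
  elsewhere.
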