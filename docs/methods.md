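# Methods

## Dissimilarity model

All dissimilarity measures are incidence-based: a species is present at
a site iff it has at least one record there (communities are species
lists, not abundance vectors). For an unordered site pair the components
are `a = |A∩B|`, `b = |A\B|`, `c = |B\A|` over a common element
universe, and

    βcc = (b+c)/(a+b+c),  β-3 = 2·min(b,c)/(a+b+c),  βrich = |b−c|/(a+b+c).

The three are exact rationals of integer counts, so additivity
βcc = β-3 + βrich holds to machine precision; tests assert it at 1e-12
and against an independent `fractions.Fraction` oracle. β-3 captures
balanced replacement of elements, βrich the surplus held by the richer
site (linked to nestedness). βcc = 1 exactly when nothing is shared;
adding a shared element can never increase βcc.

### Taxonomic dissimilarity

Each species set is expanded to the upward-closed set of (rank, name)
pairs over the group's configured rank list (coarse → fine, ending in
species). The pair identity keeps homonyms at different ranks distinct.
Taxa at **all ranks are pooled into one set** — species included — and
the same partition is applied to the pooled sets, so the components are
shared/exclusive taxon counts (Ta, Tb, Tc). Pooling (rather than
per-rank averaging or step-weighting) follows directly from the defining
formula, which counts taxa, not ranks; no rank weights are applied.

Rank lists may be ragged: a blank cell means the rank does not apply to
that lineage and contributes no taxon. A consequence worth knowing:
species dissimilarity does not bound taxonomic dissimilarity in general.
If shared species have shallow lineages (few applicable ranks) and
exclusive species deep ones, βccT can exceed βcc; the suite contains a
constructed counterexample, and the code never enforces βcc ≥ βccT. On
realistically nested classifications, shared higher taxa pull βccT below
βcc, which is the typical empirical pattern.

### Multiple-site measures

The `component-sum` default computes components for all T(T−1)/2 pairs
and forms βcc = Σ(b+c)/Σ(a+b+c), β-3 = Σ2·min(b,c)/Σ(a+b+c),
βrich = Σ|b−c|/Σ(a+b+c). This generalization was chosen because it keeps
additivity exact by construction and reduces to the pairwise partition
at T = 2 (both properties are tested). The `pair-mean` variant
(arithmetic mean of pairwise values) is exposed through config for
sensitivity analysis; it also reduces correctly at T = 2 but weights
every pair equally regardless of richness. Contribution percentages are
100·β-3/βcc and 100·βrich/βcc, summing to 100 within 0.01.

### Missing-value policy

Undefined quantities propagate as NaN with a category-tagged warning,
never as zeros: a pair of empty communities, any pair involving a site
with zero presences of the group, contribution percentages at βcc = 0,
and coverage of an empty sample. Sites with zero presences stay in the
incidence matrix and are flagged; the multi-site summary sums over
defined pairs only and requires at least two non-empty sites.

## Sample coverage

Completeness of each group × site inventory is the abundance-based
coverage estimator

    Ĉ = 1 − (f1/n)·[(n−1)·f1 / ((n−1)·f1 + 2·f2)]

from the total records n, singleton count f1 and doubleton count f2;
Ĉ = 1 when f1 = 0. It estimates the probability that a further record
belongs to an already-detected species. Edge case n = 1, f1 = 1
degenerates to 0 and is reported with a small-sample warning. Reporting
is percent with two decimals; machine outputs keep full precision. A
Monte-Carlo test (1000 resamples of a 40-species geometric-series
community at sample size 120) checks the estimator's mean against the
mean true coverage of the sampled communities.

## Ordination and correlation

NMDS uses stress majorization (SMACOF) alternating with
pool-adjacent-violators isotonic regression (ties share a fitted block),
via scikit-learn's non-metric `MDS` on the precomputed dissimilarity
matrix. Defaults: 2 dimensions, 50 random restarts keeping the lowest
Kruskal stress-1, 300 iterations, stress tolerance 1e-7, seeded and
deterministic. Coordinates are identified only up to rotation,
reflection and translation; stress and inter-point distances are the
meaningful outputs, and the suite recomputes stress-1 independently from
the returned configuration (agreement to ~0.5%; the solver reports
stress one monotone-regression step behind the final configuration).
Degenerate inputs (all-zero matrices, fewer than dims+1 sites, missing
entries) are refused rather than imputed.

The species-vs-taxonomic correlation treats the T(T−1)/2 unordered site
pairs as independent observations (Pearson r, two-sided t-based p on
n − 2 df). Pairs sharing a site are not independent, so this p-value is
anti-conservative; a Mantel-style permutation p (jointly permuting site
identities of one matrix, add-one estimator) is available via
`permutations=`, but the plain t-based p is the default to match common
practice in distance-scatter comparisons.

## Synthetic data generator

The generator emulates a multi-group, multi-site occurrence survey with
controllable compositional structure:

* **Composition**: each site receives a shared core (present at every
  site) plus site-exclusive species, so every pairwise (a, b, c) — and
  hence every partition — is fixed by design and recoverable exactly;
  this is the pipeline's primary end-to-end test. `turnover_bias`
  interpolates exclusive counts from all-equal (bias 1, pure turnover,
  βrich = 0 everywhere) to strongly graded (bias 0).
* **Classification**: a rooted hierarchy grown rank by rank with
  configurable (mean) branching; integer branching gives a deterministic
  balanced shape, fractional values draw child counts from a shifted
  Poisson. Ragged hierarchies blank configured intermediate ranks per
  lineage with a given probability.
* **Abundance**: record counts of present species are i.i.d.
  Geometric(p) on {1, 2, …}. This guarantees at least one record per
  designed presence (so incidence equals the design), produces the
  skewed long-tailed rank-abundance shape of survey data, and gives the
  closed form E[f1] = S·p used in the distributional test. Default
  p = 0.15 (mean ≈ 6.7 records per species per site), yielding
  completeness values in the mid-90s, typical of a well-sampled
  vertebrate survey.
* **Preset**: `hidalgo_like` fabricates four vertebrate-style groups
  across six ecoregion-style sites with rank depths 5, 9, 15 and 9 and
  per-site richness magnitudes spanning roughly 9–29 (amphibian-like) to
  189–309 (bird-like) species. All names are synthetic labels.

What the preset does **not** emulate: partial sharing among site subsets
(real faunas share species between some but not all sites; here overlap
is core-only, which lowers multi-site dissimilarity for species-rich
groups), spatial autocorrelation, detection error, and real taxonomic
imbalance. Passing tests therefore demonstrate correctness of the
computations and pipeline plumbing on communities with known structure,
not ecological realism of any particular dissimilarity value.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, so taxonomy and occurrence generation are independently
reproducible; identical config + seed reproduces every CSV output byte
for byte (tested).

## Problem sizes

The default suite and the reproduction script run the preset end to end
(four groups, six sites, ~1,200 species in total, 15 pairs per group),
10,000-triple additivity sweeps, 1,000-community brute-force oracle
sweeps and 1,000-replicate coverage simulations; everything completes in
well under a minute on one CPU.

## Known limitations

* Dissimilarity is incidence-based only; abundance-weighted partitions
  and Sørensen-family decompositions are out of scope.
* Taxonomic dissimilarity depends on the supplied rank lists; deeper
  classifications mechanically add shared taxa and lower βccT, so values
  are comparable only within one classification scheme.
* The pairwise-independence assumption of the default correlation
  p-value is documented above; use the permutation option when it
  matters.
* No geographic processing: records must already carry a site label.
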