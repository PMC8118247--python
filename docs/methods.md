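# Methods

This note documents the statistical models and procedures dietkit implements,
the defaults it ships, the numerical conventions it commits to, and what the
synthetic-data generator does and does not emulate.

## Diet indices

All indices are computed over the full (non-empty) stomachs of a stratum;
empty stomachs and, by default, stomachs containing only the "Other" rare-prey
category are removed first, and mixed stomachs have their Other contribution
zeroed before proportions are recomputed. A prey *occurs* in a stomach if its
count or its weight is positive — heavily digested material often has a
measurable weight but no reliable count.

Per-stomach compositions (rows summing to 100 exactly) are averaged two ways:
over only the stomachs containing the prey (prey-specific %PN/%PW) and over
all full stomachs (%N/%W). The identity %N = %PN·%FO/100 links the two; the
implementation computes both routes and asserts agreement to 1e-9, so a
regression in either code path is caught structurally. %PSIRI =
(%N + %W)/2 = %FO·(%PN+%PW)/200 inherits additivity under category merging
from %N and %W, which is what makes it comparable across taxonomic levels;
`additivity_check` verifies the lowest→generalized aggregation to 0.1.

Display rounding is half-away-from-zero to one decimal, always applied to
unrounded values. Tables are sorted by descending %PSIRI with alphabetical
tie-breaks, so output is deterministic.

## Cumulative prey curves

The randomized curve averages, over a stated number of random stomach
orderings (default 999, seed required), the count of distinct prey categories
among the first k stomachs. The exact expectation has the hypergeometric
closed form E[S_k] = S − Σ_i C(n−n_i, k)/C(n, k), implemented with log-gamma
arithmetic; it serves both as an analytic option and as the oracle the
randomized estimator is tested against. Sufficiency is judged by the OLS
slope of the *mean* curve over its last five points, threshold 0.05
categories per stomach, inclusive. The regression is on the mean curve, not
per-permutation curves, because the decision quantity is a single slope per
stratum.

## Trophic levels

TL = 1 + Σ_j P_j·TL_j is linear in the diet proportions, so stratum means can
be checked against closed-form expectations under any random-composition
model. The proportion basis defaults to weight (gravimetric proportions are
the standard choice for energetic interpretation) and can be switched to
number; both are supported because survey write-ups frequently omit which was
used. Only euphausiid (2.25) and teleost (3.24) prey trophic levels ship as
package defaults — they anchor the classic 3.25–4.24 predator range for
single-prey diets; every other category's value is taxon-specific and must be
supplied by the user (YAML `prey_tl:`). The synthetic scenarios carry a full
plausible table (squids 3.2, rockfishes 3.4, amphipods 2.5, crustaceans 2.4,
tunicates 2.1, other 2.5) so the pipeline runs end to end.

## Distance-based multivariate analysis

All tests operate on the Gower-centered matrix G = −½·J·D²·J of a Bray-Curtis
(or, for oracle checks, Euclidean) distance matrix D. For a nested sequence
of design hat matrices H_t, the sequential (Type I) sum of squares of term t
is tr(H_t G) − tr(H_{t−1} G); pseudo-F uses the residual mean square of the
full model. Term order therefore matters and is taken to be the selection
order; with Euclidean distances and a single factor this reduces exactly to
the classical ANOVA F, which the tests exploit.

Numerical conventions, fixed for reproducibility:

- **Permutation scheme** — free permutation of raw observation labels
  (equivalently, symmetric permutation of G); the simplest scheme and the one
  whose small-sample behaviour can be verified by exhaustive enumeration
  (n ≤ 8 via `permutations="exact"`).
- **p-value** — (b+1)/(m+1) with the observed statistic included; p is
  bounded below by 1/(m+1).
- **Forward selection** — at each step the candidate with the largest
  conditional pseudo-F among those with permutation p ≤ 0.05 (entry α)
  enters; ties break alphabetically; the final table is re-ranked by F. A
  `max_terms` cap supports power studies that only need the first entry.
- **Covariate screen** — pairs with |Pearson r| > 0.65 and p < 0.05 lose the
  lower-priority member; the priority list is explicit config, and every
  pairwise decision is reported.
- **Negative eigenvalues** — Bray-Curtis is non-Euclidean, so G has negative
  eigenvalues. PERMDISP and CAP retain only positive-eigenvalue principal
  coordinates and log the discarded share of inertia. This is the most common
  convention but not the only one (e.g. some implementations apply a
  sqrt(d²₊ − d²₋) correction in dispersion tests), so cross-package
  comparisons on non-Euclidean distances can differ in the third decimal;
  with Euclidean input dietkit's PERMDISP statistic matches the
  centroid-based betadisper exactly.
- **CAP / db-RDA** — canonical axes are the eigenvectors of the covariance of
  the design-fitted principal coordinates; axis %variance is the canonical
  eigenvalue over total positive inertia; overall and per-axis pseudo-F are
  tested by the same free-permutation scheme. Biplot scores are Pearson
  correlations of prey-composition columns (and continuous covariates) with
  the site scores, and level centroids for factors.
- **Dispersion test** — distances to group centroids are recomputed under
  each label permutation (betadisper-style), not merely re-grouped.

## Isotopic niche

The lipid screen removes samples with C:N strictly greater than 3.5 (a
sample at exactly 3.5 is retained); missing C:N is retained with a warning
unless strict mode is on. The six metrics are the standard Layman suite: CR
and NR are marginal ranges; TA is the convex hull area (scipy's hull; 0 for
collinear sets, undefined — reported as missing — below 3 points); CD is the
mean distance of individual points to the group centroid; MNND/SDNND are the
mean and n−1 standard deviation of nearest-neighbour distances, with
duplicate points legal (distance 0) and no point its own neighbour.

CD deserves a note: some method descriptions phrase it as a distance between
population means, but per-group tables only make sense with the
individual-to-centroid definition, which is also the standard Layman/SIBER
one; dietkit uses the individual-level definition.

## Synthetic data

The generator emulates the structure the analyses assume, with defaults
calibrated to a two-year (2013–2014), three-site (Cordell Bank, Farallon
Islands, Half Moon Bay) survey: 433 stomachs split 40/56/104/125/108 across
strata with empty-stomach probabilities (0.175, 0.268, 0.731, 0.384, 0.333)
that give ≈58% full overall; per-stratum Dirichlet prey spectra sketching
tunicate-dominated 2013 offshore diets and crustacean/tunicate mixtures in
2014; a shifted negative-binomial item count (mean 47, dispersion 0.6 —
nearly 12,000 items over ~250 full stomachs, heavy-tailed); lognormal
per-item weights whose category medians span 0.02 g (amphipods) to 15 g
(rockfishes), so numeric and gravimetric rankings genuinely disagree; and
bivariate-normal isotope groups of 30 fish placed within δ¹³C −19.0…−16.3‰
and δ¹⁵N 13.1…15.5‰, with C:N ~ N(3.3, 0.12) leaving a few percent of
samples above the 3.5 screen. Each fish draws from a substream keyed by
(seed, stratum, index), so enlarging a stratum never perturbs existing fish.

Named scenarios: `study` (the emulation above), `null` (identical strata —
for type-I error checks), `planted_location_effect` (prey spectra differ by
site only — for power and forward-selection recovery), and `heatwave_shift`
(euphausiid-rich 2013 vs tunicate-rich 2014, the marine-heat-wave diet
trade-off).

What the generator does **not** emulate: within-stratum covariate–diet
correlations (depth or length do not influence the simulated composition),
overdispersion beyond Dirichlet-multinomial, temporal autocorrelation within
trips, taxonomic misidentification, and measurement error in weights beyond
0.001-g rounding. Passing tests on synthetic data therefore demonstrate the
correctness of the estimators and tests under the stated model, not the
field realism of any particular effect size.

## Validation problem sizes

The correctness suite uses exhaustive enumeration at n = 6 (all 720
orderings), closed-form ANOVA equivalence at machine precision, 1000 null
PERMANOVA replicates (n = 30, 199 permutations) for the type-I error band
[0.03, 0.07], 200 forward-selection replicates (250 stomachs, 99
permutations, first entry only) for the >90% recovery check, 999-permutation
accumulation curves against the hypergeometric closed form, and 1000 random
point sets against an independent monotone-chain/fan-triangulation hull
oracle. These sizes were chosen as the smallest that make the binomial noise
of each check comfortably smaller than the band being asserted.

## Known limitations

- PERMANOVA supports fixed crossed terms with sequential SS only: no nested
  or random effects, no Type III marginal tests.
- Only Bray-Curtis and Euclidean distances are exposed.
- The CAP permutation test permutes raw observations; residual-permutation
  variants (permuting under a reduced model) are not implemented.
- Reconstructions from published, already-rounded table inputs can differ
  from the printed cells by up to ~0.15 because three one-decimal roundings
  propagate; tests distinguish exact identities from such reconstructions.
- The deposited per-fish supplementary datasets of the motivating survey are
  third-party files that cannot ship with the package; reproduction tests
  against them run only when the user places the files under
  `data/deposited/`.
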