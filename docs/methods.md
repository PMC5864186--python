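# Methods

This note documents the statistical procedures implemented in `ecosig`, the
synthetic data the package uses to exercise them, and the numerical and
design choices a user should know about.

## Profiling

A metagenome's ecogenomic profile with respect to a phage is the vector of
per-ORF relative abundances in hits per megabase (hits/Mb). Input is the
de facto 12-column tab-separated output of sequence-similarity search
tools. Two search orientations are supported and must be declared:
`read_query` (reads searched against translated ORFs; the subject is the
ORF) and `orf_query` (ORF proteins searched against an assembled data set;
the query is the ORF).

Validity of a hit is decided on the *query* side: identity ≥ 35%, query
coverage `(query_end − query_start + 1) / query_length` ≥ 0.5 (1-based
inclusive coordinates), e-value ≤ 1e−5, all boundaries inclusive. Multiple
HSPs between one (sequence unit, ORF) pair collapse to the single best
alignment — lowest e-value, ties broken by higher bit score — *before* the
validity filter, so duplicated rows never change a profile. A unit validly
matching k distinct ORFs contributes one count to each of them; whether
such multi-ORF units should instead count only toward their single best ORF
is not decidable from first principles, so both behaviours exist
(`best_orf_only`, default off). Data set sizes (total bp) come from the
metadata table rather than being recomputed from reads: the package
consumes search output, not sequence data.

Before ordination, data sets showing fewer than two distinct ORFs with
positive abundance are dropped (`filter_min_orf_representation`,
`min_distinct=2`), a stringency filter against spurious single-gene
matches.

## Ordination and group separation

Profiles are square-root transformed (damping dominant ORFs) and converted
to Bray–Curtis dissimilarities, `d(u,v) = Σ|u−v| / Σ(u+v) ∈ [0,1]`. A pair
of all-zero profiles has an undefined ratio; the package assigns d = 0 and
warns, since two empty profiles are maximally similar, not dissimilar.

Non-metric MDS minimises Kruskal stress-1,
`sqrt(Σ(d̂ − δ*)² / Σ d̂²)`, where d̂ are configuration distances and δ*
the disparities from isotonic (monotone) regression of d̂ on the input
dissimilarities. The optimiser is SMACOF-style majorization (Guttman
transform) alternating with isotonic regression, run from `n_starts`
random initialisations (default 1000, matching ecological practice for
publication-grade ordinations; tests use far fewer) with convergence when
the stress decrease falls below `tol` (1e−6) or `max_iter` (300) is
reached. The best configuration is centred; orientation is arbitrary, as
in any nMDS.

ANOSIM uses mean ranks for tied distances and the statistic
`R = (mean between-group rank − mean within-group rank) / (n(n−1)/4)`,
which is bounded in [−1, 1]. Significance comes from random relabelling
with `p = (1 + #{R_perm ≥ R_obs}) / (1 + n_permutations)`; the default
999 permutations give a minimum attainable p of 0.001. An exact mode
(`n_permutations="exact"`) enumerates all distinct relabellings and is
practical up to roughly n = 10. Degenerate input (all distances identical)
returns R = 0 with a warning rather than an error.

## Gut-affiliation statistics

Per ORF, abundances are compared across habitat groups with the
Kruskal–Wallis test (tie-corrected, chi-square approximation; identical
values return H = 0, p = 1 with a warning) followed by Dunn's pairwise
z-tests on the pooled ranks with tie correction. Reported group means use
the shifted log transform `log10(y + 1e−5)`, which maps absent ORFs to −5;
because both tests are rank-based, they are identical on raw and
transformed values, so the transform only affects the reported means.

Multiplicity: Dunn p-values are multiplied by the number of pairwise
comparisons and capped at 1 (the Bonferroni-family convention of common
GUI statistics software; Holm is available by option). Flags require the
omnibus Kruskal–Wallis test to be significant at α (default 0.05), the
focal-vs-comparison Dunn adjusted p ≤ α, and the focal group to have the
larger mean rank. An ORF is a *detection candidate* when significantly
greater in the focal (human gut virome) group than in environmental
viromes, an *attribution candidate* when significantly greater than every
other group, and *cosmopolitan* when present in ≥ 50% of data sets. Note
that flags control error per ORF, not genome-wide: across a G-ORF scan the
expected number of false flags on null data is roughly G·α/12, so a
70-ORF null scan still flags ~1 ORF in a quarter of cohorts. Users wanting
genome-wide control should further correct the per-ORF p-values.

## Pollution simulation

Contamination acts in abundance space: `out = env + s · source_mean`
per ORF, with strength s a fraction in [0, 1] (I/O accepts the percent
convention; 100% ↔ 1). The fixed-strength dilution series defaults to
decade steps 100%, 10%, 1%, 0.1%, 0.01% — the endpoints are the modelled
range; the intermediate grid is a configuration choice. Sequencing noise
on contaminated profiles is deliberately not modelled; contamination is an
abundance-space operation.

The Monte-Carlo simulation draws, per iteration, `n_env_per_iteration`
permuted environmental baselines — each ORF independent
`Uniform[0, max observed for that ORF across environmental viromes]` — and,
per source type (human, bovine, porcine), `n_polluted_per_type` polluted
profiles built on *fresh* baselines (so uncontaminated and polluted sets
are independent) with strengths `Uniform[0, 1]`. Defaults are 100
iterations × 100 data sets per type; the acceptance experiments use 1 and
10 iterations, which already give stable estimates at 100 data sets per
type. All randomness flows from one seed via spawned generators.

## Two-step classification

Scores are cumulative *raw* abundances over an ORF subset (no transform:
the sqrt/log transforms belong to ordination and group statistics, and
pollution adds abundance, so larger is more polluted). Prediction is
positive iff score ≥ threshold (inclusive).

ROC curves sweep thresholds over the distinct observed scores plus ±∞;
AUC is the trapezoidal area, equal to the probability that a random
positive outscores a random negative with ties counted ½. Threshold
selection maximises specificity among points with sensitivity ≥ the floor
(default 0.91), breaking ties toward higher sensitivity and then higher
threshold; if the floor is unattainable the error names the best
attainable sensitivity.

The model object (`TwoStepSourceTracker`) calibrates on one designated
iteration — step-1 ROC: polluted of any type vs uncontaminated; step-2
ROC: human vs animal pollution among the truly polluted — and evaluates on
the remaining iterations. Thresholds are selected once on the calibration
iteration and held fixed across evaluation iterations; per-iteration
re-selection can be emulated by fitting one model per iteration. With a
single iteration the model evaluates on its own calibration data (flagged
by the summary's iteration counts). Performance is reported per true type
as mean ± SEM of per-iteration accuracies, plus pooled step-1/step-2
sensitivity and specificity over individual data sets.

## Synthetic data

`generate_cohort` draws habitat-structured cohorts from a zero-inflated
lognormal: per data set and ORF, abundance is 0 with probability
1 − occurrence, else `exp(Normal(ln median, σ))` hits/Mb. Each ORF has an
archetype; parameters depend on (archetype, habitat class):

| archetype | human gut | other gut | environmental |
|---|---|---|---|
| human_gut_specific (ORFs 16, 34, 56) | occ 0.95, med 30 | occ 0.30, med 1 | occ 0.05, med 0.05 |
| gut_shared (remaining detection-subset ORFs) | occ 0.90, med 20 | occ 0.85, med 15 | occ 0.10, med 0.10 |
| cosmopolitan (10 ORFs) | occ 0.90, med 2 | occ 0.90, med 2 | occ 0.90, med 2 |
| background (rest) | occ 0.12, med 0.15 | same | same |

(medians in hits/Mb; σ = 1.0 in the human gut group — the largest
inter-individual variability — and 0.8 elsewhere). Default group sizes are
12 human gut, 8 bovine, 8 porcine and 20 environmental viromes over 70
ORFs. These choices give gut-enriched ORFs tens of hits/Mb in their home
habitats against a sparse sub-1-hits/Mb environmental background, the
ordering human gut > other gut > environmental in cumulative abundance,
and strong but imperfect separability of simulated pollution — the regime
the analysis is designed for. `CohortSpec.null()` flattens all parameters
across groups for calibration checks.

What the generator does *not* emulate: sequence content and alignment
noise (profiles are drawn directly in abundance space), inter-ORF
correlation within a data set (draws are independent given the group),
compositional coupling between ORFs, assembly effects, and geographic
structure within habitats. Tests passing on these cohorts show the
*pipeline* behaves as specified under the assumed statistical structure;
they do not certify performance on real viromes, where the marginal
distribution of per-ORF abundances is unknown.

`generate_hit_table_fixture` inverts profiling for testing: given a target
matrix whose entries are integer hit counts at the declared data set sizes,
it emits hit tables whose valid rows reproduce the target exactly, plus
decoy rows violating exactly one validity threshold each (identity 34.9,
coverage 0.49, or e-value 1.1e−5) to pin the filter boundaries.

## Numerical and edge-case conventions

- All validity-threshold comparisons are inclusive, exactly as stated.
- ANOSIM permutation comparisons use `R_perm ≥ R_obs − 1e−12` to make ties
  robust to floating-point noise.
- SEM uses the n−1 denominator; a single iteration reports SEM 0.
- `log10_shift` rejects negative input; Bray–Curtis and the sqrt transform
  reject negative abundances.
- Degenerate inputs (all-tied distances, all-identical group values) warn
  and return the conventional null value instead of raising, so cohort-wide
  scans are not aborted by one degenerate ORF.

## Problem sizes

The bundled experiments are sized for a desk machine: the separation
experiment uses one iteration of 400 profiles with 999-permutation ANOSIM
(seconds); threshold generalisation uses ten iterations of 400 profiles
(seconds); null calibration uses 500 simulated null data sets for the
ANOSIM type-I check and 500 20-ORF null cohorts for the affiliation scan
(tens of seconds). Full-size runs (100 iterations, 1000-start nMDS on
hundreds of data sets) are configuration changes, not code changes.

## Known limitations

- The affiliation scan's per-ORF error control (see above) reflects the
  GUI-statistics convention it mirrors; genome-wide control is the user's
  responsibility.
- nMDS is a local optimiser; with few starts on difficult geometries the
  reported stress may exceed the global minimum (hence the high default
  start count).
- The exact Dunn adjustment variant of the mirrored convention is not
  uniquely documented; Bonferroni-family multiplication was chosen and
  Holm offered as an alternative.
- Simulated pollution strengths are uniform on [0, 1]; real contamination
  events are likely concentrated at low strengths, where detection is
  hardest — reported accuracies are specific to the uniform-strength
  design.
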