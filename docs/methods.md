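# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations behind `gillsym`.

## The occupancy model and its null

The unit of observation is one host specimen's gill symbiont community: a
subset of a declared pool of `S` candidate symbiont species (default
`S = 7`).  Presence is derived from percent relative abundance by strict
thresholding (`abundance > threshold_percent`); the default threshold is 0,
i.e. any mapped reads count as detection.  Published detection calls of
this kind rarely state a threshold, and the choice changes richness, so the
threshold is configurable and recorded in every output header.  Richness
summaries report the sample (n−1) standard deviation.

The null model throughout is *richness-preserving random assembly*: each
host independently draws a uniformly random `k_i`-subset of the pool, where
`k_i` is its observed richness.  This preserves host-level richness exactly
and removes all species-identity signal.  Three consequences are used:

* the probability that a specific species pair is included in a host of
  richness `k` is `C(S−2, k−2)/C(S, k)`, which simplifies to
  `k(k−1)/(S(S−1))` and is zero for `k < 2`;
* for a pair never observed together, the number of hosts containing both
  is a Poisson–binomial sum with per-host success probabilities `p_i`, so
  the exact p-value for total absence is `∏_i (1 − p_i)`;
* the probability that every host includes at least one of `m` designated
  species is `∏_i [1 − C(S−m, k_i)/C(S, k_i)]`, with `C(S−m, k) = 0` when
  `k > S−m`.  An empty cohort is vacuously guaranteed (probability 1), and
  any aposymbiotic host (richness 0) forces probability 0.

## Monte Carlo randomization

Whole-community patterns are tested by simulation: each replicate redraws
every host's community under the null, and the frequency of each
combination (exact member set, not subset containment) is tabulated.
Defaults: 10 000 replicates, 95% envelopes.  Conventions:

* **Tested family.**  By default every pool subset whose size occurs among
  the group's specimens (`sizes_present`); alternatives are all non-empty
  subsets or only the observed patterns.  BH and Holm corrections are
  computed over this family, and the family choice is recorded.
* **Two-sided p.**  `p = min(1, 2·min(#{null ≥ obs}+1, #{null ≤ obs}+1) /
  (reps+1))`.  The +1 pseudocount keeps Monte Carlo p-values strictly
  positive (floor `2/(reps+1)`); it can be disabled.
* **Envelopes.**  Empirical order statistics at `floor(q·(reps−1))` and
  `ceil((1−q)·(reps−1))` with `q = (1−level)/2` — no interpolation, so
  envelope bounds are achievable counts.
* **Exact cross-check.**  For a fixed combination of size `k`, the null
  count is `Binomial(n_k, 1/C(S,k))` where `n_k` is the number of hosts of
  richness `k`; `exact_combination_null` provides this closed form and the
  test suite holds the Monte Carlo machinery to it.
* **Seeding.**  One `numpy` Generator per randomization; the per-group runs
  of a report derive their seeds deterministically from the report seed.

Subset sampling uses an argpartition of uniform deviates per replicate
(equivalent to a uniform random `k`-subset), with communities encoded as
bitmasks for counting.

## Correlations and group comparisons

Pearson and Spearman correlations (prevalence vs zero-inclusive mean
abundance) use the textbook product–moment form with two-sided p from the
t-distribution on n−2 df; Spearman applies the same t-approximation to
mid-rank correlations for all n, matching the default behaviour of the
common reference implementations.  Kruskal–Wallis applies the standard tie
correction and reports H = 0, p = 1 when all pooled values are identical
(degenerate synthetic inputs should pass through, not fail).  Dunn's post
hoc z-statistics use the tie-corrected pooled variance of mean-rank
differences, two-sided normal p-values, Holm adjustment across all
`g(g−1)/2` pairs, and an insert–absorb compact letter display: groups
sharing a letter are pairwise not significantly different, and every
non-different pair shares a letter.  Multiple-testing corrections operate
on whatever vector the caller supplies — the caller defines the family.

## Gene-content constraints

A genome is predicted to fix nitrogen iff it carries all six essential
core *nif* classes (*nifH, D, K, E, N, B*) out of the 17 recognised
classes; regulatory (*nifA, L*) and accessory (*nifM, S, T, U, V, W, Q, Z,
J*) classes never affect the call — *nifJ* in particular occurs in
non-diazotrophs.  Unknown class labels are preserved with a warning rather
than rejected, to admit other systems.

Core gene-set bounds follow from sufficiency: every community observed in
a living host must supply all symbiont-dependent functions.  Only the
inclusion-minimal observed communities (the antichain) bind, so the core
is the intersection over the antichain of each community's union gene set.
This generalises the manual choice of single-species communities plus the
smallest observed multi-species community, and reproduces it on data where
such communities occur.  "Lignocellulose-active" CAZyme subfamilies are
those whose substrate tags intersect a flat controlled vocabulary
(cellulose, xylan, mannan, β-glucan, xyloglucan, arabinan, galactan,
lignin, and their oligosaccharides); subfamilies without substrate tags
count as non-matching and are reported, not fatal.  Diversity versus
richness defaults to the per-metagenome union (one value per specimen: the
lignocellulose-active subfamily count of the union of its members'
catalogs); a `per_mag` mode contributes one value per member genome
instead, since per-genome and per-metagenome definitions both appear in
practice and differ whenever communities overlap in content.

dbCAN overview tables are filtered to calls supported by at least two of
the three annotation methods, with coordinate suffixes stripped from
subfamily tokens.

## Species delimitation

FastANI-style records are asymmetric; reciprocal values are symmetrized by
arithmetic mean (configurable to min/max; a single direction is used
as-is).  An edge joins genomes at gANI > 95 and AF > 0.60, and species are
connected components (single-linkage).  With strongly bimodal identity
distributions (high within, unreported between) the linkage choice is
inert, but it matters for borderline datasets and is therefore explicit.
Missing pairs count as below threshold, mirroring fragment-mapping ANI
tools that do not report distant pairs.  Representatives maximise
completeness − 5 × contamination (the common MIMAG-style dereplication
score), ties broken by lower strain heterogeneity, then id.

## The synthetic-data generator

Defaults emulate the reference study design: host groups Lp (14) and Tb
(22); pool of 7 species with fixers {sp1, sp2, sp4}; per-group richness
distributions Lp = (0.15, 0.50, 0.35) over k = 1..3 and
Tb = (0.10, 0.35, 0.35, 0.15, 0.05) over k = 1..5, chosen once to match
the reported group means and spreads (2.2 ± 0.7 and 2.7 ± 1.0).
Communities are k-subsets drawn with probability proportional to their
enrichment weight (uniform under the empty default); `require_fixer` uses
rejection sampling so the richness marginal is untouched, with the
acceptance rate recorded.  Within-host relative abundances are symmetric
Dirichlet (concentration 1.0); total depth is log-normal around 10⁶ reads
(σ = 0.3, arbitrary but recorded); counts are multinomial.  Planted
catalogs: fixers carry all 17 *nif* classes except that one random fixer
loses *nifJ* (never an essential class), one random non-fixer carries
*nifJ* alone; CAZyme catalogs share a planted core (default 58
subfamilies, 23 lignocellulose-tagged) plus 20 private subfamilies per
taxon, half lignocellulose-tagged.  ANI simulation draws within-cluster
gANI ~ U(97, 100) and AF ~ U(0.85, 1.0) in both directions and omits
between-cluster records by default.

What the generator does *not* emulate: taxonomic read misassignment,
uneven genome sizes (read share equals cell share here), host-group
effects on community identity beyond richness, strain-level variation
within a symbiont species, and compositional noise from assembly/binning.
Passing tests therefore demonstrate correctness of the statistical
machinery under the model's assumptions, not robustness to those upstream
artefacts.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale sizes chosen for tight oracles:
exact-enumeration checks at ≤ 4 specimens and S ≤ 5 (where full enumeration
over all richness-preserving assignments is feasible); Monte Carlo
calibration at 21 richness-2 specimens (null mean 1.0 per pair by
construction); error-control and power measurements over 50 seeded
cohorts of 36 and 22 specimens at 10 000 replicates.  Percent tables are
serialized with 4 decimals; all numeric comparisons in tests use
tolerances, never string equality.  Empirical power for a planted triplet
at enrichment weight 10 in a 22-specimen group is ~0.5, not higher: with
inclusion probability 10/44 the expected count (~5) sits near the smallest
value whose Holm-corrected Monte Carlo p across the 35-triplet family can
clear 0.05, so roughly half of cohorts fall short.  Detecting such an
effect reliably (≥ 80% power) needs enrichment weights of roughly 15 or
more at this sample size.

## Known limitations

* The null model treats hosts as independent and the pool as closed; it
  cannot express prevalence-weighted or abundance-weighted nulls
  (fixed-fixed swaps, C-score) — deliberately, as the equal-probability
  null is the model under test.
* The exact pair-absence test conditions on observed richness and is
  undefined for pairs that were observed together (use the Monte Carlo
  table for those).
* Compact letter displays are not unique; the insert–absorb construction
  is deterministic but other valid letterings exist.
* `sufficient_communities` assumes detection is complete: a missed
  low-abundance member would make a community look smaller (and more
  binding) than it is.
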