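# Methods

## Model and procedure

The unit of analysis is a *graph database*: N undirected simple graphs on
one shared vertex set (the ROI atlas), one graph per subject, each subject
carrying a group label. A *clique pattern* is a set of k ≥ 2 vertices
identified with the complete graph on them; a graph *contains* the pattern
when all k(k−1)/2 implied edges are present. Support is the number of
containing graphs; frequency is support / N.

The pipeline has four stages:

1. **Mining** — every pattern with frequency ≥ θ, reported as the
   redundant, downward-closed family (all sub-cliques listed). Redundancy
   is deliberate: per-ROI appearance counts and the group comparison both
   operate on this family, and sub-cliques of a strong clique are findings
   in their own right.
2. **Split-half robustness** — partition subjects by parity of the
   second-from-right digit of the numeric subject ID, mine each half at θ,
   keep the intersection of the two families, recount survivors on the
   full cohort. The intersection of two downward-closed families is
   downward-closed, so the retained family keeps the anti-monotonicity
   invariant. Full-cohort frequencies may fall below θ after the recount
   and are reported as-is, without a second filter.
3. **Group comparison** — candidates are the union of the two per-group
   mined families (a pattern can be frequent in one group yet fall below θ
   cohort-wide, which is exactly the interesting case). A pattern is
   tested only if its larger group support is ≥ 80%. The test is the
   Pearson χ² on the 2×2 count table, without Yates continuity correction,
   at 1 df; the family of all tested patterns, both directions jointly, is
   Holm-corrected at α = 0.01.
4. **Summaries** — size histogram, hemisphere composition (a pattern is
   left/right when all its ROIs share that hemisphere prefix, mixed when
   both occur, unknown when any ROI is unclassifiable), maximal cliques
   present in every subject, maximal cross-hemisphere cliques, and
   appearance counts of named ROIs over the redundant family.

## Algorithmic notes

*Candidate generation.* Level k+1 joins two frequent k-patterns sharing
their first k−1 vertices, with last vertices in ascending order; each
candidate therefore arises exactly once, and only the edge joining the two
last vertices is new. The implementation keeps, per pattern, the bitmask
of supporting subjects; a candidate's mask is `mask(L1) & mask(L2) &
mask(new edge)`, so support counting never rescans graphs. Completeness
follows from anti-monotonicity: both join parents of a frequent
(k+1)-clique are frequent k-cliques.

*Exact threshold arithmetic.* θ is held as a rational p/q (floats are read
through their decimal representation, so 0.8 is exactly 4/5) and the
frequency test is the integer comparison `count·q ≥ p·N`, inclusive. With
N = 413 and θ = 80% this means support ≥ 331; a pattern at exactly 4/5 of
the cohort passes. No floating-point frequency is ever compared.

*Reference miner.* `brute_force_mine` enumerates all vertex subsets of
size 2..n (guarded to n ≤ 20) with a per-graph containment test, prefiltered
by the union adjacency of the database; it shares no code path with the
apriori miner and serves as the equivalence oracle in the tests. It stops
at the first clique size with no frequent pattern, which is sound by
downward closure.

*χ² statistic.* The 2×2 statistic is evaluated from the closed-form
determinant expression in exact integer arithmetic, with a single float
division at the end; it is algebraically identical to Σ(O−E)²/E and the
tests verify agreement to 1e-9 relative error on 10⁴ random tables. When
both margins are degenerate (both supports exactly 0% or exactly 100%) the
denominator vanishes; no difference is claimable there and the statistic
is defined as 0 (p = 1).

*Holm step-down.* The i-th smallest of m raw p-values is multiplied by
m−i+1, a running maximum enforces monotonicity, values are capped at 1,
and significance is adjusted p ≤ α (inclusive). This is uniformly more
powerful than plain Bonferroni while controlling family-wise error; the
tests cross-check it against statsmodels' implementation.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` θ | 0.80 | minimum frequency (fraction of subjects); rational, inclusive |
| `max_size` | unlimited | cap on clique size; mining halts naturally at the first empty level |
| `digit_position` | 2 | ID digit (from the right) whose parity defines the deterministic split |
| `subset_size`, `runs` | 50, 20 | per-draw cohort size and repetitions of the randomized crosscheck |
| `alpha` | 0.01 | family-wise level of the Holm procedure |
| `inclusion_threshold` | 0.80 | the larger group support must reach this for a pattern to be tested |

## Synthetic data

The generator emulates what the analysis assumes about real cohorts and
nothing more: a fixed atlas, per-subject graphs formed as the union of
(a) planted cliques, each included wholesale with a group-specific
Bernoulli probability per subject, and (b) independent background edges
with probability `background_edge_prob`. Defaults: 30 vertices, groups of
238 (`female`) and 175 (`male`) — cohort sizes typical of the diffusion-MRI
studies this pipeline targets and large enough for realistic power at
θ = 0.80 — background edge probability 0.02 (sparse-connectome-like: at
N ≥ 100 subjects the binomial tail probability of a background edge
reaching 80% support is astronomically small, giving clean ground truth),
labels split half `Left-`/`lh.` and half `Right-`/`rh.` so both hemisphere
prefix conventions are exercised, and six-digit numeric subject IDs whose
second-from-right digit alternates parity so the deterministic split
produces balanced halves.

`expected_recovery` declares a planted clique expected-frequent when its
group-size-weighted mean inclusion probability is at least θ plus a margin
(default 0.05), keeping binomial noise away from the cutoff, and refuses
configurations whose background alone is expected to create frequent edges
(exact binomial tail bound, tolerance 0.01 expected edges).

What the generator does **not** model: tractography and registration
error, edge weights, spatial/geometric structure, correlated edge noise,
and inter-regional degree heterogeneity. Passing recovery tests therefore
demonstrates correctness of the mining/statistics machinery under the
planted-clique model, not robustness to real acquisition artifacts.

## Problem sizes used in verification

Randomized miner-vs-oracle equivalence runs on 100 databases of up to 14
vertices and 50 graphs at mixed densities (the enumeration oracle is the
binding constraint — subset enumeration grows as 2ⁿ). Recovery and
sex-difference detection use 20 seeds at the default 238 + 175 cohort with
30 vertices. The family-wise error simulation uses 500 seeds (300 in the
acceptance script) of a small global-null database — two groups of 50,
eight vertices, four planted triangles at equal probability 0.9 — and
bounds the observed any-rejection rate by α + 3 Monte-Carlo standard
errors; the χ² approximation at these counts is slightly conservative,
and observed rates sit well below α.

## Design choices on genuinely open points

- **Inclusive threshold.** "At least 80%" is read inclusively at exactly
  θ·N; the exact-rational comparison makes the choice well-defined.
- **Comparison candidates.** Patterns frequent in *either* group are
  tested (union of per-group families), since the inclusion rule speaks of
  the larger group frequency; both this entry point and testing a
  pre-mined (e.g. robust) family are exposed.
- **Joint Holm family.** The correction spans both directions of
  difference in one family, the conservative reading; per-direction
  correction would only enlarge the rejection set.
- **ROI counts over the redundant family.** Counting maximal patterns
  only would give smaller numbers; the summary tables record which family
  was counted.
- **Group naming.** Group-1/group-2 assignment is explicit and outputs
  label groups by name, never by position, to avoid silent swaps.

## Known limitations

- The miner's bitmask representation holds one Python integer of N bits
  per live pattern; databases of tens of thousands of subjects would
  warrant a chunked representation.
- The enumeration oracle is exponential in the atlas size and guarded to
  20 vertices; it exists for verification, not analysis.
- Hemisphere classification is prefix-based (`lh.`/`rh.`,
  `Left-`/`Right-`); atlases with other conventions classify as
  `unknown` and should supply their own mapping upstream.
- χ² p-values are asymptotic; at very small group sizes or extreme
  supports an exact test would be preferable (deliberately out of scope).
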