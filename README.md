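# braincliques

Frequent complete-subgraph analysis for human structural connectomes.

A structural connectome (braingraph) is an undirected graph whose vertices
are anatomically labeled gray-matter regions (ROIs) and whose edges mark
axonal fiber connections found by diffusion-MRI tractography. Individual
braingraphs are noisy: tractography, segmentation, and parcellation all
introduce spurious or missing edges. A *complete subgraph* (clique) that
recurs in a large fraction of subjects, however, is very unlikely to be an
artifact — it is a robust structural motif of the brain network. This
package finds those motifs in a database of subject-level graphs and tests
whether their frequencies differ between two subject groups (typically the
sexes).

It is aimed at researchers analyzing cohorts of braingraphs (or any
database of node-aligned undirected graphs) who need frequent-clique
families with exact support counts, robustness filtering, and group
comparison with family-wise error control.

## The method

**Mining.** A pattern is a vertex set `v_1 < v_2 < … < v_k` whose every
pair is joined by an edge; its *support* is the number of database graphs
containing all `k(k−1)/2` implied edges, and its *frequency* is
support / N. The miner returns every pattern with frequency ≥ θ (default
θ = 0.80), level-wise in the apriori style: level 2 is the frequent edges,
and a `(k+1)`-candidate is generated from two frequent `k`-patterns that
share their first `k−1` vertices — only the single new edge
`(v_k, v_{k+1})` needs checking, and the ascending-order convention
generates each candidate exactly once. Correctness rests on
anti-monotonicity: every sub-clique of a frequent clique is at least as
frequent, so the reported family is downward-closed by construction.
Frequency comparisons use exact rational arithmetic (`count·q ≥ p·N` for
θ = p/q), so borderline supports never depend on float rounding. Per-pattern
supporting-subject bitmasks make candidate verification a pair of AND
operations.

**Robustness.** The cohort is split into two disjoint halves by the parity
of a digit of the numeric subject ID (default: second from the right);
only patterns frequent in *both* halves are retained, and their
frequencies are then recounted on the full cohort. A randomized variant
draws two disjoint equal-size subsets from a single group, repeatedly, to
check that results are not driven by group-size imbalance.

**Group comparison.** For pattern F with per-group counts `count_i` and
group sizes `S_i`, supports `supp_i = count_i / S_i` are compared with the
Pearson χ² statistic (no continuity correction) on the 2×2 table
`[[count_1, S_1−count_1], [count_2, S_2−count_2]]`, referred to χ²(1 df).
Candidates are patterns frequent in at least one group; only patterns
whose *larger* group support reaches 80% are tested. Multiplicity over the
tested family is controlled by the Holm–Bonferroni step-down at α = 0.01.

**Synthetic ground truth.** A generator plants cliques — full edge sets
included per subject with group-specific Bernoulli probabilities — over a
sparse random background, with hemisphere-prefixed ROI labels
(`lh.`/`rh.`, `Left-`/`Right-`) and numeric subject IDs, so every pipeline
stage can be validated against known structure.

## Worked example

```python
from braincliques import (
    MiningConfig, PlantedClique, SyntheticConfig, compare_groups,
    format_pattern, generate_database, maximal_patterns,
    robust_frequent_cliques, two_group_candidates,
)

config = SyntheticConfig(
    n_vertices=16,
    group_sizes={"female": 238, "male": 175},
    planted=[
        PlantedClique((0, 1, 2, 3), {"female": 0.95, "male": 0.95}),
        PlantedClique((5, 6, 7), {"female": 0.55, "male": 0.95}),
    ],
    background_edge_prob=0.02,
    seed=42,
)
db = generate_database(config)

records = robust_frequent_cliques(db, MiningConfig(threshold=0.8))
print(f"{len(records)} frequent patterns survive the split-half filter")
for rec in maximal_patterns(records):
    print(f"  {format_pattern(rec.pattern, db.atlas)}  "
          f"support {rec.count}/{rec.n_graphs} = {float(rec.frequency):.3f}")

candidates = two_group_candidates(db, MiningConfig(0.8),
                                  group1="male", group2="female")
for c in compare_groups(candidates, db, group1="male", group2="female",
                        alpha=0.01):
    if c.significant:
        print(f"  {format_pattern(c.pattern, db.atlas)}  "
              f"male {float(c.supp1):.2f} vs female {float(c.supp2):.2f}  "
              f"chi2={c.chi2:.1f}  p_holm={c.p_holm:.2e}")
```

Output:

```
11 frequent patterns survive the split-half filter
  (Left-Sub01)(Left-Sub02)(lh.region_001)(lh.region_002)  support 394/413 = 0.954
  (lh.region_004)(lh.region_005)  male 0.96 vs female 0.55  chi2=84.7  p_holm=5.32e-19
  (lh.region_004)(lh.region_006)  male 0.96 vs female 0.56  chi2=82.1  p_holm=1.66e-18
  (lh.region_005)(lh.region_006)  male 0.96 vs female 0.56  chi2=82.1  p_holm=1.66e-18
  (lh.region_004)(lh.region_005)(lh.region_006)  male 0.96 vs female 0.55  chi2=84.7  p_holm=5.32e-19
```

The clique planted in both sexes at probability 0.95 is recovered as the
single maximal frequent pattern (observed support 0.954 of 413 subjects,
within binomial noise of the planted probability), and the clique planted
at 0.95 in males but 0.55 in females is flagged male-higher — together
with its three edges, since the mined family is downward-closed — at Holm-
adjusted p ≈ 5×10⁻¹⁹, matching the expected χ² ≈ 80 for those supports
and cohort sizes.

The same pipeline runs from the shell on edge-list files (`braincliques
generate | mine | compare | crosscheck | summarize`); see
`braincliques --help`.

## Limitations

The package analyzes presence/absence of edges only (weights are ignored),
and the synthetic generator does not model tractography noise,
inter-subject registration error, or spatial structure — see
`docs/methods.md` for the full account of assumptions, parameters, and
numerical choices.
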