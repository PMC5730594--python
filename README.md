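# funcsens

Functional sensitivity of fish assemblages to species extinction.

`funcsens` is a Python library and command-line tool for community ecologists
who want to ask: *if species disappear from an assemblage in a particular
order, how fast does its functional diversity erode, and is that faster than
chance?* It was built around freshwater and estuarine fish communities
described by categorical traits, but works for any species pool with a mixed
nominal/ordered trait table.

## The method

1. **Functional space.** Species are described by five categorical traits
   (body size as an ordered factor with six classes; vertical position,
   trophic group, spawning habitat and swimming mode as nominal factors).
   Pairwise dissimilarity is the Gower index
   `d(a, b) = (1/T) Σ_t d_t(a, b)`, where a nominal trait contributes 0/1 and
   an ordered trait with levels ranked `1..L` contributes
   `|r_a − r_b| / (L − 1)`.
2. **Functional dendrogram.** UPGMA (average linkage) clustering of the Gower
   matrix yields an ultrametric tree; its fidelity is reported as the
   cophenetic correlation *c* with the input dissimilarities. Functional
   richness (FD) of any species set is the total branch length of the minimal
   subtree spanning those species up to their most recent common ancestor, so
   FD(singleton) = 0 and FD can only decrease when species are removed.
3. **Extinction scenarios.** Six removal orders per assemblage: *random*
   (999 trajectories; their mean AUC is the functional-redundancy index),
   greedy *best-* and *worst-case*, *abundance-based* (rarest first),
   *trait-based* (highest intrinsic vulnerability score, 0–100, first) and
   *IUCN-based* (Red List clusters, CR → EN → VU → NT → LC). Each trajectory
   yields a loss curve of residual FD proportion against the proportion of
   species lost; the area under the curve (AUC ∈ [0, 1]) summarises
   sensitivity — low AUC means early, steep functional loss.
4. **Null comparison.** Directional scenarios are scored against the random
   null by a standardised effect size, `SES = (Obs − Mean_r) / sd_r`; the
   IUCN scenario is compared to random clusters of matching sizes. One-sided
   Wilcoxon tests ask whether SES values across assemblages fall below zero.
5. **Saturation.** OLS of FD on species richness with a quadratic term tests
   whether FD saturates in species-rich assemblages (functional redundancy).

A seeded synthetic-data generator produces species pools, assemblages with
realistic richness ranges and heavy-tailed abundances, and vulnerability
scores with a tunable rank-correlation to functional distinctiveness, so the
whole pipeline is testable end to end without survey data.

## Worked example

```python
import numpy as np
import funcsens as fs

# three species: A and B similar (d = 0.2), C distinct (d = 0.6 to both)
D = fs.DissimilarityMatrix(
    np.array([[0, .2, .6], [.2, 0, .6], [.6, .6, 0]]), ["A", "B", "C"])
tree = fs.build_upgma_dendrogram(D)
print(tree.functional_richness({"A", "B", "C"}))   # 1.4
print(tree.functional_richness({"A", "B"}))        # 0.4

asm = fs.Assemblage(site_id="toy", system="river",
                    abundances={"A": .01, "B": .5, "C": .2})
worst = fs.greedy_trajectory(tree, asm.species, "worst")
curve = fs.loss_curve(tree, asm, worst)
print(fs.trapezoid_auc(curve))                     # 0.3928571428571429
print(fs.redundancy_index(tree, asm, n=999, seed=0))  # 0.5853353353353354
```

The worst-case order removes the functionally singular species C first: FD
drops from 1.4 to 0.4 after one of two removals, giving AUC ≈ 0.393, well
below the random expectation of 0.583 (exact mean over all six orders:
7/12) — this assemblage's function is concentrated in one species. The
Monte-Carlo redundancy index (0.585) agrees with the exact value to within
sampling error.

A full synthetic study from the command line:

```
funcsens all --seed 1 --out results/study \
    --config myconfig.yml     # optional; defaults emulate the survey layout
```

writes `scenario_results.csv` (one row per site × scenario with AUC and SES),
`site_summary.csv`, `saturation.csv`, `spearman.csv`, `group_comparisons.csv`,
`ses_tests.csv` and the dendrogram in Newick format. `funcsens simulate`,
`dendrogram`, `scenarios` and `stats` run the individual stages.

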