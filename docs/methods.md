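# Methods

This note documents the models, conventions and design choices behind
`funcsens`, and what the synthetic-data tests do and do not demonstrate.

## Functional space and dendrogram

Species are points in a five-trait categorical space: body size (six ordered
classes of maximum total length: 0–8, 8.1–15, 15.1–30, 30.1–50, 50.1–80,
>80.1 cm), vertical position (benthic / non-benthic), trophic group (seven
categories), spawning habitat (six) and swimming mode (eight). The Gower
dissimilarity weights the five traits equally; the ordered size trait is
coded as equally spaced ranks scaled by its range (`|r_a − r_b| / (L − 1)`),
the classical treatment of ordered factors in the Gower index. Dissimilarity
is therefore in [0, 1] and equals 0 exactly when two species share their full
trait vector.

UPGMA (average linkage) is implemented in-package rather than delegated to a
library because reproducibility demanded a fixed tie rule: among cluster
pairs at exactly minimal average dissimilarity, the pair whose smallest
member labels sort first lexicographically is merged. Trees are therefore
bit-identical across runs and input orderings. Tests cross-check cophenetic
distances against an independent average-linkage implementation on tie-free
random matrices.

One dendrogram is built over the full species pool per run and reused for
every assemblage, mirroring a single pool-wide distance matrix and a single
cophenetic coefficient.

## Functional richness of a subset

FD of a species set is the total branch length of the minimal spanning
subtree up to the set's most recent common ancestor (LCA). Equivalently, an
edge contributes its length iff its subtree contains *some but not all* of
the subset's leaves. The LCA convention (rather than connecting to the global
root) guarantees FD(singleton) = 0, which the extinction simulation requires
as its terminal state; it also makes FD monotone under subset inclusion.

For repeated evaluation the pool tree is restricted per assemblage to the
induced subtree with degree-two paths contracted (≤ 2S − 1 nodes for S
species), and FD of many subsets is evaluated as one matrix product over a
leaf-membership incidence matrix. The direct pool-tree computation is kept as
an independent code path and the two are required to agree to 1e−12 in tests.

## Loss curves, AUC and the axis convention

A trajectory removes species (singly, or in clusters for the Red List
scenario) until at most one remains. The loss curve plots residual FD
proportion against the proportion of species lost. The abscissa normalises by
S − 1, so the last observable state (one species, FD = 0) sits exactly at
x = 1 and a two-species assemblage has AUC = 1/2 under any order. The
alternative normalisation by S, with an appended terminal point at (1, 0), is
available as `axis="per-species"` everywhere a curve is built. AUC is the
trapezoidal integral over x ∈ [0, 1].

Cluster trajectories place one point per cluster at cumulative-removed /
(S − 1), capped at 1; FD is recorded once per cluster.

## Scenarios

- **random** — uniform-random orders; the mean AUC of `n_random` (default
  999) trajectories is the functional-redundancy index, and the same draws
  provide the null for the abundance- and trait-based SES (one shared null
  per assemblage rather than fresh draws per scenario).
- **best / worst** — greedy: at each step every candidate removal's FD loss
  is evaluated and the arg-min / arg-max removed. Ties within 1e−12 resolve
  to the smallest species identifier. Greedy is a per-step heuristic; the
  globally optimal order is out of scope and tests only assert that greedy
  stays within the exhaustive min/max envelope.
- **abundance** — ascending standardised abundance (rarest first).
- **trait** — descending intrinsic vulnerability (0–100 composite score).
- **iucn** — clusters in the order CR > EN > VU > NT > LC; data-deficient and
  not-evaluated species are folded into LC, so they are removed last. Its
  null randomly partitions the assemblage into clusters of the same sizes.
  When every species falls in one category the null is degenerate (SD = 0)
  and the SES is reported as missing rather than fabricated.

`SES = (Obs − Mean_r) / sd_r` uses the sample SD of the replicate AUCs; the
exhaustive-enumeration test oracles use the population SD and say so.

Randomness: one master seed; each assemblage derives an independent seed
stream from the master seed and a CRC-32 of its site id, so results do not
depend on processing order and per-assemblage work could be parallelised
without changing output.

## Data model and survey conventions

Densities follow system conventions: estuaries individuals / 1000 m²,
lakes individuals / m² of net per night (CPUE), rivers individuals / m².
Sampling events of one site are pooled as total counts over total effort
(effort-weighted, invariant to proportional splitting of a sample), not as a
mean of per-sample densities. River sites enter the analysis only with
fished area > 100 m² and > 50 individuals caught (both strict; the count
filter applies to the pooled site total). Lakes and estuaries are classed
small/large at 0.68 km² and 25 km² respectively, boundary values to large.
Missing trait values are rejected outright; imputation is out of scope.

## Statistical stages

- **Saturation**: OLS `FD ~ SR + SR²` with the quadratic term's t-test
  (equivalent to the one-restriction partial F-test). Saturation is flagged
  only when the term is significant *and* negative (concave fit): a
  significant positive quadratic coefficient is convexity, not saturation, so
  both the raw coefficient and the flag are exposed and the caller can apply
  either reading.
- **Group comparisons**: Kruskal–Wallis omnibus; pairwise two-sided Wilcoxon
  rank-sum (Mann–Whitney) tests, Bonferroni-adjusted; a compact letter
  display marks groups that are statistically indistinguishable. scipy's
  implementations are used, with exact small-sample distributions where scipy
  provides them.
- **SES tests**: one-sided (less-than-zero) Wilcoxon signed-rank across
  assemblages, per system and per region/category scope, requiring ≥ 5
  non-missing SES values.

## Synthetic generator

The generator emulates the structure the analysis assumes: a 271-species
pool; per-system assemblage richness ranges (estuaries 4–57, lakes 3–19,
rivers 3–31); lognormal relative abundances (meanlog 0, sdlog 1.5), giving a
few dominants and a long rare tail; category frequencies within each trait
decaying geometrically (decay 0.7) so that some trait states are common and
others rare, which yields realistic levels of trait sharing. Site counts
default to the survey layout (49 estuaries, 302 lakes, 869 rivers); tests and
the acceptance script use smaller site counts chosen to exercise every code
path at comfortable runtimes, and state the sizes they use.

Vulnerability scores (0–100) are generated by a Gaussian copula so that their
Spearman correlation with functional distinctiveness — a species' leave-one-
out FD loss on the pool tree, exactly the quantity the worst-case scenario
exploits — targets the `coupling` parameter (ρ_Pearson = 2 sin(π·coupling/6),
pinned to ±1 at the endpoints so ties stay tied). IUCN categories are
assigned by vulnerability quantiles with proportions LC 0.70, NT 0.12,
VU 0.10, EN 0.05, CR 0.03, a typical Red List mix dominated by least-concern
species.

What the generator does *not* emulate, and hence what passing tests do not
show about real data:

- Trait correlations of real fish faunas. The synthetic pool's cophenetic
  correlation comes out near 0.6, below the ~0.74 of the real trait table;
  reproducing that value requires the real dataset (see the red check in
  `tests/test_acceptance.py`).
- Nested community assembly. Species enter assemblages uniformly at random,
  so richer synthetic assemblages are not systematically more redundant; the
  positive redundancy–richness correlations seen in real surveys are not a
  generator property, and the pipeline's correlation stage is validated on
  its own terms instead.
- Spatial structure, gear catchability, seasonal effects.

A caveat on the coupling-recovery check: all assemblages share one global
vulnerability draw, so their SES values are positively correlated. Under
neutral coupling a single unlucky draw can align with distinctiveness and
produce a spuriously significant one-sided test; with the full 271-species
pool this shared-draw variance is small, which is why the calibration checks
are run at that pool size.

## Numerical choices

- Dissimilarities validated symmetric within 1e−12, clipped to [0, 1].
- Loss-curve ordinates are clipped to [0, 1] and the intact point pinned to
  y = 1 to absorb last-bit BLAS nondeterminism between batched and single
  evaluations.
- Degenerate assemblages (FD = 0 with ≥ 2 species, i.e. all trait vectors
  identical) are skipped with a logged reason and appear in the
  `skipped_assemblages` table; they are never silently dropped.
- The exhaustive AUC oracle refuses S > 7 (factorial growth).

## Problem sizes used in checks

Enumeration-vs-Monte-Carlo agreement uses 50 assemblages with S ≤ 6 and
999 random draws; null calibration uses 200 assemblages (999-draw nulls plus
one held-out draw); coupling recovery uses 200 river-like assemblages at
couplings 0.8 and 0.0 with 999-replicate nulls; the saturation power check
uses 300 sites × 200 simulations. The acceptance script runs the full
six-scenario study over 210 assemblages (30 estuaries, 60 lakes, 120 rivers)
plus a 120-river neutral control.
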