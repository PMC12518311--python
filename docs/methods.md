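# Methods

## Scope and model

`phytoscreen` models compound activity against gastric-cancer cell lines as
four independent binary classification problems over hashed circular
fingerprints, then combines the per-cell-line predictions into a consensus
score for virtual screening and plant-source prioritization. The underlying
assumptions are the standard ones for phenotypic QSAR at this scale:

* activity is a deterministic function of 2-D structure (stereochemistry is
  deliberately discarded — chiral annotations are inconsistent across source
  databases and the fingerprints cannot see them anyway, so enantiomers are
  treated as one compound);
* an IC50 threshold of 10 µM separates active from inactive, with the active
  class defined strictly as `IC50 < 10 µM` (a value exactly at the threshold
  is inactive — the active class is the strict inequality and the complement
  absorbs equality);
* replicate measurements are trustworthy only when they agree in class;
  values are never averaged, because averaging µM-scale IC50s across assay
  protocols mixes incompatible experiments.

## Curation rules

Standardization keeps the largest covalent fragment (salt stripping),
removes stereocenters, sanitizes, and keys the molecule by the InChIKey of
the resulting canonical form. Unparsable records are dropped with a reason
code; every input row is accounted for as kept, reserved, or excluded, and
the counts sum to the input size. Compounds with retained labels in three or
more distinct cell lines are withheld from all training pools and reserved
for virtual screening, where cross-cell-line consensus is exactly what is
being evaluated.

## Dataset construction

* **Fingerprints** — 1,024-bit Morgan fingerprints of radius 2 (ECFP4
  equivalent). Only this representation is supported.
* **Balancing** — the majority class is undersampled by k-means: k is
  scanned from 2 up to the minority size (optionally capped; the cap trades
  scan breadth for runtime and the planted-structure tests use a cap of 8),
  the silhouette-optimal k wins with ties broken toward smaller k
  (parsimony), and each cluster contributes a largest-remainder-proportional
  number of uniformly drawn compounds. Largest-remainder apportionment is
  used because it sums exactly to the minority size and never exceeds a
  cluster's population; remainder ties go to the larger cluster, then the
  lower index, making the allocation deterministic. Degenerate majorities
  (all rows identical) fall back to plain random sampling with a log entry.
* **Split** — random, label-agnostic 60/20/20 train/test/external
  assignment via a seeded permutation. Stratification is deliberately not
  applied; the preceding balancing step keeps partitions near parity.
  Fewer than 10 compounds is rejected (a partition would be empty).
* **Variance filter** — binary columns with population variance
  (`p(1-p)`, divide-by-n) strictly below 0.05 on the training partition are
  removed; the kept-column list is applied unchanged to every other
  partition and to screening inputs.
* **Applicability domain** — PCA on the mean-centered (not rescaled — all
  bits share a scale) filtered training bits; the component count is the
  smallest explaining more than 90% cumulative variance; the domain radius
  is the maximum training Euclidean distance to the centroid of training
  projections, so all training compounds are in-domain by construction.
  Containment uses a 1e-9 relative tolerance so training rows are never
  excluded by floating-point jitter. Test and external metrics are always
  computed on in-domain rows only.

## Classifiers and the GA

Three families: random forest (100 Gini trees, depth capped at 100),
decision tree (Gini, grown until leaves are pure or hold a single sample),
and 5-nearest-neighbors (Euclidean on the selected bits; the neighbor count
is a free choice documented here, configurable). Probabilities are the tree
vote fraction, leaf class frequency, and neighbor vote fraction
respectively; the classification threshold is `p > 0.5`.

Variable selection is a genetic algorithm over 4–25-bit subsets with fitness
`BCR = ((Se+Sp)/2)(1−|Se−Sp|)` evaluated on the in-domain test partition.
The penalty term makes the fitness punish sensitivity/specificity imbalance;
note this means a no-signal classifier does not center on 0.5 — skewed
chance-level predictors score well below it, which is why the test suite
judges no-signal behavior against an explicit permutation null rather than
a fixed band. Operator choices (unconstrained by any stated requirement, so
fixed here and recorded in run manifests): tournament selection of size 3,
uniform set crossover at rate 0.9 with shared genes kept and disputed genes
tossed at ½, per-gene swap mutation at rate 1/|chromosome|, repair to the
4–25 window, elitism of 1 (making the best-fitness trace non-decreasing).
Fitness evaluations are cached by chromosome, so converged populations are
cheap. Full-budget defaults are a population of 1,000 over 5,000
generations; all results shipped with the package use the scaled
configuration (population 50, 50 generations) on 400-compound synthetic
datasets, and every such report states the mode.

Cross-validation is deliberately absent: models train on the training
partition, evolve against the test partition, and are reported on the
external partition, which no fitness computation may touch (the test suite
verifies this by corrupting external data and checking the evolved
population is unchanged).

## Ensembles

A pool (default 200 members; scaled runs use 20) is filled by drawing a
uniform algorithm family and a uniform-size random variable subset,
admitting candidates whose test BCR exceeds 0.65. Random generation plus
qualification is the minimal faithful construction; a pool can also be
seeded from GA variable-selection output. Exhausting the attempt budget
raises an explicit shortfall error — the signal that the dataset is
unlearnable or the floor too high. Ensembles are subsets of 2–20 pool
members aggregated by the arithmetic mean of member probabilities (no
weighting, no stacking), evolved by the same GA operator suite with fitness
equal to the aggregated test BCR. Duplicate member sets may coexist during
evolution; the final ranking is deduplicated.

## Early-recognition metrics

For a ranked list of N compounds with n actives at 1-based ranks r_i
(Ra = n/N):

```
RIE     = Σ exp(−α·r_i/N) / [ (n/N)·(1−e^(−α))/(e^(α/N)−1) ]
RIE_min = (1 − e^(+α·Ra)) / (Ra·(1 − e^(+α)))
RIE_max = (1 − e^(−α·Ra)) / (Ra·(1 − e^(−α)))
BEDROC  = (RIE − RIE_min) / (RIE_max − RIE_min)
EF(χ)   = #{actives with rank ≤ ⌊χN⌋} / (χ·n)
```

These closed forms make BEDROC exactly 1 when the actives fill the top n
ranks and exactly 0 when they fill the bottom n (an analytic identity the
test suite pins to 1e-9 against brute-force exponential sums). The α↔χ
calibration is `α = −ln(1−m)/χ` for a weight mass m; α = 160.9 concentrates
80% of the weight in the top 1%. The EF window is `⌊χN⌋` with a minimum of
one compound. Score ties are broken by a seeded random permutation before a
stable sort, so tied metrics are reproducible; by default one tie-break draw
is used.

The combination search enumerates one family (RF/DTREE/KNN/ensemble) per
cell line — 256 choices for four lines — and gives each compound the
arithmetic mean of its per-cell-line probabilities. A compound must be
in-domain for **every** model in a combination to be scored; otherwise it is
excluded from that combination's ranking. Combinations are ranked by BEDROC
at the α = 160.9 anchor, with full BEDROC(α) and EF(χ) profiles attached.
Consensus hits are the compounds exceeding a probability threshold
(0.5 / 0.55 / 0.6 by default) in *both* of two consensus models.

## Plant prioritization

Taxonomy lookups parse the pipe-and-tab `fullnamelineage.dmp` dialect and
retain only names whose lineage contains `Viridiplantae`; matching is exact
after case/whitespace normalization (no fuzzy matching), so processed-food
entries simply fail to resolve and are excluded. Associations are
deduplicated per (species, achiral InChIKey), which collapses enantiomers
reported under one species. A compound's hit status is global — it comes
from the consensus score, not from the species context. Species are ranked
both by absolute predicted-active count and by the active fraction of their
reported compounds; genus summaries count unique hit compounds with the
genus defaulting to the first binomial token. Chemical-class composition is
reported only when an external annotation column is supplied; no class
assignment is computed internally.

## What the synthetic data does and does not emulate

The generators reproduce the *statistical shape* of the real inputs: sparse
binary fingerprints (background bit density 0.05), a tunable class signal
(`effect` interpolates the informative-bit frequency between p₀ and the
extremes, so effect 0 is label-free and effect 1 is separable before
noise), majority-class cluster structure on disjoint signature-bit blocks
(planted only when a majority exists, since one-sided signatures on
balanced data would masquerade as class signal), decoy-style screening
imbalance at the 86/4,535 scale, and association tables with planted hot
species, enantiomer duplicates, and non-plant lineages. The default screen
separation of 1.4 SD places top-1% enrichment in the 12–16× regime typical
of well-performing consensus models at this ledger scale.

They do **not** emulate real chemistry: synthetic molecules are
fluorine-capped C/N chains (valid, distinct, trivially standardizable),
fingerprint bits are independent Bernoulli draws rather than correlated
substructure indicators, and decoys are score-shifted rather than
property-matched. Passing tests therefore demonstrate that the machinery is
correct — labeling, partition hygiene, GA mechanics, metric arithmetic,
domain filtering, ranking — not that any particular accuracy is attainable
on real extracts, which depends on database snapshots this package does not
ship.

## Numerical and degenerate-input choices

* IC50 exactly at threshold → inactive; non-positive IC50 → rejected.
* Silhouette ties → smaller k; k-means uses 10 seeded restarts.
* Variance threshold comparison is strict (`< 0.05` removed).
* `⌊χN⌋` EF window, minimum 1; 1-based ranks.
* BCR inputs outside [0,1] are rejected; empty confusion-matrix denominators
  yield 0 for the affected rate.
* Ensembles and pools reject configurations whose bounds are inverted or
  whose pool is smaller than the minimum ensemble size.
* All randomness flows through `numpy.random.default_rng` seeded from the
  caller; identical configurations produce byte-identical outputs.

## Limitations

* The best-model choice within a GA population is intentionally left to the
  user: results are ranked by test BCR with external metrics attached, and
  no automatic selection heuristic is applied.
* Only µM IC50 numerics are accepted; censored or mixed-unit records must be
  resolved upstream.
* The applicability domain is a single global PCA ball; compounds near the
  training boundary are treated the same as central ones.
* Scaled GA budgets (50 × 50) are used throughout the shipped results; the
  full 1,000 × 5,000 budgets are configuration defaults whose behavior is
  expected, but not demonstrated, to match at larger problem sizes.
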