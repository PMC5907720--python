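# Methods

## The problem and the approach

Epistatic (non-additive, multi-locus) contributions to complex disease are
easy to lose during feature selection: a ranker built around marginal
effects discards a purely interacting SNP pair, while a pairwise-exhaustive
ranker can miss a modest main effect buried in noise.  `epicollect`
implements *collective feature selection*: several heterogeneous rankers
each nominate their top *k*% of SNPs, and the union of the nominations is
carried to downstream modelling.  Because the union contains every
per-method selection, its sensitivity (fraction of truly causal SNPs
retained) is, by set inclusion, at least that of the best single method on
every dataset — the price is extra false positives, bounded by
(number of methods) × k.

The package contains everything needed to evaluate that claim end to end
without external data: two case/control genotype simulators, eight
rankers behind one contract, the top-k%/union layer, and a sensitivity
benchmark.

## Simulators

### Frequency-shift designs (experiment 1)

Balanced case/control panels in which causal SNPs differ between groups
only through their (joint) genotype frequencies.  All SNPs are sampled
with replacement; non-causal SNPs follow Hardy–Weinberg (HWE) proportions
at MAF *q* = 0.4 in both groups.  The eight named models place 1–4
main-effect SNPs or 1–4 interacting pairs (Table-style layout
`1SNP`…`4SNP`, `case1_control0`…`case2_control2`), with effect strength
*s* ∈ {0.1, 0.5, 0.9}:

* main effect, enriched group: `P(g) = (1−s)·P_HWE(g) + s·1[g=2]`
  (profile configurable);
* interacting pair, enriched group:
  `P(g1,g2) = (1−s)·P_HWE(g1)P_HWE(g2) + s·Diag(g1,g2)`, `Diag`
  uniform over the concordant cells {(0,0),(1,1),(2,2)} — a "diagonal"
  joint-frequency architecture whose single-locus marginals shift only
  through the diagonal mixture.

The source study that introduced these designs does not publish its
frequency tables; the diagonal mixture is this package's concrete
instantiation.  It reduces exactly to the null at *s* = 0, which the null
calibration test exploits.  Defaults: 2,000 cases + 2,000 controls, 100 or
500 SNPs, 10 replicates per parameter combination.

### Penetrance architectures (experiment 2)

Pure-strict two-locus epistasis: a 3×3 penetrance table *f* whose
HWE-weighted row and column marginal penetrances all equal the prevalence
*K*, so no single-locus signal exists.  Heritability is the
penetrance-variance definition
`h² = Σ w(g1)w(g2) (f−K)² / (K(1−K))`.

**Sampling.**  Deviation tables live in the 4-dimensional null space of
the zero-marginal constraints.  The generator draws a random direction in
that null space, computes the largest scale that keeps all penetrances in
[0, 1], rejects the direction if the target h² is unreachable, and
otherwise scales the deviation so h² is exact.  (Scaling an
isotropic-magnitude draw and rejecting out-of-range tables is hopeless at
high h²: the feasible set is a thin cone, and acceptance is ≈ 0 at
h² = 0.4, MAF 0.2.)

**Architectures.**  Detectability is scored by the analytic Bayes-optimal
two-locus balanced accuracy
`BA* = ½ + ¼ Σ_cells |P(cell|case) − P(cell|control)|`
(0.5 = undetectable, 1 = perfectly separable).  Over a candidate
population (default 10,000 models) at fixed (q, h², K), the minimum and
maximum define the *hard* and *easy* architectures.  The original
ease-of-detection measure this mimics is defined elsewhere and not
restated in our sources; BA* is used because it is closed-form, bounded,
and monotone in true detectability.

**Main effect and combination.**  A third predictive locus carries a
one-locus deviation d(g) with zero HWE mean, scaled to its own
heritability.  Two profiles are provided: *additive* (d ∝ g − 2q) and
*dominant* (d ∝ centred carrier indicator).  The dominant profile is the
default because the additive profile loads its whole deviation on the
rare homozygote: at MAF 0.2 a standalone additive locus cannot reach
h² = 0.4 for any prevalence above 0.2 without a penetrance leaving [0, 1].

The combined three-locus table is
`f(g1,g2,g3) = K + c_e·(f_epi − K) + c_m·d_main`, with the two deviation
components orthogonal under independent-locus HWE weights, so their
heritability contributions add.  The mixing weights satisfy the requested
main-effect variance share (default ⅓ — one of three predictive SNPs) and
are jointly rescaled so the combined table's heritability equals the
requested level exactly.  **Feasibility cap:** at MAF 0.2 no combined
table can reach h² = 0.4 — a pure pair at h² ≈ 0.27 already spans the
whole [0, 1] range, leaving no room for any main-effect shift (verified
numerically over prevalences 0.2–0.6 and both main profiles).  At a level
no candidate can reach, the generator falls back to the maximal
always-valid convex mixture (`c_e + c_m = 1`), which caps the combined
heritability at ≈ 0.21 for the 0.4 level.  The levels 0.1 and 0.2 are hit
exactly.  Model objects always carry the realised `h2_total`, verified
against the 27-cell table to 1e-9.

Prevalence defaults to K = 0.3: it admits the full grid (pure pairs at
h² = 0.4 and the dominant main component at all levels).  Datasets are
drawn by rejection sampling — genotypes i.i.d. HWE at MAF 0.2 for all 100
SNPs, case status Bernoulli(f), quotas of 1,000 cases and 1,000 controls —
with the three predictive SNPs in the first three columns (a `--shuffle`
flag permutes columns; truth manifests follow).

### What the simulators do and do not emulate

Real genotype panels have linkage disequilibrium, MAF spectra, missing
calls, covariates and population structure; both simulators omit all of
these (independent loci, one MAF, complete data).  Passing benchmarks
therefore demonstrate the rankers' behaviour on idealised architectures —
the relative strengths of the methods and the union's dominance — not
performance on real cohorts.

## Rankers

All rankers implement `rank(dataset, config) → FeatureRanking`; ties are
always broken by ascending column index, so every ranking is reproducible.

* **MDR** (bespoke): every 1-locus and 2-locus genotype-cell model is
  evaluated on the training data without cross-validation.  A cell is
  high-risk iff its case:control ratio *strictly* exceeds the dataset-wide
  ratio; empty cells and exact ties are low-risk (a deterministic,
  conservative rule).  A model scores training balanced accuracy
  `(TPR + TNR)/2`; a feature scores the best BA over models containing it
  (the simplest monotone extraction from a model ranking).  Joint cell
  counts for all C(p,2) pairs come from one one-hot cross-product, so the
  exhaustive scan takes ~0.1 s at p = 100, n = 2000.
* **MultiSURF\*** (bespoke): Relief-family scorer with per-instance
  distance thresholds.  Attribute difference |a−b|/2, instance distance =
  mean attribute difference; for target *i*, threshold `T_i` = mean
  distance to all others, dead band `σ_i/2`.  Near pairs update
  conventionally (miss +, hit −), far pairs inverted (miss −, hit +);
  scores divided by n.  A degenerate distance distribution yields all-zero
  scores, not an error.
* **TuRF** (bespoke wrapper): re-rank survivors, drop
  `max(1, floor(drop_fraction·current))` lowest-scoring per pass (default
  10%), until ≤ `min_features` remain; final order = survivors by
  last-pass scores, then removed features in reverse removal order.
  Returned scores are ordinal, because raw scores from different passes
  are not comparable.
* **Random forest** (scikit-learn): presets of 1,000 trees (main-effect
  screen) or 4,500 (interaction screen) with 35/70/200 candidate variables
  per split by panel width.  Importance defaults to impurity decrease —
  every SNP has the same 3-level cardinality, so the usual cardinality
  bias cannot differentiate features, and impurity is orders of magnitude
  cheaper; permutation importance is available via configuration.
* **Gradient boosting** (LightGBM): 800 or 15,000 trees, shrinkage 0.01,
  bag fraction 0.5, depth-3 trees (deep enough to express two- and
  three-way splits); importance = total split gain.
* **Penalized regressions** (scikit-learn solvers, bespoke design and
  attribution): lasso (L1), elastic net (α = 0.5), and lasso over main
  effects plus all p(p−1)/2 standardized pairwise products.  λ is the
  5-fold stratified-CV loss minimiser (not the 1-SE rule).  The default
  loss is logistic deviance — appropriate for a binary outcome — with a
  squared-error mode matching the classical shrinkage formulation.
  With interactions, feature score = max(|β_j|, max_k |γ_jk|), promoting
  either member of a selected interaction.

Stochastic learners take an explicit seed from `SelectorConfig`; no global
RNG state is touched.  MDR and MultiSURF* are exactly invariant to sample
order and equivariant to feature permutation (tested); resampling-based
learners cannot be row-order invariant even when re-seeded, because
bootstrap and fold draws attach to row positions.

## Selection, scoring, benchmark

`top_fraction` takes `k = max(1, round_half_up(p/100 · n))` features from
the head of a ranking; the percentage applies per method, not to the union
size.  `collective_union` records per-method sets, union, intersection and
per-feature provenance.  Sensitivity = |selection ∩ truth| / |truth|;
tp + fp = |selection| always.

The benchmark runner simulates replicate datasets over a parameter grid
(seeds derived per (master, cell, replicate) via `SeedSequence` spawn
keys, so results are independent of scheduling), ranks with each method,
forms selections at each percentage, scores against truth, and aggregates
means over replicates.  For the penetrance experiment it also reports
pooled recovery: merging a cell's replicates by consensus (a feature is
recovered if selected in at least half of the replicates) and pooling the
three heritability levels within an architecture, each architecture has
9 recoverable (level, feature) units.

## Numerical choices and degenerate inputs

Genotypes are strictly {0,1,2}; phenotypes strictly {0,1} with both
classes present; readers reject anything else with the offending cell
named.  No missing-data support anywhere (the simulators never emit it).
Frequency tables must sum to 1 within 1e-12; pure-strict marginals are
exact to 1e-12 and heritabilities to 1e-9 by construction.  An all-zero
coefficient vector (fully shrunk lasso) ranks features in column order by
the tie rule.  CV folds that would contain one class raise with advice
rather than fitting.

## Benchmark scale

The default presets are the full study settings (50 replicates per
penetrance cell, 10 per frequency cell, 10,000 candidate models, 4,500/
15,000 trees).  The shipped acceptance run and test suite use a reduced
preset — 5 replicates per cell, 2,000 candidate models, 500-tree forest,
1,000-tree boosting — chosen so the whole study runs in minutes on one
CPU; tree counts beyond a few hundred change importance stability, not
which SNPs lead the rankings, and the replicate count only widens the
consensus margin.  Measured with this preset: the union of top-10%
selections recovers 9/9 pooled predictive features in both architectures;
individual methods drop pooled units on the harder cells.

## Known limitations

* The combined heritability cap at the top level (≈ 0.21 instead of 0.4)
  is a mathematical property of bounded penetrances at MAF 0.2, not an
  implementation limit; the 0.4 level should be read as "the strongest
  feasible architecture".
* EDM extremes over a finite candidate population are themselves random;
  two different master seeds give (slightly) different hard/easy models.
* The union's false-positive cost is reported but not optimised; no
  score-fused or weighted ensemble is provided by design.
* Logistic-path CV over the 5,050-column interaction design is the
  slowest ranker by far; the squared-error mode exists partly as a fast
  alternative.
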