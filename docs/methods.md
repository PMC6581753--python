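# Methods

`msconnectome` implements an end-to-end analysis of structural brain
connectomes for multiple-sclerosis (MS) clinical profiling: simulation of
longitudinal connectivity cohorts, graph construction and thresholding, local
graph metrics, a graph-convolutional classifier, cross-validated evaluation,
and per-node longitudinal mixed-effects statistics.  This note records the
models, the defaults and the design choices that were genuinely open.

## Connectome model and thresholding

A connectome is a symmetric non-negative matrix `A ∈ ℕ^{q×q}` of tractography
fiber counts between `q = 84` parcellated gray-matter regions, zero diagonal.
The analysis graph applies a proportional threshold: with
`T = floor((q² − q)·τ / 2)`, the `T` heaviest unordered node pairs are kept
and everything else is zeroed, so the surviving edge density is `τ` whenever
the raw graph is dense enough.  At the study operating point `τ = 0.35`,
`q = 84`, this keeps `T = 1220` edges.

Choices the definition leaves open, fixed here:

* **Sort direction.** The thresholded graph retains the *strongest*
  connections, so edges are ranked by descending weight.
* **Rounding.** `T` is the floor of the real-valued expression.
* **Ties** at the cutoff weight are broken by lexicographic node-pair order,
  which makes the operator deterministic and the edge set monotone in `τ`.
* Pairs with zero fiber count are never eligible edges.
* If fewer than `T` positive pairs exist, all of them are kept.

## Local graph metrics

Four nodal measures in binary and weighted variants, following the
brain-connectivity-toolbox conventions:

* **Degree / strength** `D_i = Σ_j a_ij`, `D_i^w = Σ_j w_ij`.
* **Clustering coefficient** — fraction of triangles around a node; the
  weighted variant sums triangle intensities `(w̃_ij w̃_jh w̃_hi)^{1/3}` with
  weights scaled by the largest weight of the (thresholded) graph,
  `w̃ = w / max w`.  The ½ factor on the ordered-pair sum is kept in both
  variants so the weighted form reduces exactly to the binary form when all
  weights are equal.
* **Local efficiency** — the efficiency of the subgraph induced by a node's
  neighbors: `E_i = Σ_{j≠h∈N_i} (w̃_ij w̃_ih)^{1/3} / d_jh(N_i) / (k_i(k_i−1))`
  where the restricted shortest-path length `d_jh(N_i)` is computed on edge
  lengths `(1/w̃)^{1/3}`.  Distributing the cube root into the path term is
  what makes the equal-weights case collapse to the binary formula; pairs
  with no restricted path contribute zero.
* **Betweenness centrality** — fraction of all shortest paths through a node,
  normalized by `(n−1)(n−2)` over ordered endpoint pairs.  Weighted shortest
  paths treat fiber counts as affinities and use edge length `1/w`; this is
  the standard convention and is flagged as an assumption (the metric
  definition itself is silent on the transform).

Nodes with degree < 2 take clustering and efficiency 0.  Every metric is
validated against an exhaustive-enumeration oracle (all simple paths, all
triangles) on random graphs with ≤ 8 nodes, where enumeration is exact.

## Node features

Six conditions: `identity` (the q×q identity — a featureless setting where
the classifier sees only graph structure), one single-metric column (`D`,
`BC`, `CC`, `E`), or `all-graphs` (all four columns).  Metric columns are
min-max normalized to [0, 1] **per graph, per column**; normalizing within a
graph keeps each sample self-contained and avoids train/test leakage (a
cohort-level alternative would tie test-set scaling to training data).
Constant columns map to zeros; identity features are exempt.

## Graph-convolutional classifier

Architecture: one graph-convolution layer
`H = ReLU(Â X W)` with `k = 100` output channels and no bias (the layer
formula has none), dropout 0.3 on `H` during training, flatten to `q·k`, one
dense softmax layer with bias over the `C` classes.
`Â = D̃^{−1/2}(A + I)D̃^{−1/2}` is the renormalized adjacency; for weighted
graphs `A` is first divided by its maximum weight so fiber counts in the
hundreds do not swamp the unit self-loop (equal weights then reproduce the
binary pipeline exactly).

The trainable parameter count is `d·k + q·k·C + C`; for the featureless
4-class model (`d = q = 84`) that is `8400 + 33600 + 4 = 42 004 ≈ 42 000`.
The dense bias is included: it is the configuration whose count matches the
≈42 k figure, and the GC layer stays bias-free as written.

Training is full-batch Adam (learning rate 0.001, β₁ = 0.9, β₂ = 0.999) on
categorical cross-entropy with early stopping: a stratified 10 % validation
holdout per training set, patience 20 epochs, maximum 500 epochs, best
weights restored.  The implementation is plain numpy with hand-derived
gradients; a finite-difference check (tolerance 1e−5) guards them.  All
randomness (initialization, dropout, holdout, shuffling) is driven by one
seed, so training is bit-reproducible.

Weighted experiments feed the weighted `Â` (rather than weighted features on
a binary `Â`); this is flagged as an assumption of the pipeline design.

## Synthetic cohorts

No public MS connectome cohort exists, so the generator emulates one (see the
`synthetic_data` module docstring for the full generative model).  Key
points:

* Five groups (HC, CIS, RR, SP, PP) with default subject counts
  24/12/30/28/20 and per-group session counts chosen so the default cohort
  totals 580 scans, matching the study's longitudinal composition.
* Disease burden is a per-group severity in [0, 1]
  (0 / 0.2 / 0.45 / 0.7 / 0.9 by default, graded along the clinical course).
  Severity thins edges (maximal fractional density loss `c_d = 0.3`) and
  attenuates weights (maximal fractional loss `c_w = 0.5`).
* Edges live on a fixed six-module template; severity concentrates its damage
  on inter-module (long-range) pairs.  This mirrors preferential long-tract
  damage in MS and is also what makes the signal observable: a *uniform*
  weight attenuation would be removed by the max-weight scaling and degree
  normalization of `Â`, leaving nothing for the classifier.
* Fiber counts are shifted negative-binomial (dispersion 5), overdispersed
  like real streamline counts, and at least 1 on present edges.
* Subjects carry a log-normal random intercept (scale `subject_sd = 0.2`)
  shared across their sessions, plus a mild per-session multiplicative drift
  (−2 % per session) — the same subject/session structure the mixed model
  assumes, which is what makes the generator a fair test bed for it.

What the generator does **not** emulate: spatial geometry of real
parcellations, lesion topography, age/sex effects, scanner drift, or
between-session correlation beyond the shared intercept.  Passing tests
therefore show that the pipeline recovers the planted statistical structure,
not that it would reach the same scores on clinical data.

## Evaluation protocol

3-fold cross-validation stratified at the **subject** level by default: all
scans of a subject share a fold, so longitudinal scans never leak between
training and test (a per-scan split is available as an option).  Scores are
macro-averaged precision, recall and F-measure (undefined per-class ratios
score 0), reported as mean ± sd across folds.  Five tasks are predefined: HC
vs (CIS+RR), HC vs (SP+PP), the 4-class MS problem, the 5-class problem, and
(CIS+RR) vs (SP+PP).

Sample comparisons use the two-sided Wilcoxon–Mann–Whitney test: exact null
distribution when the combined sample is ≤ 20 without ties, tie-corrected
normal approximation otherwise.

## Longitudinal mixed model

Per node and metric: `value_ij = β0 + β1·group_i + β2·session_ij + u_i + ε_ij`
with subject random intercept `u_i`, REML estimation (statsmodels `MixedLM`),
treatment coding with a configurable reference group.  Fixed effects are
tested with Wald statistics; a Kenward–Roger-style degrees-of-freedom
correction is deliberately not reproduced — it is solver-specific, and the
large-sample Wald test is calibrated at the sample sizes used here (type-I
error 0.03–0.08 at α = 0.05 with 40 subjects, verified by simulation).
Pairwise group contrasts of estimated marginal means are computed only when
the omnibus group test is significant, with a Tukey studentized-range
adjustment within the node; no across-node correction by default (an FDR
pass can be applied downstream).

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own defaults: classification checks run on the
full default 580-scan cohort (the scale at which the 4-class featureless
weighted experiment reaches macro-F ≥ 0.9); metric-oracle equivalence uses
200 random graphs of ≤ 8 nodes; mixed-model calibration uses 500 null
replicates (200 in the acceptance script) at 40 subjects × 3 sessions;
pipeline-level statistical checks use 30–40-node cohorts of 10–15 subjects
per group.  Graphs much smaller than 84 nodes truncate the modular template
and carry little group signal, so classification assertions are made only on
full-size graphs.

## What the synthetic experiments do and do not show

On the default cohort the featureless (identity) weighted 4-class experiment
reaches macro-F ≈ 0.92 and a subject-level label permutation drops it to
chance, so the classifier recovers exactly the structure the generator
plants and nothing else.  The unweighted variant scores far lower (≈ 0.2):
the generator's group differences are carried predominantly by relative edge
weights, and the residual shift in which edges survive thresholding does not
generalize across subjects at the default count dispersion.  Longer training
and minibatch schedules do not change this — in-sample accuracy reaches 1.0
while held-out accuracy plateaus — so it reflects the information content of
the binary graphs, not underfitting.  The weighted > unweighted ordering is
therefore reproduced qualitatively, with a larger margin than real cohorts
show; clinical binary connectomes are more informative than these synthetic
ones.

## Known limitations

* The GCN is single-layer and CPU-only by design; no pooling or deeper
  stacks.
* The generator's group differences act through one severity axis; it cannot
  produce group-specific regional signatures beyond the intra/inter-module
  contrast.
* Mixed-model p-values are large-sample; with very few subjects per group
  (≲ 10) the per-node test is anti-conservative, and within a single cohort
  node-level tests are correlated through the shared subject draw.
* The exact rank-sum path requires tie-free data; ties always route to the
  corrected normal approximation regardless of sample size.
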