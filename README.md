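# msconnectome

Structural brain-connectome analysis of multiple-sclerosis (MS) clinical
profiles: synthetic longitudinal connectivity cohorts, proportional graph
thresholding, local graph metrics, a graph-convolutional classifier with
cross-validated evaluation, and per-node longitudinal mixed-effects group
comparison.

## The problem

MS presents in graded clinical courses — clinically isolated syndrome (CIS),
relapsing-remitting (RR), secondary-progressive (SP), primary-progressive
(PP) — and distinguishing them from structural brain connectivity is both a
classification problem and a localization problem (which regions differ?).
A connectome here is a symmetric matrix `A ∈ ℕ^{q×q}` of tractography fiber
counts between `q = 84` parcellated gray-matter regions.  The package is
aimed at methods researchers who want a tested, fully reproducible pipeline
over such matrices; because clinical MS connectome cohorts are not publicly
distributable, a first-class synthetic-cohort generator stands in for the
data (five groups, graded connectivity loss, subject random intercepts,
longitudinal sessions).

## The methods

* **Thresholding** — keep the `T = ⌊(q²−q)τ/2⌋` heaviest node pairs
  (`τ = 0.35` keeps 1220 of 3486 possible edges at `q = 84`).
* **Local metrics** — degree/strength, clustering coefficient, local
  efficiency, betweenness centrality, each in binary and weighted form under
  brain-connectivity-toolbox conventions, validated against exhaustive
  enumeration oracles.
* **Classifier** — one graph-convolution layer `H = ReLU(Â X W)` with
  `k = 100` channels on the renormalized adjacency
  `Â = D̃^{−1/2}(A+I)D̃^{−1/2}`, dropout 0.3, dense softmax head; Adam
  (lr 0.001), early stopping, 3-fold subject-level cross-validation, macro
  precision/recall/F-measure.  The featureless 4-class model has
  `84·100 + 84·100·4 + 4 = 42 004` trainable weights.  Node features per
  experimental condition: identity (featureless), one metric, or all four.
* **Statistics** — per node and metric, the linear mixed model
  `value_ij = β0 + β1·group_i + β2·session_ij + u_i + ε_ij` with subject
  random intercept, Wald tests, Tukey-adjusted pairwise group contrasts, and
  a Wilcoxon–Mann–Whitney comparison utility (exact for small tie-free
  samples).

See `docs/methods.md` for the full model descriptions and design decisions.

## Worked example

```python
from msconnectome import TASKS, TrainConfig, cross_validate, default_cohort_config
from msconnectome.synthetic_data import generate_cohort

cohort = generate_cohort(default_cohort_config(seed=1))   # 580 scans, 5 groups
result = cross_validate(cohort, TASKS["four_class"], condition="identity",
                        weighted=True, tau=0.35, train_config=TrainConfig(seed=1))
print(result.summary())
```

```
Cross-validation: task=four_class condition=identity (weighted)
  F-Measure: 0.92 (±0.02)
  Precision: 0.96 (±0.01)
  Recall   : 0.90 (±0.02)
  folds    : 3
```

The 580-scan synthetic cohort (CIS/RR/SP/PP for this task) is thresholded at
τ = 0.35, each scan's renormalized weighted adjacency is fed to the
featureless classifier, and 3-fold subject-level cross-validation yields a
mean macro F-measure of 0.92: the graded connectivity loss planted by the
generator is recoverable from graph structure alone.  Takes a few minutes on
one CPU.

Per-node statistics on the same cohort:

```python
from msconnectome.group_stats import build_metric_table, fit_all_nodes

table = build_metric_table(cohort, tau=0.35)
fits = fit_all_nodes(table, metric="degree", weighted=True, reference="HC")
print((fits["group_omnibus_pvalue"] < 0.05).mean())  # fraction of nodes flagged
```

A command-line interface mirrors these steps
(`msconnectome simulate | metrics | cv | stats`).

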