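"""Cross-validated classification experiments and their comparison tests.

Reproduces the experiment grid: five classification tasks over the clinical
groups (HC vs early MS, HC vs progressive MS, the 4-class and 5-class
problems, early vs progressive), six node-feature conditions, weighted and
unweighted graph variants, 3-fold cross-validation stratified at the subject
level (all scans of a subject share a fold, so longitudinal scans never leak
between train and test), and macro precision / recall / F-measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

from .connectome import binarize, threshold_graph
from .features import build_feature_matrix
from .gcnn import GCNClassifier, TrainConfig, prepare_inputs, renormalized_from_graph
from .synthetic_data import SubjectRecord

__all__ = [
    "TaskSpec",
    "TASKS",
    "CVResult",
    "kfold_split",
    "precision_recall_f1",
    "cross_validate",
    "wilcoxon_compare",
]


@dataclass(frozen=True)
class TaskSpec:
    """Classification task: groups map to class indices; unmapped groups are
    excluded from the task."""

    name: str
    class_map: dict[str, int]

    @property
    def n_classes(self) -> int:
        return len(set(self.class_map.values()))

    def __post_init__(self) -> None:
        classes = sorted(set(self.class_map.values()))
        if classes != list(range(len(classes))):
            raise ValueError("class indices must be 0..C-1 without gaps")


TASKS = {
    "hc_vs_early": TaskSpec("hc_vs_early", {"HC": 0, "CIS": 1, "RR": 1}),
    "hc_vs_progressive": TaskSpec("hc_vs_progressive", {"HC": 0, "SP": 1, "PP": 1}),
    "four_class": TaskSpec("four_class", {"CIS": 0, "RR": 1, "SP": 2, "PP": 3}),
    "five_class": TaskSpec("five_class", {"HC": 0, "CIS": 1, "RR": 2, "SP": 3, "PP": 4}),
    "early_vs_progressive": TaskSpec(
        "early_vs_progressive", {"CIS": 0, "RR": 0, "SP": 1, "PP": 1}),
}


@dataclass
class CVResult:
    """Per-fold macro scores with across-fold mean and standard deviation."""

    task: str
    condition: str
    weighted: bool
    fold_precision: list[float] = field(default_factory=list)
    fold_recall: list[float] = field(default_factory=list)
    fold_f1: list[float] = field(default_factory=list)
    fold_true: list[np.ndarray] = field(default_factory=list)
    fold_pred: list[np.ndarray] = field(default_factory=list)

    def _stats(self, values):
        return float(np.mean(values)), float(np.std(values))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))

    def summary(self) -> str:
        pm, ps = self._stats(self.fold_precision)
        rm, rs = self._stats(self.fold_recall)
        fm, fs = self._stats(self.fold_f1)
        variant = "weighted" if self.weighted else "unweighted"
        return "\n".join([
            f"Cross-validation: task={self.task} condition={self.condition} ({variant})",
            f"  F-Measure: {fm:.2f} (±{fs:.2f})",
            f"  Precision: {pm:.2f} (±{ps:.2f})",
            f"  Recall   : {rm:.2f} (±{rs:.2f})",
            f"  folds    : {len(self.fold_f1)}",
        ])


def kfold_split(records: list[SubjectRecord], k: int, seed: int,
                by_subject: bool = True) -> list[list[int]]:
    """Stratified k-fold record indices.

    With ``by_subject`` (default) the unit of splitting is the subject, so all
    sessions of a subject land in one fold; otherwise individual scans are
    stratified directly.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if by_subject:
        subject_group: dict[str, str] = {}
        subject_records: dict[str, list[int]] = {}
        for idx, rec in enumerate(records):
            subject_group.setdefault(rec.subject_id, rec.group)
            subject_records.setdefault(rec.subject_id, []).append(idx)
        by_class: dict[str, list[str]] = {}
        for sid, grp in subject_group.items():
            by_class.setdefault(grp, []).append(sid)
        for grp in sorted(by_class):
            sids = sorted(by_class[grp])
            if len(sids) < k:
                raise ValueError(
                    f"group {grp!r} has {len(sids)} subjects, fewer than k={k}")
            order = rng.permutation(len(sids))
            for pos, subject_pos in enumerate(order):
                folds[pos % k].extend(subject_records[sids[subject_pos]])
    else:
        by_class_idx: dict[str, list[int]] = {}
        for idx, rec in enumerate(records):
            by_class_idx.setdefault(rec.group, []).append(idx)
        for grp in sorted(by_class_idx):
            idxs = by_class_idx[grp]
            if len(idxs) < k:
                raise ValueError(
                    f"group {grp!r} has {len(idxs)} records, fewer than k={k}")
            order = rng.permutation(len(idxs))
            for pos, record_pos in enumerate(order):
                folds[pos % k].append(idxs[record_pos])
    return [sorted(fold) for fold in folds]


def precision_recall_f1(y_true, y_pred, n_classes: int) -> tuple[float, float, float]:
    """Macro-averaged precision, recall and F-measure.

    Classes absent from either vector still count in the macro average;
    undefined per-class ratios are scored 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=np.arange(n_classes), average="macro", zero_division=0)
    return float(p), float(r), float(f1)


def cross_validate(cohort: list[SubjectRecord], task: TaskSpec, condition: str,
                   weighted: bool, tau: float,
                   train_config: TrainConfig | None = None,
                   k: int = 3, gc_channels: int = 100,
                   by_subject: bool = True) -> CVResult:
    """Full experiment for one (task, condition, variant) cell.

    Each scan's matrix is proportionally thresholded at ``tau``, node features
    are built for the condition, and for every fold a fresh classifier is
    trained on the remaining folds and scored on the held-out one.
    """
    train_config = train_config or TrainConfig()
    records = [rec for rec in cohort if rec.group in task.class_map]
    if not records:
        raise ValueError("no cohort records match the task's groups")
    labels = np.array([task.class_map[rec.group] for rec in records])

    inputs = []
    for rec in records:
        graph = threshold_graph(rec.matrix, tau)
        if not weighted:
            graph = binarize(graph)
        a_hat = renormalized_from_graph(graph)
        x = build_feature_matrix(graph, condition, weighted)
        inputs.append(prepare_inputs(a_hat, x.values))
    inputs = np.stack(inputs)

    folds = kfold_split(records, k=k, seed=train_config.seed, by_subject=by_subject)
    result = CVResult(task=task.name, condition=condition, weighted=weighted)
    q, d = inputs.shape[1], inputs.shape[2]
    for fold_i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(records)), test_idx)
        model = GCNClassifier(q=q, d=d, k=gc_channels, n_classes=task.n_classes,
                              seed=train_config.seed + fold_i)
        fold_config = TrainConfig(
            learning_rate=train_config.learning_rate,
            max_epochs=train_config.max_epochs,
            patience=train_config.patience,
            batch_size=train_config.batch_size,
            validation_fraction=train_config.validation_fraction,
            seed=train_config.seed + fold_i,
        )
        model.fit(inputs[train_idx], labels[train_idx], fold_config)
        y_pred = model.predict(inputs[test_idx])
        y_true = labels[test_idx]
        p, r, f1 = precision_recall_f1(y_true, y_pred, task.n_classes)
        result.fold_precision.append(p)
        result.fold_recall.append(r)
        result.fold_f1.append(f1)
        result.fold_true.append(y_true)
        result.fold_pred.append(np.asarray(y_pred))
    return result


def wilcoxon_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney rank-sum test.

    Uses the exact null distribution when the combined sample size is at most
    20 and there are no ties, and the tie-corrected normal approximation
    otherwise.  Returns ``(U statistic, p value)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
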