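"""Metrics, global k-fold cross-validation, local per-task evaluation, sweeps.

Two evaluation regimes mirror the way kinase panels are actually used:

* **global** — pool every labelled pair, split at the pair level into k
  folds, train on k-1 and score the held-out fold, averaging metrics over
  folds;
* **local** — score each tail kinase's own test pairs with its adapted
  model and average the per-task metrics unweighted, so a 2000-pair kinase
  counts no more than a 20-pair one (the regime that exposes long-tail
  failure).

AUC is the Mann-Whitney probability that a random active outranks a random
inactive (ties count 1/2); AUPR uses the step-wise precision-recall area
(precision held at its value over each recall increment — no linear
interpolation), which for a constant scorer reduces to the positive
prevalence.  Thresholded metrics use score >= threshold with precision
defined as 0 (and flagged) when nothing is predicted positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .seeding import substream_seed


@dataclass
class MetricsReport:
    """AUC/AUPR plus thresholded metrics for one evaluation unit."""

    auc: float
    aupr: float
    ba: float
    precision: float
    recall: float
    f1: float
    n_pos: int
    n_neg: int
    threshold: float = 0.5
    no_predicted_positives: bool = False

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def mean(cls, reports: Sequence["MetricsReport"]) -> "MetricsReport":
        """Unweighted mean over evaluation units (folds or tasks)."""
        if not reports:
            raise ValueError("no reports to average")
        return cls(
            auc=float(np.mean([r.auc for r in reports])),
            aupr=float(np.mean([r.aupr for r in reports])),
            ba=float(np.mean([r.ba for r in reports])),
            precision=float(np.mean([r.precision for r in reports])),
            recall=float(np.mean([r.recall for r in reports])),
            f1=float(np.mean([r.f1 for r in reports])),
            n_pos=int(sum(r.n_pos for r in reports)),
            n_neg=int(sum(r.n_neg for r in reports)),
            threshold=reports[0].threshold,
            no_predicted_positives=any(r.no_predicted_positives for r in reports),
        )


def _check_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    if len(scores) == 0:
        raise ValueError("empty score list")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return scores, labels


def roc_auc(scores, labels) -> float:
    """P(random positive outranks random negative), ties counted 1/2."""
    scores, labels = _check_scores(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, scores))


def pr_auc(scores, labels) -> float:
    """Step-wise area under the precision-recall curve."""
    scores, labels = _check_scores(scores, labels)
    if labels.sum() == 0:
        raise ValueError("pr_auc needs at least one positive")
    return float(average_precision_score(labels, scores))


def threshold_metrics(
    scores, labels, threshold: float = 0.5
) -> tuple[float, float, float, float, bool]:
    """(BA, precision, recall, F1, no-positives flag) at score >= threshold."""
    scores, labels = _check_scores(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    no_pred_pos = (tp + fp) == 0
    precision = tp / (tp + fp) if not no_pred_pos else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    if pos.any() and (~pos).any():
        ba = (recall + specificity) / 2.0
    else:
        raise ValueError("balanced accuracy needs both classes present")
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return ba, precision, recall, f1, no_pred_pos


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Full MetricsReport for one score/label batch (both classes required)."""
    scores, labels = _check_scores(scores, labels)
    ba, precision, recall, f1, flag = threshold_metrics(scores, labels, threshold)
    return MetricsReport(
        auc=roc_auc(scores, labels),
        aupr=pr_auc(scores, labels),
        ba=ba,
        precision=precision,
        recall=recall,
        f1=f1,
        n_pos=int(labels.sum()),
        n_neg=int(len(labels) - labels.sum()),
        threshold=threshold,
        no_predicted_positives=flag,
    )


# ---------------------------------------------------------------------------
# global evaluation: k-fold cross-validation at the pair level


def kfold_cv(
    pairs: pd.DataFrame,
    trainer: Callable[[pd.DataFrame], object],
    scorer: Callable[[object, pd.DataFrame], np.ndarray],
    k: int = 10,
    seed: int = 0,
    stratified: bool = False,
    threshold: float = 0.5,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Pair-level k-fold cross-validation.

    ``trainer(train_pairs) -> model`` and ``scorer(model, test_pairs) ->
    scores`` keep the harness agnostic of the model family.  Folds partition
    the pairs (sizes differ by at most one); each serves once as the test
    set.  Returns (mean report, per-fold reports).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = pairs["label"].to_numpy()
    for label in (0, 1):
        if (labels == label).sum() < k:
            raise ValueError(f"need >= {k} pairs of class {label} for {k}-fold CV")
    split_seed = substream_seed(seed, "kfold")
    splitter = (
        StratifiedKFold(k, shuffle=True, random_state=split_seed)
        if stratified
        else KFold(k, shuffle=True, random_state=split_seed)
    )
    reports = []
    for train_idx, test_idx in splitter.split(pairs, labels):
        model = trainer(pairs.iloc[train_idx].reset_index(drop=True))
        test = pairs.iloc[test_idx].reset_index(drop=True)
        scores = np.asarray(scorer(model, test), dtype=float)
        reports.append(compute_metrics(scores, test["label"].to_numpy(), threshold))
    return MetricsReport.mean(reports), reports


# ---------------------------------------------------------------------------
# local evaluation: per tail task, unweighted mean


def local_evaluate(
    task_scores: Mapping[str, tuple[np.ndarray, np.ndarray]],
    threshold: float = 0.5,
) -> tuple[MetricsReport, dict[str, MetricsReport], list[str]]:
    """Per-task metrics and their unweighted mean across tail tasks.

    ``task_scores`` maps kinase_id to (scores, labels) on that task's own
    test pairs.  Tasks whose test set lacks one of the classes cannot
    support AUC and are skipped, not failed; their ids are returned.
    """
    per_task: dict[str, MetricsReport] = {}
    skipped: list[str] = []
    for kid in sorted(task_scores):
        scores, labels = task_scores[kid]
        labels = np.asarray(labels, dtype=int)
        if len(labels) == 0 or labels.min() == labels.max():
            skipped.append(kid)
            continue
        per_task[kid] = compute_metrics(scores, labels, threshold)
    if not per_task:
        raise ValueError("no evaluable tasks (all test sets degenerate)")
    return MetricsReport.mean(list(per_task.values())), per_task, skipped


# ---------------------------------------------------------------------------
# hyperparameter sweep harness


@dataclass
class SweepResult:
    """Mean tail-task metrics for each value along one hyperparameter axis."""

    axis: str
    values: list
    reports: list[MetricsReport]

    def __post_init__(self):
        if len(self.values) != len(self.reports):
            raise ValueError("one report per swept value required")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {self.axis: v, "auc": r.auc, "aupr": r.aupr, "ba": r.ba, "f1": r.f1}
            for v, r in zip(self.values, self.reports)
        ]
        return pd.DataFrame(rows)


SWEEP_AXES = ("inner_lr", "outer_lr", "inner_steps", "n_head_tasks")


def sweep(
    axis: str,
    values: Sequence,
    run_benchmark: Callable[[dict], MetricsReport],
    base_overrides: dict | None = None,
) -> SweepResult:
    """Re-run a full meta-train + local evaluation per value of one axis.

    ``run_benchmark(overrides) -> MetricsReport`` executes the benchmark
    with the given config overrides (all seeds fixed inside); each cell
    retrains from scratch with only ``axis`` changed.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"axis must be one of {SWEEP_AXES}")
    if not len(values):
        raise ValueError("no sweep values given")
    reports = []
    for v in values:
        overrides = dict(base_overrides or {})
        overrides[axis] = v
        reports.append(run_benchmark(overrides))
    return SweepResult(axis=axis, values=list(values), reports=reports)
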