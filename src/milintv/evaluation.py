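"""Metrics, ROC/AUC, hyperparameter sweeps and pooling comparisons.

Accuracy, precision, recall and F1 follow the usual confusion-matrix
definitions; entries with a zero denominator are *flagged undefined* rather
than coerced to 0.  The ROC is computed over a pooled bag-level score
(mean instance score by default) and the AUC by trapezoid.

:func:`sweep_alpha_beta` evaluates the decision rule over a full Cartesian
(alpha, beta) grid — the simulation analogue of the published hyperparameter
ablation — and reports the arg-max row under a chosen metric.  Among
equal-metric rows the largest alpha, then the largest beta, is preferred:
the strictest thresholds attaining the observed optimum (the most
conservative rule against spurious single instances).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import ClassCoverageError, EmptyEvaluationError, ParameterError
from .mil import ConfusionCounts, DecisionConfig, decide_dataset, pool
from .scoring import ScoredBag

#: Default sweep grids; the fine 0.05 step near 1.0 matters because reported
#: optima for the high-confidence threshold sit at 0.91-0.95.
DEFAULT_ALPHA_GRID = tuple(round(0.50 + 0.05 * i, 2) for i in range(11))
DEFAULT_BETA_GRID = tuple(range(0, 11))

METRIC_NAMES = ("acc", "precision", "recall", "f1")


@dataclass(frozen=True)
class MetricSet:
    """Classification metrics; ``None`` marks an undefined (0/0) entry."""

    acc: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    undefined: tuple[str, ...] = ()

    def get(self, name: str) -> float | None:
        if name not in METRIC_NAMES:
            raise ParameterError(f"unknown metric {name!r}")
        return getattr(self, name)


@dataclass
class RocCurve:
    """ROC points (fpr, tpr) from (0,0) to (1,1) and the trapezoid AUC."""

    points: list[tuple[float, float]]
    auc: float


def metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall, F1 from confusion counts."""
    if c.total == 0:
        raise EmptyEvaluationError("all confusion counts are zero")
    undefined: list[str] = []
    acc = (c.TP + c.TN) / c.total

    if c.TP + c.FP > 0:
        precision = c.TP / (c.TP + c.FP)
    else:
        precision = None
        undefined.append("precision")
    if c.TP + c.FN > 0:
        recall = c.TP / (c.TP + c.FN)
    else:
        recall = None
        undefined.append("recall")
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
        undefined.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(acc, precision, recall, f1, tuple(undefined))


def bag_score(scored: ScoredBag, pooling: str = "mean") -> float:
    """Continuous bag-level score for ROC analysis.

    ``mean`` (default) or ``max`` of the instance scores, or
    ``count_fraction``: the fraction of depressive instances (score > 0.5).
    """
    values = scored.score_values
    if pooling in ("mean", "max"):
        return pool(values, pooling)
    if pooling == "count_fraction":
        return sum(v > 0.5 for v in values) / len(values)
    raise ParameterError(f"unknown pooling {pooling!r}")


def roc(score_label_pairs: Sequence[tuple[float, int]]) -> RocCurve:
    """ROC curve and AUC over (bag_score, label) pairs.

    Thresholds sweep the unique scores (equal scores grouped into one step);
    AUC is the trapezoid area, equal to the Mann-Whitney pairwise statistic
    with ties counted one half.
    """
    if not score_label_pairs:
        raise EmptyEvaluationError("no scores to evaluate")
    scores = np.array([s for s, _ in score_label_pairs], dtype=float)
    labels = np.array([int(l) for _, l in score_label_pairs])
    if len(np.unique(labels)) < 2:
        raise ClassCoverageError("ROC requires both classes to be present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(
        points=[(float(x), float(y)) for x, y in zip(fpr, tpr)],
        auc=float(_trapezoid_auc(fpr, tpr)),
    )


def roc_from_bags(
    scored_bags: Sequence[ScoredBag], pooling: str = "mean"
) -> RocCurve:
    pairs = [
        (bag_score(sb, pooling), sb.bag.label)
        for sb in scored_bags
        if sb.bag.label is not None
    ]
    return roc(pairs)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Full grid table plus the arg-max row under the chosen metric."""

    table: pd.DataFrame
    best: dict
    metric: str
    variant: str


def sweep_alpha_beta(
    scored_bags: Sequence[ScoredBag],
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
    variant: str = "majority_or_count",
    metric: str = "acc",
    depressive_cutoff: float = 0.5,
) -> SweepResult:
    """Evaluate the decision rule over the full (alpha, beta) grid.

    Deterministic given its inputs; the result table has exactly
    ``len(alpha_grid) * len(beta_grid)`` rows.
    """
    if not alpha_grid or not beta_grid:
        raise ParameterError("alpha_grid and beta_grid must be nonempty")
    if metric not in METRIC_NAMES:
        raise ParameterError(f"unknown metric {metric!r}")
    rows = []
    for alpha in alpha_grid:
        for beta in beta_grid:
            config = DecisionConfig(
                alpha=alpha, beta=beta,
                depressive_cutoff=depressive_cutoff, variant=variant,
            )
            result = decide_dataset(scored_bags, config)
            if result.confusion is None:
                raise ClassCoverageError("sweep requires labeled bags")
            m = metrics(result.confusion)
            rows.append(
                {
                    "alpha": alpha, "beta": beta,
                    "acc": m.acc, "precision": m.precision,
                    "recall": m.recall, "f1": m.f1,
                }
            )
    table = pd.DataFrame(rows)
    # arg-max by metric; ties -> largest alpha, then largest beta
    values = table[metric].astype(float).fillna(-np.inf)
    order = np.lexsort((table["beta"], table["alpha"], values))
    best = table.iloc[order[-1]].to_dict()
    return SweepResult(table=table, best=best, metric=metric, variant=variant)


def compare_pooling(
    scored_bags: Sequence[ScoredBag],
    config: DecisionConfig = DecisionConfig(),
    threshold: float = 0.5,
) -> dict[str, MetricSet]:
    """Max/mean pooling thresholded at 0.5 versus the alpha/beta rule."""
    labeled = [sb for sb in scored_bags if sb.bag.label is not None]
    if not labeled:
        raise ClassCoverageError("pooling comparison requires labeled bags")
    out: dict[str, MetricSet] = {}
    for method in ("max", "mean"):
        confusion = ConfusionCounts()
        for sb in labeled:
            prediction = int(pool(sb.score_values, method) > threshold)
            confusion.add(sb.bag.label, prediction)
        out[method] = metrics(confusion)
    result = decide_dataset(labeled, config)
    out["mil"] = metrics(result.confusion)
    return out
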