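"""Performance metrics, the exhaustive feature-combination sweep, plateau
detection and cross-participant aggregation.

Per-action metrics from the one-vs-rest counts of a multiclass confusion
matrix:

    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    action-specific accuracy = (TP + TN) / (TP + FP + TN + FN)
    F1 = 2 * precision * sensitivity / (precision + sensitivity)

Overall accuracy is the trace of the matrix over the total sample count.
The sweep cross-validates every subset of the 12 features (C(12,k) subsets
at each size k, 4095 in total) for each algorithm and summarises each
metric's mean and SD over subsets at each k.  The plateau of the mean
accuracy-vs-k curve is the smallest k whose relative change from k-1 is
within 5%, and the curve's shape is summarised by a least-squares
logarithmic fit acc = a + b*ln(k).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassifierSpec, ConfusionMatrix, confusion_to_counts, crossvalidate
from .classify import ActionCounts
from .features import FEATURE_NAMES, FeatureTable

__all__ = [
    "ActionMetrics",
    "SweepResult",
    "PlateauReport",
    "action_metrics",
    "overall_accuracy",
    "enumerate_subsets",
    "feature_sweep",
    "plateau_onset",
    "fit_log_curve",
    "aggregate_participants",
]

log = logging.getLogger(__name__)

#: Metric names summarised per subset (per-action metrics averaged over actions).
SWEEP_METRICS = ("overall_accuracy", "precision", "sensitivity",
                 "action_accuracy", "f1")


@dataclass(frozen=True)
class ActionMetrics:
    """Per-action fractions in [0, 1]."""

    action: str
    precision: float
    sensitivity: float
    action_accuracy: float
    f1: float


@dataclass(frozen=True)
class SweepResult:
    """Per-(algorithm, subset-size) aggregates of one participant's sweep.

    ``per_k`` maps subset size k to ``{metric: {"mean": .., "sd": ..,
    "n_subsets": ..}}``; ``records`` retains the per-subset values as a
    tidy DataFrame (algorithm, k, subset, metric columns).
    """

    algorithm: str
    participant_id: str
    per_k: dict[int, dict[str, dict[str, float]]]
    records: pd.DataFrame | None = None


@dataclass(frozen=True)
class PlateauReport:
    """Plateau-onset analysis of a metric-vs-k curve."""

    metric: str
    onset_k: int | None
    value_at_onset: float | None
    rel_changes: list[tuple[int, float]]


def action_metrics(counts: ActionCounts) -> ActionMetrics:
    """Compute the four per-action metrics from TP/TN/FP/FN.

    Zero-denominator precision or sensitivity is reported as 0 with a
    logged warning; F1 is 0 when precision + sensitivity = 0.
    """
    if counts.total <= 0:
        raise ValueError("counts total must be positive")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if tp + fp == 0:
        log.warning("precision undefined for %s (TP+FP=0); reporting 0",
                    counts.action)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        log.warning("sensitivity undefined for %s (TP+FN=0); reporting 0",
                    counts.action)
        sensitivity = 0.0
    else:
        sensitivity = tp / (tp + fn)
    accuracy = (tp + tn) / counts.total
    if precision + sensitivity == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return ActionMetrics(action=counts.action, precision=precision,
                         sensitivity=sensitivity, action_accuracy=accuracy,
                         f1=f1)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of all samples classified correctly: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def _subset_seed(seed: int, algorithm: str, subset: Sequence[str]) -> int:
    """Deterministic per-subset fold-shuffling seed, independent of the
    order in which subsets are evaluated."""
    key = f"{seed}|{algorithm}|{','.join(subset)}"
    return zlib.crc32(key.encode()) % (2 ** 31)


def enumerate_subsets(k_range: Iterable[int] = range(1, 13),
                      subsets_per_k: int | None = None,
                      seed: int = 0,
                      feature_names: Sequence[str] = FEATURE_NAMES,
                      ) -> dict[int, list[tuple[str, ...]]]:
    """Enumerate the feature subsets the sweep will evaluate.

    With ``subsets_per_k=None`` (the default) every combination is
    returned — C(12,k) at each size, 4095 over k=1..12.  A positive
    ``subsets_per_k`` draws a seeded sample without replacement at each k
    (sizes with fewer combinations keep them all); intended for quick
    runs, never for headline results.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, list[tuple[str, ...]]] = {}
    for k in k_range:
        if not 1 <= k <= len(feature_names):
            raise ValueError(f"subset size {k} out of range")
        combos = list(combinations(feature_names, k))
        if subsets_per_k is not None and subsets_per_k < len(combos):
            idx = rng.choice(len(combos), size=subsets_per_k, replace=False)
            combos = [combos[i] for i in sorted(idx)]
        out[k] = combos
    return out


def _evaluate_subset(table: FeatureTable, spec: ClassifierSpec,
                     subset: Sequence[str], n_folds: int) -> dict[str, float]:
    cm = crossvalidate(table, spec, subset, n_folds=n_folds)
    per_action = [action_metrics(confusion_to_counts(cm, a))
                  for a in cm.action_order]
    return {
        "overall_accuracy": overall_accuracy(cm),
        "precision": float(np.mean([m.precision for m in per_action])),
        "sensitivity": float(np.mean([m.sensitivity for m in per_action])),
        "action_accuracy": float(np.mean([m.action_accuracy for m in per_action])),
        "f1": float(np.mean([m.f1 for m in per_action])),
    }


def feature_sweep(table: FeatureTable, algorithms: Sequence[ClassifierSpec],
                  k_range: Iterable[int] = range(1, 13), seed: int = 0,
                  subsets_per_k: int | None = None, n_folds: int = 5,
                  keep_records: bool = True) -> list[SweepResult]:
    """Cross-validate every feature subset for every algorithm.

    Each subset is evaluated independently with a fold-shuffling seed
    derived from (seed, algorithm, subset), so results do not depend on
    evaluation order.  Returns one :class:`SweepResult` per algorithm.
    """
    k_range = list(k_range)
    subsets_by_k = enumerate_subsets(k_range, subsets_per_k, seed)
    pid = str(table.frame["participant"].iloc[0]) if len(table) else ""
    results = []
    for spec in algorithms:
        rows = []
        per_k: dict[int, dict[str, dict[str, float]]] = {}
        for k in k_range:
            vals: dict[str, list[float]] = {m: [] for m in SWEEP_METRICS}
            for subset in subsets_by_k[k]:
                sub_spec = ClassifierSpec(
                    algorithm=spec.algorithm, hyperparams=spec.hyperparams,
                    seed=_subset_seed(seed, spec.algorithm, subset))
                try:
                    metrics = _evaluate_subset(table, sub_spec, subset, n_folds)
                except ValueError as err:
                    raise ValueError(
                        f"sweep failed for {spec.algorithm} subset {subset}: {err}"
                    ) from err
                for m in SWEEP_METRICS:
                    vals[m].append(metrics[m])
                rows.append({"algorithm": spec.algorithm, "k": k,
                             "subset": "+".join(subset), **metrics})
            per_k[k] = {
                m: {"mean": float(np.mean(vals[m])),
                    "sd": float(np.std(vals[m], ddof=1)) if len(vals[m]) > 1 else 0.0,
                    "n_subsets": float(len(vals[m]))}
                for m in SWEEP_METRICS
            }
        results.append(SweepResult(
            algorithm=spec.algorithm, participant_id=pid, per_k=per_k,
            records=pd.DataFrame(rows) if keep_records else None))
    return results


def plateau_onset(mean_metric_by_k: Mapping[int, float] | Sequence[float],
                  rel_tol: float = 0.05,
                  metric: str = "overall_accuracy") -> PlateauReport:
    """Find where a metric-vs-k curve plateaus.

    The relative change at k is |m_k - m_{k-1}| / m_{k-1}; the onset is the
    smallest k with relative change <= ``rel_tol`` (None if never).  A
    decrease within tolerance also counts, since plateaus are about the
    magnitude of change, not its sign.
    """
    if isinstance(mean_metric_by_k, Mapping):
        ks = sorted(mean_metric_by_k)
        values = [mean_metric_by_k[k] for k in ks]
    else:
        values = list(mean_metric_by_k)
        ks = list(range(1, len(values) + 1))
    if len(values) < 2:
        raise ValueError("need at least two values")
    if any(v <= 0 for v in values):
        raise ValueError("metric values must be positive")
    rel_changes = []
    onset, onset_val = None, None
    for prev_k, k, prev_v, v in zip(ks, ks[1:], values, values[1:]):
        rc = abs(v - prev_v) / prev_v
        rel_changes.append((k, rc))
        if onset is None and rc <= rel_tol:
            onset, onset_val = k, v
    return PlateauReport(metric=metric, onset_k=onset,
                         value_at_onset=onset_val, rel_changes=rel_changes)


def fit_log_curve(ks: Sequence[float], mean_accuracies: Sequence[float]
                  ) -> dict[str, float]:
    """Least-squares fit of acc = a + b*ln(k); returns a, b and R²."""
    ks = np.asarray(ks, dtype=float)
    acc = np.asarray(mean_accuracies, dtype=float)
    if ks.size < 3:
        raise ValueError("need at least three points")
    if (ks < 1).any():
        raise ValueError("k values must be >= 1")
    res = stats.linregress(np.log(ks), acc)
    return {"a": float(res.intercept), "b": float(res.slope),
            "r_squared": float(res.rvalue ** 2)}


def aggregate_participants(results: Sequence[SweepResult]) -> dict:
    """Aggregate sweep results across participants.

    ``results`` is a flat list of per-participant :class:`SweepResult`
    objects (grouped internally by algorithm).  For each (algorithm, k):
    the mean ± SD across participants of the per-k mean metrics and the
    participant min–max range; plus, per algorithm, the mean ± SD of that
    range across k and the maximum mean overall accuracy.
    """
    if not results:
        raise ValueError("no sweep results given")
    by_algo: dict[str, list[SweepResult]] = {}
    for r in results:
        by_algo.setdefault(r.algorithm, []).append(r)

    report: dict = {"algorithms": {}}
    for algo, algo_results in by_algo.items():
        k_sets = {tuple(sorted(r.per_k)) for r in algo_results}
        if len(k_sets) != 1:
            raise ValueError(f"heterogeneous k ranges for {algo}: {k_sets}")
        ks = sorted(algo_results[0].per_k)
        per_k = {}
        ranges = []
        for k in ks:
            entry = {}
            for m in SWEEP_METRICS:
                vals = np.array([r.per_k[k][m]["mean"] for r in algo_results])
                entry[m] = {
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "range": float(np.ptp(vals)),
                }
            per_k[k] = entry
            ranges.append(entry["overall_accuracy"]["range"])
        ranges = np.array(ranges)
        acc_means = [per_k[k]["overall_accuracy"]["mean"] for k in ks]
        report["algorithms"][algo] = {
            "n_participants": len(algo_results),
            "per_k": per_k,
            "range_mean": float(ranges.mean()),
            "range_sd": float(ranges.std(ddof=1)) if ranges.size > 1 else 0.0,
            "max_overall_accuracy": float(max(acc_means)),
            "max_overall_accuracy_k": int(ks[int(np.argmax(acc_means))]),
        }
    return report
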