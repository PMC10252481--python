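"""Run-evaluation arithmetic: mean accuracy, box statistics, confusion rates.

A BO run of N iterations is summarized by the arithmetic mean of its N
per-iteration accuracies, μ = Σ xᵢ / N, alongside the five-number summary
used for box plots.  Classifier test performance is summarized by a 6×6
confusion matrix whose row-normalized diagonal gives the per-class
correct-classification rate (the reference study calls these rates
"precision"); the overall figure is their unweighted mean.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np

__all__ = ["SummaryStats", "ConfusionSummary", "mean_accuracy",
           "summary_stats", "confusion_summary", "compare_table"]


@dataclass(frozen=True)
class SummaryStats:
    """Mean plus five-number summary, all in percent."""

    mean: float
    max: float
    min: float
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class ConfusionSummary:
    counts: np.ndarray            # rows = actual, columns = predicted
    classes: tuple
    per_class_rate: np.ndarray    # percent; NaN for unsupported classes
    overall: float                # unweighted mean of defined rates, percent


def mean_accuracy(values: Sequence[float]) -> float:
    """Arithmetic mean Σxᵢ/N of the per-iteration accuracies."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    return float(values.mean())


def summary_stats(values: Sequence[float]) -> SummaryStats:
    """Mean, extrema, median and linearly interpolated quartiles."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return SummaryStats(mean=float(values.mean()),
                        max=float(values.max()), min=float(values.min()),
                        median=float(med), q1=float(q1), q3=float(q3))


def confusion_summary(y_true: Sequence, y_pred: Sequence,
                      classes: Sequence) -> ConfusionSummary:
    """Tally the confusion matrix and per-actual-class correct rates.

    Rows with zero support have an undefined rate (NaN) and are excluded
    from the overall mean with a warning.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    unknown = (set(y_true) | set(y_pred)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class list: {sorted(unknown)}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    support = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = 100.0 * np.diag(counts) / support
    if (support == 0).any():
        missing = [c for c, s in zip(classes, support) if s == 0]
        warnings.warn(f"classes with zero support excluded from the overall "
                      f"rate: {missing}", stacklevel=2)
    overall = float(np.nanmean(np.where(support > 0, rate, np.nan)))
    return ConfusionSummary(counts=counts, classes=classes,
                            per_class_rate=rate, overall=overall)


def compare_table(traces: Mapping[str, Sequence]) -> list:
    """Per-variant summary rows in comparison-table order.

    ``traces`` maps a variant name to a list of runs, each run being either
    a :class:`~swarmbo.bo.Trace` or a bare sequence of per-iteration values.
    Returns one row dict per (variant, run) plus a pooled ``all-runs`` row
    per variant when there are multiple runs.
    """
    if not traces:
        raise ValueError("need at least one variant")
    rows = []
    for variant, runs in traces.items():
        if len(runs) == 0:
            raise ValueError(f"variant {variant!r} has no runs")
        pooled = []
        for i, run in enumerate(runs, start=1):
            values = np.asarray(getattr(run, "values", run), dtype=float)
            if values.size == 0:
                raise ValueError(f"variant {variant!r} run {i} is empty")
            pooled.append(values)
            s = summary_stats(values)
            rows.append({"variant": variant, "run": str(i),
                         "mean": s.mean, "max": s.max, "min": s.min})
        if len(runs) > 1:
            s = summary_stats(np.concatenate(pooled))
            rows.append({"variant": variant, "run": "all-runs",
                         "mean": s.mean, "max": s.max, "min": s.min})
    return rows


def compare_table_csv(rows: Sequence[Mapping]) -> str:
    """Serialize :func:`compare_table` rows as CSV."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["Acquisition Function", "Run",
                     "Mean Accuracy (%)", "Max Accuracy (%)",
                     "Min Accuracy (%)"])
    for r in rows:
        writer.writerow([r["variant"], r["run"],
                         f"{r['mean']:.2f}", f"{r['max']:.2f}",
                         f"{r['min']:.2f}"])
    return buf.getvalue()
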