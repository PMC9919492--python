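"""K-fold evaluation harness and cross-algorithm comparison reports.

``run_kfold`` fits one classifier spec on every fold (train parts, with the
tune part available for early stopping), predicts the held-out test part and
collects confusion counts and metrics.  Two aggregations are reported side by
side: the mean (and sample SD, ddof=1) of the per-fold metrics, and the
metrics of the fold-averaged confusion matrix.  The two can differ in the
third decimal because metric-of-mean is not mean-of-metric.

``compare_algorithms`` runs several specs on the *identical* folds so their
metric distributions are directly comparable, and adds a descriptive timing
summary (wall-clock per fit; hardware-bound, reported but never asserted on).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import FoldSplit
from .featurize import InstanceSet
from .metrics import ConfusionCounts, MetricSet, confusion, metrics_from_counts
from .models import ClassifierSpec, build

__all__ = ["FoldOutcome", "KFoldResult", "ComparisonReport", "run_kfold", "compare_algorithms"]


@dataclass(frozen=True)
class FoldOutcome:
    fold_index: int
    counts: ConfusionCounts
    metrics: MetricSet
    fit_seconds: float
    n_iterations: int | None
    single_class_test: bool = False


@dataclass
class KFoldResult:
    """All per-fold outcomes for one classifier spec, plus aggregates."""

    spec: ClassifierSpec
    folds: list[FoldOutcome]

    @property
    def K(self) -> int:
        return len(self.folds)

    def _metric_matrix(self) -> pd.DataFrame:
        return pd.DataFrame([f.metrics.as_dict() for f in self.folds])

    @property
    def mean_metrics(self) -> dict[str, float]:
        return self._metric_matrix().mean().to_dict()

    @property
    def sd_metrics(self) -> dict[str, float]:
        return self._metric_matrix().std(ddof=1).to_dict()

    @property
    def mean_confusion(self) -> ConfusionCounts:
        k = self.K
        total = self.folds[0].counts
        for f in self.folds[1:]:
            total = total + f.counts
        return total.scaled(1.0 / k)

    @property
    def metrics_of_mean_confusion(self) -> MetricSet:
        return metrics_from_counts(self.mean_confusion)

    @property
    def mean_fit_seconds(self) -> float:
        return float(np.mean([f.fit_seconds for f in self.folds]))

    @property
    def fit_seconds(self) -> list[float]:
        return [f.fit_seconds for f in self.folds]

    def summary(self) -> pd.DataFrame:
        """One row per metric: mean (SD) over folds and metric-of-mean-matrix."""
        mm = self.mean_metrics
        sd = self.sd_metrics
        of_mean = self.metrics_of_mean_confusion.as_dict()
        return pd.DataFrame(
            {
                "mean_over_folds": mm,
                "sd_over_folds": sd,
                "of_mean_confusion": of_mean,
            }
        )

    def as_dict(self) -> dict:
        cc = self.mean_confusion
        return {
            "spec": self.spec.as_dict(),
            "K": self.K,
            "mean_metrics": self.mean_metrics,
            "sd_metrics": self.sd_metrics,
            "mean_confusion": {"tp": cc.tp, "tn": cc.tn, "fp": cc.fp, "fn": cc.fn},
            "metrics_of_mean_confusion": self.metrics_of_mean_confusion.as_dict(),
            "fit_seconds": self.fit_seconds,
        }


def run_kfold(
    balanced: InstanceSet, folds: list[FoldSplit], spec: ClassifierSpec
) -> KFoldResult:
    """Fit/predict the spec on every fold of a balanced instance set."""
    if not folds:
        raise ValueError("no folds supplied")
    outcomes = []
    for fold in folds:
        clf = build(spec)
        Xtr, ytr = balanced.X[fold.train_ids], balanced.y[fold.train_ids]
        Xtu, ytu = balanced.X[fold.tune_ids], balanced.y[fold.tune_ids]
        Xte, yte = balanced.X[fold.test_ids], balanced.y[fold.test_ids]
        report = clf.fit(Xtr, ytr, Xtu, ytu)
        pred = clf.predict(Xte)
        single = len(np.unique(yte)) < 2
        if single:
            warnings.warn(
                f"fold {fold.fold_index}: single-class test set; "
                "some metrics undefined",
                RuntimeWarning,
                stacklevel=2,
            )
        cc = confusion(yte, pred)
        outcomes.append(
            FoldOutcome(
                fold_index=fold.fold_index,
                counts=cc,
                metrics=metrics_from_counts(cc),
                fit_seconds=report.wall_clock_s,
                n_iterations=report.n_iterations,
                single_class_test=single,
            )
        )
    return KFoldResult(spec=spec, folds=outcomes)


@dataclass
class ComparisonReport:
    """Results of several specs evaluated on identical folds."""

    results: list[KFoldResult] = field(default_factory=list)

    def _names(self) -> list[str]:
        names = []
        for r in self.results:
            name = r.spec.kind
            if r.spec.architecture is not None:
                name += str(list(r.spec.architecture.hidden_layers))
            names.append(name)
        return names

    def metrics_table(self) -> pd.DataFrame:
        """Mean (SD) of each metric per algorithm, over folds."""
        rows = []
        for r in self.results:
            mm, sd = r.mean_metrics, r.sd_metrics
            rows.append(
                {
                    f"{m}_{suffix}": vals[m]
                    for m in ("accuracy", "mcc", "sensitivity", "specificity")
                    for suffix, vals in (("mean", mm), ("sd", sd))
                }
            )
        return pd.DataFrame(rows, index=self._names()).rename_axis("algorithm")

    def confusion_table(self) -> pd.DataFrame:
        """Fold-averaged confusion matrix per algorithm."""
        rows = []
        for r in self.results:
            cc = r.mean_confusion
            rows.append({"tp": cc.tp, "tn": cc.tn, "fp": cc.fp, "fn": cc.fn})
        return pd.DataFrame(rows, index=self._names()).rename_axis("algorithm")

    def timing_table(self) -> pd.DataFrame:
        """Descriptive fit-time summary (seconds): min/max/mean/SD/95% CI."""
        rows = []
        for r in self.results:
            t = np.asarray(r.fit_seconds)
            mean, sd = t.mean(), t.std(ddof=1) if t.size > 1 else 0.0
            rows.append(
                {
                    "min_s": t.min(),
                    "max_s": t.max(),
                    "mean_s": mean,
                    "sd_s": sd,
                    "ci_low_s": mean - 1.96 * sd,
                    "ci_high_s": mean + 1.96 * sd,
                }
            )
        return pd.DataFrame(rows, index=self._names()).rename_axis("algorithm")

    def write(self, outdir: str | Path) -> None:
        """Emit metrics/confusion tables (CSV + JSON) and timing separately.

        Timing goes to its own file so the other artifacts stay
        byte-reproducible across reruns.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics_table().to_csv(outdir / "metrics.csv")
        self.confusion_table().to_csv(outdir / "confusion.csv")
        self.timing_table().to_csv(outdir / "timing.csv")
        payload = [r.as_dict() for r in self.results]
        for entry in payload:
            entry.pop("fit_seconds", None)
        with open(outdir / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2)


def compare_algorithms(
    balanced: InstanceSet, folds: list[FoldSplit], specs: list[ClassifierSpec]
) -> ComparisonReport:
    """Evaluate every spec on the identical precomputed folds."""
    if not specs:
        raise ValueError("at least one classifier spec required")
    return ComparisonReport(results=[run_kfold(balanced, folds, s) for s in specs])
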