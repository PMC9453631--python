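"""Repeated stratified k-fold benchmarking of tissue classifiers.

Spectra from all patients are pooled, split with 5-fold x 5-repeat
stratified cross-validation, and scored with accuracy, sensitivity
(tumor detection rate), specificity (normal recognition rate) and AUC;
aggregates are reported as mean (SD over the 25 split-level values,
ddof=1).  Tumor is the positive class throughout.

An optional patient-grouped splitter is provided for leakage-aware
evaluation; it deviates from the pooled protocol and is labelled as such
in its output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedGroupKFold

from .errors import (
    ConfigError,
    DegenerateSplitError,
    StratificationError,
    UndefinedMetricError,
)
from .estimators import CLASSIFIER_NAMES, decision_scores, make_estimator
from .features import FeatureTable


@dataclass
class CVPlan:
    n_folds: int = 5
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")

    @property
    def n_splits(self) -> int:
        return self.n_folds * self.n_repeats


def make_splits(
    table: FeatureTable, plan: CVPlan
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Label-stratified train/test index pairs, fully seeded.

    Within each repeat the test folds are disjoint and cover every row;
    per-fold class counts are within one of the proportional ideal.
    """
    y = table.y
    counts = np.bincount(y, minlength=2)
    if counts.min() < plan.n_folds:
        raise StratificationError(
            f"smallest class has {counts.min()} rows < {plan.n_folds} folds"
        )
    cv = RepeatedStratifiedKFold(
        n_splits=plan.n_folds, n_repeats=plan.n_repeats, random_state=plan.seed
    )
    return [(tr.copy(), te.copy()) for tr, te in cv.split(np.zeros(len(y)), y)]


def make_group_splits(
    table: FeatureTable, plan: CVPlan
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Patient-grouped stratified splits (deviation from the pooled protocol:
    no patient appears in both train and test of a split)."""
    y, groups = table.y, table.groups
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    for rep in range(plan.n_repeats):
        cv = StratifiedGroupKFold(
            n_splits=plan.n_folds, shuffle=True, random_state=plan.seed + rep
        )
        splits.extend(
            (tr.copy(), te.copy())
            for tr, te in cv.split(np.zeros(len(y)), y, groups)
        )
    return splits


@dataclass
class ConfusionCounts:
    """Binary confusion counts with tumor as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ConfigError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity and specificity from confusion counts."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise UndefinedMetricError("a class is absent from the test set")
    return {
        "accuracy": (counts.tp + counts.tn) / counts.total,
        "sensitivity": counts.tp / (counts.tp + counts.fn),
        "specificity": counts.tn / (counts.tn + counts.fp),
    }


def roc_and_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[pd.DataFrame, float]:
    """ROC by threshold sweep (ties grouped) and trapezoidal AUC.

    The AUC equals the Mann-Whitney U statistic normalised by n+ * n-:
    the probability that a random tumor site outscores a random normal one.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ConfigError("non-finite scores")
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC undefined with one class")
    fpr, tpr, thr = roc_curve(labels, scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return points, float(_trapezoid_auc(fpr, tpr))


@dataclass
class EvaluationReport:
    """Per-split metrics plus mean (SD) aggregates per classifier."""

    per_split: pd.DataFrame  # classifier, repeat, fold, metrics, failed
    roc_points: pd.DataFrame  # classifier, repeat, fold, fpr, tpr, threshold
    plan: CVPlan
    failures: list[str] = field(default_factory=list)

    METRICS = ("accuracy", "sensitivity", "specificity", "auc")

    def aggregate(self) -> pd.DataFrame:
        ok = self.per_split[~self.per_split["failed"]]
        rows = []
        for clf, grp in ok.groupby("classifier", sort=True):
            row: dict[str, object] = {"classifier": clf, "n_splits": len(grp)}
            for m in self.METRICS:
                row[f"{m}_mean"] = grp[m].mean()
                row[f"{m}_sd"] = grp[m].std(ddof=1)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [
            f"Repeated stratified CV: {self.plan.n_folds} folds x "
            f"{self.plan.n_repeats} repeats (seed {self.plan.seed})",
            f"{'classifier':<12}"
            + "".join(f"{m:>22}" for m in self.METRICS),
        ]
        for _, r in agg.iterrows():
            cells = "".join(
                f"{r[f'{m}_mean']:>14.3f} ({r[f'{m}_sd']:.3f})"
                for m in self.METRICS
            )
            lines.append(f"{r['classifier']:<12}{cells}")
        if self.failures:
            lines.append(f"failed splits: {len(self.failures)}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        long = self.per_split.melt(
            id_vars=["classifier", "repeat", "fold", "failed"],
            value_vars=list(self.METRICS),
            var_name="metric",
            value_name="value",
        )
        long.to_csv(path, index=False)

    def to_json(self, path) -> None:
        agg = self.aggregate().set_index("classifier")
        payload = {
            "plan": {
                "n_folds": self.plan.n_folds,
                "n_repeats": self.plan.n_repeats,
                "seed": self.plan.seed,
            },
            "aggregate": json.loads(agg.to_json(orient="index")),
            "n_failures": len(self.failures),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def run_benchmark(
    table: FeatureTable,
    plan: CVPlan | None = None,
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
    group_aware: bool = False,
) -> EvaluationReport:
    """Fit and score every classifier on every CV split.

    A split on which a classifier fails to train (or whose test fold lost a
    class, possible only with the group-aware splitter) is marked failed,
    excluded from aggregates and surfaced in the report.
    """
    plan = plan or CVPlan()
    splits = (
        make_group_splits(table, plan) if group_aware else make_splits(table, plan)
    )
    y = table.y
    X = table.X
    rows, roc_rows, failures = [], [], []
    for s, (tr, te) in enumerate(splits):
        rep, fold = divmod(s, plan.n_folds)
        for name in classifiers:
            record = {
                "classifier": name,
                "repeat": rep,
                "fold": fold,
                "failed": False,
            }
            try:
                if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                    raise DegenerateSplitError("single-class fold")
                est = make_estimator(name, plan.seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[tr], y[tr])
                pred = est.predict(X[te])
                record.update(
                    compute_metrics(ConfusionCounts.from_predictions(y[te], pred))
                )
                points, auc_val = roc_and_auc(decision_scores(est, X[te]), y[te])
                record["auc"] = auc_val
                points = points.assign(classifier=name, repeat=rep, fold=fold)
                roc_rows.append(points)
            except Exception as exc:  # noqa: BLE001 — surfaced in the report
                record["failed"] = True
                record.update({m: np.nan for m in EvaluationReport.METRICS})
                failures.append(f"{name} split {s}: {exc}")
            rows.append(record)
    per_split = pd.DataFrame(rows)
    roc_points = (
        pd.concat(roc_rows, ignore_index=True)
        if roc_rows
        else pd.DataFrame(columns=["fpr", "tpr", "threshold"])
    )
    return EvaluationReport(per_split, roc_points, plan, failures)


def plot_roc(report: EvaluationReport, path=None):
    """Mean ROC curve per classifier (one line each), matplotlib Figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    grid = np.linspace(0, 1, 201)
    for clf, grp in report.roc_points.groupby("classifier", sort=True):
        curves = []
        for _, g in grp.groupby(["repeat", "fold"]):
            curves.append(np.interp(grid, g["fpr"], g["tpr"]))
        agg = report.aggregate().set_index("classifier")
        ax.plot(
            grid,
            np.mean(curves, axis=0),
            label=f"{clf} (AUC {agg.loc[clf, 'auc_mean']:.3f})",
        )
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
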