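"""Evaluation protocol: repeated stratified k-fold CV (or 70/30 holdout),
the seven per-class quality metrics, mean/SD summaries, and pairwise
t-tests between models.

Metrics are one-vs-rest per class (B, T, TB) from a 3x3 confusion matrix:
sensitivity, specificity, precision (= positive predictive value), negative
predictive value, predicted and true prevalence, and balanced accuracy
= (sensitivity + specificity) / 2.  "Prevalence" in the headline reports is
the PREDICTED class proportion; the true class proportion is carried
alongside under its own name.  The macro value is the unweighted mean over
the three classes.  Plain overall accuracy (trace / total) is also exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import (StratifiedGroupKFold, StratifiedKFold,
                                     train_test_split)

from rootclass.models import (ModelSpec, PredictionResult, apply_minmax,
                              fit_minmax, make_model)
from rootclass.synthetic_roots import CLASS_LABELS

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "precision",
                "prevalence_predicted", "prevalence_true", "balanced_accuracy")


@dataclass
class LabeledDataset:
    """Trait matrix + class labels + per-root lineage metadata.

    ``groups`` ties augmented replicates to their source image so grouped
    cross-validation can keep a root's descendants in one fold.
    """

    traits: pd.DataFrame  # rows x 38 trait columns
    labels: np.ndarray  # in {B, T, TB}
    image_ids: list[str] = field(default_factory=list)
    groups: np.ndarray | None = None  # source image id per row

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if len(self.traits) != len(self.labels):
            raise ValueError("traits and labels differ in length")
        if self.groups is None:
            self.groups = np.asarray(
                self.image_ids if self.image_ids else
                [str(i) for i in range(len(self.labels))])
        else:
            self.groups = np.asarray(self.groups)

    def __len__(self):
        return len(self.labels)


@dataclass
class ConfusionMatrix:
    """3x3 counts indexed (true class, predicted class) in B, T, TB order."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k) or (self.counts < 0).any():
            raise ValueError("counts must be a nonnegative k x k matrix")

    @classmethod
    def from_labels(cls, true_labels, predicted_labels,
                    classes: tuple[str, ...] = CLASS_LABELS) -> "ConfusionMatrix":
        t = np.asarray(true_labels)
        p = np.asarray(predicted_labels)
        if len(t) != len(p):
            raise ValueError("label vectors differ in length")
        k = len(classes)
        idx = {c: i for i, c in enumerate(classes)}
        m = np.zeros((k, k), dtype=int)
        for a, b in zip(t, p):
            m[idx[a], idx[b]] += 1
        return cls(m, classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls_idx: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for one class under one-vs-rest collapse."""
        tp = self.counts[cls_idx, cls_idx]
        fn = self.counts[cls_idx].sum() - tp
        fp = self.counts[:, cls_idx].sum() - tp
        tn = self.total - tp - fn - fp
        return int(tp), int(fp), int(tn), int(fn)


@dataclass
class MetricReport:
    """Per-class and macro-mean values of the quality metrics."""

    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    overall_accuracy: float
    confusion: ConfusionMatrix | None = None

    def table(self) -> pd.DataFrame:
        """Metrics x (B, T, TB, macro) table, the shape of the headline
        summary tables."""
        cols = {c: [self.per_class[c][m] for m in METRIC_NAMES]
                for c in CLASS_LABELS}
        cols["macro"] = [self.macro[m] for m in METRIC_NAMES]
        return pd.DataFrame(cols, index=list(METRIC_NAMES))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Quality metrics from a confusion matrix.

    A class with a zero denominator reports NaN for that metric and is
    excluded from the macro mean with a warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    for i, c in enumerate(cm.classes):
        tp, fp, tn, fn = cm.one_vs_rest(i)
        sens = _safe_div(tp, tp + fn)
        spec = _safe_div(tn, tn + fp)
        ppv = _safe_div(tp, tp + fp)
        npv = _safe_div(tn, tn + fn)
        per_class[c] = {
            "sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv,
            "precision": ppv,
            "prevalence_predicted": (tp + fp) / cm.total,
            "prevalence_true": (tp + fn) / cm.total,
            "balanced_accuracy": (sens + spec) / 2.0,
        }
    macro = {}
    for m in METRIC_NAMES:
        vals = np.array([per_class[c][m] for c in cm.classes])
        if np.isnan(vals).any():
            warnings.warn(f"metric {m!r} undefined for some class; macro mean "
                          "taken over the defined classes", stacklevel=2)
        macro[m] = float(np.nanmean(vals))
    overall = float(np.trace(cm.counts) / cm.total)
    return MetricReport(per_class, macro, overall, cm)


@dataclass(frozen=True)
class CVPlan:
    """Cross-validation scheme: 3x-repeated stratified 5-fold, or a 70/30
    stratified holdout.  ``grouped_by_source`` keeps all augmented
    descendants of one source image in the same fold as the source."""

    scheme: str = "repeated_kfold"  # or "holdout"
    k: int = 5
    repeats: int = 3
    train_fraction: float = 0.7
    stratified: bool = True
    grouped_by_source: bool = True
    seed: int = 0
    cluster_scope: str = "full"  # or "per_fold" for unsupervised models

    def __post_init__(self):
        if self.scheme not in ("repeated_kfold", "holdout"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


def make_folds(labels, groups, plan: CVPlan) -> list[tuple[int, int, np.ndarray]]:
    """(repeat, fold, test_indices) triples for the plan.

    Stratified by class; grouped when requested so no source image
    straddles folds.  Deterministic under the plan's seed.  Classes with
    fewer members than k degrade to best-effort stratification with a
    warning (inherited from scikit-learn).
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    n = len(labels)
    if plan.scheme == "holdout":
        idx = np.arange(n)
        strat = labels if plan.stratified else None
        _, test_idx = train_test_split(
            idx, test_size=round(n * (1.0 - plan.train_fraction)),
            stratify=strat, random_state=plan.seed)
        return [(0, 0, np.sort(test_idx))]
    if n < plan.k:
        raise ValueError(f"n={n} smaller than k={plan.k}")
    out = []
    for r in range(plan.repeats):
        if plan.grouped_by_source and len(np.unique(groups)) < n:
            splitter = StratifiedGroupKFold(n_splits=plan.k, shuffle=True,
                                            random_state=plan.seed + r)
            split = splitter.split(np.zeros(n), labels, groups)
        else:
            splitter = StratifiedKFold(n_splits=plan.k, shuffle=True,
                                       random_state=plan.seed + r)
            split = splitter.split(np.zeros(n), labels)
        for f, (_, test_idx) in enumerate(split):
            out.append((r, f, np.sort(test_idx)))
    return out


@dataclass
class FoldReport:
    repeat: int
    fold: int
    report: MetricReport | None
    error: str | None = None


@dataclass
class EvaluationResult:
    """All per-fold reports, the pooled report, and per-root predictions."""

    model_name: str
    fold_reports: list[FoldReport]
    pooled: MetricReport
    predictions: pd.DataFrame  # repeat, fold, row, true, predicted, probs

    @property
    def failed_folds(self) -> list[tuple[int, int]]:
        return [(fr.repeat, fr.fold) for fr in self.fold_reports if fr.error]

    def macro_balanced_accuracies(self) -> np.ndarray:
        """Per-(fold, repeat) macro balanced accuracy vector for t-tests."""
        return np.array([fr.report.macro["balanced_accuracy"]
                         for fr in self.fold_reports if fr.report is not None])


def _prediction_rows(repeat, fold, indices, truths, preds):
    rows = []
    for i, tr, pr in zip(indices, truths, preds):
        rows.append({"repeat": repeat, "fold": fold, "row": int(i),
                     "true": tr, "predicted": pr.predicted_class,
                     "prob_B": pr.probabilities[0],
                     "prob_T": pr.probabilities[1],
                     "prob_TB": pr.probabilities[2],
                     "max_probability": pr.max_probability})
    return rows


def evaluate_model(spec: ModelSpec, dataset: LabeledDataset, plan: CVPlan,
                   seed: int | None = None) -> EvaluationResult:
    """Run the CV protocol for one model and collect metrics + predictions.

    Supervised models: min-max normalization is fit on each training fold
    only, then the model is trained on the fold and scored on its test
    portion.  Unsupervised models (default scope "full"): the full matrix
    is normalized and clustered once, clusters are aligned to classes by
    optimal agreement, and metrics are scored within each test fold; scope
    "per_fold" clusters and aligns each test portion independently.

    A model failure in one fold marks that fold failed and the run
    continues.
    """
    seed = plan.seed if seed is None else seed
    folds = make_folds(dataset.labels, dataset.groups, plan)
    X = dataset.traits
    y = dataset.labels
    fold_reports: list[FoldReport] = []
    pred_rows: list[dict] = []
    pooled_true: list[str] = []
    pooled_pred: list[str] = []

    full_preds: list[PredictionResult] | None = None
    if not spec.supervised and plan.cluster_scope == "full":
        params = fit_minmax(X)
        Xn = apply_minmax(X, params)
        model = make_model(spec, seed)
        model.fit(Xn)
        model.align(y)
        full_preds = model.predict(Xn)

    for repeat, fold, test_idx in folds:
        try:
            if spec.supervised:
                train_mask = np.ones(len(dataset), dtype=bool)
                train_mask[test_idx] = False
                params = fit_minmax(X[train_mask])
                Xtr = apply_minmax(X[train_mask], params)
                Xte = apply_minmax(X.iloc[test_idx] if isinstance(X, pd.DataFrame)
                                   else X[test_idx], params)
                model = make_model(spec, seed + repeat)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(Xtr, y[train_mask])
                preds = model.predict(Xte)
            elif full_preds is not None:
                preds = [full_preds[i] for i in test_idx]
            else:  # per-fold clustering of the test portion
                params = fit_minmax(X.iloc[test_idx] if isinstance(X, pd.DataFrame)
                                    else X[test_idx])
                Xte = apply_minmax(X.iloc[test_idx] if isinstance(X, pd.DataFrame)
                                   else X[test_idx], params)
                model = make_model(spec, seed + repeat)
                model.fit(Xte)
                model.align(y[test_idx])
                preds = model.predict(Xte)
        except Exception as exc:
            fold_reports.append(FoldReport(repeat, fold, None, str(exc)))
            continue
        truths = y[test_idx]
        cm = ConfusionMatrix.from_labels(truths, [p.predicted_class for p in preds])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = compute_metrics(cm)
        fold_reports.append(FoldReport(repeat, fold, rep))
        pred_rows.extend(_prediction_rows(repeat, fold, test_idx, truths, preds))
        pooled_true.extend(truths)
        pooled_pred.extend(p.predicted_class for p in preds)

    if not pooled_true:
        raise RuntimeError(f"model {spec.name!r} failed in every fold")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled = compute_metrics(ConfusionMatrix.from_labels(pooled_true,
                                                             pooled_pred))
    return EvaluationResult(spec.name, fold_reports, pooled,
                            pd.DataFrame(pred_rows))


def summarize_cv(reports: list[MetricReport]) -> pd.DataFrame:
    """Mean and sample SD (n-1) per metric per class over fold reports."""
    if len(reports) < 2:
        raise ValueError("need at least two fold reports to summarize")
    rows = []
    for c in CLASS_LABELS + ("macro",):
        for m in METRIC_NAMES:
            vals = np.array([r.macro[m] if c == "macro" else r.per_class[c][m]
                             for r in reports])
            rows.append({"class": c, "metric": m,
                         "mean": float(np.nanmean(vals)),
                         "sd": float(np.nanstd(vals, ddof=1))})
    return pd.DataFrame(rows)


def compare_models(reports_a, reports_b, paired: bool = True
                   ) -> tuple[float, float]:
    """Two-sided t-test on per-fold macro balanced accuracies.

    Accepts EvaluationResult objects or plain vectors.  Paired when the
    folds match; identical vectors give (t, p) = (0, 1).
    """
    def vec(r):
        if isinstance(r, EvaluationResult):
            return r.macro_balanced_accuracies()
        return np.asarray(r, dtype=float)

    a, b = vec(reports_a), vec(reports_b)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal-length vectors")
        d = a - b
        if np.allclose(d, 0):
            return 0.0, 1.0
        t, p = stats.ttest_rel(a, b)
    else:
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            return 0.0, 1.0
        t, p = stats.ttest_ind(a, b)
    return float(t), float(p)
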