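"""Threshold classification, subject-wise repeated validation and reporting.

Each clinical task is a binary problem: label 1 iff the subject's scale
value is strictly greater than the task cutoff.  A regularized linear
discriminant (pooled within-class covariance with a small ridge, features
standardized on the training split) scores every test attempt; the
validation protocol repeatedly holds out all attempts of 2 randomly drawn
subjects (100 iterations by default), so no subject ever contributes to
both sides of a split.  Per-iteration metrics are summarized as mean +/- SD
over iterations, with undefined values (e.g. AUC on a single-class test
set) excluded and counted rather than imputed.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .emg_io import ClinicalScores, GestureLabel
from .exceptions import (
    ConfigurationError,
    LabelingError,
    ProtocolError,
    ValidationError,
)
from .features import (
    FeatureConfig,
    ThresholdTask,
    pair_columns,
    task_pair_for,
)

logger = logging.getLogger(__name__)

CURVE_GRID = np.linspace(0.0, 1.0, 101)


def binarize_label(scores: ClinicalScores, task: ThresholdTask) -> int:
    """1 iff the subject's scale value strictly exceeds the task cutoff."""
    value = getattr(scores, task.scale, None)
    if value is None:
        raise LabelingError(f"subject {scores.subject_id}: missing {task.scale}")
    return int(value > task.cutoff)


# ---------------------------------------------------------------------------
# linear discriminant


@dataclass
class LdaModel:
    """Two-class linear discriminant with ridge-regularized pooled covariance."""

    center: np.ndarray
    scale: np.ndarray
    means: np.ndarray          # (2, dim) standardized class means
    priors: np.ndarray         # (2,)
    w: np.ndarray              # decision direction in standardized space
    bias: float

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        """Signed discriminant scores; > 0 predicts class 1."""
        z = (np.asarray(x, dtype=float) - self.center) / self.scale
        return z @ self.w + self.bias

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.decision_scores(x) > 0).astype(int)


def fit_lda(x: np.ndarray, y: np.ndarray, ridge: float = 1e-6) -> LdaModel:
    """Fit the discriminant on standardized features.

    The decision direction is ``w = (S + ridge I)^-1 (mu1 - mu0)`` with S the
    pooled within-class covariance; the bias places the boundary at the
    equal-cost Bayes point for the fitted class priors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ConfigurationError("x must be (n, dim) aligned with y")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite feature values")
    classes = np.unique(y)
    if set(classes) != {0, 1}:
        raise ProtocolError("training set must contain both classes")
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    z = (x - center) / scale
    mu = np.stack([z[y == c].mean(axis=0) for c in (0, 1)])
    n0, n1 = np.sum(y == 0), np.sum(y == 1)
    resid = np.vstack([z[y == 0] - mu[0], z[y == 1] - mu[1]])
    dof = max(n0 + n1 - 2, 1)
    cov = resid.T @ resid / dof
    cov += ridge * np.eye(cov.shape[0])
    w = np.linalg.solve(cov, mu[1] - mu[0])
    priors = np.array([n0, n1], dtype=float) / (n0 + n1)
    bias = float(-0.5 * w @ (mu[0] + mu[1]) + np.log(priors[1] / priors[0]))
    return LdaModel(center, scale, mu, priors, w, bias)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class IterationMetrics:
    """Scores of one validation split (NaN marks an undefined metric)."""

    iteration: int
    test_subjects: tuple[str, ...]
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    rec: float
    prec: float
    spec: float
    f1: float
    auc_roc: float
    auc_prc: float
    roc_points: np.ndarray | None = None   # (n, 2) fpr, tpr
    prc_points: np.ndarray | None = None   # (n, 2) recall, precision

    METRIC_NAMES = ("acc", "rec", "prec", "spec", "f1", "auc_roc", "auc_prc")


def auc(labels: Sequence[int], scores: Sequence[float], kind: str = "ROC"):
    """Area under the ROC or PRC curve, with the curve points.

    ROC: trapezoid over the ranked-score curve (ties averaged), equal to the
    concordance probability with ties counted 1/2.  PRC: stepwise curve with
    the average-precision sum (no interpolation).  Returns ``(nan, None)``
    when only one class is present.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0 or len(np.unique(labels)) < 2:
        return float("nan"), None
    if kind == "ROC":
        fpr, tpr, _ = roc_curve(labels, scores)
        return float(roc_auc_score(labels, scores)), np.column_stack([fpr, tpr])
    if kind == "PRC":
        prec, rec, _ = precision_recall_curve(labels, scores)
        ap = float(average_precision_score(labels, scores))
        return ap, np.column_stack([rec[::-1], prec[::-1]])
    raise ConfigurationError(f"unknown curve kind {kind!r}")


def compute_metrics(
    labels: Sequence[int],
    scores: Sequence[float],
    iteration: int = 0,
    test_subjects: tuple[str, ...] = (),
    with_curves: bool = True,
) -> IterationMetrics:
    """Confusion counts at decision threshold 0 plus the ranking metrics.

    Precision is undefined (NaN) when nothing is predicted positive; recall
    and specificity are undefined on single-class test sets.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ConfigurationError("empty test set")
    pred = (scores > 0).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    acc_ = (tp + tn) / labels.size
    rec_ = tp / (tp + fn) if tp + fn else float("nan")
    prec_ = tp / (tp + fp) if tp + fp else float("nan")
    spec_ = tn / (tn + fp) if tn + fp else float("nan")
    if np.isnan(rec_) or np.isnan(prec_) or prec_ + rec_ == 0:
        f1_ = float("nan")
    else:
        f1_ = 2 * prec_ * rec_ / (prec_ + rec_)
    auc_roc, roc_pts = auc(labels, scores, "ROC")
    auc_prc, prc_pts = auc(labels, scores, "PRC")
    if not with_curves:
        roc_pts = prc_pts = None
    return IterationMetrics(
        iteration, tuple(test_subjects), tp, fp, tn, fn,
        acc_, rec_, prec_, spec_, f1_, auc_roc, auc_prc, roc_pts, prc_pts,
    )


# ---------------------------------------------------------------------------
# validation protocol


@dataclass
class LabeledDataset:
    """Attempt-level design matrix with subject ids and binary labels."""

    task: ThresholdTask
    gesture_set: tuple[GestureLabel, ...]
    x: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.y) == len(self.subject_ids)):
            raise ConfigurationError("misaligned dataset arrays")

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)


def build_task_dataset(
    feature_table: pd.DataFrame,
    scores: dict[str, ClinicalScores],
    task: ThresholdTask,
    gesture_set: Sequence[GestureLabel],
    n_channels: int = 4,
) -> LabeledDataset:
    """Assemble per-attempt vectors for a task and a 1- or 2-gesture set.

    For two-gesture sets, attempts are paired by attempt index and truncated
    to the shorter list; subjects missing any gesture of the set are excluded
    (logged).
    """
    gesture_set = tuple(GestureLabel(g) for g in gesture_set)
    if not 1 <= len(gesture_set) <= 2:
        raise ConfigurationError("gesture sets have 1 or 2 labels")
    cols_per_gesture = [
        pair_columns(task_pair_for(g, task), n_channels) for g in gesture_set
    ]
    rows, labels, sids = [], [], []
    for sid, sub in feature_table.groupby("subject_id", sort=True):
        if str(sid) not in scores:
            raise LabelingError(f"no clinical scores for subject {sid}")
        label = binarize_label(scores[str(sid)], task)
        per_gesture = []
        missing = False
        for g in gesture_set:
            block = sub[sub["label"] == g.value].sort_values("attempt_index")
            if block.empty:
                missing = True
                break
            per_gesture.append(block)
        if missing:
            logger.warning(
                "subject %s lacks gesture(s) for set %s; excluded",
                sid, "-".join(g.value for g in gesture_set),
            )
            continue
        n_att = min(len(b) for b in per_gesture)
        for i in range(n_att):
            vec = np.concatenate(
                [
                    b.iloc[i][cols].to_numpy(dtype=float)
                    for b, cols in zip(per_gesture, cols_per_gesture)
                ]
            )
            rows.append(vec)
            labels.append(label)
            sids.append(str(sid))
    if not rows:
        raise ProtocolError(f"no usable subjects for task {task.name}")
    return LabeledDataset(
        task, gesture_set, np.vstack(rows), np.asarray(labels), np.asarray(sids)
    )


def run_repeated_holdout(
    dataset: LabeledDataset,
    n_iter: int = 100,
    n_test_subjects: int = 2,
    seed: int | np.random.Generator = 0,
    ridge: float = 1e-6,
    aggregation: str = "attempt",
    max_redraws: int = 1000,
    with_curves: bool = True,
) -> list[IterationMetrics]:
    """Repeated subject-wise holdout: each iteration tests all attempts of
    ``n_test_subjects`` randomly drawn subjects and trains on the rest.

    Draws with a single-class training set are redrawn (bounded); attempt-level
    scoring is the default, ``aggregation='subject'`` majority-votes each test
    subject's predictions and averages its scores instead.
    """
    if aggregation not in ("attempt", "subject"):
        raise ConfigurationError("aggregation must be 'attempt' or 'subject'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subjects = dataset.subjects
    if subjects.size < n_test_subjects + 2:
        raise ProtocolError(
            f"need at least {n_test_subjects + 2} subjects, have {subjects.size}"
        )
    results = []
    for it in range(n_iter):
        for _ in range(max_redraws):
            test_subjects = rng.choice(subjects, size=n_test_subjects, replace=False)
            test_mask = np.isin(dataset.subject_ids, test_subjects)
            y_train = dataset.y[~test_mask]
            if len(np.unique(y_train)) == 2:
                break
        else:
            raise ProtocolError(
                f"no two-class training split found in {max_redraws} redraws"
            )
        model = fit_lda(dataset.x[~test_mask], y_train, ridge=ridge)
        scores = model.decision_scores(dataset.x[test_mask])
        labels = dataset.y[test_mask]
        if aggregation == "subject":
            sub_scores, sub_labels = [], []
            sids = dataset.subject_ids[test_mask]
            for s in test_subjects:
                m = sids == s
                sub_scores.append(float(np.mean(scores[m])))
                sub_labels.append(int(labels[m][0]))
            scores = np.asarray(sub_scores)
            labels = np.asarray(sub_labels)
        results.append(
            compute_metrics(
                labels, scores, iteration=it,
                test_subjects=tuple(sorted(map(str, test_subjects))),
                with_curves=with_curves,
            )
        )
    return results


def run_subject_kfold(
    dataset: LabeledDataset,
    n_folds: int = 10,
    seed: int | np.random.Generator = 0,
    ridge: float = 1e-6,
    aggregation: str = "attempt",
    with_curves: bool = True,
) -> list[IterationMetrics]:
    """Alternative validation mode: one pass of subject-wise k-fold CV.

    Subjects are shuffled once and partitioned into ``n_folds`` groups; each
    fold's attempts form one test set.  Folds whose complement is
    single-class are skipped with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subjects = dataset.subjects.copy()
    if subjects.size < n_folds:
        raise ProtocolError(f"need at least {n_folds} subjects for {n_folds}-fold CV")
    rng.shuffle(subjects)
    folds = np.array_split(subjects, n_folds)
    results = []
    for it, fold in enumerate(folds):
        test_mask = np.isin(dataset.subject_ids, fold)
        y_train = dataset.y[~test_mask]
        if len(np.unique(y_train)) < 2:
            warnings.warn(f"fold {it}: single-class training set, skipped", stacklevel=2)
            continue
        model = fit_lda(dataset.x[~test_mask], y_train, ridge=ridge)
        scores = model.decision_scores(dataset.x[test_mask])
        labels = dataset.y[test_mask]
        if aggregation == "subject":
            sids = dataset.subject_ids[test_mask]
            scores = np.array([float(np.mean(scores[sids == s])) for s in fold])
            labels = np.array([int(labels[sids == s][0]) for s in fold])
        results.append(
            compute_metrics(labels, scores, iteration=it,
                            test_subjects=tuple(sorted(map(str, fold))),
                            with_curves=with_curves)
        )
    if not results:
        raise ProtocolError("every fold had a single-class training set")
    return results


# ---------------------------------------------------------------------------
# summaries


@dataclass
class ValidationSummary:
    """Mean/SD of every metric over iterations plus averaged curve bands."""

    n_iterations: int
    means: dict[str, float]
    sds: dict[str, float]
    undefined_counts: dict[str, int]
    roc_band: np.ndarray | None = None   # (101, 3): grid, mean TPR, SD
    prc_band: np.ndarray | None = None   # (101, 3): grid, mean precision, SD


def _vertical_average(curves: list[np.ndarray], grid: np.ndarray) -> np.ndarray | None:
    interp = []
    for pts in curves:
        if pts is None:
            continue
        x, y = pts[:, 0], pts[:, 1]
        order = np.argsort(x, kind="stable")
        interp.append(np.interp(grid, x[order], y[order]))
    if not interp:
        return None
    stack = np.vstack(interp)
    return np.column_stack([grid, stack.mean(axis=0), stack.std(axis=0, ddof=1)])


def summarize(iterations: Sequence[IterationMetrics]) -> ValidationSummary:
    """Aggregate repeated-holdout iterations.

    Means and sample SDs are computed over the iterations where a metric is
    defined; the count of undefined iterations is reported per metric.  Curve
    bands are vertical averages on a fixed 101-point grid.
    """
    if len(iterations) < 2:
        raise ConfigurationError("summaries need at least 2 iterations")
    means, sds, undef = {}, {}, {}
    for name in IterationMetrics.METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in iterations], dtype=float)
        ok = ~np.isnan(vals)
        undef[name] = int(np.sum(~ok))
        if ok.sum() == 0:
            means[name] = float("nan")
            sds[name] = float("nan")
        else:
            means[name] = float(vals[ok].mean())
            sds[name] = float(vals[ok].std(ddof=1)) if ok.sum() > 1 else 0.0
    roc_band = _vertical_average([m.roc_points for m in iterations], CURVE_GRID)
    prc_band = _vertical_average([m.prc_points for m in iterations], CURVE_GRID)
    return ValidationSummary(len(iterations), means, sds, undef, roc_band, prc_band)


# ---------------------------------------------------------------------------
# model comparison


def compare_models(acc_a: Sequence[float], acc_b: Sequence[float]) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U comparison of two accuracy samples.

    Exact enumeration for small tie-free samples (< 20 per group), otherwise
    the tie-corrected normal approximation.  Returns (U of the first sample,
    p-value, significance stars at 0.05 / 0.01 / 0.001).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size < 20 and b.size < 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
    return float(res.statistic), p, stars


# ---------------------------------------------------------------------------
# the full task x gesture-set matrix


def gesture_sets(labels: Sequence[GestureLabel] = tuple(GestureLabel)) -> list[tuple[GestureLabel, ...]]:
    """The 7 single-gesture sets followed by the 21 unordered pairs."""
    labels = [GestureLabel(g) for g in labels]
    singles = [(g,) for g in labels]
    pairs = [tuple(p) for p in itertools.combinations(labels, 2)]
    return singles + pairs


def run_task_matrix(
    feature_table: pd.DataFrame,
    scores: dict[str, ClinicalScores],
    tasks: Sequence[ThresholdTask] | None = None,
    sets: Sequence[Sequence[GestureLabel]] | None = None,
    n_iter: int = 100,
    n_test_subjects: int = 2,
    seed: int = 0,
    n_channels: int = 4,
    aggregation: str = "attempt",
) -> pd.DataFrame:
    """Evaluate every task over every gesture set.

    Returns one row per (task, gesture set) with mean/SD of each metric, the
    count of undefined-AUC iterations, a best-entry flag per task, and the
    Mann-Whitney comparison of each entry's accuracies against the task's
    best entry (U, p, stars).
    """
    from .features import BUILTIN_TASKS

    tasks = list(tasks) if tasks is not None else list(BUILTIN_TASKS)
    sets = [tuple(GestureLabel(g) for g in s) for s in (sets or gesture_sets())]
    root = np.random.default_rng(seed)
    rows = []
    accs: dict[tuple[str, str], np.ndarray] = {}
    for task in tasks:
        for gset in sets:
            set_name = "-".join(g.value for g in gset)
            rng = np.random.default_rng(root.integers(2**31))
            try:
                ds = build_task_dataset(feature_table, scores, task, gset, n_channels)
                iters = run_repeated_holdout(
                    ds, n_iter=n_iter, n_test_subjects=n_test_subjects, seed=rng,
                    aggregation=aggregation, with_curves=False,
                )
            except ProtocolError as exc:
                warnings.warn(f"{task.name} / {set_name}: {exc}", stacklevel=2)
                continue
            summ = summarize(iters)
            accs[(task.name, set_name)] = np.array([m.acc for m in iters])
            row = {"task": task.name, "gesture_set": set_name,
                   "kind": "single" if len(gset) == 1 else "pair",
                   "n_iterations": summ.n_iterations}
            for name in IterationMetrics.METRIC_NAMES:
                row[f"{name}_mean"] = summ.means[name]
                row[f"{name}_sd"] = summ.sds[name]
            row["auc_undefined"] = summ.undefined_counts["auc_roc"]
            rows.append(row)
    report = pd.DataFrame(rows)
    report["best"] = False
    report["U_vs_best"] = np.nan
    report["p_vs_best"] = np.nan
    report["stars_vs_best"] = ""
    for task_name, block in report.groupby("task"):
        best_idx = block["acc_mean"].idxmax()
        best_set = report.loc[best_idx, "gesture_set"]
        report.loc[best_idx, "best"] = True
        for idx in block.index:
            gset = report.loc[idx, "gesture_set"]
            if gset == best_set:
                continue
            u, p, stars = compare_models(accs[(task_name, gset)], accs[(task_name, best_set)])
            report.loc[idx, ["U_vs_best", "p_vs_best", "stars_vs_best"]] = (u, p, stars)
    return report
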