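"""Evaluation statistics for prognosis models.

Classification and regression metrics, the attention alignment score (AAS)
against therapist-annotated key-event windows, attention entropy, Brier
score with reliability binning, subject-wise cross-validation planning with
validation carve-outs, Cohen's kappa for inter-rater agreement, and paired
t-tests across folds.

Degenerate inputs follow explicit conventions instead of silently producing
numbers: vanishing denominators yield zero (classification) or NaN
(kappa, R²) together with a boolean flag on the result object.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .cohortsim import AnnotationSet

__all__ = [
    "ConfusionTable",
    "ClassificationResult",
    "RegressionResult",
    "MetricReport",
    "CalibrationTable",
    "FoldPlan",
    "TTestResult",
    "classification_metrics",
    "regression_metrics",
    "attention_alignment_score",
    "attention_entropy",
    "brier_score",
    "reliability_table",
    "subject_folds",
    "cohen_kappa",
    "paired_fold_ttest",
    "compute_report",
]


@dataclass
class ConfusionTable:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ClassificationResult:
    confusion: ConfusionTable
    accuracy: float
    precision: float
    recall: float
    f1: float
    zero_division: bool = False


@dataclass
class RegressionResult:
    rmse: float
    mae: float
    r2: float
    degenerate_r2: bool = False


@dataclass
class MetricReport:
    """Full metric suite for one evaluation split."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    rmse: float
    mae: float
    r2: float
    aas: float
    aas_chance: float
    ae_mean: float
    brier: float
    n: int
    threshold: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "accuracy", "precision", "recall", "f1", "rmse", "mae", "r2",
            "aas", "aas_chance", "ae_mean", "brier", "n", "threshold")}


@dataclass
class CalibrationTable:
    """Reliability-diagram table on equal-width probability bins."""

    edges: np.ndarray          # (n_bins + 1,)
    counts: np.ndarray         # (n_bins,)
    mean_predicted: np.ndarray # (n_bins,) NaN where empty
    observed_freq: np.ndarray  # (n_bins,) NaN where empty
    empty_bins: np.ndarray     # (n_bins,) bool

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "bin_low": self.edges[:-1], "bin_high": self.edges[1:],
            "count": self.counts, "mean_predicted": self.mean_predicted,
            "observed_freq": self.observed_freq,
        })


@dataclass
class FoldPlan:
    """Subject-wise cross-validation assignment."""

    k: int
    test_subjects: list[list[str]]
    val_subjects: list[list[str]]
    train_subjects: list[list[str]]

    def fold(self, i: int):
        return (self.train_subjects[i], self.val_subjects[i],
                self.test_subjects[i])

    def validate(self, subjects: list[str]) -> None:
        all_test = [s for fold in self.test_subjects for s in fold]
        if sorted(all_test) != sorted(subjects):
            raise ValueError("test sets must partition the subjects")
        for tr, va, te in zip(self.train_subjects, self.val_subjects,
                              self.test_subjects):
            tr_s, va_s, te_s = set(tr), set(va), set(te)
            if tr_s & va_s or tr_s & te_s or va_s & te_s:
                raise ValueError("train/val/test must be pairwise disjoint")


@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    mean_diff: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# classification / regression
# ---------------------------------------------------------------------------

def classification_metrics(yhat: np.ndarray, y: np.ndarray,
                           threshold: float = 0.5) -> ClassificationResult:
    """Accuracy, precision, recall and F1 at a probability threshold.

    Labels are binarized at the same threshold rule as the generator
    (positive = functional independence, y >= threshold).  Vanishing
    denominators yield 0 with the ``zero_division`` flag set.
    """
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if yhat.size == 0:
        raise ValueError("empty input")
    pred = yhat >= threshold
    true = y >= threshold
    tp = int(np.sum(pred & true))
    tn = int(np.sum(~pred & ~true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    conf = ConfusionTable(tp, tn, fp, fn)
    acc = (tp + tn) / conf.total
    flag = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, flag = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, flag = 0.0, True
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, flag = 0.0, True
    if flag:
        warnings.warn("zero denominator in precision/recall/F1; returned 0",
                      RuntimeWarning, stacklevel=2)
    return ClassificationResult(conf, acc, precision, recall, f1, flag)


def regression_metrics(yhat: np.ndarray, y: np.ndarray) -> RegressionResult:
    """RMSE, MAE and R² (SST about the mean of y).

    Constant targets make R² undefined; it is returned as NaN with the
    ``degenerate_r2`` flag.
    """
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if yhat.shape != y.shape or y.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    err = yhat - y
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        warnings.warn("constant targets: R² undefined", RuntimeWarning,
                      stacklevel=2)
        return RegressionResult(rmse, mae, float("nan"), True)
    r2 = 1.0 - float(np.sum(err**2)) / sst
    return RegressionResult(rmse, mae, r2, False)


# ---------------------------------------------------------------------------
# attention metrics
# ---------------------------------------------------------------------------

def _sample_aas(alpha: np.ndarray, annotated: np.ndarray) -> float:
    """Top-K overlap: K = number of annotated frames; ties toward earlier
    frames (stable sort on descending weight)."""
    K = annotated.size
    order = np.argsort(-alpha, kind="stable")
    top = set(order[:K].tolist())
    return len(top & set(annotated.tolist())) / K


def attention_alignment_score(alphas, annotations) -> tuple[float, float]:
    """Mean attention alignment score and its chance level.

    For each sample, the K most-attended frames (K = annotated frame count)
    are intersected with the annotated frames; the sample score is the
    overlap fraction.  Chance level is the mean annotated coverage K/T —
    the expected score of uninformative attention.

    Samples with empty annotations are skipped with a warning.
    """
    scores, chances = [], []
    for alpha, ann in zip(alphas, annotations):
        alpha = np.asarray(alpha, dtype=float)
        if abs(alpha.sum() - 1.0) > 1e-6:
            raise ValueError("α must sum to 1 per sample")
        annotated = (ann.annotated_frames if isinstance(ann, AnnotationSet)
                     else np.asarray(ann))
        if annotated.size == 0:
            warnings.warn("sample with empty annotation windows skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        scores.append(_sample_aas(alpha, annotated))
        chances.append(annotated.size / alpha.size)
    if not scores:
        raise ValueError("no annotated samples")
    return float(np.mean(scores)), float(np.mean(chances))


def attention_entropy(alpha: np.ndarray) -> float:
    """Shannon entropy −Σ α ln α of one attention distribution (0·ln 0 = 0)."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.min() < 0:
        raise ValueError("α must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(alpha > 0, alpha * np.log(alpha), 0.0)
    return float(-plogp.sum())


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def brier_score(p: np.ndarray, y_binary: np.ndarray) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y_binary, dtype=float)
    if p.size == 0:
        raise ValueError("empty input")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def reliability_table(p: np.ndarray, y_binary: np.ndarray,
                      n_bins: int = 10) -> CalibrationTable:
    """Equal-width probability bins on [0, 1] (last bin right-closed)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p = np.asarray(p, dtype=float)
    y = np.asarray(y_binary, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.minimum((p * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums_p = np.bincount(idx, weights=p, minlength=n_bins)
    sums_y = np.bincount(idx, weights=y, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_p = np.where(counts > 0, sums_p / np.maximum(counts, 1), np.nan)
        freq = np.where(counts > 0, sums_y / np.maximum(counts, 1), np.nan)
    return CalibrationTable(edges=edges, counts=counts, mean_predicted=mean_p,
                            observed_freq=freq, empty_bins=counts == 0)


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

def subject_folds(subject_ids: list[str], k: int, val_fraction: float,
                  seed: int) -> FoldPlan:
    """Subject-wise k-fold plan with a per-fold validation carve-out.

    Subjects are shuffled by the seed and partitioned into k near-equal
    test groups; within each fold, ceil(val_fraction · n_train) subjects
    (at least one) are moved from training to validation.  Assignment is by
    subject only — a participant's trials never span two splits.
    """
    subjects = list(subject_ids)
    if k > len(subjects):
        raise ValueError("k exceeds the number of subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    shuffled = [subjects[i] for i in order]
    test_groups = [list(g) for g in np.array_split(np.array(shuffled), k)]
    trains, vals = [], []
    for i in range(k):
        remaining = [s for s in shuffled if s not in set(test_groups[i])]
        n_val = max(1, math.ceil(val_fraction * len(remaining)))
        pick = rng.permutation(len(remaining))[:n_val]
        val = [remaining[j] for j in sorted(pick)]
        train = [s for s in remaining if s not in set(val)]
        trains.append(train)
        vals.append(val)
    plan = FoldPlan(k=k, test_subjects=test_groups, val_subjects=vals,
                    train_subjects=trains)
    plan.validate(subjects)
    return plan


def cohen_kappa(rater_a: np.ndarray, rater_b: np.ndarray) -> float:
    """Chance-corrected agreement κ = (p_o − p_e)/(1 − p_e) for binary marks.

    Returns NaN (with a warning) when the marginals force p_e = 1.
    """
    a = np.asarray(rater_a).astype(int)
    b = np.asarray(rater_b).astype(int)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("marks must be equal-length and non-empty")
    n = a.size
    p_o = float(np.mean(a == b))
    pa1, pb1 = a.mean(), b.mean()
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if abs(1.0 - p_e) < 1e-12:
        warnings.warn("degenerate marginals (p_e = 1): κ undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def paired_fold_ttest(metric_a: np.ndarray, metric_b: np.ndarray) -> TTestResult:
    """Two-sided paired t-test on per-fold metric differences.

    Zero-variance nonzero-mean differences are flagged degenerate rather
    than assigned a fabricated p-value.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length metric vectors with n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return TTestResult(t=0.0, p=1.0, df=n - 1, mean_diff=0.0)
        warnings.warn("zero-variance nonzero-mean differences: t undefined",
                      RuntimeWarning, stacklevel=2)
        return TTestResult(t=float("inf") if d.mean() > 0 else float("-inf"),
                           p=float("nan"), df=n - 1,
                           mean_diff=float(d.mean()), degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TTestResult(t=float(t), p=float(p), df=n - 1,
                       mean_diff=float(d.mean()))


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def compute_report(yhat: np.ndarray, y: np.ndarray, alphas, annotations,
                   threshold: float = 0.5) -> MetricReport:
    """Assemble the full metric suite for one set of predictions."""
    cls = classification_metrics(yhat, y, threshold)
    reg = regression_metrics(yhat, y)
    aas, chance = attention_alignment_score(alphas, annotations)
    ae = float(np.mean([attention_entropy(a) for a in alphas]))
    bs = brier_score(yhat, (np.asarray(y) >= threshold).astype(float))
    return MetricReport(
        accuracy=cls.accuracy, precision=cls.precision, recall=cls.recall,
        f1=cls.f1, rmse=reg.rmse, mae=reg.mae, r2=reg.r2, aas=aas,
        aas_chance=chance, ae_mean=ae, brier=bs, n=int(np.asarray(y).size),
        threshold=threshold)
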