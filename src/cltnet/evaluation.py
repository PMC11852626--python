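"""Classification metrics: accuracy, Cohen's kappa, confusion matrix,
one-vs-rest ROC with micro/macro averaging and AUC, and the paired Wilcoxon
signed-rank test.

These are written out explicitly (rather than delegated) because the exact
conventions matter for the reported numbers: kappa from the confusion
marginals, ROC by threshold sweep with trapezoidal AUC, macro averaging on a
fixed 101-point FPR grid, and a Wilcoxon variant that switches from exact
null enumeration to a tie-corrected normal approximation at n = 12.
scikit-learn and scipy serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["EvaluationReport", "confusion_and_accuracy", "cohen_kappa",
           "roc_auc", "ROCResult", "wilcoxon_paired", "evaluation_report",
           "significance_mark"]

#: FPR grid used for macro-averaged ROC interpolation.
MACRO_FPR_GRID = np.linspace(0.0, 1.0, 101)


def confusion_and_accuracy(true_labels, predicted_labels, n_classes: int
                           ) -> tuple[np.ndarray, float]:
    """Confusion matrix (rows = true class) and overall accuracy.

    Accuracy is the proportion of correct predictions — trace over total;
    in the binary case this equals (TP+TN)/(TP+FN+FP+TN).
    """
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if t.size == 0:
        raise ValueError("empty label vectors")
    if t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes:
        raise ValueError("labels must lie in [0, n_classes)")
    conf = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(conf, (t, p), 1)
    return conf, float(np.trace(conf) / conf.sum())


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement k = (P_a - P_e) / (1 - P_e).

    P_a is the observed agreement (trace/n); P_e the expected agreement of
    independent raters with the observed marginals. Degenerate rule: when
    P_e = 1 (all mass in one cell), k is 1 for perfect agreement and 0
    otherwise, with a warning.
    """
    conf = np.asarray(confusion, dtype=np.float64)
    n = conf.sum()
    if n < 1:
        raise ValueError("confusion matrix must contain at least one count")
    p_a = np.trace(conf) / n
    p_e = float((conf.sum(axis=1) * conf.sum(axis=0)).sum() / n ** 2)
    if p_e >= 1.0 - 1e-15:
        log.warning("cohen_kappa: P_e = 1 (degenerate marginals); returning %d",
                    1 if p_a >= 1.0 - 1e-15 else 0)
        return 1.0 if p_a >= 1.0 - 1e-15 else 0.0
    return float((p_a - p_e) / (1.0 - p_e))


def _binary_roc(y: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest ROC curve by descending-threshold sweep.

    Returns (fpr, tpr) starting at (0, 0) and ending at (1, 1); tied scores
    collapse into a single operating point.
    """
    order = np.argsort(-score, kind="stable")
    y = y[order]
    score = score[order]
    distinct = np.r_[np.flatnonzero(np.diff(score)), len(score) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    P, Nn = y.sum(), (1 - y).sum()
    tpr = np.r_[0.0, tp / P] if P else np.r_[0.0, np.zeros(len(tp))]
    fpr = np.r_[0.0, fp / Nn] if Nn else np.r_[0.0, np.zeros(len(fp))]
    return fpr, tpr


def _auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


@dataclass
class ROCResult:
    """Per-class, micro- and macro-averaged ROC curves with their AUCs."""

    per_class: dict[int, tuple[np.ndarray, np.ndarray]]
    micro: tuple[np.ndarray, np.ndarray]
    macro: tuple[np.ndarray, np.ndarray]
    auc: dict[str, float]
    excluded_classes: tuple[int, ...] = ()


def roc_auc(true_labels, score_matrix) -> ROCResult:
    """One-vs-rest ROC analysis of a class-probability matrix.

    Micro averaging pools every (indicator, score) pair across classes;
    macro averaging linearly interpolates each class curve onto a common
    101-point FPR grid and averages the TPRs. AUCs use the trapezoidal
    rule. A class absent from the truth has no one-vs-rest curve; it is
    excluded from the macro average with a warning.
    """
    y = np.asarray(true_labels, dtype=np.int64)
    S = np.asarray(score_matrix, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] != y.shape[0]:
        raise ValueError("score_matrix must be (n, n_classes) matching labels")
    n_classes = S.shape[1]
    per_class, aucs, excluded = {}, {}, []
    macro_tprs = []
    for c in range(n_classes):
        yc = (y == c).astype(np.int64)
        if yc.sum() == 0 or yc.sum() == len(yc):
            excluded.append(c)
            log.warning("roc_auc: class %d has a one-sided truth vector; "
                        "excluded from per-class/macro curves", c)
            continue
        fpr, tpr = _binary_roc(yc, S[:, c])
        per_class[c] = (fpr, tpr)
        aucs[f"class_{c}"] = _auc(fpr, tpr)
        macro_tprs.append(np.interp(MACRO_FPR_GRID, fpr, tpr))

    onehot = np.zeros_like(S)
    onehot[np.arange(len(y)), y] = 1.0
    micro_fpr, micro_tpr = _binary_roc(onehot.ravel().astype(np.int64), S.ravel())
    aucs["micro"] = _auc(micro_fpr, micro_tpr)

    if macro_tprs:
        macro_tpr = np.mean(macro_tprs, axis=0)
    else:
        macro_tpr = np.full_like(MACRO_FPR_GRID, np.nan)
    aucs["macro"] = _auc(MACRO_FPR_GRID, macro_tpr) if macro_tprs else float("nan")

    return ROCResult(per_class=per_class,
                     micro=(micro_fpr, micro_tpr),
                     macro=(MACRO_FPR_GRID.copy(), macro_tpr),
                     auc=aucs,
                     excluded_classes=tuple(excluded))


def significance_mark(p: float) -> str:
    """'**' below 0.01, '*' below 0.05, '' otherwise."""
    return "**" if p < 0.01 else "*" if p < 0.05 else ""


def wilcoxon_paired(scores_a, scores_b, exact_max_n: int = 12
                    ) -> tuple[float, float, str]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; tied magnitudes get midranks. For n <=
    ``exact_max_n`` the null is enumerated exactly over all 2^n sign
    assignments; above that a normal approximation with tie correction is
    used (no continuity correction). Returns (statistic, p, mark) where the
    statistic is min(W+, W-). All differences zero gives p = 1 with a
    warning.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        log.warning("wilcoxon_paired: all differences are zero")
        return 0.0, 1.0, ""
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)

    if n <= exact_max_n:
        # enumerate all sign assignments of the ranked magnitudes
        masks = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        null_w = masks @ ranks
        p_low = float((null_w <= w_plus).mean())
        p_high = float((null_w >= w_plus).mean())
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(((counts ** 3 - counts)).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = min(1.0, p)
    return stat, p, significance_mark(p)


@dataclass
class EvaluationReport:
    """Bundle of the metrics computed for one model/dataset pair."""

    accuracy: float
    kappa: float
    confusion: np.ndarray
    per_class_rates: dict[int, dict[str, float]]
    roc: ROCResult | None
    n: int
    class_names: tuple[str, ...] = ()

    def auc_values(self) -> list[float]:
        return list(self.roc.auc.values()) if self.roc is not None else []

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "confusion": self.confusion.tolist(),
            "per_class_rates": {int(k): v for k, v in self.per_class_rates.items()},
            "n": self.n,
            "class_names": list(self.class_names),
        }
        if self.roc is not None:
            out["auc"] = self.roc.auc
            out["roc"] = {
                "per_class": {int(c): [f.tolist(), t.tolist()]
                              for c, (f, t) in self.roc.per_class.items()},
                "micro": [self.roc.micro[0].tolist(), self.roc.micro[1].tolist()],
                "macro": [self.roc.macro[0].tolist(), self.roc.macro[1].tolist()],
            }
        return out


def per_class_rates(confusion: np.ndarray) -> dict[int, dict[str, float]]:
    """One-vs-rest TPR/FPR per class from a multiclass confusion matrix."""
    conf = np.asarray(confusion, dtype=np.float64)
    n = conf.sum()
    rates = {}
    for c in range(conf.shape[0]):
        tp = conf[c, c]
        fn = conf[c].sum() - tp
        fp = conf[:, c].sum() - tp
        tn = n - tp - fn - fp
        rates[c] = {
            "tpr": float(tp / (tp + fn)) if tp + fn else float("nan"),
            "fpr": float(fp / (fp + tn)) if fp + tn else float("nan"),
        }
    return rates


def evaluation_report(true_labels, score_matrix, class_names=()) -> EvaluationReport:
    """Full evaluation of probability scores: argmax prediction (ties toward
    the lowest class index), confusion/accuracy/kappa, per-class rates, ROC."""
    y = np.asarray(true_labels, dtype=np.int64)
    S = np.asarray(score_matrix, dtype=np.float64)
    n_classes = S.shape[1]
    pred = np.argmax(S, axis=1)
    conf, acc = confusion_and_accuracy(y, pred, n_classes)
    return EvaluationReport(
        accuracy=acc,
        kappa=cohen_kappa(conf),
        confusion=conf,
        per_class_rates=per_class_rates(conf),
        roc=roc_auc(y, S),
        n=len(y),
        class_names=tuple(class_names) if class_names else tuple(str(i) for i in range(n_classes)),
    )
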