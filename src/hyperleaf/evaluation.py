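"""Classification metrics, one-vs-rest ROC/AUC, and the repeated-run
significance procedure (Dunn's test with Bonferroni correction).

Per-class metrics collapse the K x K confusion matrix one-vs-rest to
(TP, TN, FP, FN):

    accuracy  = (TP + TN) / (TP + FN + FP + TN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Macro values are unweighted class means; overall accuracy is trace/total.
0/0 terms (a class never predicted, an empty class) are defined as 0, with a
warning.  The multi-class MCC is the macro mean of the per-class binary MCC,
consistent with the macro precision/recall/F1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "confusion",
    "MetricsReport",
    "classification_metrics",
    "roc_auc_ovr_macro",
    "dunn_bonferroni",
    "DunnResult",
]


def confusion(y_true, y_pred, K: int) -> np.ndarray:
    """K x K count matrix, rows = true class, cols = predicted (labels 1..K)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 1 or y.max() > K):
            raise ValueError(f"{name} contains labels outside 1..{K}")
    cm = np.zeros((K, K), dtype=np.int64)
    np.add.at(cm, (y_true - 1, y_pred - 1), 1)
    return cm


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_mcc: float
    per_class: dict = field(default_factory=dict)
    auc: float | None = None

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_mcc": self.macro_mcc,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"0/0 in {what}; defined as 0")
        return 0.0
    return num / den


def classification_metrics(cm: np.ndarray) -> MetricsReport:
    """Per-class one-vs-rest metrics and their unweighted macro means."""
    cm = np.asarray(cm, dtype=np.float64)
    K = cm.shape[0]
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    per_class = {}
    P, R, F, M = [], [], [], []
    for k in range(K):
        tp = cm[k, k]
        fn = cm[k, :].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        prec = _safe_div(tp, tp + fp, f"precision of class {k + 1}")
        rec = _safe_div(tp, tp + fn, f"recall of class {k + 1}")
        f1 = _safe_div(2 * prec * rec, prec + rec, f"F1 of class {k + 1}")
        denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
        per_class[k + 1] = {"precision": prec, "recall": rec, "f1": f1, "mcc": mcc,
                            "tp": tp, "tn": tn, "fp": fp, "fn": fn}
        P.append(prec)
        R.append(rec)
        F.append(f1)
        M.append(mcc)
    return MetricsReport(
        accuracy=float(np.trace(cm) / total),
        macro_precision=float(np.mean(P)),
        macro_recall=float(np.mean(R)),
        macro_f1=float(np.mean(F)),
        macro_mcc=float(np.mean(M)),
        per_class=per_class,
    )


def roc_auc_ovr_macro(scores: np.ndarray, y_true) -> float:
    """Macro one-vs-rest AUC via the midrank Mann-Whitney statistic.

    ``scores`` is n x K (higher = more confident in class k+1).  Classes
    absent from ``y_true`` are excluded from the macro mean with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    K = scores.shape[1]
    aucs = []
    for k in range(K):
        pos = y_true == k + 1
        n_pos = int(pos.sum())
        n_neg = pos.size - n_pos
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"class {k + 1} absent from y_true; excluded from macro AUC")
            continue
        ranks = stats.rankdata(scores[:, k])  # midranks on ties
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs.append(auc)
    if not aucs:
        raise ValueError("no class present in y_true")
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# Dunn's test with Bonferroni correction + compact letter display
# ---------------------------------------------------------------------------

@dataclass
class DunnResult:
    groups: list
    p_values: dict          # (group_i, group_j) -> Bonferroni-adjusted p
    z_values: dict
    letters: dict           # group -> significance letters (Table-style superscripts)
    kruskal_p: float


def dunn_bonferroni(samples_by_group: dict, alpha: float = 0.05) -> DunnResult:
    """Kruskal-Wallis on pooled ranks, Dunn pairwise z statistics, Bonferroni
    adjustment (p x n_pairs, capped at 1), and a compact letter display
    (groups sorted by median; groups sharing a letter are not significantly
    different)."""
    groups = list(samples_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: np.asarray(samples_by_group[g], dtype=np.float64) for g in groups}
    for g, v in data.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has {v.size} values (< 3)")
    pooled = np.concatenate([data[g] for g in groups])
    N = pooled.size
    if np.ptp(pooled) == 0:
        pairs = {p: 1.0 for p in itertools.combinations(groups, 2)}
        zs = {p: 0.0 for p in pairs}
        letters = {g: "a" for g in groups}
        return DunnResult(groups, pairs, zs, letters, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kw_p = float(stats.kruskal(*[data[g] for g in groups]).pvalue)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    offset = 0
    for g in groups:
        n_g = data[g].size
        mean_ranks[g] = ranks[offset:offset + n_g].mean()
        sizes[g] = n_g
        offset += n_g
    # tie correction to the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    n_pairs = len(groups) * (len(groups) - 1) // 2
    p_values, z_values = {}, {}
    for gi, gj in itertools.combinations(groups, 2):
        se = np.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
        z = 0.0 if se == 0 else (mean_ranks[gi] - mean_ranks[gj]) / se
        raw = 2.0 * stats.norm.sf(abs(z))
        p_values[(gi, gj)] = min(1.0, raw * n_pairs)
        z_values[(gi, gj)] = float(z)
    letters = _compact_letters(groups, data, p_values, alpha)
    return DunnResult(groups, p_values, z_values, letters, kw_p)


def _compact_letters(groups, data, p_values, alpha):
    """Greedy letter assignment: groups in descending median order; a group
    joins an existing letter if not significantly different from every
    current member, else opens a new letter."""

    def different(a, b):
        key = (a, b) if (a, b) in p_values else (b, a)
        return p_values[key] < alpha

    order = sorted(groups, key=lambda g: -np.median(data[g]))
    letter_sets: list[list] = []
    for g in order:
        placed = False
        for members in letter_sets:
            if all(not different(g, m) for m in members):
                members.append(g)
                placed = True
        if not placed:
            letter_sets.append([g])
    letters = {g: "" for g in groups}
    for idx, members in enumerate(letter_sets):
        ch = chr(ord("a") + idx)
        for g in members:
            letters[g] += ch
    return letters
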