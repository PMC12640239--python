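"""Edge-level scoring of inferred association matrices against a reference.

All scoring is over the n(n-1)/2 unordered off-diagonal metabolite pairs
(undirected evaluation, diagonal excluded).  Signed associations are
compared by absolute value.  Thresholding is strict: an edge is predicted
when |A(x, y)| > tau.

Degenerate denominators are defined rather than raised: F1 = 0 when there
are no true edges and no predictions, MCC = 0 when any denominator factor
vanishes, FDR = 0 when nothing is predicted (no predictions, no false
discoveries); each case is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """The reference has no edges or no non-edges, so ranking metrics are undefined."""


@dataclass(frozen=True)
class BinaryNetwork:
    """Thresholded (binary, symmetric, zero-diagonal) network."""

    names: tuple[str, ...]
    values: np.ndarray
    threshold_used: float | str = "given"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        n = len(self.names)
        if v.shape != (n, n):
            raise ValueError("binary network shape does not match names")
        if not np.array_equal(v, v.T):
            raise ValueError("binary network is not symmetric")
        v = (v != 0).astype(np.int8)
        np.fill_diagonal(v, 0)
        object.__setattr__(self, "values", v)

    @property
    def n_edges(self) -> int:
        return int(self.values.sum() // 2)

    def edge_set(self) -> set[tuple[str, str]]:
        iu, ju = np.nonzero(np.triu(self.values, k=1))
        return {(self.names[i], self.names[j]) for i, j in zip(iu, ju)}


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricResult:
    metric: str
    value: float
    threshold: float | None = None


def _upper(values: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(values.shape[0], k=1)
    return values[iu, ju]


def binarize(assoc, tau: float) -> BinaryNetwork:
    """Edges where |A(x, y)| > tau (strict)."""
    b = (assoc.magnitudes() > tau).astype(np.int8)
    np.fill_diagonal(b, 0)
    return BinaryNetwork(assoc.names, b, threshold_used=float(tau))


def confusion(pred: BinaryNetwork, ref) -> ConfusionCounts:
    """Confusion counts over unordered off-diagonal pairs."""
    if tuple(pred.names) != tuple(ref.names):
        raise ValueError("name order mismatch between prediction and reference")
    p = _upper(pred.values).astype(bool)
    r = _upper(np.asarray(ref.values)).astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(p & r)),
        FP=int(np.sum(p & ~r)),
        FN=int(np.sum(~p & r)),
        TN=int(np.sum(~p & ~r)),
    )


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall: 2TP / (2TP + FP + FN)."""
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        logger.debug("F1 denominator zero -> 0")
        return 0.0
    return 2 * c.TP / denom


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    factors = [c.TP + c.FP, c.TP + c.FN, c.TN + c.FP, c.TN + c.FN]
    if 0 in factors:
        logger.debug("MCC denominator factor zero -> 0")
        return 0.0
    num = c.TP * c.TN - c.FP * c.FN
    return num / math.sqrt(math.prod(float(f) for f in factors))


def fdr(c: ConfusionCounts) -> float:
    """False discovery rate FP / (TP + FP); 0 when nothing is predicted."""
    if c.TP + c.FP == 0:
        logger.debug("no predicted edges -> FDR 0")
        return 0.0
    return c.FP / (c.TP + c.FP)


_CRITERIA = {"F1": f1, "MCC": mcc, "FDR": fdr}


def threshold_candidates(assoc) -> np.ndarray:
    """Midpoints between consecutive sorted unique |A| values, plus one
    candidate below the minimum and one above the maximum."""
    vals = np.unique(_upper(assoc.magnitudes()))
    mids = (vals[:-1] + vals[1:]) / 2 if vals.size > 1 else np.empty(0)
    return np.concatenate([[vals[0] - 1.0], mids, [vals[-1] + 1.0]])


def optimal_threshold(assoc, ref, criterion: str = "F1") -> tuple[float, MetricResult]:
    """Threshold maximizing F1 or MCC over the candidate set; ties -> smallest tau.

    Candidates sweep from below the smallest to above the largest |A| value,
    so the scan covers every distinct binary network the matrix can produce.
    Computed incrementally from the descending pair ranking.
    """
    if criterion not in ("F1", "MCC"):
        raise ValueError("criterion must be 'F1' or 'MCC'")
    scores = _upper(assoc.magnitudes())
    labels = _upper(np.asarray(ref.values)).astype(bool)
    n_pos = int(labels.sum())
    n_pairs = labels.size
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    cum_tp = np.cumsum(labels[order])
    # predicting the top t pairs: boundaries where the sorted score changes
    distinct_end = np.flatnonzero(np.diff(sorted_scores, append=-np.inf))  # last index of each run
    t_values = np.concatenate([[0], distinct_end + 1])  # number of predicted edges
    tp = np.concatenate([[0], cum_tp[distinct_end]]).astype(float)
    fp = t_values - tp
    fn = n_pos - tp
    tn = n_pairs - t_values - fn
    if criterion == "F1":
        denom = 2 * tp + fp + fn
        crit = np.divide(2 * tp, denom, out=np.zeros_like(tp), where=denom > 0)
    else:
        prod = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        crit = np.divide(tp * tn - fp * fn, np.sqrt(prod), out=np.zeros_like(tp), where=prod > 0)
    cands = threshold_candidates(assoc)[::-1]  # descending: aligned with t_values
    assert cands.size == t_values.size
    best = int(np.argmax(crit))
    # ties -> smallest tau: among equal criteria prefer the largest t (last max)
    ties = np.flatnonzero(crit == crit[best])
    best = int(ties[-1])
    tau_star = float(cands[best])
    return tau_star, MetricResult(criterion, float(crit[best]), threshold=tau_star)


def _scores_labels(assoc, ref) -> tuple[np.ndarray, np.ndarray]:
    if tuple(assoc.names) != tuple(ref.names):
        raise ValueError("name order mismatch between association and reference")
    scores = _upper(assoc.magnitudes())
    labels = _upper(np.asarray(ref.values)).astype(bool)
    if labels.all() or not labels.any():
        raise UndefinedMetricError("reference needs at least one edge and one non-edge")
    return scores, labels


def auroc(assoc, ref) -> MetricResult:
    """Area under the ROC curve via the Mann-Whitney rank statistic (ties averaged)."""
    scores, labels = _scores_labels(assoc, ref)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return MetricResult("AUROC", float(auc))


def aupr(assoc, ref) -> MetricResult:
    """Area under the precision-recall curve, step-wise (no interpolation)."""
    from sklearn.metrics import average_precision_score

    scores, labels = _scores_labels(assoc, ref)
    return MetricResult("AUPR", float(average_precision_score(labels, scores)))


def evaluate_all(assoc, ref) -> dict[str, MetricResult]:
    """F1/MCC at their optimal thresholds, FDR and MCC at the F1-optimal
    threshold, plus threshold-free AUROC and AUPR."""
    tau_f1, best_f1 = optimal_threshold(assoc, ref, "F1")
    _, best_mcc = optimal_threshold(assoc, ref, "MCC")
    c = confusion(binarize(assoc, tau_f1), ref)
    return {
        "F1": best_f1,
        "MCC_opt": MetricResult("MCC", best_mcc.value, best_mcc.threshold),
        "MCC": MetricResult("MCC", mcc(c), tau_f1),
        "FDR": MetricResult("FDR", fdr(c), tau_f1),
        "AUROC": auroc(assoc, ref),
        "AUPR": aupr(assoc, ref),
    }
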