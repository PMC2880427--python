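"""Outer validation loop and performance statistics.

The outer loop is leave-one-out over samples: the full inner analysis
(component choice, jackknife probe selection, refit) is repeated with the
held-out sample removed, so that sample never influences the probe set or
model order used to predict it.  Accuracy, sensitivity, specificity, ROC/AUC,
a label-permutation null, a learning curve over balanced subsets, and Fisher
exact tests of covariates among the misclassified samples are computed from
the per-sample outer scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BloodsigError
from .pls import predict_score
from .plsjack import select_and_refit

logger = logging.getLogger(__name__)


@dataclass
class CVResult:
    """Per-sample outer-fold predictions and aggregate confusion counts."""

    records: pd.DataFrame  # array_id, y_true, score, y_pred, n_selected, a_opt
    selected_sets: list = field(default_factory=list)  # probe ids per fold

    def __post_init__(self) -> None:
        needed = {"array_id", "y_true", "score", "y_pred"}
        if not needed <= set(self.records.columns):
            raise BloodsigError(f"CV records need columns {sorted(needed)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def scores(self) -> np.ndarray:
        return self.records["score"].to_numpy(dtype=float)

    @property
    def y_true(self) -> np.ndarray:
        return self.records["y_true"].to_numpy(dtype=float)

    @property
    def y_pred(self) -> np.ndarray:
        return self.records["y_pred"].to_numpy(dtype=float)

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        """(TP, FN, TN, FP) from the +1/-1 codes."""
        t, p = self.y_true, self.y_pred
        TP = int(((t == 1) & (p == 1)).sum())
        FN = int(((t == 1) & (p == -1)).sum())
        TN = int(((t == -1) & (p == -1)).sum())
        FP = int(((t == -1) & (p == 1)).sum())
        return TP, FN, TN, FP


@dataclass
class PermutationResult:
    k: int
    accuracies: np.ndarray  # per successful permutation
    aucs: np.ndarray
    observed_accuracy: float
    observed_auc: float
    p_accuracy: float
    p_auc: float
    max_accuracy: float
    max_auc: float
    seed: int
    n_failed: int = 0


@dataclass
class LearningCurveResult:
    fractions: np.ndarray
    reps: int
    mean_auc: np.ndarray
    sd_auc: np.ndarray
    auc_values: list  # list of arrays, one per fraction
    seed: int


# --------------------------------------------------------------------------

def double_cv(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    A_max: Optional[int] = None,
    probe_ids: Optional[Sequence] = None,
    array_ids: Optional[Sequence] = None,
    gram: Optional[np.ndarray] = None,
    store_selected: bool = False,
) -> CVResult:
    """Leave-one-out double cross-validation of the full analysis.

    Each sample is predicted by a classifier built (selection, order choice
    and refit included) on the other n-1 samples.  Fold failures are
    recorded as NaN scores and the run continues.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 6:
        raise BloodsigError("double CV needs at least 6 samples")
    if (y == 1).sum() < 3 or (y == -1).sum() < 3:
        raise BloodsigError("double CV needs at least 3 samples per class")
    probe_ids = (
        np.array([f"p{i}" for i in range(p)], dtype=object)
        if probe_ids is None
        else np.asarray(probe_ids, dtype=object)
    )
    array_ids = (
        np.array([f"s{i}" for i in range(n)], dtype=object)
        if array_ids is None
        else np.asarray(array_ids, dtype=object)
    )
    K = X @ X.T if gram is None else gram

    rows = []
    selected_sets: list = []
    all_idx = np.arange(n)
    for i in range(n):
        tr = np.delete(all_idx, i)
        try:
            sel = select_and_refit(
                X[tr],
                y[tr],
                alpha=alpha,
                A_max=A_max,
                probe_ids=probe_ids,
                gram=K[np.ix_(tr, tr)],
            )
            score = float(
                predict_score(sel.model, X[i, sel.selected_idx][None, :], sel.a_opt2)[0]
            )
            pred = 1.0 if score > 0 else -1.0
            rows.append(
                {
                    "array_id": array_ids[i],
                    "y_true": y[i],
                    "score": score,
                    "y_pred": pred,
                    "n_selected": len(sel.selected_idx),
                    "a_opt": sel.a_opt2,
                }
            )
            if store_selected:
                selected_sets.append(set(sel.selected_probe_ids))
        except BloodsigError as exc:  # degenerate fold: record and continue
            logger.warning("outer fold %d failed: %s", i, exc)
            rows.append(
                {
                    "array_id": array_ids[i],
                    "y_true": y[i],
                    "score": np.nan,
                    "y_pred": np.nan,
                    "n_selected": 0,
                    "a_opt": 0,
                }
            )
            if store_selected:
                selected_sets.append(set())
    return CVResult(records=pd.DataFrame(rows), selected_sets=selected_sets)


def confusion_metrics(cv: CVResult) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as percentages."""
    if len(cv) == 0:
        raise BloodsigError("empty CV result")
    TP, FN, TN, FP = cv.confusion
    n_case = TP + FN
    n_heal = TN + FP
    if n_case == 0 or n_heal == 0:
        raise BloodsigError("both classes required for confusion metrics")
    accuracy = 100.0 * (TP + TN) / (n_case + n_heal)
    sensitivity = 100.0 * TP / n_case
    specificity = 100.0 * TN / n_heal
    return accuracy, sensitivity, specificity


def roc_auc(
    scores: np.ndarray, truth: np.ndarray
) -> tuple[float, np.ndarray]:
    """AUC by the rank (Mann-Whitney) statistic with tie half-credit.

    ``truth`` is +1/-1 (or boolean, True = case).  Also returns the ROC
    curve as (1-specificity, sensitivity) points over all distinct score
    thresholds, from (0,0) to (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = truth > 0
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise BloodsigError("both classes required for ROC")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))

    order = np.argsort(-scores, kind="stable")
    sorted_pos = pos[order]
    sorted_scores = scores[order]
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tps = np.cumsum(sorted_pos)[distinct]
    fps = np.cumsum(~sorted_pos)[distinct]
    curve = np.column_stack(
        (np.r_[0.0, fps / n0], np.r_[0.0, tps / n1])
    )
    return auc, curve


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    seed: int,
    alpha: float = 0.05,
    A_max: Optional[int] = None,
    observed: Optional[CVResult] = None,
) -> PermutationResult:
    """Label-permutation null of the double-CV accuracy and AUC.

    The class labels are permuted against the fixed (already preprocessed)
    expression matrix and the entire double cross-validation is rerun for
    each of the ``k`` seeded permutations.  Empirical p-values use the
    plus-one convention and are therefore never zero.
    """
    if k < 1:
        raise BloodsigError("k must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    K = X @ X.T
    if observed is None:
        observed = double_cv(X, y, alpha=alpha, A_max=A_max, gram=K)
    obs_acc = confusion_metrics(observed)[0] / 100.0
    obs_auc = roc_auc(observed.scores, observed.y_true)[0]

    rng = np.random.default_rng(seed)
    accs, aucs = [], []
    n_failed = 0
    for _ in range(k):
        yp = rng.permutation(y)
        try:
            cv = double_cv(X, yp, alpha=alpha, A_max=A_max, gram=K)
            accs.append(confusion_metrics(cv)[0] / 100.0)
            aucs.append(roc_auc(cv.scores, cv.y_true)[0])
        except BloodsigError as exc:
            n_failed += 1
            logger.warning("permutation failed and was excluded: %s", exc)
    accs = np.asarray(accs)
    aucs = np.asarray(aucs)
    if accs.size == 0:
        raise BloodsigError("all permutations failed")
    m = accs.size
    return PermutationResult(
        k=k,
        accuracies=accs,
        aucs=aucs,
        observed_accuracy=obs_acc,
        observed_auc=obs_auc,
        p_accuracy=float((1 + (accs >= obs_acc).sum()) / (m + 1)),
        p_auc=float((1 + (aucs >= obs_auc).sum()) / (m + 1)),
        max_accuracy=float(accs.max()),
        max_auc=float(aucs.max()),
        seed=seed,
        n_failed=n_failed,
    )


def learning_curve(
    X: np.ndarray,
    y: np.ndarray,
    fractions: Sequence[float],
    reps: int,
    seed: int,
    alpha: float = 0.05,
    A_max: Optional[int] = None,
) -> LearningCurveResult:
    """Double-CV AUC over random class-balanced subsets of growing size."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    fractions = np.asarray(list(fractions), dtype=float)
    if ((fractions <= 0) | (fractions > 1)).any():
        raise BloodsigError("fractions must lie in (0, 1]")
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == -1)
    rng = np.random.default_rng(seed)
    mean_auc, sd_auc, values = [], [], []
    for frac in fractions:
        n_pos = int(round(frac * pos.size))
        n_neg = int(round(frac * neg.size))
        if n_pos < 3 or n_neg < 3:
            raise BloodsigError(
                f"fraction {frac} leaves fewer than 3 samples in a class"
            )
        aucs = []
        for _ in range(reps):
            sub = np.concatenate(
                (
                    rng.choice(pos, n_pos, replace=False),
                    rng.choice(neg, n_neg, replace=False),
                )
            )
            cv = double_cv(X[sub], y[sub], alpha=alpha, A_max=A_max)
            aucs.append(roc_auc(cv.scores, cv.y_true)[0])
        aucs = np.asarray(aucs)
        values.append(aucs)
        mean_auc.append(float(aucs.mean()))
        sd_auc.append(float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0)
    return LearningCurveResult(
        fractions=fractions,
        reps=reps,
        mean_auc=np.asarray(mean_auc),
        sd_auc=np.asarray(sd_auc),
        auc_values=values,
        seed=seed,
    )


def misclass_association(
    cv: CVResult,
    feature: Sequence[bool],
    among: str = "false_negatives",
) -> tuple[np.ndarray, float]:
    """Fisher exact test of a binary covariate among misclassified samples.

    Restricted to the relevant true class (cases for false negatives,
    healthy for false positives), the 2x2 table crosses the covariate with
    misclassification; the two-sided exact hypergeometric p is returned.
    ``feature`` is aligned with the CV records (entries outside the relevant
    class are ignored).
    """
    if among not in ("false_negatives", "false_positives"):
        raise BloodsigError("among must be false_negatives or false_positives")
    feature = np.asarray(feature, dtype=bool)
    if feature.shape[0] != len(cv):
        raise BloodsigError("feature length does not match CV records")
    truth_code = 1.0 if among == "false_negatives" else -1.0
    rel = cv.y_true == truth_code
    mis = cv.y_pred[rel] != cv.y_true[rel]
    f = feature[rel]
    if f.all() or (~f).all():
        raise BloodsigError("covariate has a single level in the relevant class")
    table = np.array(
        [
            [int((f & mis).sum()), int((f & ~mis).sum())],
            [int((~f & mis).sum()), int((~f & ~mis).sum())],
        ]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)
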