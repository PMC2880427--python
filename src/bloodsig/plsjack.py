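"""Component selection, jackknife coefficient testing and probe selection.

The inner analysis loop is: leave-one-out cross-validation of the PLS1
classifier picks the model order with minimal misclassification rate (ties
broken toward fewer components) and yields one coefficient vector per
leave-one-out segment; the jackknife compares the full-model coefficients
with the segment coefficients to test each probe against zero; probes with
p <= alpha are kept and the model is rebuilt on them, with a second LOO-CV
choosing the final model order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .containers import BloodsigError
from . import _kernel
from .pls import PLSModel, fit_pls1

logger = logging.getLogger(__name__)


@dataclass
class JackknifeResult:
    """Per-probe jackknife test of PLS regression coefficients."""

    b_full: np.ndarray  # coefficient per probe at the chosen model order
    se: np.ndarray  # jackknife standard error
    t: np.ndarray  # b_full / se
    p: np.ndarray  # two-sided Student-t tail, M-1 degrees of freedom
    M: int  # number of leave-one-out segments


@dataclass
class LooCvResult:
    a_opt: int
    err: np.ndarray  # misclassification rate, index a-1 for a components
    B_segments: np.ndarray  # (n_segments, p) coefficients at a_opt
    preds: np.ndarray  # (n, A_max) held-out predictions per model order


@dataclass
class SelectionResult:
    selected_probe_ids: np.ndarray
    selected_idx: np.ndarray  # column indices into the input matrix
    model: PLSModel
    a_opt2: int
    a_opt1: int
    err1: np.ndarray
    err2: np.ndarray
    jackknife: JackknifeResult
    fallback_used: bool = False


def default_a_max(n: int) -> int:
    return max(1, min(30, n - 2))


def loo_cv(
    X: np.ndarray,
    y: np.ndarray,
    A_max: Optional[int] = None,
    gram: Optional[np.ndarray] = None,
) -> LooCvResult:
    """Leave-one-out CV of model order plus per-segment coefficients.

    For each held-out sample the model is refitted on the rest and the
    sample predicted at every order 1..A_max; err[a-1] is the fraction
    misclassified by the sign rule.  The optimal order is the smallest one
    attaining the minimum.  The segment coefficient vectors at that order
    are returned for jackknife testing.

    ``gram`` may supply the precomputed uncentered X X' to avoid
    recomputation inside outer loops.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise BloodsigError("need at least 3 samples for LOO-CV")
    A_max = default_a_max(n) if A_max is None else A_max
    if not 1 <= A_max <= n - 2:
        raise BloodsigError(f"A_max={A_max} outside 1..n-2={n - 2}")
    A_max = min(A_max, p)
    K = X @ X.T if gram is None else gram

    preds, V, idx, _ = _kernel.loo_sweep(K, y, A_max)
    miss = (np.where(preds > 0, 1.0, -1.0) != y[:, None]).mean(axis=0)
    a_opt = int(np.argmin(miss)) + 1
    B_segments = _kernel.fold_coefs_probe_space(X, V[:, :, a_opt - 1], idx)
    return LooCvResult(a_opt=a_opt, err=miss, B_segments=B_segments, preds=preds)


def jackknife_test(b_full: np.ndarray, B_segments: np.ndarray) -> JackknifeResult:
    """Jackknife significance of each coefficient against zero.

    se_i^2 = ((M-1)/M) * sum_m (b_full_i - b_{m,i})^2 over the M
    leave-one-out segments; t = b_full/se is referred to a Student t with
    M-1 degrees of freedom (two-sided).  A coefficient with zero jackknife
    variance gets p = 0 when nonzero (perfectly stable) and p = 1 when zero.
    """
    b_full = np.asarray(b_full, dtype=float)
    B_segments = np.asarray(B_segments, dtype=float)
    M = B_segments.shape[0]
    if M < 3:
        raise BloodsigError("need at least 3 segments for the jackknife")
    se = np.sqrt((M - 1) / M * ((b_full[None, :] - B_segments) ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b_full / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=M - 1)
    zero_se = se == 0
    p[zero_se & (b_full != 0)] = 0.0
    p[zero_se & (b_full == 0)] = 1.0
    return JackknifeResult(b_full=b_full, se=se, t=t, p=np.clip(p, 0.0, 1.0), M=M)


def select_and_refit(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    A_max: Optional[int] = None,
    probe_ids: Optional[Sequence] = None,
    gram: Optional[np.ndarray] = None,
) -> SelectionResult:
    """Jackknife probe selection followed by a refit with a second LOO-CV.

    Runs the inner LOO-CV, tests every coefficient by jackknife, keeps
    probes with p <= alpha (falling back to the single smallest-p probe if
    none pass), refits PLS1 on the survivors and re-selects the model order
    by a second LOO-CV.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    probe_ids = (
        np.array([f"p{i}" for i in range(p)], dtype=object)
        if probe_ids is None
        else np.asarray(probe_ids, dtype=object)
    )
    K = X @ X.T if gram is None else gram

    loo1 = loo_cv(X, y, A_max, gram=K)
    b_full = _kernel.full_fit_coefs(K, X, y, loo1.a_opt)
    jk = jackknife_test(b_full, loo1.B_segments)

    sel = np.flatnonzero(jk.p <= alpha)
    fallback = False
    if sel.size == 0:
        sel = np.array([int(np.argmin(jk.p))])
        fallback = True
        logger.warning(
            "no probe passed the jackknife threshold alpha=%.3g; "
            "falling back to the single smallest-p probe",
            alpha,
        )

    Xs = X[:, sel]
    A_max2 = None if A_max is None else min(A_max, Xs.shape[1], n - 2)
    loo2 = loo_cv(Xs, y, A_max2)
    model = fit_pls1(Xs, y, loo2.a_opt, probe_ids=probe_ids[sel])
    return SelectionResult(
        selected_probe_ids=probe_ids[sel],
        selected_idx=sel,
        model=model,
        a_opt2=loo2.a_opt,
        a_opt1=loo1.a_opt,
        err1=loo1.err,
        err2=loo2.err,
        jackknife=jk,
        fallback_used=fallback,
    )
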