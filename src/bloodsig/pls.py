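"""PLS1 regression core (NIPALS) and the -1/+1 threshold classifier.

The predictor matrix is samples x probes; the response is the dummy-coded
class vector (-1 healthy, +1 case).  A sample is called diseased when its
predicted value is strictly greater than zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .containers import BloodsigError, CLASS_CASE, CLASS_HEALTHY


@dataclass
class PLSModel:
    """A fitted PLS1 model.

    Attributes
    ----------
    x_mean, x_scale : per-probe centering and scaling applied at fit time.
    y_mean : response mean.
    A : number of latent components.
    W, P : (p, A) weight and x-loading matrices.
    q : (A,) y-loadings.
    T : (n, A) score matrix (columns mutually orthogonal).
    B : (p, A) regression coefficient vectors; column a-1 is the
        coefficient vector of the model truncated to a components.
    probe_ids : optional identifiers enabling id-keyed prediction.
    """

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    A: int
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    B: np.ndarray
    probe_ids: Optional[np.ndarray] = None


def fit_pls1(
    X: np.ndarray,
    y: np.ndarray,
    A: int,
    probe_ids: Optional[Sequence] = None,
    scale: bool = False,
) -> PLSModel:
    """Fit a PLS1 model with A latent components by NIPALS deflation.

    ``X`` is samples x probes with no missing values.  By default probes are
    centered but not rescaled (the pipeline standardizes upstream); pass
    ``scale=True`` to divide by per-probe sample sd as well.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise BloodsigError("X must be 2-D (samples x probes)")
    n, p = X.shape
    if len(y) != n:
        raise BloodsigError("y length does not match X")
    if np.ptp(y) == 0:
        raise BloodsigError("constant response; both classes must be present")
    if not 1 <= A <= min(n - 1, p):
        raise BloodsigError(
            f"A={A} outside valid range 1..min(n-1={n - 1}, p={p})"
        )

    x_mean = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd <= 0).any():
            raise BloodsigError("zero-variance probe cannot be scaled")
        x_scale = sd
    else:
        x_scale = np.ones(p)
    y_mean = float(y.mean())

    Xa = (X - x_mean) / x_scale
    ya = y - y_mean
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    used = 0
    for a in range(A):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break  # predictor space exhausted; remaining components are null
        w /= nw
        t = Xa @ w
        c = float(t @ t)
        if c < 1e-12:
            break
        p_load = Xa.T @ t / c
        q_a = float(ya @ t) / c
        Xa = Xa - np.outer(t, p_load)
        ya = ya - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_load, t, q_a
        used += 1

    B = np.zeros((p, A))
    for a in range(1, used + 1):
        PtW = P[:, :a].T @ W[:, :a]
        coef = np.linalg.solve(PtW, q[:a])
        B[:, a - 1] = W[:, :a] @ coef
    for a in range(used + 1, A + 1):  # exhausted orders repeat the last
        B[:, a - 1] = B[:, used - 1] if used else 0.0

    return PLSModel(
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        A=A,
        W=W,
        P=P,
        q=q,
        T=T,
        B=B,
        probe_ids=None if probe_ids is None else np.asarray(probe_ids, dtype=object),
    )


def predict_score(
    model: PLSModel,
    X_new: Union[np.ndarray, pd.DataFrame],
    a: Optional[int] = None,
) -> np.ndarray:
    """Continuous prediction scores for new samples at model order ``a``.

    ``X_new`` may be an array in the model's probe order or a DataFrame
    whose columns are probe ids (realigned by id).
    """
    a = model.A if a is None else a
    if not 1 <= a <= model.A:
        raise BloodsigError(f"a={a} outside 1..{model.A}")
    if isinstance(X_new, pd.DataFrame):
        if model.probe_ids is None:
            raise BloodsigError("model has no probe_ids for id-keyed alignment")
        missing = [pid for pid in model.probe_ids if pid not in X_new.columns]
        if missing:
            raise BloodsigError(f"probes absent from X_new: {missing[:5]}")
        X_new = X_new.loc[:, list(model.probe_ids)].to_numpy(dtype=float)
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(model.x_mean):
        raise BloodsigError(
            f"X_new has {X_new.shape[1]} probes, model expects {len(model.x_mean)}"
        )
    Xc = (X_new - model.x_mean) / model.x_scale
    return model.y_mean + Xc @ model.B[:, a - 1]


def classify(score) -> Union[str, np.ndarray]:
    """Threshold rule: score strictly greater than 0 is a disease case."""
    arr = np.asarray(score, dtype=float)
    if not np.isfinite(arr).all():
        raise BloodsigError("non-finite prediction score")
    labels = np.where(arr > 0, CLASS_CASE, CLASS_HEALTHY)
    if np.isscalar(score) or arr.ndim == 0:
        return str(labels)
    return labels.astype(object)
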