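"""Sample-space (kernel) formulation of PLS1 used by the cross-validation
loops.

For n samples and p probes with p >> n, every NIPALS quantity can be carried
in n-dimensional sample space using only the Gram matrix K = Xc Xc' of the
centered training data.  Because NIPALS score vectors are mutually
orthogonal, the accumulated deflation operator is the symmetric projector
G_a = I - sum_{i<a} t_i t_i'/c_i, which gives the recurrences

    s_a   = G_a y            (so the weight vector is w_a = Xc' s_a/||.||),
    t_a   = G_a K s_a / ||Xc' s_a||,
    p_a   = Xc' t_a / c_a,
    s_a+1 = s_a - q_a t_a,

with one K-matvec per component and no explicit projector.  The regression
coefficient vector at model order a is B_a = Xc' v_a with
v_a = R (P'W)^{-1} q computed from Gram products alone; a leave-one-out
sweep therefore never touches probe space except for one final matrix
product, which is what makes the nested double cross-validation affordable.

All routines are batched over a leading "fold" axis so an entire LOO sweep
runs as a handful of batched matmuls per latent component.
"""

from __future__ import annotations

import numpy as np

_DEAD = 1e-12  # relative threshold below which a component is rank-exhausted


def center_gram_batch(Ksub: np.ndarray, inplace: bool = False) -> np.ndarray:
    """Double-center each Gram matrix in a (F, n, n) stack."""
    rowm = Ksub.mean(axis=2, keepdims=True)
    colm = Ksub.mean(axis=1, keepdims=True)
    gm = rowm.mean(axis=1, keepdims=True)
    out = Ksub if inplace else Ksub.copy()
    out -= rowm
    out -= colm
    out += gm
    return out


_loo_idx_cache: dict[int, np.ndarray] = {}


def loo_indices(n: int) -> np.ndarray:
    """(n, n-1) training-index matrix for leave-one-out folds (cached)."""
    idx = _loo_idx_cache.get(n)
    if idx is None:
        base = np.arange(n)
        idx = np.tile(base, (n, 1))[~np.eye(n, dtype=bool)].reshape(n, n - 1)
        if len(_loo_idx_cache) > 64:
            _loo_idx_cache.clear()
        _loo_idx_cache[n] = idx
    return idx


def kernel_pls_batch(
    Kc: np.ndarray, yc: np.ndarray, A: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run A components of PLS1 on each fold of a centered Gram stack.

    Parameters
    ----------
    Kc : (F, n, n) centered Gram matrices.
    yc : (F, n) centered responses.
    A : number of latent components.

    Returns
    -------
    R : (F, n, A) sample-space weight representations (w_a = Xc' r_a).
        Rank-exhausted components are all-zero columns.
    T : (F, n, A) score vectors.
    q : (F, A) y-loadings.
    c : (F, A) squared score norms (1.0 for dead components).
    """
    F, n, _ = Kc.shape
    R = np.zeros((F, n, A))
    T = np.zeros((F, n, A))
    q = np.zeros((F, A))
    cvec = np.ones((F, A))
    s = yc.copy()
    scale = np.einsum("fii->f", Kc) / max(n, 1) + 1.0

    for a in range(A):
        Ks = np.matmul(Kc, s[:, :, None])[:, :, 0]
        nw2 = np.einsum("fi,fi->f", s, Ks)  # ||Xc' s||^2
        alive = nw2 > _DEAD * scale
        nw = np.sqrt(np.where(alive, nw2, 1.0))
        if a > 0:
            # project out previous scores: t = G Ks
            Tprev = T[:, :, :a]
            coef = np.einsum("fna,fn->fa", Tprev, Ks) / cvec[:, :a]
            t = Ks - np.matmul(Tprev, coef[:, :, None])[:, :, 0]
        else:
            t = Ks
        t = t / nw[:, None]
        c = np.einsum("fi,fi->f", t, t)
        alive &= c > _DEAD * scale
        t[~alive] = 0.0
        c_safe = np.where(alive, c, 1.0)
        qa = np.where(alive, np.einsum("fi,fi->f", yc, t) / c_safe, 0.0)
        r = s / nw[:, None]
        r[~alive] = 0.0
        R[:, :, a] = r
        T[:, :, a] = t
        q[:, a] = qa
        cvec[:, a] = c_safe
        s = s - qa[:, None] * t
    return R, T, q, cvec


def sample_coefs_batch(
    R: np.ndarray,
    T: np.ndarray,
    q: np.ndarray,
    cvec: np.ndarray,
    Kc: np.ndarray,
) -> np.ndarray:
    """Coefficient vectors in sample space for every model order.

    Returns V of shape (F, n, A); column a-1 satisfies B_a = Xc' V[..., a-1]
    for the model with a components.
    """
    F, n, A = R.shape
    KR = np.matmul(Kc, R)
    # (P'W)[i,j] = p_i' w_j = (t_i/c_i)' K r_j
    PtW = np.einsum("fni,fnj->fij", T, KR) / cvec[:, :, None]
    # rank-exhausted components have zero rows/columns; pin the diagonal so
    # the triangular system stays solvable (their q is 0, so they drop out)
    diag = np.einsum("faa->fa", PtW)
    f_idx, a_idx = np.nonzero(np.abs(diag) < 0.5)
    PtW[f_idx, a_idx, a_idx] = 1.0
    V = np.zeros((F, n, A))
    for a in range(1, A + 1):
        coef = np.linalg.solve(PtW[:, :a, :a], q[:, :a, None])[:, :, 0]
        V[:, :, a - 1] = np.matmul(R[:, :, :a], coef[:, :, None])[:, :, 0]
    return V


def loo_sweep(
    K: np.ndarray, y: np.ndarray, A: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-out predictions for every model order 1..A.

    Parameters
    ----------
    K : (n, n) uncentered Gram matrix of the training data.
    y : (n,) response.

    Returns
    -------
    preds : (n, A) prediction of each held-out sample at each model order.
    V : (n, n-1, A) sample-space coefficient vectors per fold.
    idx : (n, n-1) training indices per fold.
    ybar : (n,) training response means per fold.
    """
    n = len(y)
    base = np.arange(n)
    idx = loo_indices(n)
    Ksub = K[idx[:, :, None], idx[:, None, :]]
    colm = Ksub.mean(axis=1)
    gm = colm.mean(axis=1)
    Kc = center_gram_batch(Ksub, inplace=True)
    ysub = y[idx]
    ybar = ysub.mean(axis=1)
    yc = ysub - ybar[:, None]
    # centered cross-gram between the held-out sample and its training set
    kv = K[base[:, None], idx]
    kc = kv - kv.mean(axis=1, keepdims=True) - colm + gm[:, None]

    R, T, q, cvec = kernel_pls_batch(Kc, yc, A)
    V = sample_coefs_batch(R, T, q, cvec, Kc)
    preds = ybar[:, None] + np.einsum("fn,fna->fa", kc, V)
    return preds, V, idx, ybar


def fold_coefs_probe_space(
    X: np.ndarray, V_a: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """Map per-fold sample-space coefficients to probe space.

    B_f = Xc_f' v_f where Xc_f is fold f's centered training matrix.
    Returns an (n_folds, p) array via a single gemm.
    """
    n, p = X.shape
    F, nt = V_a.shape
    Vt = np.zeros((n, F))
    Vt[idx, np.arange(F)[:, None]] = V_a
    s = V_a.sum(axis=1)
    colsum = X.sum(axis=0)
    B = X.T @ Vt - (np.outer(colsum, s) - X.T * s) / nt
    return B.T


def full_fit_coefs(
    K: np.ndarray, X: np.ndarray, y: np.ndarray, A: int
) -> np.ndarray:
    """Probe-space coefficient vector of the full-data fit at order A."""
    Kc = center_gram_batch(K[None, :, :])
    yc = (y - y.mean())[None, :]
    R, T, q, cvec = kernel_pls_batch(Kc, yc, A)
    V = sample_coefs_batch(R, T, q, cvec, Kc)
    v = V[0, :, A - 1]
    xbar = X.mean(axis=0)
    return X.T @ v - xbar * v.sum()
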