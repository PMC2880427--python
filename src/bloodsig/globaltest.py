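"""Permutation-based global test of a probe set with per-probe influence.

For a standardized predictor matrix X (samples x probes) and centered
response y, each probe's influence is Q_i = (sum_j x_ij (y_j - ybar))^2 and
the set statistic is the mean of the Q_i.  A seeded permutation null of the
response yields the null mean E_i and sd s_i of each influence, the z-score
z_i = (Q_i - E_i)/s_i, and the set-level permutation p-value.  Probes with
z above a threshold (default 2, strict) form the "core" subset, split into
up- and down-regulated by the sign of their covariance with the case code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import BloodsigError


@dataclass
class GlobalTestResult:
    probe_ids: np.ndarray
    Q: np.ndarray  # observed influence per probe
    E: np.ndarray  # permutation-null mean of the influence
    sd: np.ndarray  # permutation-null sd
    z: np.ndarray  # (Q - E) / sd
    direction: np.ndarray  # 'up' or 'down' per probe
    set_p: float  # permutation p for the whole set
    B: int
    seed: int


def gene_influences(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-probe influence Q_i = (x_i . (y - ybar))^2."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise BloodsigError("constant response")
    yc = y - y.mean()
    return (yc @ X) ** 2


def set_statistic(Q: np.ndarray) -> float:
    """Set-level statistic: mean influence over probes."""
    return float(np.mean(Q))


def null_calibrate(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 10_000,
    seed: int = 0,
    probe_ids=None,
) -> GlobalTestResult:
    """Estimate the permutation null of every influence and the set p-value.

    ``B`` seeded permutations of the response are scored in one pass; the
    set p uses the plus-one convention, so it is never zero.
    """
    if B < 100:
        raise BloodsigError("B must be >= 100 for stable null moments")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if probe_ids is None:
        probe_ids = np.array([f"p{i}" for i in range(p)], dtype=object)
    else:
        probe_ids = np.asarray(probe_ids, dtype=object)

    yc = y - y.mean()
    Q = (yc @ X) ** 2
    q_set = set_statistic(Q)

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((B, n)), axis=1)
    Yperm = yc[order]  # (B, n); permuting centered y keeps it centered
    S = Yperm @ X  # (B, p)
    Qperm = S**2
    E = Qperm.mean(axis=0)
    sd = Qperm.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (Q - E) / np.where(sd > 0, sd, 1.0), 0.0)

    cov = yc @ X
    direction = np.where(cov > 0, "up", "down").astype(object)
    n_zero = int((cov == 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} probes have zero covariance with the response; "
            "direction set to 'up'",
            stacklevel=2,
        )
        direction[cov == 0] = "up"

    set_p = float((1 + (Qperm.mean(axis=1) >= q_set).sum()) / (B + 1))
    return GlobalTestResult(
        probe_ids=probe_ids,
        Q=Q,
        E=E,
        sd=sd,
        z=z,
        direction=direction,
        set_p=set_p,
        B=B,
        seed=seed,
    )


def core_probes(
    result: GlobalTestResult, z_min: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Probes with z strictly above z_min, split by direction."""
    core = result.z > z_min
    up = result.probe_ids[core & (result.direction == "up")]
    down = result.probe_ids[core & (result.direction == "down")]
    return up, down


def z_summary(result: GlobalTestResult) -> dict:
    """Median and sd of z within the up and down groups."""
    out = {}
    for name in ("up", "down"):
        sel = result.direction == name
        zz = result.z[sel]
        out[name] = {
            "n": int(sel.sum()),
            "median_z": float(np.median(zz)) if zz.size else float("nan"),
            "sd_z": float(np.std(zz, ddof=1)) if zz.size > 1 else float("nan"),
        }
    return out
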