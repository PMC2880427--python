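"""Preprocessing chain for quality-annotated log2 intensity matrices.

The chain runs, in fixed order:

1. quality masking (SNR < 3 or flag > 8191 set missing),
2. probe filtering (> 5% missing entries over all arrays),
3. per-probe standardization (mean 0, sample sd 1 over observed entries),
4. k-nearest-neighbour imputation over probes (k = 10),
5. per-probe batch mean-centering (one-way ANOVA batch-effect removal),
6. exclusion of technical-control arrays,
7. averaging of biological replicate arrays per subject,
8. within-array normalization by global mean subtraction.

Preprocessing is performed once on the full dataset, outside any
cross-validation; see the package docs for the information-leakage caveat
this carries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ANNOTATION_COLUMNS,
    CLASS_TECHNICAL,
    BloodsigError,
    ExpressionMatrix,
    SampleAnnotation,
)


@dataclass
class PreprocessParams:
    """Thresholds of the preprocessing chain."""

    snr_min: float = 3.0  # strict: masked when snr < snr_min
    flag_max: float = 8191.0  # strict: masked when flag > flag_max
    max_missing_frac: float = 0.05  # probes with more are excluded
    knn_k: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise BloodsigError("max_missing_frac must lie in [0, 1]")
        if self.knn_k < 1:
            raise BloodsigError("knn_k must be >= 1")


@dataclass
class PreprocessReport:
    """Bookkeeping of one pipeline run."""

    n_probes_in: int = 0
    n_probes_out: int = 0
    n_arrays_in: int = 0
    n_arrays_out: int = 0
    n_masked_entries: int = 0
    steps: list = field(default_factory=list)

    def log(self, step: str, **info) -> None:
        self.steps.append({"step": step, **info})


# --------------------------------------------------------------------------
# individual stages
# --------------------------------------------------------------------------

def mask_low_quality(
    matrix: ExpressionMatrix, params: PreprocessParams | None = None
) -> ExpressionMatrix:
    """Mark measurements with SNR below or flag above threshold as missing.

    Both comparisons are strict: an entry at exactly ``snr_min`` or exactly
    ``flag_max`` is retained.
    """
    params = params or PreprocessParams()
    if matrix.snr is None or matrix.flag is None:
        raise BloodsigError(
            "quality grids (snr, flag) are required for masking and are absent"
        )
    out = matrix.copy()
    out.missing_mask |= (matrix.snr < params.snr_min) | (
        matrix.flag > params.flag_max
    )
    return out


def filter_probes(
    matrix: ExpressionMatrix, params: PreprocessParams | None = None
) -> ExpressionMatrix:
    """Drop probes whose missing fraction exceeds ``max_missing_frac``."""
    params = params or PreprocessParams()
    if matrix.n_arrays == 0:
        return matrix.copy()
    frac = matrix.missing_mask.mean(axis=1)
    keep = np.flatnonzero(frac <= params.max_missing_frac)
    return matrix.take_probes(keep)


def standardize(matrix: ExpressionMatrix, on_constant: str = "error") -> ExpressionMatrix:
    """Center and scale each probe to mean 0, sample (n-1) sd 1.

    Only observed entries enter the moments.  A zero-variance probe raises
    (``on_constant='error'``) or is dropped with a warning
    (``on_constant='drop'``, used by the pipeline).
    """
    out = matrix.copy()
    obs = ~out.missing_mask
    n_obs = obs.sum(axis=1)
    if (n_obs < 2).any():
        bad = matrix.probe_ids[n_obs < 2]
        raise BloodsigError(
            f"probes with fewer than 2 observed values cannot be standardized: "
            f"{list(bad[:5])}"
        )
    vals = np.where(obs, out.values, 0.0)
    mean = vals.sum(axis=1) / n_obs
    centered = np.where(obs, out.values - mean[:, None], 0.0)
    sd = np.sqrt((centered**2).sum(axis=1) / (n_obs - 1))
    const = sd <= 0
    if const.any():
        bad = list(matrix.probe_ids[const][:5])
        if on_constant == "drop":
            warnings.warn(
                f"dropping {int(const.sum())} zero-variance probes: {bad}",
                stacklevel=2,
            )
            return standardize(matrix.take_probes(np.flatnonzero(~const)))
        raise BloodsigError(f"zero-variance probes cannot be scaled: {bad}")
    out.values = centered / sd[:, None]
    out.values[~obs] = 0.0
    return out


def knn_impute(
    matrix: ExpressionMatrix, params: PreprocessParams | None = None
) -> ExpressionMatrix:
    """Fill missing entries from the k nearest probes.

    Distances between probes are Euclidean over mutually observed arrays,
    rescaled by the number of shared arrays (root mean squared difference),
    so probes with few shared observations are comparable to complete pairs.
    An imputed value is the 1/(distance + 1e-6)-weighted mean of the values
    of the ``k`` nearest probes observed at the target array.  With fewer
    than ``k`` eligible neighbours all eligible ones are used; with none the
    probe's own observed mean is used.
    """
    params = params or PreprocessParams()
    out = matrix.copy()
    obs = ~out.missing_mask
    if (~obs).sum() == 0:
        return out
    if (obs.sum(axis=1) == 0).any():
        bad = matrix.probe_ids[obs.sum(axis=1) == 0]
        raise BloodsigError(f"probes with no observed values: {list(bad[:5])}")

    V = np.where(obs, out.values, 0.0)
    O = obs.astype(float)
    # pairwise mean squared difference over shared arrays via three gemms
    sq = V**2
    shared = O @ O.T
    cross = V @ V.T
    ssum = sq @ O.T
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = (ssum + ssum.T - 2.0 * cross) / shared
    dist = np.sqrt(np.maximum(msd, 0.0))
    np.fill_diagonal(dist, np.inf)
    dist[shared == 0] = np.inf  # no mutually observed arrays

    eps = 1e-6
    probe_mean = V.sum(axis=1) / O.sum(axis=1)
    miss_rows, miss_cols = np.nonzero(~obs)
    for i, j in zip(miss_rows, miss_cols):
        eligible = np.flatnonzero(obs[:, j] & np.isfinite(dist[i]))
        if eligible.size == 0:
            out.values[i, j] = probe_mean[i]
            continue
        d = dist[i, eligible]
        if eligible.size > params.knn_k:
            order = np.argsort(d, kind="stable")[: params.knn_k]
            eligible = eligible[order]
            d = d[order]
        w = 1.0 / (d + eps)
        out.values[i, j] = float(np.dot(w, out.values[eligible, j]) / w.sum())
    out.missing_mask[:] = False
    return out


def batch_adjust(
    matrix: ExpressionMatrix, annot: SampleAnnotation
) -> ExpressionMatrix:
    """Subtract the within-batch mean of every probe (one-way ANOVA removal).

    After adjustment every probe has mean exactly 0 within each batch.  The
    grand level is not added back; the pipeline re-normalizes arrays later.
    Technical-control arrays, if still present, take part in the batch means.
    """
    annot.check_matches(matrix)
    if matrix.missing_mask.any():
        raise BloodsigError("batch adjustment requires a complete matrix")
    batches = annot.aligned_to(matrix.array_ids)["batch_id"].to_numpy()
    out = matrix.copy()
    for b in pd.unique(batches):
        cols = np.flatnonzero(batches == b)
        if cols.size < 2:
            raise BloodsigError(
                f"batch {b!r} has a single array; mean-centering would zero it"
            )
        out.values[:, cols] -= out.values[:, cols].mean(axis=1, keepdims=True)
    return out


def drop_technical_controls(
    matrix: ExpressionMatrix, annot: SampleAnnotation
) -> tuple[ExpressionMatrix, SampleAnnotation]:
    """Remove technical-control arrays from matrix and annotation."""
    annot.check_matches(matrix)
    aligned = annot.aligned_to(matrix.array_ids)
    keep = np.flatnonzero(
        (aligned["class_label"] != CLASS_TECHNICAL).to_numpy()
    )
    out = matrix.take_arrays(keep)
    return out, annot.subset(out.array_ids)


def collapse_replicates(
    matrix: ExpressionMatrix, annot: SampleAnnotation
) -> tuple[ExpressionMatrix, SampleAnnotation]:
    """Average biological replicate arrays so one array per subject remains.

    Arrays sharing a subject_id are replaced by their per-probe mean, under
    the first replicate's array_id.  Class labels must agree within a group.
    """
    annot.check_matches(matrix)
    aligned = annot.aligned_to(matrix.array_ids)
    subjects = aligned["subject_id"].to_numpy()
    keep_cols: list[int] = []
    new_values: list[np.ndarray] = []
    rows = []
    seen: set = set()
    for j, subj in enumerate(subjects):
        if subj in seen:
            continue
        seen.add(subj)
        cols = np.flatnonzero(subjects == subj)
        labels = set(aligned["class_label"].to_numpy()[cols])
        if len(labels) > 1:
            raise BloodsigError(
                f"subject {subj!r} has conflicting class labels {sorted(labels)}"
            )
        new_values.append(matrix.values[:, cols].mean(axis=1))
        rows.append(aligned.iloc[j])
    if not rows:
        empty = ExpressionMatrix(
            probe_ids=matrix.probe_ids,
            array_ids=np.array([], dtype=object),
            values=np.empty((matrix.n_probes, 0)),
        )
        return empty, SampleAnnotation(
            pd.DataFrame(columns=ANNOTATION_COLUMNS)
        )
    table = pd.DataFrame(rows).reset_index(drop=True)
    out = ExpressionMatrix(
        probe_ids=matrix.probe_ids,
        array_ids=table["array_id"].to_numpy(dtype=object),
        values=np.column_stack(new_values),
    )
    return out, SampleAnnotation(table)


def global_mean_subtract(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Within-array normalization: subtract each array's mean over probes."""
    if matrix.missing_mask.any():
        raise BloodsigError("global mean subtraction requires a complete matrix")
    out = matrix.copy()
    if out.n_probes:
        out.values -= out.values.mean(axis=0, keepdims=True)
    return out


# --------------------------------------------------------------------------
# full chain
# --------------------------------------------------------------------------

def preprocess_pipeline(
    matrix: ExpressionMatrix,
    annot: SampleAnnotation,
    params: PreprocessParams | None = None,
) -> tuple[ExpressionMatrix, SampleAnnotation, PreprocessReport]:
    """Run the full chain in fixed order and report the bookkeeping."""
    params = params or PreprocessParams()
    annot.check_matches(matrix)
    report = PreprocessReport(
        n_probes_in=matrix.n_probes, n_arrays_in=matrix.n_arrays
    )

    m = mask_low_quality(matrix, params)
    report.n_masked_entries = int(m.missing_mask.sum())
    report.log("mask_low_quality", n_masked=report.n_masked_entries)

    m = filter_probes(m, params)
    report.log("filter_probes", n_probes=m.n_probes)

    m = standardize(m, on_constant="drop")
    report.log("standardize", n_probes=m.n_probes)

    n_to_impute = int(m.missing_mask.sum())
    m = knn_impute(m, params)
    report.log("knn_impute", n_imputed=n_to_impute)

    m = batch_adjust(m, annot)
    report.log("batch_adjust")

    m, ann = drop_technical_controls(m, annot)
    report.log("drop_technical_controls", n_arrays=m.n_arrays)

    m, ann = collapse_replicates(m, ann)
    report.log("collapse_replicates", n_arrays=m.n_arrays)

    m = global_mean_subtract(m)
    report.log("global_mean_subtract")

    report.n_probes_out = m.n_probes
    report.n_arrays_out = m.n_arrays
    return m, ann, report
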