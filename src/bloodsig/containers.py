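"""In-memory containers shared across the pipeline.

The expression data live in a probes x arrays grid, matching the on-disk TSV
layout of single-channel array exports.  A parallel boolean ``missing_mask``
marks entries excluded from downstream arithmetic; the quality fields
(signal-to-noise ratio and scanner flag) that drive the masking travel with
the matrix so the preprocessor can apply the quality rules itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

CLASS_CASE = "case"
CLASS_HEALTHY = "control_healthy"
CLASS_TECHNICAL = "technical_control"

STUDY_CLASSES = (CLASS_CASE, CLASS_HEALTHY)


class BloodsigError(ValueError):
    """Base class for pipeline contract violations."""


@dataclass
class ExpressionMatrix:
    """Probes x arrays log2 intensity grid with quality companions.

    Parameters
    ----------
    probe_ids, array_ids
        Unique identifiers for rows and columns.
    values
        float array, shape (n_probes, n_arrays), log2 scale.
    missing_mask
        bool array, same shape; True marks an entry treated as missing.
        Masked entries may still hold a number, but no downstream arithmetic
        uses it.
    snr, flag
        Optional per-measurement quality grids (same shape).
    """

    probe_ids: np.ndarray
    array_ids: np.ndarray
    values: np.ndarray
    missing_mask: Optional[np.ndarray] = None
    snr: Optional[np.ndarray] = None
    flag: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.array_ids = np.asarray(self.array_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        shape = (len(self.probe_ids), len(self.array_ids))
        if self.values.shape != shape:
            raise BloodsigError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.array_ids)} arrays"
            )
        if self.missing_mask is None:
            self.missing_mask = np.zeros(shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != shape:
                raise BloodsigError("missing_mask shape mismatch")
        for name in ("snr", "flag"):
            grid = getattr(self, name)
            if grid is not None:
                grid = np.asarray(grid, dtype=float)
                if grid.shape != shape:
                    raise BloodsigError(f"{name} shape mismatch")
                setattr(self, name, grid)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise BloodsigError("probe_ids are not unique")
        if len(set(self.array_ids)) != len(self.array_ids):
            raise BloodsigError("array_ids are not unique")

    # -- basic introspection -------------------------------------------------
    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_probes, self.n_arrays)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            probe_ids=self.probe_ids.copy(),
            array_ids=self.array_ids.copy(),
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            snr=None if self.snr is None else self.snr.copy(),
            flag=None if self.flag is None else self.flag.copy(),
        )

    # -- subsetting ----------------------------------------------------------
    def take_probes(self, row_idx: np.ndarray) -> "ExpressionMatrix":
        row_idx = np.asarray(row_idx)
        return ExpressionMatrix(
            probe_ids=self.probe_ids[row_idx],
            array_ids=self.array_ids,
            values=self.values[row_idx],
            missing_mask=self.missing_mask[row_idx],
            snr=None if self.snr is None else self.snr[row_idx],
            flag=None if self.flag is None else self.flag[row_idx],
        )

    def take_arrays(self, col_idx: np.ndarray) -> "ExpressionMatrix":
        col_idx = np.asarray(col_idx)
        return ExpressionMatrix(
            probe_ids=self.probe_ids,
            array_ids=self.array_ids[col_idx],
            values=self.values[:, col_idx],
            missing_mask=self.missing_mask[:, col_idx],
            snr=None if self.snr is None else self.snr[:, col_idx],
            flag=None if self.flag is None else self.flag[:, col_idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view with masked entries as NaN (probes x arrays)."""
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.probe_ids, columns=self.array_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        vals = frame.to_numpy(dtype=float)
        mask = np.isnan(vals)
        return cls(
            probe_ids=frame.index.to_numpy(dtype=object),
            array_ids=frame.columns.to_numpy(dtype=object),
            values=np.where(mask, 0.0, vals),
            missing_mask=mask,
        )


ANNOTATION_COLUMNS = [
    "array_id",
    "subject_id",
    "batch_id",
    "class_label",
    "replicate_group",
]


@dataclass
class SampleAnnotation:
    """Per-array sample annotation (class, batch, subject, replicate)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise BloodsigError(f"annotation missing columns: {missing}")
        self.table = self.table[ANNOTATION_COLUMNS].reset_index(drop=True)
        if self.table["array_id"].duplicated().any():
            raise BloodsigError("duplicate array_id in annotation")
        bad = ~self.table["class_label"].isin(
            [CLASS_CASE, CLASS_HEALTHY, CLASS_TECHNICAL]
        )
        if bad.any():
            raise BloodsigError(
                f"unknown class labels: {sorted(self.table.loc[bad, 'class_label'].unique())}"
            )

    def __len__(self) -> int:
        return len(self.table)

    def copy(self) -> "SampleAnnotation":
        return SampleAnnotation(self.table.copy())

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        """Every array in the matrix must have exactly one annotation row."""
        ann_ids = set(self.table["array_id"])
        mat_ids = list(matrix.array_ids)
        missing = [a for a in mat_ids if a not in ann_ids]
        if missing:
            raise BloodsigError(f"arrays without annotation: {missing[:5]} ...")

    def aligned_to(self, array_ids: Sequence) -> pd.DataFrame:
        """Annotation rows reordered to the given array order."""
        tab = self.table.set_index("array_id")
        sub = tab.loc[list(array_ids)].reset_index()
        return sub[ANNOTATION_COLUMNS]

    def subset(self, array_ids: Iterable) -> "SampleAnnotation":
        keep = self.table["array_id"].isin(set(array_ids))
        return SampleAnnotation(self.table.loc[keep].copy())

    @property
    def is_technical_control(self) -> pd.Series:
        return self.table["class_label"] == CLASS_TECHNICAL


def response_from_labels(labels: Sequence[str]) -> np.ndarray:
    """Dummy-coded response: healthy control -> -1, disease case -> +1."""
    labels = list(labels)
    y = np.empty(len(labels), dtype=float)
    for i, lab in enumerate(labels):
        if lab == CLASS_CASE:
            y[i] = 1.0
        elif lab == CLASS_HEALTHY:
            y[i] = -1.0
        else:
            raise BloodsigError(
                f"cannot code class {lab!r}; only study classes allowed"
            )
    if not ((y == 1).any() and (y == -1).any()):
        raise BloodsigError("both classes must be present in the response")
    return y
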