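"""Readers and writers for the pipeline's text formats.

* Matrix TSV: first column ``probe_id``, one column per array, tab-separated,
  missing written as ``NA``.
* Annotation CSV: ``array_id,subject_id,batch_id,class_label,replicate_group``.
* GEO Series Matrix: ``!``-prefixed header lines with the expression table
  between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import BloodsigError, ExpressionMatrix, SampleAnnotation


def write_matrix_tsv(matrix: ExpressionMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")


def read_matrix_tsv(
    path,
    snr_path=None,
    flag_path=None,
    log2: bool = False,
) -> ExpressionMatrix:
    """Read a matrix TSV, optionally with matching SNR/flag grids.

    With ``log2=True`` the values are assumed linear-scale and are
    log2-transformed on read (non-positive entries become missing).
    """
    frame = pd.read_csv(path, sep="\t", index_col="probe_id", na_values=["NA"])
    vals = frame.to_numpy(dtype=float)
    mask = np.isnan(vals)
    if log2:
        nonpos = ~mask & (vals <= 0)
        mask |= nonpos
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(mask, 0.0, np.log2(np.where(mask, 1.0, vals)))
    else:
        vals = np.where(mask, 0.0, vals)
    matrix = ExpressionMatrix(
        probe_ids=frame.index.to_numpy(dtype=object),
        array_ids=frame.columns.to_numpy(dtype=object),
        values=vals,
        missing_mask=mask,
    )
    if snr_path is not None:
        matrix.snr = _read_grid_like(snr_path, matrix)
    if flag_path is not None:
        matrix.flag = _read_grid_like(flag_path, matrix)
    return matrix


def _read_grid_like(path, matrix: ExpressionMatrix) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t", index_col="probe_id", na_values=["NA"])
    if list(frame.index) != list(matrix.probe_ids) or list(frame.columns) != list(
        matrix.array_ids
    ):
        frame = frame.reindex(index=matrix.probe_ids, columns=matrix.array_ids)
        if frame.isna().all(axis=None) and matrix.n_probes > 0:
            raise BloodsigError(f"quality grid {path} does not match matrix ids")
    return frame.to_numpy(dtype=float)


def read_annotation_csv(path) -> SampleAnnotation:
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "replicate_group" in table.columns:
        table["replicate_group"] = table["replicate_group"].fillna("")
    return SampleAnnotation(table)


def read_geo_series_matrix(path, log2: bool = False) -> ExpressionMatrix:
    """Parse a GEO Series Matrix text file into an ExpressionMatrix.

    Only the expression table is read; ``!``-prefixed metadata lines are
    skipped.  Values of ``null``/``NA``/empty are treated as missing.
    """
    path = Path(path)
    header: Optional[list[str]] = None
    rows: list[list[str]] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if not in_table or not line:
                continue
            fields = [f.strip().strip('"') for f in line.split("\t")]
            if header is None:
                header = fields
            else:
                rows.append(fields)
    if header is None:
        raise BloodsigError(f"{path} contains no series matrix table")
    array_ids = header[1:]
    probe_ids = [r[0] for r in rows]
    vals = np.full((len(rows), len(array_ids)), np.nan)
    for i, r in enumerate(rows):
        for j, cell in enumerate(r[1:]):
            if cell and cell.lower() not in ("na", "null", "nan"):
                vals[i, j] = float(cell)
    mask = np.isnan(vals)
    if log2:
        nonpos = ~mask & (vals <= 0)
        mask |= nonpos
        vals = np.where(mask, 0.0, np.log2(np.where(mask, 1.0, vals)))
    return ExpressionMatrix(
        probe_ids=np.asarray(probe_ids, dtype=object),
        array_ids=np.asarray(array_ids, dtype=object),
        values=np.where(mask, 0.0, vals),
        missing_mask=mask,
    )
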