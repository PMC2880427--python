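"""Synthetic batched-microarray data generator.

Emulates the structure of a whole-blood case/control microarray study run in
processing batches: each batch holds a fixed number of study samples (half
disease cases, half healthy controls) plus technical-control arrays hybridised
from one shared reference RNA.  Probe intensities are on the log2 scale with

* a per-probe baseline level,
* a zero-mean per-probe per-batch additive shift (the batch effect),
* a subject-level biological deviation shared by replicate arrays of the
  same subject,
* fresh array-level technical noise, and
* a planted case-vs-control shift on a known subset of signal probes.

Low-quality measurements receive a signal-to-noise ratio below the masking
threshold, and a configurable fraction of entries carries a failed-spot flag,
so the quality rules of the preprocessor are exercised.  The ground truth
(which probes carry signal, and with what signed shift) is returned alongside
the data so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .containers import (
    CLASS_CASE,
    CLASS_HEALTHY,
    CLASS_TECHNICAL,
    ANNOTATION_COLUMNS,
    BloodsigError,
    ExpressionMatrix,
    SampleAnnotation,
)


class UnbalancedBatchError(BloodsigError):
    """Raised when batches cannot hold equal numbers of cases and controls."""


@dataclass
class SimConfig:
    """Study-design and noise parameters of the generator.

    Defaults reproduce the layout of the emulated study: 13 batches of 10
    study samples plus 2 technical controls (156 arrays, 130 study samples),
    with 3 subjects contributing two arrays each so that 127 distinct
    subjects remain after replicate averaging.
    """

    n_batches: int = 13
    samples_per_batch: int = 10
    controls_per_batch: int = 2
    n_probes: int = 2000
    n_signal_probes: int = 100
    effect_size: float = 0.5  # standardized mean shift, units of noise_sd
    batch_sd: float = 0.5  # sd of per-probe per-batch additive shifts
    noise_sd: float = 1.0  # within-group sd (biological + technical)
    baseline_mean: float = 8.0  # log2 scale
    baseline_sd: float = 1.5
    missing_snr_threshold: float = 3.0
    p_low_snr: float = 0.01
    p_bad_flag: float = 0.001  # fraction of entries flagged as failed spots
    n_replicate_subjects: int = 3
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_batches": self.n_batches,
            "samples_per_batch": self.samples_per_batch,
            "controls_per_batch": self.controls_per_batch,
            "n_probes": self.n_probes,
            "n_signal_probes": self.n_signal_probes,
            "n_replicate_subjects": self.n_replicate_subjects,
        }
        for name, v in counts.items():
            if v < 0:
                raise BloodsigError(f"{name} must be >= 0, got {v}")
        if self.n_signal_probes > self.n_probes:
            raise BloodsigError("n_signal_probes exceeds n_probes")
        for name in ("effect_size", "batch_sd", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise BloodsigError(f"{name} must be >= 0")
        if not 0 <= self.p_low_snr <= 1 or not 0 <= self.p_bad_flag <= 1:
            raise BloodsigError("probabilities must lie in [0, 1]")
        if self.samples_per_batch % 2 != 0:
            raise UnbalancedBatchError(
                "samples_per_batch must be even to balance cases and "
                f"controls within each batch (got {self.samples_per_batch})"
            )
        n_study = self.n_batches * self.samples_per_batch
        if self.n_replicate_subjects * 2 > n_study // 2:
            raise BloodsigError("too many replicate subjects for the design")

    @property
    def n_study_arrays(self) -> int:
        return self.n_batches * self.samples_per_batch

    @property
    def n_arrays(self) -> int:
        return self.n_batches * (self.samples_per_batch + self.controls_per_batch)


@dataclass
class SimTruth:
    """Ground truth of the planted signal."""

    signal_probe_ids: np.ndarray
    signed_effects: np.ndarray  # case minus control shift, log2 units

    def __post_init__(self) -> None:
        self.signal_probe_ids = np.asarray(self.signal_probe_ids, dtype=object)
        self.signed_effects = np.asarray(self.signed_effects, dtype=float)
        if len(self.signal_probe_ids) != len(self.signed_effects):
            raise BloodsigError("truth arrays length mismatch")


def generate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, SimTruth]:
    """Generate one synthetic dataset with annotation and ground truth.

    The per-probe batch shifts are centered across batches, so the grand mean
    of every probe is exactly invariant to ``batch_sd``.  Within-group
    variance splits evenly between a subject-level deviation (shared by
    replicate arrays of one subject) and array-level technical noise, giving
    replicate arrays a correlation of 0.5 on null probes.  All randomness is
    drawn from independent child streams of ``config.seed``, so changing one
    parameter does not reshuffle unrelated draws.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (
        rng_base,
        rng_batch,
        rng_subj,
        rng_noise,
        rng_sign,
        rng_snr,
        rng_flag,
        rng_ref,
    ) = [np.random.default_rng(s) for s in ss.spawn(8)]

    P = config.n_probes
    half = config.samples_per_batch // 2
    n_study = config.n_study_arrays
    n_arrays = config.n_arrays

    probe_ids = np.array([f"probe_{i:05d}" for i in range(P)], dtype=object)

    # --- design: subjects, classes, batches, replicates ---------------------
    # Per batch: `half` cases then `half` healthy controls then the
    # technical controls; order within the file is batch by batch.
    records = []  # (array_id, subject_id, batch_id, class_label, rep_group)
    subject_of_array = []  # subject index per study array, -1 for controls
    class_code = []  # +1 case, -1 healthy, 0 technical control

    next_subject = 0
    # Replicate subjects are healthy controls; subject r occupies one healthy
    # slot in batches r and r+1 (distinct slots on collision), mimicking
    # repeat draws from the same woman at different processing dates.
    rep_assignment: dict[tuple[int, int], int] = {}
    for r in range(config.n_replicate_subjects):
        b0 = r % max(config.n_batches - 1, 1)
        slot = 0
        while (b0, slot) in rep_assignment or (b0 + 1, slot) in rep_assignment:
            slot += 1
            if slot >= half:
                raise BloodsigError("cannot place replicate subjects")
        rep_assignment[(b0, slot)] = r
        rep_assignment[(b0 + 1, slot)] = r

    rep_subject_index: dict[int, int] = {}
    a = 0
    for b in range(config.n_batches):
        batch_id = f"batch_{b + 1:02d}"
        for s in range(half):  # cases
            array_id = f"array_{a + 1:03d}"
            subj = next_subject
            next_subject += 1
            records.append(
                (array_id, f"subject_{subj + 1:03d}", batch_id, CLASS_CASE, "")
            )
            subject_of_array.append(subj)
            class_code.append(1)
            a += 1
        for s in range(half):  # healthy controls
            array_id = f"array_{a + 1:03d}"
            key = (b, s)
            if key in rep_assignment:
                r = rep_assignment[key]
                if r in rep_subject_index:
                    subj = rep_subject_index[r]
                else:
                    subj = next_subject
                    next_subject += 1
                    rep_subject_index[r] = subj
                rep_group = f"rep_{r + 1:02d}"
            else:
                subj = next_subject
                next_subject += 1
                rep_group = ""
            records.append(
                (
                    array_id,
                    f"subject_{subj + 1:03d}",
                    batch_id,
                    CLASS_HEALTHY,
                    rep_group,
                )
            )
            subject_of_array.append(subj)
            class_code.append(-1)
            a += 1
        for c in range(config.controls_per_batch):
            array_id = f"array_{a + 1:03d}"
            records.append(
                (array_id, "reference", batch_id, CLASS_TECHNICAL, "")
            )
            subject_of_array.append(-1)
            class_code.append(0)
            a += 1
    assert a == n_arrays
    total_subjects = next_subject

    annot = SampleAnnotation(
        pd.DataFrame(records, columns=ANNOTATION_COLUMNS)
    )
    array_ids = annot.table["array_id"].to_numpy(dtype=object)
    batch_index = np.repeat(
        np.arange(config.n_batches),
        config.samples_per_batch + config.controls_per_batch,
    )
    class_code = np.asarray(class_code)
    subject_of_array = np.asarray(subject_of_array)

    # --- probe-level components --------------------------------------------
    baseline = rng_base.normal(config.baseline_mean, config.baseline_sd, size=P)

    raw_shift = rng_batch.standard_normal((P, config.n_batches))
    raw_shift -= raw_shift.mean(axis=1, keepdims=True)  # exactly zero-mean
    batch_shift = raw_shift * config.batch_sd

    signal_idx = np.arange(config.n_signal_probes)
    signs = rng_sign.choice([-1.0, 1.0], size=config.n_signal_probes)
    signed_effects = signs * config.effect_size * config.noise_sd
    effect_col = np.zeros(P)
    effect_col[signal_idx] = signed_effects

    comp_sd = config.noise_sd / np.sqrt(2.0)
    subj_dev = rng_subj.normal(0.0, comp_sd, size=(P, total_subjects))
    ref_profile = baseline + rng_ref.normal(0.0, comp_sd, size=P)
    tech_noise = rng_noise.normal(0.0, comp_sd, size=(P, n_arrays))

    values = np.empty((P, n_arrays))
    study = class_code != 0
    values[:, study] = (
        baseline[:, None]
        + subj_dev[:, subject_of_array[study]]
        + np.where(class_code[study] == 1, 1.0, 0.0)[None, :] * effect_col[:, None]
    )
    values[:, ~study] = ref_profile[:, None]
    values += batch_shift[:, batch_index]
    values += tech_noise

    # --- quality grids ------------------------------------------------------
    low = rng_snr.random((P, n_arrays)) < config.p_low_snr
    snr = rng_snr.uniform(10.0, 50.0, size=(P, n_arrays))
    snr[low] = rng_snr.uniform(
        0.0, config.missing_snr_threshold, size=int(low.sum())
    )
    flag = np.zeros((P, n_arrays))
    flag[rng_flag.random((P, n_arrays)) < config.p_bad_flag] = 9000.0

    matrix = ExpressionMatrix(
        probe_ids=probe_ids,
        array_ids=array_ids,
        values=values,
        snr=snr,
        flag=flag,
    )
    truth = SimTruth(
        signal_probe_ids=probe_ids[signal_idx], signed_effects=signed_effects
    )
    return matrix, annot, truth


def simulate_plain(
    n_samples: int,
    n_probes: int,
    n_signal: int = 0,
    effect: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batch-free classification instance for the classifier studies.

    Returns a standard-normal samples x probes matrix ``X`` (unit
    within-group sd), a balanced -1/+1 response ``y``, and the indices of
    the ``n_signal`` planted probes, whose case-vs-control mean difference
    is ``effect`` (in sd units) with random sign per probe.
    """
    if n_samples % 2 != 0:
        raise BloodsigError("n_samples must be even for a balanced design")
    if n_signal > n_probes:
        raise BloodsigError("n_signal exceeds n_probes")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_samples, n_probes))
    y = np.array([1.0] * (n_samples // 2) + [-1.0] * (n_samples // 2))
    signal_idx = np.arange(n_signal)
    if n_signal:
        signs = rng.choice([-1.0, 1.0], size=n_signal)
        # split the shift symmetrically so probe means stay near zero
        X[np.ix_(y == 1, signal_idx)] += 0.5 * effect * signs
        X[np.ix_(y == -1, signal_idx)] -= 0.5 * effect * signs
    return X, y, signal_idx


# --------------------------------------------------------------------------
# on-disk round trip
# --------------------------------------------------------------------------

def write_dataset(
    matrix: ExpressionMatrix,
    annot: SampleAnnotation,
    dir_path,
) -> dict[str, Path]:
    """Write matrix TSV, annotation CSV and SNR/flag TSVs to a directory.

    Missing entries are written as ``NA``.  The files round-trip losslessly
    through :func:`bloodsig.io.read_matrix_tsv` /
    :func:`bloodsig.io.read_annotation_csv`.
    """
    from .io import write_matrix_tsv  # local import to avoid cycle

    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": dir_path / "matrix.tsv",
        "annotation": dir_path / "annotation.csv",
    }
    write_matrix_tsv(matrix, paths["matrix"])
    annot.table.to_csv(paths["annotation"], index=False)
    if matrix.snr is not None:
        paths["snr"] = dir_path / "snr.tsv"
        _write_grid(matrix.probe_ids, matrix.array_ids, matrix.snr, paths["snr"])
    if matrix.flag is not None:
        paths["flag"] = dir_path / "flag.tsv"
        _write_grid(
            matrix.probe_ids, matrix.array_ids, matrix.flag, paths["flag"]
        )
    return paths


def _write_grid(probe_ids, array_ids, grid, path) -> None:
    pd.DataFrame(grid, index=probe_ids, columns=array_ids).to_csv(
        path, sep="\t", index_label="probe_id", na_rep="NA"
    )
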