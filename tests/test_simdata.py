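"""Generator contracts: layout, determinism, planted signal, batch structure."""

import numpy as np
import pytest
from scipy import stats

from bloodsig.containers import CLASS_CASE, CLASS_HEALTHY, CLASS_TECHNICAL
from bloodsig.io import read_annotation_csv, read_matrix_tsv
from bloodsig.simdata import (
    SimConfig,
    UnbalancedBatchError,
    generate_dataset,
    simulate_plain,
    write_dataset,
)


class TestLayout:
    def test_default_design_counts(self, default_sim):
        cfg, matrix, annot, truth = default_sim
        assert matrix.n_arrays == 13 * 12 == 156
        counts = annot.table["class_label"].value_counts()
        assert counts[CLASS_TECHNICAL] == 26
        assert counts[CLASS_CASE] + counts[CLASS_HEALTHY] == 130
        # 3 replicate subjects -> 127 distinct study subjects
        study = annot.table[annot.table["class_label"] != CLASS_TECHNICAL]
        assert study["subject_id"].nunique() == 127

    def test_batches_balanced(self, default_sim):
        _, _, annot, _ = default_sim
        per_batch = annot.table.groupby("batch_id")["class_label"].value_counts()
        for b in annot.table["batch_id"].unique():
            assert per_batch[b][CLASS_CASE] == per_batch[b][CLASS_HEALTHY] == 5
            assert per_batch[b][CLASS_TECHNICAL] == 2

    def test_odd_batch_size_rejected(self):
        with pytest.raises(UnbalancedBatchError):
            generate_dataset(
                SimConfig(samples_per_batch=5, n_probes=10, n_signal_probes=0)
            )

    def test_replicate_groups_consistent(self, default_sim):
        _, _, annot, _ = default_sim
        reps = annot.table[annot.table["replicate_group"] != ""]
        sizes = reps.groupby("replicate_group")["array_id"].count()
        assert (sizes == 2).all()
        # one subject per group, identical class within
        per = reps.groupby("replicate_group")
        assert (per["subject_id"].nunique() == 1).all()
        assert (per["class_label"].nunique() == 1).all()


class TestStatisticalStructure:
    def test_seeded_determinism(self, small_sim):
        cfg, matrix, annot, truth = small_sim
        m2, a2, t2 = generate_dataset(cfg)
        assert np.array_equal(matrix.values, m2.values)
        assert np.array_equal(matrix.snr, m2.snr)
        assert np.array_equal(matrix.flag, m2.flag)
        assert annot.table.equals(a2.table)

    def test_null_effect_has_no_mean_shift(self):
        cfg = SimConfig(
            n_batches=4,
            samples_per_batch=10,
            controls_per_batch=0,
            n_probes=300,
            n_signal_probes=30,
            effect_size=0.0,
            batch_sd=0.0,
            n_replicate_subjects=0,
            seed=3,
        )
        matrix, annot, _ = generate_dataset(cfg)
        labels = annot.aligned_to(matrix.array_ids)["class_label"].to_numpy()
        case = matrix.values[:, labels == CLASS_CASE]
        heal = matrix.values[:, labels == CLASS_HEALTHY]
        diff = case.mean(axis=1) - heal.mean(axis=1)
        se = np.sqrt(
            case.var(axis=1, ddof=1) / case.shape[1]
            + heal.var(axis=1, ddof=1) / heal.shape[1]
        )
        assert (np.abs(diff) <= 3 * se).mean() > 0.98

    def test_planted_effect_recovery(self):
        """Large effect, no batch shift: t-tests find the planted probes."""
        cfg = SimConfig(
            n_batches=6,
            samples_per_batch=20,
            controls_per_batch=0,
            n_probes=1000,
            n_signal_probes=50,
            effect_size=2.0,
            batch_sd=0.0,
            n_replicate_subjects=0,
            seed=5,
        )
        matrix, annot, truth = generate_dataset(cfg)
        labels = annot.aligned_to(matrix.array_ids)["class_label"].to_numpy()
        case = matrix.values[:, labels == CLASS_CASE]
        heal = matrix.values[:, labels == CLASS_HEALTHY]
        p = stats.ttest_ind(case, heal, axis=1).pvalue
        hit = p < 0.05 / cfg.n_probes
        planted = np.isin(matrix.probe_ids, truth.signal_probe_ids)
        assert hit[planted].mean() >= 0.90
        assert hit[~planted].sum() <= 1  # <= 1 false positive per 950 nulls

    def test_grand_mean_invariant_to_batch_sd(self):
        base = dict(
            n_batches=5,
            samples_per_batch=4,
            controls_per_batch=1,
            n_probes=200,
            n_signal_probes=0,
            n_replicate_subjects=0,
            seed=9,
        )
        m0, _, _ = generate_dataset(SimConfig(batch_sd=0.0, **base))
        m1, _, _ = generate_dataset(SimConfig(batch_sd=2.0, **base))
        gm0 = m0.values.mean(axis=1)
        gm1 = m1.values.mean(axis=1)
        assert np.abs(gm0 - gm1).max() < 0.02

    def test_technical_controls_correlate_within_batch(self, default_sim):
        cfg, matrix, annot, _ = default_sim
        tab = annot.aligned_to(matrix.array_ids)
        for b in ["batch_01", "batch_07"]:
            in_b = tab["batch_id"].to_numpy() == b
            is_tc = tab["class_label"].to_numpy() == CLASS_TECHNICAL
            tc = np.flatnonzero(in_b & is_tc)
            study = np.flatnonzero(in_b & ~is_tc)
            cc = np.corrcoef(matrix.values[:, tc[0]], matrix.values[:, tc[1]])[0, 1]
            cs = np.mean(
                [
                    np.corrcoef(matrix.values[:, tc[0]], matrix.values[:, j])[0, 1]
                    for j in study
                ]
            )
            assert cc > cs

    def test_low_quality_entries_under_threshold(self, small_sim):
        cfg, matrix, _, _ = small_sim
        low = matrix.snr < cfg.missing_snr_threshold
        assert low.any()  # p_low_snr > 0 in the fixture
        assert (matrix.flag > 8191).any()

    def test_simulate_plain_effect_and_balance(self):
        X, y, sig = simulate_plain(40, 100, n_signal=10, effect=2.0, seed=0)
        assert (y == 1).sum() == (y == -1).sum() == 20
        diff = np.abs(X[y == 1].mean(0) - X[y == -1].mean(0))
        assert diff[sig].mean() > 1.0  # planted shift visible
        assert diff[10:].mean() < 0.5


class TestRoundTrip:
    def test_write_then_read_identity(self, small_sim, tmp_path):
        _, matrix, annot, _ = small_sim
        m = matrix.copy()
        m.missing_mask[0, 0] = True  # exercise NA round trip
        paths = write_dataset(m, annot, tmp_path)
        m2 = read_matrix_tsv(paths["matrix"], paths["snr"], paths["flag"])
        a2 = read_annotation_csv(paths["annotation"])
        assert list(m2.probe_ids) == list(m.probe_ids)
        assert list(m2.array_ids) == list(m.array_ids)
        obs = ~m.missing_mask
        assert np.allclose(m2.values[obs], m.values[obs])
        assert np.array_equal(m2.missing_mask, m.missing_mask)
        assert np.allclose(m2.snr, m.snr)
        assert a2.table.equals(annot.table)

    def test_empty_matrix_roundtrip(self, tmp_path):
        from bloodsig.containers import ExpressionMatrix, SampleAnnotation
        import pandas as pd

        empty = ExpressionMatrix(
            probe_ids=np.array([], dtype=object),
            array_ids=np.array(["a1", "a2"], dtype=object),
            values=np.empty((0, 2)),
        )
        annot = SampleAnnotation(
            pd.DataFrame(
                {
                    "array_id": ["a1", "a2"],
                    "subject_id": ["s1", "s2"],
                    "batch_id": ["b1", "b1"],
                    "class_label": ["case", "control_healthy"],
                    "replicate_group": ["", ""],
                }
            )
        )
        paths = write_dataset(empty, annot, tmp_path)
        m2 = read_matrix_tsv(paths["matrix"])
        assert m2.shape == (0, 2)

    def test_small_fixture_file_shape(self, tmp_path):
        from bloodsig.containers import ExpressionMatrix, SampleAnnotation
        import pandas as pd

        m = ExpressionMatrix(
            probe_ids=np.array(["p1", "p2", "p3"], dtype=object),
            array_ids=np.array(["a1", "a2"], dtype=object),
            values=np.arange(6.0).reshape(3, 2),
        )
        annot = SampleAnnotation(
            pd.DataFrame(
                {
                    "array_id": ["a1", "a2"],
                    "subject_id": ["s1", "s2"],
                    "batch_id": ["b1", "b1"],
                    "class_label": ["case", "control_healthy"],
                    "replicate_group": ["", ""],
                }
            )
        )
        paths = write_dataset(m, annot, tmp_path)
        lines = paths["matrix"].read_text().strip().splitlines()
        assert len(lines) == 4  # header + 3 probes
        assert lines[0].split("\t") == ["probe_id", "a1", "a2"]
        assert all(len(l.split("\t")) == 3 for l in lines[1:])
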