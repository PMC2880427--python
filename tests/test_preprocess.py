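"""Preprocessing stage contracts and the end-to-end chain."""

import numpy as np
import pandas as pd
import pytest

from bloodsig.containers import BloodsigError, ExpressionMatrix, SampleAnnotation
from bloodsig.preprocess import (
    PreprocessParams,
    batch_adjust,
    collapse_replicates,
    drop_technical_controls,
    filter_probes,
    global_mean_subtract,
    knn_impute,
    mask_low_quality,
    preprocess_pipeline,
    standardize,
)


def make_matrix(values, snr=None, flag=None, mask=None):
    values = np.asarray(values, dtype=float)
    p, a = values.shape
    return ExpressionMatrix(
        probe_ids=np.array([f"p{i}" for i in range(p)], dtype=object),
        array_ids=np.array([f"a{j}" for j in range(a)], dtype=object),
        values=values,
        missing_mask=mask,
        snr=snr,
        flag=flag,
    )


def make_annot(batches, classes=None, subjects=None):
    n = len(batches)
    return SampleAnnotation(
        pd.DataFrame(
            {
                "array_id": [f"a{j}" for j in range(n)],
                "subject_id": subjects or [f"s{j}" for j in range(n)],
                "batch_id": batches,
                "class_label": classes or ["case"] * (n // 2) + ["control_healthy"] * (n - n // 2),
                "replicate_group": [""] * n,
            }
        )
    )


class TestMasking:
    @pytest.mark.parametrize(
        "snr,flag,masked",
        [
            (2.9, 0, True),  # SNR below threshold
            (3.0, 8191, False),  # both thresholds are strict
            (10, 9000, True),  # failed-spot flag
            (10, 100, False),
        ],
    )
    def test_threshold_rules(self, snr, flag, masked):
        m = make_matrix([[1.0]], snr=[[snr]], flag=[[flag]])
        out = mask_low_quality(m)
        assert bool(out.missing_mask[0, 0]) is masked

    def test_flag_grid_counts(self):
        m = make_matrix(
            [[1.0, 2.0], [3.0, 4.0]],
            snr=np.full((2, 2), 10.0),
            flag=[[0, 9000], [100, 8191]],
        )
        out = mask_low_quality(m)
        assert out.missing_mask.sum() == 1
        assert out.missing_mask[0, 1]

    def test_missing_quality_grids_error(self):
        m = make_matrix([[1.0]])
        with pytest.raises(BloodsigError, match="quality"):
            mask_low_quality(m)


class TestProbeFilter:
    def test_five_percent_boundary_of_156(self):
        # 8/156 = 5.13% excluded, 7/156 = 4.49% retained
        vals = np.zeros((2, 156))
        mask = np.zeros((2, 156), dtype=bool)
        mask[0, :8] = True
        mask[1, :7] = True
        out = filter_probes(make_matrix(vals, mask=mask))
        assert list(out.probe_ids) == ["p1"]

    def test_fully_observed_retained_and_order_preserved(self):
        vals = np.zeros((3, 10))
        mask = np.zeros((3, 10), dtype=bool)
        mask[1] = True
        out = filter_probes(make_matrix(vals, mask=mask), PreprocessParams())
        assert list(out.probe_ids) == ["p0", "p2"]


class TestStandardize:
    def test_hand_example(self):
        out = standardize(make_matrix([[1.0, 2.0, 3.0]]))
        assert np.allclose(out.values, [[-1.0, 0.0, 1.0]])

    def test_idempotent(self, rng):
        m = make_matrix(rng.standard_normal((5, 8)))
        once = standardize(m)
        twice = standardize(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_constant_row_errors_with_probe_name(self):
        with pytest.raises(BloodsigError, match="p0"):
            standardize(make_matrix([[2.0, 2.0, 2.0]]))

    def test_moments_use_observed_entries_only(self):
        mask = np.array([[False, False, False, True]])
        out = standardize(make_matrix([[1.0, 2.0, 3.0, 99.0]], mask=mask))
        assert np.allclose(out.values[0, :3], [-1.0, 0.0, 1.0])


class TestKnnImpute:
    def test_agreeing_neighbors(self, rng):
        base = rng.standard_normal(6)
        vals = np.tile(base, (12, 1))
        vals[11] = base  # target identical to the others
        mask = np.zeros((12, 6), dtype=bool)
        mask[11, 2] = True
        out = knn_impute(make_matrix(vals, mask=mask))
        assert np.isclose(out.values[11, 2], base[2])
        assert not out.missing_mask.any()

    def test_k1_matches_nearest_complete_neighbor(self, rng):
        vals = rng.standard_normal((8, 6))
        vals[0] = vals[3] + 0.01 * rng.standard_normal(6)  # probe 3 nearest
        mask = np.zeros((8, 6), dtype=bool)
        mask[0, 4] = True
        out = knn_impute(make_matrix(vals, mask=mask), PreprocessParams(knn_k=1))
        # exhaustive scan oracle
        target = vals[0].copy()
        best, bestd = None, np.inf
        for i in range(1, 8):
            shared = [j for j in range(6) if j != 4]
            d = np.sqrt(np.mean((target[shared] - vals[i][shared]) ** 2))
            if d < bestd:
                best, bestd = i, d
        assert best == 3
        assert np.isclose(out.values[0, 4], vals[3, 4])

    def test_matches_bruteforce_oracle(self, rng):
        """Weighted-mean imputation equals an exhaustive neighbour search."""
        p, a, k = 40, 15, 10
        vals = rng.standard_normal((p, a))
        mask = rng.random((p, a)) < 0.08
        mask[:, 0] = False  # keep every probe observed somewhere
        m = make_matrix(vals, mask=mask)
        out = knn_impute(m, PreprocessParams(knn_k=k))

        obs = ~mask
        for i, j in zip(*np.nonzero(mask)):
            cands = []
            for other in range(p):
                if other == i or not obs[other, j]:
                    continue
                shared = obs[i] & obs[other]
                if not shared.any():
                    continue
                d = np.sqrt(np.mean((vals[i, shared] - vals[other, shared]) ** 2))
                cands.append((d, other))
            cands.sort()
            cands = cands[:k]
            w = np.array([1.0 / (d + 1e-6) for d, _ in cands])
            v = np.array([vals[o, j] for _, o in cands])
            assert np.isclose(out.values[i, j], np.dot(w, v) / w.sum())

    def test_zero_eligible_falls_back_to_probe_mean(self):
        vals = np.array([[1.0, 3.0, 5.0], [0.0, 0.0, 1.0]])
        mask = np.array([[False, False, True], [False, False, True]])
        out = knn_impute(make_matrix(vals, mask=mask))
        # no probe is observed at array 2 except none -> probe mean fallback
        assert np.isclose(out.values[0, 2], 2.0)


class TestBatchAdjust:
    def test_hand_example(self):
        m = make_matrix([[4.0, 6.0, 6.0, 8.0]])
        annot = make_annot(["b1", "b1", "b2", "b2"])
        out = batch_adjust(m, annot)
        assert np.allclose(out.values, [[-1.0, 1.0, -1.0, 1.0]])

    def test_single_batch_equals_centering(self, rng):
        vals = rng.standard_normal((4, 6))
        m = make_matrix(vals)
        out = batch_adjust(m, make_annot(["b1"] * 6))
        assert np.allclose(out.values, vals - vals.mean(axis=1, keepdims=True))

    def test_invariant_to_batch_shift(self, rng):
        vals = rng.standard_normal((3, 6))
        batches = ["b1", "b1", "b1", "b2", "b2", "b2"]
        out1 = batch_adjust(make_matrix(vals), make_annot(batches))
        shifted = vals.copy()
        shifted[:, 3:] += 7.5
        out2 = batch_adjust(make_matrix(shifted), make_annot(batches))
        assert np.allclose(out1.values, out2.values)

    def test_singleton_batch_errors(self, rng):
        m = make_matrix(rng.standard_normal((2, 3)))
        with pytest.raises(BloodsigError, match="single"):
            batch_adjust(m, make_annot(["b1", "b1", "b2"]))


class TestArrayReduction:
    def test_drop_technical_controls(self, rng):
        m = make_matrix(rng.standard_normal((2, 4)))
        annot = make_annot(
            ["b1"] * 4,
            classes=["case", "control_healthy", "technical_control", "technical_control"],
        )
        out, ann = drop_technical_controls(m, annot)
        assert out.n_arrays == 2
        assert not ann.is_technical_control.any()

    def test_collapse_replicates_mean_and_identity(self):
        m = make_matrix([[1.0, 3.0, 5.0]])
        annot = make_annot(
            ["b1"] * 3,
            classes=["case", "case", "control_healthy"],
            subjects=["s1", "s1", "s2"],
        )
        out, ann = collapse_replicates(m, annot)
        assert out.n_arrays == 2
        assert np.allclose(out.values, [[2.0, 5.0]])
        # no replicates -> identity
        m2 = make_matrix([[1.0, 2.0]])
        out2, _ = collapse_replicates(m2, make_annot(["b1", "b1"]))
        assert np.allclose(out2.values, m2.values)

    def test_conflicting_labels_error(self):
        m = make_matrix([[1.0, 2.0]])
        annot = make_annot(
            ["b1", "b1"],
            classes=["case", "control_healthy"],
            subjects=["s1", "s1"],
        )
        with pytest.raises(BloodsigError, match="conflicting"):
            collapse_replicates(m, annot)


class TestGlobalMeanSubtract:
    def test_column_means_zero_and_idempotent(self, rng):
        m = make_matrix(rng.standard_normal((7, 4)) + 3.0)
        out = global_mean_subtract(m)
        assert np.abs(out.values.mean(axis=0)).max() < 1e-12
        again = global_mean_subtract(out)
        assert np.allclose(out.values, again.values)


class TestPipeline:
    def test_default_sim_bookkeeping(self, default_sim):
        """156 arrays in -> 130 after control drop -> 127 after averaging."""
        _, matrix, annot, _ = default_sim
        out, ann, report = preprocess_pipeline(matrix, annot)
        assert report.n_arrays_in == 156
        assert report.n_arrays_out == 127
        steps = {s["step"]: s for s in report.steps}
        assert steps["drop_technical_controls"]["n_arrays"] == 130
        assert not out.missing_mask.any()
        assert not ann.is_technical_control.any()
        assert np.abs(out.values.mean(axis=0)).max() < 1e-10

    def test_batch_variance_share_drops_under_null(self):
        """Batch mean-centering removes between-batch structure."""
        from bloodsig.simdata import SimConfig, generate_dataset

        cfg = SimConfig(
            n_batches=4,
            samples_per_batch=8,
            controls_per_batch=0,
            n_probes=150,
            n_signal_probes=0,
            effect_size=0.0,
            batch_sd=1.0,
            n_replicate_subjects=0,
            seed=21,
        )
        matrix, annot, _ = generate_dataset(cfg)
        batches = annot.aligned_to(matrix.array_ids)["batch_id"].to_numpy()

        def between_share(vals):
            grand = vals.mean(axis=1, keepdims=True)
            tot = ((vals - grand) ** 2).sum()
            between = 0.0
            for b in np.unique(batches):
                cols = batches == b
                bm = vals[:, cols].mean(axis=1, keepdims=True)
                between += cols.sum() * ((bm - grand) ** 2).sum()
            return between / tot

        m = standardize(matrix)
        before = between_share(m.values)
        after = between_share(batch_adjust(m, annot).values)
        assert after < before

    def test_zero_missing_tolerance(self, small_sim):
        _, matrix, annot, _ = small_sim
        params = PreprocessParams(max_missing_frac=0.0)
        out, _, report = preprocess_pipeline(matrix, annot, params)
        fully_obs = ~(
            (matrix.snr < params.snr_min) | (matrix.flag > params.flag_max)
        ).any(axis=1)
        assert report.steps[1]["n_probes"] == int(fully_obs.sum())
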