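"""ROI feedback: activation mapping, voxel selection, weighted baseline, PSC."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nfbsim as nfb
from nfbsim.design import Condition, label_volumes
from nfbsim.roi import (
    BaselineBuffer,
    RoiDefinition,
    compute_activation_stat,
    compute_psc_feedback,
    select_top_voxels,
    sigmoid_weights,
    train_roi_model,
    update_baseline,
    weighted_baseline_mean,
)


def _buffer(values):
    buf = BaselineBuffer()
    for v in values:
        buf.append(v)
    return buf


class TestWeightedBaseline:
    def test_single_volume_returns_it(self):
        assert weighted_baseline_mean(_buffer([104.5])) == 104.5

    def test_equal_values_any_weights(self):
        assert weighted_baseline_mean(_buffer([100.0] * 7)) == pytest.approx(100.0)

    def test_matches_brute_force(self):
        """m = sum(sig(k) x_k) / sum(sig(k)), hand-computed."""
        x = [100.0, 102.0, 104.0]
        w = [1 / (1 + np.exp(-(k - 1.5))) for k in (1, 2, 3)]
        expected = sum(wi * xi for wi, xi in zip(w, x)) / sum(w)
        assert weighted_baseline_mean(_buffer(x)) == pytest.approx(expected, abs=1e-12)

    def test_sigmoid_downweights_early_volumes(self):
        w = sigmoid_weights(15)
        assert np.all(np.diff(w) > 0)
        assert w[0] < w[-1]

    def test_empty_buffer_rejected(self):
        with pytest.raises(ValueError):
            weighted_baseline_mean(BaselineBuffer())


class TestPscFeedback:
    def test_current_equals_baseline_gives_zero(self):
        assert compute_psc_feedback(100.0, _buffer([100.0] * 5)) == pytest.approx(0.0, abs=1e-12)

    def test_one_percent(self):
        assert compute_psc_feedback(101.0, _buffer([100.0] * 5)) == pytest.approx(0.01)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            compute_psc_feedback(1.0, _buffer([0.0, 0.0]))

    @given(st.floats(min_value=50.0, max_value=200.0))
    def test_monotone_in_current_mean(self, curr):
        buf = _buffer([100.0, 101.0, 99.0])
        f1 = compute_psc_feedback(curr, buf)
        f2 = compute_psc_feedback(curr + 1.0, buf)
        assert f2 > f1

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_scale_invariance(self, c):
        """Multiplying all intensities by c > 0 leaves PSC unchanged."""
        base = [100.0, 102.0, 98.0]
        f1 = compute_psc_feedback(105.0, _buffer(base))
        f2 = compute_psc_feedback(105.0 * c, _buffer([x * c for x in base]))
        assert f2 == pytest.approx(f1, rel=1e-9)


class TestBaselineBuffer:
    def test_update_appends_selected_voxel_mean(self):
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[0, 0, 0] = mask[0, 1, 0] = True
        roi = RoiDefinition("r", mask, Condition.TENDERNESS)
        model = nfb.TrainedRoiModel(roi, np.array([0, 1]), 1.0, np.zeros((2, 2, 1)))
        vol = np.full((2, 2, 1), 100.0)
        buf = BaselineBuffer()
        update_baseline(buf, vol, model)
        assert buf.B == 1 and buf.roi_means == [100.0]

    def test_full_neutral_block_gives_B_15(self):
        buf = BaselineBuffer()
        for _ in range(15):  # 30 s at TR 2
            buf.append(100.0)
        assert buf.B == 15

    def test_update_outside_neutral_rejected(self):
        with pytest.raises(ValueError):
            update_baseline(BaselineBuffer(), np.zeros((1, 1, 1)), None, "tenderness")

    def test_reset(self):
        buf = _buffer([1.0, 2.0])
        buf.reset()
        assert buf.B == 0


class TestSelection:
    def test_count_is_ceil_fraction(self):
        stat = np.arange(1000, dtype=float).reshape(10, 10, 10)
        mask = np.ones((10, 10, 10), dtype=bool)
        assert select_top_voxels(stat, mask, 0.10).size == 100
        assert select_top_voxels(stat, mask, 0.0015).size == 2  # ceil(1.5)

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(0)
        stat = rng.normal(size=(6, 5, 4))
        mask = rng.random((6, 5, 4)) > 0.3
        sel = select_top_voxels(stat, mask, 0.25)
        idx = np.flatnonzero(mask.ravel())
        order = sorted(idx, key=lambda i: (-stat.ravel()[i], i))
        expected = np.sort(order[: int(np.ceil(0.25 * idx.size))])
        assert np.array_equal(sel, expected)

    def test_ties_break_to_lowest_index(self):
        stat = np.zeros((3, 3, 1))
        mask = np.ones((3, 3, 1), dtype=bool)
        assert np.array_equal(select_top_voxels(stat, mask, 0.5), np.arange(5))

    def test_nan_stats_sort_last(self):
        stat = np.array([np.nan, 1.0, 2.0, np.nan]).reshape(4, 1, 1)
        mask = np.ones((4, 1, 1), dtype=bool)
        assert np.array_equal(select_top_voxels(stat, mask, 0.5), np.array([1, 2]))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            select_top_voxels(np.zeros((2, 2, 1)), np.zeros((2, 2, 1), dtype=bool), 0.1)


class TestActivationStat:
    def test_constant_data_gives_zero(self, roi_design):
        sched = roi_design.runs[0]
        labels = label_volumes(sched, 0)
        vols = np.full((4, 4, 2, sched.n_volumes), 500.0)
        mask = np.ones((4, 4, 2), dtype=bool)
        stat = compute_activation_stat(vols, labels, RoiDefinition("r", mask, "tenderness"))
        assert np.all(stat == 0.0)

    def test_noise_free_phantom_recovers_effect(self, noiseless_roi_session):
        """Planted 2% voxels score ~0.02; unplanted ROI voxels ~0."""
        sess = noiseless_roi_session
        run = sess.runs[0]
        labels = label_volumes(run.schedule, 2)
        roi = nfb.default_rois(sess.roi_masks)[Condition.TENDERNESS]
        stat = compute_activation_stat(run.nfb_volumes, labels, roi)
        planted = sess.ground_truth.planted_effects[0].voxels
        in_roi = np.flatnonzero(roi.mask.ravel())
        unplanted = np.setdiff1d(in_roi, planted)
        assert np.nanmean(stat.ravel()[planted]) == pytest.approx(0.02, abs=0.004)
        assert np.abs(stat.ravel()[unplanted]).max() < 0.002

    def test_equals_per_block_recomputation(self, noiseless_roi_session):
        """The 4-block average equals an independent per-block brute force."""
        sess = noiseless_roi_session
        run = sess.runs[0]
        sched = run.schedule
        labels = label_volumes(sched, 2)
        roi = nfb.default_rois(sess.roi_masks)[Condition.ANGUISH]
        stat = compute_activation_stat(run.nfb_volumes, labels, roi)

        # brute force: scan label runs manually
        flat = run.nfb_volumes.reshape(-1, sched.n_volumes)
        v = int(sess.ground_truth.planted_effects[1].voxels[0])
        blocks, cur, start = [], labels[0], 0
        for i, lab in enumerate(labels + ["sentinel"]):
            if lab != cur:
                blocks.append((cur, start, i))
                cur, start = lab, i
        vals = []
        for j, (lab, s, e) in enumerate(blocks):
            if lab == "anguish":
                prev = next(
                    (s2, e2) for lab2, s2, e2 in reversed(blocks[:j]) if lab2 == "neutral"
                )
                neut = flat[v, prev[0] : prev[1]].mean()
                vals.append((flat[v, s:e].mean() - neut) / neut)
        assert len(vals) == 4
        assert stat.ravel()[v] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_zero_neutral_mean_excluded_with_warning(self, roi_design):
        sched = roi_design.runs[0]
        labels = label_volumes(sched, 0)
        vols = np.full((2, 2, 1, sched.n_volumes), 100.0)
        vols[0, 0, 0, :] = 0.0
        mask = np.ones((2, 2, 1), dtype=bool)
        with pytest.warns(RuntimeWarning):
            stat = compute_activation_stat(vols, labels, RoiDefinition("r", mask, "tenderness"))
        assert np.isnan(stat[0, 0, 0])
        assert np.all(stat.ravel()[1:] == 0.0)


def test_trained_model_selects_planted_voxels_noise_free(noiseless_roi_session):
    sess = noiseless_roi_session
    run = sess.runs[0]
    labels = label_volumes(run.schedule, 2)
    roi = nfb.default_rois(sess.roi_masks)[Condition.TENDERNESS]
    model = train_roi_model(run.nfb_volumes, labels, roi, 0.10)
    assert model.selected_voxels.size == 100
    planted = set(sess.ground_truth.planted_effects[0].voxels.tolist())
    assert set(model.selected_voxels.tolist()) == planted


def test_model_serialization(tmp_path, noiseless_roi_session):
    sess = noiseless_roi_session
    run = sess.runs[0]
    labels = label_volumes(run.schedule, 2)
    roi = nfb.default_rois(sess.roi_masks)[Condition.TENDERNESS]
    model = train_roi_model(run.nfb_volumes, labels, roi)
    nfb.roi.save_roi_model(model, tmp_path)
    assert (tmp_path / "septo_hypothalamic_selected.nii").exists()
    assert (tmp_path / "septo_hypothalamic_model.yaml").exists()
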