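"""Distance-weighted maps, edge ground truth and the region/edge losses,
checked against brute-force oracles and hand arithmetic."""

import numpy as np
import pytest

from shouldermorph.celunet import (
    LossConfig,
    compute_distance_weight_map,
    edge_loss,
    extract_edge_labels,
    inverse_frequency_weights,
    region_loss,
)
from shouldermorph.volumes import LabelVolume

SP = (1.0, 1.0, 1.0)


def brute_force_dwm(mask):
    """exp(-EDT) with EDT from all-pairs distances to boundary voxels."""
    from shouldermorph.celunet import _class_boundary

    boundary = np.argwhere(_class_boundary(mask)).astype(float)
    coords = np.argwhere(np.ones_like(mask)).astype(float)
    d = np.linalg.norm(coords[:, None, :] - boundary[None, :, :], axis=2).min(axis=1)
    return np.exp(-d).reshape(mask.shape)


class TestDistanceWeightMap:
    def test_boundary_voxels_weight_one(self):
        labels = np.zeros((7, 7, 7), dtype=np.int16)
        labels[2:5, 2:5, 2:5] = 1
        dwm = compute_distance_weight_map(LabelVolume(labels, SP), classes=(1,))[1]
        edges = extract_edge_labels(LabelVolume(labels, SP)).data == 1
        np.testing.assert_allclose(dwm[edges], 1.0)
        assert np.all(dwm > 0) and np.all(dwm <= 1)

    def test_axis_aligned_distance_two(self):
        """A voxel two steps straight out from a flat face has EDT = 2."""
        labels = np.zeros((9, 9, 9), dtype=np.int16)
        labels[2:7, 2:7, 2:7] = 1
        dwm = compute_distance_weight_map(LabelVolume(labels, SP), classes=(1,))[1]
        # boundary face at x=6; voxel at x=8 is 2 away
        assert dwm[8, 4, 4] == pytest.approx(np.exp(-2.0))

    def test_matches_brute_force_oracle(self):
        """5x5x5 cube centred in 9^3: module DWM equals all-pairs exp(-d)."""
        labels = np.zeros((9, 9, 9), dtype=np.int16)
        labels[2:7, 2:7, 2:7] = 1
        dwm = compute_distance_weight_map(LabelVolume(labels, SP), classes=(1,))[1]
        np.testing.assert_allclose(dwm, brute_force_dwm(labels == 1), atol=1e-12)

    def test_matches_brute_force_on_random_blobs(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            labels = (rng.random((8, 8, 8)) < 0.3).astype(np.int16)
            if not labels.any():
                continue
            dwm = compute_distance_weight_map(LabelVolume(labels, SP), classes=(1,))[1]
            np.testing.assert_allclose(dwm, brute_force_dwm(labels == 1), atol=1e-12)

    def test_absent_class_rejected(self):
        labels = np.zeros((6, 6, 6), dtype=np.int16)
        labels[1:3, 1:3, 1:3] = 1
        with pytest.raises(ValueError, match="class 2"):
            compute_distance_weight_map(LabelVolume(labels, SP), classes=(1, 2))


class TestEdgeLabels:
    def test_uniform_background_no_edges(self):
        labels = np.zeros((6, 6, 6), dtype=np.int16)
        assert extract_edge_labels(LabelVolume(labels, SP)).data.sum() == 0

    def test_isolated_voxel_is_edge(self):
        labels = np.zeros((5, 5, 5), dtype=np.int16)
        labels[2, 2, 2] = 1
        edges = extract_edge_labels(LabelVolume(labels, SP)).data
        assert edges[2, 2, 2] == 1 and edges.sum() == 1

    def test_cube_26_edge_voxels(self):
        """3^3 solid cube: all but the centre voxel are boundary."""
        labels = np.zeros((7, 7, 7), dtype=np.int16)
        labels[2:5, 2:5, 2:5] = 1
        edges = extract_edge_labels(LabelVolume(labels, SP)).data
        assert (edges == 1).sum() == 26
        assert edges[3, 3, 3] == 0

    def test_touching_grid_border_counts_as_edge(self):
        labels = np.ones((3, 3, 3), dtype=np.int16)
        edges = extract_edge_labels(LabelVolume(labels, SP)).data
        assert (edges == 1).sum() == 26


def two_voxel_toy():
    """2 classes x 2 voxels with hand-checkable numbers."""
    pred = np.array([[0.8, 0.4], [0.2, 0.6]])
    truth = np.array([[1.0, 0.0], [0.0, 1.0]])
    dwm = np.ones_like(truth)
    return pred, truth, dwm


class TestRegionLoss:
    def test_perfect_prediction_near_zero(self):
        _, truth, dwm = two_voxel_toy()
        cfg = LossConfig(class_weights={0: 0.5, 1: 0.5}, epsilon=1e-7)
        loss = float(region_loss(truth, truth, dwm, cfg).data)
        # Dice term vanishes; CE bounded by -log(1 - eps) approx eps
        assert 0.0 <= loss <= 2 * 1e-6

    def test_alpha_one_is_one_minus_weighted_dice(self):
        pred, truth, dwm = two_voxel_toy()
        cfg = LossConfig(alpha=1.0, class_weights={0: 0.5, 1: 0.5})
        loss = float(region_loss(pred, truth, dwm, cfg).data)
        # soft Dice per class: c0 2*0.8/(1.2+1)=0.7273, c1 2*0.6/(0.8+1)=0.6667
        d = 0.5 * (2 * 0.8 / 2.2) + 0.5 * (2 * 0.6 / 1.8)
        assert loss == pytest.approx(1.0 - d, abs=1e-12)

    def test_toy_value_matches_hand_arithmetic(self):
        pred, truth, dwm = two_voxel_toy()
        cfg = LossConfig(alpha=0.5, class_weights={0: 0.5, 1: 0.5})
        loss = float(region_loss(pred, truth, dwm, cfg).data)
        d = 0.5 * (2 * 0.8 / 2.2) + 0.5 * (2 * 0.6 / 1.8)
        ce = -(0.5 * np.log(0.8) + 0.5 * np.log(0.6)) / (0.5 + 0.5)
        assert loss == pytest.approx(0.5 * (1 - d) + 0.5 * ce, abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        logits = rng.random((3, 10))
        pred = logits / logits.sum(axis=0)
        truth = np.eye(3)[rng.integers(3, size=10)].T
        dwm = rng.uniform(0.1, 1.0, truth.shape)
        cfg = LossConfig(class_weights={0: 0.2, 1: 0.3, 2: 0.5})
        perm = rng.permutation(10)
        a = float(region_loss(pred, truth, dwm, cfg).data)
        b = float(region_loss(pred[:, perm], truth[:, perm], dwm[:, perm], cfg).data)
        assert a == pytest.approx(b, rel=1e-12)

    def test_class_weight_scaling_unnormalised(self):
        """With normalisation off, scaling every k_c by t scales the CE term."""
        pred, truth, dwm = two_voxel_toy()
        base = LossConfig(alpha=0.0, class_weights={0: 0.5, 1: 0.5}, normalize=False)
        scaled = LossConfig(alpha=0.0, class_weights={0: 1.5, 1: 1.5}, normalize=False)
        a = float(region_loss(pred, truth, dwm, base).data)
        b = float(region_loss(pred, truth, dwm, scaled).data)
        assert b == pytest.approx(3.0 * a, rel=1e-12)

    def test_decreases_along_mixing_path_to_truth(self):
        """Convexly mixing a random prediction toward the truth lowers the
        loss monotonically (checked at 5 mixing points)."""
        rng = np.random.default_rng(2)
        raw = rng.random((3, 20))
        pred = raw / raw.sum(axis=0)
        truth = np.eye(3)[rng.integers(3, size=20)].T
        dwm = rng.uniform(0.2, 1.0, truth.shape)
        cfg = LossConfig(class_weights={0: 1 / 3, 1: 1 / 3, 2: 1 / 3})
        losses = []
        for lam in np.linspace(0, 1, 5):
            mixed = (1 - lam) * pred + lam * truth
            losses.append(float(region_loss(mixed, truth, dwm, cfg).data))
        assert all(l >= 0 for l in losses)
        assert all(losses[i + 1] < losses[i] for i in range(4))

    def test_shape_mismatch_and_nonfinite_rejected(self):
        pred, truth, dwm = two_voxel_toy()
        with pytest.raises(ValueError, match="shape"):
            region_loss(pred[:, :1], truth, dwm)
        bad = pred.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            region_loss(bad, truth, dwm)


class TestEdgeLoss:
    def test_perfect_edges_near_zero(self):
        _, truth, dwm = two_voxel_toy()
        cfg = LossConfig(class_weights={0: 0.5, 1: 0.5})
        loss = float(edge_loss(truth, truth, dwm, cfg).data)
        assert 0.0 <= loss <= 2 * 1e-6

    def test_beta_one_is_forward_ce_alone(self):
        pred, truth, dwm = two_voxel_toy()
        cfg = LossConfig(beta=1.0, class_weights={0: 0.5, 1: 0.5})
        loss = float(edge_loss(pred, truth, dwm, cfg).data)
        fwd = -(0.5 * np.log(0.8) + 0.5 * np.log(0.6)) / 1.0
        assert loss == pytest.approx(fwd, abs=1e-9)

    def test_toy_value_matches_hand_arithmetic(self):
        pred, truth, dwm = two_voxel_toy()
        cfg = LossConfig(beta=0.5, class_weights={0: 0.5, 1: 0.5})
        loss = float(edge_loss(pred, truth, dwm, cfg).data)
        fwd = -(0.5 * np.log(0.8) + 0.5 * np.log(0.6)) / 1.0
        rev = -(0.5 * np.log(1 - 0.4) + 0.5 * np.log(1 - 0.2)) / 1.0
        assert loss == pytest.approx(0.5 * fwd + 0.5 * rev, abs=1e-9)


def test_inverse_frequency_weights_sum_to_one():
    truth = np.zeros((3, 4, 4, 4))
    truth[0] = 1
    truth[0, :2] = 0
    truth[1, :2] = 1
    truth[1, 0, 0, 0] = 0
    truth[2, 0, 0, 0] = 1
    w = inverse_frequency_weights(truth)
    assert w.sum() == pytest.approx(1.0)
    # the rarest class gets the largest weight
    counts = truth.reshape(3, -1).sum(axis=1)
    assert w[counts.argmin()] == w.max()
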