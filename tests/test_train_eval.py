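"""Patch extraction, focal loss, octahedral augmentation and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from icodwi.networks import ArchitectureSpec, build_network
from icodwi.spherical_signal import SamplingScheme
from icodwi.synthetic_data import generate_directions
from icodwi.train_eval import (
    build_rotated_testset,
    evaluate,
    extract_patches,
    focal_loss,
    focal_loss_with_grad,
    octahedral_augment,
    octahedral_group,
    performance_drop_map,
    rotate_grid_exact,
    train,
    PatchDataset,
)


class TestExtractPatches:
    def test_full_stride_interior_centers_of_9_cube(self, noise_free_phantom):
        vol, labels, mask = noise_free_phantom
        # crop a 9^3 region with all voxels masked and labeled
        import dataclasses
        sub = dataclasses.replace(
            vol, values=vol.values[11:20, 11:20, 11:20],
            mask=np.ones((9, 9, 9), dtype=bool))
        ds = extract_patches(sub, labels[11:20, 11:20, 11:20], patch_size=7)
        assert len(ds) == 27  # 3^3 interior centers

    def test_labels_match_volume_at_stored_coordinates(self, phantom_pair):
        (vol, labels, mask), _ = phantom_pair
        ds = extract_patches(vol, labels, patch_size=7, max_patches=100,
                             seed=0)
        for (x, y, z), lab in zip(ds.coords, ds.labels):
            assert labels[x, y, z] == lab
            assert mask[x, y, z]

    def test_patch_size_one_gives_single_voxels(self, phantom_pair):
        (vol, labels, _), _ = phantom_pair
        ds = extract_patches(vol, labels, patch_size=1, max_patches=50, seed=0)
        assert ds.patches.shape[1:4] == (1, 1, 1)
        center = ds.patches[:, 0, 0, 0, :]
        for i, (x, y, z) in enumerate(ds.coords):
            assert np.array_equal(center[i], vol.values[x, y, z])

    def test_balanced_subsampling_equalizes_classes(self, phantom_pair):
        (vol, labels, _), _ = phantom_pair
        ds = extract_patches(vol, labels, patch_size=7, max_patches=200,
                             seed=3, balance=True)
        counts = np.bincount(ds.labels, minlength=4)
        assert (counts == 50).all()

    def test_deterministic_given_seed(self, phantom_pair):
        (vol, labels, _), _ = phantom_pair
        a = extract_patches(vol, labels, patch_size=7, max_patches=60, seed=9)
        b = extract_patches(vol, labels, patch_size=7, max_patches=60, seed=9)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.patches, b.patches)


class TestFocalLoss:
    def test_confident_correct_prediction_has_zero_loss(self):
        p = np.array([[1.0 - 3e-9, 1e-9, 1e-9, 1e-9]])
        assert focal_loss(p, np.array([0])) < 1e-15

    def test_gamma_zero_reduces_to_weighted_cross_entropy(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(4), size=6)
        y = rng.integers(0, 4, 6)
        alpha = (0.35, 0.35, 0.15, 0.15)
        got = focal_loss(p, y, gamma=0.0)
        expected = np.mean([-alpha[c] * np.log(p[i, c])
                            for i, c in enumerate(y)])
        assert abs(got - expected) < 1e-12

    def test_hand_computed_value_for_half_confidence_wm(self):
        # WM is class 2 with alpha 0.15: 0.15 * (1-0.5)^2 * ln 2
        p = np.array([[0.2, 0.2, 0.5, 0.1]])
        assert abs(focal_loss(p, np.array([2])) - 0.15 * 0.25 * np.log(2)) \
            < 1e-12

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([[0.5, 0.5, 0.5, 0.5]]), np.array([0]))

    def test_logit_form_matches_probability_form(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(5, 4))
        y = rng.integers(0, 4, 5)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        loss_z, _ = focal_loss_with_grad(z, y)
        assert abs(loss_z - focal_loss(p, y)) < 1e-9


class TestOctahedralGroup:
    def test_24_integer_rotations_closed_under_composition(self):
        g = octahedral_group().elements
        assert len(g) == 24
        assert set(np.unique(g)) <= {-1, 0, 1}
        flat = {tuple(E.ravel()) for E in g}
        for A in g[::5]:
            for B in g[::7]:
                assert tuple((A @ B).ravel()) in flat
        for E in g:
            assert round(np.linalg.det(E)) == 1

    def test_grid_rotation_is_exact_involution_for_180(self):
        rng = np.random.default_rng(2)
        vals = rng.random(size=(6, 6, 6, 4))
        R = np.diag([-1, -1, 1])
        twice = rotate_grid_exact(rotate_grid_exact(vals, R), R)
        assert np.array_equal(twice, vals)

    def test_grid_rotation_respects_composition(self):
        g = octahedral_group().elements
        rng = np.random.default_rng(3)
        vals = rng.random(size=(5, 5, 5))
        A, B = g[5], g[17]
        lhs = rotate_grid_exact(rotate_grid_exact(vals, B), A)
        rhs = rotate_grid_exact(vals, A @ B)
        assert np.array_equal(lhs, rhs)


@pytest.fixture(scope="module")
def scheme():
    return generate_directions(30, seed=4)


class TestOctahedralAugment:

    def test_isotropic_signal_invariant_under_any_rotation(self, scheme):
        patch = np.full((3, 3, 3, 30), 0.7)
        for R in octahedral_group().elements[::5]:
            out = octahedral_augment(patch, scheme, R)
            assert np.abs(out - 0.7).max() < 1e-9

    def test_double_180_restores_grid_exactly(self, scheme):
        # direction-constant signals are untouched by the (row-stochastic)
        # Watson resampling, isolating the grid permutation: applying a
        # 180-degree rotation twice must restore the patch bit-for-bit
        rng = np.random.default_rng(5)
        per_voxel = rng.random(size=(3, 3, 3, 1))
        patch = np.repeat(per_voxel, 30, axis=-1)
        R = np.diag([1, -1, -1])
        twice = octahedral_augment(
            octahedral_augment(patch, scheme, R), scheme, R)
        assert np.abs(twice - patch).max() < 1e-12

    def test_values_stay_in_per_voxel_range(self, scheme):
        rng = np.random.default_rng(6)
        patch = rng.random(size=(3, 3, 3, 30))
        out = octahedral_augment(patch, scheme, octahedral_group().elements[7])
        assert out.min() >= patch.min() - 1e-12
        assert out.max() <= patch.max() + 1e-12

    def test_non_octahedral_rotation_rejected(self, scheme):
        from icodwi.icosa_group import rotation_about_axis
        with pytest.raises(ValueError):
            octahedral_augment(np.zeros((3, 3, 3, 30)), scheme,
                               rotation_about_axis([0, 0, 1], 2 * np.pi / 5))


class TestRotatedTestset:
    def _dataset(self, n=40):
        rng = np.random.default_rng(7)
        scheme = generate_directions(20, seed=8)
        return PatchDataset(
            patches=rng.random(size=(n, 3, 3, 3, 20)),
            labels=rng.integers(0, 4, n),
            coords=np.zeros((n, 3), dtype=int),
            scheme=scheme)

    def test_seeded_and_label_preserving(self):
        ds = self._dataset()
        a = build_rotated_testset(ds, seed=1)
        b = build_rotated_testset(ds, seed=1)
        assert np.array_equal(a.patches, b.patches)
        assert np.array_equal(a.labels, ds.labels)
        c = build_rotated_testset(ds, seed=2)
        assert not np.array_equal(a.patches, c.patches)

    def test_rotation_draws_uniform_over_24_elements(self):
        # chi-square on the generator's own draw stream
        rng = np.random.default_rng(0)
        draws = rng.integers(0, 24, size=10000)
        counts = np.bincount(draws, minlength=24)
        chi2 = ((counts - 10000 / 24) ** 2 / (10000 / 24)).sum()
        assert chi2 < stats.chi2.ppf(0.9973, df=23)  # 3-sigma bound


class TestEvaluate:
    def test_perfect_predictions_score_one(self):
        y = np.repeat(np.arange(4), 5)
        rep = evaluate(y, y)
        assert np.allclose(rep.class_accuracy, 1.0)
        assert np.allclose(rep.class_dice, 1.0)
        assert rep.overall_accuracy == 1.0

    def test_dice_from_hand_confusion(self):
        # class 0: TP=3, FP=1, FN=1 -> Dice 0.75
        labels = np.array([0, 0, 0, 0, 1, 1])
        preds = np.array([0, 0, 0, 1, 0, 1])
        rep = evaluate(preds, labels)
        assert abs(rep.class_dice[0] - 0.75) < 1e-12
        assert abs(rep.class_accuracy[0] - 0.75) < 1e-12

    def test_constant_predictor_on_balanced_labels(self):
        labels = np.repeat(np.arange(4), 10)
        preds = np.full(40, 2)
        rep = evaluate(preds, labels)
        assert rep.overall_accuracy == 0.25

    def test_mean_and_sd_across_scans(self):
        labels = np.array([0, 0, 0, 0])
        preds = np.array([0, 0, 0, 1])
        scans = np.array([0, 0, 1, 1])
        rep = evaluate(preds, labels, scans)
        assert rep.n_scans == 2
        assert abs(rep.overall_accuracy - 0.75) < 1e-12
        assert abs(rep.overall_accuracy_sd - 0.25) < 1e-12

    def test_class_absent_everywhere_is_flagged(self):
        labels = np.array([0, 1, 2, 0])
        preds = labels.copy()
        rep = evaluate(preds, labels)
        assert rep.missing == (3,)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_confusion_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 4, 60)
        preds = rng.integers(0, 4, 60)
        rep = evaluate(preds, labels)
        conf = np.zeros((4, 4))
        for l, p in zip(labels, preds):
            conf[l, p] += 1
        for c in range(4):
            if conf[c].sum() == 0:
                continue
            assert abs(rep.class_accuracy[c] - conf[c, c] / conf[c].sum()) \
                < 1e-12
            denom = 2 * conf[c, c] + (conf[:, c].sum() - conf[c, c]) \
                + (conf[c].sum() - conf[c, c])
            if denom:
                assert abs(rep.class_dice[c] - 2 * conf[c, c] / denom) < 1e-12
        assert abs(rep.overall_accuracy - np.trace(conf) / 60) < 1e-12


class TestPerformanceDropMap:
    def test_no_drop_gives_exp_minus_alpha(self):
        assert abs(performance_drop_map(0.8, 0.8) - np.exp(-20)) < 1e-25

    def test_exp_decay_decreases_with_larger_drop(self):
        small = performance_drop_map(0.8, 0.79)
        large = performance_drop_map(0.8, 0.5)
        assert large < small

    def test_logistic_is_half_at_no_change(self):
        assert abs(performance_drop_map(0.7, 0.7, formula="logistic") - 0.5) \
            < 1e-12

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            performance_drop_map(0.0, 0.5)


@pytest.fixture(scope="module")
def tiny_setup():
    spec = ArchitectureSpec("baseline_so3", (1, 5), patch_size=1)
    rng = np.random.default_rng(0)
    ds = PatchDataset(
        patches=rng.random(size=(40, 1, 1, 1, 30)),
        labels=rng.integers(0, 4, 40),
        coords=np.zeros((40, 3), dtype=int),
        scheme=generate_directions(30, seed=1))
    return spec, ds


class TestTrain:

    def test_loss_history_recorded_and_finite(self, tiny_setup, group):
        spec, ds = tiny_setup
        net = build_network(spec, seed=0, group=group)
        hist = train(net, ds, epochs=3, batch_size=20, seed=0)
        assert len(hist.epoch_loss) == 3
        assert all(np.isfinite(l) for l in hist.epoch_loss)
        assert hist.epoch_loss[-1] <= hist.epoch_loss[0]

    def test_same_seed_gives_identical_final_weights(self, tiny_setup, group):
        spec, ds = tiny_setup
        states = []
        for _ in range(2):
            net = build_network(spec, seed=4, group=group)
            train(net, ds, epochs=2, batch_size=20, seed=7)
            states.append(net.state_dict())
        for k in states[0]:
            assert np.array_equal(states[0][k], states[1][k])

    def test_augmented_training_runs_and_differs(self, tiny_setup, group):
        spec, ds = tiny_setup
        net_a = build_network(spec, seed=4, group=group)
        train(net_a, ds, epochs=1, batch_size=20, seed=7, augment_seed=1)
        net_b = build_network(spec, seed=4, group=group)
        train(net_b, ds, epochs=1, batch_size=20, seed=7)
        diffs = [np.abs(net_a.state_dict()[k] - net_b.state_dict()[k]).max()
                 for k in net_a.state_dict()]
        assert max(diffs) > 0

    def test_empty_dataset_rejected(self, tiny_setup, group):
        spec, ds = tiny_setup
        import dataclasses
        empty = dataclasses.replace(ds, patches=ds.patches[:0],
                                    labels=ds.labels[:0],
                                    coords=ds.coords[:0])
        net = build_network(spec, seed=0, group=group)
        with pytest.raises(ValueError):
            train(net, empty, epochs=1)
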