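"""Training protocol: folds, augmentation, learning behavior, persistence."""

import dataclasses

import numpy as np
import pytest

from cavityseg import (
    AugmentConfig,
    TrainConfig,
    augment_pair,
    desk_config,
    fine_tune,
    generate_cohort,
    load_model,
    make_folds,
    predict_slices,
    save_model,
    train,
)
from cavityseg.errors import ConsistencyError
from cavityseg.segmenter import sample_augment_params

from conftest import stack_pairs


# ------------------------------------------------------------------ folds --

class TestMakeFolds:
    def test_45_subjects_5_folds_protocol(self):
        ids = [f"s{i:02d}" for i in range(45)]
        folds = make_folds(ids, k=5, seed=1)
        assert len(folds) == 5
        all_test: list[str] = []
        for f in folds:
            assert len(f.test_ids) == 9
            assert len(f.val_ids) == 9
            assert len(f.train_ids) == 27
            assert set(f.train_ids) | set(f.val_ids) | set(f.test_ids) == set(ids)
            all_test.extend(f.test_ids)
        # each subject held out for testing exactly once
        assert sorted(all_test) == sorted(ids)

    def test_deterministic_from_seed(self):
        ids = [f"s{i}" for i in range(20)]
        assert make_folds(ids, 5, seed=3) == make_folds(ids, 5, seed=3)
        assert make_folds(ids, 5, seed=3) != make_folds(ids, 5, seed=4)

    def test_no_subject_in_two_sets(self):
        for f in make_folds([f"s{i}" for i in range(17)], k=4, seed=0):
            assert not set(f.train_ids) & set(f.val_ids)
            assert not set(f.train_ids) & set(f.test_ids)
            assert not set(f.val_ids) & set(f.test_ids)

    def test_k_larger_than_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=3)


# ------------------------------------------------------------ augmentation --

class TestAugmentation:
    def test_disabled_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((32, 32)).astype(np.float32)
        msk = (rng.random((32, 32)) > 0.8).astype(np.float32)
        aug = AugmentConfig(hflip=False, vflip=False, max_rotation_deg=0, max_shift_frac=0)
        out_i, out_m = augment_pair(img, msk, aug, rng)
        np.testing.assert_array_equal(out_i, img)
        np.testing.assert_array_equal(out_m, msk)

    def test_pairs_transformed_identically(self):
        # a cavity on the left must land on the same side in image and mask
        rng = np.random.default_rng(1)
        img = np.zeros((32, 32), np.float32)
        msk = np.zeros((32, 32), np.float32)
        img[12:20, 2:8] = 1.0
        msk[12:20, 2:8] = 1.0
        aug = AugmentConfig(hflip=True, vflip=True, max_rotation_deg=0, max_shift_frac=0)
        for _ in range(20):
            out_i, out_m = augment_pair(img, msk, aug, rng)
            np.testing.assert_array_equal(out_i > 0.5, out_m > 0.5)

    def test_mask_stays_binary_under_rotation(self):
        rng = np.random.default_rng(2)
        msk = np.zeros((32, 32), np.float32)
        msk[10:20, 10:20] = 1.0
        aug = AugmentConfig(hflip=False, vflip=False, max_rotation_deg=10, max_shift_frac=0.1)
        for _ in range(10):
            _, out_m = augment_pair(msk.copy(), msk, aug, rng)
            assert set(np.unique(out_m)) <= {0.0, 1.0}

    def test_empirical_bounds_over_1000_draws(self):
        rng = np.random.default_rng(3)
        aug = AugmentConfig()
        angles, shifts = [], []
        for _ in range(1000):
            p = sample_augment_params(aug, rng)
            angles.append(abs(p["angle_deg"]))
            shifts.extend(abs(s) for s in p["shift_frac"])
        assert max(angles) <= 10.0
        assert max(shifts) <= 0.10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            augment_pair(
                np.zeros((8, 8), np.float32), np.zeros((8, 9), np.float32),
                AugmentConfig(), np.random.default_rng(0),
            )


# -------------------------------------------------------------- training --

@pytest.fixture(scope="module")
def quick_model():
    """A weak but functional axial model: 6 phantoms, 4 epochs."""
    cohort = generate_cohort(8, seed=11)
    cfg = desk_config(seed=3, epochs=4)
    model = train(
        stack_pairs(cohort[:6], "axial"), stack_pairs(cohort[6:], "axial"), cfg
    )
    return model, cohort


class TestTraining:
    def test_overfits_single_slice(self):
        cohort = generate_cohort(1, seed=4)
        pairs = stack_pairs(cohort, "axial")
        img_stack, msk_stack = pairs[0]
        # pick the most informative slice and train on 8 copies of it
        best = int(msk_stack.slices.sum(axis=(1, 2)).argmax())
        for stack in (img_stack, msk_stack):
            stack.slices = np.repeat(stack.slices[best : best + 1], 8, axis=0)
            stack.transform_log = stack.transform_log[:8]
            stack.slice_index_map = list(range(8))
        cfg = dataclasses.replace(
            desk_config(seed=0),
            epochs=200, batch_size=8, learning_rate=3e-3,
            augmentation=AugmentConfig(False, False, 0.0, 0.0),
        )
        model = train([(img_stack, msk_stack)], [], cfg)
        proba = predict_slices(model, img_stack)
        pred = proba >= 0.5
        truth = msk_stack.slices > 0.5
        dice = 2 * (pred & truth).sum() / (pred.sum() + truth.sum())
        assert dice > 0.95

    def test_learning_progress_and_selection_rule(self, quick_model):
        model, _ = quick_model
        val = [h["val_dsc"] for h in model.history]
        assert val[-1] > val[0]
        # training loss trends downward (linear fit slope < 0)
        losses = [h["train_loss"] for h in model.history]
        slope = np.polyfit(np.arange(len(losses)), losses, 1)[0]
        assert slope < 0
        # the kept parameters correspond to the best-validation-DSC epoch
        assert max(val) == pytest.approx(
            max(h["val_dsc"] for h in model.history)
        )

    def test_prediction_range_and_determinism(self, quick_model):
        model, cohort = quick_model
        stack = stack_pairs(cohort[:1], "axial")[0][0]
        p1 = predict_slices(model, stack)
        p2 = predict_slices(model, stack)
        assert p1.min() >= 0.0 and p1.max() <= 1.0
        np.testing.assert_array_equal(p1, p2)

    def test_plane_mismatch_rejected(self, quick_model):
        model, cohort = quick_model
        coronal = stack_pairs(cohort[:1], "coronal")[0][0]
        with pytest.raises(ConsistencyError):
            predict_slices(model, coronal)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train([], [], desk_config())

    def test_train_deterministic_given_seed(self):
        cohort = generate_cohort(2, seed=6)
        cfg = desk_config(seed=5, epochs=1)
        m1 = train(stack_pairs(cohort[:1], "axial"), stack_pairs(cohort[1:], "axial"), cfg)
        m2 = train(stack_pairs(cohort[:1], "axial"), stack_pairs(cohort[1:], "axial"), cfg)
        for k in m1.net.params:
            np.testing.assert_array_equal(m1.net.params[k], m2.net.params[k])


class TestFineTune:
    def test_zero_epochs_is_identity(self, quick_model):
        model, cohort = quick_model
        cfg = dataclasses.replace(model.config, epochs=0)
        tuned = fine_tune(model, stack_pairs(cohort[:2], "axial"),
                          stack_pairs(cohort[2:3], "axial"), cfg)
        for k in model.net.params:
            np.testing.assert_array_equal(tuned.net.params[k], model.net.params[k])

    def test_continues_from_existing_weights_and_improves(self, quick_model):
        model, _ = quick_model
        # new distribution: larger, differently-seeded cavities
        new = generate_cohort(6, {"cavity_radius_mm": (12.0, 16.0)}, seed=77)
        new_train = stack_pairs(new[:4], "axial")
        new_val = stack_pairs(new[4:], "axial")
        # pre-fine-tune validation DSC on the new distribution
        from cavityseg.segmenter import _collect, _global_dice
        x_va, y_va, _, _ = _collect(new_val, "axial")
        pre = _global_dice(
            model.net.predict_proba(x_va[..., None].astype(np.float32)) >= 0.5, y_va
        )
        cfg = dataclasses.replace(model.config, epochs=3, seed=123)
        tuned = fine_tune(model, new_train, new_val, cfg)
        post = max(h["val_dsc"] for h in tuned.history)
        assert post >= pre


class TestPersistence:
    def test_save_load_round_trip(self, quick_model, tmp_path):
        model, cohort = quick_model
        p = tmp_path / "axial.npz"
        save_model(model, p)
        back = load_model(p)
        assert back.plane == model.plane
        assert back.config == model.config
        stack = stack_pairs(cohort[:1], "axial")[0][0]
        np.testing.assert_array_equal(
            predict_slices(back, stack), predict_slices(model, stack)
        )


def test_pretrained_encoder_flag_rejected():
    with pytest.raises(ValueError, match="pretrained"):
        TrainConfig(pretrained_encoder=True)
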