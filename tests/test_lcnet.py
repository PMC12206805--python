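import numpy as np
import pytest

from hyperleaf.lcnet import (
    ARCH_IDS,
    ArchitectureConfig,
    TrainConfig,
    analytic_parameter_count,
    build_model,
    channel_shuffle,
    conv_out_len,
    count_flops,
    count_parameters,
    learning_rate,
    repeat_experiment,
    to_model_input,
    train_cnn,
)


class TestConvOutLen:
    def test_spectral_reduction_chains(self):
        # 30 bands: 30 -> 15 -> 8; 15 bands: 15 -> 8 -> 4
        assert conv_out_len(30, 3, 2, 1) == 15
        assert conv_out_len(15, 3, 2, 1) == 8
        assert conv_out_len(8, 3, 2, 1) == 4

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_same_padding_identity(self, k):
        for L in range(1, 40):
            assert conv_out_len(L, k, 1, (k - 1) // 2) == L

    def test_matches_enumeration(self):
        # oracle: count valid window positions explicitly
        for L in range(1, 30):
            for k in (1, 3, 5):
                for s in (1, 2, 3):
                    for p in (0, 1, 2):
                        padded = L + 2 * p
                        if padded < k:
                            continue
                        expected = len(range(0, padded - k + 1, s))
                        assert conv_out_len(L, k, s, p) == expected

    def test_degenerate_output_is_an_error(self):
        with pytest.raises(ValueError):
            conv_out_len(1, 3, 1, 0)


class TestChannelShuffle:
    def test_four_channels_two_groups(self):
        fm = np.arange(4).reshape(4, 1, 1)
        out = channel_shuffle(fm, groups=2)
        assert out[:, 0, 0].tolist() == [0, 2, 1, 3]

    def test_inverse_with_swapped_group_shape(self, rng):
        fm = rng.normal(size=(8, 3, 3))
        once = channel_shuffle(fm, groups=2)
        back = channel_shuffle(once, groups=4)  # swapped reshape undoes it
        assert np.array_equal(back, fm)

    def test_per_channel_content_preserved(self, rng):
        fm = rng.normal(size=(6, 4, 4))
        out = channel_shuffle(fm, groups=2)
        orig = {tuple(np.sort(fm[c].ravel())) for c in range(6)}
        new = {tuple(np.sort(out[c].ravel())) for c in range(6)}
        assert orig == new

    def test_indivisible_channels_is_an_error(self, rng):
        with pytest.raises(ValueError):
            channel_shuffle(rng.normal(size=(5, 2, 2)), groups=2)


class TestArchitectures:
    @pytest.mark.parametrize("n_bands", [15, 30])
    def test_hybrid_shape_walk(self, n_bands):
        model = build_model(ArchitectureConfig("hybrid_lcnet", n_bands))
        probe = np.zeros((1, 1, n_bands, 112, 112), np.float32)
        shapes = dict(model.trace(probe))
        d1 = conv_out_len(n_bands, 3, 2, 1)
        d2 = conv_out_len(d1, 3, 2, 1)
        assert shapes["stem.conv1"] == (16, d1, 56, 56)
        assert shapes["stem.conv2"] == (32, d2, 28, 28)
        assert shapes["stem.pool_spectral"] == (32, 2, 28, 28)
        assert shapes["bridge.reshape"] == (64, 28, 28)
        assert shapes["stage.down1"] == (128, 14, 14)
        assert shapes["stage.down2"] == (256, 7, 7)
        assert shapes["head.conv"] == (512, 7, 7)
        assert shapes["head.fc"] == (6,)

    def test_shufflenet_2d_stage_plan(self):
        model = build_model(ArchitectureConfig("shufflenetv2_2d", 30))
        probe = np.zeros((1, 30, 112, 112), np.float32)
        shapes = dict(model.trace(probe))
        assert shapes["stem.conv"] == (24, 56, 56)
        assert shapes["stem.pool"] == (24, 28, 28)
        assert shapes["stage2.down"] == (32, 14, 14)
        assert shapes["stage3.down"] == (64, 7, 7)
        assert shapes["stage4.down"] == (128, 4, 4)
        assert shapes["head.conv"] == (1024, 4, 4)
        names = [n for n, _ in model.named_layers]
        assert sum(n.startswith("stage2") for n in names) == 4
        assert sum(n.startswith("stage3") for n in names) == 8
        assert sum(n.startswith("stage4") for n in names) == 4

    @pytest.mark.parametrize("arch", ARCH_IDS)
    def test_framework_params_equal_analytic_sum(self, arch):
        for n_bands in (15, 30):
            model = build_model(ArchitectureConfig(arch, n_bands))
            assert count_parameters(model) == analytic_parameter_count(model)

    def test_too_few_bands_for_3d_stem_is_an_error(self):
        with pytest.raises(ValueError, match=">= 8"):
            ArchitectureConfig("hybrid_lcnet", 7)

    def test_unknown_architecture_is_an_error(self):
        with pytest.raises(ValueError):
            ArchitectureConfig("alexnet", 30)


class TestAccounting:
    def test_pointwise_conv_flop_formula(self):
        from hyperleaf._nn import Conv

        conv = Conv(256, 512, (1, 1), (1, 1), (0, 0))
        assert conv.macs((7, 7)) == 256 * 512 * 49

    def test_doubling_area_doubles_conv_macs_not_params(self):
        from hyperleaf._nn import Conv

        conv = Conv(8, 16, (3, 3), (1, 1), (1, 1))
        assert conv.macs((14, 14)) == 2 * conv.macs((7, 14))
        assert conv.param_count_formula() == 9 * 8 * 16

    def test_hybrid_strictly_cheaper_than_pure_3d(self):
        e_hybrid = count_flops(build_model(ArchitectureConfig("hybrid_lcnet", 30)))
        e_3d = count_flops(build_model(ArchitectureConfig("lcnet3d", 30)))
        assert e_hybrid.flops < e_3d.flops
        assert "2*MAC" in e_hybrid.convention


class TestTrainingProtocol:
    def test_learning_rate_schedule_checkpoints(self):
        cfg = TrainConfig()
        assert learning_rate(cfg, 1) == 0.001
        assert learning_rate(cfg, 20) == 0.001
        assert learning_rate(cfg, 21) == 0.0005
        assert learning_rate(cfg, 41) == 0.00025
        with pytest.raises(ValueError):
            learning_rate(cfg, 0)

    def test_training_is_deterministic_and_learns(self):
        from hyperleaf.synthleaf import simulate_image_dataset

        images, labels, _ = simulate_image_dataset(6, n_bands=15, size=112, seed=3)
        X = to_model_input(images, "hybrid_lcnet")
        tr = np.concatenate([np.flatnonzero(labels == c)[:4] for c in range(1, 7)])
        va = np.concatenate([np.flatnonzero(labels == c)[4:] for c in range(1, 7)])
        cfg = TrainConfig(epochs=4, batch_size=8, seed=5)
        histories = []
        for _ in range(2):
            model = build_model(ArchitectureConfig("hybrid_lcnet", 15), seed=5)
            res = train_cnn(model, (X[tr], labels[tr]), (X[va], labels[va]), cfg)
            histories.append(res.history)
        assert histories[0] == histories[1]
        losses = [h["train_loss"] for h in histories[0]]
        assert losses[-1] < losses[0]

    def test_empty_loader_is_an_error(self):
        model = build_model(ArchitectureConfig("hybrid_lcnet", 15))
        X = np.zeros((0, 1, 15, 112, 112), np.float32)
        with pytest.raises(ValueError):
            train_cnn(model, (X, np.zeros(0)), (X, np.zeros(0)), TrainConfig())


class TestRepeatExperiment:
    @staticmethod
    def _stub_runner(record):
        def runner(arch, train, val, test, seed):
            record.append({"arch": arch, "seed": seed,
                           "test_y": np.asarray(test[1]).copy(),
                           "train_n": len(train[1]), "val_n": len(val[1])})
            rng = np.random.default_rng(seed)
            y = np.asarray(test[1]).copy()
            flip = rng.random(y.size) < (0.1 if arch == "hybrid_lcnet" else 0.4)
            y[flip] = 1 + (y[flip] % 6)
            return y
        return runner

    @pytest.fixture
    def tiny_pool(self, rng):
        n = 60
        images = rng.uniform(size=(n, 8, 8, 3)).astype(np.float32)
        labels = np.repeat(np.arange(1, 7), 10)
        leaf_ids = np.arange(n)
        test_images = rng.uniform(size=(30, 8, 8, 3)).astype(np.float32)
        test_labels = np.repeat(np.arange(1, 7), 5)
        return (images, labels, leaf_ids), (test_images, test_labels)

    def test_test_fold_frozen_and_cells_formatted(self, tiny_pool):
        record = []
        out = repeat_experiment(
            ["hybrid_lcnet", "lcnet2d"], *tiny_pool, n_repeats=5, seed=0,
            runner=self._stub_runner(record),
        )
        test_sets = [r["test_y"] for r in record]
        for t in test_sets[1:]:
            assert np.array_equal(t, test_sets[0])
        for arch, stats in out["per_arch"].items():
            assert len(stats["values"]) == 5
            assert "±" in stats["cell"]
        assert out["dunn"] is not None

    def test_single_repeat_has_zero_sd(self, tiny_pool):
        out = repeat_experiment(
            ["hybrid_lcnet"], *tiny_pool, n_repeats=1, seed=0,
            runner=self._stub_runner([]),
        )
        assert out["per_arch"]["hybrid_lcnet"]["accuracy_sd"] == 0.0

    def test_resplit_is_stratified_and_covers_pool(self, tiny_pool):
        record = []
        repeat_experiment(["hybrid_lcnet"], *tiny_pool, n_repeats=2, seed=1,
                          runner=self._stub_runner(record))
        for r in record:
            assert r["train_n"] + r["val_n"] == 60
            assert r["val_n"] == 12  # 25% of the pool, 2 leaves per class
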