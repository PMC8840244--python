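import numpy as np
import pytest

from shallowbp.autoencoder import (
    ModelHandle,
    TrainConfig,
    UNetConfig,
    UNetFeatureExtractor,
    build_autoencoder,
    count_parameters,
    extract_features,
    reconstruct,
    train_autoencoder,
)

TINY = dict(depth=1, width=8, kernel=3, in_channels=1, n_features=16)


def _smooth(rng, n, length=1024, channels=1):
    from scipy.ndimage import uniform_filter1d

    x = rng.uniform(0, 1, (n, length, channels))
    return uniform_filter1d(x, 31, axis=1).astype(np.float32)


class TestConfig:
    def test_length_must_divide_by_pooling(self):
        with pytest.raises(ValueError, match="divisible"):
            UNetConfig(depth=3, input_length=1020)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(kernel=4)

    def test_published_layout_bottleneck_is_512_by_128(self):
        cfg = UNetConfig(depth=1, width=128, kernel=3, in_channels=4, n_features=1024)
        assert cfg.bottleneck_length == 512
        assert cfg.bottleneck_channels == 128


class TestParameterCounts:
    def test_feature_dense_weights_published_layout(self):
        cfg = UNetConfig(depth=1, width=128, kernel=3, in_channels=4, n_features=1024)
        backbone, feature_dense, _ = count_parameters(cfg)
        assert feature_dense == 512 * 128 * 1024 == 67_108_864

    def test_backbone_matches_hand_summed_layout(self):
        # conv 4->128, 128->128, 128->256, 256->256, transpose 256->128,
        # conv 256->128, 128->128, 1x1 128->1
        hand = 1664 + 49280 + 98560 + 196864 + 65664 + 98432 + 49280 + 129
        cfg = UNetConfig(depth=1, width=128, kernel=3, in_channels=4, n_features=1024)
        assert count_parameters(cfg)[0] == hand == 559_873

    def test_minimal_config_feature_dense_is_512(self):
        cfg = UNetConfig(depth=1, width=1, kernel=1, in_channels=1, n_features=1)
        assert count_parameters(cfg)[1] == 512

    @pytest.mark.parametrize("depth", [1, 4])
    @pytest.mark.parametrize("width", [32, 256])
    @pytest.mark.parametrize("kernel", [3, 11])
    @pytest.mark.parametrize("channels", [1, 4])
    def test_closed_form_equals_built_model_at_grid_corners(
        self, depth, width, kernel, channels
    ):
        cfg = UNetConfig(
            depth=depth, width=width, kernel=kernel, in_channels=channels, n_features=8
        )
        model = build_autoencoder(cfg, seed=0)
        assert model.net.n_params() == count_parameters(cfg)[2]


class TestForward:
    def test_zero_input_gives_finite_1024_output(self):
        cfg = UNetConfig(**TINY)
        model = build_autoencoder(cfg, seed=0)
        y, f = model.net.forward(np.zeros((2, 1024, 1), dtype=np.float32))
        assert y.shape == (2, 1024)
        assert np.all(np.isfinite(y)) and np.all(np.isfinite(f))

    def test_untrained_output_varies_with_input(self, rng):
        model = build_autoencoder(UNetConfig(**TINY), seed=0)
        x = _smooth(rng, 2)
        y, _ = model.net.forward(x)
        assert not np.allclose(y[0], y[1])

    def test_depth_one_has_single_pool_and_upsample(self):
        model = build_autoencoder(UNetConfig(**TINY), seed=0)
        assert len(model.net.pools) == 1
        assert len(model.net.dec) == 1

    def test_gradients_match_directional_finite_differences(self, rng):
        cfg = UNetConfig(depth=2, width=4, kernel=3, in_channels=2, n_features=5,
                         input_length=16)
        model = build_autoencoder(cfg, seed=1)
        X = rng.standard_normal((4, 16, 2)).astype(np.float32)
        Y = rng.standard_normal((4, 16)).astype(np.float32)

        def loss():
            p, _ = model.net.forward(X)
            return float(np.mean((p - Y) ** 2))

        p0, _ = model.net.forward(X)
        err = p0 - Y
        model.net.backward((2.0 / err.size) * err)
        for layer in model.net.layers():
            if not layer.params:
                continue
            g = {k: layer.grads[k].copy() for k in layer.params}
            ana = sum(float(np.sum(v * v)) for v in g.values())
            if ana == 0:
                continue
            eps = 1e-3 / np.sqrt(ana)
            for k in layer.params:
                layer.params[k] += (eps * g[k]).astype(np.float32)
            lp = loss()
            for k in layer.params:
                layer.params[k] -= (2 * eps * g[k]).astype(np.float32)
            lm = loss()
            for k in layer.params:
                layer.params[k] += (eps * g[k]).astype(np.float32)
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(ana, rel=0.05)


class TestTraining:
    def test_memorizes_tiny_identity_task(self, rng):
        X = _smooth(rng, 8)
        Y = X[:, :, 0].copy()
        model = build_autoencoder(UNetConfig(**TINY), seed=0)
        train_autoencoder(
            model, X, Y,
            TrainConfig(batch_size=4, max_epochs=150, patience=150, val_fraction=0.25, seed=0),
        )
        mse = float(np.mean((reconstruct(model, X) - Y) ** 2))
        assert mse < 1e-3

    def test_patience_zero_trains_exactly_one_epoch(self, rng):
        X, Y = _smooth(rng, 10), _smooth(rng, 10)[:, :, 0]
        model = build_autoencoder(UNetConfig(**TINY), seed=0)
        train_autoencoder(model, X, Y, TrainConfig(batch_size=4, max_epochs=50, patience=0, seed=0))
        assert len(model.history) == 1

    def test_reruns_bitwise_identical(self, rng):
        X, Y = _smooth(rng, 12), _smooth(rng, 12)[:, :, 0]
        tcfg = TrainConfig(batch_size=4, max_epochs=3, patience=3, seed=7)
        runs = []
        for _ in range(2):
            m = build_autoencoder(UNetConfig(**TINY), seed=7)
            train_autoencoder(m, X, Y, tcfg)
            runs.append((m.history, extract_features(m, X)))
        assert runs[0][0] == runs[1][0]
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_restored_weights_reproduce_best_val_metric(self, rng):
        X, Y = _smooth(rng, 20), _smooth(rng, 20)[:, :, 0]
        tcfg = TrainConfig(batch_size=8, max_epochs=12, patience=12, seed=1)
        m = build_autoencoder(UNetConfig(**TINY), seed=1)
        train_autoencoder(m, X, Y, tcfg)
        best = min(h["val_mae"] for h in m.history)
        # recompute the monitored metric on the restored weights
        rng2 = np.random.default_rng(tcfg.seed)
        perm = rng2.permutation(20)
        val_idx = perm[: max(1, round(0.2 * 20))]
        val_mae = float(np.mean(np.abs(reconstruct(m, X[val_idx]) - Y[val_idx])))
        assert val_mae == pytest.approx(best, abs=1e-6)

    def test_small_batch_warning_and_reduction(self, rng):
        X, Y = _smooth(rng, 6), _smooth(rng, 6)[:, :, 0]
        m = build_autoencoder(UNetConfig(**TINY), seed=0)
        with pytest.warns(UserWarning, match="batch size reduced"):
            train_autoencoder(m, X, Y, TrainConfig(batch_size=64, max_epochs=1, patience=1, seed=0))

    def test_ppg_target_ablation_runs_unchanged(self, rng):
        X = _smooth(rng, 8)
        cfg = UNetConfig(depth=1, width=8, kernel=3, in_channels=1, n_features=16, target="PPG")
        m = build_autoencoder(cfg, seed=0)
        train_autoencoder(m, X, X[:, :, 0], TrainConfig(batch_size=4, max_epochs=2, patience=2, seed=0))
        assert extract_features(m, X).shape == (8, 16)


class TestFeatureExtraction:
    def test_shape_and_duplicate_determinism(self, rng):
        X, Y = _smooth(rng, 10), _smooth(rng, 10)[:, :, 0]
        m = build_autoencoder(UNetConfig(**TINY), seed=0)
        train_autoencoder(m, X, Y, TrainConfig(batch_size=4, max_epochs=2, patience=2, seed=0))
        F = extract_features(m, X)
        assert F.shape == (10, 16)
        dup = np.concatenate([X[:1], X[:1]])
        Fd = extract_features(m, dup)
        assert np.array_equal(Fd[0], Fd[1])

    def test_untrained_model_refuses_extraction(self, rng):
        m = build_autoencoder(UNetConfig(**TINY), seed=0)
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            extract_features(m, _smooth(rng, 2))

    def test_channel_mismatch_rejected(self, rng):
        X, Y = _smooth(rng, 8), _smooth(rng, 8)[:, :, 0]
        m = build_autoencoder(UNetConfig(**TINY), seed=0)
        train_autoencoder(m, X, Y, TrainConfig(batch_size=4, max_epochs=1, patience=1, seed=0))
        with pytest.raises(ValueError):
            extract_features(m, _smooth(rng, 2, channels=2))

    def test_features_separate_low_and_high_pressure_groups(self):
        from shallowbp.pipeline import stack_channels
        from shallowbp.preprocess import preprocess_store
        from shallowbp.synth import SyntheticConfig, generate

        def make(sbp, seed):
            cfg = SyntheticConfig(
                n_records=15, sbp_mean=sbp, sbp_std=3.0, dbp_mean=60.0, dbp_std=3.0,
                seed=seed,
            )
            return generate(cfg)[0]

        lo, hi = make(100.0, 1), make(160.0, 2)
        from shallowbp.segment_io import SegmentStore

        both = SegmentStore(
            [r for r in lo] + [
                type(r)(r.segment_id + "_hi", r.subject_id, r.channels) for r in hi
            ]
        )
        pre = preprocess_store(both)
        X = stack_channels(pre.store, ("PPG",))
        Y = pre.store.channel_matrix("ABP").astype(np.float32)
        m = build_autoencoder(
            UNetConfig(depth=1, width=8, kernel=3, in_channels=1, n_features=16), seed=0
        )
        train_autoencoder(m, X, Y, TrainConfig(batch_size=8, max_epochs=10, patience=10, seed=0))
        F = extract_features(m, X)
        is_hi = np.array(["_hi" in s for s in pre.store.segment_ids()])
        from scipy.spatial.distance import cdist

        d_lo_hi = cdist(F[~is_hi], F[is_hi]).mean()
        d_within = (cdist(F[~is_hi], F[~is_hi]).mean() + cdist(F[is_hi], F[is_hi]).mean()) / 2
        assert d_lo_hi > d_within


class TestSklearnFacade:
    def test_fit_transform_composes(self, rng):
        X, Y = _smooth(rng, 12), _smooth(rng, 12)[:, :, 0]
        est = UNetFeatureExtractor(
            depth=1, width=8, kernel=3, in_channels=1, n_features=16,
            batch_size=4, max_epochs=2, patience=2, random_state=0,
        )
        F = est.fit(X, Y).transform(X)
        assert F.shape == (12, 16)
        assert est.n_features_out_ == 16

    def test_get_params_roundtrip(self):
        est = UNetFeatureExtractor(width=8)
        params = est.get_params()
        est2 = UNetFeatureExtractor(**params)
        assert est2.get_params() == params


class TestCheckpoint:
    def test_save_load_preserves_features(self, rng, tmp_path):
        X, Y = _smooth(rng, 8), _smooth(rng, 8)[:, :, 0]
        m = build_autoencoder(UNetConfig(**TINY), seed=3)
        train_autoencoder(m, X, Y, TrainConfig(batch_size=4, max_epochs=2, patience=2, seed=3))
        path = str(tmp_path / "model.npz")
        m.save(path)
        m2 = ModelHandle.load(path)
        assert m2.config == m.config
        assert np.array_equal(extract_features(m2, X), extract_features(m, X))
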