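"""Landmark heatmaps, divergence losses, decoding, model and training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsareg import _nn
from dsareg.landmark_detection import (
    DecodeMode,
    LossKind,
    TrainingConfig,
    build_model,
    decode_heatmap,
    heatmap_loss,
    kfold_by_source,
    load_model,
    make_target_heatmap,
    normalize_heatmap,
    save_model,
    split_by_source,
    train_landmark_model,
    _loss_and_grad,
)


class TestTargetHeatmap:
    def test_sums_to_one_with_mode_at_point(self):
        g = make_target_heatmap((30.0, 20.0), (64, 64), sigma=3)
        assert g.sum() == pytest.approx(1.0, abs=1e-9)
        r, c = np.unravel_index(g.argmax(), g.shape)
        assert (c, r) == (30, 20)

    def test_gaussian_falloff_ratio(self):
        g = make_target_heatmap((32.0, 32.0), (64, 64), sigma=2)
        assert g[32, 34] / g[32, 32] == pytest.approx(np.exp(-0.5), abs=1e-9)

    def test_center_of_mass_recovers_interior_points(self):
        rng = np.random.default_rng(0)
        sigma = 3.0
        for _ in range(50):
            pt = rng.uniform(4 * sigma, 64 - 1 - 4 * sigma, 2)
            g = make_target_heatmap(tuple(pt), (64, 64), sigma)
            com = decode_heatmap(g, DecodeMode.CENTER_OF_MASS)
            assert np.linalg.norm(np.array(com) - pt) < 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_target_heatmap((5, 5), (32, 32), sigma=0)
        with pytest.raises(ValueError):
            make_target_heatmap((40, 5), (32, 32), sigma=2)


class TestHeatmapLoss:
    def test_zero_for_identical_distributions(self):
        g = make_target_heatmap((10, 10), (32, 32), 2)
        assert heatmap_loss(g, g, "kl") == pytest.approx(0.0, abs=1e-9)
        assert heatmap_loss(g, g, "js") == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_onehots_reach_max_js(self):
        a = np.zeros((8, 8)); a[1, 1] = 1.0
        b = np.zeros((8, 8)); b[6, 6] = 1.0
        assert heatmap_loss(a, b, "js") == pytest.approx(np.log(2), abs=1e-6)

    def test_kl_matches_four_term_hand_sum(self):
        target = np.array([[0.4, 0.1], [0.3, 0.2]])
        pred = np.full((2, 2), 0.25)
        hand = sum(t * np.log(t / 0.25) for t in (0.4, 0.1, 0.3, 0.2))
        assert heatmap_loss(pred, target, "kl") == pytest.approx(hand, abs=1e-12)
        assert heatmap_loss(pred, target, "kl") == pytest.approx(0.1064401, abs=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_js_symmetric_bounded_kl_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((6, 6)); p /= p.sum()
        q = rng.random((6, 6)); q /= q.sum()
        js_pq = heatmap_loss(p, q, "js")
        assert js_pq == pytest.approx(heatmap_loss(q, p, "js"), abs=1e-12)
        assert 0 <= js_pq <= np.log(2) + 1e-12
        assert heatmap_loss(p, q, "kl") >= 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            heatmap_loss(np.ones((2, 2)) / 4, np.ones((3, 3)) / 9)


class TestDecodeHeatmap:
    def test_one_hot_both_modes(self):
        g = np.zeros((20, 20)); g[7, 12] = 1.0
        assert decode_heatmap(g, "argmax") == (12.0, 7.0)
        assert decode_heatmap(g, "center_of_mass") == (12.0, 7.0)

    def test_symmetric_gaussian_subpixel_center(self):
        g = make_target_heatmap((20.5, 20.5), (42, 42), 3)
        com = decode_heatmap(g, "center_of_mass")
        assert com == pytest.approx((20.5, 20.5), abs=0.05)

    def test_bimodal_weighted_mean(self):
        g = np.zeros((40, 40))
        g[10, 10] = 0.6
        g[30, 30] = 0.4
        assert decode_heatmap(g, "argmax") == (10.0, 10.0)
        assert decode_heatmap(g, "center_of_mass") == pytest.approx((18.0, 18.0))

    def test_argmax_tie_breaks_lowest_row_then_column(self):
        g = np.zeros((10, 10))
        g[2, 5] = g[7, 3] = 1.0
        assert decode_heatmap(g, "argmax") == (5.0, 2.0)
        g2 = np.zeros((10, 10))
        g2[4, 8] = g2[4, 1] = 1.0
        assert decode_heatmap(g2, "argmax") == (1.0, 4.0)

    def test_all_zero_map_rejected(self):
        with pytest.raises(ValueError):
            decode_heatmap(np.zeros((5, 5)))

    def test_argmax_and_com_agree_on_unimodal_maps(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pt = rng.uniform(12, 50, 2)
            g = make_target_heatmap(tuple(pt), (64, 64), sigma=2.5)
            am = np.array(decode_heatmap(g, "argmax"))
            com = np.array(decode_heatmap(g, "center_of_mass"))
            assert np.linalg.norm(am - com) <= 1.0


class TestModel:
    def test_forward_shape_range_and_determinism(self):
        cfg = TrainingConfig(depth=3, base_channels=4, image_size=32, seed=12)
        m1 = build_model(cfg)
        m2 = build_model(cfg)
        img = np.random.default_rng(0).random((32, 32))
        maps1 = m1.predict_heatmaps(img)
        maps2 = m2.predict_heatmaps(img)
        assert maps1.shape == (2, 32, 32)
        assert np.all((maps1 > 0) & (maps1 < 1))
        assert np.array_equal(maps1, maps2)

    def test_parameter_count_matches_layer_formula(self):
        cfg = TrainingConfig(depth=3, base_channels=8, image_size=128)
        model = build_model(cfg)

        def conv3(cin, cout):
            return 9 * cin * cout + cout

        ch = [8, 16, 32]
        expected = (
            conv3(1, ch[0]) + conv3(ch[0], ch[0])            # encoder level 0
            + conv3(ch[0], ch[1]) + conv3(ch[1], ch[1])      # encoder level 1
            + conv3(ch[1], ch[2]) + conv3(ch[2], ch[2])      # bottleneck
            + conv3(ch[2] + ch[1], ch[1]) + conv3(ch[1], ch[1])  # decoder level 1
            + conv3(ch[1] + ch[0], ch[0]) + conv3(ch[0], ch[0])  # decoder level 0
            + (ch[0] * 2 + 2)                                # 1x1 head
        )
        assert model.n_params == expected

    def test_bottleneck_collapse_rejected(self):
        with pytest.raises(ValueError, match="collapses"):
            build_model(TrainingConfig(depth=6, base_channels=2, image_size=16))

    def test_backprop_matches_finite_differences(self, monkeypatch):
        """Analytic gradients agree with central differences (float64;
        biases perturbed away from zero to avoid exact ReLU kinks)."""
        monkeypatch.setattr(_nn, "DTYPE", np.float64)
        cfg = TrainingConfig(depth=3, base_channels=2, image_size=16, seed=3)
        model = build_model(cfg)
        rng = np.random.default_rng(0)
        for p in model.parameters():
            if p.ndim == 1:
                p += rng.uniform(0.01, 0.05, p.shape)
        x = rng.random((2, 1, 16, 16))
        t = np.stack([np.stack([make_target_heatmap((3, 4), (16, 16), 1.5),
                                make_target_heatmap((5, 11), (16, 16), 1.5)])] * 2)
        for kind in (LossKind.KL, LossKind.JS):
            logits = model.forward(x)
            _, dz = _loss_and_grad(logits, t, kind)
            model.backward(dz)
            grads = [g.copy() for g in model.gradients()]
            params = model.parameters()
            for pi in range(0, len(params), 3):
                p, g = params[pi], grads[pi]
                idx = tuple(rng.integers(s) for s in p.shape)
                eps, old = 1e-6, p[idx]
                p[idx] = old + eps
                lp, _ = _loss_and_grad(model.forward(x), t, kind)
                p[idx] = old - eps
                lm, _ = _loss_and_grad(model.forward(x), t, kind)
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[idx], rel=1e-4, abs=1e-10)


class TestSplits:
    def test_split_never_shares_source_ids(self):
        src = [f"p{i}" for i in range(20) for _ in range(2)]
        for seed in range(100):
            tr, va = split_by_source(src, 0.25, seed)
            assert len(tr) and len(va)
            assert not (set(np.array(src)[tr]) & set(np.array(src)[va]))

    def test_threefold_cv_is_disjoint_and_covers(self):
        src = [f"p{i}" for i in range(9) for _ in range(2)]
        folds = list(kfold_by_source(src, k=3, seed=0))
        assert len(folds) == 3
        all_val = []
        for tr, va in folds:
            assert not (set(np.array(src)[tr]) & set(np.array(src)[va]))
            all_val.extend(va)
        assert sorted(all_val) == list(range(len(src)))


class TestTraining:
    def test_smoke_run_produces_checkpoint_and_metrics(self, tmp_path):
        rng = np.random.default_rng(0)
        images = rng.random((2, 32, 32))
        landmarks = [{"ICA": (8.0, 8.0), "M1": (20.0, 24.0)}] * 2
        cfg = TrainingConfig(epochs=1, batch_size=1, depth=2, base_channels=2,
                             image_size=32, val_fraction=0.5, seed=0)
        model, metrics = train_landmark_model(images, landmarks, ["a", "b"], cfg)
        assert len(metrics) == 1 and metrics.is_best.iloc[0]
        save_model(model, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        img = rng.random((32, 32))
        assert np.array_equal(back.predict_heatmaps(img), model.predict_heatmaps(img))

    def test_checkpoint_epoch_has_minimal_validation_error(self):
        rng = np.random.default_rng(1)
        images = rng.random((4, 32, 32))
        landmarks = [{"ICA": (8.0, 8.0), "M1": (20.0, 24.0)}] * 4
        cfg = TrainingConfig(epochs=3, batch_size=2, depth=2, base_channels=2,
                             image_size=32, val_fraction=0.5, seed=0)
        _, metrics = train_landmark_model(images, landmarks, list("aabb"), cfg)
        best = metrics[metrics.is_best].val_com_error_px.iloc[0]
        assert best <= metrics.val_com_error_px.min() + 1e-12

    def test_normalize_heatmap_is_distribution(self):
        raw = np.random.default_rng(2).random((16, 16)) * 0.9
        p = normalize_heatmap(raw)
        assert p.sum() == pytest.approx(1.0) and p.min() > 0
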