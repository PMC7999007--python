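import numpy as np
import pytest

from craniomsp.phantom import (
    AngleGrid,
    build_rotation_dataset,
    default_phantom_specs,
)
from craniomsp.rotation_classifier import (
    ClassifierConfig,
    angle_to_label,
    build_classifier,
    label_to_angle,
    load_classifier,
    predict_angles,
    preprocess,
    save_classifier,
    train_classifier,
)
from craniomsp.volume_io import Volume


class TestAngleCodec:
    def test_grid_extremes_and_center(self):
        assert angle_to_label(-5.0).index == 0
        assert angle_to_label(0.0).index == 10
        assert angle_to_label(5.0).index == 20

    def test_codec_round_trips_all_21_values(self):
        grid = AngleGrid()
        for i in range(21):
            deg = label_to_angle(i, grid)
            lab = angle_to_label(deg, grid)
            assert lab.index == i and lab.degrees == deg
            assert deg == -5 + 0.5 * i

    def test_off_grid_angle_rejected_not_rounded(self):
        with pytest.raises(ValueError, match="not on the grid"):
            angle_to_label(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            angle_to_label(5.5)
        with pytest.raises(ValueError):
            label_to_angle(21)


class TestPreprocess:
    def test_output_is_quarter_of_resized_grid(self):
        vol = Volume(np.zeros((64, 64, 40), np.uint8))
        cfg = ClassifierConfig(input_side=32)
        out = preprocess(vol, cfg)
        assert out.shape == (16, 16, 32)

    def test_half_in_plane_quarter_matches_paper_ratio(self):
        # 256-square in-plane, side 128 -> 64x64 quarter
        vol = Volume(np.zeros((256, 256, 8), np.uint8))
        cfg = ClassifierConfig(input_side=128)
        assert preprocess(vol, cfg).shape == (64, 64, 128)

    def test_resize_is_shape_idempotent(self):
        cfg = ClassifierConfig(input_side=32)
        vol = Volume(np.zeros((32, 32, 32), np.uint8))
        once = preprocess(vol, cfg)
        assert once.shape == (16, 16, 32)

    def test_binary_preserved_by_nearest_neighbor(self, small_phantom):
        out = preprocess(small_phantom, ClassifierConfig(input_side=32))
        assert set(np.unique(out.data)) <= {0, 1}

    def test_quarter_is_anterior_left(self):
        data = np.zeros((8, 8, 2), np.uint8)
        data[:4, 4:, :] = 1  # left-anterior quadrant marked
        cfg = ClassifierConfig(input_side=8)
        out = preprocess(Volume(data), cfg)
        assert out.shape == (4, 4, 8)
        assert out.data.all()  # the kept quarter is exactly the marked one

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            preprocess(Volume(np.zeros((1, 4, 4))), ClassifierConfig())


class TestBuildClassifier:
    def test_output_width_is_n_labels(self):
        cfg = ClassifierConfig(input_side=32, n_labels=21)
        model = build_classifier(cfg)
        x = np.zeros((2, 1, 16, 16, 32), np.float32)
        assert model.forward(x).shape == (2, 21)

    def test_two_class_variant(self):
        cfg = ClassifierConfig(input_side=16, n_labels=2)
        model = build_classifier(cfg)
        x = np.zeros((1, 1, 8, 8, 16), np.float32)
        assert model.forward(x).shape == (1, 2)

    def test_construction_deterministic(self):
        cfg = ClassifierConfig(seed=3)
        a, b = build_classifier(cfg), build_classifier(cfg)
        assert a.n_params() == b.n_params()
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.val, pb.val)


def _tiny_dataset(n_angles=3):
    """Coarse-grid dataset from 2 small phantoms (fast to train on)."""
    specs = default_phantom_specs(2, (16, 16, 16), seed=0)
    grid = AngleGrid(-4.0, 4.0, 8.0 / (n_angles - 1))
    return build_rotation_dataset(specs, grid, seed=0), grid


class TestTrainClassifier:
    def test_single_class_dataset_rejected(self, small_spec):
        ds = build_rotation_dataset([small_spec], AngleGrid(0, 0, 0.5))
        cfg = ClassifierConfig(input_side=16, n_labels=1 + 1, epochs=1)
        model = build_classifier(cfg)
        with pytest.raises(ValueError, match="single class"):
            train_classifier(model, ds, "coronal", cfg,
                             grid=AngleGrid(0, 0, 0.5))

    def test_identical_seeds_identical_histories(self):
        ds, grid = _tiny_dataset()
        cfg = ClassifierConfig(input_side=16, n_labels=3, epochs=2,
                               batch_size=16, seed=5, holdout_fraction=0.3)
        runs = []
        for _ in range(2):
            model = build_classifier(cfg)
            tr = train_classifier(model, ds, "coronal", cfg, grid=grid)
            runs.append(tr.accuracy_history)
        assert runs[0] == runs[1]

    def test_plane_selects_label(self):
        ds, grid = _tiny_dataset()
        cfg = ClassifierConfig(input_side=16, n_labels=3, epochs=1,
                               batch_size=16, seed=0, holdout_fraction=0.3)
        cor = train_classifier(build_classifier(cfg), ds, "coronal", cfg,
                               grid=grid)
        tra = train_classifier(build_classifier(cfg), ds, "transverse", cfg,
                               grid=grid)
        assert cor.plane == "coronal" and tra.plane == "transverse"


class TestPredict:
    def _trained_pair(self):
        ds, grid = _tiny_dataset()
        cfg = ClassifierConfig(input_side=16, n_labels=3, epochs=1,
                               batch_size=16, seed=0, holdout_fraction=0.3)
        cor = train_classifier(build_classifier(cfg), ds, "coronal", cfg,
                               grid=grid)
        tra = train_classifier(build_classifier(cfg), ds, "transverse", cfg,
                               grid=grid)
        return cor, tra

    def test_predictions_are_grid_members(self, small_spec):
        cor, tra = self._trained_pair()
        from craniomsp.phantom import render_rotated

        vol = render_rotated(
            default_phantom_specs(1, (16, 16, 16), seed=0)[0], 4.0, -4.0,
            supersample=2,
        )
        c, t = predict_angles(cor, tra, vol)
        assert cor.grid.contains(c) and tra.grid.contains(t)

    def test_wrong_plane_order_rejected(self):
        cor, tra = self._trained_pair()
        with pytest.raises(ValueError, match="coronal, transverse"):
            predict_angles(tra, cor, Volume(np.zeros((16, 16, 16))))

    def test_tie_break_prefers_smaller_angle_magnitude(self):
        from craniomsp.rotation_classifier import _decode

        grid = AngleGrid(-1.0, 1.0, 0.5)  # angles -1,-0.5,0,0.5,1
        logits = np.array([3.0, 1.0, 1.0, 3.0, 0.0])  # tie between -1, 0.5
        assert _decode(logits, grid) == 0.5


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        ds, grid = _tiny_dataset()
        cfg = ClassifierConfig(input_side=16, n_labels=3, epochs=1,
                               batch_size=16, seed=0, holdout_fraction=0.3)
        tr = train_classifier(build_classifier(cfg), ds, "coronal", cfg,
                              grid=grid)
        p = tmp_path / "clf.npz"
        save_classifier(tr, p)
        back = load_classifier(p)
        assert back.plane == tr.plane
        assert back.accuracy_history == tr.accuracy_history
        x = preprocess(ds[0].volume, cfg).data.astype(np.float32)[None, None]
        np.testing.assert_allclose(
            tr.model.forward(x), back.model.forward(x), atol=1e-6
        )
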