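import numpy as np
import pytest

from craniomsp.metrics import dice
from craniomsp.phantom import (
    AngleGrid,
    Deformation,
    PhantomSpec,
    build_rotation_dataset,
    default_phantom_specs,
    make_phantom,
    render_rotated,
    rotate_volume,
)
from craniomsp.volume_io import Volume


class TestPhantomSpec:
    def test_radii_must_fit_grid(self):
        with pytest.raises(ValueError, match="exceed"):
            PhantomSpec(grid_shape=(16, 16, 16), shell_radii=(10, 10, 10),
                        shell_thickness=2)

    def test_scaled_preserves_relative_geometry(self):
        spec = PhantomSpec().scaled((32, 32, 32))
        assert spec.grid_shape == (32, 32, 32)
        assert spec.shell_radii[0] == pytest.approx(12.0)


class TestMakePhantom:
    def test_symmetric_phantom_equals_its_x_reflection(self, small_phantom):
        np.testing.assert_array_equal(
            small_phantom.data, small_phantom.data[::-1]
        )

    def test_deterministic_given_spec_and_seed(self, small_spec):
        a = make_phantom(small_spec, seed=7)
        b = make_phantom(small_spec, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_noise_seed_changes_volume(self, small_spec):
        from dataclasses import replace

        noisy = replace(small_spec, noise_rate=0.05)
        a = make_phantom(noisy, seed=1)
        b = make_phantom(noisy, seed=2)
        assert not np.array_equal(a.data, b.data)

    def test_deformation_breaks_left_right_balance(self, small_spec):
        from dataclasses import replace

        spec = replace(
            small_spec,
            deformation=Deformation(side="left", amplitude_mm=3, extent_mm=8),
        )
        vol = make_phantom(spec, seed=0)
        nx = vol.shape[0]
        left = int(vol.data[: nx // 2].sum())
        right = int(vol.data[nx // 2:].sum())
        assert left > right

    def test_phantom_is_binary(self, small_phantom):
        assert small_phantom.is_mask()


class TestRotateVolume:
    def test_zero_rotation_is_identity(self, small_phantom):
        out = rotate_volume(small_phantom, 0.0, 0.0)
        np.testing.assert_array_equal(out.data, small_phantom.data)

    def test_rotation_round_trip_dice(self):
        # 64-cube shell: rotate +3 then -3 degrees, NN loss only
        x, y, z = np.ogrid[-31.5:32, -31.5:32, -31.5:32]
        r2 = x**2 + y**2 + z**2
        shell = (r2 <= 26**2) & (r2 >= 20**2)
        vol = Volume(shell.astype(np.uint8))
        back = rotate_volume(rotate_volume(vol, 3.0, 0.0), -3.0, 0.0)
        assert dice(vol, back) >= 0.95

    def test_quarter_turn_swaps_bar_axes(self):
        bar = np.zeros((33, 33, 33), np.uint8)
        bar[4:29, 14:19, 14:19] = 1  # elongated along x
        out = rotate_volume(Volume(bar), 0.0, 90.0)
        ext = [np.ptp(np.nonzero(out.data)[i]) for i in range(3)]
        assert ext[1] > ext[0]  # now elongated along y

    def test_preserves_binarity_and_shape(self, small_phantom):
        out = rotate_volume(small_phantom, 2.5, -1.5)
        assert out.is_mask() and out.shape == small_phantom.shape

    def test_non_finite_angle_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            rotate_volume(small_phantom, np.nan, 0.0)


class TestRenderRotated:
    def test_zero_angles_match_make_phantom(self, small_spec):
        a = render_rotated(small_spec, 0.0, 0.0, seed=0)
        b = make_phantom(small_spec, seed=0)
        np.testing.assert_array_equal(a.data, b.data)

    def test_sub_voxel_rotations_are_distinguishable(self, small_spec):
        """Adjacent half-degree classes must differ: the analytic render
        preserves rotation information below the voxel pitch."""
        for cor in (-5.0, -2.0, 0.0, 3.5):
            a = render_rotated(small_spec, cor, 0.0)
            b = render_rotated(small_spec, cor + 0.5, 0.0)
            assert (a.data != b.data).sum() > 0

    def test_rotation_moves_mass_consistently_with_grid_rotation(
        self, small_spec
    ):
        exact = render_rotated(small_spec, 5.0, 0.0)
        resampled = rotate_volume(make_phantom(small_spec), 5.0, 0.0)
        assert dice(exact, resampled) >= 0.85  # thin shell: NN loss


class TestAngleGrid:
    def test_default_has_21_values(self):
        grid = AngleGrid()
        assert len(grid) == 21
        assert grid.angles[0] == -5.0 and grid.angles[-1] == 5.0

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            AngleGrid(-5, 5, 0.3)

    def test_degenerate_grid(self):
        grid = AngleGrid(0, 0, 0.5)
        assert len(grid) == 1


class TestRotationDataset:
    def test_single_base_default_grid_has_441_samples(self, small_phantom):
        ds = build_rotation_dataset([small_phantom], AngleGrid())
        assert len(ds) == 441

    def test_size_formula_exact(self, small_phantom):
        ds = build_rotation_dataset(
            [small_phantom] * 3, AngleGrid(-1, 1, 0.5)
        )
        assert len(ds) == 3 * 5**2

    def test_empty_bases_rejected(self):
        with pytest.raises(ValueError):
            build_rotation_dataset([], AngleGrid())

    def test_degenerate_grid_returns_base(self, small_phantom):
        ds = build_rotation_dataset([small_phantom], AngleGrid(0, 0, 0.5))
        assert len(ds) == 1
        np.testing.assert_array_equal(ds[0].volume.data, small_phantom.data)

    def test_enumeration_order_and_labels(self, small_spec):
        grid = AngleGrid(-0.5, 0.5, 0.5)
        ds = build_rotation_dataset([small_spec], grid)
        pairs = [(s.coronal_deg, s.transverse_deg) for s in ds]
        want = [(c, t) for c in (-0.5, 0.0, 0.5) for t in (-0.5, 0.0, 0.5)]
        assert pairs == want
        cor, tra = ds.labels()
        np.testing.assert_allclose(cor, [p[0] for p in pairs])
        np.testing.assert_allclose(tra, [p[1] for p in pairs])

    def test_spec_bases_render_analytically(self, small_spec):
        ds = build_rotation_dataset([small_spec], AngleGrid(-0.5, 0.5, 0.5))
        ref = render_rotated(small_spec, -0.5, -0.5, soft_edge_mm=0.6)
        np.testing.assert_array_equal(ds[0].volume.data, ref.data)

    def test_partial_volume_render_bounds_and_binary_limit(self, small_spec):
        aa = render_rotated(small_spec, 1.3, -0.7, supersample=2)
        assert aa.data.min() >= 0 and aa.data.max() <= 1
        assert not aa.is_mask()  # boundary voxels carry fractions
        hard = render_rotated(small_spec, 1.3, -0.7)
        # thresholded partial-volume render agrees with the binary render
        agree = ((aa.data >= 0.5) == hard.data.astype(bool)).mean()
        assert agree > 0.98


def test_default_phantom_specs_vary_but_stay_symmetric():
    specs = default_phantom_specs(4, (32, 32, 32), seed=3)
    radii = {s.shell_radii for s in specs}
    assert len(radii) == 4
    for s in specs:
        v = make_phantom(s, seed=0)
        np.testing.assert_array_equal(v.data, v.data[::-1])
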