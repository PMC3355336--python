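"""Class templates, opacity modulation and the compositing projection."""

import numpy as np
import pytest

from chromacube import (
    MSDataset, class_template, modulate_opacity, composite_mass_axis,
    write_template, read_template, ColorSpec,
)
from chromacube.volume_compare import VolumeTemplate, DEFAULT_K

from conftest import make_dataset


def ds_from_cube(cube, sample_id="s"):
    cube = np.asarray(cube, dtype=np.float64)
    r1, r2, m = cube.shape
    return MSDataset(sample_id, 2.0 * np.arange(r1), (2.0 / r2) * np.arange(r2),
                     50 + np.arange(m), cube, 2.0)


class TestClassTemplate:
    def test_identical_datasets_have_zero_variance(self, rng):
        ds = make_dataset(rng, (3, 2, 4))
        t = class_template([ds, ds, ds])
        assert np.all(t.variance_norm == 0)
        assert np.allclose(t.mean, ds.intensity.astype(np.float64))

    def test_single_varying_voxel_normalizes_to_one(self):
        a = np.zeros((2, 2, 2)); a[0, 0, 0] = 2.0
        b = np.zeros((2, 2, 2)); b[0, 0, 0] = 4.0
        t = class_template([ds_from_cube(a), ds_from_cube(b)])
        assert t.variance_norm[0, 0, 0] == 1.0
        assert t.mean[0, 0, 0] == 3.0
        assert np.all(t.variance_norm[t.mean == 0] == 0)

    def test_matches_brute_force_oracle(self, rng):
        cubes = [rng.random((2, 2, 2)) * 10 for _ in range(4)]
        t = class_template([ds_from_cube(c) for c in cubes])
        stack = np.stack(cubes).astype(np.float32).astype(np.float64)
        mean = sum(stack) / 4
        var = sum((c - mean) ** 2 for c in stack) / 4
        assert np.allclose(t.mean, mean, rtol=1e-10)
        assert np.allclose(t.variance_norm, var / var.max(), rtol=1e-10)

    def test_single_dataset_idempotent(self, rng):
        ds = make_dataset(rng, (2, 3, 2))
        t = class_template([ds])
        assert np.array_equal(t.mean, ds.intensity.astype(np.float64))
        assert np.all(t.variance_norm == 0)

    def test_axis_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="axes"):
            class_template([make_dataset(rng, (2, 2, 2)),
                            make_dataset(rng, (3, 2, 2))])


class TestModulateOpacity:
    def test_printed_constant_half(self):
        assert modulate_opacity(1.0, 1.0, DEFAULT_K) == 0.5
        assert DEFAULT_K == 0.5

    def test_zero_variance_is_identity(self):
        for a in (0.0, 0.3, 1.0):
            assert modulate_opacity(a, 0.0, 0.5) == a

    def test_k_zero_is_identity(self):
        assert modulate_opacity(0.7, 1.0, 0.0) == 0.7

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            modulate_opacity(1.0, 1.0, -0.1)

    def test_monotonicity(self):
        vs = np.linspace(0, 1, 11)
        outs = [modulate_opacity(0.8, v, 0.5) for v in vs]
        assert all(b <= a for a, b in zip(outs, outs[1:]))
        als = [modulate_opacity(a, 0.5, 0.5) for a in vs]
        assert all(b >= a for a, b in zip(als, als[1:]))


class TestComposite:
    def _template(self, mean, var=None, k=0.5):
        mean = np.asarray(mean, dtype=np.float64)
        var = np.zeros_like(mean) if var is None else np.asarray(var, dtype=np.float64)
        return VolumeTemplate(mean, var, n=2, k=k)

    def _spec(self, vmax):
        return ColorSpec(domain=(0.0, vmax), scale="linear")

    def test_opaque_single_voxel_shows_its_color(self):
        mean = np.zeros((1, 1, 3))
        mean[0, 0, 1] = 10.0
        t = self._template(mean)
        spec = self._spec(10.0)
        img = composite_mass_axis(t, spec, base_alpha_scale=1.0)
        from chromacube.colormap import map_color
        assert tuple(img[0, 0]) == map_color(10.0, spec)

    def test_all_zero_template_is_background(self):
        t = self._template(np.zeros((2, 2, 3)))
        img = composite_mass_axis(t, self._spec(1.0), background=(7, 8, 9))
        assert np.all(img == np.array([7, 8, 9], dtype=np.uint8))

    def test_over_operator_hand_case(self):
        # two voxels, alpha 0.5 each -> 0.5*C1 + 0.25*C2 + 0.25*bg
        mean = np.array([[[5.0, 10.0]]])
        spec = ColorSpec(domain=(0.0, 10.0), scale="linear",
                         scheme="discrete",
                         bins=[(5.0, (100, 0, 0)), (10.0, (0, 200, 0))])
        img = composite_mass_axis(
            VolumeTemplate(mean, np.zeros_like(mean), n=2, k=0.0),
            spec, base_alpha_scale=0.5)
        # scale_value: 5->0.5, 10->1.0 => alphas 0.25, 0.5; over-operator oracle
        a1, a2 = 0.25, 0.5
        c1, c2 = np.array([100, 0, 0]), np.array([0, 200, 0])
        expect = a1 * c1 + (1 - a1) * a2 * c2  # black background
        assert np.allclose(img[0, 0], np.rint(expect), atol=1.0)

    def test_opaque_front_voxel_hides_back(self):
        mean = np.array([[[10.0, 10.0]]])
        spec = ColorSpec(domain=(0.0, 10.0), scale="linear", scheme="discrete",
                         bins=[(10.0, (50, 60, 70))])
        t = self._template(mean)
        img = composite_mass_axis(t, spec, base_alpha_scale=1.0)
        assert tuple(img[0, 0]) == (50, 60, 70)

    def test_binary_alpha_reduces_to_nearest_opaque_lookup(self, rng):
        # alpha in {0, 1}: the pixel is exactly the first opaque voxel's colour
        mean = (rng.random((4, 3, 6)) > 0.6).astype(np.float64)  # 0 or 1
        spec = ColorSpec(domain=(0.0, 1.0), scale="linear", scheme="discrete",
                         bins=[(0.0, (0, 0, 0)), (1.0, (200, 10, 30))])
        t = self._template(mean)
        img = composite_mass_axis(t, spec, base_alpha_scale=1.0,
                                  background=(1, 2, 3))
        for i in range(4):
            for j in range(3):
                nz = np.nonzero(mean[i, j])[0]
                if nz.size:
                    assert tuple(img[i, j]) == (200, 10, 30)
                else:
                    assert tuple(img[i, j]) == (1, 2, 3)

    def test_invalid_alpha_scale_rejected(self):
        t = self._template(np.zeros((1, 1, 1)))
        with pytest.raises(ValueError):
            composite_mass_axis(t, self._spec(1.0), base_alpha_scale=0.0)


def test_template_omv_round_trip(rng, tmp_path):
    dss = [make_dataset(rng, (3, 2, 4)) for _ in range(3)]
    t = class_template(dss, k=0.4)
    p = tmp_path / "t.omv"
    write_template(t, p)
    back = read_template(p)
    assert back.n == t.n and back.k == t.k
    assert np.allclose(back.mean, t.mean, rtol=1e-6)
    assert np.allclose(back.variance_norm, t.variance_norm, atol=1e-7)
    assert np.array_equal(back.mass_axis, t.mass_axis)
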