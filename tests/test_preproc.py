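import inspect

import numpy as np
import pytest

from eomseg.preproc import (
    PatchSet,
    _target_dims,
    augment,
    resample_isometric,
    resample_labels,
    sample_patches,
    unwindow,
    window_hu,
)
from eomseg.pipeline import preprocess_pair
from eomseg.volume import CTVolume, LabelVolume


def _vol(arr, spacing=(0.5, 0.5), slice_spacing=3.0):
    return CTVolume(np.asarray(arr, dtype=np.float32), spacing, slice_spacing, "t")


class TestWindowing:
    def test_endpoints_and_centre(self):
        v = np.array([[[-75.0, 175.0, 50.0]]])
        out = window_hu(v)
        assert out[0, 0, 0] == 0.0
        assert out[0, 0, 1] == 1.0
        assert out[0, 0, 2] == pytest.approx(0.5)

    def test_clipping(self):
        assert window_hu(np.array(-1000.0)) == 0.0
        assert window_hu(np.array(4000.0)) == 1.0

    def test_monotone_in_hu(self, rng):
        hu = np.sort(rng.uniform(-500, 500, 200))
        out = window_hu(hu)
        assert np.all(np.diff(out) >= 0)

    def test_bad_width(self):
        with pytest.raises(ValueError):
            window_hu(np.zeros(3), width=0)

    def test_unwindow_inverts_inside_window(self, rng):
        hu = rng.uniform(-75, 175, 50)
        assert unwindow(window_hu(hu)) == pytest.approx(hu, abs=1e-3)


class TestResampling:
    def test_dimension_formula(self):
        assert _target_dims((512, 512), (0.5, 0.5), 1.0) == (256, 256)
        assert _target_dims((512, 512), (0.35, 0.35), 1.0) == (179, 179)

    def test_exact_ratio(self):
        vol = _vol(np.zeros((2, 64, 64)), (0.5, 0.5))
        out = resample_isometric(vol, 1.0)
        assert out.voxels.shape == (2, 32, 32)
        assert out.pixel_spacing == (1.0, 1.0)
        assert out.slice_spacing == vol.slice_spacing

    def test_constant_preserved(self):
        vol = _vol(np.full((1, 40, 40), 37.0), (0.4, 0.4))
        out = resample_isometric(vol)
        assert out.voxels == pytest.approx(37.0, abs=1e-4)

    def test_roundtrip_dims_within_one_pixel(self):
        vol = _vol(np.zeros((1, 101, 87)), (0.37, 0.43))
        iso = resample_isometric(vol, 1.0)
        back = resample_isometric(iso, 0.37)  # row spacing
        assert abs(back.voxels.shape[1] - 101) <= 1

    def test_bad_target(self):
        with pytest.raises(ValueError):
            resample_isometric(_vol(np.zeros((1, 8, 8))), -1.0)

    def test_labels_nearest_no_new_values(self):
        lab = np.zeros((1, 40, 40), dtype=np.uint8)
        lab[0, 5:15, 5:15] = 3
        lab[0, 20:30, 20:30] = 7
        lv = LabelVolume(lab, (0.5, 0.5), 3.0)
        out = resample_labels(lv, 1.0)
        assert set(np.unique(out.labels)) <= {0, 3, 7}

    def test_label_area_scaling(self):
        """Upsampling a disk scales pixel count by the squared spacing ratio."""
        r, cx = 12, 32
        yy, xx = np.mgrid[:64, :64]
        disk = ((yy - cx) ** 2 + (xx - cx) ** 2 <= r * r).astype(np.uint8)
        lv = LabelVolume(disk[None], (1.0, 1.0), 3.0)
        out = resample_labels(lv, 0.5)  # 2× upsampling
        n_in = disk.sum()
        n_out = (out.labels > 0).sum()
        perim = 2 * np.pi * r * 2  # in output pixels
        assert abs(n_out - 4 * n_in) <= perim

    def test_single_label_passthrough(self):
        lv = LabelVolume(np.full((1, 20, 20), 5, dtype=np.uint8), (0.5, 0.5), 3.0)
        assert set(np.unique(resample_labels(lv).labels)) == {5}


@pytest.fixture(scope="module")
def pre(phantom_triple):
    vol, lab, _ = phantom_triple
    return preprocess_pair(vol, lab)


class TestPatchSampling:
    def test_half_orbit_half_not(self, pre):
        vol, lab = pre
        ps = sample_patches(vol, lab, 20, seed=0)
        flags = [p["orbit"] for p in ps.provenance]
        assert sum(flags) == 10 and len(flags) == 20

    def test_orbit_patches_contain_muscle(self, pre):
        vol, lab = pre
        ps = sample_patches(vol, lab, 10, seed=1)
        for im, lb, prov in zip(ps.image_patches, ps.label_patches, ps.provenance):
            assert im.shape == lb.shape == (128, 128)
            if prov["orbit"]:
                assert np.any(lb > 0)
            else:
                assert not np.any(lb > 0)

    def test_deterministic_under_seed(self, pre):
        vol, lab = pre
        a = sample_patches(vol, lab, 8, seed=3)
        b = sample_patches(vol, lab, 8, seed=3)
        assert a.provenance == b.provenance

    def test_offsets_stay_inside_volume(self, pre):
        vol, lab = pre
        ps = sample_patches(vol, lab, 12, seed=5)
        _, r, c = vol.voxels.shape
        for p in ps.provenance:
            assert 0 <= p["row"] and p["row"] + 128 <= r
            assert 0 <= p["col"] and p["col"] + 128 <= c

    def test_too_small_volume_rejected(self):
        vol = _vol(np.zeros((1, 64, 64)), (1.0, 1.0))
        lab = LabelVolume(np.zeros((1, 64, 64), np.uint8), (1.0, 1.0), 3.0)
        with pytest.raises(ValueError, match="smaller than patch"):
            sample_patches(vol, lab, 2)


class TestAugment:
    def _patchset(self, rng, n=4):
        ims = [rng.random((32, 32)).astype(np.float32) * 0.5 + 0.25 for _ in range(n)]
        lbs = [rng.integers(0, 3, (32, 32)).astype(np.uint8) for _ in range(n)]
        return PatchSet(ims, lbs, [{"orbit": True}] * n)

    def test_identity_transform(self, rng):
        ps = self._patchset(rng)
        out = augment(ps, seed=0, rotation_deg_range=(0, 0), scale_range=(1, 1), noise_sd_hu=0)
        for a, b in zip(out.image_patches, ps.image_patches):
            assert np.allclose(a, b)
        for a, b in zip(out.label_patches, ps.label_patches):
            assert np.array_equal(a, b)

    def test_label_set_never_grows(self, rng):
        ps = self._patchset(rng)
        out = augment(ps, seed=1)
        for a, b in zip(out.label_patches, ps.label_patches):
            assert set(np.unique(a)) <= set(np.unique(b))

    def test_noise_sd_in_hu(self):
        """Gaussian HU noise on a constant patch has the configured sd."""
        const = np.full((128, 128), 0.5, dtype=np.float32)  # HU 50, window centre
        ps = PatchSet([const], [np.zeros((128, 128), np.uint8)], [{}])
        out = augment(ps, seed=2, rotation_deg_range=(0, 0), scale_range=(1, 1),
                      noise_sd_hu=10.0)
        diff = unwindow(out.image_patches[0]) - unwindow(const)
        assert 8.5 <= diff.std() <= 11.5

    def test_no_flip_parameter_exists(self):
        """Horizontal flipping is prohibited at the interface level."""
        assert not any(
            "flip" in name for name in inspect.signature(augment).parameters
        )

    def test_geometry_preserves_left_right_order(self, rng):
        """A left-bright/right-dark patch stays left-bright under augmentation."""
        im = np.zeros((64, 64), dtype=np.float32)
        im[:, :32] = 0.9
        im[:, 32:] = 0.1
        ps = PatchSet([im], [np.zeros((64, 64), np.uint8)], [{}])
        out = augment(ps, seed=3, noise_sd_hu=0)
        res = out.image_patches[0]
        assert res[:, :24].mean() > res[:, 40:].mean()


def test_patchset_archive_roundtrip(tmp_path, rng):
    from eomseg.preproc import load_patchset, save_patchset

    ims = [rng.random((16, 16)).astype(np.float32) for _ in range(3)]
    lbs = [rng.integers(0, 4, (16, 16)).astype(np.uint8) for _ in range(3)]
    prov = [{"source_id": "t", "slice": i, "row": 0, "col": 0, "orbit": True}
            for i in range(3)]
    ps = PatchSet(ims, lbs, prov)
    save_patchset(ps, tmp_path / "cache", settings={"seed": 5, "patch": 16})
    back = load_patchset(tmp_path / "cache")
    assert len(back) == 3
    assert back.provenance == prov
    for a, b in zip(back.image_patches, ims):
        assert np.array_equal(a, b)
    import json

    manifest = json.loads((tmp_path / "cache.json").read_text())
    assert manifest["settings"]["seed"] == 5
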