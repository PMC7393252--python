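"""Phantom generator (with brute-force rasterization oracle) and NIfTI I/O."""

import numpy as np
import pytest

import autopath as ap
from autopath.data_io import (
    PhantomSpec,
    SpecRanges,
    apply_window,
    read_manifest,
    read_nifti,
    split_sizes,
    write_manifest,
    write_nifti,
)


def _brute_force_ellipsoid_count(shape, center, radii):
    count = 0
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                v = (
                    ((z - center[0]) / radii[0]) ** 2
                    + ((y - center[1]) / radii[1]) ** 2
                    + ((x - center[2]) / radii[2]) ** 2
                )
                if v <= 1.0:
                    count += 1
    return count


def test_ellipsoid_mask_matches_brute_force_rasterization():
    spec = PhantomSpec(shape=(16, 32, 32), n_objects=1, radius_range=(6.0, 6.0),
                       noise_sd=0.0, seed=21)
    case = ap.generate_phantom(spec)
    (obj,) = case.meta["objects"]
    expected = _brute_force_ellipsoid_count((16, 32, 32), obj["center"], obj["radii"])
    assert int(case.mask.sum()) == expected
    assert expected > 0


def test_phantom_is_deterministic_in_seed():
    spec = PhantomSpec(seed=99, object_kind="blob", difficulty=0.5)
    c1, c2 = ap.generate_phantom(spec), ap.generate_phantom(spec)
    np.testing.assert_array_equal(c1.volume.data, c2.volume.data)
    np.testing.assert_array_equal(c1.mask, c2.mask)


def test_no_objects_gives_pure_background():
    spec = PhantomSpec(n_objects=0, noise_sd=0.0, bg_intensity=0.3, seed=1)
    case = ap.generate_phantom(spec)
    assert not case.mask.any()
    np.testing.assert_array_equal(case.volume.data, np.full(spec.shape, 0.3, np.float32))


def test_noiseless_intensities_are_class_means():
    spec = PhantomSpec(noise_sd=0.0, fg_intensity=1.0, bg_intensity=0.0, seed=4)
    case = ap.generate_phantom(spec)
    fg_vals = case.volume.data[case.mask == 1]
    bg_vals = case.volume.data[case.mask == 0]
    assert (fg_vals == 1.0).all() and (bg_vals == 0.0).all()


def test_difficulty_reduces_contrast():
    easy = ap.generate_phantom(PhantomSpec(noise_sd=0.0, difficulty=0.0, seed=4))
    hard = ap.generate_phantom(PhantomSpec(noise_sd=0.0, difficulty=1.0, seed=4))
    assert hard.volume.data.max() < easy.volume.data.max()


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(object_kind="cube")
    with pytest.raises(ValueError):
        PhantomSpec(noise_sd=-1.0)
    with pytest.raises(ValueError):
        PhantomSpec(difficulty=1.5)
    with pytest.raises(ValueError):
        PhantomSpec(fg_intensity=0.0, bg_intensity=0.0)
    with pytest.raises(ValueError):
        ap.generate_phantom(PhantomSpec(shape=(3, 3, 3)))


def test_split_sizes_and_disjointness():
    assert split_sizes(20) == (14, 3, 3)
    assert split_sizes(40) == (28, 6, 6)
    cases = ap.make_dataset(20, seed=3)
    ids = [c.id for c in cases]
    assert len(set(ids)) == 20
    train, val, test = ap.split_cases(cases)
    assert (len(train), len(val), len(test)) == (14, 3, 3)
    assert set(c.id for c in train).isdisjoint(c.id for c in test)


def test_dataset_is_deterministic_in_seed():
    c1 = ap.make_dataset(5, seed=11)
    c2 = ap.make_dataset(5, seed=11)
    for a, b in zip(c1, c2):
        np.testing.assert_array_equal(a.volume.data, b.volume.data)
        assert a.meta["split"] == b.meta["split"]


def test_foreground_fraction_within_geometric_bounds():
    """Monte-Carlo check: fg fraction stays in the range the radius bounds imply."""
    cases = ap.make_dataset(200, seed=17)
    ranges = SpecRanges()
    d, h, w = ranges.shape
    n_vox = d * h * w
    rmin = ranges.radius_range[0]
    # one object at minimal radii (discretization can only shrink it slightly)
    lo = 0.5 * (4 / 3) * np.pi * rmin**3 / n_vox
    # two objects at per-axis caps, ignoring overlap
    rz_hi = min(ranges.radius_range[1], (d - 2) / 2)
    r_hi = min(ranges.radius_range[1], (h - 2) / 2)
    hi = 1.1 * 2 * (4 / 3) * np.pi * rz_hi * r_hi**2 / n_vox
    fracs = np.array([c.mask.mean() for c in cases])
    assert (fracs > lo).all() and (fracs < hi).all()


def test_nifti_roundtrip_is_lossless(tmp_path):
    case = ap.generate_phantom(PhantomSpec(seed=8))
    case.volume.spacing = (2.5, 0.8, 0.8)
    vp, mp = tmp_path / "vol.nii.gz", tmp_path / "mask.nii.gz"
    write_nifti(case, vp, mp)
    back = read_nifti(vp, mp)
    np.testing.assert_array_equal(back.volume.data, case.volume.data)
    np.testing.assert_array_equal(back.mask, case.mask)
    np.testing.assert_allclose(back.volume.spacing, (2.5, 0.8, 0.8), rtol=1e-5)


def test_intensity_windowing_maps_hu_to_unit_interval():
    data = np.array([[-1000.0, -200.0], [250.0, 1000.0]])[None]
    out = apply_window(data)
    np.testing.assert_allclose(out, [[[0.0, 0.0], [1.0, 1.0]]])
    mid = apply_window(np.array([[[25.0]]]))
    np.testing.assert_allclose(mid, 0.5)


def test_windowed_read(tmp_path):
    vol = np.linspace(-1000, 1000, 4 * 8 * 8).reshape(4, 8, 8).astype(np.float32)
    case = ap.Case(id="w", volume=ap.Volume(vol), mask=np.zeros_like(vol, dtype=np.uint8))
    vp = tmp_path / "v.nii.gz"
    write_nifti(case, vp)
    back = read_nifti(vp, window=True)
    assert back.volume.data.min() == 0.0 and back.volume.data.max() == 1.0


def test_2d_file_rejected(tmp_path):
    import nibabel as nib

    path = tmp_path / "flat.nii.gz"
    nib.save(nib.Nifti1Image(np.zeros((4, 4), dtype=np.float32), np.eye(4)), str(path))
    with pytest.raises(ValueError):
        read_nifti(path)


def test_manifest_roundtrip(tmp_path):
    cases = ap.make_dataset(4, seed=2)
    manifest = write_manifest(cases, tmp_path / "data")
    back = read_manifest(manifest)
    assert [c.id for c in back] == [c.id for c in cases]
    assert [c.meta["split"] for c in back] == [c.meta["split"] for c in cases]
    np.testing.assert_array_equal(back[0].volume.data, cases[0].volume.data)


def test_achievable_dice_degrades_with_difficulty():
    """Harder phantoms (lower contrast, rougher boundaries) cap what a fixed
    small model budget can learn: mean held-out Dice over seeds should not
    increase with difficulty."""
    shape = (8, 32, 32)

    def mean_dice(difficulty):
        scores = []
        for seed in (0, 1, 2):
            ranges = SpecRanges(shape=shape, object_kind="blob",
                                difficulty=(difficulty, difficulty))
            cases = ap.make_dataset(16, spec_ranges=ranges, seed=100 + seed)
            train, val, _ = ap.split_cases(cases)
            net = ap.build_backbone(ap.BackboneConfig(depth_variant="tiny-2", seed=seed))
            ap.pretrain_segmenter(net, train, ap.TrainConfig(seed=seed), epochs=8)
            scores.append(ap.evaluate_dice(net, val))
        return float(np.mean(scores))

    d0, d05, d1 = mean_dice(0.0), mean_dice(0.5), mean_dice(1.0)
    assert d0 >= d05 - 0.03
    assert d05 >= d1 - 0.03
    assert d0 > d1
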