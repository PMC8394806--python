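"""Data operations: resize, rotation/translation, augmentation law, manifests."""

import dataclasses
import math

import numpy as np
import pytest

from adenoceph.dataops import (AugmentConfig, ManifestParseError,
                               RoiViolationError, UnsupportedShapeError,
                               augment_dataset, read_manifest, resize_with_landmarks,
                               rotate_sample, split_dataset, translate_sample,
                               write_dataset)
from adenoceph.geometry import LandmarkSet, compute_an
from adenoceph.synth import CephSample, SynthConfig, generate_case


def _sample_with(coords, size=100, image=None):
    img = image if image is not None else np.zeros((size, size), dtype=np.float32)
    lms = LandmarkSet.from_array(coords)
    r = compute_an(lms).ratio
    return CephSample(image=img, landmarks=lms, true_ratio=r,
                      true_label="hypertrophic" if r > 0.6 else "normal", id="t")


def test_resize_scales_landmarks():
    img = np.zeros((2300, 2300), dtype=np.float32)
    s = _sample_with([[1150, 1150], [1150, 500], [1300, 800], [1500, 900]],
                     image=img)
    out = resize_with_landmarks(s, 256)
    assert out.image.shape == (256, 256)
    c = out.landmarks.as_array()
    assert c[0] == pytest.approx([128.0, 128.0], abs=1e-9)
    assert out.true_ratio == s.true_ratio
    assert compute_an(out.landmarks).ratio == pytest.approx(
        compute_an(s.landmarks).ratio, abs=1e-9)


def test_resize_identity_and_errors():
    s = _sample_with([[10, 10], [10, 50], [30, 30], [50, 35]])
    assert resize_with_landmarks(s, 100) is s
    bad = dataclasses.replace(s, image=np.zeros((100, 50), dtype=np.float32))
    with pytest.raises(UnsupportedShapeError):
        resize_with_landmarks(bad, 64)


def test_rotate_zero_is_identity():
    s = _sample_with([[20, 20], [20, 60], [40, 40], [60, 45]])
    out = rotate_sample(s, 0.0)
    assert np.array_equal(out.image, s.image)
    assert np.array_equal(out.landmarks.as_array(), s.landmarks.as_array())


def test_rotate_center_is_fixed_point():
    s = _sample_with([[49.5, 49.5], [20, 60], [40, 40], [60, 45]])
    out = rotate_sample(s, 90.0)
    assert out.landmarks.as_array()[0] == pytest.approx([49.5, 49.5], abs=1e-9)


def test_rotate_matches_rotation_matrix_oracle():
    s = _sample_with([[60, 49.5], [30, 60], [45, 40], [55, 35]])
    angle = 20.0
    out = rotate_sample(s, angle)
    th = math.radians(angle)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    c = np.array([49.5, 49.5])
    expected = (s.landmarks.as_array() - c) @ R.T + c
    assert np.allclose(out.landmarks.as_array(), expected, atol=1e-9)


def test_rotate_moves_image_content_with_landmarks():
    cfg = SynthConfig.scaled(64)
    s = generate_case(cfg, 0.7, np.random.default_rng(0))
    out = rotate_sample(s, 15.0)
    # the bright condyle knob at Ar must follow the landmark
    ar = out.landmarks.Ar
    assert out.image[int(round(ar.y)), int(round(ar.x))] > 0.5


def test_rotate_out_of_bounds_raises():
    s = _sample_with([[98, 95], [20, 60], [40, 40], [60, 45]])
    with pytest.raises(RoiViolationError):
        rotate_sample(s, 20.0)


def test_translate_examples():
    s = _sample_with([[20, 20], [20, 60], [40, 40], [60, 45]],
                     image=np.random.default_rng(0).random((100, 100)).astype(np.float32))
    out = translate_sample(s, 0.0, 0.0)
    assert np.array_equal(out.image, s.image)
    out = translate_sample(s, 10.0, 0.0)
    assert np.allclose(out.landmarks.as_array()[:, 0],
                       s.landmarks.as_array()[:, 0] + 10, atol=1e-9)
    assert np.allclose(out.landmarks.as_array()[:, 1],
                       s.landmarks.as_array()[:, 1], atol=1e-9)
    # vacated pixels are zero-filled
    assert np.all(out.image[:, :9] == 0.0)
    assert compute_an(out.landmarks).ratio == pytest.approx(s.true_ratio, abs=1e-9)


def test_augmentation_count_law(small_dataset):
    cfg = AugmentConfig(axial_shift=3, diagonal_shift=5)
    out = augment_dataset(small_dataset[:3], cfg)
    assert len(out) == 3 * 17
    assert augment_dataset([], cfg) == []
    cfg5 = AugmentConfig(n_rotations=5, axial_shift=3, diagonal_shift=5,
                         include_original=False)
    assert len(augment_dataset(small_dataset[:2], cfg5)) == 2 * (8 + 5)


def test_augmentation_preserves_labels_and_ratio(small_dataset):
    cfg = AugmentConfig(axial_shift=3, diagonal_shift=5)
    for src in small_dataset[:3]:
        for v in augment_dataset([src], cfg):
            assert v.true_label == src.true_label
            assert compute_an(v.landmarks).ratio == pytest.approx(
                src.true_ratio, abs=1e-6)


def test_augmentation_guard_halves_until_valid():
    # landmark 2 px from the right edge: +10 shift must be halved to fit
    s = _sample_with([[97, 50], [30, 60], [45, 40], [55, 35]])
    cfg = AugmentConfig()
    out = augment_dataset([s], cfg)
    assert len(out) == 17
    for v in out:
        c = v.landmarks.as_array()
        assert c.min() >= 0 and c.max() <= 99


def test_augmentation_determinism(small_dataset):
    cfg = AugmentConfig(axial_shift=3, diagonal_shift=5)
    a = augment_dataset(small_dataset[:2], cfg)
    b = augment_dataset(small_dataset[:2], cfg)
    for x, y in zip(a, b):
        assert x.id == y.id
        assert np.array_equal(x.image, y.image)


def test_rotation_angles_evenly_spaced():
    cfg = AugmentConfig()
    assert cfg.rotation_angles() == [-20.0, -15.0, -10.0, -5.0, 5.0, 10.0, 15.0, 20.0]


def test_split_dataset_disjoint(small_dataset):
    split = split_dataset(small_dataset, sizes=(6, 3, 3), seed=0)
    ids = [s.id for part in (split.train, split.validation, split.test) for s in part]
    assert len(ids) == len(set(ids)) == 12
    split2 = split_dataset(small_dataset, sizes=(6, 3, 3), seed=0)
    assert [s.id for s in split2.train] == [s.id for s in split.train]


def test_manifest_round_trip(tmp_path, small_dataset):
    manifest = write_dataset(small_dataset[:10], tmp_path)
    back = read_manifest(manifest)
    assert len(back) == 10
    for orig, rec in zip(small_dataset[:10], back):
        assert rec.id == orig.id and rec.path == orig.path
        assert np.allclose(rec.landmarks.as_array(),
                           orig.landmarks.as_array(), atol=1e-6)
        assert rec.true_ratio == pytest.approx(orig.true_ratio, abs=1e-6)
        assert rec.image.shape == orig.image.shape


def test_manifest_missing_value_names_line(tmp_path, small_dataset):
    manifest = write_dataset(small_dataset[:3], tmp_path)
    lines = manifest.read_text().splitlines()
    cols = lines[2].split(",")
    cols[2] = ""  # blank Ba_x on data line 2 (file line 3)
    lines[2] = ",".join(cols)
    manifest.write_text("\n".join(lines) + "\n")
    with pytest.raises(ManifestParseError, match="line 3.*Ba_x"):
        read_manifest(manifest)


def test_manifest_missing_image_file(tmp_path, small_dataset):
    manifest = write_dataset(small_dataset[:2], tmp_path)
    (tmp_path / "images" / f"{small_dataset[0].id}.png").unlink()
    with pytest.raises(FileNotFoundError):
        read_manifest(manifest)
    # metadata-only read still works
    assert len(read_manifest(manifest, load_images=False)) == 2
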