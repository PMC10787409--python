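"""I/O roundtrips, subject-level split hygiene, threefold augmentation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuffseg import dataio
from cuffseg.errors import FormatError, PairingError, ShapeError, SplitError
from cuffseg.dataio import (Manifest, SplitSpec, augment_threefold, flip_pair,
                            largest_remainder_counts, read_image, read_mask,
                            rotate_pair, split_by_subject, to_model_input,
                            write_image, write_mask)


def make_manifest(subject_slices: dict[str, int]) -> Manifest:
    rows = [{"subject_id": s, "slice_index": i,
             "image_path": f"{s}_{i}.png", "mask_path": f"{s}_{i}_m.png"}
            for s, n in subject_slices.items() for i in range(n)]
    return Manifest(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# PNG I/O
# ---------------------------------------------------------------------------

def test_mask_roundtrip_preserves_binarization(tmp_path, rng):
    mask = (rng.uniform(size=(32, 32)) > 0.7).astype(np.uint8)
    p = tmp_path / "m.png"
    write_mask(p, mask)
    back = read_mask(p)
    np.testing.assert_array_equal(back, mask)
    # on disk the file holds only {0, 255}
    from PIL import Image

    vals = set(np.unique(np.asarray(Image.open(p))))
    assert vals <= {0, 255}


def test_image_roundtrip_and_grayscale_replication(tmp_path, rng):
    img = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
    p = tmp_path / "i.png"
    write_image(p, img)
    np.testing.assert_array_equal(read_image(p), img)

    from PIL import Image

    gray = rng.integers(0, 256, size=(128, 128)).astype(np.uint8)
    gp = tmp_path / "g.png"
    Image.fromarray(gray, mode="L").save(gp, format="PNG")
    arr = read_image(gp)
    assert arr.shape == (128, 128, 3)
    for c in range(3):
        np.testing.assert_array_equal(arr[:, :, c], gray)


def test_mask_mean_equals_foreground_fraction(tmp_path):
    mask = np.zeros((10, 10), dtype=np.uint8)
    mask[:3] = 1
    p = tmp_path / "m.png"
    write_mask(p, mask)
    assert read_mask(p).mean() == pytest.approx(0.3)


def test_non_png_is_rejected(tmp_path, rng):
    from PIL import Image

    p = tmp_path / "x.jpg"
    Image.fromarray(rng.integers(0, 255, (8, 8, 3)).astype(np.uint8)).save(
        p, format="JPEG")
    with pytest.raises(FormatError, match="PNG"):
        read_image(p)
    garbage = tmp_path / "y.png"
    garbage.write_bytes(b"not an image at all")
    with pytest.raises(FormatError):
        read_image(garbage)


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def test_largest_remainder_60_subjects():
    assert largest_remainder_counts(60, (0.70, 0.15, 0.15)) == [42, 9, 9]


def test_largest_remainder_matches_enumeration_oracle():
    """Counts sum to n and each is within 1 of the exact quota."""
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(3, 200))
        raw = rng.uniform(0.05, 1.0, size=3)
        fr = tuple(raw / raw.sum())
        counts = largest_remainder_counts(n, fr)
        assert sum(counts) == n
        for c, f in zip(counts, fr):
            assert abs(c - n * f) < 1.0


def test_split_60_subjects_gives_42_9_9():
    man = make_manifest({f"P{i:02d}": 3 for i in range(60)})
    tr, va, te = split_by_subject(man, SplitSpec(seed=0))
    assert (len(tr.subjects), len(va.subjects), len(te.subjects)) == (42, 9, 9)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(n_subjects=st.integers(3, 40), seed=st.integers(0, 10_000),
       slices=st.integers(1, 4))
def test_no_subject_ever_appears_in_two_splits(n_subjects, seed, slices):
    man = make_manifest({f"P{i}": slices for i in range(n_subjects)})
    try:
        parts = split_by_subject(man, SplitSpec(seed=seed))
    except SplitError:
        assert n_subjects < 3 or min(
            largest_remainder_counts(n_subjects, (0.7, 0.15, 0.15))) == 0
        return
    sets = [set(p.subjects) for p in parts]
    assert sets[0] | sets[1] | sets[2] == set(man.subjects)
    assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) \
        and not (sets[1] & sets[2])
    # slices travel with their subject
    assert sum(len(p) for p in parts) == len(man)


def test_split_is_deterministic():
    man = make_manifest({f"P{i}": 2 for i in range(20)})
    a = split_by_subject(man, SplitSpec(seed=33))
    b = split_by_subject(man, SplitSpec(seed=33))
    for x, y in zip(a, b):
        assert x.rows.equals(y.rows)


def test_split_errors():
    with pytest.raises(SplitError):
        split_by_subject(make_manifest({"A": 2, "B": 2}), SplitSpec())
    with pytest.raises(SplitError):
        SplitSpec(fractions=(0.5, 0.2, 0.2))
    with pytest.raises(SplitError):
        split_by_subject(make_manifest({f"P{i}": 1 for i in range(4)}),
                         SplitSpec(fractions=(0.98, 0.01, 0.01)))


def test_manifest_rejects_duplicates():
    rows = pd.DataFrame([{"subject_id": "A", "slice_index": 0,
                          "image_path": "x", "mask_path": "y"}] * 2)
    with pytest.raises(FormatError):
        Manifest(rows)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _pairs(n, rng, size=12):
    out = []
    for _ in range(n):
        img = rng.integers(0, 256, size=(size, size, 3)).astype(np.uint8)
        mask = (rng.uniform(size=(size, size)) > 0.8).astype(np.uint8)
        out.append((img, mask))
    return out


def test_augmentation_factor_is_exactly_three(rng):
    for n in (1, 7, 200):
        assert len(augment_threefold(_pairs(n, rng))) == 3 * n


def test_corpus_contains_original_rotation_and_both_flips(rng):
    aug = augment_threefold(_pairs(4, rng))
    kinds = {a.transform for a in aug}
    assert kinds == {"original", "rotate90", "hflip", "vflip"}


def test_flip_is_involution(rng):
    img, mask = _pairs(1, rng)[0]
    for axis in ("horizontal", "vertical"):
        i2, m2 = flip_pair(*flip_pair(img, mask, axis), axis)
        np.testing.assert_array_equal(i2, img)
        np.testing.assert_array_equal(m2, mask)


def test_rotation_four_times_is_identity(rng):
    img, mask = _pairs(1, rng)[0]
    i, m = img, mask
    for _ in range(4):
        i, m = rotate_pair(i, m, 90)
    np.testing.assert_array_equal(i, img)
    np.testing.assert_array_equal(m, mask)


def test_transform_equivariance_image_and_mask(rng):
    """The same geometric map is applied to image and mask."""
    pairs = _pairs(6, rng)
    for ap in augment_threefold(pairs):
        src_img, src_mask = pairs[ap.source_index]
        if ap.transform == "original":
            expected = src_mask
        elif ap.transform.startswith("rotate"):
            expected = rotate_pair(src_img, src_mask, 90)[1]
        else:
            axis = "horizontal" if ap.transform == "hflip" else "vertical"
            expected = flip_pair(src_img, src_mask, axis)[1]
        np.testing.assert_array_equal(ap.mask, expected)


def test_arbitrary_angle_keeps_mask_binary(rng):
    img, mask = _pairs(1, rng, size=32)[0]
    ri, rm = rotate_pair(img, mask, 37.0)
    assert set(np.unique(rm)) <= {0, 1}
    assert ri.shape == img.shape and rm.shape == mask.shape


def test_unpaired_input_raises(rng):
    img, mask = _pairs(1, rng)[0]
    with pytest.raises(PairingError):
        augment_threefold([(img, mask[:-2])])


# ---------------------------------------------------------------------------
# model input
# ---------------------------------------------------------------------------

def test_to_model_input_scaling():
    ones = np.full((32, 32, 3), 255, dtype=np.uint8)
    out = to_model_input(ones)
    assert out.shape == (3, 32, 32) and out.dtype == np.float32
    assert (out == 1.0).all()
    assert (to_model_input(np.zeros((32, 32, 3), np.uint8)) == 0.0).all()
    mid = to_model_input(np.full((32, 32, 3), 128, np.uint8))
    assert mid[0, 0, 0] == pytest.approx(128 / 255)


def test_to_model_input_rejects_bad_sizes():
    with pytest.raises(ShapeError, match="32"):
        to_model_input(np.zeros((30, 32, 3), np.uint8))
    with pytest.raises(ShapeError):
        to_model_input(np.zeros((32, 32), np.uint8))
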