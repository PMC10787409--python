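"""Image/mask/manifest I/O, subject-level splitting, threefold augmentation.

The evaluation hygiene rule implemented here is strict: subjects — not
slices — are the unit of the train/validation/test partition, because
slices of one subject are correlated and would otherwise leak between
splits.  Augmentation expands the corpus exactly threefold with geometric
transforms applied identically to image and mask: every input contributes
its original, one rotated copy, and one flipped copy (the flip axis
alternates by sample index so both horizontal and vertical flips occur).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

from .errors import FormatError, PairingError, ShapeError, SplitError

MANIFEST_COLUMNS = ("subject_id", "slice_index", "image_path", "mask_path")


# ---------------------------------------------------------------------------
# image / mask I/O
# ---------------------------------------------------------------------------

def _open_png(path: str | Path) -> Image.Image:
    try:
        img = Image.open(path)
    except FileNotFoundError:
        raise
    except UnidentifiedImageError as e:
        raise FormatError(f"{path}: not a decodable image (expected PNG)") from e
    if img.format != "PNG":
        raise FormatError(f"{path}: expected a PNG file, got {img.format}")
    if img.mode not in ("L", "RGB", "RGBA", "LA", "P"):
        raise FormatError(
            f"{path}: expected an 8-bit grayscale or RGB PNG, got mode {img.mode}")
    return img


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG as (H, W, 3); grayscale files are channel-replicated."""
    img = _open_png(path)
    if img.mode != "RGB":
        if img.mode in ("RGBA", "LA", "P"):
            img = img.convert("RGB")
        else:
            arr = np.asarray(img, dtype=np.uint8)
            return np.repeat(arr[:, :, None], 3, axis=2)
    return np.asarray(img, dtype=np.uint8)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG as binary (H, W); pixels >= 128 count as foreground."""
    img = _open_png(path)
    arr = np.asarray(img.convert("L"), dtype=np.uint8)
    return (arr >= 128).astype(np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    image = np.asarray(image, dtype=np.uint8)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ShapeError(f"image must be (H, W, 3) uint8, got {image.shape}")
    Image.fromarray(image, mode="RGB").save(path, format="PNG")


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ShapeError(f"mask must be (H, W), got {mask.shape}")
    Image.fromarray((mask > 0).astype(np.uint8) * 255, mode="L").save(
        path, format="PNG")


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

@dataclass
class Manifest:
    """Table of (subject_id, slice_index, image_path, mask_path) rows."""

    rows: pd.DataFrame

    def __post_init__(self):
        df = self.rows
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        if df.duplicated(subset=["subject_id", "slice_index"]).any():
            raise FormatError("manifest has duplicate (subject_id, slice_index) rows")
        self.rows = df.reset_index(drop=True)

    def __len__(self):
        return len(self.rows)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.rows["subject_id"].unique())

    def validate_paths(self) -> None:
        for col in ("image_path", "mask_path"):
            for p in self.rows[col]:
                if not Path(p).exists():
                    raise FormatError(f"manifest path does not exist: {p}")

    @classmethod
    def read_csv(cls, path: str | Path) -> "Manifest":
        return cls(pd.read_csv(path, dtype={"subject_id": str}))

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test fractions plus the shuffle seed."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self):
        fr = tuple(float(f) for f in self.fractions)
        if any(f < 0 or f > 1 for f in fr):
            raise SplitError(f"each fraction must lie in [0, 1], got {fr}")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise SplitError(f"fractions must sum to 1, got {sum(fr)}")
        object.__setattr__(self, "fractions", fr)


def largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Apportion ``n`` items to fractions by largest-remainder rounding."""
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def split_by_subject(manifest: Manifest, spec: SplitSpec
                     ) -> tuple[Manifest, Manifest, Manifest]:
    """Partition a manifest into train/val/test with subjects kept whole."""
    subjects = manifest.subjects
    if len(subjects) < 3:
        raise SplitError(
            f"need at least 3 subjects to split, got {len(subjects)}")
    rng = np.random.default_rng(spec.seed)
    shuffled = [subjects[i] for i in rng.permutation(len(subjects))]
    counts = largest_remainder_counts(len(subjects), spec.fractions)
    if any(c == 0 for c in counts):
        raise SplitError(
            f"a split would be empty under fractions {spec.fractions} with "
            f"{len(subjects)} subjects; use more subjects")
    bounds = np.cumsum([0] + counts)
    parts = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        chosen = set(shuffled[lo:hi])
        sub = manifest.rows[manifest.rows["subject_id"].isin(chosen)]
        parts.append(Manifest(sub.copy()))
    return tuple(parts)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def rotate_pair(image: np.ndarray, mask: np.ndarray, degrees: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """Rotate image and mask by the same angle (counter-clockwise).

    Multiples of 90 degrees are exact array rotations; arbitrary angles use
    bilinear resampling for the image and nearest-neighbour for the mask so
    the mask stays binary.
    """
    if degrees % 90 == 0:
        k = int(degrees // 90) % 4
        return np.rot90(image, k, axes=(0, 1)).copy(), np.rot90(mask, k).copy()
    img = ndimage.rotate(image, degrees, axes=(1, 0), reshape=False,
                         order=1, mode="constant", cval=0)
    msk = ndimage.rotate(mask, degrees, axes=(1, 0), reshape=False,
                         order=0, mode="constant", cval=0)
    return img.astype(image.dtype), (msk > 0).astype(mask.dtype)


def flip_pair(image: np.ndarray, mask: np.ndarray, axis: str
              ) -> tuple[np.ndarray, np.ndarray]:
    """Mirror image and mask; ``axis`` is "horizontal" or "vertical"."""
    if axis == "horizontal":           # mirror left-right
        return image[:, ::-1].copy(), mask[:, ::-1].copy()
    if axis == "vertical":             # mirror top-bottom
        return image[::-1].copy(), mask[::-1].copy()
    raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


@dataclass
class AugmentedPair:
    image: np.ndarray
    mask: np.ndarray
    source_index: int
    transform: str                      # "original" | "rotate<deg>" | "hflip" | "vflip"


def augment_threefold(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                      rotation_deg: float = 90.0) -> list[AugmentedPair]:
    """Expand a paired corpus exactly threefold.

    Per input pair the output holds the original, one rotated copy, and one
    flipped copy; the flip axis alternates with the sample index so both
    horizontal and vertical flips occur across the corpus.
    """
    out: list[AugmentedPair] = []
    for i, pair in enumerate(pairs):
        if len(pair) != 2:
            raise PairingError(f"entry {i} is not an (image, mask) pair")
        image, mask = pair
        if image.shape[:2] != mask.shape[:2]:
            raise PairingError(
                f"entry {i}: image {image.shape[:2]} and mask "
                f"{mask.shape[:2]} sizes differ")
        out.append(AugmentedPair(image, mask, i, "original"))
        rimg, rmsk = rotate_pair(image, mask, rotation_deg)
        out.append(AugmentedPair(rimg, rmsk, i, f"rotate{rotation_deg:g}"))
        axis = "horizontal" if i % 2 == 0 else "vertical"
        fimg, fmsk = flip_pair(image, mask, axis)
        out.append(AugmentedPair(fimg, fmsk, i, axis[0] + "flip"))
    return out


# ---------------------------------------------------------------------------
# model input conversion
# ---------------------------------------------------------------------------

def to_model_input(image: np.ndarray) -> np.ndarray:
    """8-bit (H, W, 3) -> float32 (3, H, W) scaled to [0, 1]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ShapeError(f"expected an (H, W, 3) image, got {image.shape}")
    h, w = image.shape[:2]
    if h % 32 or w % 32:
        raise ShapeError(
            f"input size {h} x {w} is not divisible by 32 (encoder stride law)")
    return (image.astype(np.float32) / 255.0).transpose(2, 0, 1)
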