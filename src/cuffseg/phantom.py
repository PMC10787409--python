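"""Synthetic shoulder-MRI-like phantoms with exact ground-truth masks.

Real supraspinatus MRI datasets are private clinical data, so the pipeline
is exercised on generated phantoms that reproduce the properties that make
the segmentation problem hard: a single elongated, crescent-shaped target
(the muscle-tendon unit seen in an oblique-coronal slice), nearby distractor
structures whose intensities sit close to the target's (adjacent muscles
have similar grayscale on MRI), additive noise, and a handful of correlated
slices per subject.

Determinism contract: a fixed ``(PhantomConfig, seed)`` pair yields a
byte-identical dataset.  Geometry and intensity are drawn from independent
seeded streams, so changing a pure-intensity knob (``contrast``,
``noise_sigma``) never moves the geometry — a property the difficulty
monotonicity tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, DataError

#: 4-connectivity structuring element for component labelling
FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

_GEOMETRY_RETRIES = 200


@dataclass(frozen=True)
class PhantomConfig:
    """Knobs of the phantom generator.

    ``contrast`` is the mean 8-bit intensity gap between the target and the
    distractor structures; small values emulate the near-identical grayscale
    of adjacent muscles.  ``target_area_frac`` bounds the mask area as a
    fraction of the image.
    """

    image_size: int = 512
    target_area_frac: tuple[float, float] = (0.02, 0.10)
    contrast: float = 25.0
    noise_sigma: float = 8.0
    n_distractors: int = 3
    slices_per_subject: tuple[int, int] = (3, 5)
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32 or self.image_size % 32:
            raise ConfigurationError(
                f"image_size must be >= 32 and divisible by 32 (the encoder "
                f"downsamples by a total stride of 32), got {self.image_size}")
        lo, hi = self.target_area_frac
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(
                f"target_area_frac must satisfy 0 < low <= high < 1, got {lo}, {hi}")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be non-negative")
        if self.n_distractors < 0:
            raise ConfigurationError("n_distractors must be non-negative")
        slo, shi = self.slices_per_subject
        if not (1 <= slo <= shi):
            raise ConfigurationError(
                f"slices_per_subject must be an increasing range >= 1, got {slo}, {shi}")


@dataclass
class PhantomSample:
    """One synthetic slice: 8-bit RGB image, binary mask, provenance tags."""

    image: np.ndarray            # (H, W, 3) uint8
    mask: np.ndarray             # (H, W) uint8 in {0, 1}
    subject_id: str
    slice_index: int


@dataclass
class PhantomDataset:
    samples: list[PhantomSample]
    manifest: pd.DataFrame       # subject_id, slice_index, image_path, mask_path

    def __len__(self):
        return len(self.samples)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _ellipse_mask(size: int, cx: float, cy: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _crescent_mask(size: int, p: dict) -> np.ndarray:
    """Crescent = outer filled ellipse minus an offset carving ellipse."""
    outer = _ellipse_mask(size, p["cx"], p["cy"], p["a"], p["b"], p["theta"])
    # the carving ellipse is offset along the outer ellipse's minor axis
    ox = p["cx"] - np.sin(p["theta"]) * p["carve_shift"]
    oy = p["cy"] + np.cos(p["theta"]) * p["carve_shift"]
    carve = _ellipse_mask(size, ox, oy, p["a"] * p["carve_ax"],
                          p["b"] * p["carve_bx"], p["theta"])
    return outer & ~carve


def _is_valid_mask(mask: np.ndarray, frac_lo: float, frac_hi: float) -> bool:
    area = int(mask.sum())
    frac = area / mask.size
    if not (frac_lo <= frac <= frac_hi):
        return False
    _, n = ndimage.label(mask, structure=FOUR_CONNECTED)
    return n == 1


def _draw_base_geometry(size: int, cfg: PhantomConfig,
                        rng: np.random.Generator) -> dict:
    """Sample crescent parameters until the mask invariants hold."""
    lo, hi = cfg.target_area_frac
    mid = np.sqrt(lo * hi)
    for _ in range(_GEOMETRY_RETRIES):
        a = size * rng.uniform(0.24, 0.34)
        b = a * rng.uniform(0.32, 0.48)
        p = {
            "cx": size * rng.uniform(0.42, 0.58),
            "cy": size * rng.uniform(0.42, 0.58),
            "a": a,
            "b": b,
            "theta": rng.uniform(-0.26, 0.26),   # roughly horizontal course
            "carve_shift": b * rng.uniform(0.55, 0.95),
            "carve_ax": rng.uniform(0.92, 1.08),
            "carve_bx": rng.uniform(0.95, 1.30),
        }
        mask = _crescent_mask(size, p)
        area = mask.sum()
        if area:
            # rescale axes toward the middle of the allowed area band
            scale = float(np.sqrt(mid * mask.size / area))
            scale = float(np.clip(scale, 0.5, 2.0))
            p["a"] *= scale
            p["b"] *= scale
            p["carve_shift"] *= scale
            mask = _crescent_mask(size, p)
        if _is_valid_mask(mask, lo, hi):
            return p
    raise DataError("could not sample a valid crescent geometry; "
                    "loosen target_area_frac")


def _perturb_geometry(base: dict, size: int, cfg: PhantomConfig,
                      rng: np.random.Generator) -> dict:
    """Slice-level jitter of the shared subject geometry."""
    lo, hi = cfg.target_area_frac
    for _ in range(_GEOMETRY_RETRIES):
        s = rng.uniform(0.94, 1.06)
        p = dict(base)
        p["cx"] = base["cx"] + size * rng.uniform(-0.02, 0.02)
        p["cy"] = base["cy"] + size * rng.uniform(-0.02, 0.02)
        p["a"] = base["a"] * s
        p["b"] = base["b"] * s
        p["carve_shift"] = base["carve_shift"] * s
        p["theta"] = base["theta"] + rng.uniform(-0.05, 0.05)
        if _is_valid_mask(_crescent_mask(size, p), lo, hi):
            return p
    return dict(base)  # jitter kept failing: fall back to the base shape


def _distractor_geometries(mask: np.ndarray, size: int, n: int,
                           rng: np.random.Generator) -> list[dict]:
    """Elliptic distractors; the first one abuts the target boundary."""
    out = []
    if n == 0:
        return out
    boundary = mask & ~ndimage.binary_erosion(mask)
    ys, xs = np.nonzero(boundary)
    for k in range(n):
        a = size * rng.uniform(0.05, 0.11)
        b = a * rng.uniform(0.45, 0.9)
        theta = rng.uniform(0, np.pi)
        if k == 0 and len(xs):
            i = rng.integers(len(xs))
            cx, cy = float(xs[i]), float(ys[i])   # centred on the boundary
        else:
            cx = size * rng.uniform(0.1, 0.9)
            cy = size * rng.uniform(0.1, 0.9)
        out.append({"cx": cx, "cy": cy, "a": a, "b": b, "theta": theta})
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_BACKGROUND_MEAN = 45.0


def _render(mask: np.ndarray, distractors: list[dict], size: int,
            cfg: PhantomConfig, t_mean: float, smooth_field: np.ndarray,
            noise_field: np.ndarray, distractor_units: np.ndarray,
            channel_jitter: np.ndarray) -> np.ndarray:
    """Compose the 8-bit image from pre-drawn unit variates.

    All randomness enters through the pre-drawn arguments, so intensity
    knobs (contrast, noise_sigma) act purely arithmetically: at a fixed
    seed, lowering ``contrast`` moves distractor pixels monotonically
    toward the target intensity and changes nothing else.
    """
    bg_amp = min(10.0, 2.0 * cfg.noise_sigma)
    img = _BACKGROUND_MEAN + bg_amp * smooth_field
    for d, u in zip(distractors, distractor_units):
        dmask = _ellipse_mask(size, d["cx"], d["cy"], d["a"], d["b"], d["theta"])
        dmask &= ~mask.astype(bool)              # never overwrite the target
        img[dmask] = t_mean - (0.4 + 0.6 * u) * cfg.contrast
    img[mask.astype(bool)] = t_mean
    img = img + cfg.noise_sigma * noise_field
    gray = np.clip(img, 0, 255)
    chans = [np.clip(gray + j, 0, 255) for j in channel_jitter]
    return np.rint(np.stack(chans, axis=-1)).astype(np.uint8)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_subject(config: PhantomConfig, subject_id: str,
                     rng: np.random.Generator) -> list[PhantomSample]:
    """Generate all slices of one synthetic subject.

    Slices share a base crescent geometry with per-slice shift/scale/angle
    jitter, so intra-subject correlation exists — the reason splits must be
    made at the subject level.
    """
    size = config.image_size
    # independent streams: geometry may reject-and-retry, intensity may not
    geom_rng, intensity_rng = rng.spawn(2)
    n_slices = int(geom_rng.integers(config.slices_per_subject[0],
                                     config.slices_per_subject[1] + 1))
    base = _draw_base_geometry(size, config, geom_rng)
    t_mean = float(np.clip(intensity_rng.normal(165.0, 10.0), 145.0, 190.0))
    samples = []
    for idx in range(n_slices):
        p = base if idx == 0 else _perturb_geometry(base, size, config, geom_rng)
        mask = _crescent_mask(size, p).astype(np.uint8)
        distractors = _distractor_geometries(mask.astype(bool), size,
                                             config.n_distractors, geom_rng)
        smooth = ndimage.gaussian_filter(
            intensity_rng.standard_normal((size, size)), sigma=size / 8.0)
        smooth /= max(np.abs(smooth).max(), 1e-9)
        noise = intensity_rng.standard_normal((size, size))
        d_units = intensity_rng.uniform(0.0, 1.0, size=max(config.n_distractors, 1))
        jitter = intensity_rng.uniform(-2.0, 2.0, size=3)
        slice_t_mean = t_mean + float(intensity_rng.uniform(-4.0, 4.0))
        image = _render(mask, distractors, size, config, slice_t_mean,
                        smooth, noise, d_units, jitter)
        samples.append(PhantomSample(image=image, mask=mask,
                                     subject_id=subject_id, slice_index=idx))
    return samples


def generate_dataset(config: PhantomConfig, n_subjects: int) -> PhantomDataset:
    """Generate ``n_subjects`` independent subjects plus a manifest."""
    if n_subjects < 1:
        raise DataError(f"n_subjects must be >= 1, got {n_subjects}")
    samples: list[PhantomSample] = []
    rows = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        rng = np.random.default_rng([config.seed, i])
        for s in generate_subject(config, sid, rng):
            samples.append(s)
            rows.append({
                "subject_id": sid,
                "slice_index": s.slice_index,
                "image_path": f"images/{sid}_{s.slice_index:02d}.png",
                "mask_path": f"masks/{sid}_{s.slice_index:02d}.png",
            })
    return PhantomDataset(samples=samples, manifest=pd.DataFrame(rows))


def write_dataset(dataset: PhantomDataset, out_dir: str | Path) -> Path:
    """Materialise a dataset: RGB PNG images, {0,255} mask PNGs, CSV manifest."""
    from . import dataio

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for s, row in zip(dataset.samples, dataset.manifest.itertuples(index=False)):
        dataio.write_image(out / row.image_path, s.image)
        dataio.write_mask(out / row.mask_path, s.mask)
    manifest = dataset.manifest.copy()
    manifest["image_path"] = [str(out / p) for p in manifest["image_path"]]
    manifest["mask_path"] = [str(out / p) for p in manifest["mask_path"]]
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
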