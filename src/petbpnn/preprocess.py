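"""Image preparation: autocrop, bilinear resize, APPN block averaging.

The preparation pipeline turns a raw grayscale slice into a fixed-length
vector of normalized block means ("average pixel per node"):

1. ``autocrop``  — remove the surrounding black frame (minimal bounding box
   of pixels above ``crop_threshold * max``).
2. ``resize``    — bilinear interpolation onto a ``target_size``-square grid,
   using the corner-aligned sampling convention (output pixel ``i`` samples
   source coordinate ``i * (n - 1) / (target_size - 1)``).
3. ``appn``      — partition into non-overlapping ``segment_size``-square
   blocks in row-major order (top-left block first) and take each block's
   arithmetic mean, divided by the nominal intensity maximum so every
   feature lies in [0, 1].

With the defaults (200-pixel grid, 10-pixel segments) the result is a
400-element feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ShapeError, ValidationError
from .image_io import Manifest, RawImage, load_image

__all__ = [
    "PrepConfig",
    "FeatureVector",
    "autocrop",
    "resize",
    "appn",
    "prepare",
    "prepare_images",
]


@dataclass
class PrepConfig:
    """Parameters of the image-preparation phase.

    ``intensity_max`` overrides the normalization denominator; when ``None``
    the per-image nominal bit-depth maximum is used if known, otherwise the
    image's own maximum (callers working with float data should supply the
    dataset-wide maximum to preserve between-image uptake differences).
    """

    target_size: int = 200
    segment_size: int = 10
    crop_threshold: float = 0.0
    intensity_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.target_size < 1 or self.segment_size < 1:
            raise ValidationError("target_size and segment_size must be >= 1")
        if self.target_size % self.segment_size != 0:
            raise ValidationError(
                f"target_size {self.target_size} not divisible by "
                f"segment_size {self.segment_size}"
            )
        if not 0.0 <= self.crop_threshold < 1.0:
            raise ValidationError("crop_threshold must lie in [0, 1)")

    @property
    def n_features(self) -> int:
        return (self.target_size // self.segment_size) ** 2


@dataclass
class FeatureVector:
    """Ordered normalized block means; the network's input pattern."""

    values: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()

    def __len__(self) -> int:
        return self.values.size


def autocrop(img: RawImage, crop_threshold: float = 0.0) -> RawImage:
    """Crop to the minimal bounding box of pixels above ``crop_threshold * max``."""
    thr = crop_threshold * float(img.pixels.max())
    mask = img.pixels > thr
    if not mask.any():
        raise DegenerateInputError(
            f"image {img.source_id!r} has no pixel above threshold {thr}"
        )
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    cropped = img.pixels[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    return RawImage(cropped, source_id=img.source_id, nominal_max=img.nominal_max)


def _resize2d(a: np.ndarray, target: int) -> np.ndarray:
    # separable bilinear interpolation, corner-aligned
    def coords(n: int) -> np.ndarray:
        return np.linspace(0.0, n - 1.0, target)

    r = coords(a.shape[0])
    c = coords(a.shape[1])
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, a.shape[0] - 1)
    c1 = np.minimum(c0 + 1, a.shape[1] - 1)
    fr = (r - r0)[:, None]
    fc = (c - c0)[None, :]
    rows = a[r0, :] * (1.0 - fr) + a[r1, :] * fr
    return rows[:, c0] * (1.0 - fc) + rows[:, c1] * fc


def resize(img: RawImage, target_size: int) -> RawImage:
    """Bilinear resize onto a ``target_size``-square grid."""
    if target_size < 1:
        raise ValueError(f"target_size must be >= 1, got {target_size}")
    out = _resize2d(img.pixels, target_size)
    # interpolation is a convex combination; clip off float round-off only
    out = np.clip(out, img.pixels.min(), img.pixels.max())
    return RawImage(out, source_id=img.source_id, nominal_max=img.nominal_max)


def appn(
    img: RawImage,
    segment_size: int,
    intensity_max: Optional[float] = None,
) -> FeatureVector:
    """Block means over non-overlapping square segments, normalized to [0, 1].

    Blocks are taken in row-major order.  The normalization denominator is,
    in order of precedence: ``intensity_max``, the image's ``nominal_max``,
    the image's own maximum intensity.
    """
    h, w = img.pixels.shape
    if h != w:
        raise ShapeError(f"appn requires a square image, got {h}x{w}")
    if h % segment_size != 0:
        raise ShapeError(
            f"image side {h} not divisible by segment_size {segment_size}"
        )
    n = h // segment_size
    means = img.pixels.reshape(n, segment_size, n, segment_size).mean(axis=(1, 3))
    denom = intensity_max
    if denom is None:
        denom = img.nominal_max
    if denom is None:
        denom = float(img.pixels.max())
    if denom <= 0:
        denom = 1.0
    values = np.clip(means.ravel() / denom, 0.0, 1.0)
    return FeatureVector(values, source_id=img.source_id)


def prepare(img: RawImage, cfg: PrepConfig) -> FeatureVector:
    """Full preparation: autocrop -> resize -> appn.  Deterministic."""
    cropped = autocrop(img, cfg.crop_threshold)
    resized = resize(cropped, cfg.target_size)
    return appn(resized, cfg.segment_size, intensity_max=cfg.intensity_max)


def prepare_images(
    images: Iterable[tuple[str, str, RawImage]],
    cfg: PrepConfig,
) -> pd.DataFrame:
    """Prepare a labelled collection of in-memory images into a feature table.

    ``images`` yields ``(source_id, label, RawImage)``.  When
    ``cfg.intensity_max`` is unset and any image lacks a nominal bit-depth
    maximum, the dataset-wide intensity maximum is used as the shared
    normalization denominator so that between-image contrast is preserved.

    Returns a DataFrame with columns ``source_id, label, f000..fNNN``.
    """
    items = list(images)
    cfg_max = cfg.intensity_max
    if cfg_max is None and any(im.nominal_max is None for _, _, im in items):
        cfg_max = max(float(im.pixels.max()) for _, _, im in items)
    rows = []
    for source_id, label, im in items:
        fv = prepare(
            im,
            PrepConfig(
                target_size=cfg.target_size,
                segment_size=cfg.segment_size,
                crop_threshold=cfg.crop_threshold,
                intensity_max=cfg_max,
            ),
        )
        rows.append((source_id, label, fv.values))
    n_feat = cfg.n_features
    cols = [f"f{i:03d}" for i in range(n_feat)]
    data = pd.DataFrame(
        [list(v) for _, _, v in rows], columns=cols, dtype=np.float64
    )
    data.insert(0, "label", [label for _, label, _ in rows])
    data.insert(0, "source_id", [sid for sid, _, _ in rows])
    return data


def prepare_manifest(manifest: Manifest, cfg: PrepConfig) -> pd.DataFrame:
    """Load every manifest entry from disk and prepare it (see prepare_images)."""
    images = [
        (e.source_id, e.label, load_image(e.path)) for e in manifest.entries
    ]
    return prepare_images(images, cfg)
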