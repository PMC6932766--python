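"""Synthetic amyloid-PET-like phantom slices.

Each phantom is an elliptical "brain" on a black frame: a high-uptake
interior core surrounded by a cortical rim band whose uptake rises with
disease class (NC baseline, then graded increments for SMC < EMCI < LMCI <
AD, expressed as fractions of the core-rim contrast).  The slice is blurred
with a Gaussian kernel of configurable FWHM (emulating the uniform-resolution
filtering applied upstream to real PET data) and Gaussian noise is added
inside the brain support afterwards, clipped at zero.  Position and size are
randomly jittered per image.

Only the relative rim/core contrast is calibrated; absolute intensities are
arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ValidationError
from .image_io import CLASS_LABELS, Manifest, ManifestEntry, RawImage, save_image, save_manifest

__all__ = ["PhantomConfig", "generate_phantom", "generate_images", "generate_dataset"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Default per-class rim-uptake increments as fractions of core-rim contrast.
DEFAULT_EFFECT_SIZES = {"SMC": 0.05, "EMCI": 0.12, "LMCI": 0.30, "AD": 0.60}


@dataclass
class PhantomConfig:
    image_size: int = 256
    brain_axes: tuple[float, float] = (0.30, 0.36)  # semi-axes / image_size (rows, cols)
    rim_width: float = 0.18  # rim band thickness as fraction of the semi-axes
    core_uptake: float = 1.0
    rim_uptake_nc: float = 0.35
    effect_size: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    noise_sigma: float = 0.08
    smooth_fwhm_px: float = 8.0
    jitter: float = 0.05  # max relative translation / scale perturbation
    n_per_class: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValidationError("image_size must be >= 16")
        if not 0.0 < self.rim_uptake_nc < self.core_uptake:
            raise ValidationError("need 0 < rim_uptake_nc < core_uptake")
        if not 0.0 < self.rim_width < 1.0:
            raise ValidationError("rim_width must lie in (0, 1)")
        order = ("SMC", "EMCI", "LMCI", "AD")
        missing = [c for c in order if c not in self.effect_size]
        if missing:
            raise ValidationError(f"effect_size missing classes: {missing}")
        vals = [self.effect_size[c] for c in order]
        if any(v < 0 for v in vals) or any(a > b for a, b in zip(vals, vals[1:])):
            raise ValidationError(
                "effect sizes must be >= 0 and monotone over SMC <= EMCI <= LMCI <= AD"
            )
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.smooth_fwhm_px < 0 or self.jitter < 0:
            raise ValidationError("smooth_fwhm_px and jitter must be >= 0")
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")

    def rim_uptake(self, cls: str) -> float:
        """Rim intensity for a class: NC baseline plus its graded increment."""
        if cls not in CLASS_LABELS:
            raise ValidationError(f"unknown class label {cls!r}")
        effect = 0.0 if cls == "NC" else self.effect_size[cls]
        return self.rim_uptake_nc + effect * (self.core_uptake - self.rim_uptake_nc)


def generate_phantom(
    cls: str, cfg: PhantomConfig, rng: int | np.random.Generator = 0
) -> RawImage:
    """One phantom slice for a class; deterministic given the rng seed."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = cfg.image_size
    j = cfg.jitter
    cy = n / 2.0 + rng.uniform(-j, j) * n
    cx = n / 2.0 + rng.uniform(-j, j) * n
    scale = 1.0 + rng.uniform(-j, j)
    a = cfg.brain_axes[0] * n * scale
    b = cfg.brain_axes[1] * n * scale

    yy, xx = np.mgrid[0:n, 0:n]
    r2 = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2
    inner = (1.0 - cfg.rim_width) ** 2
    img = np.zeros((n, n))
    img[r2 <= 1.0] = cfg.rim_uptake(cls)
    img[r2 <= inner] = cfg.core_uptake

    if cfg.smooth_fwhm_px > 0:
        img = gaussian_filter(img, sigma=cfg.smooth_fwhm_px * _FWHM_TO_SIGMA)
    if cfg.noise_sigma > 0:
        support = img > 1e-6  # keep the surrounding frame black
        noise = rng.normal(0.0, cfg.noise_sigma, size=img.shape)
        img = img + noise * support
    img = np.clip(img, 0.0, None)
    return RawImage(img, source_id=f"{cls}_phantom")


def generate_images(cfg: PhantomConfig) -> list[tuple[str, str, RawImage]]:
    """All phantoms for a dataset, in memory: ``(source_id, label, image)``.

    Per-image seeds are spawned from ``cfg.seed`` so each image is
    reproducible independently of generation order.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(CLASS_LABELS) * cfg.n_per_class)
    out = []
    k = 0
    for cls in CLASS_LABELS:
        for i in range(cfg.n_per_class):
            rng = np.random.default_rng(children[k])
            k += 1
            img = generate_phantom(cls, cfg, rng)
            sid = f"{cls}_{i:04d}"
            img.source_id = sid
            out.append((sid, cls, img))
    return out


def generate_dataset(cfg: PhantomConfig, out_dir: str | Path) -> Manifest:
    """Write phantoms as 8-bit PNGs plus a ``manifest.csv`` into ``out_dir``.

    Intensities are quantized against a fixed ceiling of 1.25x core uptake so
    that the stored gray levels are comparable across images and classes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vmax = 1.25 * cfg.core_uptake
    entries = []
    for sid, cls, img in generate_images(cfg):
        path = out_dir / f"{sid}.png"
        quantized = np.round(np.clip(img.pixels / vmax, 0.0, 1.0) * 255.0)
        save_image(RawImage(quantized, source_id=sid, nominal_max=255.0), path)
        entries.append(ManifestEntry(sid, str(path), cls))
    manifest = Manifest(entries)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
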