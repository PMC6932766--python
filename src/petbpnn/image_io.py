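"""Reading grayscale images and dataset manifests.

Raster formats (PNG, TIFF) are read with :mod:`imageio`; NIfTI-1 volumes
(``.nii`` / ``.nii.gz``) with :mod:`nibabel`.  Volumes follow the convention
that the *last two* axes are the in-plane axes and ``slice_index`` indexes the
first axis (default: the middle plane).

A manifest is a CSV file with header ``source_id,path,label`` mapping each
image to one of the five study groups ``NC, SMC, EMCI, LMCI, AD``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np

from .exceptions import FormatError, ValidationError

#: The five diagnostic groups, in increasing order of disease severity.
CLASS_LABELS = ("NC", "SMC", "EMCI", "LMCI", "AD")

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


@dataclass
class RawImage:
    """A 2D grayscale pixel grid in arbitrary (non-negative) scanner units.

    Parameters
    ----------
    pixels:
        2D float array, every entry finite and >= 0.
    source_id:
        Opaque identifier for provenance tracking.
    nominal_max:
        The nominal intensity ceiling implied by the storage format
        (255 for 8-bit rasters, 65535 for 16-bit), or ``None`` when the
        source carries no bit-depth convention (float NIfTI data).
    """

    pixels: np.ndarray
    source_id: str = ""
    nominal_max: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"RawImage requires a 2D array, got ndim={self.pixels.ndim}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValidationError(f"empty image of shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("image contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValidationError("image contains negative intensities")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ManifestEntry:
    source_id: str
    path: str
    label: str


@dataclass
class Manifest:
    """Bookkeeping of image files and their class labels."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for i, e in enumerate(self.entries):
            if e.label not in CLASS_LABELS:
                raise ValidationError(
                    f"entry {i} (source_id={e.source_id!r}): unknown label "
                    f"{e.label!r}; expected one of {CLASS_LABELS}"
                )
            if e.source_id in seen:
                raise ValidationError(f"duplicate source_id {e.source_id!r}")
            seen.add(e.source_id)

    def __len__(self) -> int:
        return len(self.entries)

    def class_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in CLASS_LABELS}
        for e in self.entries:
            counts[e.label] += 1
        return counts

    def ids_for(self, label: str) -> list[str]:
        return [e.source_id for e in self.entries if e.label == label]


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def load_image(path: str | Path, slice_index: Optional[int] = None) -> RawImage:
    """Read a 2D grayscale image from a raster file or a NIfTI volume.

    Multi-channel rasters are collapsed to a single channel by the unweighted
    mean over channels.  For 3D volumes ``slice_index`` selects a plane along
    the first axis (default: the middle plane); 2D inputs ignore it.
    Intensities are preserved exactly as read — no rescaling happens here.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if _is_nifti(path):
        import nibabel as nib

        try:
            vol = np.asarray(nib.load(str(path)).get_fdata())
        except Exception as exc:  # nibabel raises many concrete types
            raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
        vol = np.squeeze(vol)
        if vol.ndim == 2:
            plane = vol
        elif vol.ndim == 3:
            idx = vol.shape[0] // 2 if slice_index is None else slice_index
            if not 0 <= idx < vol.shape[0]:
                raise IndexError(
                    f"slice_index {idx} out of range for volume with "
                    f"{vol.shape[0]} planes"
                )
            plane = vol[idx]
        else:
            raise FormatError(f"unsupported volume dimensionality {vol.ndim}")
        return RawImage(np.clip(plane, 0.0, None), source_id=path.stem)

    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot read image file {path}: {exc}") from exc
    nominal = None
    if arr.dtype == np.uint8:
        nominal = 255.0
    elif arr.dtype == np.uint16:
        nominal = 65535.0
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:  # channels last; unweighted channel mean
        arr = arr.mean(axis=2)
    elif arr.ndim != 2:
        raise FormatError(f"unsupported raster dimensionality {arr.ndim}")
    return RawImage(arr, source_id=path.stem, nominal_max=nominal)


def save_image(img: RawImage, path: str | Path) -> None:
    """Write a RawImage as PNG/TIFF.

    Integer-valued images round-trip exactly: values <= 255 are stored as
    uint8, values <= 65535 as uint16.  Non-integer images are stored as
    uint16 after rounding.
    """
    px = img.pixels
    if px.max(initial=0.0) <= 255 and np.allclose(px, np.round(px)):
        out = np.round(px).astype(np.uint8)
    else:
        out = np.round(np.clip(px, 0, 65535)).astype(np.uint16)
    iio.imwrite(Path(path), out)


def load_manifest(path: str | Path) -> Manifest:
    """Parse a ``source_id,path,label`` CSV; labels validated case-insensitively."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such manifest: {path}")
    entries: list[ManifestEntry] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"source_id", "path", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(
                f"manifest must have header columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row_no, row in enumerate(reader, start=2):
            label = row["label"].strip().upper()
            if label not in CLASS_LABELS:
                raise ValidationError(
                    f"row {row_no}: unknown label {row['label']!r} "
                    f"(expected one of {CLASS_LABELS})"
                )
            entries.append(
                ManifestEntry(row["source_id"].strip(), row["path"].strip(), label)
            )
    return Manifest(entries)


def save_manifest(manifest: Manifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "path", "label"])
        for e in manifest.entries:
            writer.writerow([e.source_id, e.path, e.label])
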