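"""Reading and writing flow volumes and en face images.

Disk formats: multi-page TIFF and ``.npy`` for volumes, 8-bit PNG for
2D images. The in-memory contract everywhere in the package is a float
array in ``[0, 1]`` with axes ``(z, y, x)`` — depth, slow, fast. Integer
files are mapped to that range through ``VolumeMeta.scale`` (1/255 for
uint8, 1/65535 for uint16); writing refuses out-of-range data rather than
clipping silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .exceptions import FormatError, ValidationError

__all__ = ["VolumeMeta", "read_volume", "write_volume", "read_image", "write_image"]

_DTYPES = {
    "uint8": (np.uint8, 255.0),
    "uint16": (np.uint16, 65535.0),
    "float32": (np.float32, 1.0),
}


@dataclass(frozen=True)
class VolumeMeta:
    """On-disk representation of a volume: always ZYX axes, with ``scale``
    mapping stored integers back into [0, 1]."""

    axes_order: str = "ZYX"
    dtype_on_disk: str = "float32"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.axes_order != "ZYX":
            raise ValidationError("axes_order is fixed to 'ZYX'")
        if self.scale <= 0:
            raise ValidationError("scale must be > 0")
        if self.dtype_on_disk not in _DTYPES:
            raise ValidationError(f"dtype_on_disk must be one of {sorted(_DTYPES)}")


def _meta_for(dtype: np.dtype) -> VolumeMeta:
    if dtype == np.uint8:
        return VolumeMeta(dtype_on_disk="uint8", scale=1.0 / 255.0)
    if dtype == np.uint16:
        return VolumeMeta(dtype_on_disk="uint16", scale=1.0 / 65535.0)
    if dtype in (np.float32, np.float64):
        return VolumeMeta(dtype_on_disk="float32", scale=1.0)
    raise FormatError(f"unsupported on-disk dtype {dtype}")


def read_volume(path: str | Path) -> tuple[np.ndarray, VolumeMeta]:
    """Read a volume from multi-page TIFF or ``.npy``.

    Returns a float64 array in [0, 1] with (z, y, x) axes, together with
    the metadata describing how it was stored. A 2D file is promoted to a
    single-slice volume.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix == ".npy":
        raw = np.load(path)
    else:
        try:
            with tifffile.TiffFile(path) as tf:
                shapes = [p.shape for p in tf.pages]
                for idx, shape in enumerate(shapes):
                    if shape != shapes[0]:
                        raise FormatError(
                            f"ragged TIFF: page {idx} has shape {shape}, "
                            f"page 0 has {shapes[0]}"
                        )
                raw = tf.asarray()
        except FormatError:
            raise
        except Exception as exc:  # pragma: no cover - backend specific
            raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if raw.ndim == 2:
        raw = raw[None]
    if raw.ndim != 3:
        raise FormatError(f"expected a 2D image or 3D volume, got shape {raw.shape}")
    meta = _meta_for(raw.dtype)
    volume = raw.astype(np.float64) * meta.scale
    if volume.max(initial=0.0) > 1.0 + 1e-9 or volume.min(initial=0.0) < 0.0:
        raise FormatError(f"{path}: stored values fall outside [0, 1] after scaling")
    return np.clip(volume, 0.0, 1.0), meta


def write_volume(volume: np.ndarray, path: str | Path,
                 meta: VolumeMeta | None = None) -> Path:
    """Write a [0, 1] volume to TIFF or ``.npy``; :func:`read_volume`
    inverts it exactly for float32 and within half an LSB for integers."""
    path = Path(path)
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValidationError(f"expected (z, y, x) volume, got shape {volume.shape}")
    if not np.all(np.isfinite(volume)) or volume.min() < 0.0 or volume.max() > 1.0:
        raise ValidationError("volume values must be finite and within [0, 1]")
    if meta is None:
        meta = VolumeMeta()
    np_dtype, full_scale = _DTYPES[meta.dtype_on_disk]
    if meta.dtype_on_disk == "float32":
        data = volume.astype(np.float32)
    else:
        data = np.rint(volume * full_scale).astype(np_dtype)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".npy":
        np.save(path, data)
    else:
        tifffile.imwrite(path, data, photometric="minisblack")
    return path


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as float64 in [0, 1] (RGB inputs are
    averaged to gray)."""
    raw = iio.imread(Path(path))
    if raw.ndim == 3:
        raw = raw.mean(axis=2)
    img = raw.astype(np.float64)
    if np.issubdtype(raw.dtype, np.integer):
        img /= float(np.iinfo(raw.dtype).max)
    return np.clip(img, 0.0, 1.0)


def write_image(image: np.ndarray, path: str | Path) -> Path:
    """Write a [0, 1] grayscale or RGB image as 8-bit PNG."""
    path = Path(path)
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)) or image.min() < 0.0 or image.max() > 1.0:
        raise ValidationError("image values must be finite and within [0, 1]")
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.rint(image * 255.0).astype(np.uint8))
    return path
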