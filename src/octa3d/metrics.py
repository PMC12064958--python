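"""Vascular image-quality metrics.

An en face angiogram is quantified through a fixed chain: global adaptive
(Otsu) binarization separates vessel from background, morphological
thinning reduces the vessel mask to a 1-pixel skeleton, and four scalars
summarize quality:

* **CNR**  = (mu_s - mu_b) / sqrt(sigma_s^2 + sigma_b^2), the contrast-to-
  noise ratio between the signal (white) and background (black) regions,
  with population standard deviations;
* **VD**   = white pixels / all pixels (vessel density);
* **VDI**  = white pixels / skeleton pixels (vessel diameter index, an
  average-caliber proxy);
* **VC**   = fraction of skeleton pixels lying in 8-connected components
  of at least 5 pixels (vessel continuity; 1 means fully connected).

For volumes, a per-B-scan CNR profile is computed with a stated avascular
depth band as background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _sk_skeletonize

from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "MetricsReport",
    "binarize",
    "skeletonize",
    "cnr",
    "cross_sectional_cnr",
    "vessel_density",
    "vessel_diameter_index",
    "vessel_continuity",
    "evaluate_image",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MetricsReport:
    """The four scalar metrics for one image (plus an optional per-B-scan
    CNR profile when computed for a volume)."""

    cnr: float
    vd: float
    vdi: float
    vc: float
    per_slice_cnr: list[float] | None = None

    def as_dict(self) -> dict:
        out = {"cnr": self.cnr, "vd": self.vd, "vdi": self.vdi, "vc": self.vc}
        if self.per_slice_cnr is not None:
            out["per_slice_cnr"] = list(self.per_slice_cnr)
        return out


def binarize(image: np.ndarray) -> np.ndarray:
    """Global adaptive (Otsu) threshold; pixels above threshold are vessel."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValidationError(f"expected a 2D image, got shape {image.shape}")
    if float(image.max() - image.min()) <= 0.0:
        raise DegenerateInputError("constant image has no threshold")
    return image > threshold_otsu(image)


def skeletonize(binary: np.ndarray) -> np.ndarray:
    """Morphological thinning to 1-pixel-wide, 8-connected centerlines."""
    binary = np.asarray(binary)
    if binary.dtype != bool:
        raise ValidationError("expected a boolean mask")
    return _sk_skeletonize(binary)


def cnr(image: np.ndarray, signal_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Contrast-to-noise ratio between two disjoint regions
    (population standard deviations)."""
    image = np.asarray(image, dtype=np.float64)
    signal_mask = np.asarray(signal_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if signal_mask.shape != image.shape or background_mask.shape != image.shape:
        raise ValidationError("masks must match the image shape")
    if np.any(signal_mask & background_mask):
        raise ValidationError("signal and background masks overlap")
    if not signal_mask.any() or not background_mask.any():
        raise ValidationError("both masks must be nonempty")
    sig = image[signal_mask]
    bg = image[background_mask]
    var_s, var_b = float(sig.var()), float(bg.var())
    if var_s == 0.0 and var_b == 0.0:
        raise DegenerateInputError("both regions have zero variance")
    return float((sig.mean() - bg.mean()) / np.sqrt(var_s + var_b))


def cross_sectional_cnr(volume: np.ndarray,
                        background_depth_band: tuple[int, int]) -> list[float]:
    """Per-B-scan CNR along the slow axis.

    Each B-scan ``volume[:, y, :]`` is binarized adaptively to find the
    signal region; the stated depth band ``[z0, z1)`` — known to be
    avascular — supplies the background. Band pixels that land in the
    detected signal mask are excluded from the background (with a warning).
    Degenerate frames (constant, or with an unusable region split) yield 0.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValidationError(f"expected (z, y, x) volume, got shape {volume.shape}")
    z0, z1 = int(background_depth_band[0]), int(background_depth_band[1])
    if not (0 <= z0 < z1 <= volume.shape[0]):
        raise ValidationError(f"background band {background_depth_band} outside depth range")
    values: list[float] = []
    overlap_frames = 0
    for y in range(volume.shape[1]):
        bscan = volume[:, y, :]
        try:
            signal = binarize(bscan)
        except DegenerateInputError:
            values.append(0.0)
            continue
        band = np.zeros_like(signal)
        band[z0:z1] = True
        if np.any(band & signal):
            overlap_frames += 1
            band &= ~signal
        if not band.any() or not signal.any():
            values.append(0.0)
            continue
        try:
            values.append(cnr(bscan, signal & ~band, band))
        except DegenerateInputError:
            values.append(0.0)
    if overlap_frames:
        warnings.warn(
            f"background band overlapped detected signal in {overlap_frames} "
            "B-scan(s); overlapping pixels were excluded from the background",
            stacklevel=2,
        )
    return values


def vessel_density(binary: np.ndarray) -> float:
    """Fraction of white (vessel) pixels."""
    binary = np.asarray(binary, dtype=bool)
    if binary.size == 0:
        raise ValidationError("empty image")
    return float(binary.sum() / binary.size)


def vessel_diameter_index(binary: np.ndarray, skeleton: np.ndarray) -> float:
    """Total vessel area divided by total skeleton length (in pixels)."""
    binary = np.asarray(binary, dtype=bool)
    skeleton = np.asarray(skeleton, dtype=bool)
    n_skel = int(skeleton.sum())
    if n_skel == 0:
        raise DegenerateInputError("empty skeleton")
    return float(binary.sum() / n_skel)


def vessel_continuity(skeleton: np.ndarray, min_length: int = 5) -> float:
    """Fraction of skeleton pixels in 8-connected components of size
    >= ``min_length`` (the continuity rule counts component size, and a
    vessel needs at least five continuous skeleton pixels to count)."""
    skeleton = np.asarray(skeleton, dtype=bool)
    total = int(skeleton.sum())
    if total == 0:
        raise DegenerateInputError("empty skeleton")
    labels, n_comp = ndimage.label(skeleton, structure=_EIGHT_CONNECTED)
    sizes = np.bincount(labels.ravel())[1:]
    connected = int(sizes[sizes >= min_length].sum())
    return float(connected / total)


def evaluate_image(image: np.ndarray, min_length: int = 5) -> MetricsReport:
    """Full metric chain for one en face image.

    Binarize → skeletonize → CNR (white region vs its complement), VD,
    VDI, VC.
    """
    binary = binarize(image)
    skeleton = skeletonize(binary)
    return MetricsReport(
        cnr=cnr(image, binary, ~binary),
        vd=vessel_density(binary),
        vdi=vessel_diameter_index(binary, skeleton),
        vc=vessel_continuity(skeleton, min_length=min_length),
    )


def evaluate_volume(volume: np.ndarray, background_depth_band: tuple[int, int],
                    z_range: tuple[int, int] | None = None) -> MetricsReport:
    """Evaluate a volume: metric chain on its en face MIP plus the
    per-B-scan CNR profile against the stated avascular band."""
    from .projection import mip  # local import to avoid a cycle

    report = evaluate_image(mip(volume, z_range))
    per_slice = cross_sectional_cnr(volume, background_depth_band)
    return MetricsReport(cnr=report.cnr, vd=report.vd, vdi=report.vdi,
                         vc=report.vc, per_slice_cnr=per_slice)
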