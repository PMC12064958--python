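"""En face projection and multi-acquisition registration/averaging.

High-quality reference angiograms are built the way a practitioner would
at the scope: acquire the same tissue several times, project each volume
to an en face image (maximum intensity projection), register the repeats
to a chosen reference with scale-invariant features, crop away the
unmatched periphery, and average. Averaging n registered repeats lowers
the background noise variance by ~1/n while leaving the vessel signal in
place, which is what makes the result usable as a training label.

Transforms are 3×3 homogeneous matrices in (row, col) convention mapping
reference coordinates to the moving image's coordinates, matching the
convention of :mod:`octa3d.phantom`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import EuclideanTransform

from .exceptions import RegistrationError, ValidationError

__all__ = [
    "RegistrationResult",
    "mip",
    "depth_encoded_mip",
    "register_enface",
    "average_registered",
]


@dataclass(frozen=True)
class RegistrationResult:
    """Registered, commonly-cropped en face repeats.

    ``transforms[i]`` maps reference coordinates into image ``i``'s frame
    (identity for the reference itself); ``crop_box`` is ``(top, left,
    height, width)``, 0-based and half-open, in the reference frame.
    """

    registered_images: list[np.ndarray]
    transforms: list[np.ndarray]
    crop_box: tuple[int, int, int, int]
    reference_index: int = 0


def mip(volume: np.ndarray, z_range: tuple[int, int] | None = None) -> np.ndarray:
    """Maximum intensity projection along depth over the half-open slab
    ``[z0, z1)`` (full depth when omitted)."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValidationError(f"expected (z, y, x) volume, got shape {volume.shape}")
    depth = volume.shape[0]
    if z_range is None:
        z0, z1 = 0, depth
    else:
        z0, z1 = int(z_range[0]), int(z_range[1])
    if not (0 <= z0 < z1 <= depth):
        raise ValidationError(f"z_range {z_range} invalid for depth {depth}")
    return volume[z0:z1].max(axis=0)


def depth_encoded_mip(volume: np.ndarray) -> np.ndarray:
    """Depth-encoded en face projection.

    Each pixel takes the hue of the depth at which its intensity column
    peaks — green at the shallowest slice, red at the deepest, blended
    linearly between — with brightness scaled by the MIP value, so columns
    with no signal stay black. Returns an (y, x, 3) RGB image in [0, 1].
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3 or volume.shape[0] < 1:
        raise ValidationError("expected a nonempty (z, y, x) volume")
    depth = volume.shape[0]
    peak = volume.max(axis=0)
    z_star = volume.argmax(axis=0)
    frac = z_star / (depth - 1) if depth > 1 else np.zeros_like(peak)
    rgb = np.stack([frac, 1.0 - frac, np.zeros_like(frac)], axis=-1)
    return rgb * peak[..., None]


def _estimate_rigid(
    ref_img: np.ndarray,
    mov_img: np.ndarray,
    index: int,
    *,
    max_ratio: float,
    residual_threshold: float,
    min_matches: int,
) -> np.ndarray:
    """SIFT + ratio-test matching + RANSAC rigid fit; returns the forward
    3×3 matrix (reference → moving) in (row, col) coordinates."""
    sift_ref, sift_mov = SIFT(), SIFT()
    try:
        sift_ref.detect_and_extract(ref_img)
        sift_mov.detect_and_extract(mov_img)
    except RuntimeError as exc:
        raise RegistrationError(f"image {index}: no usable features ({exc})") from exc
    if len(sift_ref.keypoints) < min_matches or len(sift_mov.keypoints) < min_matches:
        raise RegistrationError(f"image {index}: too few keypoints for registration")
    # a rigid model needs only 2 correspondences; if the strict ratio test
    # leaves too few matches or no consensus, retry once with a relaxed
    # ratio before giving up
    model = None
    for ratio in (max_ratio, max(max_ratio, 0.9)):
        matches = match_descriptors(
            sift_ref.descriptors, sift_mov.descriptors, cross_check=True, max_ratio=ratio
        )
        if len(matches) < min_matches:
            continue
        src = sift_ref.keypoints[matches[:, 0]].astype(np.float64)
        dst = sift_mov.keypoints[matches[:, 1]].astype(np.float64)
        model, inliers = ransac(
            (src, dst),
            EuclideanTransform,
            min_samples=2,
            residual_threshold=residual_threshold,
            max_trials=5000,
            rng=0,
        )
        if model is not None and inliers is not None and inliers.sum() >= min_matches:
            break
        model = None
    if model is None:
        if len(matches) < min_matches:
            raise RegistrationError(
                f"image {index}: only {len(matches)} feature matches "
                f"(need >= {min_matches})"
            )
        raise RegistrationError(f"image {index}: RANSAC found no consistent rigid model")
    # guided refinement: re-collect correspondences under a relaxed ratio,
    # keep those consistent with the RANSAC model, and least-squares re-fit
    loose = match_descriptors(
        sift_ref.descriptors, sift_mov.descriptors, cross_check=True, max_ratio=0.9
    )
    src_l = sift_ref.keypoints[loose[:, 0]].astype(np.float64)
    dst_l = sift_mov.keypoints[loose[:, 1]].astype(np.float64)
    good = model.residuals(src_l, dst_l) < residual_threshold
    if good.sum() >= min_matches:
        refined = EuclideanTransform.from_estimate(src_l[good], dst_l[good])
        if refined:
            model = refined
    return np.asarray(model.params, dtype=np.float64)


def _largest_valid_rectangle(valid: np.ndarray) -> tuple[int, int, int, int]:
    """Largest axis-aligned rectangle of all-True pixels (histogram-stack
    algorithm); returns (top, left, height, width)."""
    h, w = valid.shape
    heights = np.zeros(w, dtype=np.int64)
    best = (0, 0, 0, 0)
    best_area = 0
    for row in range(h):
        heights = np.where(valid[row], heights + 1, 0)
        stack: list[int] = []
        for col in range(w + 1):
            cur = heights[col] if col < w else 0
            while stack and heights[stack[-1]] >= cur:
                top_idx = stack.pop()
                rect_h = int(heights[top_idx])
                left = stack[-1] + 1 if stack else 0
                rect_w = col - left
                if rect_h * rect_w > best_area:
                    best_area = rect_h * rect_w
                    best = (row - rect_h + 1, left, rect_h, rect_w)
            stack.append(col)
    if best_area == 0:
        raise RegistrationError("no common valid region after registration")
    return best


def register_enface(
    images: list[np.ndarray],
    reference_index: int = 0,
    *,
    max_ratio: float = 0.75,
    residual_threshold: float = 2.0,
    min_matches: int = 4,
    smoothing_sigma: float = 1.5,
) -> RegistrationResult:
    """Register repeated en face acquisitions to a common reference frame.

    Every non-reference image is aligned by SIFT keypoint matching
    (ratio test + cross-check) followed by a RANSAC rigid (rotation +
    translation) fit, then resampled bilinearly into the reference frame.
    Features are detected on lightly Gaussian-smoothed copies
    (``smoothing_sigma`` pixels) so granular noise does not swamp the
    descriptors; the warp itself is applied to the original images.
    Pixels that fall outside an image after warping are invalid, and the
    output is cropped to the largest rectangle valid in *all* repeats, so
    averaging never dilutes with padding.
    """
    if len(images) < 2:
        raise ValidationError("need at least 2 images to register")
    shapes = {np.asarray(im).shape for im in images}
    if len(shapes) != 1:
        raise ValidationError(f"images must share one shape, got {shapes}")
    if not 0 <= reference_index < len(images):
        raise ValidationError("reference_index out of range")
    images = [np.asarray(im, dtype=np.float64) for im in images]
    if smoothing_sigma > 0:
        smoothed = [ndimage.gaussian_filter(im, smoothing_sigma) for im in images]
    else:
        smoothed = images
    ref = images[reference_index]
    transforms: list[np.ndarray] = []
    registered: list[np.ndarray] = []
    valid_all = np.ones(ref.shape, dtype=bool)
    for idx, img in enumerate(images):
        if idx == reference_index:
            transforms.append(np.eye(3))
            registered.append(img.copy())
            continue
        fwd = _estimate_rigid(
            smoothed[reference_index], smoothed[idx], idx,
            max_ratio=max_ratio,
            residual_threshold=residual_threshold,
            min_matches=min_matches,
        )
        if np.allclose(fwd, np.eye(3), atol=1e-9):  # snap exact matches
            fwd = np.eye(3)
            transforms.append(fwd)
            registered.append(img.copy())
            continue
        transforms.append(fwd)
        warped = ndimage.affine_transform(
            img, fwd[:2, :2], offset=fwd[:2, 2], order=1, mode="constant", cval=0.0
        )
        # validity = source pixel centre lands inside the frame
        # (nearest-neighbour warp of an all-ones support image)
        support = ndimage.affine_transform(
            np.ones_like(img), fwd[:2, :2], offset=fwd[:2, 2],
            order=0, mode="constant", cval=0.0,
        )
        valid_all &= support > 0.5
        registered.append(warped)
    top, left, height, width = _largest_valid_rectangle(valid_all)
    cropped = [im[top:top + height, left:left + width] for im in registered]
    return RegistrationResult(
        registered_images=cropped,
        transforms=transforms,
        crop_box=(top, left, height, width),
        reference_index=reference_index,
    )


def average_registered(result: RegistrationResult) -> np.ndarray:
    """Pixelwise arithmetic mean of the registered, cropped repeats."""
    imgs = result.registered_images
    if len(imgs) < 1:
        raise ValidationError("nothing to average")
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValidationError("registered images must share one shape")
    return np.clip(np.mean(imgs, axis=0), 0.0, 1.0)
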