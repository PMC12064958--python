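"""Depth-by-depth volumetric enhancement.

The trained 2D generator is applied independently to every C-scan slice
of a flow volume and the results are restacked, so slice ``z`` of the
output depends on slice ``z`` of the input only. Slices whose size does
not meet the generator's divisibility contract are reflect-padded to the
next multiple (reflect, not zero, so border vessels are not attenuated at
the pad seam) and cropped back afterwards.
"""

from __future__ import annotations

import time

import numpy as np

from .exceptions import ValidationError

__all__ = ["pad_or_tile", "crop_back", "enhance_volume"]


def pad_or_tile(slice_2d: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad a 2D slice up to the next multiple of ``multiple`` in
    each axis; returns the padded slice and the original ``(h, w)`` as the
    crop spec that inverts the padding exactly."""
    slice_2d = np.asarray(slice_2d)
    if slice_2d.ndim != 2:
        raise ValidationError(f"expected a 2D slice, got shape {slice_2d.shape}")
    if multiple < 1:
        raise ValidationError("multiple must be >= 1")
    h, w = slice_2d.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return slice_2d, (h, w)
    # reflect needs >= 2 samples along the padded axis; degenerate 1-pixel
    # axes fall back to edge replication
    mode = "reflect" if min(h, w) >= 2 else "edge"
    return np.pad(slice_2d, ((0, ph), (0, pw)), mode=mode), (h, w)


def crop_back(slice_2d: np.ndarray, crop_spec: tuple[int, int]) -> np.ndarray:
    """Invert :func:`pad_or_tile`."""
    h, w = crop_spec
    return slice_2d[:h, :w]


def enhance_volume(volume: np.ndarray, generator, multiple: int | None = None,
                   timings: list[float] | None = None) -> np.ndarray:
    """Apply ``generator`` to each C-scan slice of ``volume``.

    ``generator`` is either an object with a ``forward(image, train=False)``
    method (a trained network, applied with frozen normalization
    statistics, hence deterministic) or any callable mapping a 2D [0, 1]
    image to one of the same shape. ``multiple`` is the spatial
    divisibility the generator requires (``2**n_levels``; inferred from a
    network's spec when omitted). Per-slice wall-clock timings are
    appended to ``timings`` when a list is supplied.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValidationError(f"expected (z, y, x) volume, got shape {volume.shape}")
    if multiple is None:
        spec = getattr(generator, "spec", None)
        multiple = 2 ** spec.n_levels if spec is not None else 1
    runner = getattr(generator, "forward", None)

    out = np.empty_like(volume)
    for z in range(volume.shape[0]):
        t0 = time.perf_counter()
        padded, crop_spec = pad_or_tile(volume[z], multiple)
        if runner is not None:
            enhanced = runner(padded, train=False)
        else:
            enhanced = generator(padded)
        enhanced = np.asarray(enhanced, dtype=np.float64)
        if enhanced.shape != padded.shape:
            raise ValidationError(
                f"generator changed slice shape {padded.shape} -> {enhanced.shape}"
            )
        out[z] = crop_back(enhanced, crop_spec)
        if timings is not None:
            timings.append(time.perf_counter() - t0)
    return np.clip(out, 0.0, 1.0)
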