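"""Training-set synthesis for the C-scan enhancement network.

A single C-scan slice looks like a faint vascular pattern buried in the
granular noise of an avascular slice. High-quality C-scan labels cannot be
acquired directly, so the training input is *synthesized*: a single-shot
en face angiogram E is superimposed on an avascular C-scan noise image C,

    S = norm(alpha * E + beta * C),

and the registered-and-averaged en face image serves as the label. ``norm``
is per-image min–max normalization to [0, 1], which makes the alpha/beta
trade-off scale-free. Default weights alpha = 0.25, beta = 0.75. The
training set additionally contains noise-only pairs (noise → black) and
black pairs (black → black) so the network learns to erase structureless
input, and pairs are rotated/cropped for augmentation each epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .exceptions import ValidationError

__all__ = [
    "SynthesisWeights",
    "TrainingPair",
    "synthesize_input",
    "build_training_set",
    "augment",
    "train_test_split",
]


@dataclass(frozen=True)
class SynthesisWeights:
    """Weights of the en face image (alpha) and the noise image (beta)."""

    alpha: float = 0.25
    beta: float = 0.75

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise ValidationError("weights must be >= 0 with alpha + beta > 0")


@dataclass(frozen=True)
class TrainingPair:
    """One (degraded input, clean label) image pair."""

    input: np.ndarray
    label: np.ndarray
    tag: str = "vascular"  # vascular | noise_only | black

    def __post_init__(self) -> None:
        if self.input.shape != self.label.shape:
            raise ValidationError("input and label must share a shape")
        if self.tag not in {"vascular", "noise_only", "black"}:
            raise ValidationError(f"unknown tag {self.tag!r}")


def synthesize_input(E: np.ndarray, C: np.ndarray, w: SynthesisWeights) -> np.ndarray:
    """Weighted superposition of angiogram and noise, min–max normalized.

    Returns ``(s - s.min()) / (s.max() - s.min())`` for
    ``s = alpha*E + beta*C``; a constant weighted sum (no dynamic range)
    maps to the zero image, since all-black inputs are a sanctioned
    training class.
    """
    E = np.asarray(E, dtype=np.float64)
    C = np.asarray(C, dtype=np.float64)
    if E.shape != C.shape:
        raise ValidationError(f"shape mismatch: E {E.shape} vs C {C.shape}")
    s = w.alpha * E + w.beta * C
    lo, hi = float(s.min()), float(s.max())
    if hi - lo <= 1e-12:
        return np.zeros_like(s)
    return (s - lo) / (hi - lo)


def build_training_set(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    noise_images: list[np.ndarray],
    w: SynthesisWeights,
    n_noise_only: int = 20,
    n_black: int = 20,
    seed: int = 0,
) -> list[TrainingPair]:
    """Assemble the full training set.

    For each ``(E, label)`` pair a noise image is drawn uniformly (with
    replacement) from the avascular pool and superimposed on E; then
    ``n_noise_only`` noise→black pairs and ``n_black`` black→black pairs
    are appended. Deterministic for a fixed seed.
    """
    if not pairs:
        raise ValidationError("pairs must be nonempty")
    if (n_noise_only > 0 or pairs) and not noise_images:
        if n_noise_only > 0:
            raise ValidationError("noise pool empty but n_noise_only > 0")
        raise ValidationError("noise pool empty: cannot synthesize degraded inputs")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: list[TrainingPair] = []
    for E, label in pairs:
        C = noise_images[int(rng.integers(len(noise_images)))]
        out.append(TrainingPair(input=synthesize_input(E, C, w),
                                label=np.asarray(label, dtype=np.float64),
                                tag="vascular"))
    for _ in range(n_noise_only):
        C = np.asarray(noise_images[int(rng.integers(len(noise_images)))], dtype=np.float64)
        out.append(TrainingPair(input=C.copy(), label=np.zeros_like(C), tag="noise_only"))
    shape = out[0].input.shape
    for _ in range(n_black):
        z = np.zeros(shape, dtype=np.float64)
        out.append(TrainingPair(input=z, label=z.copy(), tag="black"))
    return out


def augment(pair: TrainingPair, seed: int,
            min_crop_fraction: float = 0.75) -> TrainingPair:
    """Random 90°-multiple rotation and random crop-then-resize, applied
    identically to input and label so they stay pixel-aligned.

    Rotations are restricted to multiples of 90° to avoid interpolation
    artifacts; the crop side length is drawn uniformly over the integer
    sizes in ``[min_crop_fraction * n, n]`` (a full-frame draw leaves the
    pair bitwise unchanged). Requires square images.
    """
    h, w = pair.input.shape
    if h != w:
        raise ValidationError("augmentation requires square images")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    k = int(rng.integers(4))
    size = int(rng.integers(int(np.ceil(min_crop_fraction * h)), h + 1))
    top = int(rng.integers(0, h - size + 1))
    left = int(rng.integers(0, h - size + 1))

    def tf(img: np.ndarray) -> np.ndarray:
        out = np.rot90(img, k)
        if size != h or top != 0 or left != 0:
            out = out[top:top + size, left:left + size]
            if size != h:
                out = resize(out, (h, w), order=1, anti_aliasing=False,
                             preserve_range=True)
        return np.ascontiguousarray(np.clip(out, 0.0, 1.0))

    return TrainingPair(input=tf(pair.input), label=tf(pair.label), tag=pair.tag)


def train_test_split(items: list, n_test: int, seed: int = 0) -> tuple[list, list]:
    """Disjoint random split into (train, test) with ``n_test`` held out."""
    if not 0 <= n_test <= len(items):
        raise ValidationError("n_test out of range")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    order = rng.permutation(len(items))
    test_idx = set(order[:n_test].tolist())
    train = [items[i] for i in range(len(items)) if i not in test_idx]
    test = [items[i] for i in sorted(test_idx)]
    return train, test
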