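"""Synthetic OCTA-like phantom volumes.

Real OCT angiography volumes of skin show a handful of statistical features
that every stage of this pipeline leans on: blood vessels form branching
networks oriented mostly in the en face (lateral) plane, signal decays
roughly exponentially with depth, the flow signal is corrupted by granular
multiplicative speckle plus a low additive background, repeated acquisitions
of the same tissue differ by small rigid motion drift, and superficial
slices above the vasculature contain pure noise. This module generates
volumes with exactly those features — nothing more — so the registration,
synthesis, training and metric stages can be exercised and tested without
any acquisition hardware or downloads.

Axis convention: volumes are indexed ``(z, y, x)`` = (depth, slow, fast).
A C-scan slice is ``volume[z]``; a B-scan is ``volume[:, y, :]``.
All intensities live in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "PhantomConfig",
    "DriftParams",
    "RepeatAcquisition",
    "generate_clean_volume",
    "add_speckle",
    "simulate_repeat_acquisitions",
    "avascular_cscan",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic vasculature and its noise model.

    Parameters
    ----------
    shape
        Volume shape ``(depth, height, width)`` in voxels; every axis ≥ 8.
    n_trees
        Number of vessel-tree root points.
    branch_prob
        Per-step probability of a bifurcation while growing a branch.
    radius_range
        ``(min, max)`` vessel radius in voxels; each branch draws one radius.
    lateral_bias
        Fraction in ``[0, 1]`` by which the axial (z) component of the walk
        direction is suppressed; 1 keeps vessels perfectly in-plane.
    attenuation_coeff
        Per-voxel exponential decay of vessel intensity with depth (≥ 0).
    vessel_intensity
        Peak vessel reflectivity at zero depth, in (0, 1]. Kept well below
        1 by default so multiplicative speckle rarely saturates the
        clipping range (saturated vessels would look artificially uniform).
    speckle_shape
        Gamma shape parameter (> 0) of the unit-mean multiplicative speckle;
        smaller values mean rougher speckle (variance = 1/shape).
    speckle_grain
        Noise grain size ``(gz, gy, gx)`` in voxels: noise is drawn on a
        coarse grid and replicated over blocks of this size, giving the
        granular texture of coherent imaging. The axial grain defaults to
        the scale of a vessel caliber, so a depth column crosses O(1)
        independent grains and en face maximum projections remain
        approximately unbiased estimates of the underlying reflectivity —
        the regime in which averaged projections can serve as reference
        labels.
    background_level
        Mean of the additive background noise, in ``[0, 1)``.
    seed
        Root seed of the vessel-geometry random stream.
    """

    shape: tuple[int, int, int] = (64, 128, 128)
    n_trees: int = 8
    branch_prob: float = 0.04
    radius_range: tuple[float, float] = (1.0, 3.0)
    lateral_bias: float = 0.85
    attenuation_coeff: float = 0.015
    vessel_intensity: float = 0.45
    speckle_shape: float = 2.0
    speckle_grain: tuple[int, int, int] = (8, 2, 2)
    background_level: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ConfigurationError(
                f"shape must be 3 axes, each >= 8 voxels, got {self.shape}"
            )
        if self.n_trees < 0:
            raise ConfigurationError("n_trees must be >= 0")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ConfigurationError("branch_prob must lie in [0, 1]")
        if not 0.0 <= self.lateral_bias <= 1.0:
            raise ConfigurationError("lateral_bias must lie in [0, 1]")
        rmin, rmax = self.radius_range
        if rmin > rmax or rmin < 0:
            raise ConfigurationError("radius_range must satisfy 0 <= min <= max")
        if self.attenuation_coeff < 0:
            raise ConfigurationError("attenuation_coeff must be >= 0")
        if not 0.0 < self.vessel_intensity <= 1.0:
            raise ConfigurationError("vessel_intensity must lie in (0, 1]")
        if self.speckle_shape <= 0:
            raise ConfigurationError("speckle_shape must be > 0")
        if len(self.speckle_grain) != 3 or any(int(g) < 1 for g in self.speckle_grain):
            raise ConfigurationError("speckle_grain must be 3 ints >= 1")
        if not 0.0 <= self.background_level < 1.0:
            raise ConfigurationError("background_level must lie in [0, 1)")


@dataclass(frozen=True)
class DriftParams:
    """Bounds of the rigid inter-acquisition motion drift.

    ``max_shift`` is the in-plane translation bound in pixels and
    ``max_rotation`` the in-plane rotation bound in degrees; both applied
    uniformly at random within ``[-bound, +bound]``.
    """

    max_shift: float = 4.0
    max_rotation: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_shift < 0 or self.max_rotation < 0:
            raise ConfigurationError("drift bounds must be >= 0")


@dataclass(frozen=True)
class RepeatAcquisition:
    """One simulated repeat: the noisy warped volume plus its ground truth.

    ``matrix`` is the 3×3 homogeneous forward transform in (row, col)
    convention mapping reference (clean) pixel coordinates to this repeat's
    coordinates; tests use it as a known-transform oracle.
    """

    volume: np.ndarray
    shift: tuple[float, float]
    rotation_deg: float
    matrix: np.ndarray
    noise_seed: int


def _ball_offsets(radius: int) -> np.ndarray:
    r = max(int(radius), 0)
    ax = np.arange(-r, r + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = zz**2 + yy**2 + xx**2 <= r**2 + 1e-9
    return np.stack([zz[keep], yy[keep], xx[keep]], axis=1)


def _grow_tree(rng: np.random.Generator, config: PhantomConfig) -> list[tuple[np.ndarray, float]]:
    """Grow one vessel tree as a biased 3D random walk with Bernoulli
    bifurcation; returns (centerline point, radius) samples."""
    depth, height, width = config.shape
    rmin, rmax = config.radius_range
    axial = 1.0 - config.lateral_bias

    def rand_dir() -> np.ndarray:
        v = rng.standard_normal(3)
        v[0] *= axial
        n = np.linalg.norm(v)
        if n < 1e-9:  # fully lateral bias and unlucky draw
            v = np.array([0.0, 1.0, 0.0])
            n = 1.0
        return v / n

    root = np.array([
        rng.uniform(0.2 * depth, 0.9 * depth),
        rng.uniform(0.1 * height, 0.9 * height),
        rng.uniform(0.1 * width, 0.9 * width),
    ])
    main_steps = max(height, width)
    stack = [(root, rand_dir(), float(rng.uniform(rmin, rmax)), main_steps, 0)]
    points: list[tuple[np.ndarray, float]] = []
    while stack:
        pos, direction, radius, steps, gen = stack.pop()
        pos = pos.copy()
        direction = direction.copy()
        for _ in range(steps):
            pos = pos + direction
            if not (0 <= pos[0] < depth and 0 <= pos[1] < height and 0 <= pos[2] < width):
                break
            points.append((pos.copy(), radius))
            wobble = rng.standard_normal(3) * 0.25
            wobble[0] *= axial
            direction = direction + wobble
            direction[0] *= 1.0 - 0.5 * config.lateral_bias
            n = np.linalg.norm(direction)
            direction = direction / n if n > 1e-9 else rand_dir()
            if gen < 3 and rng.random() < config.branch_prob:
                child_dir = direction + rng.standard_normal(3) * 0.8
                child_dir[0] *= axial
                cn = np.linalg.norm(child_dir)
                child_dir = child_dir / cn if cn > 1e-9 else rand_dir()
                child_radius = max(rmin, radius * 0.8)
                stack.append((pos.copy(), child_dir, child_radius, steps // 2, gen + 1))
    return points


def generate_clean_volume(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate a noise-free flow volume and its ground-truth vessel mask.

    Vessel centerlines are biased 3D random walks dilated by a spherical
    element of per-branch radius; voxel intensity inside the mask is
    ``vessel_intensity * exp(-attenuation_coeff * z)``, zero elsewhere. Deterministic for a
    fixed ``config.seed``: tree ``i`` always consumes the same substream, so
    increasing ``n_trees`` only adds vessels.

    Returns
    -------
    (volume, mask)
        ``volume`` float64 in [0, 1]; ``mask`` boolean, same shape.
    """
    depth, height, width = config.shape
    mask = np.zeros(config.shape, dtype=bool)
    root_ss = np.random.SeedSequence(config.seed)
    by_radius: dict[int, list[np.ndarray]] = {}
    for tree in range(config.n_trees):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(tree,)))
        for pos, radius in _grow_tree(rng, config):
            by_radius.setdefault(int(round(radius)), []).append(np.round(pos).astype(np.int64))
    del root_ss
    for radius, pts in by_radius.items():
        coords = np.asarray(pts)  # (N, 3)
        offs = _ball_offsets(radius)  # (M, 3)
        voxels = (coords[:, None, :] + offs[None, :, :]).reshape(-1, 3)
        ok = (
            (voxels[:, 0] >= 0) & (voxels[:, 0] < depth)
            & (voxels[:, 1] >= 0) & (voxels[:, 1] < height)
            & (voxels[:, 2] >= 0) & (voxels[:, 2] < width)
        )
        voxels = voxels[ok]
        mask[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = True
    decay = config.vessel_intensity * np.exp(
        -config.attenuation_coeff * np.arange(depth, dtype=np.float64))
    volume = mask.astype(np.float64) * decay[:, None, None]
    return volume, mask


def add_speckle(volume: np.ndarray, config: PhantomConfig, seed: int) -> np.ndarray:
    """Corrupt a clean volume with multiplicative speckle and additive
    background noise.

    The speckle is unit-mean gamma with shape ``config.speckle_shape``
    (a standard surrogate for coherent-imaging granularity), constant over
    ``speckle_grain``-sized cells; the background is gamma-distributed
    with mean ``config.background_level`` and the same grain. The result
    is clipped to [0, 1]. Works on 2D images (lateral grains apply) as
    well as 3D volumes.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if not np.all(np.isfinite(volume)):
        raise ValidationError("volume contains non-finite values")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    grain = tuple(int(g) for g in config.speckle_grain)
    if volume.ndim == 2:
        grain = grain[1:]
    speckle = _grained_field(rng, volume.shape, grain, config.speckle_shape, 1.0)
    out = volume * speckle
    if config.background_level > 0:
        out = out + _grained_field(rng, volume.shape, grain, 3.0, config.background_level)
    return np.clip(out, 0.0, 1.0)


def _grained_field(rng: np.random.Generator, shape: tuple[int, ...],
                   grain: tuple[int, ...], gamma_shape: float, mean: float) -> np.ndarray:
    """Gamma noise with the given mean, drawn on a coarse grid and
    block-replicated to ``grain``-sized cells."""
    coarse = tuple(-(-s // g) for s, g in zip(shape, grain))
    field = rng.gamma(shape=gamma_shape, scale=mean / gamma_shape, size=coarse)
    if any(g > 1 for g in grain):
        field = np.kron(field, np.ones(grain))
    return field[tuple(slice(0, s) for s in shape)]


def drift_matrix(shift: tuple[float, float], rotation_deg: float,
                 shape: tuple[int, int]) -> np.ndarray:
    """3×3 homogeneous forward map (reference → moved frame) in (row, col)
    coordinates: rotation by ``rotation_deg`` about the image centre followed
    by translation ``shift = (dy, dx)``."""
    theta = np.deg2rad(rotation_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    centre = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    t = centre - rot @ centre + np.asarray(shift, dtype=np.float64)
    out = np.eye(3)
    out[:2, :2] = rot
    out[:2, 2] = t
    return out


def _warp_volume(volume: np.ndarray, forward: np.ndarray) -> np.ndarray:
    """Apply an in-plane rigid forward map to every C-scan slice
    (bilinear, zero fill outside the frame)."""
    inv = np.linalg.inv(forward)
    out = np.empty_like(volume)
    for z in range(volume.shape[0]):
        out[z] = ndimage.affine_transform(
            volume[z], inv[:2, :2], offset=inv[:2, 2], order=1, mode="constant", cval=0.0
        )
    return out


def simulate_repeat_acquisitions(
    clean: np.ndarray,
    n_repeats: int,
    drift: DriftParams,
    config: PhantomConfig,
) -> list[RepeatAcquisition]:
    """Simulate consecutive acquisitions of the same tissue.

    Each repeat is the clean volume moved by an independent rigid in-plane
    drift (uniform within the :class:`DriftParams` bounds, identical for
    every depth slice, as whole-volume subject motion would be) and then
    corrupted by independent speckle/background noise. The applied forward
    transforms are returned so tests can use them as oracles.
    """
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    clean = np.asarray(clean, dtype=np.float64)
    repeats: list[RepeatAcquisition] = []
    for k in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence(drift.seed, spawn_key=(k,)))
        dy = float(rng.uniform(-drift.max_shift, drift.max_shift)) if drift.max_shift > 0 else 0.0
        dx = float(rng.uniform(-drift.max_shift, drift.max_shift)) if drift.max_shift > 0 else 0.0
        rot = (
            float(rng.uniform(-drift.max_rotation, drift.max_rotation))
            if drift.max_rotation > 0
            else 0.0
        )
        noise_seed = int(rng.integers(0, 2**31))
        matrix = drift_matrix((dy, dx), rot, clean.shape[1:])
        if dy == 0.0 and dx == 0.0 and rot == 0.0:
            warped = clean
        else:
            warped = _warp_volume(clean, matrix)
        noisy = add_speckle(warped, config, seed=noise_seed)
        repeats.append(
            RepeatAcquisition(
                volume=noisy, shift=(dy, dx), rotation_deg=rot,
                matrix=matrix, noise_seed=noise_seed,
            )
        )
    return repeats


def avascular_cscan(config: PhantomConfig, seed: int) -> np.ndarray:
    """A superficial C-scan slice containing no vessels: pure background
    plus granular noise, values in [0, 1]."""
    _, height, width = config.shape
    if config.background_level == 0:
        return np.zeros((height, width), dtype=np.float64)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    img = _grained_field(rng, (height, width), tuple(config.speckle_grain[1:]),
                         3.0, config.background_level)
    return np.clip(img, 0.0, 1.0)
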