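"""Synthetic phantoms, PSFs and the noisy forward model.

Every test and demo input is generated here, seeded and reproducible:
bead and filament phantoms standing in for fluorescence z-stacks, sampled
Gaussian and astigmatic ("hourglass") PSFs, and the forward model

    MI = OI (*) PSF + shot noise

with ``(*)`` circular convolution and Poisson counting noise at a chosen
photon scale (expected counts per intensity unit), the standard noise
model of photon-limited detectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .conv import circular_convolve, normalize_psf
from .validation import DTYPE, as_volume

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "make_gaussian_psf",
    "make_astigmatic_psf",
    "make_bead_phantom",
    "make_filament_phantom",
    "make_phantom",
    "forward_model",
]

_KINDS = ("beads", "points", "filaments")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic object volume.

    ``size`` is the bead radius in voxels for ``beads`` (ignored for
    ``points``, which are single voxels) and the filament length in steps
    for ``filaments``. A fixed seed reproduces the volume bit-for-bit.
    """

    shape: Tuple[int, int, int]
    kind: str = "beads"
    count: int = 8
    size: float = 3.0
    intensity: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError("shape must be a positive integer triple")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.size < 0:
            raise ValueError("size must be >= 0")
        if not self.intensity > 0:
            raise ValueError("intensity must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Shot-noise recipe: Poisson counting at *photon_scale* counts per unit."""

    model: str = "poisson"
    photon_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("poisson", "none"):
            raise ValueError("noise model must be 'poisson' or 'none'")
        if not self.photon_scale > 0:
            raise ValueError("photon_scale must be positive")


def make_gaussian_psf(shape: Sequence[int], sigmas: Sequence[float]) -> np.ndarray:
    """Anisotropic Gaussian PSF sampled at voxel centers, unit total mass.

    Centered at ``floor(size/2)`` per axis — the kernel-center convention
    of the convolution engine — so isotropic PSFs on odd grids are exactly
    flip-invariant.
    """
    shape = tuple(int(s) for s in shape)
    sig = tuple(float(s) for s in sigmas)
    if len(shape) != 3 or len(sig) != 3:
        raise ValueError("shape and sigmas must be triples")
    if any(s <= 0 for s in sig):
        raise ValueError("sigmas must be positive")
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = (s // 2 for s in shape)
    q = (
        ((zz - cz) / sig[0]) ** 2
        + ((yy - cy) / sig[1]) ** 2
        + ((xx - cx) / sig[2]) ** 2
    )
    return normalize_psf(np.exp(-0.5 * q))


def make_astigmatic_psf(
    shape: Sequence[int], waist_sigma: float, spread_rate: float
) -> np.ndarray:
    """Hourglass PSF emulating instrumental astigmatism, unit total mass.

    Each z-slice is a 2-D Gaussian. At the waist (central slice) it is
    isotropic with ``waist_sigma``; moving away by ``|dz|`` slices, the
    width along one lateral axis grows linearly as
    ``waist_sigma + spread_rate * |dz|``, with the elongation axis
    switching between y (below the waist) and x (above it) — the 90-degree
    rotation across the focus characteristic of astigmatism.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError("shape must be a triple")
    if not waist_sigma > 0 or not spread_rate > 0:
        raise ValueError("waist_sigma and spread_rate must be positive")
    nz, ny, nx = shape
    zc = nz // 2
    y = np.arange(ny) - ny // 2
    x = np.arange(nx) - nx // 2
    vol = np.empty(shape, dtype=np.float64)
    for z in range(nz):
        dz = z - zc
        grown = waist_sigma + spread_rate * abs(dz)
        sy, sx = (grown, waist_sigma) if dz < 0 else (waist_sigma, grown)
        if dz == 0:
            sy = sx = waist_sigma
        gy = np.exp(-0.5 * (y / sy) ** 2)
        gx = np.exp(-0.5 * (x / sx) ** 2)
        plane = np.outer(gy, gx)
        vol[z] = plane / plane.sum()  # equal per-slice energy along z
    return normalize_psf(vol)


def _ball_mask(radius: float) -> np.ndarray:
    m = int(np.ceil(radius))
    zz, yy, xx = np.ogrid[-m : m + 1, -m : m + 1, -m : m + 1]
    return zz**2 + yy**2 + xx**2 <= radius**2


def make_bead_phantom(spec: PhantomSpec) -> np.ndarray:
    """Non-overlapping spheres at seeded uniform-random integer positions.

    A voxel belongs to a bead iff its center lies within the radius, so
    every bead rasterizes to the same voxel count and the total intensity
    is exactly ``count * voxels_per_sphere * intensity``. Raises if the
    requested count cannot be placed without overlap in bounded retries.
    """
    if spec.kind not in ("beads", "points"):
        raise ValueError(f"bead phantom requires kind 'beads' or 'points', got {spec.kind!r}")
    radius = 0.0 if spec.kind == "points" else float(spec.size)
    margin = int(np.ceil(radius))
    shape = tuple(int(s) for s in spec.shape)
    lo = np.array([margin] * 3)
    hi = np.array(shape) - 1 - margin
    if np.any(hi < lo):
        raise ValueError(f"objects of radius {radius} do not fit in shape {shape}")
    rng = np.random.default_rng(spec.seed)
    centers: list = []
    min_sq = (2.0 * radius) ** 2
    attempts = 0
    max_attempts = 200 * max(spec.count, 1)
    while len(centers) < spec.count:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {spec.count} non-overlapping beads of radius "
                f"{radius} in shape {shape} after {max_attempts} attempts"
            )
        attempts += 1
        c = rng.integers(lo, hi + 1)
        if all(float(np.sum((c - o) ** 2)) > min_sq for o in centers):
            centers.append(c)
    vol = np.zeros(shape, dtype=DTYPE)
    mask = _ball_mask(radius)
    for c in centers:
        sl = tuple(slice(int(ci) - margin, int(ci) + margin + 1) for ci in c)
        vol[sl][mask] = spec.intensity
    return vol


def make_filament_phantom(spec: PhantomSpec) -> np.ndarray:
    """Seeded random-walk polylines of unit width and constant intensity."""
    if spec.kind != "filaments":
        raise ValueError(f"filament phantom requires kind 'filaments', got {spec.kind!r}")
    shape = tuple(int(s) for s in spec.shape)
    rng = np.random.default_rng(spec.seed)
    vol = np.zeros(shape, dtype=DTYPE)
    upper = np.array(shape, dtype=np.float64) - 1e-3
    for _ in range(spec.count):
        pos = rng.uniform(np.zeros(3), upper)
        direction = rng.normal(size=3)
        direction /= max(float(np.linalg.norm(direction)), 1e-12)
        for _ in range(int(spec.size)):
            idx = tuple(int(v) for v in pos)
            vol[idx] = spec.intensity
            direction = direction + 0.25 * rng.normal(size=3)
            direction /= max(float(np.linalg.norm(direction)), 1e-12)
            pos = np.clip(pos + direction, 0.0, upper)
    return vol


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "filaments":
        return make_filament_phantom(spec)
    return make_bead_phantom(spec)


def forward_model(oi, psf, noise: Optional[NoiseSpec] = None) -> np.ndarray:
    """Blur the object image with the PSF and optionally add shot noise.

    Poisson noise draws seeded counts with mean ``photon_scale * blurred``
    and rescales back, so intensities keep their units and ``photon_scale``
    dials the signal-to-noise ratio.
    """
    o = as_volume(oi, "object image")
    p = normalize_psf(psf)
    blurred = circular_convolve(o, p)
    np.maximum(blurred, 0.0, out=blurred)
    if noise is None or noise.model == "none":
        return blurred
    rng = np.random.default_rng(noise.seed)
    counts = rng.poisson(noise.photon_scale * blurred.astype(np.float64))
    return (counts / noise.photon_scale).astype(DTYPE)
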