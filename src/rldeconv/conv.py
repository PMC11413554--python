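"""Circular (periodic-boundary) 3-D convolution and the naive inverse filter.

The FFT implements convolution under periodic boundary conditions, so the
volume's own data wraps around at the edges instead of an arbitrary pad
value. All kernels are centered at their geometric center voxel,
``floor(size / 2)`` per axis, for both odd and even sizes; the same
convention is shared by the FFT path, the direct-summation oracle and the
PSF flip, so that a delta kernel at the center is the identity element.

Arithmetic is 32-bit floating point (64-bit accumulation for global sums),
matching the precision class of typical GPU deconvolution pipelines.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _fft

from .validation import DTYPE, as_volume

__all__ = [
    "flip_psf",
    "normalize_psf",
    "kernel_center",
    "circular_convolve",
    "direct_circular_convolve",
    "inverse_filter",
]


def kernel_center(shape) -> tuple[int, int, int]:
    """Geometric center index, floor(size/2) per axis."""
    return tuple(int(s) // 2 for s in shape)


def flip_psf(psf) -> np.ndarray:
    """Reverse the PSF along every axis.

    The flipped PSF is the kernel of the correlation step in the RL update;
    flipping is an involution and leaves centro-symmetric PSFs unchanged.
    """
    p = as_volume(psf, "psf")
    return np.ascontiguousarray(p[::-1, ::-1, ::-1])


def normalize_psf(psf) -> np.ndarray:
    """Scale the PSF to unit total mass.

    A unit-sum PSF makes blurring flux-preserving, which in turn makes the
    RL update conserve the total intensity of the measured image.
    """
    p = as_volume(psf, "psf")
    total = float(p.sum(dtype=np.float64))
    if total <= 0.0:
        raise ValueError("degenerate PSF: total mass must be positive")
    return (p.astype(np.float64) / total).astype(DTYPE)


def _check_fits(vol_shape, kernel_shape) -> None:
    if any(int(k) > int(v) for k, v in zip(kernel_shape, vol_shape)):
        raise ValueError(
            f"kernel shape {tuple(kernel_shape)} exceeds volume shape "
            f"{tuple(vol_shape)} in at least one axis"
        )


def _embed_kernel(kernel: np.ndarray, shape) -> np.ndarray:
    """Zero-pad *kernel* to *shape* with its center voxel moved to index 0.

    After the roll, circular convolution with the embedded kernel places the
    kernel's center on each output voxel, i.e. a centered delta is identity.
    """
    padded = np.zeros(shape, dtype=DTYPE)
    pz, py, px = kernel.shape
    padded[:pz, :py, :px] = kernel
    cz, cy, cx = kernel_center(kernel.shape)
    return np.roll(padded, (-cz, -cy, -cx), axis=(0, 1, 2))


def circular_convolve(vol, kernel) -> np.ndarray:
    """FFT circular convolution of a volume with a (non-negative) kernel.

    The output has the volume's shape; the periodic boundary conserves total
    mass: ``sum(out) == sum(vol) * sum(kernel)``.
    """
    v = as_volume(vol, "volume", allow_negative=True)
    k = as_volume(kernel, "kernel")
    _check_fits(v.shape, k.shape)
    k_hat = _fft.rfftn(_embed_kernel(k, v.shape))
    out = _fft.irfftn(_fft.rfftn(v) * k_hat, s=v.shape)
    return np.ascontiguousarray(out, dtype=DTYPE)


def direct_circular_convolve(vol, kernel) -> np.ndarray:
    """Summation-form circular convolution (test oracle, O(N * K) cost).

    Accumulates one shifted copy of the volume per kernel voxel, with the
    same centering convention as :func:`circular_convolve` but no FFT, in
    float64. Intended for small inputs.
    """
    v = as_volume(vol, "volume", allow_negative=True).astype(np.float64)
    k = as_volume(kernel, "kernel").astype(np.float64)
    _check_fits(v.shape, k.shape)
    center = kernel_center(k.shape)
    out = np.zeros_like(v)
    for idx in np.ndindex(k.shape):
        w = k[idx]
        if w == 0.0:
            continue
        shift = tuple(int(i) - int(c) for i, c in zip(idx, center))
        out += w * np.roll(v, shift, axis=(0, 1, 2))
    return out.astype(DTYPE)


def inverse_filter(mi, psf, clamp_fraction: float = 1e-6) -> np.ndarray:
    """Naive Fourier-division deconvolution, ``IFFT(FFT(MI) / FFT(PSF))``.

    This is the textbook one-shot inverse; it is exact on noiseless data
    with a well-conditioned PSF but amplifies noise wherever the PSF
    spectrum is small, which is the failure mode the iterative RL algorithm
    avoids. Spectral magnitudes below ``clamp_fraction * max|FFT(PSF)|``
    are raised to that floor (phase preserved) purely to prevent division
    overflow — the clamp does not cure the noise amplification.
    """
    m = as_volume(mi, "measured image")
    p = as_volume(psf, "psf")
    if float(p.sum(dtype=np.float64)) <= 0.0:
        raise ValueError("degenerate PSF: total mass must be positive")
    _check_fits(m.shape, p.shape)
    if clamp_fraction <= 0:
        raise ValueError("clamp_fraction must be positive")
    h = _fft.fftn(_embed_kernel(p, m.shape))
    mag = np.abs(h)
    floor = clamp_fraction * float(mag.max())
    small = mag < floor
    boost = small & (mag > 0)
    h[boost] *= floor / mag[boost]
    h[mag == 0] = floor
    out = _fft.ifftn(_fft.fftn(m) / h).real
    return np.ascontiguousarray(out, dtype=DTYPE)
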