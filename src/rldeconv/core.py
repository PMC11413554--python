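"""The Richardson-Lucy iteration and the multi-iteration driver.

The RL update restores an image blurred by a known PSF under a Poisson
noise model. Writing ``EI_n`` for the estimate at iteration ``n``, ``MI``
for the measured image and ``FSP`` for the axis-reversed (flipped) PSF,

    EI_{n+1} = EI_n * [ FSP (*) ( MI / (PSF (*) EI_n) ) ]

with ``(*)`` the circular convolution of :mod:`rldeconv.conv`. Under a
unit-sum PSF and periodic boundaries the update conserves the total
intensity of ``MI`` and preserves non-negativity, and a blur-consistent
estimate (``MI = PSF (*) EI``) is a fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import fft as _fft

from .conv import _check_fits, _embed_kernel, flip_psf, normalize_psf
from .validation import DTYPE, as_volume

__all__ = [
    "DeconvConfig",
    "FFTConvolver",
    "resolve_backend",
    "rl_iteration",
    "rl_deconvolve",
]

_LOGGER = logging.getLogger(__name__)

#: Progress hook signature: (completed_units, total_units). The unit is one
#: iteration in the non-block path and one block in the block path.
ProgressCallback = Callable[[int, int], None]

_BACKEND_TAGS = ("auto", "cpu")


def resolve_backend(tag: str) -> str:
    """Map a backend selector to a concrete backend.

    ``cpu`` is the reference implementation. ``auto`` probes for an
    accelerated backend and falls back to the CPU path; no accelerated
    backend is registered in this build, so both tags resolve to ``cpu``.
    """
    if tag not in _BACKEND_TAGS:
        raise ValueError(f"unknown backend {tag!r}; expected one of {_BACKEND_TAGS}")
    return "cpu"


@dataclass
class DeconvConfig:
    """Parameters of a deconvolution run.

    Attributes
    ----------
    iterations : int
        Number of RL iterations (>= 0). There is no universally accepted
        stopping criterion; typical fluorescence work uses 5-20.
    epsilon : float, optional
        Floor applied to the re-blur denominator to guard the division.
        Defaults to ``1e-12 * max(MI)``, small enough not to disturb flux
        conservation at float32 precision.
    callback : callable, optional
        Progress hook ``(completed_units, total_units)``.
    backend : str
        ``auto`` or ``cpu`` (see :func:`resolve_backend`).
    padding_fract : float
        Overlap width between adjacent blocks as a multiple of the PSF
        size (block path only; default 1.2).
    max_block_voxels : int, optional
        Memory budget: maximum voxel count of a padded block. ``None``
        disables splitting.
    """

    iterations: int = 10
    epsilon: Optional[float] = None
    callback: Optional[ProgressCallback] = None
    backend: str = "auto"
    padding_fract: float = 1.2
    max_block_voxels: Optional[int] = None

    def __post_init__(self) -> None:
        if int(self.iterations) < 0:
            raise ValueError("iterations must be >= 0")
        self.iterations = int(self.iterations)
        if self.epsilon is not None and not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if not self.padding_fract > 0:
            raise ValueError("padding_fract must be positive")
        if self.max_block_voxels is not None and int(self.max_block_voxels) < 1:
            raise ValueError("max_block_voxels must be a positive integer")
        resolve_backend(self.backend)


class FFTConvolver:
    """Caches PSF and flipped-PSF spectra for a fixed processing shape.

    Each RL iteration needs one convolution with the PSF and one with its
    flip; precomputing both spectra once per run halves the FFT count of
    every iteration.
    """

    def __init__(self, psf: np.ndarray, shape) -> None:
        _check_fits(shape, psf.shape)
        self.shape = tuple(int(s) for s in shape)
        self._psf_hat = _fft.rfftn(_embed_kernel(psf, self.shape))
        self._fsp_hat = _fft.rfftn(_embed_kernel(flip_psf(psf), self.shape))

    def blur(self, vol: np.ndarray) -> np.ndarray:
        """Circular convolution with the PSF."""
        return _fft.irfftn(_fft.rfftn(vol) * self._psf_hat, s=self.shape)

    def correlate(self, vol: np.ndarray) -> np.ndarray:
        """Circular convolution with the flipped PSF."""
        return _fft.irfftn(_fft.rfftn(vol) * self._fsp_hat, s=self.shape)


def _default_epsilon(mi: np.ndarray) -> float:
    peak = float(mi.max())
    if peak > 0:
        return 1e-12 * peak
    return float(np.finfo(DTYPE).tiny)


def _check_unit_sum(psf: np.ndarray) -> None:
    total = float(psf.sum(dtype=np.float64))
    if abs(total - 1.0) > 1e-4:
        raise ValueError(
            f"PSF must be normalized to unit sum (got {total:.6g}); "
            "apply normalize_psf first"
        )


def _rl_step(
    estimate: np.ndarray,
    mi: np.ndarray,
    conv: FFTConvolver,
    eps: float,
) -> np.ndarray:
    denom = conv.blur(estimate)
    np.maximum(denom, DTYPE(eps), out=denom)
    out = estimate * conv.correlate(mi / denom)
    # float round-off can leave tiny negative dust; RL estimates are >= 0
    np.maximum(out, 0.0, out=out)
    return out


def rl_iteration(estimate, mi, psf, epsilon: Optional[float] = None) -> np.ndarray:
    """Apply one Richardson-Lucy update to *estimate*.

    *psf* must already be normalized to unit sum; *estimate* and *mi* must
    share a shape and be non-negative.
    """
    e = as_volume(estimate, "estimate")
    m = as_volume(mi, "measured image")
    p = as_volume(psf, "psf")
    if e.shape != m.shape:
        raise ValueError(
            f"estimate shape {e.shape} does not match measured image shape {m.shape}"
        )
    _check_unit_sum(p)
    conv = FFTConvolver(p, m.shape)
    eps = _default_epsilon(m) if epsilon is None else float(epsilon)
    return _rl_step(e, m, conv, eps)


def rl_deconvolve(mi, psf, config: Optional[DeconvConfig] = None) -> np.ndarray:
    """Run the full RL deconvolution of *mi* with *psf*.

    The PSF is normalized internally; the initial estimate is the measured
    image itself, so ``iterations=0`` returns *mi* unchanged. The progress
    callback is invoked once after each completed iteration.
    """
    cfg = config if config is not None else DeconvConfig()
    m = as_volume(mi, "measured image")
    p = normalize_psf(psf)
    resolve_backend(cfg.backend)
    estimate = m.copy()
    if cfg.iterations == 0:
        return estimate
    conv = FFTConvolver(p, m.shape)
    eps = _default_epsilon(m) if cfg.epsilon is None else float(cfg.epsilon)
    for i in range(cfg.iterations):
        estimate = _rl_step(estimate, m, conv, eps)
        _LOGGER.info("RL iteration %d/%d complete", i + 1, cfg.iterations)
        if cfg.callback is not None:
            cfg.callback(i + 1, cfg.iterations)
    return estimate
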