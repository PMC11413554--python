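"""Analytic oracles: valid-region calculus and Gaussian RL propagation.

Valid region
------------
Convolution at a voxel needs a full PSF-width neighbourhood of real data,
so every discrete convolution shrinks the region whose values depend only
on measured data (not on boundary/padded values) by ``w_PSF - 1`` samples.
One RL iteration performs two convolutions, hence the valid width shrinks
by ``2 * w_PSF - 2`` per iteration. A 512-sample block with a 32-sample
PSF retains ``512 - 10 * (2*32 - 2) = -108`` valid samples after 10
iterations — i.e. nothing: the entire result formally depends on boundary
values, which is why practical RL runs accept formally-invalid output.

Gaussian propagation
--------------------
If the measured image equals the PSF (a point-like object) and both are
centered Gaussians, one RL iteration maps a Gaussian estimate to another
Gaussian whose amplitude is independent of the input amplitude. With PSF
variance ``r2`` and estimate variance ``b2`` (continuous, infinite-domain
convolution), the ratio image is Gaussian with variance
``t = r2*(r2 + b2)/b2`` and the next estimate has variance

    v = b2 * (r2 + t) / (b2 + r2 + t)

For ``b2 = r2`` this gives ``v = 0.75 * r2``: the first iteration narrows
the profile to 75% relative variance, the anchor used for acceptance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .conv import normalize_psf
from .core import rl_iteration

__all__ = [
    "GaussianModel",
    "ValidRegionQuery",
    "valid_width",
    "gaussian_rl_step",
    "gaussian_variance_step",
    "fit_gaussian_profile",
    "simulate_gaussian_rl_1d",
]


@dataclass(frozen=True)
class GaussianModel:
    """Amplitude/mean/variance triple of a 1-D Gaussian profile."""

    amplitude: float
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if not self.variance > 0:
            raise ValueError("variance must be positive")


@dataclass(frozen=True)
class ValidRegionQuery:
    """Inputs of the valid-width rule: data width, PSF width, iterations."""

    data_width: int
    psf_width: int
    iterations: int

    def __post_init__(self) -> None:
        if self.data_width < 1 or self.psf_width < 1:
            raise ValueError("widths must be >= 1")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


def valid_width(data_width: int, psf_width: int, iterations: int) -> int:
    """Valid samples remaining after *iterations* RL iterations.

    Each iteration's two convolutions shrink the valid region by
    ``2 * psf_width - 2`` samples. The result may be negative, meaning the
    whole result depends on boundary values.
    """
    q = ValidRegionQuery(int(data_width), int(psf_width), int(iterations))
    return q.data_width - q.iterations * (2 * q.psf_width - 2)


def gaussian_rl_step(estimate: GaussianModel, psf: GaussianModel) -> GaussianModel:
    """One RL iteration on Gaussian data in closed form (MI = PSF).

    Continuous, infinite-domain limit. The output amplitude does not depend
    on the input estimate's amplitude. Both Gaussians must share a center.
    """
    if not math.isclose(estimate.mean, psf.mean, abs_tol=1e-12):
        raise ValueError("closed form requires estimate and PSF centered together")
    r2 = psf.variance
    b2 = estimate.variance
    # ratio MI / (PSF (*) EI) is Gaussian with variance t (needs r2 + b2 > r2,
    # always true); then correlate with the PSF and multiply by the estimate
    t = r2 * (r2 + b2) / b2
    v = b2 * (r2 + t) / (b2 + r2 + t)

    def conv_amp(a1: float, s1: float, a2: float, s2: float) -> float:
        return a1 * a2 * math.sqrt(2.0 * math.pi * s1 * s2 / (s1 + s2))

    c_blur = conv_amp(psf.amplitude, r2, estimate.amplitude, b2)
    ratio_amp = psf.amplitude / c_blur
    corr_amp = conv_amp(psf.amplitude, r2, ratio_amp, t)
    out_amp = estimate.amplitude * corr_amp
    return GaussianModel(amplitude=out_amp, mean=psf.mean, variance=v)


def gaussian_variance_step(estimate_var: float, psf_var: float) -> float:
    """Variance after one RL iteration on Gaussians with MI = PSF.

    ``gaussian_variance_step(1, 1) == 0.75`` exactly: equal unit variances
    narrow to 75% in the first iteration.
    """
    if not estimate_var > 0 or not psf_var > 0:
        raise ValueError("variances must be positive")
    t = psf_var * (psf_var + estimate_var) / estimate_var
    return estimate_var * (psf_var + t) / (psf_var + t + estimate_var)


def fit_gaussian_profile(samples, coordinates) -> GaussianModel:
    """Measure a 1-D profile by moments: peak amplitude, mean, variance.

    The mean and variance are the first and second central moments of the
    mass-normalized profile; samples must be non-negative with positive
    total mass.
    """
    s = np.asarray(samples, dtype=np.float64).ravel()
    x = np.asarray(coordinates, dtype=np.float64).ravel()
    if s.shape != x.shape:
        raise ValueError("samples and coordinates must have equal length")
    if np.any(s < 0):
        raise ValueError("samples must be non-negative")
    total = s.sum()
    if not total > 0:
        raise ValueError("profile has zero total mass")
    w = s / total
    mean = float(w @ x)
    variance = float(w @ (x - mean) ** 2)
    return GaussianModel(amplitude=float(s.max()), mean=mean, variance=variance)


def simulate_gaussian_rl_1d(
    iterations: int,
    psf_sigma: float = 1.0,
    estimate_sigma: Optional[float] = None,
    step: float = 0.01,
    half_width: float = 10.0,
) -> List[float]:
    """Discrete oracle for the Gaussian closed form.

    Samples a Gaussian PSF on a fine 1-D grid, sets MI = PSF and the
    initial estimate to a Gaussian of ``estimate_sigma`` (default: the PSF
    sigma), runs the full discrete RL iteration on the (1, 1, N) volume and
    returns the moment-fitted variance after each iteration.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    x = np.arange(-half_width, half_width + step / 2, step)
    psf_profile = np.exp(-0.5 * (x / psf_sigma) ** 2)
    e_sigma = psf_sigma if estimate_sigma is None else float(estimate_sigma)
    est_profile = np.exp(-0.5 * (x / e_sigma) ** 2)

    psf = normalize_psf(psf_profile.reshape(1, 1, -1))
    mi = psf_profile.reshape(1, 1, -1)
    estimate = est_profile.reshape(1, 1, -1)
    variances = []
    for _ in range(iterations):
        estimate = rl_iteration(estimate, mi, psf)
        variances.append(fit_gaussian_profile(estimate[0, 0], x).variance)
    return variances
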