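"""Shared input checks for 3-D intensity arrays."""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def as_volume(
    data,
    name: str = "volume",
    *,
    allow_negative: bool = False,
) -> np.ndarray:
    """Coerce *data* to a contiguous float32 (z, y, x) array, validating it.

    Parameters
    ----------
    data : array-like
        Must be 3-D with finite values. Intensities (measured images, PSFs,
        RL estimates) must additionally be non-negative.
    name : str
        Label used in error messages.
    allow_negative : bool
        Permit negative values (e.g. for generic linear-operator inputs).
    """
    arr = np.asarray(data)
    if arr.ndim != 3:
        raise ValueError(
            f"{name} must be a 3-D array with axis order (z, y, x); "
            f"got {arr.ndim} dimension(s)"
        )
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    out = np.ascontiguousarray(arr, dtype=DTYPE)
    if not np.all(np.isfinite(out)):
        raise ValueError(f"{name} contains non-finite values")
    if not allow_negative and np.any(out < 0):
        raise ValueError(f"{name} contains negative intensities")
    return out
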