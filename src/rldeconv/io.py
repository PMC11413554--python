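"""Volume I/O: multi-page TIFF with axis order (z, y, x), pages = z.

Inputs may be 8/16-bit unsigned or 32-bit float grayscale; integers are
promoted to float32 (exact for 8/16-bit values). Output is always 32-bit
float, so a write/read round trip is bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .validation import DTYPE, as_volume

__all__ = ["read_volume", "write_volume"]

_TIFF_SUFFIXES = (".tif", ".tiff")


def _check_suffix(path: Path) -> None:
    if path.suffix.lower() == ".mrc":
        raise ValueError(
            "MRC files are not supported by this build; convert to multi-page TIFF"
        )
    if path.suffix.lower() not in _TIFF_SUFFIXES:
        raise ValueError(
            f"unsupported file extension {path.suffix!r}; expected .tif/.tiff"
        )


def read_volume(path) -> np.ndarray:
    """Read a 3-D volume from a multi-page TIFF.

    Rejects 2-D images (a single page is not a z-stack) and negative
    intensities; returns a float32 (z, y, x) array.
    """
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"no such file: {p}")
    _check_suffix(p)
    arr = tifffile.imread(p)
    if arr.ndim == 2:
        raise ValueError(
            f"{p} holds a single 2-D image; expected a 3-D z-stack laid out as "
            "multi-page TIFF with pages = z and axis order (z, y, x)"
        )
    if arr.ndim != 3:
        raise ValueError(f"{p} has {arr.ndim} dimensions; expected 3 (z, y, x)")
    if np.issubdtype(arr.dtype, np.signedinteger) and arr.min() < 0:
        raise ValueError(f"{p} contains negative intensities")
    return as_volume(arr, f"volume from {p.name}")


def write_volume(vol, path) -> None:
    """Write a volume as 32-bit float multi-page TIFF (one page per z-slice)."""
    p = Path(path)
    _check_suffix(p)
    v = as_volume(vol, "volume", allow_negative=True).astype(DTYPE)
    tifffile.imwrite(p, v, photometric="minisblack")
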