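"""Shared helpers for the test suite."""

import numpy as np


def rel_norm(actual, expected) -> float:
    """Norm-wise relative difference ||a - b|| / ||b|| in float64."""
    a = np.asarray(actual, dtype=np.float64)
    b = np.asarray(expected, dtype=np.float64)
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))


def rmse(a, b) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def total(a) -> float:
    return float(np.asarray(a).sum(dtype=np.float64))
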