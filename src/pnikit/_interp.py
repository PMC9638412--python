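"""Separable bilinear resampling shared by the Gaussian-pyramid expand step and
the network's upsampling layers.

Convention (used everywhere in the package): pixel centers sit at half-integer
positions, i.e. output center i maps to source coordinate
``(i + 0.5) * n_in / n_out - 0.5``, clamped to the valid range so edge rows and
columns are replicated rather than extrapolated.
"""

from __future__ import annotations

import numpy as np


def interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) linear-interpolation matrix for one axis.

    Each row holds the two bilinear weights of the output sample.  The matrix
    form makes the adjoint (needed for backpropagation) a plain transpose.
    """
    if n_in < 1 or n_out < 1:
        raise ValueError("axis lengths must be positive")
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(np.intp)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = src - i0
    m = np.zeros((n_out, n_in))
    m[np.arange(n_out), i0] += 1.0 - frac
    m[np.arange(n_out), i1] += frac
    return m


def bilinear_resize(a: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinearly resample the last two axes of ``a`` to ``out_shape``."""
    h_out, w_out = out_shape
    h_in, w_in = a.shape[-2], a.shape[-1]
    mr = interp_matrix(h_in, h_out)
    mc = interp_matrix(w_in, w_out)
    # rows: contract a's H axis with mr, then W with mc
    tmp = np.tensordot(a, mr, axes=([a.ndim - 2], [1]))  # (..., W, Hout)
    out = np.tensordot(tmp, mc, axes=([a.ndim - 2], [1]))  # (..., Hout, Wout)
    return out
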