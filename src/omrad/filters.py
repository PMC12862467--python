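"""Intensity-domain filters feeding the texture features.

Three filters are first-class because the selected signature uses them:
a magnitude-preserving logarithm transform, the Laplacian of Gaussian at
sigma = 3.0 mm, and a single-level undecimated (stationary) 3D wavelet
decomposition (Coiflet-1) whose LHL/HLH/HHH subbands carry texture.

The wavelet transform is computed as separable circular correlation with
the Coiflet-1 analysis filters (coefficients from PyWavelets).  For an
orthogonal pair (|H|^2 + |G|^2 = 2 at every frequency) the undecimated
transform is inverted exactly by convolving each subband with the same
filters and dividing by 2 per axis, which is what
:func:`reconstruct_from_subbands` does.
"""

from __future__ import annotations

from dataclasses import replace
from itertools import product

import numpy as np
import pywt
from scipy import ndimage

from .errors import InputError, ParameterError
from .image_io import VolumeGrid

__all__ = [
    "logarithm_transform",
    "laplacian_of_gaussian",
    "wavelet_subbands",
    "reconstruct_from_subbands",
    "SUBBAND_NAMES",
]

_WAVELET = "coif1"
#: Subband names; the n-th letter is the filter (L=low/H=high pass) on axis n.
SUBBAND_NAMES = tuple("".join(c) for c in product("LH", repeat=3))


def logarithm_transform(vol: VolumeGrid) -> VolumeGrid:
    """Signed log compression rescaled back to the input magnitude range.

    ``y = sign(x) * log(|x| + 1)`` followed by multiplication with
    ``max|x| / max|y|`` so the output spans the same magnitude range as
    the input.  An all-zero volume is a fixed point.
    """
    x = np.asarray(vol.voxels, dtype=np.float64)
    y = np.sign(x) * np.log1p(np.abs(x))
    max_y = np.abs(y).max()
    if max_y > 0:
        y *= np.abs(x).max() / max_y
    return replace(vol, voxels=y)


def laplacian_of_gaussian(vol: VolumeGrid, sigma_mm: float = 3.0) -> VolumeGrid:
    """LoG response with sigma given in millimetres.

    A bright blob on a dark background yields a negative centre response
    (plain Laplacian of the Gaussian-smoothed image, no sign flip).
    """
    if sigma_mm <= 0:
        raise ParameterError(f"sigma_mm must be positive, got {sigma_mm}")
    if not vol.is_isotropic:
        raise ParameterError("LoG filtering requires an isotropic grid")
    sigma = sigma_mm / vol.spacing[0]
    # explicit separable kernels with a zero-sum correction on the
    # second-derivative tap so constants and affine ramps map exactly to 0
    # (a truncated sampled Gaussian kernel leaves a small DC residual)
    radius = max(int(np.ceil(4.0 * sigma)), 1)
    t = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(t**2) / (2.0 * sigma**2))
    g /= g.sum()
    d2 = ((t**2 - sigma**2) / sigma**4) * g
    d2 -= d2.mean()
    x = np.asarray(vol.voxels, dtype=np.float64)
    out = np.zeros_like(x)
    for axis in range(3):
        part = x
        for other in range(3):
            kern = d2 if other == axis else g
            part = ndimage.correlate1d(part, kern, axis=other, mode="nearest")
        out += part
    return replace(vol, voxels=out)


def _analysis_filters() -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(_WAVELET)
    return np.asarray(w.dec_lo, dtype=np.float64), np.asarray(w.dec_hi, dtype=np.float64)


def wavelet_subbands(vol: VolumeGrid) -> dict[str, VolumeGrid]:
    """Single-level stationary 3D wavelet decomposition (Coiflet-1).

    Returns the 8 shape-preserving subbands ``LLL .. HHH``; the first
    letter names the filter applied along axis 0 (physical x).  Boundary
    handling is periodic (circular correlation).
    """
    lo, hi = _analysis_filters()
    x = np.asarray(vol.voxels, dtype=np.float64)
    if min(x.shape) < len(lo):
        raise InputError(
            f"volume extent {x.shape} smaller than the wavelet filter length {len(lo)}"
        )
    out: dict[str, VolumeGrid] = {}
    for name in SUBBAND_NAMES:
        sub = x
        for axis, letter in enumerate(name):
            kern = lo if letter == "L" else hi
            sub = ndimage.correlate1d(sub, kern, axis=axis, mode="wrap", origin=0)
        out[name] = replace(vol, voxels=sub)
    return out


def reconstruct_from_subbands(subbands: dict[str, VolumeGrid]) -> VolumeGrid:
    """Invert :func:`wavelet_subbands` (exact up to numerical round-off)."""
    lo, hi = _analysis_filters()
    acc = None
    ref = subbands["LLL"]
    for name in SUBBAND_NAMES:
        sub = np.asarray(subbands[name].voxels, dtype=np.float64)
        for axis, letter in enumerate(name):
            kern = lo if letter == "L" else hi
            sub = ndimage.convolve1d(sub, kern, axis=axis, mode="wrap", origin=0)
        acc = sub if acc is None else acc + sub
    return replace(ref, voxels=acc / 8.0)
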