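"""Non-decimated (stationary) wavelet transforms along spatial and temporal axes.

Thin wrapper over PyWavelets' ``swtn``/``iswtn`` with the energy-preserving
normalization, so that the analysis operator is a Parseval tight frame:
``sum_i |c_i|^2 == ||u||^2`` and the round trip is exact to machine
precision.  Complex input is supported natively.

The dynamic image series is stored as (t, y, x); ``axes=(1, 2)`` gives the
spatial transform, ``axes=(0,)`` the temporal one.
"""

from __future__ import annotations

import numpy as np
import pywt

__all__ = ["nwt_forward", "nwt_inverse", "nwt_threshold"]


def _check(data: np.ndarray, axes: tuple[int, ...], levels: int):
    need = 2 ** levels
    for ax in axes:
        n = data.shape[ax]
        if n % need or n < need:
            raise ValueError(
                f"axis {ax} has length {n}; the undecimated transform at "
                f"{levels} level(s) needs a multiple of {need} "
                f"(minimum {need})")


def nwt_forward(data: np.ndarray, wavelet: str = "db2", levels: int = 1,
                axes: tuple[int, ...] = (-2, -1)) -> list:
    """Undecimated wavelet decomposition along ``axes``.

    Returns the PyWavelets ``swtn`` coefficient list (approximation array
    first, then one dict of detail bands per level), normalized so the
    transform preserves energy.
    """
    data = np.asarray(data)
    axes = tuple(ax % data.ndim for ax in axes)
    _check(data, axes, levels)
    return pywt.swtn(data, wavelet, level=levels, axes=axes,
                     trim_approx=True, norm=True)


def nwt_inverse(coeffs: list, wavelet: str = "db2",
                axes: tuple[int, ...] = (-2, -1)) -> np.ndarray:
    """Exact inverse of :func:`nwt_forward`."""
    ndim = coeffs[0].ndim
    axes = tuple(ax % ndim for ax in axes)
    return pywt.iswtn(coeffs, wavelet, axes=axes, norm=True)


def _soft(x: np.ndarray, thr: float) -> np.ndarray:
    mag = np.abs(x)
    scale = np.maximum(mag - thr, 0.0) / np.maximum(mag, 1e-30)
    return x * scale


def nwt_threshold(data: np.ndarray, thr: float, wavelet: str = "db2",
                  levels: int = 1, axes: tuple[int, ...] = (-2, -1)
                  ) -> np.ndarray:
    """Complex magnitude soft-thresholding of the detail bands.

    The approximation band is left untouched; this is the proximal step of
    the l1 penalty on the tight-frame coefficients (exact up to the usual
    frame redundancy approximation).
    """
    if thr <= 0:
        return np.asarray(data)
    coeffs = nwt_forward(data, wavelet, levels, axes)
    out = [coeffs[0]]
    for level in coeffs[1:]:
        out.append({k: _soft(v, thr) for k, v in level.items()})
    return nwt_inverse(out, wavelet, axes)


def nwt_l1(data: np.ndarray, wavelet: str = "db2", levels: int = 1,
           axes: tuple[int, ...] = (-2, -1)) -> float:
    """l1 norm of the detail coefficients (for objective tracking)."""
    coeffs = nwt_forward(data, wavelet, levels, axes)
    return float(sum(np.sum(np.abs(v)) for level in coeffs[1:]
                     for v in level.values()))
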