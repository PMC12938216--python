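"""ESPIRiT coil-sensitivity estimation from the time-averaged FC data.

Autocalibrated eigenvector maps: all flow-compensated readouts are pooled
and gridded (density-compensated adjoint NUFFT) into one time-averaged
multi-coil image; its central Cartesian k-space block forms the calibration
region.  A block-Hankel calibration matrix is decomposed by SVD, kernels
above the singular-value threshold are transformed to image space, and the
per-pixel eigendecomposition of the resulting C x C operator yields the
sensitivity maps wherever the leading eigenvalue is close to one.

All steps are deterministic: LAPACK's SVD/eigh plus a fixed per-pixel phase
normalization to a reference coil.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as spfft

from .nufft import NufftPlan
from .phantom import CoilMaps, KSpaceData
from .trajectory import density_compensation_weights

__all__ = ["estimate_coil_maps", "espirit_maps", "CalibrationError"]


class CalibrationError(ValueError):
    """Raised when the pooled FC data cannot support calibration."""


def time_averaged_fc_image(kspace: KSpaceData) -> np.ndarray:
    """Gridding reconstruction of the pooled flow-compensated readouts."""
    sel = kspace.encoding == "FC"
    if not np.any(sel):
        raise CalibrationError("no flow-compensated readouts present")
    traj = kspace.traj[sel].reshape(-1, 2)
    data = np.moveaxis(kspace.data[sel], 1, 0).reshape(
        kspace.data.shape[1], -1)
    matrix = int(kspace.header["matrix"])
    pixel = float(kspace.header["fov_mm"]) / matrix
    w = density_compensation_weights(traj)
    plan = NufftPlan(traj, matrix, pixel)
    return plan.adjoint(data, weights=w)


def estimate_coil_maps(kspace: KSpaceData, calib_size: int = 24,
                       kernel_size: int = 6, sigma_rel: float = 0.02,
                       eig_cutoff: float = 0.95) -> CoilMaps:
    """ESPIRiT maps from the time-averaged flow-compensated image."""
    img = time_averaged_fc_image(kspace)
    matrix = img.shape[-1]
    if calib_size + kernel_size > matrix:
        raise CalibrationError(
            f"matrix {matrix} too small for a {calib_size} calibration "
            f"region with {kernel_size} kernels")
    ksp = spfft.fftshift(spfft.fft2(spfft.ifftshift(img, axes=(-2, -1)),
                                    axes=(-2, -1)), axes=(-2, -1))
    return CoilMaps(espirit_maps(ksp, calib_size, kernel_size,
                                 sigma_rel, eig_cutoff))


def espirit_maps(ksp: np.ndarray, calib_size: int = 24, kernel_size: int = 6,
                 sigma_rel: float = 0.02, eig_cutoff: float = 0.95
                 ) -> np.ndarray:
    """ESPIRiT on Cartesian multi-coil k-space (n_coils, N, N)."""
    nc, ny, nx = ksp.shape
    c, k = calib_size, kernel_size
    y0, x0 = (ny - c) // 2, (nx - c) // 2
    calib = ksp[:, y0:y0 + c, x0:x0 + c]

    # block-Hankel calibration matrix: sliding k x k patches
    npos = c - k + 1
    rows = np.empty((npos * npos, nc * k * k), complex)
    idx = 0
    for iy in range(npos):
        for ix in range(npos):
            rows[idx] = calib[:, iy:iy + k, ix:ix + k].ravel()
            idx += 1
    _, s, vh = np.linalg.svd(rows, full_matrices=False)
    if s[0] <= 0:
        raise CalibrationError("calibration region is empty")
    kernels = vh[s > sigma_rel * s[0]].conj()          # (n_kern, nc*k*k)
    nk = kernels.shape[0]
    kernels = kernels.reshape(nk, nc, k, k)

    # transform kernels to image space (zero-padded, flipped)
    pad = np.zeros((nk, nc, ny, nx), complex)
    pad[:, :, :k, :k] = kernels[:, :, ::-1, ::-1]
    pad = np.roll(pad, (-(k // 2), -(k // 2)), axis=(-2, -1))
    # scale so the per-pixel operator has unit leading eigenvalue over the
    # object support (kernels are unit-norm over nc*k*k entries)
    kern_img = spfft.fftshift(
        spfft.ifft2(pad, axes=(-2, -1)), axes=(-2, -1)) * (ny * nx / k)

    # per-pixel nc x nc operator G^H G, leading eigenvector = sensitivity
    g = np.transpose(kern_img, (2, 3, 0, 1))           # (ny, nx, nk, nc)
    gram = np.einsum("...ki,...kj->...ij", g.conj(), g)
    eigval, eigvec = np.linalg.eigh(gram)
    lead = eigval[..., -1]
    maps = eigvec[..., -1]                             # (ny, nx, nc)

    # deterministic phase: reference the coil with the largest mean weight
    ref = int(np.argmax(np.mean(np.abs(maps), axis=(0, 1))))
    phase = np.exp(-1j * np.angle(maps[..., ref]))
    maps = maps * phase[..., None]
    maps = np.where(lead[..., None] >= eig_cutoff, maps, 0.0)
    return np.transpose(maps, (2, 0, 1))
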