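"""ISMRM Raw Data (MRD)-style HDF5 I/O and NIfTI image-series export.

The raw-data writer lays one acquisition per readout under ``/dataset`` with
its trajectory attached, an XML header carrying FOV / matrix / TR / VENC,
and user parameters for the velocity-encoding label and frame index (the
MRD standard reserves no canonical slot for phase-contrast encoding labels,
so the keys below are fixed and documented here):

* ``/dataset/xml``            — XML header (encoded FOV, matrix, TR, VENC)
* ``/dataset/data``           — (n_acq, n_coils, n_k) complex64 samples
* ``/dataset/traj``           — (n_acq, n_k, 2) float32, cycles/mm
* ``/dataset/encoding_label`` — "FC"/"FE" per acquisition
* ``/dataset/frame_index``, ``/dataset/base_angle_deg``,
  ``/dataset/timestamp_ms``   — per-acquisition metadata

Since all readouts share one interleaf length the fixed-length layout is
lossless.  Image series go to NIfTI with the frame interval in
``pixdim[4]`` and venc/units/config hash in the description plus a JSON
sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from xml.etree import ElementTree as ET

import h5py
import numpy as np

from .phantom import KSpaceData

__all__ = ["write_mrd", "read_mrd", "MrdFormatError",
           "write_image_series", "read_image_series"]


class MrdFormatError(ValueError):
    """Malformed raw-data file; the message names the offending record."""


def _header_xml(header: dict) -> str:
    root = ET.Element("ismrmrdHeader")
    enc = ET.SubElement(root, "encoding")
    fov = ET.SubElement(enc, "encodedSpace")
    ET.SubElement(fov, "fieldOfView_mm").text = str(header.get("fov_mm"))
    ET.SubElement(fov, "matrixSize").text = str(header.get("matrix"))
    seq = ET.SubElement(root, "sequenceParameters")
    ET.SubElement(seq, "TR").text = str(header.get("tr_ms"))
    up = ET.SubElement(root, "userParameters")
    for key, val in sorted(header.items()):
        p = ET.SubElement(up, "userParameterDouble")
        ET.SubElement(p, "name").text = str(key)
        ET.SubElement(p, "value").text = str(val)
    return ET.tostring(root, encoding="unicode")


def write_mrd(kspace: KSpaceData, path) -> Path:
    """Write the k-space bundle; round-trips losslessly via
    :func:`read_mrd`."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("dataset")
        g.create_dataset("xml", data=_header_xml(kspace.header))
        g.create_dataset("data", data=kspace.data.astype(np.complex64))
        g.create_dataset("traj", data=kspace.traj.astype(np.float32))
        g.create_dataset("encoding_label",
                         data=np.char.encode(kspace.encoding, "ascii"))
        g.create_dataset("base_angle_deg", data=kspace.base_angle)
        g.create_dataset("timestamp_ms", data=kspace.timestamp)
        g.create_dataset("frame_index", data=kspace.frame_index)
        for key, val in kspace.header.items():
            g.attrs[key] = val
    return path


def read_mrd(path) -> KSpaceData:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "dataset" not in f:
            raise MrdFormatError(f"{path}: missing /dataset group")
        g = f["dataset"]
        for name in ("data", "traj", "encoding_label"):
            if name not in g:
                raise MrdFormatError(
                    f"{path}: missing required record /dataset/{name}")
        data = g["data"][()].astype(np.complex64)
        traj = g["traj"][()].astype(np.float32)
        if traj.shape[:1] != data.shape[:1] or traj.shape[1] != data.shape[2]:
            raise MrdFormatError(
                f"{path}: /dataset/traj shape {traj.shape} inconsistent "
                f"with data {data.shape}")
        enc = np.char.decode(g["encoding_label"][()].astype("S2"), "ascii")
        header = {k: _native(v) for k, v in g.attrs.items()}
        return KSpaceData(
            data=data, traj=traj, encoding=enc,
            base_angle=g["base_angle_deg"][()],
            timestamp=g["timestamp_ms"][()],
            frame_index=g["frame_index"][()].astype(int),
            header=header)


def _native(v):
    if isinstance(v, np.generic):
        return v.item()
    return v


# ---------------------------------------------------------------------------
# NIfTI image series


def write_image_series(array: np.ndarray, path, pixel_mm: float,
                       frame_interval_ms: float, units: str,
                       metadata: dict | None = None) -> Path:
    """Write a (n_frames, N, N) series as NIfTI (x, y, t on disk).

    ``units`` and any metadata land in the description field (truncated to
    the NIfTI limit) and, completely, in a JSON sidecar next to the file.
    """
    import nibabel as nib
    path = Path(path)
    array = np.asarray(array)
    vol = np.moveaxis(array, 0, -1)[:, :, None, :]  # x, y, z=1, t
    affine = np.diag([pixel_mm, pixel_mm, 1.0, 1.0])
    img = nib.Nifti1Image(vol.astype(np.float32), affine)
    img.header["pixdim"][4] = frame_interval_ms * 1e-3
    img.header.set_xyzt_units(xyz="mm", t="sec")
    meta = {"units": units, "frame_interval_ms": frame_interval_ms}
    if metadata:
        meta.update(metadata)
    img.header["descrip"] = json.dumps(meta)[:79].encode()
    nib.save(img, path)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, default=str))
    return path


def read_image_series(path) -> tuple[np.ndarray, dict]:
    """Read back a series written by :func:`write_image_series`."""
    import nibabel as nib
    path = Path(path)
    img = nib.load(path)
    vol = np.asanyarray(img.dataobj)
    array = np.moveaxis(vol[:, :, 0, :], -1, 0)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return array, meta
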