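"""NIfTI / bvec-bval / YAML readers and writers.

Volumes travel as NIfTI with the isotropic voxel spacing (μm, stored as mm in
the header per NIfTI convention is avoided — the header zooms carry the
spacing in μm directly, with the unit code set to micron). Vector and tensor
fields are 4D NIfTI with the component axis last. Gradient schemes use
FSL-style ``bvec``/``bval`` text files (three rows of direction components,
one row of b-values).
"""
from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import yaml

from .core import TensorField3D, Volume3D

_MICRON_CODE = 3  # NIfTI xyzt_units spatial code for micrometres


def _affine(spacing: float) -> np.ndarray:
    aff = np.diag([spacing, spacing, spacing, 1.0])
    return aff


def save_volume(path: str | os.PathLike, volume: Volume3D) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), _affine(volume.spacing))
    img.header.set_xyzt_units(xyz=_MICRON_CODE)
    nib.save(img, os.fspath(path))


def load_volume(path: str | os.PathLike) -> Volume3D:
    img = nib.load(os.fspath(path))
    zooms = img.header.get_zooms()[:3]
    return Volume3D(np.asarray(img.dataobj, dtype=float), float(zooms[0]))


def save_vector_field(path: str | os.PathLike, field: np.ndarray, spacing: float) -> None:
    """Write an (nx, ny, nz, k) field as 4D NIfTI."""
    img = nib.Nifti1Image(np.asarray(field, dtype=np.float32), _affine(spacing))
    img.header.set_xyzt_units(xyz=_MICRON_CODE)
    nib.save(img, os.fspath(path))


def load_vector_field(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    img = nib.load(os.fspath(path))
    return np.asarray(img.dataobj, dtype=float), float(img.header.get_zooms()[0])


_TENSOR_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def save_tensor_field(path: str | os.PathLike, field: TensorField3D) -> None:
    """Write the 6 unique components (xx, yy, zz, xy, xz, yz) as 4D NIfTI."""
    comps = np.stack([field.tensors[..., i, j] for i, j in _TENSOR_IDX], axis=-1)
    save_vector_field(path, comps, field.spacing)


def load_tensor_field(path: str | os.PathLike) -> TensorField3D:
    comps, spacing = load_vector_field(path)
    t = np.empty(comps.shape[:3] + (3, 3))
    for k, (i, j) in enumerate(_TENSOR_IDX):
        t[..., i, j] = comps[..., k]
        t[..., j, i] = comps[..., k]
    return TensorField3D(t, spacing)


def save_bvec_bval(prefix: str | os.PathLike, directions: np.ndarray, bvals: np.ndarray) -> None:
    """Write FSL-style ``<prefix>.bvec`` / ``<prefix>.bval`` files."""
    prefix = os.fspath(prefix)
    np.savetxt(prefix + ".bvec", np.asarray(directions).T, fmt="%.10f")
    np.savetxt(prefix + ".bval", np.asarray(bvals)[None, :], fmt="%.6g")


def load_bvec_bval(prefix: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    prefix = os.fspath(prefix)
    directions = np.loadtxt(prefix + ".bvec").T
    bvals = np.atleast_1d(np.loadtxt(prefix + ".bval")).ravel()
    return directions, bvals


def save_yaml(path: str | os.PathLike, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def load_yaml(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
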