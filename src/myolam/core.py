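"""Shared in-memory containers for volumes, tensor fields and orientation data.

Conventions used throughout the package:

* voxel indices are 0-based, positions are voxel centers, spatial units are
  micrometres (μm);
* volumes are isotropic (a single scalar spacing);
* orientation vectors are *axial* (defined up to sign) unless stated
  otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidityError(ValueError):
    """A parameter or input violates a documented precondition."""


class ResolutionError(ValidityError):
    """The requested structure cannot be represented on the voxel grid."""


@dataclass
class Volume3D:
    """Scalar 3D image with isotropic voxel spacing in μm."""

    data: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidityError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not self.spacing > 0:
            raise ValidityError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates in μm."""
        return tuple(np.arange(n) * self.spacing for n in self.shape)  # type: ignore[return-value]


@dataclass
class TensorField3D:
    """Per-voxel symmetric 3x3 tensor field (structure or diffusion tensor)."""

    tensors: np.ndarray  # (nx, ny, nz, 3, 3)
    spacing: float

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors)
        if self.tensors.ndim != 5 or self.tensors.shape[-2:] != (3, 3):
            raise ValidityError("tensors must have shape (nx, ny, nz, 3, 3)")
        if not self.spacing > 0:
            raise ValidityError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]  # type: ignore[return-value]

    def trace(self) -> np.ndarray:
        return np.trace(self.tensors, axis1=-2, axis2=-1)


@dataclass
class GroundTruth:
    """Known per-voxel orthonormal structural triad of a phantom.

    ``m`` is the myocyte long-axis, ``s`` the sheet in-plane direction and
    ``n`` the sheet (laminar) normal; each has shape ``(nx, ny, nz, 3)``.
    """

    m: np.ndarray
    s: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        for name in ("m", "s", "n"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 4 or v.shape[-1] != 3:
                raise ValidityError(f"{name} must have shape (nx, ny, nz, 3)")
            setattr(self, name, v)


@dataclass
class EigenField:
    """Sorted eigen-decomposition of a tensor field.

    ``eigvals[..., 0] >= eigvals[..., 1] >= eigvals[..., 2]`` and
    ``eigvecs[..., i, :]`` is the unit eigenvector paired with
    ``eigvals[..., i]``.
    """

    eigvals: np.ndarray  # (nx, ny, nz, 3), descending
    eigvecs: np.ndarray  # (nx, ny, nz, 3, 3), row i <-> eigvals[..., i]
    spacing: float
    flags: dict[str, np.ndarray] = field(default_factory=dict)


def normalize(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Unit-normalize vectors along ``axis``; zero vectors raise."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(norm == 0):
        raise ValidityError("cannot normalize a zero vector")
    return v / norm


def fix_eigenvector_signs(eigvecs: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude component positive.

    Ties are broken by the first component attaining the maximum magnitude
    (via argmax), giving a deterministic axial representative.
    """
    vecs = np.asarray(eigvecs, dtype=float)
    comp = np.argmax(np.abs(vecs), axis=-1, keepdims=True)
    lead = np.take_along_axis(vecs, comp, axis=-1)
    sign = np.where(lead < 0, -1.0, 1.0)
    return vecs * sign


def sorted_eigh(tensors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decompose symmetric tensors, sorted by descending eigenvalue.

    Returns ``(eigvals, eigvecs)`` with ``eigvecs[..., i, :]`` the unit
    eigenvector of ``eigvals[..., i]``, sign-fixed per
    :func:`fix_eigenvector_signs`.
    """
    tensors = np.asarray(tensors, dtype=float)
    if not np.all(np.isfinite(tensors)):
        raise ValidityError("tensor field contains non-finite components")
    w, v = np.linalg.eigh(tensors)  # ascending, columns are eigenvectors
    w = w[..., ::-1]
    v = np.swapaxes(v, -2, -1)[..., ::-1, :]  # rows, descending order
    return w, fix_eigenvector_signs(v)
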