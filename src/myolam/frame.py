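"""Cylindrical cardiac reference frame, projection angles and ROI cuboids.

The frame is defined by a user-supplied left-ventricular long-axis point and
direction (apex → base). At every voxel off the axis, the local orthonormal
basis is: longitudinal ``l`` (the axis direction, constant), radial ``r``
(the normalized rejection of the voxel offset from ``l``), and
circumferential ``c = l × r`` (right-handed).

Four projection angles are defined for an *axial* vector field (v ≡ −v),
each folded into (−90°, +90°]:

* helix angle α′ = atan2(v·l, v·c): between the short-axis plane and the
  projection of v onto the wall-tangent (c–l) plane;
* myocyte transverse angle α″ = atan2(v·r, v·c): between the wall-tangent
  plane and the projection onto the short-axis (c–r) plane;
* sheet elevation β′ = atan2(v·l, v·r): between the short-axis plane and
  the projection onto the long-axis (r–l) plane;
* sheet transverse β″ = atan2(v·c, v·r): between the longitudinal–radial
  plane and the projection onto the short-axis plane.

These are the *apparent* (projected) sheet angles; the absolute sheet angle
is deliberately not computed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidityError, normalize

_DEGENERATE_TOL = 1e-12


@dataclass
class CardiacFrame:
    """Per-voxel (c, l, r) basis; ``on_axis`` flags undefined voxels."""

    c: np.ndarray  # (..., 3) circumferential
    l: np.ndarray  # (..., 3) longitudinal (constant)
    r: np.ndarray  # (..., 3) radial
    on_axis: np.ndarray  # (...,) bool
    axis_point: np.ndarray = None  # type: ignore[assignment]
    axis_direction: np.ndarray = None  # type: ignore[assignment]


def build_frame(shape: tuple[int, int, int], spacing: float,
                axis_point, axis_direction) -> CardiacFrame:
    """Local cylindrical basis for every voxel of a grid.

    ``axis_point`` is in μm in voxel-centre coordinates; ``axis_direction``
    need not be normalized. Voxels lying exactly on the axis are flagged and
    must be excluded from angle maps.
    """
    l_hat = normalize(np.asarray(axis_direction, dtype=float))
    p0 = np.asarray(axis_point, dtype=float)
    idx = np.indices(shape).astype(float)
    pos = np.stack([idx[i] * spacing for i in range(3)], axis=-1) - p0
    axial = np.einsum("...i,i->...", pos, l_hat)
    rej = pos - axial[..., None] * l_hat
    norm = np.linalg.norm(rej, axis=-1)
    on_axis = norm < _DEGENERATE_TOL
    safe = np.where(on_axis, 1.0, norm)
    r = rej / safe[..., None]
    r[on_axis] = np.array([np.nan, np.nan, np.nan])
    l = np.broadcast_to(l_hat, r.shape).copy()
    c = np.cross(l, r)
    return CardiacFrame(c=c, l=l, r=r, on_axis=on_axis,
                        axis_point=p0, axis_direction=l_hat)


def fold_axial_degrees(angle: np.ndarray) -> np.ndarray:
    """Fold angles (degrees) into (−90, +90] under the v ≡ −v symmetry."""
    a = np.asarray(angle, dtype=float)
    out = (a + 90.0) % 180.0 - 90.0
    out = np.where(out == -90.0, 90.0, out)
    return out


def _projection_angle(v: np.ndarray, num_basis: np.ndarray, den_basis: np.ndarray
                      ) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    num = np.einsum("...i,...i->...", v, num_basis)
    den = np.einsum("...i,...i->...", v, den_basis)
    ang = np.degrees(np.arctan2(num, den))
    out = fold_axial_degrees(ang)
    degenerate = (np.abs(num) < _DEGENERATE_TOL) & (np.abs(den) < _DEGENERATE_TOL)
    return np.where(degenerate, np.nan, out)


def helix_angle(v: np.ndarray, frame: CardiacFrame) -> np.ndarray:
    """α′ — 0° for circumferential vectors, +90° for longitudinal."""
    return _projection_angle(v, frame.l, frame.c)


def transverse_angle_myocyte(v: np.ndarray, frame: CardiacFrame) -> np.ndarray:
    """α″ — 0° for circumferential vectors, 90° for radial."""
    return _projection_angle(v, frame.r, frame.c)


def sheet_elevation(v: np.ndarray, frame: CardiacFrame) -> np.ndarray:
    """β′ — 0° for radial vectors, 90° for longitudinal."""
    return _projection_angle(v, frame.l, frame.r)


def sheet_transverse(v: np.ndarray, frame: CardiacFrame) -> np.ndarray:
    """β″ — 0° for radial vectors, 90° for circumferential."""
    return _projection_angle(v, frame.c, frame.r)


def angle_maps(v: np.ndarray, frame: CardiacFrame) -> dict[str, np.ndarray]:
    """All four projection angles of an axial vector field; NaN on-axis."""
    out = {
        "helix": helix_angle(v, frame),
        "transverse_myocyte": transverse_angle_myocyte(v, frame),
        "sheet_elevation": sheet_elevation(v, frame),
        "sheet_transverse": sheet_transverse(v, frame),
    }
    for k in out:
        out[k] = np.where(frame.on_axis, np.nan, out[k])
    return out


@dataclass
class ROISpec:
    """Cuboid ROI in frame coordinates.

    ``theta_range`` is an angular sector in degrees (measured about the long
    axis from +x, counter-clockwise, interval possibly wrapping past 180);
    ``radial_range`` the transmural span in μm (endocardium first);
    ``z_range`` the longitudinal span in μm along the axis.
    """

    name: str
    theta_range: tuple[float, float]
    radial_range: tuple[float, float]
    z_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.radial_range[0] < self.radial_range[1]:
            raise ValidityError("radial_range must be increasing")
        if not self.z_range[0] < self.z_range[1]:
            raise ValidityError("z_range must be increasing")


def standard_rois(radial_range: tuple[float, float], z_range: tuple[float, float],
                  half_width_deg: float = 30.0) -> list[ROISpec]:
    """Lateral / anterior / septal / posterior equatorial sectors.

    Sector centres at 0°, 90°, 180° and 270° about the long axis; with
    ``half_width_deg`` below 45° the four sectors do not overlap.
    """
    if half_width_deg >= 45.0:
        raise ValidityError("sectors of half-width >= 45 degrees would overlap")
    names = ["lateral", "anterior", "septal", "posterior"]
    return [
        ROISpec(name, (c - half_width_deg, c + half_width_deg), radial_range, z_range)
        for name, c in zip(names, [0.0, 90.0, 180.0, 270.0])
    ]


def roi_membership(shape: tuple[int, int, int], spacing: float,
                   frame: CardiacFrame, roi: ROISpec
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean membership mask and normalized transmural depth per voxel.

    Depth is 0 at the ROI's endocardial radius and 1 at its epicardial
    radius. Voxels on the axis are never members.
    """
    idx = np.indices(shape).astype(float)
    pos = np.stack([idx[i] * spacing for i in range(3)], axis=-1) - frame.axis_point
    l_hat = frame.axis_direction
    z = np.einsum("...i,i->...", pos, l_hat)
    rej = pos - z[..., None] * l_hat
    rho = np.linalg.norm(rej, axis=-1)

    # azimuth about the axis relative to a fixed reference perpendicular
    ref = np.eye(3)[int(np.argmin(np.abs(l_hat)))]
    e1 = normalize(ref - np.dot(ref, l_hat) * l_hat)
    e2 = np.cross(l_hat, e1)
    theta = np.degrees(np.arctan2(np.einsum("...i,i->...", rej, e2),
                                  np.einsum("...i,i->...", rej, e1))) % 360.0

    t0, t1 = np.mod(roi.theta_range[0], 360.0), np.mod(roi.theta_range[1], 360.0)
    if roi.theta_range[1] - roi.theta_range[0] >= 360.0:
        in_theta = np.ones_like(theta, dtype=bool)
    elif t0 <= t1:
        in_theta = (theta >= t0) & (theta <= t1)
    else:  # sector wraps through 0
        in_theta = (theta >= t0) | (theta <= t1)
    r0, r1 = roi.radial_range
    z0, z1 = roi.z_range
    member = in_theta & (rho >= r0) & (rho <= r1) & (z >= z0) & (z <= z1)
    member &= ~frame.on_axis
    depth = np.where(member, (rho - r0) / (r1 - r0), np.nan)
    return member, depth


def extract_roi(field: np.ndarray, shape: tuple[int, int, int], spacing: float,
                frame: CardiacFrame, roi: ROISpec) -> dict[str, np.ndarray]:
    """Values of ``field`` inside the ROI plus their transmural depths.

    ``field`` may be scalar per voxel or vector-valued (extra trailing
    axes). Returns ``{"values", "depth", "mask", "empty"}``; an empty
    selection sets the warning flag rather than raising.
    """
    member, depth = roi_membership(shape, spacing, frame, roi)
    values = np.asarray(field)[member]
    return {"values": values, "depth": depth[member], "mask": member,
            "empty": not bool(member.any())}
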