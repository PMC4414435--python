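"""Direct laminar-normal measurement from an intensity isosurface.

The structural volume is upsampled 4× by tricubic spline interpolation
(50 μm → 12.5 μm voxels), an isosurface is extracted at a threshold between
the lamina and interstice intensities, and the triangle mesh is partitioned
into 200 μm boxes aligned with the DTI/ST grid. Within each box the axial
mean normal n^FI is the principal eigenvector of the area-weighted scatter
matrix Σ wᵢ nᵢ nᵢᵀ of the contained face normals — a sign-invariant mean,
as triangle normals are orientation-ambiguous. Boxes whose normals are not
tightly concentrated (branching or multiple laminar orientations) are
rejected by thresholding the von Mises–Fisher concentration parameter K.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import ValidityError, Volume3D

K_THRESHOLD = 7.0  # vMF concentration below which a box's normals are too spread
MIN_FACES = 10
K_CAP = 1e6  # sentinel for perfectly concentrated boxes (R̄ = 1)


def upsample(volume: Volume3D, factor: int = 4) -> Volume3D:
    """Tricubic spline upsampling at the voxel centres of the refined grid.

    The output spacing is ``input spacing / factor``; refined voxel ``i``
    sits at position ``(i + 0.5)/factor - 0.5`` in input index units, so the
    refined centres tile the same physical extent.
    """
    if int(factor) != factor or factor < 1:
        raise ValidityError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return Volume3D(np.array(volume.data, dtype=float, copy=True), volume.spacing)
    coords = np.meshgrid(
        *[(np.arange(n * factor) + 0.5) / factor - 0.5 for n in volume.shape],
        indexing="ij",
    )
    out = ndimage.map_coordinates(np.asarray(volume.data, dtype=float),
                                  np.stack(coords), order=3, mode="mirror")
    return Volume3D(out, volume.spacing / factor)


@dataclass
class IsoMesh:
    """Triangle isosurface: vertices in μm, per-face unit normals and areas."""

    vertices: np.ndarray  # (n_verts, 3), μm
    faces: np.ndarray  # (n_faces, 3) vertex indices
    face_normals: np.ndarray  # (n_faces, 3), unit, oriented toward brighter side
    face_areas: np.ndarray  # (n_faces,), μm²

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)


def isosurface(volume: Volume3D, threshold: float) -> IsoMesh:
    """Marching-cubes isosurface with normals oriented toward brighter voxels.

    A threshold outside the intensity range yields an empty mesh (with a
    warning flag on the returned object) rather than an error.
    """
    data = np.asarray(volume.data, dtype=float)
    if not (data.min() < threshold < data.max()):
        mesh = IsoMesh(np.empty((0, 3)), np.empty((0, 3), dtype=int),
                       np.empty((0, 3)), np.empty(0))
        mesh.empty_warning = True  # type: ignore[attr-defined]
        return mesh
    spacing = (volume.spacing,) * 3
    verts, faces, _, _ = measure.marching_cubes(data, level=threshold, spacing=spacing)

    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    ok = areas > 0
    faces, cross, areas = faces[ok], cross[ok], areas[ok]
    normals = cross / (2.0 * areas[:, None])

    # orient toward the brighter (interstice) side via the intensity gradient
    centroids = verts[faces].mean(axis=1) / volume.spacing  # index units
    grad = np.gradient(data)
    g = np.stack([ndimage.map_coordinates(gi, centroids.T, order=1, mode="nearest")
                  for gi in grad], axis=-1)
    flip = np.einsum("ij,ij->i", normals, g) < 0
    normals[flip] *= -1.0
    return IsoMesh(verts, faces, normals, areas)


@dataclass
class BoxNormalSummary:
    """Per-box FI result on the 200 μm DTI/ST grid."""

    box_index: tuple[int, int, int]
    n_fi: np.ndarray  # unit axial mean normal (NaN if undefined)
    resultant_length: float  # R̄ in [0, 1]
    concentration: float  # vMF K
    n_faces: int
    keep: bool
    degenerate: bool = False  # near-tied scatter eigenvalues (multiple planes)


def axial_mean_normal(normals: np.ndarray, weights: np.ndarray | None = None
                      ) -> tuple[np.ndarray, float, bool]:
    """Axial mean of unit normals: principal scatter eigenvector and R̄.

    Returns ``(mean_axis, resultant_length, degenerate)``. The resultant
    length is computed after sign-aligning every normal with the mean axis;
    the degenerate flag is set when the top two scatter eigenvalues are
    within 5% (no single dominant orientation).
    """
    normals = np.asarray(normals, dtype=float)
    if len(normals) == 0:
        return np.full(3, np.nan), np.nan, True
    w = np.ones(len(normals)) if weights is None else np.asarray(weights, dtype=float)
    scatter = np.einsum("i,ij,ik->jk", w / w.sum(), normals, normals)
    evals, evecs = np.linalg.eigh(scatter)
    mean_axis = evecs[:, -1]
    signed = np.where(normals @ mean_axis >= 0, 1.0, -1.0)
    resultant = np.einsum("i,i,ij->j", w, signed, normals) / w.sum()
    r_bar = float(np.linalg.norm(resultant))
    degenerate = bool(evals[-1] - evals[-2] < 0.05 * max(evals[-1], 1e-300))
    return mean_axis, min(r_bar, 1.0), degenerate


def vmf_concentration(normals: np.ndarray, weights: np.ndarray | None = None) -> float:
    """vMF concentration K̂ = R̄(3 − R̄²)/(1 − R̄²) of sign-aligned normals.

    The closed-form 3-dimensional approximation of the maximum-likelihood
    estimate. Perfect concentration (R̄ = 1) returns the cap sentinel.
    Fewer than two normals is undefined (NaN).
    """
    normals = np.asarray(normals, dtype=float)
    if len(normals) < 2:
        return float("nan")
    _, r_bar, _ = axial_mean_normal(normals, weights)
    return concentration_from_resultant(r_bar)


def concentration_from_resultant(r_bar: float) -> float:
    """K̂ as a function of the mean resultant length alone."""
    if not 0 <= r_bar <= 1:
        raise ValidityError("resultant length must lie in [0, 1]")
    if r_bar >= 1.0 - 1e-12:
        return K_CAP
    return float(r_bar * (3.0 - r_bar**2) / (1.0 - r_bar**2))


def box_axial_normal(mesh: IsoMesh, box_um: float = 200.0,
                     k_threshold: float = K_THRESHOLD, min_faces: int = MIN_FACES,
                     origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
                     ) -> list[BoxNormalSummary]:
    """Axial mean normal and concentration per 200 μm grid box.

    Faces are assigned to boxes by centroid; boxes are anchored at
    ``origin`` so that they coincide with the native DTI/ST voxels. The keep
    flag requires both K ≥ ``k_threshold`` (inclusive) and at least
    ``min_faces`` contained faces.
    """
    if mesh.n_faces == 0:
        return []
    centroids = mesh.face_centroids() - np.asarray(origin, dtype=float)
    box_idx = np.floor(centroids / box_um).astype(int)
    order = np.lexsort(box_idx.T[::-1])
    sorted_idx = box_idx[order]
    boundaries = np.nonzero(np.any(np.diff(sorted_idx, axis=0) != 0, axis=1))[0] + 1
    groups = np.split(order, boundaries)

    summaries = []
    for grp in groups:
        idx = tuple(int(i) for i in box_idx[grp[0]])
        normals = mesh.face_normals[grp]
        areas = mesh.face_areas[grp]
        n_faces = len(grp)
        if n_faces < 2:
            summaries.append(BoxNormalSummary(idx, np.full(3, np.nan), np.nan,
                                              np.nan, n_faces, keep=False))
            continue
        mean_axis, r_bar, degenerate = axial_mean_normal(normals, areas)
        k = concentration_from_resultant(r_bar)
        keep = (k >= k_threshold) and (n_faces >= min_faces)
        summaries.append(BoxNormalSummary(idx, mean_axis, r_bar, k, n_faces,
                                          keep=keep, degenerate=degenerate))
    return summaries


def filter_boxes(summaries: list[BoxNormalSummary],
                 k_threshold: float = K_THRESHOLD,
                 min_faces: int = MIN_FACES) -> list[BoxNormalSummary]:
    """Boxes passing the (inclusive) concentration and face-count thresholds."""
    return [s for s in summaries
            if np.isfinite(s.concentration)
            and s.concentration >= k_threshold and s.n_faces >= min_faces]
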