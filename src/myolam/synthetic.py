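"""Synthetic laminar phantoms, tensor fields and diffusion-weighted signals.

The generators emulate the two image types the downstream analyses consume:

* a contrast-enhanced FLASH-like structural volume in which bright
  sheetlet-interstices alternate with dark myolaminae (laminar repeat
  ~80–120 μm at 50 μm isotropic voxels), together with the exact per-voxel
  structural triad (myocyte ``m``, sheet in-plane ``s``, sheet normal ``n``);
* monoexponential diffusion-weighted signals from a prescribed tensor field,
  with Rician noise as produced by magnitude MR reconstruction.

Two phantom geometries are available: an infinite laminar *slab* stack with a
fixed normal, and a cylindrical *annulus* whose myocyte direction follows a
linear transmural helix-angle rule (classically spanning ~120° from
endocardium to epicardium).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import (
    GroundTruth,
    ResolutionError,
    TensorField3D,
    ValidityError,
    Volume3D,
    normalize,
)

# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Parameters of a laminar phantom.

    Parameters
    ----------
    shape
        Voxels per axis.
    spacing
        Isotropic voxel spacing, μm.
    lamina_period
        Sheetlet + interstice repeat distance, μm. Must be at least two
        voxels so the laminar structure is resolvable.
    interstice_fraction
        Fraction (0–1) of each period occupied by the bright interstice.
    geometry
        ``"slab"`` or ``"annulus"``.
    helix_endo, helix_epi
        Transmural helix-angle endpoints in degrees (annulus only).
    sheet_elevation_rule
        Sheet-normal elevation angle in degrees as a function of normalized
        transmural depth (annulus only); a constant or a callable.
    noise_sigma
        Additive Gaussian intensity noise on the structural volume.
    seed
        Seed for the phantom's noise stream.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 50.0
    lamina_period: float = 120.0
    interstice_fraction: float = 0.4
    geometry: str = "slab"
    helix_endo: float = 60.0
    helix_epi: float = -60.0
    sheet_elevation_rule: float | Callable[[np.ndarray], np.ndarray] = 0.0
    noise_sigma: float = 0.0
    seed: int = 0
    background: float = 20.0
    contrast: float = 80.0
    inner_radius: float | None = None
    outer_radius: float | None = None

    def validate(self) -> None:
        if self.lamina_period < 2 * self.spacing:
            raise ResolutionError(
                f"lamina_period {self.lamina_period} μm is below the 2-voxel "
                f"limit ({2 * self.spacing} μm)"
            )
        if not 0 < self.interstice_fraction < 1:
            raise ValidityError("interstice_fraction must lie strictly in (0, 1)")
        if self.geometry not in ("slab", "annulus"):
            raise ValidityError(f"unknown geometry {self.geometry!r}")
        for a in (self.helix_endo, self.helix_epi):
            if not -90.0 <= a <= 90.0:
                raise ValidityError("helix angles must lie in [-90, 90] degrees")
        if self.noise_sigma < 0:
            raise ValidityError("noise_sigma must be non-negative")


GYROMAGNETIC_RATIO = 2 * np.pi * 42.58e6  # proton, rad s^-1 T^-1


@dataclass
class GradientScheme:
    """Diffusion gradient table: unit directions plus b-values, s/mm²."""

    directions: np.ndarray  # (n, 3); zero rows mark b0 acquisitions
    bvals: np.ndarray  # (n,)
    delta: float = 3.6e-3  # gradient pulse duration, s
    Delta: float = 11.5e-3  # gradient pulse separation, s
    gamma: float = GYROMAGNETIC_RATIO

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        if self.directions.ndim != 2 or self.directions.shape[1] != 3:
            raise ValidityError("directions must have shape (n, 3)")
        if self.bvals.shape != (self.directions.shape[0],):
            raise ValidityError("bvals must match the number of directions")
        if np.any(self.bvals < 0):
            raise ValidityError("b-values must be non-negative")
        if not self.delta < self.Delta:
            raise ValidityError("gradient duration delta must be below separation Delta")
        norms = np.linalg.norm(self.directions, axis=1)
        weighted = self.bvals > 0
        if np.any(np.abs(norms[weighted] - 1.0) > 1e-8):
            raise ValidityError("diffusion-weighted directions must be unit length")

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvals == 0


# Jones-style optimized direction sets; the 6-direction set is the classical
# dual-gradient scheme, the 12-direction set an electrostatic arrangement.
_DIRS6 = np.array(
    [[1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1], [0, 1, 1], [0, 1, -1]],
    dtype=float,
) / np.sqrt(2)

_PHI = (1 + np.sqrt(5)) / 2
_DIRS12 = np.array(
    [
        [0, 1, _PHI], [0, 1, -_PHI], [0, -1, _PHI], [0, -1, -_PHI],
        [1, _PHI, 0], [1, -_PHI, 0], [-1, _PHI, 0], [-1, -_PHI, 0],
        [_PHI, 0, 1], [_PHI, 0, -1], [-_PHI, 0, 1], [-_PHI, 0, -1],
    ],
    dtype=float,
)
_DIRS12 /= np.linalg.norm(_DIRS12, axis=1, keepdims=True)


def standard_scheme(n_dir: int = 6, b: float = 1000.0, **kwargs) -> GradientScheme:
    """Standard 6- or 12-direction scheme plus one leading b0 acquisition."""
    if n_dir == 6:
        dirs = _DIRS6
    elif n_dir == 12:
        dirs = _DIRS12
    else:
        raise ValidityError("n_dir must be 6 or 12")
    directions = np.vstack([np.zeros(3), dirs])
    bvals = np.concatenate([[0.0], np.full(n_dir, float(b))])
    return GradientScheme(directions, bvals, **kwargs)


# ---------------------------------------------------------------------------
# Laminar intensity profile
# ---------------------------------------------------------------------------


def lamina_profile(t: np.ndarray, period: float, interstice_fraction: float) -> np.ndarray:
    """Periodic raised-cosine laminar weight in [0, 1].

    ``t`` is a signed distance along the sheet normal (μm). Each period holds
    one smooth bright bump (the interstice) of full width
    ``interstice_fraction * period`` centred at phase 0; elsewhere the weight
    is 0 (lamina). The raised-cosine shape keeps intensity gradients
    well-defined on the voxel grid.
    """
    s = np.mod(np.asarray(t, dtype=float) / period, 1.0)
    d = np.minimum(s, 1.0 - s)  # phase distance from the bump centre, in periods
    h = interstice_fraction / 2.0
    w = np.where(d < h, 0.5 * (1.0 + np.cos(np.pi * d / h)), 0.0)
    return w


def _intensity(weight: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    return spec.background + spec.contrast * weight


# ---------------------------------------------------------------------------
# Phantom generators
# ---------------------------------------------------------------------------


def make_slab_phantom(spec: PhantomSpec, normal=(0.0, 0.0, 1.0)) -> tuple[Volume3D, GroundTruth]:
    """Stacked-laminae phantom with a single fixed sheet normal.

    The intensity at a voxel with centre position ``p`` is the laminar
    profile of ``p · n̂``, plus optional additive Gaussian noise. The
    ground-truth normal is ``n̂`` everywhere; ``m`` and ``s`` are a fixed
    orthonormal completion lying in the lamina plane.
    """
    spec.validate()
    n_hat = normalize(np.asarray(normal, dtype=float))

    idx = np.indices(spec.shape).astype(float)
    pos = idx * spec.spacing  # (3, nx, ny, nz), voxel centres
    t = np.einsum("i,i...->...", n_hat, pos)
    vol = _intensity(lamina_profile(t, spec.lamina_period, spec.interstice_fraction), spec)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)

    # orthonormal completion: m = most orthogonal grid axis, projected into
    # the lamina plane; s closes the right-handed triad
    axes = np.eye(3)
    a = axes[int(np.argmin(np.abs(n_hat)))]
    m_hat = normalize(a - np.dot(a, n_hat) * n_hat)
    s_hat = np.cross(n_hat, m_hat)

    ones = np.ones(spec.shape + (1,))
    truth = GroundTruth(m=ones * m_hat, s=ones * s_hat, n=ones * n_hat)
    return Volume3D(vol, spec.spacing), truth


def _elevation_at(spec: PhantomSpec, depth: np.ndarray) -> np.ndarray:
    rule = spec.sheet_elevation_rule
    if callable(rule):
        return np.asarray(rule(depth), dtype=float)
    return np.full_like(depth, float(rule))


def helix_angle_rule(spec: PhantomSpec, depth: np.ndarray) -> np.ndarray:
    """Linear transmural helix rule, degrees (0 = endocardium, 1 = epicardium)."""
    return spec.helix_endo + (spec.helix_epi - spec.helix_endo) * np.asarray(depth)


def make_annulus_phantom(spec: PhantomSpec) -> tuple[Volume3D, GroundTruth]:
    """Cylindrical-annulus phantom with a transmural helix-angle rule.

    Within the annulus (axis along z, centred in the xy plane) the myocyte
    direction ``m`` makes the helix angle α(depth) with the circumferential
    direction in the wall-tangent plane, interpolated linearly from
    ``helix_endo`` at the inner wall to ``helix_epi`` at the outer wall. The
    sheet normal ``n`` is the radial direction tilted out of the short-axis
    plane by ``sheet_elevation_rule(depth)``. The laminar intensity pattern
    is periodic in radius (concentric laminae); voxels outside the annulus
    are set to the background level.

    The frame is right-handed with circumferential = longitudinal × radial.
    """
    spec.validate()
    if spec.geometry != "annulus":
        raise ValidityError("spec.geometry must be 'annulus'")
    nx, ny, nz = spec.shape
    extent = min(nx, ny) * spec.spacing
    r_out = spec.outer_radius if spec.outer_radius is not None else 0.45 * extent
    r_in = spec.inner_radius if spec.inner_radius is not None else 0.5 * r_out
    if not r_in < r_out:
        raise ValidityError("inner radius must be below outer radius")
    if (r_out - r_in) < 3 * spec.spacing:
        raise ResolutionError("annulus wall thinner than 3 voxels")

    idx = np.indices(spec.shape).astype(float)
    cx = (nx - 1) / 2.0 * spec.spacing
    cy = (ny - 1) / 2.0 * spec.spacing
    x = idx[0] * spec.spacing - cx
    y = idx[1] * spec.spacing - cy
    rho = np.hypot(x, y)
    inside = (rho >= r_in) & (rho <= r_out)
    depth = np.clip((rho - r_in) / (r_out - r_in), 0.0, 1.0)

    safe_rho = np.where(rho == 0, 1.0, rho)
    r_hat = np.stack([x / safe_rho, y / safe_rho, np.zeros_like(x)], axis=-1)
    l_hat = np.broadcast_to(np.array([0.0, 0.0, 1.0]), r_hat.shape)
    c_hat = np.cross(l_hat, r_hat)

    alpha = np.deg2rad(helix_angle_rule(spec, depth))[..., None]
    m = np.cos(alpha) * c_hat + np.sin(alpha) * l_hat

    beta = np.deg2rad(_elevation_at(spec, depth))[..., None]
    e_t = np.cross(m, r_hat)  # in-plane direction orthogonal to m and r
    n = np.cos(beta) * r_hat + np.sin(beta) * e_t
    s = np.cross(n, m)

    weight = lamina_profile(rho, spec.lamina_period, spec.interstice_fraction)
    vol = np.where(inside, _intensity(weight, spec), spec.background)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)

    # outside the annulus the triad is meaningless; keep it orthonormal anyway
    fallback = np.array([1.0, 0.0, 0.0])
    bad = ~inside
    m[bad] = fallback
    s[bad] = [0.0, 1.0, 0.0]
    n[bad] = [0.0, 0.0, 1.0]

    truth = GroundTruth(m=m, s=s, n=n)
    truth.inside = inside  # type: ignore[attr-defined]
    truth.depth = depth  # type: ignore[attr-defined]
    return Volume3D(vol, spec.spacing), truth


# ---------------------------------------------------------------------------
# Tensor fields and diffusion-weighted signal simulation
# ---------------------------------------------------------------------------


def make_tensor_field(
    truth: GroundTruth, eigvals: tuple[float, float, float], spacing: float = 200.0
) -> TensorField3D:
    """Build D = λ1 m mᵀ + λ2 s sᵀ + λ3 n nᵀ per voxel (λ in mm²/s)."""
    lam = np.asarray(eigvals, dtype=float)
    if lam.shape != (3,) or np.any(lam <= 0):
        raise ValidityError("eigvals must be three positive values")
    if not (lam[0] >= lam[1] >= lam[2]):
        raise ValidityError("eigvals must be sorted descending")
    D = (
        lam[0] * np.einsum("...i,...j->...ij", truth.m, truth.m)
        + lam[1] * np.einsum("...i,...j->...ij", truth.s, truth.s)
        + lam[2] * np.einsum("...i,...j->...ij", truth.n, truth.n)
    )
    return TensorField3D(D, spacing)


def simulate_dwi(
    tensors: TensorField3D,
    scheme: GradientScheme,
    S0: float = 1000.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Monoexponential diffusion-weighted stack, shape (..., n_acq).

    Noiseless signal per acquisition k: ``S_k = S0 exp(-b_k g_kᵀ D g_k)``
    (b0 acquisitions give S0). Noise, when requested, is Rician: the
    magnitude of the complex signal with independent Gaussian noise of
    standard deviation ``noise_sigma`` on both channels.
    """
    if S0 <= 0:
        raise ValidityError("S0 must be positive")
    if noise_sigma < 0:
        raise ValidityError("noise_sigma must be non-negative")
    g = scheme.directions
    adc = np.einsum("ki,...ij,kj->...k", g, tensors.tensors, g)  # mm²/s
    signal = S0 * np.exp(-scheme.bvals * adc)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        re = signal + rng.normal(0.0, noise_sigma, size=signal.shape)
        im = rng.normal(0.0, noise_sigma, size=signal.shape)
        signal = np.hypot(re, im)
    return signal
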