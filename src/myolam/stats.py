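"""Axial orientation comparison statistics.

All orientation fields here are axial (v ≡ −v), so deviation angles live in
[0°, 90°] and angle differences are circular with period 180°. Summary
statistics follow the robust conventions used for these comparisons:
median ± MAD and median ± IQR, alongside mean ± SD.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import EigenField, ValidityError


def axial_angle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Deviation |cos⁻¹|a·b|| in degrees between unit axial vectors, ∈ [0, 90].

    Vectorized over leading axes; NaN inputs (flagged voxels) propagate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    dot = np.abs(np.einsum("...i,...i->...", a, b))
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(dot / (na * nb), 0.0, 1.0)
        out = np.degrees(np.arccos(cosang))
    out = np.where((na == 0) | (nb == 0), np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def angle_pair_difference(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Circular difference of two axial angles (degrees), ∈ [0, 90].

    d = min(|x − y|, 180 − |x − y|): 80° and −80° differ by 20°, not 160°.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = np.abs(x - y)
    out = np.minimum(d, 180.0 - d)
    if out.ndim == 0:
        return float(out)
    return out


def summarize(values) -> dict[str, float]:
    """Median, MAD, IQR (Q3 − Q1, linear-interpolation quantiles), mean, SD.

    NaNs are dropped (complete-case); an empty input returns all-NaN with a
    flag rather than raising.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {"median": np.nan, "mad": np.nan, "iqr": np.nan,
                "mean": np.nan, "sd": np.nan, "n": 0, "empty": True}
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    q1, q3 = np.quantile(v, [0.25, 0.75])
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return {"median": med, "mad": mad, "iqr": float(q3 - q1),
            "mean": float(np.mean(v)), "sd": sd, "n": int(v.size), "empty": False}


def quadrant_rose(deviations, n_bins: int = 9) -> pd.DataFrame:
    """Histogram of deviation angles over [0°, 90°] in equal-width bins.

    The last bin is right-closed so 90° is counted. Values outside [0, 90]
    are rejected. Returns a DataFrame with bin edges and counts; counts sum
    to the input size.
    """
    v = np.asarray(deviations, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if np.any((v < 0) | (v > 90)):
        raise ValidityError("deviation angles must lie in [0, 90] degrees")
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})


def axial_circular_mean(angles_deg: np.ndarray) -> float:
    """Mean of axial angles (period 180°) by the angle-doubling trick."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float) * 2.0)
    mean = np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))
    out = np.degrees(mean) / 2.0
    if out <= -90.0:
        out += 180.0
    return float(out)


def axial_circular_sd(angles_deg: np.ndarray) -> float:
    """Circular standard deviation (period 180°), mapped back to degrees."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float) * 2.0)
    r = float(np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a))))
    r = min(r, 1.0)
    if r == 0.0:
        return np.inf
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))) / 2.0)


def transmural_profile(angles_deg, depth, n_bins: int = 10) -> pd.DataFrame:
    """Per-depth-bin circular mean and dispersion of an axial angle map.

    ``depth`` is the normalized transmural coordinate in [0, 1] per sample;
    bins are equal width, the last right-closed. Empty bins are flagged.
    Dispersion is the period-180 circular SD.
    """
    a = np.asarray(angles_deg, dtype=float).ravel()
    d = np.asarray(depth, dtype=float).ravel()
    ok = np.isfinite(a) & np.isfinite(d)
    a, d = a[ok], d[ok]
    if np.any((d < 0) | (d > 1)):
        raise ValidityError("depth must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for i in range(n_bins):
        sel = a[which == i]
        if sel.size == 0:
            rows.append({"depth_mid": (edges[i] + edges[i + 1]) / 2, "mean": np.nan,
                         "sd": np.nan, "n": 0, "empty": True})
        else:
            rows.append({"depth_mid": (edges[i] + edges[i + 1]) / 2,
                         "mean": axial_circular_mean(sel),
                         "sd": axial_circular_sd(sel), "n": int(sel.size),
                         "empty": False})
    return pd.DataFrame(rows)


_EIGEN_PAIRS = {
    # (small index, large index) into the descending-sorted eigenvalues
    ("dti", "laminar"): (2, 1),  # λ3 vs λ2
    ("st", "laminar"): (1, 0),  # λ2 vs λ1 (ST laminar pair is λ1, λ2)
    ("dti", "myocyte"): (1, 0),  # λ2 vs λ1
    ("st", "myocyte"): (2, 1),  # λ3 vs λ2
}


def eigen_confidence_distribution(result: EigenField, modality: str, pair: str,
                                  cutoffs: tuple[float, ...] = (85.0, 90.0, 95.0)
                                  ) -> dict:
    """Per-voxel eigenvalue-ratio distribution for an assignment pair.

    The ratio 100·λ_small/λ_large measures sorting confidence: 100% means
    the two eigenvalues are identical and the corresponding eigenvectors
    cannot be meaningfully ordered. ``modality`` is ``"st"`` or ``"dti"``,
    ``pair`` is ``"laminar"`` or ``"myocyte"``. Also reports, for each
    cutoff, the fraction of voxels whose ratio is at least that value.
    """
    key = (modality.lower(), pair.lower())
    if key not in _EIGEN_PAIRS:
        raise ValidityError(f"unknown modality/pair combination {key}")
    i_small, i_large = _EIGEN_PAIRS[key]
    small = result.eigvals[..., i_small]
    large = result.eigvals[..., i_large]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(large > 0, 100.0 * small / large, np.nan)
    flat = ratio[np.isfinite(ratio)]
    return {
        "ratio": ratio,
        "summary": summarize(flat),
        "fraction_at_least": {c: float(np.mean(flat >= c)) if flat.size else np.nan
                              for c in cutoffs},
    }
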