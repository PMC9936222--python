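"""Histogram-free and histogram-based intensity features, IVH, local
intensity peaks and mesh-free morphology.

Conventions for degenerate inputs (documented rather than emitting NaN):
skewness and excess kurtosis of a zero-variance sample are 0; any ratio
with a zero denominator is 0. Moments use the population (n) denominator.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "statistical_features",
    "intensity_histogram_features",
    "intensity_volume_histogram_features",
    "local_intensity_features",
    "morphology_features",
]


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean, variance, skewness, excess kurtosis (degenerate -> 0)."""
    mu = float(np.mean(x))
    d = x - mu
    m2 = float(np.mean(d**2))
    # relative floor so constant inputs with rounding dust stay degenerate
    if m2 <= (1e-12 * max(1.0, float(np.max(np.abs(x))))) ** 2:
        return mu, 0.0, 0.0, 0.0
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return mu, m2, m3 / m2**1.5, m4 / m2**2 - 3.0


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def statistical_features(values: np.ndarray) -> dict[str, float]:
    """The 18 intensity-statistics (``stat.*``) features of an ROI."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("statistical_features requires a non-empty ROI")
    mu, var, skew, kurt = _moments(x)
    p10, med, p90 = np.percentile(x, [10, 50, 90])
    p25, p75 = np.percentile(x, [25, 75])
    mad = float(np.mean(np.abs(x - mu)))
    in_decile = x[(x >= p10) & (x <= p90)]
    rmu = float(np.mean(in_decile)) if in_decile.size else 0.0
    rmad = float(np.mean(np.abs(in_decile - rmu))) if in_decile.size else 0.0
    return {
        "stat.mean": mu,
        "stat.var": var,
        "stat.skew": skew,
        "stat.kurt": kurt,
        "stat.median": float(med),
        "stat.min": float(x.min()),
        "stat.p10": float(p10),
        "stat.p90": float(p90),
        "stat.max": float(x.max()),
        "stat.iqr": float(p75 - p25),
        "stat.range": float(x.max() - x.min()),
        "stat.mad": mad,
        "stat.rmad": rmad,
        "stat.medad": float(np.mean(np.abs(x - med))),
        "stat.cov": _safe_div(np.sqrt(var), mu),
        "stat.qcod": _safe_div(p75 - p25, p75 + p25),
        "stat.energy": float(np.sum(x**2)),
        "stat.rms": float(np.sqrt(np.mean(x**2))),
    }


def histogram_gradient(counts: np.ndarray) -> np.ndarray:
    """Central-difference gradient of histogram counts n_1..n_Ng.

    End bins use one-sided differences; a single-bin histogram has
    gradient [0].
    """
    n = np.asarray(counts, dtype=float)
    if n.size == 1:
        return np.zeros(1)
    grad = np.empty_like(n)
    grad[0] = n[1] - n[0]
    grad[-1] = n[-1] - n[-2]
    if n.size > 2:
        grad[1:-1] = (n[2:] - n[:-2]) / 2.0
    return grad


def intensity_histogram_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    """The 23 intensity-histogram (``ih.*``) features.

    Parameters
    ----------
    levels
        Discretized grey levels (integers >= 1) of the ROI voxels.
    n_levels
        Number of histogram bins Ng; defaults to the maximum occupied level.
    """
    g = np.asarray(levels, dtype=np.int64).ravel()
    if g.size == 0:
        raise ValueError("intensity_histogram_features requires non-empty input")
    ng = int(n_levels) if n_levels is not None else int(g.max())
    counts = np.bincount(g, minlength=ng + 1)[1:].astype(float)
    p = counts / g.size
    lv = np.arange(1, ng + 1, dtype=float)

    mu, var, skew, kurt = _moments(g.astype(float))
    p10, med, p90 = np.percentile(g, [10, 50, 90])
    p25, p75 = np.percentile(g, [25, 75])
    mad = float(np.mean(np.abs(g - mu)))
    in_decile = g[(g >= p10) & (g <= p90)].astype(float)
    rmu = float(np.mean(in_decile)) if in_decile.size else 0.0
    rmad = float(np.mean(np.abs(in_decile - rmu))) if in_decile.size else 0.0
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    grad = histogram_gradient(counts)
    i_max = int(np.argmax(grad))
    i_min = int(np.argmin(grad))
    return {
        "ih.mean": mu,
        "ih.var": var,
        "ih.skew": skew,
        "ih.kurt": kurt,
        "ih.median": float(med),
        "ih.min": float(g.min()),
        "ih.p10": float(p10),
        "ih.p90": float(p90),
        "ih.max": float(g.max()),
        "ih.mode": float(lv[np.argmax(counts)]),
        "ih.iqr": float(p75 - p25),
        "ih.range": float(g.max() - g.min()),
        "ih.mad": mad,
        "ih.rmad": rmad,
        "ih.medad": float(np.mean(np.abs(g - med))),
        "ih.cov": _safe_div(np.sqrt(var), mu),
        "ih.qcod": _safe_div(p75 - p25, p75 + p25),
        "ih.entropy": entropy,
        "ih.uniformity": float(np.sum(p**2)),
        "ih.max.grad": float(grad[i_max]),
        "ih.max.grad.g": float(lv[i_max]),
        "ih.min.grad": float(grad[i_min]),
        "ih.min.grad.g": float(lv[i_min]),
    }


def intensity_volume_histogram_features(values: np.ndarray) -> dict[str, float]:
    """The 7 intensity-volume-histogram (``ivh.*``) features.

    The IVH curve nu(theta) is the fraction of ROI volume with intensity
    >= theta. V_x is nu evaluated at the intensity x% up the ROI range;
    I_x is the largest observed intensity whose volume fraction is still
    >= x%. A constant ROI yields zero differences and V10 = V90 = 1.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("intensity_volume_histogram_features requires non-empty input")
    n = x.size
    vmin, vmax = x[0], x[-1]
    rng = vmax - vmin

    def volume_fraction(theta: float) -> float:
        return float((x >= theta).sum()) / n

    def intensity_at_fraction(frac: float) -> float:
        # largest intensity retaining at least `frac` of the volume
        ok = [v for v in np.unique(x) if volume_fraction(v) >= frac]
        return float(ok[-1]) if ok else float(vmin)

    v10 = volume_fraction(vmin + 0.10 * rng) if rng > 0 else 1.0
    v90 = volume_fraction(vmin + 0.90 * rng) if rng > 0 else 1.0
    i10 = intensity_at_fraction(0.10)
    i90 = intensity_at_fraction(0.90)
    auc = _safe_div(float(np.mean(x - vmin)), rng)
    return {
        "ivh.v10": v10,
        "ivh.v90": v90,
        "ivh.i10": i10,
        "ivh.i90": i90,
        "ivh.diff.v10.v90": v10 - v90,
        "ivh.diff.i10.i90": i10 - i90,
        "ivh.auc": auc,
    }


def _sphere_kernel(spacing: tuple[float, float, float], radius_mm: float) -> np.ndarray:
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    dist2 = sum(g**2 for g in grids)
    return (dist2 <= radius_mm**2).astype(float)


def local_intensity_features(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    radius_mm: float = 6.2,
) -> dict[str, float]:
    """Local and global intensity peak (``loc.*``).

    The peak is the mean intensity in a ~1 cm^3 sphere (radius 6.2 mm)
    centred on a voxel; the sphere may extend past the ROI but is clipped
    at the image boundary. Local peak: best sphere mean over the ROI
    maxima. Global peak: best sphere mean over all ROI voxels.
    """
    vol = np.asarray(volume, dtype=float)
    m = np.asarray(mask, dtype=bool)
    kernel = _sphere_kernel(spacing, radius_mm)
    num = ndimage.convolve(vol, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(vol), kernel, mode="constant", cval=0.0)
    sphere_mean = num / den
    roi_vals = vol[m]
    at_max = m & (vol == roi_vals.max())
    return {
        "loc.peak.local": float(sphere_mean[at_max].max()),
        "loc.peak.global": float(sphere_mean[m].max()),
    }


def morphology_features(
    mask: np.ndarray, spacing: tuple[float, float, float]
) -> dict[str, float]:
    """Nine mesh-free morphology (``morph.*``) features.

    Volume is voxel-counting volume; surface area is the summed area of
    exposed voxel faces. Compactness, sphericity and their variants
    follow the usual volume/area combinations; the maximum 3D diameter
    is the largest centre-to-centre distance between surface voxels.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("morphology_features requires a non-empty mask")
    sx, sy, sz = (float(s) for s in spacing)
    voxel_vol = sx * sy * sz
    volume = float(m.sum()) * voxel_vol

    padded = np.pad(m, 1)
    face_areas = (sy * sz, sx * sz, sx * sy)
    area = 0.0
    for axis, fa in enumerate(face_areas):
        d = np.diff(padded.astype(np.int8), axis=axis)
        area += float(np.abs(d).sum()) * fa

    eroded = ndimage.binary_erosion(padded, structure=ndimage.generate_binary_structure(3, 1))
    surface = padded & ~eroded
    coords = np.argwhere(surface).astype(float) * np.array([sx, sy, sz])
    if coords.shape[0] == 1:
        diam = 0.0
    else:
        from scipy.spatial.distance import pdist

        diam = float(pdist(coords).max())

    sph_num = (36.0 * np.pi * volume**2) ** (1.0 / 3.0)
    return {
        "morph.vol.approx": volume,
        "morph.area.approx": area,
        "morph.av": _safe_div(area, volume),
        "morph.comp.1": _safe_div(volume, np.sqrt(np.pi) * area**1.5),
        "morph.comp.2": _safe_div(36.0 * np.pi * volume**2, area**3),
        "morph.sph.dispr": _safe_div(area, sph_num),
        "morph.sphericity": _safe_div(sph_num, area),
        "morph.asphericity": _safe_div(area, sph_num) - 1.0 if sph_num > 0 else 0.0,
        "morph.diam": diam,
    }
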